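"""Neutral forward drift simulations and the allele-frequency trajectory test.

Two drift models are provided: a plain haploid Wright-Fisher binomial chain,
and a sex-structured chain that tracks copy counts separately among male and
female reproducers with four binomial transmission draws per generation.
The trajectory test reports the Monte-Carlo probability that pure drift moves
an allele at least as far from its starting frequency as observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "SexStructuredCounts",
    "TrajectoryTest",
    "wf_step",
    "sexed_step",
    "simulate_wf_trajectories",
    "simulate_sexed_trajectories",
    "trajectory_pvalue",
    "exact_trajectory_pvalue_g1",
    "two_line_pvalue",
]


@dataclass
class SexStructuredCounts:
    """Numbers of reproducing males and females per generation (index 0 = start)."""

    males: Sequence[int]
    females: Sequence[int]

    def __post_init__(self):
        self.males = [int(m) for m in self.males]
        self.females = [int(f) for f in self.females]
        if len(self.males) != len(self.females):
            raise ValueError("male and female count lists must have equal length")
        if any(m < 1 for m in self.males) or any(f < 1 for f in self.females):
            raise ValueError("all reproducer counts must be >= 1")

    @property
    def generations(self) -> int:
        return len(self.males) - 1


@dataclass
class TrajectoryTest:
    """Result container for per-line trajectory tests on one SNP."""

    p0: float
    pf_minus: float
    pf_plus: float
    g: int
    p_minus: float
    p_plus: float
    se_minus: float
    se_plus: float

    @property
    def combined(self) -> float:
        return two_line_pvalue(self.p_minus, self.p_plus)


def wf_step(x: int, N: int, rng: np.random.Generator):
    """One haploid Wright-Fisher generation: Binomial(N, x/N) copies."""
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x > N):
        raise ValueError(f"copy count outside [0, {N}]")
    return rng.binomial(N, x / N)


def sexed_step(xm, xf, nm_g: int, nf_g: int, nm_next: int, nf_next: int,
               rng: np.random.Generator):
    """One generation of the sex-structured drift model.

    ``xm``/``xf`` are copy counts among the ``2*nm_g`` male and ``2*nf_g``
    female alleles. Returns the counts at the next generation, formed by four
    binomial draws: sons inherit Binomial(nm_next, xm/2nm_g) copies from sires
    plus Binomial(nm_next, xf/2nf_g) from dams, and symmetrically for
    daughters.
    """
    if min(nm_g, nf_g, nm_next, nf_next) < 1:
        raise ValueError("reproducer counts must be >= 1")
    xm = np.asarray(xm)
    xf = np.asarray(xf)
    if np.any(xm < 0) or np.any(xm > 2 * nm_g) or np.any(xf < 0) or np.any(xf > 2 * nf_g):
        raise ValueError("copy counts outside the allele-count range")
    pm = xm / (2.0 * nm_g)
    pf = xf / (2.0 * nf_g)
    xmm = rng.binomial(nm_next, pm)
    xmf = rng.binomial(nm_next, pf)
    xfm = rng.binomial(nf_next, pm)
    xff = rng.binomial(nf_next, pf)
    return xmm + xmf, xfm + xff


def _snap_count(p0: float, n_alleles: int, what: str) -> int:
    x0 = p0 * n_alleles
    snapped = int(round(x0))
    if abs(x0 - snapped) > 1e-9:
        warnings.warn(
            f"{what}: p0={p0} is off the {n_alleles}-allele grid; "
            f"snapped to {snapped}/{n_alleles}"
        )
    return snapped


def simulate_wf_trajectories(p0: float, g: int, N: int, n_sims: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Final allele frequencies of ``n_sims`` haploid WF chains of length ``g``."""
    x = np.full(n_sims, _snap_count(p0, N, "wright-fisher"), dtype=np.int64)
    for _ in range(g):
        x = rng.binomial(N, x / N)
    return x / N


def simulate_sexed_trajectories(p0: float, counts: SexStructuredCounts, n_sims: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Final pooled allele frequencies under the sex-structured model."""
    nm0, nf0 = counts.males[0], counts.females[0]
    xm = np.full(n_sims, _snap_count(p0, 2 * nm0, "sex-structured males"), dtype=np.int64)
    xf = np.full(n_sims, _snap_count(p0, 2 * nf0, "sex-structured females"), dtype=np.int64)
    for gi in range(counts.generations):
        xm, xf = sexed_step(xm, xf, counts.males[gi], counts.females[gi],
                            counts.males[gi + 1], counts.females[gi + 1], rng)
    tot = 2 * (counts.males[-1] + counts.females[-1])
    return (xm + xf) / tot


def trajectory_pvalue(p0: float, pf: float, g: int, model: str = "wright-fisher",
                      N: int | None = None, counts: SexStructuredCounts | None = None,
                      n_sims: int = 100_000, seed: int | None = None):
    """Monte-Carlo probability that drift alone moves p0 at least as far as pf.

    Simulates ``n_sims`` neutral trajectories of ``g`` generations from ``p0``
    and returns the proportion with ``(pj - p0)**2 >= (pf - p0)**2``, together
    with its binomial standard error.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not (0.0 <= p0 <= 1.0 and 0.0 <= pf <= 1.0):
        raise ValueError("frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    if model == "wright-fisher":
        if N is None:
            raise ValueError("wright-fisher model needs the haploid size N")
        pj = simulate_wf_trajectories(p0, g, N, n_sims, rng)
    elif model == "sex-structured":
        if counts is None:
            raise ValueError("sex-structured model needs SexStructuredCounts")
        if counts.generations != g:
            raise ValueError(f"counts cover {counts.generations} generations, expected {g}")
        pj = simulate_sexed_trajectories(p0, counts, n_sims, rng)
    else:
        raise ValueError(f"unknown model {model!r}")
    hits = (pj - p0) ** 2 >= (pf - p0) ** 2
    phat = hits.mean()
    se = float(np.sqrt(phat * (1.0 - phat) / n_sims))
    return float(phat), se


def exact_trajectory_pvalue_g1(p0: float, pf: float, N: int) -> float:
    """Exact one-generation trajectory p-value by binomial enumeration (oracle)."""
    x0 = _snap_count(p0, N, "exact enumeration")
    p0g = x0 / N
    thresh = (pf - p0) ** 2
    total = 0.0
    for x in range(N + 1):
        if ((x / N) - p0) ** 2 >= thresh:
            total += comb(N, x) * p0g ** x * (1 - p0g) ** (N - x)
    return total


def two_line_pvalue(p_minus: float, p_plus: float) -> float:
    """Combined evidence across the two lines: the product of per-line values."""
    for p in (p_minus, p_plus):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0,1]")
    return p_minus * p_plus
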