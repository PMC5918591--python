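"""Population tree and drift-kinship estimation from genome-wide Reynolds distances.

The kinship matrix ``F`` summarizes the drift each population accumulated since
the common ancestral population: ``F[i][j]`` is the length of the tree path
shared by the root-to-``i`` and root-to-``j`` paths, with the root placed on
the outgroup's pendant branch and the outgroup itself treated as the (drift
free) ancestral reference.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

__all__ = [
    "DistanceMatrix",
    "PopulationKinship",
    "reynolds_distances",
    "build_kinship",
    "ne_from_inbreeding",
    "inbreeding_from_ne",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Reynolds distances between population labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a, b) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class PopulationKinship:
    """Rooted population tree plus the drift kinship matrix it implies.

    ``populations`` lists labels with the outgroup first; ``F`` is indexed the
    same way. ``F`` rows/columns for the outgroup are identically zero.
    """

    populations: list
    F: np.ndarray
    newick: str

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        n = len(self.populations)
        if self.F.shape != (n, n):
            raise ValueError("F shape does not match populations")

    @property
    def outgroup(self):
        return self.populations[0]

    @property
    def inbreeding(self) -> dict:
        return {p: float(self.F[i, i]) for i, p in enumerate(self.populations)}

    def selected_submatrix(self, pops=None) -> tuple[list, np.ndarray]:
        """F restricted to the non-outgroup populations (or an explicit list)."""
        pops = pops if pops is not None else self.populations[1:]
        idx = [self.populations.index(p) for p in pops]
        return list(pops), self.F[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.F, index=self.populations, columns=self.populations) \
            .to_csv(path, sep="\t")


def reynolds_distances(freqs) -> DistanceMatrix:
    """Reynolds-Weir-Cockerham coancestry distance between every population pair.

    Per-locus numerator/denominator are the 1983 estimators for biallelic loci
    (sample sizes = observed diploid counts), combined as a ratio of sums over
    loci. Loci monomorphic and identical in both populations of a pair
    contribute nothing.

    The coancestry ratio is doubled so distances are additive in drift units:
    under pure drift E[numerator] = p0 q0 (F_i + F_j) while
    E[denominator] = 2 p0 q0, so twice the ratio estimates F_i + F_j -- the
    scale on which tree branch lengths read directly as drift coefficients.
    """
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    P = freqs.frequencies[pops].to_numpy(dtype=float)
    N = freqs.allele_counts[pops].to_numpy(dtype=float) / 2.0  # diploid counts
    k = len(pops)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = P[:, i], P[:, j]
            n1, n2 = N[:, i], N[:, j]
            ok = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 >= 1) & (n2 >= 1)
            p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
            al1 = 2.0 * p1 * (1.0 - p1)
            al2 = 2.0 * p2 * (1.0 - p2)
            sq = (p1 - p2) ** 2
            corr = (n1 + n2) * (n1 * al1 + n2 * al2) / (4.0 * n1 * n2 * (n1 + n2 - 1.0))
            a = sq - corr
            ab = sq + (4.0 * n1 * n2 - n1 - n2) * (n1 * al1 + n2 * al2) \
                / (4.0 * n1 * n2 * (n1 + n2 - 1.0))
            keep = ab > 0  # skip loci with no variation in either population
            denom = ab[keep].sum()
            theta = a[keep].sum() / denom if denom > 0 else 0.0
            D[i, j] = D[j, i] = max(2.0 * theta, 0.0)
    return DistanceMatrix(labels=list(pops), values=D)


def build_kinship(dist: DistanceMatrix, outgroup) -> PopulationKinship:
    """Neighbour-joining tree rooted on the outgroup branch, summarized as ``F``.

    The root sits at the midpoint of the outgroup's terminal branch; shared
    drift of populations i, j is the root-to-MRCA path length, computed from
    tip-to-tip distances on the (negative-length clamped) NJ tree. The
    outgroup's own drift is defined as 0.
    """
    if outgroup not in dist.labels:
        raise ValueError(f"outgroup {outgroup!r} not among populations")
    others = [p for p in dist.labels if p != outgroup]
    order = [outgroup] + others
    n = len(order)
    if n < 2:
        raise ValueError("need the outgroup plus at least one population")

    if n == 2:
        d = dist.get(outgroup, others[0])
        F = np.array([[0.0, 0.0], [0.0, d]])
        newick = f"({outgroup}:0,{others[0]}:{d});"
        return PopulationKinship(order, F, newick)

    ids = [str(p) for p in dist.labels]
    tree = _skbio_nj(_SkbioDM(dist.values, ids))
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative NJ branch length(s) to 0")

    tipdist = tree.tip_tip_distances(list(map(str, order)))
    d = np.asarray(tipdist.data)
    # reorder to `order`
    perm = [list(tipdist.ids).index(str(p)) for p in order]
    d = d[np.ix_(perm, perm)]
    l_out = float(tree.find(str(outgroup)).length or 0.0)
    half = l_out / 2.0
    F = np.zeros((n, n))
    for i in range(1, n):
        F[i, i] = d[0, i] - half
        for j in range(i + 1, n):
            F[i, j] = F[j, i] = (d[0, i] + d[0, j] - d[i, j]) / 2.0 - half
    F = np.clip(F, 0.0, None)
    buf = io.StringIO()
    tree.write(buf)
    return PopulationKinship(order, F, buf.getvalue().strip())


def ne_from_inbreeding(F: float, g: int) -> float:
    """Diploid effective size N solving ``F = 1 - (1 - 1/(2N))**g``.

    ``F <= 0`` signals no detectable drift and returns ``inf``; ``F >= 1``
    is unattainable in finite populations and raises.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if F >= 1.0:
        raise ValueError("inbreeding coefficient must be < 1")
    if F <= 0.0:
        return float("inf")
    return 1.0 / (2.0 * (1.0 - (1.0 - F) ** (1.0 / g)))


def inbreeding_from_ne(N: float, g: int) -> float:
    """Forward evaluation ``F = 1 - (1 - 1/(2N))**g`` for N diploid reproducers."""
    if N <= 0:
        raise ValueError("N must be positive")
    if g < 1:
        raise ValueError("g must be >= 1")
    return 1.0 - (1.0 - 1.0 / (2.0 * N)) ** g
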