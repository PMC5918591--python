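"""Single-SNP FLK scan against the drift-kinship null.

The statistic contrasts per-line allele frequencies with the ancestral
(outgroup) frequency through the quadratic form
``(p - p0 1)' V^-1 (p - p0 1)`` with ``V = p0 (1 - p0) F``; under neutral
drift it is chi-squared with one degree of freedom per selected line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import PopulationKinship
from .regions import GenomicRegion, merge_positions

__all__ = [
    "ScanResult",
    "flk_statistic",
    "flk_scan",
    "compute_qvalues",
    "build_flk_regions",
]

_P0_EPS = 1e-6


@dataclass
class ScanResult:
    """Per-SNP scan table (snp, chrom, bp, stat, p_value, q_value) plus metadata."""

    table: pd.DataFrame
    method: str = "flk"
    generation: int | None = None
    populations: list = field(default_factory=list)

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] <= q_threshold]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _null_precision(kinship: PopulationKinship, pops) -> np.ndarray:
    _, F = kinship.selected_submatrix(pops)
    # guard near-singular drift matrices with a pseudo-inverse
    cond = np.linalg.cond(F) if np.all(np.isfinite(F)) else np.inf
    if not np.isfinite(cond) or cond > 1e12:
        return np.linalg.pinv(F)
    return np.linalg.inv(F)


def flk_statistic(p: np.ndarray, p0: float, kinship: PopulationKinship,
                  pops=None) -> float:
    """FLK quadratic form for one SNP; NaN when p0 is (numerically) fixed."""
    p = np.asarray(p, dtype=float)
    if p0 < _P0_EPS or p0 > 1.0 - _P0_EPS:
        return float("nan")
    Finv = _null_precision(kinship, pops)
    d = p - p0
    return float(d @ Finv @ d / (p0 * (1.0 - p0)))


def flk_scan(freqs, kinship: PopulationKinship, df: int | None = None,
             generation: int | None = None) -> ScanResult:
    """Genome scan: FLK statistic and chi-squared(df) upper-tail p-value per SNP.

    The outgroup column of ``freqs`` supplies p0; all remaining populations in
    the kinship are the selected lines. SNPs with a fixed p0 or a missing line
    frequency get NaN statistic/p-value and are excluded from q-values.
    """
    lines = kinship.populations[1:]
    if df is None:
        df = len(lines)
    if df < 1:
        raise ValueError("df must be >= 1")
    for pop in kinship.populations:
        if pop not in freqs.frequencies.columns:
            raise ValueError(f"population {pop!r} absent from frequency set")
    p0 = freqs.frequencies[kinship.populations[0]].to_numpy(dtype=float)
    P = freqs.frequencies[lines].to_numpy(dtype=float)
    Finv = _null_precision(kinship, lines)
    D = P - p0[:, None]
    stat = np.einsum("si,ij,sj->s", D, Finv, D) / (p0 * (1.0 - p0))
    bad = (p0 < _P0_EPS) | (p0 > 1.0 - _P0_EPS) | np.isnan(P).any(axis=1) | np.isnan(p0)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"skipped {n_bad} SNP(s) with fixed p0 or missing line frequency")
    stat = np.where(bad, np.nan, stat)
    pval = stats.chi2.sf(stat, df)
    table = pd.DataFrame({
        "snp": freqs.frequencies.index,
        "chrom": freqs.snp_map["chrom"].to_numpy() if freqs.snp_map is not None else "NA",
        "bp": freqs.snp_map["bp"].to_numpy() if freqs.snp_map is not None else -1,
        "stat": stat,
        "p_value": pval,
    }).reset_index(drop=True)
    q = np.full(len(table), np.nan)
    ok = ~np.isnan(pval)
    q[ok] = compute_qvalues(pval[ok])
    table["q_value"] = q
    return ScanResult(table=table, method="flk", generation=generation,
                      populations=list(kinship.populations))


def compute_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """Storey q-values with a plain Benjamini-Hochberg fallback.

    pi0 is estimated at lambda = 0.5; when fewer than 100 p-values are supplied
    or the estimate leaves (0, 1], pi0 = 1 (exact BH). Output preserves input
    order and is monotone in p-value rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    n = p.size
    pi0 = 1.0
    if method == "storey" and n >= 100:
        lam = 0.5
        est = (p > lam).sum() / (n * (1.0 - lam))
        if 0.0 < est <= 1.0:
            pi0 = est
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def build_flk_regions(scan: ScanResult, q_threshold: float = 0.05,
                      merge_distance: int = 1_000_000,
                      exclude: list[GenomicRegion] | None = None) -> list[GenomicRegion]:
    """Merge significant FLK SNPs into regions, skipping SNPs inside ``exclude``.

    Significant SNPs (q <= threshold) on the same chromosome closer than
    ``merge_distance`` join one region; isolated significant SNPs form 1-SNP
    regions.
    """
    sig = scan.significant(q_threshold)
    if exclude:
        keep = [not any(r.contains(row["chrom"], row["bp"]) for r in exclude)
                for _, row in sig.iterrows()]
        sig = sig[np.asarray(keep, dtype=bool)] if len(sig) else sig
    if sig.empty:
        return []
    score = -np.log10(np.maximum(sig["p_value"].to_numpy(), 1e-300))
    return merge_positions(sig["chrom"], sig["bp"].astype(int), score,
                           sig["snp"], merge_distance, generation=scan.generation)
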