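"""Haplotype-based hapFLK scan.

The FLK quadratic form is applied to every haplotype-cluster frequency vector
and summed over clusters; because no chi-squared null is available for this
sum, p-values come from a normal null whose location/scale are estimated by
robust regression of the genome-wide order statistics on standard normal
quantiles (the selected upper tail is excluded from the fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .flkscan import ScanResult, compute_qvalues
from .hapcluster import ClusterFrequencies
from .kinship import PopulationKinship
from .regions import GenomicRegion, merge_positions

__all__ = [
    "NullFit",
    "hapflk_statistic",
    "hapflk_statistics",
    "fit_null_normal",
    "hapflk_scan",
    "merge_generation_regions",
]

_CLUSTER_EPS = 1e-9


@dataclass
class NullFit:
    """Location/scale of the fitted normal null for hapFLK values."""

    location: float
    scale: float

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"degenerate null scale {self.scale}")

    def pvalue(self, x) -> np.ndarray:
        return stats.norm.sf((np.asarray(x, dtype=float) - self.location) / self.scale)


def hapflk_statistic(cluster_freqs: np.ndarray, p0_clusters: np.ndarray,
                     kinship: PopulationKinship, pops=None) -> float:
    """hapFLK at one locus: FLK quadratic form summed over clusters.

    ``cluster_freqs`` has shape (n_selected_pops, K); ``p0_clusters`` (K,) are
    the outgroup cluster frequencies. Clusters carried by nobody (outgroup
    frequency ~0 and absent from every population) drop out of the sum.
    """
    P = np.asarray(cluster_freqs, dtype=float)
    p0 = np.asarray(p0_clusters, dtype=float)
    _, F = kinship.selected_submatrix(pops)
    Finv = np.linalg.pinv(F)
    total = 0.0
    for k in range(p0.size):
        if p0[k] < _CLUSTER_EPS and P[:, k].max(initial=0.0) < _CLUSTER_EPS:
            continue
        v = p0[k] * (1.0 - p0[k])
        if v < _CLUSTER_EPS:
            continue
        d = P[:, k] - p0[k]
        total += float(d @ Finv @ d / v)
    return total


def hapflk_statistics(freqs: ClusterFrequencies, kinship: PopulationKinship) -> np.ndarray:
    """Per-locus hapFLK averaged over EM runs.

    The outgroup population of ``kinship`` must be present in ``freqs``; the
    remaining kinship populations are the selected lines.
    """
    outgroup = kinship.populations[0]
    lines = kinship.populations[1:]
    for pop in kinship.populations:
        if pop not in freqs.populations:
            raise ValueError(f"population {pop!r} missing from cluster frequencies")
    oi = freqs.populations.index(outgroup)
    li = [freqs.populations.index(p) for p in lines]
    n_runs, _, L, _ = freqs.freqs.shape
    out = np.zeros(L)
    for r in range(n_runs):
        for l in range(L):
            out[l] += hapflk_statistic(freqs.freqs[r][li, l, :],
                                       freqs.freqs[r][oi, l, :], kinship)
    return out / n_runs


def fit_null_normal(values, lower: float = 0.05, upper: float = 0.80) -> NullFit:
    """Robust normal null from genome-wide hapFLK values.

    Order statistics between the ``lower`` and ``upper`` empirical quantiles
    are regressed on standard normal quantiles with a Huber-robust linear fit;
    intercept and slope give location and scale. The window is asymmetric
    because selection contaminates the upper tail specifically: excluding the
    top 20% keeps the fit stable under a few percent of inflated values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 100:
        raise ValueError("need at least 100 genome-wide values to fit the null")
    if np.ptp(x) < 1e-12:
        raise ValueError("near-constant input: null scale degenerate")
    n = x.size
    lo = int(np.floor(n * lower))
    hi = int(np.ceil(n * upper))
    idx = np.arange(lo, hi)
    qn = stats.norm.ppf((idx + 0.5) / n)
    fit = sm.RLM(x[idx], sm.add_constant(qn), M=sm.robust.norms.HuberT()).fit()
    loc, scale = float(fit.params[0]), float(fit.params[1])
    return NullFit(location=loc, scale=scale)


def hapflk_scan(freqs: ClusterFrequencies, kinship: PopulationKinship,
                q_threshold: float = 0.05, merge_distance: int = 1_000_000,
                generation: int | None = None):
    """Full hapFLK scan: statistics, normal-null p-values, q-values and regions.

    Returns ``(ScanResult, regions)``; significant loci (q <= threshold) closer
    than ``merge_distance`` merge into one region.
    """
    stat = hapflk_statistics(freqs, kinship)
    null = fit_null_normal(stat)
    pval = null.pvalue(stat)
    qval = compute_qvalues(pval)
    table = pd.DataFrame({
        "snp": freqs.snp_map["snp"].to_numpy(),
        "chrom": freqs.snp_map["chrom"].to_numpy(),
        "bp": freqs.snp_map["bp"].to_numpy(),
        "stat": stat,
        "p_value": pval,
        "q_value": qval,
    })
    scan = ScanResult(table=table, method="hapflk", generation=generation,
                      populations=list(kinship.populations))
    sig = scan.significant(q_threshold)
    if sig.empty:
        return scan, []
    score = -np.log10(np.maximum(sig["p_value"].to_numpy(), 1e-300))
    regions = merge_positions(sig["chrom"], sig["bp"].astype(int), score,
                              sig["snp"], merge_distance, generation=generation)
    return scan, regions


def _gap_has_no_snp(chrom, lo: int, hi: int, snp_map: pd.DataFrame | None) -> bool:
    if snp_map is None:
        return False
    sel = (snp_map["chrom"].astype(str) == str(chrom)) \
        & (snp_map["bp"] > lo) & (snp_map["bp"] < hi)
    return not bool(sel.any())


def merge_generation_regions(per_generation_regions,
                             snp_map: pd.DataFrame | None = None) -> list[GenomicRegion]:
    """Union regions detected at different generations.

    Regions on one chromosome merge when they overlap, abut, or are separated
    by a gap containing no genotyped SNP (requires ``snp_map``). The merged
    region carries the sorted union of detection generations and the best
    (maximum) peak score.
    """
    flat = [r for regs in per_generation_regions for r in regs]
    if not flat:
        return []
    flat.sort(key=lambda r: (str(r.chrom), r.start, r.end))
    merged: list[GenomicRegion] = []
    for r in flat:
        if merged:
            last = merged[-1]
            same = str(last.chrom) == str(r.chrom)
            joinable = same and (
                r.start <= last.end + 1
                or _gap_has_no_snp(r.chrom, last.end, r.start, snp_map)
            )
            if joinable:
                better = (r.peak_score or -np.inf) > (last.peak_score or -np.inf)
                merged[-1] = GenomicRegion(
                    chrom=last.chrom,
                    start=last.start,
                    end=max(last.end, r.end),
                    peak_snp=r.peak_snp if better else last.peak_snp,
                    peak_score=max(filter(lambda v: v is not None,
                                          (r.peak_score, last.peak_score)),
                                   default=None),
                    generations=tuple(sorted(set(last.generations) | set(r.generations))),
                    n_snps=last.n_snps + r.n_snps,
                )
                continue
        merged.append(r)
    return merged
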