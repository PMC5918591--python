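"""Post-hoc summaries: pairwise LD, region-wise LD averages, QTL/selection
region intersection, and the Bayes-factor enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeTable
from .regions import GenomicRegion

__all__ = [
    "LdPairTable",
    "ld_r2",
    "region_mean_r2",
    "enrichment_test",
    "intersect_regions",
]


@dataclass
class LdPairTable:
    """Per-pair LD records: snp_a, snp_b, chrom, bp_a, bp_b, distance, r2."""

    table: pd.DataFrame
    max_distance: int

    def __post_init__(self):
        r2 = self.table["r2"]
        if len(r2) and ((r2 < -1e-9) | (r2 > 1 + 1e-9)).any():
            raise ValueError("r2 outside [0,1]")


def ld_r2(gt: GenotypeTable, max_distance: int = 500_000,
          maf_min: float = 0.1) -> LdPairTable:
    """Composite LD: squared dosage correlation for same-chromosome SNP pairs.

    Pairs must be closer than ``max_distance`` bp (strict) and both SNPs must
    have MAF strictly above ``maf_min``. Zero-variance SNPs are skipped.
    """
    maf = gt.maf()
    keep = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > maf_min)
    rows = []
    snp_map = gt.snp_map
    for chrom, grp in snp_map.iloc[keep].groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        snps = grp["snp"].to_numpy()
        D = gt.dosages[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(D, axis=0)
        for a in range(len(idx)):
            if var[a] <= 0:
                continue
            for b in range(a + 1, len(idx)):
                dist = int(bp[b] - bp[a])
                if dist >= max_distance:
                    break
                if var[b] <= 0:
                    continue
                xa, xb = D[:, a], D[:, b]
                ok = ~(np.isnan(xa) | np.isnan(xb))
                if ok.sum() < 3:
                    continue
                r = np.corrcoef(xa[ok], xb[ok])[0, 1]
                if np.isnan(r):
                    continue
                rows.append((snps[a], snps[b], str(chrom), int(bp[a]), int(bp[b]),
                             dist, float(r * r)))
    table = pd.DataFrame(rows, columns=["snp_a", "snp_b", "chrom", "bp_a",
                                        "bp_b", "distance", "r2"])
    return LdPairTable(table=table, max_distance=max_distance)


def region_mean_r2(pairs: LdPairTable, categories: dict) -> pd.DataFrame:
    """Mean/SD of r2 per region category.

    ``categories`` maps a category name to a list of :class:`GenomicRegion`;
    a pair belongs to a category when both of its SNPs fall inside one of the
    category's regions. Besides the pooled across-pair SD, the across-region
    SD of per-region means is reported. Empty categories get NaN.
    """
    t = pairs.table
    rows = []
    for name, regions in categories.items():
        vals = []
        per_region_means = []
        for reg in regions:
            inside = t[(t["chrom"].astype(str) == str(reg.chrom))
                       & (t["bp_a"] >= reg.start) & (t["bp_a"] <= reg.end)
                       & (t["bp_b"] >= reg.start) & (t["bp_b"] <= reg.end)]
            if len(inside):
                vals.append(inside["r2"].to_numpy())
                per_region_means.append(float(inside["r2"].mean()))
        if vals:
            pooled = np.concatenate(vals)
            rows.append((name, len(pooled), float(pooled.mean()),
                         float(pooled.std(ddof=1)) if len(pooled) > 1 else np.nan,
                         float(np.std(per_region_means, ddof=1))
                         if len(per_region_means) > 1 else np.nan))
        else:
            rows.append((name, 0, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["category", "n_pairs", "mean_r2",
                                      "sd_pairs", "sd_region_means"])
    genome = t["r2"].to_numpy()
    out.loc[len(out)] = ("genome-wide", len(genome),
                         float(genome.mean()) if len(genome) else np.nan,
                         float(genome.std(ddof=1)) if len(genome) > 1 else np.nan,
                         np.nan)
    return out


def enrichment_test(bf_inside, bf_outside):
    """Two-sided Welch t-test comparing Bayes factors inside vs outside regions."""
    a = np.asarray(bf_inside, dtype=float)
    b = np.asarray(bf_outside, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.array_equal(np.sort(a)[:1], np.sort(b)[:1]) or a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def intersect_regions(qtl: list[GenomicRegion],
                      signatures: list[GenomicRegion]) -> dict:
    """Map each QTL region to names of overlapping selection signatures.

    Any bp overlap (closed intervals, touching endpoints included) counts; a
    QTL with no overlap maps to ``"-"``.
    """
    out = {}
    for i, q in enumerate(qtl):
        qname = q.name or f"qtl-{i + 1}"
        hits = [s.name or f"signature-{j + 1}"
                for j, s in enumerate(signatures) if q.overlaps(s)]
        out[qname] = hits if hits else "-"
    return out
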