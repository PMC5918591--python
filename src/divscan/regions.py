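"""Genomic interval helpers shared by every scan module.

Coordinates are 1-based, closed on both ends (the convention of the report
tables); touching endpoints count as overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["GenomicRegion", "merge_positions", "regions_to_frame",
           "regions_to_bed"]


@dataclass(frozen=True)
class GenomicRegion:
    """Chromosome interval with the peak SNP of the signal it summarizes."""

    chrom: str
    start: int
    end: int
    peak_snp: str | None = None
    peak_score: float | None = None
    generations: tuple = ()
    name: str | None = None
    n_snps: int = 0

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (str(self.chrom) == str(other.chrom)
                and self.start <= other.end and other.start <= self.end)

    def contains(self, chrom, bp: int) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= bp <= self.end


def merge_positions(chroms: Sequence, bps: Sequence[int], scores: Sequence[float],
                    snps: Sequence[str], merge_distance: int,
                    generation=None) -> list[GenomicRegion]:
    """Merge significant SNP positions into regions.

    Consecutive SNPs on the same chromosome closer than ``merge_distance``
    (strict) join one region; higher ``scores`` win the peak. Input order is
    irrelevant (positions are sorted internally).
    """
    df = pd.DataFrame({"chrom": list(map(str, chroms)), "bp": bps,
                       "score": scores, "snp": snps})
    df = df.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)
    gens = (int(generation),) if generation is not None else ()
    out: list[GenomicRegion] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cur = None
        for _, row in grp.iterrows():
            if cur is not None and row["bp"] - cur["end"] < merge_distance:
                cur["end"] = int(row["bp"])
                cur["n"] += 1
                if row["score"] > cur["score"]:
                    cur["score"], cur["snp"] = float(row["score"]), row["snp"]
            else:
                if cur is not None:
                    out.append(GenomicRegion(chrom, cur["start"], cur["end"],
                                             cur["snp"], cur["score"], gens,
                                             n_snps=cur["n"]))
                cur = {"start": int(row["bp"]), "end": int(row["bp"]),
                       "score": float(row["score"]), "snp": row["snp"], "n": 1}
        if cur is not None:
            out.append(GenomicRegion(chrom, cur["start"], cur["end"],
                                     cur["snp"], cur["score"], gens, n_snps=cur["n"]))
    return out


def regions_to_frame(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    """Flatten regions into the report-table schema (length in Mb, generation list)."""
    rows = []
    for i, r in enumerate(regions, start=1):
        rows.append({
            "name": r.name or f"region-{i}",
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "length_mb": round((r.end - r.start + 1) / 1e6, 3),
            "peak_snp": r.peak_snp,
            "peak_score": r.peak_score,
            "n_snps": r.n_snps,
            "generations": ",".join(map(str, r.generations)),
        })
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "length_mb",
                                       "peak_snp", "peak_score", "n_snps", "generations"])


def regions_to_bed(regions: Iterable[GenomicRegion], path) -> None:
    """Write regions as true BED (0-based, half-open) with name and score columns."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            name = r.name or f"region-{i}"
            score = 0 if r.peak_score is None else min(1000, int(round(r.peak_score)))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{score}\n")
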