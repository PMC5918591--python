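"""Genotype/phenotype I/O, chip-style QC filters and per-population allele frequencies.

The central exchange object is :class:`GenotypeTable`: an individuals x SNPs
dosage matrix (counted-allele copies 0/1/2, ``NaN`` for missing) together with
a SNP map (chromosome, 1-based bp) and per-individual metadata (line label,
generation index, sex, hatch).

Supported on-disk formats:

* ``plink-text`` -- .ped/.map pairs,
* ``plink-binary`` -- .bed/.bim/.fam triplets (SNP-major v1.00),
* ``tsv`` -- a plain-text trio ``<prefix>.geno.tsv`` / ``.snps.tsv`` / ``.inds.tsv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "AlleleFrequencySet",
    "GenotypeParseError",
    "EmptyPanelWarning",
    "read_genotypes",
    "write_genotypes",
    "filter_genotypes",
    "allele_frequencies",
    "read_phenotypes",
]

SNP_COLUMNS = ["snp", "chrom", "bp", "a1", "a2"]
IND_COLUMNS = ["id", "line", "generation", "sex", "hatch"]


class GenotypeParseError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


class EmptyPanelWarning(UserWarning):
    """Raised when QC removes every SNP (or every individual)."""


@dataclass
class GenotypeTable:
    """Dosage matrix plus SNP map and individual metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        Counted-allele copy numbers in {0, 1, 2}; ``NaN`` encodes missing.
    snp_map : DataFrame
        Columns ``snp, chrom, bp, a1, a2``; bp strictly increasing per chromosome.
    individuals : DataFrame
        Columns ``id, line, generation, sex, hatch``.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_ind, n_snp = self.dosages.shape
        if len(self.snp_map) != n_snp:
            raise GenotypeParseError(
                f"SNP map has {len(self.snp_map)} rows but dosage matrix has {n_snp} columns"
            )
        if len(self.individuals) != n_ind:
            raise GenotypeParseError(
                f"individual table has {len(self.individuals)} rows but dosage matrix has {n_ind}"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise GenotypeParseError(f"dosage value {bad!r} outside {{0,1,2,missing}}")
        if self.snp_map["snp"].duplicated().any():
            raise GenotypeParseError("duplicate SNP ids")
        if self.individuals["id"].duplicated().any():
            raise GenotypeParseError("duplicate individual ids")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise GenotypeParseError(
                    f"bp positions not strictly increasing on chromosome {chrom}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, ind_idx=None, snp_idx=None) -> "GenotypeTable":
        """Return a new table restricted to the given positional indices (order kept)."""
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeTable(
            dosages=self.dosages[np.ix_(ind_idx, snp_idx)],
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            individuals=self.individuals.iloc[ind_idx].reset_index(drop=True),
        )

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls (NaN if no calls)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)


@dataclass
class AlleleFrequencySet:
    """Per-SNP, per-population counted-allele frequencies and observed allele counts.

    ``frequencies``/``allele_counts`` are DataFrames indexed by SNP id with one
    column per population; a frequency is NaN when the population has no
    non-missing call at the SNP.
    """

    frequencies: pd.DataFrame
    allele_counts: pd.DataFrame
    snp_map: pd.DataFrame = field(default=None)

    @property
    def populations(self) -> list:
        return list(self.frequencies.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise GenotypeParseError(f"{path}:{lineno}: expected 3-4 columns, got {len(parts)}")
        chrom, snp = parts[0], parts[1]
        try:
            bp = int(parts[-1])
        except ValueError as exc:
            raise GenotypeParseError(f"{path}:{lineno}: bad bp position {parts[-1]!r}") from exc
        rows.append((snp, chrom, bp, "A", "B"))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_ped(path: Path, n_snp: int, counted_alleles: Sequence[str] | None):
    inds, genos = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snp:
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {6 + 2 * n_snp} fields for {n_snp} SNPs, got {len(parts)}"
            )
        fid, iid, _, _, sex, pheno = parts[:6]
        inds.append((iid, fid, 0, int(sex) if sex in ("0", "1", "2") else 0, "0"))
        genos.append(parts[6:])
    alleles = np.array(genos, dtype="U8").reshape(len(genos), n_snp, 2) if genos else np.empty((0, n_snp, 2), dtype="U8")
    dosages = np.full((len(genos), n_snp), np.nan)
    counted = []
    for j in range(n_snp):
        col = alleles[:, j, :]
        seen = set(col.ravel().tolist()) - {"0"}
        if counted_alleles is not None:
            cnt = counted_alleles[j]
        elif seen == {"A"}:
            cnt = "B"  # writer convention: monomorphic reference column
        else:
            cnt = max(seen) if seen else "B"
        counted.append(cnt)
        miss = (col == "0").any(axis=1)
        dosages[:, j] = (col == cnt).sum(axis=1)
        dosages[miss, j] = np.nan
    individuals = pd.DataFrame(inds, columns=IND_COLUMNS)
    return dosages, individuals, counted


def _read_bed(prefix: Path) -> GenotypeTable:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise GenotypeParseError(f"{prefix.with_suffix('.bed')}: bad magic bytes")
    if raw[2] != 0x01:
        raise GenotypeParseError("only SNP-major .bed supported")
    n_ind, n_snp = len(fam), len(bim)
    bytes_per_snp = (n_ind + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_snp:
        raise GenotypeParseError(
            f".bed payload is {body.size} bytes, expected {bytes_per_snp * n_snp}"
        )
    body = body.reshape(n_snp, bytes_per_snp)
    # unpack 2-bit codes: 00=hom a1, 01=missing, 10=het, 11=hom a2
    codes = np.zeros((n_snp, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n_ind]
    lut = np.array([0.0, np.nan, 1.0, 2.0])
    dosages = lut[codes].T  # counted allele = a2
    snp_map = bim[["snp", "chrom", "bp", "a1", "a2"]].copy()
    individuals = pd.DataFrame(
        {"id": fam["iid"].astype(str), "line": fam["fid"].astype(str),
         "generation": 0, "sex": fam["sex"], "hatch": "0"}
    )
    return GenotypeTable(dosages, snp_map, individuals)


def read_genotypes(path, format: str = "plink-text", counted_alleles=None) -> GenotypeTable:
    """Read a :class:`GenotypeTable` from ``path`` (a file prefix without extension).

    ``format`` is one of ``plink-text``, ``plink-binary``, ``tsv``. For
    ``plink-text``, ``counted_alleles`` optionally fixes the counted allele per
    SNP (otherwise the lexicographically larger observed allele is counted).
    """
    prefix = Path(path)
    if format == "plink-text":
        map_path = prefix.with_suffix(".map")
        ped_path = prefix.with_suffix(".ped")
        for p in (map_path, ped_path):
            if not p.exists():
                raise FileNotFoundError(p)
        snp_map = _read_map(map_path)
        dosages, individuals, counted = _read_ped(ped_path, len(snp_map), counted_alleles)
        snp_map = snp_map.assign(a2=counted)
        return GenotypeTable(dosages, snp_map, individuals)
    if format == "plink-binary":
        return _read_bed(prefix)
    if format == "tsv":
        geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", index_col=0)
        snp_map = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
        inds = pd.read_csv(f"{prefix}.inds.tsv", sep="\t")
        if list(geno.columns) != list(snp_map["snp"].astype(str)):
            raise GenotypeParseError("geno.tsv columns do not match snps.tsv order")
        return GenotypeTable(geno.to_numpy(dtype=float), snp_map, inds)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(gt: GenotypeTable, path, format: str = "plink-text") -> None:
    """Write ``gt`` under prefix ``path`` in the requested format."""
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink-text":
        with prefix.with_suffix(".map").open("w") as fh:
            for _, row in gt.snp_map.iterrows():
                fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['bp']}\n")
        a1 = gt.snp_map["a1"].to_numpy(dtype="U8")
        a2 = gt.snp_map["a2"].to_numpy(dtype="U8")
        with prefix.with_suffix(".ped").open("w") as fh:
            for i in range(gt.n_individuals):
                ind = gt.individuals.iloc[i]
                fields = [str(ind["line"]), str(ind["id"]), "0", "0", str(ind["sex"]), "-9"]
                d = gt.dosages[i]
                for j in range(gt.n_snps):
                    if np.isnan(d[j]):
                        fields += ["0", "0"]
                    elif d[j] == 0:
                        fields += [a1[j], a1[j]]
                    elif d[j] == 1:
                        fields += [a1[j], a2[j]]
                    else:
                        fields += [a2[j], a2[j]]
                fh.write(" ".join(fields) + "\n")
    elif format == "plink-binary":
        with prefix.with_suffix(".bim").open("w") as fh:
            for _, row in gt.snp_map.iterrows():
                fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['bp']}\t{row['a1']}\t{row['a2']}\n")
        with prefix.with_suffix(".fam").open("w") as fh:
            for _, ind in gt.individuals.iterrows():
                fh.write(f"{ind['line']} {ind['id']} 0 0 {ind['sex']} -9\n")
        n_ind = gt.n_individuals
        bytes_per_snp = (n_ind + 3) // 4
        code_lut = {0.0: 0b00, 1.0: 0b10, 2.0: 0b11}
        out = np.empty(3 + bytes_per_snp * gt.n_snps, dtype=np.uint8)
        out[:3] = (0x6C, 0x1B, 0x01)
        padded = np.full((gt.n_snps, bytes_per_snp * 4), 0b00, dtype=np.uint8)
        for j in range(gt.n_snps):
            col = gt.dosages[:, j]
            codes = np.where(np.isnan(col), 0b01,
                             np.select([col == 0, col == 1, col == 2], [0b00, 0b10, 0b11]))
            padded[j, :n_ind] = codes
        packed = np.zeros((gt.n_snps, bytes_per_snp), dtype=np.uint8)
        for k in range(4):
            packed |= (padded[:, k::4].astype(np.uint8) << (2 * k))
        out[3:] = packed.ravel()
        out.tofile(prefix.with_suffix(".bed"))
    elif format == "tsv":
        geno = pd.DataFrame(gt.dosages, index=gt.individuals["id"],
                            columns=gt.snp_map["snp"].astype(str))
        geno.to_csv(f"{prefix}.geno.tsv", sep="\t")
        gt.snp_map.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
        gt.individuals.to_csv(f"{prefix}.inds.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (id, line, generation, sex, hatch, traits...)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"id"} - set(df.columns)
    if missing:
        raise GenotypeParseError(f"phenotype file lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# QC and frequencies
# ---------------------------------------------------------------------------

def filter_genotypes(gt: GenotypeTable, maf_min: float = 0.05,
                     snp_callrate_min: float = 0.95,
                     ind_callrate_min: float = 0.95) -> GenotypeTable:
    """Apply chip-QC filters with *strict* thresholds.

    Individuals with call rate > ``ind_callrate_min`` are kept first; then SNPs
    with minor allele frequency > ``maf_min`` and call rate > ``snp_callrate_min``
    (computed on the retained individuals). Order is preserved.
    """
    for name, t in (("maf_min", maf_min), ("snp_callrate_min", snp_callrate_min),
                    ("ind_callrate_min", ind_callrate_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name}={t} outside [0,1]")
    keep_ind = np.flatnonzero(gt.individual_call_rate() > ind_callrate_min)
    if keep_ind.size == 0:
        warnings.warn("all individuals removed by call-rate filter", EmptyPanelWarning)
    sub = gt.subset(ind_idx=keep_ind)
    keep_snp = np.flatnonzero(
        np.nan_to_num(sub.maf(), nan=0.0) > maf_min
    )
    cr = sub.snp_call_rate()
    keep_snp = keep_snp[cr[keep_snp] > snp_callrate_min]
    if keep_snp.size == 0:
        warnings.warn("all SNPs removed by QC filters", EmptyPanelWarning)
    return sub.subset(snp_idx=keep_snp)


def allele_frequencies(gt: GenotypeTable, grouping: Mapping[str, str]) -> AlleleFrequencySet:
    """Counted-allele frequencies per population defined by ``grouping`` (id -> label).

    Frequency = sum of dosages / number of non-missing alleles. A population
    with zero non-missing calls at a SNP gets a NaN frequency there.
    """
    ids = gt.individuals["id"].astype(str)
    unknown = set(map(str, grouping)) - set(ids)
    if unknown:
        raise KeyError(f"grouping names unknown individuals: {sorted(unknown)[:5]}")
    labels = ids.map(lambda i: grouping.get(i, grouping.get(str(i))))
    if labels.isna().any():
        raise KeyError("every individual must be assigned to exactly one population")
    pops = list(dict.fromkeys(labels))
    freqs, counts = {}, {}
    for pop in pops:
        rows = gt.dosages[(labels == pop).to_numpy()]
        n_alleles = 2.0 * (~np.isnan(rows)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = np.nansum(rows, axis=0)
            f = np.where(n_alleles > 0, s / np.where(n_alleles > 0, n_alleles, 1.0), np.nan)
        freqs[pop] = f
        counts[pop] = n_alleles
    idx = gt.snp_map["snp"]
    return AlleleFrequencySet(
        frequencies=pd.DataFrame(freqs, index=idx),
        allele_counts=pd.DataFrame(counts, index=idx),
        snp_map=gt.snp_map.copy(),
    )
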