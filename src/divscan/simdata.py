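"""Synthetic two-line divergent sib-selection experiment.

Produces everything the analysis stages consume: founder genotypes with
blockwise LD (recombinant mosaics of a small ancestral haplotype pool), a
correlated two-trait polygenic architecture, divergent truncation selection on
a full-sib phenotype index over several generations with sex-specific
reproducer counts, genotyped-sire subsets per generation and a final
phenotyped cohort -- plus the ground truth needed by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forwardsim import SexStructuredCounts
from .genio import GenotypeTable, write_genotypes

__all__ = [
    "BreedingDesign",
    "TraitArchitecture",
    "SimulationTruth",
    "ExperimentResult",
    "default_snp_map",
    "simulate_founders",
    "simulate_architecture",
    "run_breeding_experiment",
    "export_study_layout",
]

TRAIT_COLUMNS = ("PM_pHu", "SART_pHu")


@dataclass
class BreedingDesign:
    """Two-line divergent selection design (defaults mirror the study layout
    at reduced scale: 19% of sires and 50% of dams selected, sires genotyped
    in early generations, a final phenotyped cohort of both sexes)."""

    generations: int = 6
    sire_fraction: float = 0.19
    dam_fraction: float = 0.50
    n_offspring: int = 120          # per line, per generation (G1..G-1)
    n_g0_genotyped_sires: int = 51
    n_genotyped_sires: int = 20     # per line, per generation G1..G-1
    final_males: int = 60
    final_females: int = 70

    def __post_init__(self):
        for name in ("sire_fraction", "dam_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        if self.generations < 1:
            raise ValueError("need at least one generation")

    @property
    def final_cohort(self) -> int:
        return self.final_males + self.final_females

    def reproducer_counts(self) -> SexStructuredCounts:
        """Per-generation reproducing male/female counts implied by the design."""
        nm = [max(1, round(self.sire_fraction * self.n_offspring / 2))] * self.generations
        nf = [max(1, round(self.dam_fraction * self.n_offspring / 2))] * self.generations
        return SexStructuredCounts(males=nm + [nm[-1]], females=nf + [nf[-1]])


@dataclass
class TraitArchitecture:
    """QTL positions/effects and variance targets for the two traits."""

    qtl_indices: np.ndarray
    effects: np.ndarray           # (n_qtl, 2)
    h2: tuple = (0.4, 0.4)
    rg: float = 0.54
    residual_corr: float = 0.2

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (self.qtl_indices.size, 2):
            raise ValueError("effects must be (n_qtl, 2)")
        for h in self.h2:
            if not 0.0 < h < 1.0:
                raise ValueError("h2 must be in (0,1)")
        if abs(self.rg) > 1.0:
            raise ValueError("|rg| must be <= 1")

    def genetic_values(self, dosages: np.ndarray) -> np.ndarray:
        X = dosages[:, self.qtl_indices]
        return X @ self.effects


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the synthetic study."""

    qtl: pd.DataFrame                       # snp, chrom, bp, effect_1, effect_2
    line_freqs: dict                        # (line, generation) -> (L,) allele freq
    selected_parents: dict                  # (line, generation) -> list of ids
    line_means: dict                        # (line, generation) -> mean genetic value


@dataclass
class ExperimentResult:
    genotyped: dict                         # (line, generation) -> GenotypeTable
    phenotypes: pd.DataFrame                # final-cohort phenotype table
    truth: SimulationTruth
    design: BreedingDesign
    pedigree_ok: bool = True


def default_snp_map(n_snp: int, n_chrom: int = 5, spacing: int = 50_000) -> pd.DataFrame:
    """Evenly spaced SNP map over ``n_chrom`` chromosomes."""
    per = int(np.ceil(n_snp / n_chrom))
    rows = []
    i = 0
    for c in range(1, n_chrom + 1):
        for j in range(per):
            if i >= n_snp:
                break
            rows.append((f"snp{i + 1}", str(c), (j + 1) * spacing, "A", "B"))
            i += 1
    return pd.DataFrame(rows, columns=["snp", "chrom", "bp", "a1", "a2"])


def _mosaic(pool: np.ndarray, switch_p: np.ndarray, rng) -> np.ndarray:
    """One haplotype as a mosaic of pool rows; switch_p[l] = switch prob entering locus l."""
    H, L = pool.shape
    src = np.empty(L, dtype=np.int64)
    cur = rng.integers(H)
    switches = rng.random(L) < switch_p
    for l in range(L):
        if switches[l]:
            cur = rng.integers(H)
        src[l] = cur
    return pool[src, np.arange(L)]


def _interval_switch_probs(snp_map: pd.DataFrame, rate: float) -> np.ndarray:
    bp = snp_map["bp"].to_numpy(dtype=float)
    chrom = snp_map["chrom"].astype(str).to_numpy()
    p = np.ones(len(bp))
    same = np.empty(len(bp), dtype=bool)
    same[0] = False
    same[1:] = chrom[1:] == chrom[:-1]
    d = np.empty(len(bp))
    d[1:] = np.diff(bp)
    p[same] = 1.0 - np.exp(-rate * d[same])
    return p


def simulate_founders(n_ind: int, n_snp: int, snp_map: pd.DataFrame | None = None,
                      n_ancestral_haplotypes: int = 20, recomb_rate: float = 1e-8,
                      seed: int | None = None) -> GenotypeTable:
    """Founder cohort with blockwise LD.

    Each founder haplotype is a recombinant mosaic of ``n_ancestral_haplotypes``
    pool haplotypes (switch probability ``1 - exp(-recomb_rate * bp)`` per
    inter-SNP interval, forced at chromosome starts). The returned table has a
    ``haplotypes`` attribute of shape (n_ind, 2, L) used by the breeding step.
    """
    if n_ancestral_haplotypes < 2:
        raise ValueError("need at least 2 ancestral haplotypes")
    rng = np.random.default_rng(seed)
    snp_map = default_snp_map(n_snp) if snp_map is None else snp_map.reset_index(drop=True)
    L = len(snp_map)
    anc_freq = rng.uniform(0.1, 0.9, size=L)
    pool = (rng.random((n_ancestral_haplotypes, L)) < anc_freq).astype(np.int8)
    switch_p = _interval_switch_probs(snp_map, recomb_rate)
    haps = np.empty((n_ind, 2, L), dtype=np.int8)
    for i in range(n_ind):
        haps[i, 0] = _mosaic(pool, switch_p, rng)
        haps[i, 1] = _mosaic(pool, switch_p, rng)
    dosages = haps.sum(axis=1).astype(float)
    sexes = np.tile([1, 2], (n_ind + 1) // 2)[:n_ind]
    individuals = pd.DataFrame({
        "id": [f"G0-{i + 1}" for i in range(n_ind)],
        "line": "G0", "generation": 0, "sex": sexes, "hatch": "h1",
    })
    gt = GenotypeTable(dosages, snp_map, individuals)
    gt.haplotypes = haps
    gt.ancestral_freq = anc_freq
    return gt


def simulate_architecture(gt: GenotypeTable, n_qtl: int = 50, h2=(0.4, 0.4),
                          rg: float = 0.54, residual_corr: float = 0.2,
                          seed: int | None = None,
                          qtl_indices=None) -> TraitArchitecture:
    """Correlated two-trait polygenic architecture on ``n_qtl`` random SNPs.

    Effects are bivariate normal with correlation ``rg`` and are rescaled so
    the realized genetic variance in the founders equals ``h2`` exactly on the
    phenotypic-variance-1 scale.
    """
    rng = np.random.default_rng(seed)
    poly = np.flatnonzero(np.nan_to_num(gt.maf(), nan=0.0) > 0.05)
    if qtl_indices is None:
        if poly.size < n_qtl:
            raise ValueError(f"only {poly.size} polymorphic SNPs for {n_qtl} QTL")
        qtl_indices = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    else:
        qtl_indices = np.asarray(qtl_indices, dtype=int)
        n_qtl = qtl_indices.size
    cov = np.array([[1.0, rg], [rg, 1.0]])
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_qtl)
    X = gt.dosages[:, qtl_indices]
    X = X - X.mean(axis=0)
    g1 = X @ eff[:, 0]
    g2 = X @ eff[:, 1]
    if g1.var() <= 0 or g2.var() <= 0:
        raise ValueError("degenerate genetic variance; increase n_qtl or diversity")
    if abs(rg) == 1.0:
        eff[:, 1] = np.sign(rg) * eff[:, 0]
    else:
        # rotate trait-2 effects so the realized correlation of genetic values
        # in the founders equals rg exactly (LD and effect sampling otherwise
        # scatter it widely at moderate QTL counts)
        r_raw = np.corrcoef(g1, g2)[0, 1]
        resid = eff[:, 1] / g2.std() - r_raw * eff[:, 0] / g1.std()
        g_resid = X @ resid
        eff[:, 1] = rg * eff[:, 0] / g1.std() \
            + np.sqrt(1.0 - rg ** 2) * resid / max(g_resid.std(), 1e-12)
    for t in range(2):
        g = X @ eff[:, t]
        eff[:, t] *= np.sqrt(h2[t] / g.var())
    return TraitArchitecture(qtl_indices=qtl_indices, effects=eff, h2=tuple(h2),
                             rg=rg, residual_corr=residual_corr)


def _phenotypes(haps, arch: TraitArchitecture, rng) -> tuple[np.ndarray, np.ndarray]:
    dos = haps.sum(axis=1).astype(float)
    g = arch.genetic_values(dos)
    re_sd = np.sqrt([1.0 - arch.h2[0], 1.0 - arch.h2[1]])
    rc = arch.residual_corr
    cov = np.array([[re_sd[0] ** 2, rc * re_sd[0] * re_sd[1]],
                    [rc * re_sd[0] * re_sd[1], re_sd[1] ** 2]])
    e = rng.multivariate_normal([0.0, 0.0], cov, size=haps.shape[0])
    return g, g + e


def _meiosis(parent_haps: np.ndarray, switch_p: np.ndarray, rng) -> np.ndarray:
    """One gamete from a diploid parent: mosaic of its two haplotypes."""
    L = parent_haps.shape[1]
    cur = rng.integers(2)
    gam = np.empty(L, dtype=np.int8)
    switches = rng.random(L) < switch_p
    for l in range(L):
        if switches[l]:
            cur = rng.integers(2)
        gam[l] = parent_haps[cur, l]
    return gam


def _sib_index(phen: np.ndarray, fams: np.ndarray) -> np.ndarray:
    """Mean phenotype of an individual's full sibs (self excluded); falls back
    to the own phenotype for singletons / founders (fam id < 0)."""
    idx = np.array(phen, dtype=float)
    out = np.empty(len(phen))
    for i in range(len(phen)):
        if fams[i] < 0:
            out[i] = idx[i]
            continue
        sibs = (fams == fams[i])
        sibs[i] = False
        out[i] = idx[sibs].mean() if sibs.any() else idx[i]
    return out


def run_breeding_experiment(founders: GenotypeTable, arch: TraitArchitecture,
                            design: BreedingDesign, seed: int | None = None,
                            recomb_rate: float = 1e-8) -> ExperimentResult:
    """Run the two-line divergent sib-selection experiment.

    Both lines start from the same founder cohort; at every generation the top
    ``sire_fraction`` males and ``dam_fraction`` females by sib index (line
    'plus' upward on trait 1, line 'minus' downward) reproduce. Gametes follow
    Mendelian sampling with recombination. Emits genotyped sires for G0 and
    each intermediate generation, and the full phenotyped final cohort.
    """
    rng = np.random.default_rng(seed)
    if not hasattr(founders, "haplotypes"):
        raise ValueError("founders must come from simulate_founders (haplotypes needed)")
    snp_map = founders.snp_map
    switch_p = _interval_switch_probs(snp_map, recomb_rate)
    L = founders.n_snps

    genotyped: dict = {}
    line_freqs: dict = {}
    selected_parents: dict = {}
    line_means: dict = {}

    g0_haps = founders.haplotypes
    g0_sex = founders.individuals["sex"].to_numpy()
    g0_ids = founders.individuals["id"].to_numpy()
    g0_g, g0_phen = _phenotypes(g0_haps, arch, rng)

    # genotyped G0 sires
    males0 = np.flatnonzero(g0_sex == 1)
    pick = rng.choice(males0, size=min(design.n_g0_genotyped_sires, males0.size),
                      replace=False)
    genotyped[("G0", 0)] = GenotypeTable(
        g0_haps[pick].sum(axis=1).astype(float), snp_map,
        founders.individuals.iloc[pick].reset_index(drop=True))
    line_freqs[("G0", 0)] = g0_haps.sum(axis=(1,)).astype(float).mean(axis=0) / 2.0

    pedigree_ok = True
    phen_rows = []

    for line, direction in (("plus", +1), ("minus", -1)):
        haps, sex, ids = g0_haps, g0_sex, g0_ids
        fams = np.full(len(ids), -1)
        gvals, phen = g0_g, g0_phen
        for gen in range(1, design.generations + 1):
            final = gen == design.generations
            n_off = design.final_cohort if final else design.n_offspring
            index = direction * _sib_index(phen[:, 0], fams)
            males = np.flatnonzero(sex == 1)
            females = np.flatnonzero(sex == 2)
            n_sires = max(1, round(design.sire_fraction * males.size))
            n_dams = max(1, round(design.dam_fraction * females.size))
            if males.size == 0 or females.size == 0:
                raise RuntimeError(f"line {line} went extinct at generation {gen}")
            sires = males[np.argsort(-index[males], kind="mergesort")[:n_sires]]
            dams = females[np.argsort(-index[females], kind="mergesort")[:n_dams]]
            selected_parents[(line, gen)] = {
                "sires": list(ids[sires]), "dams": list(ids[dams])}

            new_haps = np.empty((n_off, 2, L), dtype=np.int8)
            new_fams = np.empty(n_off, dtype=np.int64)
            new_sex = np.empty(n_off, dtype=np.int64)
            # round-robin dam-to-sire mating; full sibs share (sire, dam)
            pairs = [(sires[d % n_sires], dams[d % n_dams])
                     for d in range(max(n_sires, n_dams))]
            for o in range(n_off):
                s_idx, d_idx = pairs[o % len(pairs)]
                new_haps[o, 0] = _meiosis(haps[s_idx], switch_p, rng)
                new_haps[o, 1] = _meiosis(haps[d_idx], switch_p, rng)
                new_fams[o] = o % len(pairs)
                new_sex[o] = 1 if o % 2 == 0 else 2
            if final:
                # enforce the configured sex split in the phenotyped cohort
                new_sex[:design.final_males] = 1
                new_sex[design.final_males:] = 2
            # pedigree sanity: each child allele must exist in a parent
            if gen == 1:
                for o in (0,):
                    s_idx, d_idx = pairs[o % len(pairs)]
                    if not (np.isin(new_haps[o, 0], haps[s_idx]).all()
                            and np.isin(new_haps[o, 1], haps[d_idx]).all()):
                        pedigree_ok = False

            ids = np.array([f"{line}-G{gen}-{o + 1}" for o in range(n_off)])
            haps, sex, fams = new_haps, new_sex, new_fams
            gvals, phen = _phenotypes(haps, arch, rng)
            line_freqs[(line, gen)] = haps.sum(axis=1).astype(float).mean(axis=0) / 2.0
            line_means[(line, gen)] = float(gvals[:, 0].mean())

            inds = pd.DataFrame({
                "id": ids, "line": line, "generation": gen, "sex": sex,
                "hatch": np.where(np.arange(n_off) % 2 == 0, "h1", "h2"),
            })
            if final:
                genotyped[(line, gen)] = GenotypeTable(
                    haps.sum(axis=1).astype(float), snp_map, inds)
                for o in range(n_off):
                    phen_rows.append((ids[o], line, gen, int(sex[o]),
                                      inds["hatch"].iloc[o],
                                      phen[o, 0], phen[o, 1]))
            else:
                sires_now = np.flatnonzero(sex == 1)
                take = rng.choice(sires_now,
                                  size=min(design.n_genotyped_sires, sires_now.size),
                                  replace=False)
                genotyped[(line, gen)] = GenotypeTable(
                    haps[take].sum(axis=1).astype(float), snp_map,
                    inds.iloc[take].reset_index(drop=True))

    qtl_df = pd.DataFrame({
        "snp": snp_map["snp"].to_numpy()[arch.qtl_indices],
        "chrom": snp_map["chrom"].to_numpy()[arch.qtl_indices],
        "bp": snp_map["bp"].to_numpy()[arch.qtl_indices],
        "effect_1": arch.effects[:, 0],
        "effect_2": arch.effects[:, 1],
    })
    phenotypes = pd.DataFrame(
        phen_rows, columns=["id", "line", "generation", "sex", "hatch",
                            TRAIT_COLUMNS[0], TRAIT_COLUMNS[1]])
    truth = SimulationTruth(qtl=qtl_df, line_freqs=line_freqs,
                            selected_parents=selected_parents, line_means=line_means)
    return ExperimentResult(genotyped=genotyped, phenotypes=phenotypes,
                            truth=truth, design=design, pedigree_ok=pedigree_ok)


def export_study_layout(result: ExperimentResult, outdir, format: str = "plink-text") -> dict:
    """Write per-generation/line genotype files, the phenotype TSV and truth TSVs.

    Returns a mapping of logical names to the file prefixes/paths written.
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for (line, gen), gt in result.genotyped.items():
        prefix = outdir / f"{line}_G{gen}"
        write_genotypes(gt, prefix, format=format)
        written[f"{line}_G{gen}"] = str(prefix)
    phen_path = outdir / "phenotypes.tsv"
    result.phenotypes.to_csv(phen_path, sep="\t", index=False)
    written["phenotypes"] = str(phen_path)
    truth_path = outdir / "truth_qtl.tsv"
    result.truth.qtl.to_csv(truth_path, sep="\t", index=False)
    written["truth_qtl"] = str(truth_path)
    freq_rows = []
    for (line, gen), f in result.truth.line_freqs.items():
        for l, v in enumerate(f):
            freq_rows.append((line, gen, l, v))
    pd.DataFrame(freq_rows, columns=["line", "generation", "snp_index", "freq"]) \
        .to_csv(outdir / "truth_freqs.tsv", sep="\t", index=False)
    written["truth_freqs"] = str(outdir / "truth_freqs.tsv")
    return written
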