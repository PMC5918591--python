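# divscan

Selection-signature scans and QTL mapping for two-line divergent selection
experiments, driven by a synthetic breeding-scheme simulator.

The package implements, as a tested reusable pipeline:

* **genio** — PLINK text/binary and TSV genotype I/O, chip-style QC filters
  (strict MAF / call-rate thresholds), per-population allele frequencies.
* **kinship** — genome-wide Reynolds distances, neighbour-joining population
  tree rooted on an outgroup, drift kinship matrix `F`, and the
  `F = 1-(1-1/(2N))^g` inbreeding/effective-size conversions.
* **flkscan** — single-SNP FLK: quadratic-form differentiation statistic
  against the kinship null, chi-squared p-values, Storey/BH q-values, and
  significant-region construction (merge rule < 1 Mb).
* **hapcluster** — local haplotype-cluster HMM for unphased genotypes
  (Scheet–Stephens style), fitted by exact EM with multiple restarts;
  per-population cluster frequencies; masking cross-validation for K.
* **hapflkscan** — hapFLK (FLK summed over cluster frequencies), robust
  normal null fit, per-generation scans, cross-generation region merging.
* **forwardsim** — neutral Wright–Fisher and sex-structured drift
  simulations and the Monte-Carlo trajectory p-value, with exact
  enumeration oracles for one-generation grids.
* **qtlscan** — Bayes Cπ multi-marker regression (spike-and-slab Gibbs
  sampler, numba-jitted), Bayes factors, QTL regions with 1 Mb flanks,
  phenotype pre-correction for sex/hatch (and optionally line).
* **posthoc** — pairwise LD (r²) tables, region-wise LD summaries, the
  QTL-BF enrichment test (Welch), QTL-vs-signature intersection.
* **simdata** — the synthetic study: founders with blockwise LD, correlated
  two-trait architecture, six generations of divergent sib selection with
  sex-specific reproducer counts, genotyped-sire subsets, phenotyped final
  cohort, and ground-truth outputs.
* **cli** — `divscan` command-line interface orchestrating the stages from a
  single YAML config with one global seed.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (type-I error
calibration, trajectory-test oracle equivalence, hapFLK sweep power,
Bayes Cπ recovery, region rules, deterministic end-to-end run); the other
files are per-module unit and property tests. The full suite takes a few
minutes on one CPU; the non-acceptance part runs in seconds.

## CLI

Run the whole pipeline on a bundled synthetic study:

```bash
divscan run --out runs/demo --seed 1
# or with a config file
divscan run --config examples/run.yaml --out runs/demo
```

Stages (`simulate, qc, kinship, flk, hapflk, trajtest, bayescpi, posthoc,
report`) can be selected with `--stages`; every stage writes TSV tables and a
log into the run directory, and reruns with the same seed are byte-identical.

One-off utilities:

```bash
divscan trajtest --p0 0.2 --pf 0.9 --g 5 --n 60 --nsims 1000000 --seed 1
divscan trajtest --p0 0.2 --pf 0.9 --g 5 --model sex-structured \
    --nm-list 6,6,6,6,6,6 --nf-list 15,15,15,15,15,15
divscan ne -f 0.08 --g 5
```

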