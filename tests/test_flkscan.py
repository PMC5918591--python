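import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from divscan import flkscan, genio, kinship
from divscan.regions import GenomicRegion

from test_kinship import freq_set


def two_line_kinship(f_minus=0.08, f_plus=0.07, shared=0.0):
    F = np.array([[0.0, 0.0, 0.0],
                  [0.0, f_minus, shared],
                  [0.0, shared, f_plus]])
    return kinship.PopulationKinship(["G0", "minus", "plus"], F, "(G0,minus,plus);")


def neutral_freq_set(rng, L, ne=(30, 35), g=5):
    """Exact drift frequencies: outgroup = ancestral grid frequency."""
    p0 = np.round(rng.uniform(0.1, 0.9, L) * 60) / 60
    freqs = {"G0": p0}
    counts = {"G0": np.full(L, 1e6)}
    for line, N in zip(("minus", "plus"), ne):
        n = 2 * N
        x = np.round(p0 * n).astype(int)
        for _ in range(g):
            x = rng.binomial(n, x / n)
        freqs[line] = x / n
        counts[line] = np.full(L, float(n))
    return freq_set(freqs, counts), p0


def true_kinship(ne=(30, 35), g=5):
    return two_line_kinship(kinship.inbreeding_from_ne(ne[0], g),
                            kinship.inbreeding_from_ne(ne[1], g))


class TestFlkStatistic:
    def test_zero_at_null(self):
        kin = two_line_kinship()
        assert flkscan.flk_statistic(np.array([0.4, 0.4]), 0.4, kin) == pytest.approx(0.0)

    def test_single_population_hand_value(self):
        kin = kinship.PopulationKinship(
            ["G0", "L"], np.array([[0.0, 0.0], [0.0, 0.08]]), "(G0,L);")
        # (0.1)^2 / (0.08 * 0.25) = 0.5
        assert flkscan.flk_statistic(np.array([0.6]), 0.5, kin) == pytest.approx(0.5)

    def test_allele_relabel_invariance(self, rng):
        kin = two_line_kinship(shared=0.01)
        p = rng.uniform(0.2, 0.8, 2)
        p0 = 0.37
        s1 = flkscan.flk_statistic(p, p0, kin)
        s2 = flkscan.flk_statistic(1 - p, 1 - p0, kin)
        assert s1 == pytest.approx(s2)

    def test_fixed_p0_flagged(self):
        kin = two_line_kinship()
        assert np.isnan(flkscan.flk_statistic(np.array([0.5, 0.5]), 0.0, kin))


class TestFlkScan:
    def test_zero_statistic_pvalue_one(self):
        afs = freq_set({"G0": np.array([0.5, 0.4]),
                        "minus": np.array([0.5, 0.4]),
                        "plus": np.array([0.5, 0.4])},
                       {p: np.full(2, 60.0) for p in ("G0", "minus", "plus")})
        scan = flkscan.flk_scan(afs, two_line_kinship())
        assert np.allclose(scan.table["p_value"], 1.0)

    def test_chi2_quantile_round_trip(self):
        q95 = stats.chi2.ppf(0.95, 2)
        assert stats.chi2.sf(q95, 2) == pytest.approx(0.05)
        # scan-level: statistic at the 0.95 quantile maps to p-value 0.05
        kin = two_line_kinship(0.08, 0.08)
        p0 = 0.5
        # craft deviations giving exactly the q95 statistic
        dev = np.sqrt(q95 * 0.08 * p0 * (1 - p0) / 2)
        afs = freq_set({"G0": np.array([p0]), "minus": np.array([p0 + dev]),
                        "plus": np.array([p0 + dev])},
                       {p: np.array([60.0]) for p in ("G0", "minus", "plus")})
        scan = flkscan.flk_scan(afs, kin)
        assert scan.table["p_value"].iloc[0] == pytest.approx(0.05)

    def test_neutral_distribution_matches_chi2(self, rng):
        # the chi-squared null is asymptotic: at 2N=60 binomial drift departs by
        # KS distance ~0.017, so the check runs at one replicate's size (2,000)
        # where that deviation sits well below the alpha=0.01 critical value
        afs, _ = neutral_freq_set(rng, 2000)
        scan = flkscan.flk_scan(afs, true_kinship())
        st_vals = scan.table["stat"].dropna()
        ks = stats.kstest(st_vals, "chi2", args=(2,))
        assert ks.pvalue > 0.01

    def test_type_i_error_level(self, rng):
        fracs = []
        for _ in range(20):
            afs, _ = neutral_freq_set(rng, 2000)
            scan = flkscan.flk_scan(afs, true_kinship())
            fracs.append(np.nanmean(scan.table["p_value"] < 0.05))
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert np.mean(fracs) == pytest.approx(0.05, abs=3 * se)

    def test_power_ordering_under_selection(self, rng):
        # one locus driven to fixation in one line exceeds the genome median
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            afs, p0 = neutral_freq_set(rng, 400)
            f = afs.frequencies.copy()
            f.iloc[0, f.columns.get_loc("minus")] = 1.0  # fixation at SNP 0
            afs = genio.AlleleFrequencySet(f, afs.allele_counts, afs.snp_map)
            scan = flkscan.flk_scan(afs, true_kinship())
            st_vals = scan.table["stat"]
            if st_vals.iloc[0] > st_vals.median():
                hits += 1
        assert hits / n_rep >= 0.95

    def test_missing_population_rejected(self):
        afs = freq_set({"G0": np.array([0.5])}, {"G0": np.array([60.0])})
        with pytest.raises(ValueError):
            flkscan.flk_scan(afs, two_line_kinship())


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(flkscan.compute_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_bh_hand_example(self):
        p = [0.001, 0.01, 0.02, 0.8, 0.9]
        q = flkscan.compute_qvalues(p)
        np.testing.assert_allclose(q, [0.005, 0.025, 0.02 * 5 / 3, 0.9, 0.9])

    def test_empty(self):
        assert flkscan.compute_qvalues([]).size == 0

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=500)
        q = flkscan.compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_equivariance(self, pvals):
        p = np.asarray(pvals)
        q = flkscan.compute_qvalues(p)
        perm = np.random.RandomState(0).permutation(len(p))
        q_perm = flkscan.compute_qvalues(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])


def scan_from_hits(bps, chroms=None, qs=None):
    n = len(bps)
    table = pd.DataFrame({
        "snp": [f"s{i}" for i in range(n)],
        "chrom": chroms or ["1"] * n,
        "bp": bps,
        "stat": 10.0,
        "p_value": 1e-5,
        "q_value": qs or [0.01] * n,
    })
    return flkscan.ScanResult(table=table, generation=5)


class TestBuildFlkRegions:
    def test_merge_rule_hand_example(self):
        regions = flkscan.build_flk_regions(
            scan_from_hits([1_000_000, 1_500_000, 3_000_000]), merge_distance=1_000_000)
        assert [(r.start, r.end) for r in regions] == \
            [(1_000_000, 1_500_000), (3_000_000, 3_000_000)]
        assert regions[0].generations == (5,)

    def test_no_significant_snps(self):
        scan = scan_from_hits([1_000_000], qs=[0.5])
        assert flkscan.build_flk_regions(scan) == []

    def test_exclude_region_drops_snp(self):
        scan = scan_from_hits([1_000_000, 5_000_000])
        excl = [GenomicRegion("1", 900_000, 1_100_000)]
        regions = flkscan.build_flk_regions(scan, exclude=excl)
        assert [(r.start, r.end) for r in regions] == [(5_000_000, 5_000_000)]

    def test_idempotent_and_order_independent(self):
        bps = [3_000_000, 1_000_000, 1_500_000]
        a = flkscan.build_flk_regions(scan_from_hits(bps))
        b = flkscan.build_flk_regions(scan_from_hits(sorted(bps)))
        assert [(r.start, r.end) for r in a] == [(r.start, r.end) for r in b]


def test_regions_to_bed(tmp_path):
    from divscan.regions import regions_to_bed
    regs = [GenomicRegion("1", 1_000_000, 1_500_000, name="r1", peak_score=7.2),
            GenomicRegion("2", 5, 10)]
    path = tmp_path / "r.bed"
    regions_to_bed(regs, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["1", "999999", "1500000", "r1", "7"]
    assert lines[1].split("\t") == ["2", "4", "10", "region-2", "0"]
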