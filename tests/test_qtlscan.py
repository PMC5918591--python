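import numpy as np
import pandas as pd
import pytest

from divscan import qtlscan
from conftest import make_table


class TestPriorSpec:
    def test_scale_rule_arithmetic(self):
        # S2 = sigma_hat^2 (nu - 2) / nu with nu = 4.2, sigma_hat^2 = 2
        p = qtlscan.PriorSpec(sigma2_a_prior=2.0)
        assert p.s2_a == pytest.approx(2.0 * 2.2 / 4.2)

    def test_prior_mean(self):
        assert qtlscan.PriorSpec().pi_mean == pytest.approx(0.005)

    def test_nu_must_exceed_two(self):
        with pytest.raises(ValueError):
            qtlscan.PriorSpec(nu=2.0)


class TestMcmcSpec:
    def test_burnin_bounds(self):
        with pytest.raises(ValueError):
            qtlscan.McmcSpec(n_iter=100, burn_in=100)

    def test_retained_count(self):
        assert qtlscan.McmcSpec(n_iter=1000, burn_in=200, thin=40).n_retained == 20


class TestPrecorrect:
    def test_single_level_centers(self):
        y = np.array([1.0, 2.0, 3.0])
        cov = pd.DataFrame({"sex": ["m", "m", "m"]})
        out = qtlscan.precorrect_phenotypes(y, cov)
        np.testing.assert_allclose(out, y - y.mean())

    def test_balanced_sex_effect_removed(self):
        # base 5.0 with +1/-1 sex effects -> all residuals zero
        y = np.array([6.0, 4.0, 6.0, 4.0])
        cov = pd.DataFrame({"sex": ["m", "f", "m", "f"]})
        out = qtlscan.precorrect_phenotypes(y, cov)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        y = rng.normal(size=40)
        cov = pd.DataFrame({"sex": rng.choice(["m", "f"], 40),
                            "hatch": rng.choice(["h1", "h2", "h3"], 40)})
        once = qtlscan.precorrect_phenotypes(y, cov)
        twice = qtlscan.precorrect_phenotypes(once, cov)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_confounded_design_rejected(self):
        y = np.arange(4.0)
        cov = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["x", "x", "y", "y"]})
        with pytest.raises(ValueError, match="singular|confounded"):
            qtlscan.precorrect_phenotypes(y, cov)


class TestBayesFactor:
    def test_q_equals_pi_gives_one(self):
        assert qtlscan.bayes_factor(0.005, 0.005) == pytest.approx(1.0)

    def test_hand_value(self):
        assert qtlscan.bayes_factor(0.5, 0.005) == pytest.approx(199.0)

    def test_monotone_in_inclusion(self):
        qs = np.linspace(0.01, 0.99, 50)
        bfs = qtlscan.bayes_factor(qs, 0.005)
        assert np.all(np.diff(bfs) > 0)

    def test_classification_thresholds(self):
        assert qtlscan.classify_bf(10) == ""
        assert qtlscan.classify_bf(20) == "strong"
        assert qtlscan.classify_bf(150) == "strong"
        assert qtlscan.classify_bf(151) == "very strong"


def run_sampler(y, gt, n_iter=4000, burn_in=800, thin=8, seed=0, priors=None):
    mcmc = qtlscan.McmcSpec(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    return qtlscan.run_bayescpi(y, gt, priors=priors, mcmc=mcmc)


class TestRunBayescpi:
    def test_conjugate_single_snp_matches_closed_form(self, rng):
        # pi forced ~1 and variances pinned by a huge-nu prior: posterior mean
        # of the single effect must equal the ridge-regression closed form
        n = 200
        x = rng.binomial(2, 0.5, n).astype(float)
        a_true, s2e, s2a = 0.5, 1.0, 0.25
        y = x * a_true + rng.normal(0, np.sqrt(s2e), n)
        gt = make_table(x[:, None])
        priors = qtlscan.PriorSpec(pi_alpha=1e9, pi_beta=1.0, nu=1e7,
                                   sigma2_a_prior=s2a, sigma2_e_prior=s2e)
        res = run_sampler(y, gt, n_iter=6000, burn_in=1000, thin=5, priors=priors)
        xc = x - x.mean()
        yc = y  # sampler centers dosages; mu absorbs the phenotype mean
        lam = xc @ xc / s2e + 1.0 / s2a
        closed_form = (xc @ (yc - yc.mean())) / (lam * s2e)
        post_mean = res.table["effect"].iloc[0] * res.table["inclusion"].iloc[0]
        assert res.table["inclusion"].iloc[0] > 0.99
        assert post_mean == pytest.approx(closed_form, abs=0.03)

    def test_null_trait_pi_near_prior(self, rng):
        n, M = 150, 200
        X = rng.binomial(2, 0.4, (n, M)).astype(float)
        y = rng.normal(size=n)
        res = run_sampler(y, make_table(X), seed=3)
        pi = res.chains["pi"]
        assert abs(pi.mean() - 0.005) < 3 * pi.std() + 1e-3
        assert res.table["bf"].max() < 20

    def test_planted_qtl_recovered(self, rng):
        n, M = 250, 300
        X = rng.binomial(2, 0.5, (n, M)).astype(float)
        idx = [50, 200]
        y = X[:, idx] @ np.array([0.7, -0.7]) + rng.normal(size=n)
        res = run_sampler(y, make_table(X), seed=5)
        top = set(res.top(5)["snp"])
        assert {"snp51", "snp201"} <= top

    def test_chains_valid_and_reproducible(self, rng):
        n, M = 80, 60
        X = rng.binomial(2, 0.5, (n, M)).astype(float)
        y = rng.normal(size=n)
        r1 = run_sampler(y, make_table(X), n_iter=1000, burn_in=200, thin=4, seed=9)
        r2 = run_sampler(y, make_table(X), n_iter=1000, burn_in=200, thin=4, seed=9)
        assert np.array_equal(r1.table["bf"], r2.table["bf"])
        assert ((r1.chains["pi"] >= 0) & (r1.chains["pi"] <= 1)).all()
        assert (r1.chains["sigma2_a"] > 0).all()
        assert (r1.chains["sigma2_e"] > 0).all()

    def test_missing_dosages_mean_imputed(self, rng):
        n, M = 60, 30
        X = rng.binomial(2, 0.5, (n, M)).astype(float)
        X[rng.random((n, M)) < 0.05] = np.nan
        y = rng.normal(size=n)
        res = run_sampler(y, make_table(X), n_iter=500, burn_in=100, thin=4)
        assert np.isfinite(res.table["bf"]).all()

    def test_length_mismatch_rejected(self, rng):
        gt = make_table(rng.binomial(2, 0.5, (10, 5)).astype(float))
        with pytest.raises(ValueError):
            run_sampler(np.zeros(9), gt, n_iter=100, burn_in=10)


def result_from_hits(bps, bfs, chroms=None):
    table = pd.DataFrame({
        "snp": [f"s{i}" for i in range(len(bps))],
        "chrom": chroms or ["1"] * len(bps),
        "bp": bps, "inclusion": 0.5, "bf": bfs, "effect": 0.1,
    })
    return qtlscan.QTLScanResult(table=table)


class TestBuildQtlRegions:
    def test_single_snp_flanked(self):
        res = result_from_hits([5_000_000], [30.0])
        regions = qtlscan.build_qtl_regions(res, bf_threshold=20)
        assert [(r.start, r.end) for r in regions] == [(4_000_000, 6_000_000)]

    def test_nearby_snps_merged_then_flanked(self):
        res = result_from_hits([5_000_000, 5_800_000], [30.0, 40.0])
        regions = qtlscan.build_qtl_regions(res)
        assert [(r.start, r.end) for r in regions] == [(4_000_000, 6_800_000)]
        assert regions[0].peak_score == 40.0

    def test_no_hits(self):
        res = result_from_hits([1_000_000], [5.0])
        assert qtlscan.build_qtl_regions(res) == []

    def test_clipping_at_chromosome_bounds(self):
        res = result_from_hits([500_000], [25.0])
        regions = qtlscan.build_qtl_regions(res, chrom_sizes={"1": 1_200_000})
        assert [(r.start, r.end) for r in regions] == [(1, 1_200_000)]
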