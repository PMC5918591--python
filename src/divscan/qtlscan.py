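"""Bayes C-pi multi-marker association mapping with Bayes factors.

Model: ``y_j = mu + sum_i x_ij a_i d_i + e_j`` with a spike-and-slab prior on
SNP effects (``a_i ~ N(0, sigma2_a)`` with probability ``pi``, else 0),
``pi ~ Beta(alpha, beta)`` and scaled inverse chi-squared priors on both
variance components with scale ``S2 = sigma_hat^2 (nu - 2) / nu``. All unknowns
are updated by single-site Gibbs sampling; evidence per SNP is the Bayes
factor, the posterior-to-prior odds of inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genio import GenotypeTable
from .regions import GenomicRegion, merge_positions

__all__ = [
    "PriorSpec",
    "McmcSpec",
    "QTLScanResult",
    "precorrect_phenotypes",
    "run_bayescpi",
    "bayes_factor",
    "classify_bf",
    "build_qtl_regions",
]


@dataclass
class PriorSpec:
    """Prior hyper-parameters of the Bayes C-pi model."""

    pi_alpha: float = 0.5e4
    pi_beta: float = 99.5e4
    nu: float = 4.2
    sigma2_a_prior: float = 0.01
    sigma2_e_prior: float = 1.0

    def __post_init__(self):
        for name in ("pi_alpha", "pi_beta", "nu", "sigma2_a_prior", "sigma2_e_prior"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2 for the scale rule S2 = s2*(nu-2)/nu")

    @property
    def pi_mean(self) -> float:
        return self.pi_alpha / (self.pi_alpha + self.pi_beta)

    def scale(self, sigma2_hat: float) -> float:
        return sigma2_hat * (self.nu - 2.0) / self.nu

    @property
    def s2_a(self) -> float:
        return self.scale(self.sigma2_a_prior)

    @property
    def s2_e(self) -> float:
        return self.scale(self.sigma2_e_prior)


@dataclass
class McmcSpec:
    """Gibbs chain schedule. Defaults are a scaled-down version of the full
    400k/80k/400 schedule, suitable for tests and desk-scale reruns."""

    n_iter: int = 40_000
    burn_in: int = 8_000
    thin: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class QTLScanResult:
    """Per-SNP inclusion probabilities, Bayes factors and effects, plus chains."""

    table: pd.DataFrame
    chains: dict = field(default_factory=dict)
    priors: PriorSpec = None
    mcmc: McmcSpec = None
    trait: str | None = None

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("bf", ascending=False).head(n)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def precorrect_phenotypes(y, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of an OLS fit of ``y`` on categorical covariates, re-centered.

    Raises on a confounded (rank-deficient) design.
    """
    y = np.asarray(y, dtype=float)
    X = [np.ones(len(y))]
    for col in covariates.columns:
        dummies = pd.get_dummies(covariates[col].astype(str), drop_first=True)
        for c in dummies.columns:
            X.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded covariates: design matrix is singular")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid - resid.mean()


@njit(cache=True)
def _gibbs_core(Xt, y, xtx, pi_alpha, pi_beta, nu, s2_a, s2_e,
                n_iter, burn_in, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    M, n = Xt.shape
    mu = y.mean()
    e = y - mu
    a = np.zeros(M)
    delta = np.zeros(M, dtype=np.int64)
    sigma_a = s2_a * nu / (nu - 2.0)
    sigma_e = s2_e * nu / (nu - 2.0)
    pi = pi_alpha / (pi_alpha + pi_beta)

    n_ret = (n_iter - burn_in + thin - 1) // thin
    incl_count = np.zeros(M)
    eff_sum = np.zeros(M)
    mu_ch = np.empty(n_ret)
    pi_ch = np.empty(n_ret)
    sa_ch = np.empty(n_ret)
    se_ch = np.empty(n_ret)
    ridx = 0
    log_prior_odds = np.log(pi) - np.log(1.0 - pi)

    for it in range(n_iter):
        # overall mean (flat prior)
        ebar = e.sum() / n
        mu_new = ebar + mu + np.random.normal(0.0, 1.0) * np.sqrt(sigma_e / n)
        e += mu - mu_new
        mu = mu_new

        m_in = 0
        ssq_a = 0.0
        for i in range(M):
            c = xtx[i]
            if c <= 0.0:
                delta[i] = 0
                a[i] = 0.0
                continue
            if delta[i] == 1:
                # restore residual without SNP i
                for j in range(n):
                    e[j] += Xt[i, j] * a[i]
            r = 0.0
            for j in range(n):
                r += Xt[i, j] * e[j]
            lam = c / sigma_e + 1.0 / sigma_a
            logodds = log_prior_odds - 0.5 * np.log(sigma_a * lam) \
                + r * r / (2.0 * lam * sigma_e * sigma_e)
            if logodds > 35.0:
                p_in = 1.0
            elif logodds < -35.0:
                p_in = 0.0
            else:
                p_in = 1.0 / (1.0 + np.exp(-logodds))
            if np.random.random() < p_in:
                mean_a = r / (lam * sigma_e)
                a_i = mean_a + np.random.normal(0.0, 1.0) / np.sqrt(lam)
                a[i] = a_i
                delta[i] = 1
                for j in range(n):
                    e[j] -= Xt[i, j] * a_i
                m_in += 1
                ssq_a += a_i * a_i
            else:
                delta[i] = 0
                a[i] = 0.0

        # variance components: scaled inverse chi-squared full conditionals
        sigma_a = (nu * s2_a + ssq_a) / np.random.chisquare(nu + m_in)
        sse = 0.0
        for j in range(n):
            sse += e[j] * e[j]
        sigma_e = (nu * s2_e + sse) / np.random.chisquare(nu + n)
        # inclusion probability
        pi = np.random.beta(pi_alpha + m_in, pi_beta + M - m_in)
        if pi <= 1e-12:
            pi = 1e-12
        elif pi >= 1.0 - 1e-12:
            pi = 1.0 - 1e-12
        log_prior_odds = np.log(pi) - np.log(1.0 - pi)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for i in range(M):
                if delta[i] == 1:
                    incl_count[i] += 1.0
                    eff_sum[i] += a[i]
            mu_ch[ridx] = mu
            pi_ch[ridx] = pi
            sa_ch[ridx] = sigma_a
            se_ch[ridx] = sigma_e
            ridx += 1

    return incl_count, eff_sum, mu_ch, pi_ch, sa_ch, se_ch


def run_bayescpi(y, gt: GenotypeTable, priors: PriorSpec | None = None,
                 mcmc: McmcSpec | None = None, trait: str | None = None) -> QTLScanResult:
    """Run the Bayes C-pi Gibbs sampler on precorrected phenotypes ``y``.

    Missing dosages are mean-imputed per SNP before sampling. When ``priors``
    is None, variance prior points are set from the phenotypic variance (half
    residual, half genic spread over the expected number of included SNPs).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != gt.n_individuals:
        raise ValueError("phenotype length does not match genotype table")
    X = gt.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    X -= X.mean(axis=0)

    M = gt.n_snps
    if priors is None:
        vy = float(np.var(y))
        if vy <= 0:
            raise ValueError("phenotype has zero variance")
        # slab variance point: half the phenotypic variance spread over all
        # markers (GBLUP-style); the weak nu=4.2 prior lets sigma2_a adapt
        # upward when real QTL enter the model
        mean_2pq = max(float(np.mean(np.var(X, axis=0))), 1e-6)
        priors = PriorSpec(
            sigma2_a_prior=0.5 * vy / (M * mean_2pq),
            sigma2_e_prior=0.5 * vy,
        )
    mcmc = mcmc or McmcSpec()

    Xt = np.ascontiguousarray(X.T)
    xtx = np.einsum("ij,ij->i", Xt, Xt)
    incl, eff_sum, mu_ch, pi_ch, sa_ch, se_ch = _gibbs_core(
        Xt, y, xtx, priors.pi_alpha, priors.pi_beta, priors.nu,
        priors.s2_a, priors.s2_e, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
        mcmc.seed,
    )
    if not np.isfinite(se_ch).all():
        raise RuntimeError("non-finite residual-variance samples: sampler diverged")
    S = mcmc.n_retained
    if S < 1:
        raise ValueError("schedule retains zero samples")
    q = (incl + 0.5) / (S + 1.0)  # smoothed inclusion probability
    bf = bayes_factor(q, priors.pi_mean)
    eff = np.where(incl > 0, eff_sum / np.maximum(incl, 1.0), 0.0)
    table = pd.DataFrame({
        "snp": gt.snp_map["snp"].to_numpy(),
        "chrom": gt.snp_map["chrom"].to_numpy(),
        "bp": gt.snp_map["bp"].to_numpy(),
        "inclusion": q,
        "bf": bf,
        "effect": eff,
    })
    table["evidence"] = [classify_bf(b) for b in bf]
    chains = {"mu": mu_ch, "pi": pi_ch, "sigma2_a": sa_ch, "sigma2_e": se_ch}
    return QTLScanResult(table=table, chains=chains, priors=priors, mcmc=mcmc,
                         trait=trait)


def bayes_factor(posterior_inclusion, prior_pi: float):
    """Posterior-to-prior inclusion odds ratio.

    ``BF = [q/(1-q)] / [pi/(1-pi)]``; callers should pass a smoothed ``q``
    (``(count + 0.5)/(S + 1)``) so the ratio stays finite.
    """
    q = np.asarray(posterior_inclusion, dtype=float)
    if np.any((q < 0) | (q > 1)) or not 0 < prior_pi < 1:
        raise ValueError("probabilities must lie in [0,1] (prior strictly inside)")
    post_odds = q / (1.0 - q)
    prior_odds = prior_pi / (1.0 - prior_pi)
    out = post_odds / prior_odds
    return float(out) if np.isscalar(posterior_inclusion) else out


def classify_bf(bf: float) -> str:
    """Evidence label: 20-150 'strong', >150 'very strong', else ''."""
    if bf > 150:
        return "very strong"
    if bf >= 20:
        return "strong"
    return ""


def build_qtl_regions(result: QTLScanResult, bf_threshold: float = 20.0,
                      merge_distance: int = 1_000_000, flank: int = 1_000_000,
                      chrom_sizes: dict | None = None) -> list[GenomicRegion]:
    """Candidate QTL regions: merge BF >= threshold SNPs, then add flanks.

    SNPs closer than ``merge_distance`` join one region; each region is then
    extended by ``flank`` bp on both sides (clipped at 1 and, when
    ``chrom_sizes`` is given, at the chromosome end).
    """
    hits = result.table[result.table["bf"] >= bf_threshold]
    if hits.empty:
        return []
    raw = merge_positions(hits["chrom"], hits["bp"].astype(int),
                          hits["bf"].to_numpy(), hits["snp"], merge_distance)
    out = []
    for r in raw:
        end = r.end + flank
        if chrom_sizes and str(r.chrom) in {str(k) for k in chrom_sizes}:
            size = next(v for k, v in chrom_sizes.items() if str(k) == str(r.chrom))
            end = min(end, int(size))
        out.append(GenomicRegion(chrom=r.chrom, start=max(1, r.start - flank),
                                 end=end, peak_snp=r.peak_snp,
                                 peak_score=r.peak_score, n_snps=r.n_snps))
    return out
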