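"""Local haplotype-cluster HMM for unphased genotypes, fitted by EM.

Each haplotype follows a Markov chain over K latent clusters along a
chromosome; a diploid individual is an unordered pair of such chains and its
genotype at a locus is the sum of two Bernoulli draws with cluster-specific
allele frequencies. The implementation works on ordered pairs (a K*K tensor
state space), which is algebraically identical to the unordered-pair model
because every quantity of interest is symmetric in the two chains.

Parameters per run:

* ``theta[l, k]`` -- counted-allele frequency of cluster k at locus l,
* ``alpha[l, k]`` -- cluster weights used at chain starts and as jump
  destinations entering locus l,
* ``rho[l]`` -- probability that a haplotype switches cluster in the interval
  ending at locus l (fixed at 1 at chromosome starts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genio import GenotypeTable

__all__ = [
    "ClusterRun",
    "ClusterModel",
    "ClusterFrequencies",
    "fit_cluster_model",
    "cluster_frequencies",
    "select_K",
    "hmm_loglikelihood",
    "enumerate_loglikelihood",
]

_THETA_CLIP = 1e-6
_RHO_CLIP = 1e-5


@dataclass
class ClusterRun:
    """Parameters and posteriors of one EM repetition."""

    theta: np.ndarray          # (L, K)
    alpha: np.ndarray          # (L, K)
    rho: np.ndarray            # (L,)
    loglik_path: np.ndarray    # per-iteration total log-likelihood
    memberships: np.ndarray    # (n_ind, L, K) posterior haplotype-cluster usage

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1])


@dataclass
class ClusterModel:
    """Fitted cluster HMM: K, the SNP map it was fitted on, and the EM runs."""

    K: int
    snp_map: pd.DataFrame
    individual_ids: list
    runs: list = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def best_run(self) -> ClusterRun:
        return max(self.runs, key=lambda r: r.loglik)

    def save(self, path) -> None:
        """Serialize the fitted model to a JSON text container."""
        import json
        payload = {
            "K": self.K,
            "individual_ids": self.individual_ids,
            "snp_map": self.snp_map.to_dict(orient="list"),
            "runs": [{
                "theta": r.theta.tolist(),
                "alpha": r.alpha.tolist(),
                "rho": r.rho.tolist(),
                "loglik_path": r.loglik_path.tolist(),
                "memberships": r.memberships.tolist(),
            } for r in self.runs],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        runs = [ClusterRun(theta=np.asarray(r["theta"]),
                           alpha=np.asarray(r["alpha"]),
                           rho=np.asarray(r["rho"]),
                           loglik_path=np.asarray(r["loglik_path"]),
                           memberships=np.asarray(r["memberships"]))
                for r in payload["runs"]]
        return cls(K=payload["K"], snp_map=pd.DataFrame(payload["snp_map"]),
                   individual_ids=payload["individual_ids"], runs=runs)


@dataclass
class ClusterFrequencies:
    """Per-run, per-population, per-locus cluster frequencies (sum to 1 per locus)."""

    populations: list
    freqs: np.ndarray  # (n_runs, n_pops, L, K)
    snp_map: pd.DataFrame

    def run(self, r: int) -> np.ndarray:
        return self.freqs[r]

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table (population, bp, cluster, frequency), run-averaged."""
        mean = self.freqs.mean(axis=0)  # (n_pops, L, K)
        rows = []
        bps = self.snp_map["bp"].to_numpy()
        chroms = self.snp_map["chrom"].to_numpy()
        for pi, pop in enumerate(self.populations):
            for l in range(mean.shape[1]):
                for k in range(mean.shape[2]):
                    rows.append((pop, chroms[l], int(bps[l]), k, mean[pi, l, k]))
        return pd.DataFrame(rows, columns=["population", "chrom", "bp", "cluster", "frequency"])


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _chain_breaks(snp_map: pd.DataFrame) -> np.ndarray:
    """Boolean per locus: True where a new chromosome (chain) starts."""
    chroms = snp_map["chrom"].astype(str).to_numpy()
    breaks = np.ones(len(chroms), dtype=bool)
    breaks[1:] = chroms[1:] != chroms[:-1]
    return breaks


def _genotype_codes(dosages: np.ndarray) -> np.ndarray:
    codes = np.where(np.isnan(dosages), 3, dosages).astype(np.int64)
    return codes


def _emissions(theta_l: np.ndarray, codes_l: np.ndarray) -> np.ndarray:
    """Emission tensor (n, K, K) for one locus given genotype codes {0,1,2,3=missing}."""
    t = theta_l
    u = 1.0 - t
    E = np.empty((4, t.size, t.size))
    E[0] = np.outer(u, u)
    E[1] = np.outer(t, u) + np.outer(u, t)
    E[2] = np.outer(t, t)
    E[3] = 1.0
    return E[codes_l]


def _transition(alpha_l: np.ndarray, rho_l: float) -> np.ndarray:
    K = alpha_l.size
    return (1.0 - rho_l) * np.eye(K) + rho_l * np.tile(alpha_l, (K, 1))


def _forward_backward(codes, theta, alpha, rho, breaks):
    """Scaled forward-backward over ordered cluster pairs, batched over individuals.

    Returns (loglik_total, fwd, bwd_scaledE, scales) where ``fwd[l]`` is the
    scaled forward tensor (n, K, K) and ``bwd[l]`` the scaled backward tensor.
    """
    n, L = codes.shape
    K = theta.shape[1]
    fwd = np.empty((L, n, K, K))
    scales = np.empty((L, n))
    for l in range(L):
        E = _emissions(theta[l], codes[:, l])
        if breaks[l]:
            prior = np.outer(alpha[l], alpha[l])
            a = prior[None, :, :] * E
        else:
            T = _transition(alpha[l], rho[l])
            a = (T.T[None] @ fwd[l - 1] @ T[None]) * E
        s = a.sum(axis=(1, 2))
        s = np.where(s > 0, s, 1e-300)
        fwd[l] = a / s[:, None, None]
        scales[l] = s
    bwd = np.empty((L, n, K, K))
    bwd[L - 1] = 1.0
    for l in range(L - 2, -1, -1):
        if breaks[l + 1]:
            bwd[l] = 1.0
        else:
            E = _emissions(theta[l + 1], codes[:, l + 1])
            G = E * bwd[l + 1] / scales[l + 1][:, None, None]
            T = _transition(alpha[l + 1], rho[l + 1])
            bwd[l] = T[None] @ G @ T.T[None]
    # chain-break independence: bwd at the locus before a break must also fold in
    # the likelihood of the next chain segment, which is constant across states
    # after scaling; the scaled recursion above already yields state-constant 1.
    loglik = float(np.log(scales).sum())
    return loglik, fwd, bwd, scales


def hmm_loglikelihood(dosages: np.ndarray, theta, alpha, rho, breaks) -> float:
    """Total log-likelihood of a dosage matrix under the given parameters."""
    codes = _genotype_codes(np.asarray(dosages, dtype=float))
    ll, *_ = _forward_backward(codes, theta, alpha, rho, breaks)
    return ll


def enumerate_loglikelihood(dosages: np.ndarray, theta, alpha, rho, breaks) -> float:
    """Brute-force path-enumeration likelihood (oracle; feasible for tiny L, K)."""
    codes = _genotype_codes(np.asarray(dosages, dtype=float))
    n, L = codes.shape
    K = theta.shape[1]
    if (K * K) ** L > 2_000_000:
        raise ValueError("instance too large for enumeration")
    from itertools import product
    total_ll = 0.0
    for i in range(n):
        tot = 0.0
        for path in product(range(K * K), repeat=L):
            pairs = [(s // K, s % K) for s in path]
            p = 1.0
            for l, (k1, k2) in enumerate(pairs):
                if breaks[l]:
                    p *= alpha[l][k1] * alpha[l][k2]
                else:
                    T = _transition(alpha[l], rho[l])
                    pk1, pk2 = pairs[l - 1]
                    p *= T[pk1, k1] * T[pk2, k2]
                g = codes[i, l]
                t1, t2 = theta[l][k1], theta[l][k2]
                if g == 0:
                    p *= (1 - t1) * (1 - t2)
                elif g == 1:
                    p *= t1 * (1 - t2) + (1 - t1) * t2
                elif g == 2:
                    p *= t1 * t2
            tot += p
        total_ll += np.log(tot)
    return float(total_ll)


def _em_iteration(codes, theta, alpha, rho, breaks):
    """One exact EM pass; returns (loglik, theta', alpha', rho', memberships)."""
    n, L = codes.shape
    K = theta.shape[1]
    loglik, fwd, bwd, scales = _forward_backward(codes, theta, alpha, rho, breaks)

    theta_num = np.zeros((L, K))
    theta_den = np.zeros((L, K))
    alpha_new = np.zeros((L, K))
    rho_num = np.zeros(L)
    memberships = np.empty((n, L, K))

    for l in range(L):
        gamma = fwd[l] * bwd[l]
        gamma /= np.maximum(gamma.sum(axis=(1, 2), keepdims=True), 1e-300)
        m1 = gamma.sum(axis=2)  # (n, K) chain-1 membership
        m2 = gamma.sum(axis=1)
        msum = m1 + m2
        memberships[:, l, :] = msum / 2.0
        g = codes[:, l]
        obs = g != 3
        theta_den[l] = msum[obs].sum(axis=0)
        # expected counted-allele copies assigned to each cluster
        hom2 = obs & (g == 2)
        theta_num[l] += msum[hom2].sum(axis=0)
        het = obs & (g == 1)
        if het.any():
            t = theta[l]
            e1 = np.outer(t, 1 - t) + np.outer(1 - t, t)
            W1 = np.outer(t, 1 - t) / np.maximum(e1, 1e-300)  # alt on chain 1
            gam_h = gamma[het]
            theta_num[l] += np.einsum("nab,ab->na", gam_h, W1).sum(axis=0) \
                + np.einsum("nab,ba->nb", gam_h, W1).sum(axis=0)

        if breaks[l]:
            alpha_new[l] = msum.sum(axis=0)
            rho_num[l] = 2.0 * n  # forced re-draw
        else:
            T = _transition(alpha[l], rho[l])
            E = _emissions(theta[l], codes[:, l])
            G = E * bwd[l] / scales[l][:, None, None]
            C1 = T[None] * (fwd[l - 1] @ T[None] @ np.swapaxes(G, 1, 2))
            C2 = T[None] * (np.swapaxes(fwd[l - 1], 1, 2) @ T[None] @ G)
            C = C1.sum(axis=0) + C2.sum(axis=0)
            tot = C.sum()
            if tot > 0:
                C = C * (2.0 * n / tot)
            diag = np.diag(C).copy()
            off = C - np.diag(diag)
            jump_from_diag = diag * (rho[l] * alpha[l]) / np.maximum(
                (1.0 - rho[l]) + rho[l] * alpha[l], 1e-300)
            rho_num[l] = off.sum() + jump_from_diag.sum()
            alpha_new[l] = off.sum(axis=0) + jump_from_diag

    theta_new = theta_num / np.maximum(theta_den, 1e-300)
    theta_new = np.clip(theta_new, _THETA_CLIP, 1.0 - _THETA_CLIP)
    tot = alpha_new.sum(axis=1, keepdims=True)
    alpha_new = np.where(tot > 0, alpha_new / np.maximum(tot, 1e-300), 1.0 / K)
    alpha_new = np.clip(alpha_new, 1e-6, 1.0)
    alpha_new /= alpha_new.sum(axis=1, keepdims=True)
    rho_new = np.clip(rho_num / (2.0 * n), _RHO_CLIP, 1.0)
    rho_new[breaks] = 1.0
    return loglik, theta_new, alpha_new, rho_new, memberships


def fit_cluster_model(gt: GenotypeTable, K: int, n_em_runs: int = 3,
                      max_iter: int = 100, seed: int | None = None,
                      tol: float = 1e-6) -> ClusterModel:
    """Fit the K-cluster HMM with ``n_em_runs`` random EM restarts.

    Each run starts from seeded random cluster allele frequencies in
    [0.05, 0.95], uniform destination weights and a moderate jump rate, and
    iterates exact EM until the relative log-likelihood change drops below
    ``tol`` (or ``max_iter``). All runs are retained.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    codes = _genotype_codes(gt.dosages)
    n, L = codes.shape
    if L < 1:
        raise ValueError("need at least one SNP")
    breaks = _chain_breaks(gt.snp_map)
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_em_runs):
        theta = rng.uniform(0.05, 0.95, size=(L, K))
        alpha = np.full((L, K), 1.0 / K)
        rho = np.full(L, 0.05)
        rho[breaks] = 1.0
        ll_path = []
        memberships = None
        prev = -np.inf
        for _it in range(max_iter):
            ll, theta, alpha, rho, memberships = _em_iteration(
                codes, theta, alpha, rho, breaks)
            ll_path.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol * max(abs(prev), 1.0):
                break
            prev = ll
        runs.append(ClusterRun(theta=theta, alpha=alpha, rho=rho,
                               loglik_path=np.asarray(ll_path),
                               memberships=memberships))
    return ClusterModel(K=K, snp_map=gt.snp_map.copy(),
                        individual_ids=list(gt.individuals["id"].astype(str)),
                        runs=runs)


def cluster_frequencies(model: ClusterModel, grouping: Mapping[str, str]) -> ClusterFrequencies:
    """Population cluster frequencies: posterior memberships averaged per population.

    ``grouping`` maps individual id -> population label; every id in it must
    belong to the fitted model. Frequencies sum to 1 at every locus.
    """
    ids = model.individual_ids
    unknown = set(map(str, grouping)) - set(ids)
    if unknown:
        raise KeyError(f"grouping names individuals absent from the model: {sorted(unknown)[:5]}")
    labels = [grouping.get(i) for i in ids]
    if any(lab is None for lab in labels):
        raise KeyError("every fitted individual needs a population label")
    pops = list(dict.fromkeys(labels))
    labels = np.asarray(labels)
    n_runs = model.n_runs
    L, K = model.runs[0].theta.shape
    freqs = np.empty((n_runs, len(pops), L, K))
    for r, run in enumerate(model.runs):
        for pi, pop in enumerate(pops):
            sel = labels == pop
            freqs[r, pi] = run.memberships[sel].mean(axis=0)
    return ClusterFrequencies(populations=pops, freqs=freqs, snp_map=model.snp_map)


def _imputation_error(gt: GenotypeTable, K: int, mask_frac: float,
                      fold_seed: int) -> float:
    rng = np.random.default_rng(fold_seed)
    obs = ~np.isnan(gt.dosages)
    mask = obs & (rng.random(gt.dosages.shape) < mask_frac)
    if not mask.any():
        return 0.0
    masked = gt.dosages.copy()
    truth = gt.dosages[mask]
    masked[mask] = np.nan
    masked_gt = GenotypeTable(masked, gt.snp_map, gt.individuals)
    model = fit_cluster_model(masked_gt, K, n_em_runs=1, max_iter=50,
                              seed=fold_seed + 7919)
    run = model.best_run
    codes = _genotype_codes(masked)
    _, fwd, bwd, _ = _forward_backward(codes, run.theta, run.alpha, run.rho,
                                       _chain_breaks(gt.snp_map))
    n, L = codes.shape
    pred = np.empty((n, L))
    for l in range(L):
        gamma = fwd[l] * bwd[l]
        gamma /= np.maximum(gamma.sum(axis=(1, 2), keepdims=True), 1e-300)
        t = run.theta[l]
        # E[g] = E[theta_k1] + E[theta_k2]
        pred[:, l] = gamma.sum(axis=2) @ t + gamma.sum(axis=1) @ t
    return float(np.mean((pred[mask] - truth) ** 2))


def select_K(gt: GenotypeTable, candidate_Ks, folds: int = 3, seed: int | None = None,
             mask_frac: float = 0.1) -> int:
    """Pick K by masking cross-validation on genotype imputation error.

    For each fold a seeded random ``mask_frac`` of observed genotypes is hidden,
    the model is fitted on the rest, and hidden genotypes are imputed by their
    posterior expectation; the K with the lowest mean squared error wins (ties
    go to the smaller K). Candidate order is irrelevant.
    """
    cands = sorted(set(int(k) for k in candidate_Ks))
    if not cands:
        raise ValueError("need at least one candidate K")
    if len(cands) == 1:
        return cands[0]
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=folds)
    errors = {k: np.mean([_imputation_error(gt, k, mask_frac, int(s)) for s in base])
              for k in cands}
    best = min(errors.values())
    # parsimony: the smallest K within a whisker of the best error wins
    tol = max(1e-8, 0.02 * abs(best))
    return min(k for k in cands if errors[k] <= best + tol)
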