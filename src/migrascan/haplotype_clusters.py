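"""Haplotype-mosaic hidden Markov model (K-cluster EM fit).

Each haplotype is modelled as a mosaic of K ancestral cluster haplotypes:
hidden state = cluster membership at a site, emission = Bernoulli(theta_ks)
on the observed allele, and between adjacent sites the chain either stays in
its cluster or, with a distance-dependent probability
r_s = 1 - exp(-rho * d_s), jumps to a cluster drawn from global weights
alpha. This is the standard parameterization behind fastPHASE-style models
and is what hapFLK consumes: per-population cluster frequencies are the
posterior memberships averaged over a population's haplotypes.

EM is run from several random starts (independent seeded fits are kept so
the scan statistic can be averaged over them, which smooths out label
switching and local optima).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusterFit:
    """One converged EM fit."""

    theta: np.ndarray  # (K, S) cluster allele frequencies
    alpha: np.ndarray  # (K,) jump weights
    log_likelihood: float
    seed: int
    converged: bool
    n_iter: int


@dataclass
class HaplotypeClusterModel:
    """K-cluster haplotype-mosaic HMM with E independent EM fits.

    Parameters
    ----------
    K : number of clusters (>= 1).
    n_fits : independent EM restarts retained (default 20).
    switch_rate : rho per bp in r_s = 1 - exp(-rho * d_s). Default 5e-5
        (haplotype blocks of order 20 kb).
    tol : EM stops when the log-likelihood gain drops below this.
    """

    K: int
    n_fits: int = 20
    switch_rate: float = 5e-5
    max_iter: int = 200
    tol: float = 1e-4
    seed: int | None = None
    fits: list = field(default_factory=list)
    _switch: np.ndarray | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")

    # -- model fitting -------------------------------------------------

    def _switch_probs(self, matrix: HaplotypeMatrix) -> np.ndarray:
        """Per-interval switch probability; scaffold boundaries restart."""
        d = np.diff(matrix.positions).astype(float)
        same = matrix.scaffold[1:] == matrix.scaffold[:-1]
        r = 1.0 - np.exp(-self.switch_rate * np.maximum(d, 1.0))
        return np.where(same, r, 1.0)

    def fit(self, matrix: HaplotypeMatrix) -> "HaplotypeClusterModel":
        if matrix.n_sites < 2:
            raise ValueError("need at least 2 sites to fit the cluster model")
        self._switch = self._switch_probs(matrix)
        ss = np.random.SeedSequence(self.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(self.n_fits)]
        self.fits = [self._fit_once(matrix, s) for s in seeds]
        if not any(f.converged for f in self.fits):
            warnings.warn("no EM fit converged; keeping best log-likelihood fits")
        return self

    def _emission_table(self, theta, alleles):
        """Emission probabilities (S, H, K); missing alleles emit 1."""
        x = alleles.T[:, :, None]  # (S, H, 1)
        th = theta.T[:, None, :]  # (S, 1, K)
        e = np.where(x == 1, th, 1.0 - th)
        return np.where(x == MISSING, 1.0, e)

    def _forward_backward(self, matrix, theta, alpha):
        """Scaled forward-backward over all haplotypes at once.

        Returns (log_likelihood, gamma (H,S,K), jump_counts (K,)).
        """
        H, S = matrix.alleles.shape
        K = self.K
        r = self._switch
        E = self._emission_table(theta, matrix.alleles)
        fwd = np.empty((S, H, K))
        cs = np.empty((S, H))
        f = alpha[None, :] * E[0]
        cs[0] = f.sum(axis=1)
        fwd[0] = f / cs[0][:, None]
        for s in range(1, S):
            # fwd rows sum to 1 after scaling, so the jump mass is alpha
            f = ((1 - r[s - 1]) * fwd[s - 1] + r[s - 1] * alpha[None, :]) * E[s]
            cs[s] = f.sum(axis=1)
            fwd[s] = f / cs[s][:, None]
        bwd = np.ones((H, K))
        gamma = np.empty((S, H, K))
        gamma[S - 1] = fwd[S - 1]
        jumps = np.zeros(K)
        for s in range(S - 2, -1, -1):
            eb = E[s + 1] * bwd  # (H, K)
            # expected jump-to-k transitions between s and s+1
            jumps += (r[s] * alpha[None, :] * eb / cs[s + 1][:, None]).sum(axis=0)
            bwd = (1 - r[s]) * eb + r[s] * (alpha[None, :] * eb).sum(axis=1, keepdims=True)
            bwd /= cs[s + 1][:, None]
            g = fwd[s] * bwd
            gamma[s] = g / g.sum(axis=1, keepdims=True)
        loglik = float(np.log(cs).sum())
        return loglik, np.swapaxes(gamma, 0, 1), jumps

    def _fit_once(self, matrix, seed) -> ClusterFit:
        rng = np.random.default_rng(seed)
        H, S = matrix.alleles.shape
        K = self.K
        p, _ = _safe_freq(matrix.alleles)
        theta = np.clip(
            p[None, :] + rng.uniform(-0.3, 0.3, size=(K, S)), 0.02, 0.98
        )
        alpha = np.full(K, 1.0 / K)
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            loglik, gamma, jumps = self._forward_backward(matrix, theta, alpha)
            # M step (missing alleles excluded from theta)
            ok = (matrix.alleles != MISSING).T  # (S, H)
            ones = (matrix.alleles == 1).T  # (S, H)
            denom = np.einsum("hsk,sh->sk", gamma, ok.astype(float))
            numer = np.einsum("hsk,sh->sk", gamma, ones.astype(float))
            theta = np.clip((numer / np.maximum(denom, 1e-12)).T, 1e-4, 1 - 1e-4)
            start_mass = gamma[:, 0, :].sum(axis=0)
            alpha = jumps + start_mass
            alpha = alpha / alpha.sum()
            if loglik - prev < self.tol and it > 1:
                converged = True
                prev = loglik
                break
            prev = loglik
        return ClusterFit(
            theta=theta,
            alpha=alpha,
            log_likelihood=prev,
            seed=seed,
            converged=converged,
            n_iter=it,
        )

    # -- posterior queries ---------------------------------------------

    def posteriors(self, matrix: HaplotypeMatrix, fit: ClusterFit) -> np.ndarray:
        """Posterior cluster memberships (H, S, K) under one fit."""
        if self._switch is None or len(self._switch) != matrix.n_sites - 1:
            self._switch = self._switch_probs(matrix)
        _, gamma, _ = self._forward_backward(matrix, fit.theta, fit.alpha)
        return gamma

    def cluster_frequencies(self, matrix: HaplotypeMatrix, fit: ClusterFit, hidx: dict, pops):
        """Per-population, per-site cluster frequencies (S, K, npop)."""
        gamma = self.posteriors(matrix, fit)
        out = np.empty((matrix.n_sites, self.K, len(pops)))
        for j, p in enumerate(pops):
            out[:, :, j] = gamma[hidx[p]].mean(axis=0)
        return out

    def impute(self, matrix: HaplotypeMatrix, fit: ClusterFit) -> np.ndarray:
        """Posterior P(allele = 1) for every haplotype x site."""
        gamma = self.posteriors(matrix, fit)
        return np.einsum("hsk,ks->hs", gamma, fit.theta)


def _safe_freq(alleles):
    ok = alleles != MISSING
    n = ok.sum(axis=0)
    p = np.where(ok, alleles, 0).sum(axis=0) / np.maximum(n, 1)
    return np.clip(p, 0.02, 0.98), n


def select_K(
    matrix: HaplotypeMatrix,
    candidate_Ks,
    mask_fraction: float = 0.05,
    seed: int | None = None,
    n_fits: int = 1,
    **model_kwargs,
):
    """Choose K by held-out imputation accuracy.

    A random fraction of observed alleles is masked, the model is fitted on
    the masked data, and K is scored by how well the posterior imputes the
    masked alleles. Ties break toward smaller K.

    Returns (best_K, {K: accuracy}).
    """
    if mask_fraction <= 0:
        raise ValueError("mask_fraction must be positive")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(matrix.alleles != MISSING)
    take = rng.choice(len(obs), size=max(1, int(mask_fraction * len(obs))), replace=False)
    masked = matrix.alleles.copy()
    truth = []
    for i, j in obs[take]:
        truth.append((i, j, matrix.alleles[i, j]))
        masked[i, j] = MISSING
    masked_matrix = HaplotypeMatrix(
        alleles=masked,
        positions=matrix.positions,
        scaffold=matrix.scaffold,
        ref_alt=matrix.ref_alt,
        sample_ids=matrix.sample_ids,
    )
    acc = {}
    for K in sorted(candidate_Ks):
        model = HaplotypeClusterModel(
            K=K, n_fits=n_fits, seed=int(rng.integers(2**31 - 1)), **model_kwargs
        ).fit(masked_matrix)
        best = max(model.fits, key=lambda f: f.log_likelihood)
        prob = model.impute(masked_matrix, best)
        hits = [int((prob[i, j] > 0.5) == bool(a)) for i, j, a in truth]
        acc[K] = float(np.mean(hits))
    best_K = max(sorted(acc), key=lambda k: acc[k])  # ties -> smaller K
    return best_K, acc
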