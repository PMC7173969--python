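"""Fine-mapping of strongly associated SNPs inside scan outlier regions.

Candidate SNPs (p < 1e-4 inside a called region) get signed association
z-scores from per-SNP FLK: each SNP's centered population-frequency vector
is whitened by the inverse square root of p0(1-p0)F, the z magnitude is the
whitened norm (so z^2 = FLK) and the sign is the loading on the leading
orthogonal component across the region's SNPs. The SNP-by-SNP signal
correlation matrix is the correlation of those whitened vectors — the
FLK-based stand-in for GWAS LD.

Posteriors over causal configurations follow the multivariate-normal
enumeration model: under configuration C, z ~ N(0, S + sigma2 * S I_C S)
with S the signal correlation, prior gamma^|C| (1-gamma)^(m-|C|).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import multivariate_normal

log = logging.getLogger(__name__)


@dataclass
class FinemapInput:
    positions: np.ndarray
    z: np.ndarray
    sigma: np.ndarray  # SNP x SNP signal correlation
    ridge: float = 0.0


@dataclass
class FinemapResult:
    configurations: list  # tuples of SNP indices
    posteriors: np.ndarray
    inclusion: np.ndarray  # per-SNP inclusion probability
    rho_set: list  # SNP indices of the rho-confidence causal set
    rho: float


def select_candidate_snps(pvalues, positions, region, p_threshold: float = 1e-4):
    """Indices of SNPs inside `region` (scaffold, start, end; 0-based
    half-open on position-1) with p below the threshold."""
    pvalues = np.asarray(pvalues, dtype=float)
    positions = np.asarray(positions)
    scaffold, start, end = region
    inside = (positions - 1 >= start) & (positions - 1 < end)
    keep = np.flatnonzero(inside & (pvalues < p_threshold))
    if len(keep) == 0:
        warnings.warn("no SNPs below the p-value threshold in region; skipping")
    return keep


def flk_signal_correlation(P: np.ndarray, F: np.ndarray, ridge: float = 1e-8):
    """Whitened frequency deviations and their SNP-by-SNP correlation.

    P is (m, npop) of per-population frequencies for the m candidate SNPs.
    Returns (FinemapInput-ready sigma, whitened (m, npop), z signed scores).
    Rank-deficient F is ridge-regularized (lambda recorded via the return).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    m, npop = P.shape
    if m < 2:
        raise ValueError("need >= 2 SNPs for a signal correlation matrix")
    F = np.asarray(F, dtype=float)
    lam = 0.0
    evals = np.linalg.eigvalsh(F)
    if evals.min() < 1e-10:
        lam = ridge + abs(evals.min())
        F = F + lam * np.eye(npop)
    vals, vecs = np.linalg.eigh(F)
    F_isqrt = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    Fi = vecs @ np.diag(1.0 / vals) @ vecs.T
    w = Fi.sum(axis=0) / Fi.sum()
    p0 = P @ w
    scale = np.sqrt(np.maximum(p0 * (1 - p0), 1e-12))
    W = (P - p0[:, None]) @ F_isqrt / scale[:, None]
    norms = np.linalg.norm(W, axis=1)
    # sign from the loading on the leading orthogonal component
    _, _, vt = np.linalg.svd(W, full_matrices=False)
    sign = np.sign(W @ vt[0])
    sign[sign == 0] = 1.0
    z = sign * norms
    safe = np.where(norms > 0, norms, 1.0)
    U = W / safe[:, None]
    sigma = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(sigma, 1.0)
    return sigma, W, z, lam


def caviar_posterior(
    z,
    sigma,
    max_causal: int = 2,
    gamma: float = 0.01,
    sigma2: float = 5.2,
    rho: float = 0.95,
    enumeration_cap: int = 50,
) -> FinemapResult:
    """Posterior over causal configurations by exhaustive enumeration.

    Configurations of size 1..max_causal are scored by the multivariate
    normal likelihood of z with covariance sigma + sigma2 * sigma I_C sigma
    and binomial prior gamma^|C| (1-gamma)^(m-|C|) (at least one causal SNP
    is assumed, as in the original method; the prior renormalizes over the
    enumerated configurations). The rho-confidence set is grown by
    inclusion probability until the contained configurations' mass reaches
    rho.
    """
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    m = len(z)
    if m > enumeration_cap:
        raise ValueError(
            f"{m} SNPs exceeds the enumeration cap ({enumeration_cap}); "
            "raise the cap or tighten the p-value threshold"
        )
    base = sigma + 1e-8 * np.eye(m)
    configs, logpost = [], []
    for size in range(1, max_causal + 1):
        for C in combinations(range(m), size):
            cov = base.copy()
            if C:
                ind = np.zeros(m)
                ind[list(C)] = 1.0
                cov = cov + sigma2 * (sigma * ind[None, :]) @ sigma
            ll = multivariate_normal.logpdf(z, mean=np.zeros(m), cov=cov,
                                            allow_singular=True)
            lp = size * np.log(gamma) + (m - size) * np.log1p(-gamma)
            configs.append(C)
            logpost.append(ll + lp)
    logpost = np.array(logpost)
    post = np.exp(logpost - logpost.max())
    post /= post.sum()
    inclusion = np.zeros(m)
    for C, pr in zip(configs, post):
        for i in C:
            inclusion[i] += pr
    order = np.argsort(-inclusion)
    rho_set: list = []
    mass = 0.0
    for k in range(m + 1):
        chosen = set(order[:k])
        mass = sum(pr for C, pr in zip(configs, post) if set(C) <= chosen)
        rho_set = sorted(chosen)
        if mass >= rho:
            break
    return FinemapResult(
        configurations=configs,
        posteriors=post,
        inclusion=inclusion,
        rho_set=rho_set,
        rho=rho,
    )
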