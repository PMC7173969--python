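"""hapFLK: the FLK quadratic form applied to local haplotype-cluster
frequencies, with robust chi-square normalization, a label-permutation
genome-wide threshold, and tree-based attribution of the selected population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .datamodel import HaplotypeMatrix, PopulationMap, haplotype_index, allele_frequencies
from .flk import KinshipMatrix, kinship_from_tree, reynolds_matrix
from .haplotype_clusters import HaplotypeClusterModel

log = logging.getLogger(__name__)

DEGENERATE_EPS = 1e-8


@dataclass
class ScanPValues:
    """Per-position raw statistic, normalized statistic and p-value."""

    raw: np.ndarray
    normalized: np.ndarray
    pvalues: np.ndarray
    df: float
    scale: float
    threshold: float | None = None  # genome-wide permutation threshold on p


def population_frequencies(matrix: HaplotypeMatrix, hidx: dict, pops) -> np.ndarray:
    """Observed per-population ALT frequencies, (S, npop)."""
    cols = []
    for p in pops:
        f, _ = allele_frequencies(matrix, hidx[p])
        cols.append(f)
    return np.stack(cols, axis=1)


def kinship_from_matrix(
    matrix: HaplotypeMatrix, hidx: dict, pops, outgroup: str | None = None
) -> KinshipMatrix:
    """Reynolds distances on observed frequencies -> NJ tree -> kinship.

    `pops` should include the outgroup when one is given; it is used only
    for rooting and excluded from F.

    The tree's path lengths are doubled before use: the Reynolds coancestry
    distance between two independently drifted populations estimates
    (F_A + F_B)/2, so root-to-tip and root-to-MRCA path lengths are halves
    of the frequency variances/covariances the FLK quadratic form needs.
    Because the distances are computed on *sample* frequencies without a
    finite-sample correction, each population's binomial sampling noise is
    absorbed into its own tip branch and F stays the effective covariance
    of observed frequencies (keeping FLK calibrated at small sample sizes).
    """
    freqs = {p: population_frequencies(matrix, hidx, [p])[:, 0] for p in pops}
    kin = kinship_from_tree(reynolds_matrix(freqs), outgroup=outgroup)
    return KinshipMatrix(F=2.0 * kin.F, tree_newick=kin.tree_newick, rooting=kin.rooting)


def hapflk_statistic(cluster_freqs: np.ndarray, F: np.ndarray) -> np.ndarray:
    """hapFLK raw statistic per site from one fit's cluster frequencies.

    cluster_freqs is (S, K, npop). Each cluster's population-frequency
    vector goes through the FLK quadratic form; clusters sum, and the sum
    is halved: cluster frequencies sum to one, so a two-cluster model that
    mirrors a biallelic SNP counts the same deviation twice — the half
    makes that construction reduce exactly to per-SNP FLK (for K > 2 it is
    a constant scale, absorbed by the robust normalization). Degenerate
    clusters (ancestral frequency at 0 or 1) contribute 0.
    """
    S, K, npop = cluster_freqs.shape
    Fi = np.linalg.inv(F)
    w = Fi.sum(axis=0) / Fi.sum()
    p0 = np.einsum("skp,p->sk", cluster_freqs, w)
    d = cluster_freqs - p0[:, :, None]
    quad = np.einsum("skp,pq,skq->sk", d, Fi, d)
    var = p0 * (1 - p0)
    contrib = np.where(var > DEGENERATE_EPS, quad / np.maximum(var, DEGENERATE_EPS), 0.0)
    return contrib.sum(axis=1) / 2.0


def hapflk(
    model: HaplotypeClusterModel,
    matrix: HaplotypeMatrix,
    hidx: dict,
    kinship: KinshipMatrix,
) -> np.ndarray:
    """Raw hapFLK per site, averaged over the model's EM fits."""
    pops = kinship.populations
    F = kinship.values()
    stats = []
    for fit in model.fits:
        cf = model.cluster_frequencies(matrix, fit, hidx, pops)
        stats.append(hapflk_statistic(cf, F))
    return np.mean(stats, axis=0)


def normalize_and_pvalue(raw, min_sites: int = 1000, trim_top: float = 0.01) -> ScanPValues:
    """Robust-fit the genome-wide raw values to a scaled chi-square.

    Sorted raw values are regressed (statsmodels RLM, Huber) on chi-square
    theoretical quantiles; the degrees of freedom minimize the robust
    relative residual, the slope is the scale. The top `trim_top` order
    statistics are excluded from the fit so selected regions cannot drag
    the null. p-values come from the fitted chi-square.
    """
    raw = np.asarray(raw, dtype=float)
    ok = np.isfinite(raw)
    x = np.sort(raw[ok])
    n = len(x)
    if n < min_sites:
        raise ValueError(f"need >= {min_sites} positions to normalize, got {n}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad <= 0:
        raise ValueError("zero robust scale: raw statistics are degenerate")
    q = (np.arange(1, n + 1) - 0.5) / n
    hi = int(np.floor(n * (1 - trim_top)))
    xs, qs = x[:hi], q[:hi]

    def objective(logdf):
        df = np.exp(logdf)
        tq = chi2.ppf(qs, df)
        fit = sm.RLM(xs, tq[:, None], M=sm.robust.norms.HuberT()).fit()
        slope = float(fit.params[0])
        if slope <= 0:
            return np.inf
        return float(np.median(np.abs(xs - slope * tq)) / slope)

    # crude df guess from robust moments of a chi-square: median ~ df - 2/3
    df0 = max(med, 0.5)
    res = minimize_scalar(
        objective,
        bounds=(np.log(max(df0 / 20, 0.1)), np.log(df0 * 20 + 10)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    df = float(np.exp(res.x))
    tq = chi2.ppf(qs, df)
    slope = float(sm.RLM(xs, tq[:, None], M=sm.robust.norms.HuberT()).fit().params[0])
    normalized = np.full_like(raw, np.nan)
    normalized[ok] = raw[ok] / slope
    pvals = np.full_like(raw, np.nan)
    pvals[ok] = np.maximum(chi2.sf(normalized[ok], df), np.finfo(float).tiny)
    return ScanPValues(raw=raw, normalized=normalized, pvalues=pvals, df=df, scale=slope)


def hapflk_scan(
    matrix: HaplotypeMatrix,
    popmap: PopulationMap,
    model: HaplotypeClusterModel,
    outgroup: str | None = None,
    min_sites: int = 1000,
) -> ScanPValues:
    """Fit-free rescan: cluster model must already be fitted on `matrix`."""
    hidx = haplotype_index(matrix, popmap)
    pops = popmap.populations(include_outgroup=False)
    tree_pops = pops + ([outgroup] if outgroup else [])
    kin = kinship_from_matrix(matrix, hidx, tree_pops, outgroup=outgroup)
    raw = hapflk(model, matrix, hidx, kin)
    return normalize_and_pvalue(raw, min_sites=min_sites)


def permutation_threshold(
    matrix: HaplotypeMatrix,
    popmap: PopulationMap,
    model: HaplotypeClusterModel,
    n_perm: int = 100,
    seed: int | None = None,
    outgroup: str | None = None,
    min_sites: int = 1000,
):
    """Genome-wide p-value threshold from shuffled population labels.

    Individuals are permuted across populations (sizes preserved); the full
    hapFLK + normalization pipeline is recomputed per shuffle (the cluster
    model is label-free and is reused); the threshold is the 5th percentile
    of the per-shuffle minimum p-values.

    Returns (threshold, per-shuffle minimum p-values).
    """
    rng = np.random.default_rng(seed)
    mins = []
    for _ in range(n_perm):
        shuffled = popmap.shuffled(rng)
        scan = hapflk_scan(
            matrix, shuffled, model, outgroup=outgroup, min_sites=min_sites
        )
        mins.append(float(np.nanmin(scan.pvalues)))
    mins = np.array(mins)
    # lower-order percentile: E[F(X_(k))] = k/(n+1) keeps the family-wise
    # error near 5% at any n_perm (interpolation would inflate it when
    # n_perm is small)
    return float(np.percentile(mins, 5, method="lower")), mins


@dataclass
class PopulationAssignment:
    """Outcome of the local-vs-global branch-length comparison."""

    populations: list  # selected population(s); empty if no positive excess
    excess: dict  # per-population local-minus-global terminal branch length
    tied: bool
    low_confidence: bool


def _terminal_branch_lengths(distances) -> dict:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    pops = list(distances.index)
    tree = nj(DistanceMatrix(distances.to_numpy(), ids=pops))
    out = {}
    for tip in tree.tips():
        out[tip.name] = max(float(tip.length or 0.0), 0.0)
    return out


def assign_selected_population(
    matrix: HaplotypeMatrix,
    hidx: dict,
    pops,
    region_sites,
    rel_tol: float = 0.05,
) -> PopulationAssignment:
    """Which population shows selection in a region: the one whose terminal
    branch in the region-restricted NJ tree exceeds its genome-wide branch
    the most. Ties (within `rel_tol` of the top excess) are all reported.
    """
    region_sites = np.asarray(region_sites)
    low_confidence = False
    if len(region_sites) < 10:
        warnings.warn("region has <10 SNPs: population assignment is low-confidence")
        low_confidence = True
    freqs_global = {p: allele_frequencies(matrix, hidx[p])[0] for p in pops}
    local = matrix.take_sites(region_sites)
    freqs_local = {p: allele_frequencies(local, hidx[p])[0] for p in pops}
    glob = _terminal_branch_lengths(reynolds_matrix(freqs_global))
    loc = _terminal_branch_lengths(reynolds_matrix(freqs_local))
    excess = {p: loc[p] - glob[p] for p in pops}
    top = max(excess.values())
    if top <= 0:
        return PopulationAssignment([], excess, tied=False, low_confidence=low_confidence)
    winners = [p for p, v in excess.items() if v >= top - rel_tol * abs(top)]
    return PopulationAssignment(
        sorted(winners, key=lambda p: -excess[p]),
        excess,
        tied=len(winners) > 1,
        low_confidence=low_confidence,
    )
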