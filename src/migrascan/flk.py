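"""FLK: frequency differentiation tested against a hierarchical-drift null.

The kinship matrix F captures how much drift each population accumulated
since the common ancestor (diagonal) and how much of it is shared through
the population tree (off-diagonal). It is built from Reynolds distances via
neighbour joining, rooted on an outgroup when available and at the midpoint
otherwise: F_ii is the root-to-tip path length, F_ij the root-to-MRCA path.

The Reynolds distance used here is the coancestry distance on observed
sample frequencies, d = sum_l (p1-p2)^2 / sum_l (p1+p2-2*p1*p2), without a
finite-sample correction: the sampling variance of each population's
frequencies is then absorbed into its own tip branch, so F is the effective
covariance of the *observed* frequencies and the FLK chi-square reference
stays calibrated at small sample sizes (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from skbio import DistanceMatrix
from skbio.tree import nj

log = logging.getLogger(__name__)


def reynolds_distance(p1, p2) -> float:
    """Reynolds coancestry distance between two allele-frequency vectors,
    averaged over sites as a ratio of sums. NaN sites are skipped."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ok = ~(np.isnan(p1) | np.isnan(p2))
    if not ok.any():
        raise ValueError("no shared sites between populations")
    p1, p2 = p1[ok], p2[ok]
    num = np.sum((p1 - p2) ** 2)
    den = np.sum(p1 + p2 - 2 * p1 * p2)
    if den == 0:
        return 0.0
    return float(num / den)


def reynolds_matrix(freqs: dict) -> pd.DataFrame:
    """Pairwise Reynolds distances from {population: frequency vector}."""
    pops = list(freqs)
    d = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = reynolds_distance(freqs[a], freqs[b])
            d.loc[a, b] = d.loc[b, a] = v
    return d


@dataclass
class KinshipMatrix:
    """Population co-drift matrix F with its source tree and rooting record."""

    F: pd.DataFrame
    tree_newick: str
    rooting: str  # "outgroup:<name>" or "midpoint"

    @property
    def populations(self):
        return list(self.F.index)

    def values(self) -> np.ndarray:
        return self.F.to_numpy()


def kinship_from_tree(distances: pd.DataFrame, outgroup: str | None = None) -> KinshipMatrix:
    """NJ tree on Reynolds distances -> kinship matrix F.

    Negative NJ branch lengths are truncated to zero (warned). When an
    outgroup is named, the tree is rooted at its attachment point and the
    outgroup is dropped from F; otherwise midpoint rooting is used.
    """
    pops = list(distances.index)
    if len(pops) < 3:
        raise ValueError("kinship needs at least 3 populations in the tree")
    dm = DistanceMatrix(distances.to_numpy(), ids=pops)
    tree = nj(dm)
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"truncated {n_neg} negative NJ branch lengths to 0")
    if outgroup is not None:
        if outgroup not in pops:
            raise KeyError(f"outgroup {outgroup!r} not among populations")
        og = tree.find(outgroup)
        tree = tree.root_at(og.parent)
        keep = [p for p in pops if p != outgroup]
        rooting = f"outgroup:{outgroup}"
    else:
        tree = tree.root_at_midpoint()
        keep = pops
        rooting = "midpoint"
    root = tree.root()
    d_root = {p: root.distance(tree.find(p)) for p in keep}
    F = pd.DataFrame(0.0, index=keep, columns=keep)
    for i, a in enumerate(keep):
        F.loc[a, a] = d_root[a]
        for b in keep[i + 1 :]:
            tip = tree.find(a).distance(tree.find(b))
            shared = max(0.0, (d_root[a] + d_root[b] - tip) / 2)
            F.loc[a, b] = F.loc[b, a] = shared
    return KinshipMatrix(F=F, tree_newick=str(tree).strip(), rooting=rooting)


def flk_values(P: np.ndarray, F: np.ndarray):
    """Vectorized FLK over sites.

    P is (S, npop) of per-population allele frequencies. Returns
    (statistic, p_value) arrays; sites where the estimated ancestral
    frequency hits 0 or 1 (or any frequency is missing) are NaN.

    FLK = (p - p0*1)' [p0(1-p0) F]^-1 (p - p0*1), with
    p0 = (1'F^-1 p)/(1'F^-1 1), referred to chi-square(npop - 1).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    F = np.asarray(F, dtype=float)
    npop = F.shape[0]
    if P.shape[1] != npop:
        raise ValueError("frequency matrix and kinship dimension mismatch")
    Fi = np.linalg.inv(F)
    w = Fi.sum(axis=0) / Fi.sum()
    p0 = P @ w
    d = P - p0[:, None]
    quad = np.einsum("sp,pq,sq->s", d, Fi, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = quad / (p0 * (1 - p0))
    bad = (
        np.isnan(P).any(axis=1)
        | ~np.isfinite(p0)
        | (p0 <= 0)
        | (p0 >= 1)
    )
    stat = np.where(bad, np.nan, stat)
    pval = chi2.sf(stat, df=npop - 1)
    return stat, pval


def flk(p, kinship: KinshipMatrix):
    """FLK statistic and chi-square p-value for a single site's frequency
    vector (ordered as kinship.populations)."""
    stat, pval = flk_values(np.asarray(p, dtype=float)[None, :], kinship.values())
    return float(stat[0]), float(pval[0])
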