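"""nSL: haplotype-length decay measured in segregating sites.

For a focal site, SL_A is the mean — over all pairs of haplotypes carrying
the ancestral allele — of the number of segregating sites spanned by the
maximal interval around the focal site on which the two haplotypes are
identical (inclusive of both boundary sites, truncated at scaffold ends and
at missing data); SL_D is the same over derived-allele carriers, and
raw nSL = ln(SL_A / SL_D). Long shared haplotypes around a recently swept
derived allele push nSL negative. Raw scores are standardized within
derived-allele-frequency bins, and windows are summarized by the maximum
absolute standardized score.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from itertools import combinations

from .datamodel import MISSING, HaplotypeMatrix, WindowTable
from .polarize import AncestralCalls

log = logging.getLogger(__name__)


def pairwise_sl(alleles_a, alleles_b, site: int):
    """Identity-interval length (in segregating sites, inclusive) around
    `site` for one haplotype pair; None if the pair differs or is missing
    at the focal site. Missing data truncates the interval."""
    a = np.asarray(alleles_a)
    b = np.asarray(alleles_b)
    if a[site] == MISSING or b[site] == MISSING or a[site] != b[site]:
        return None
    brk = np.flatnonzero((a != b) | (a == MISSING) | (b == MISSING))
    j = np.searchsorted(brk, site)
    left = brk[j - 1] if j > 0 else -1
    right = brk[j] if j < len(brk) else len(a)
    return int(right - left - 1)


def _pair_interval_lengths(a, b):
    """Vectorized identity-interval length at every site for one pair.

    Returns (lengths (S,), valid (S,) bool): valid where the pair is
    identical and non-missing at the focal site.
    """
    S = len(a)
    diff = (a != b) | (a == MISSING) | (b == MISSING)
    brk = np.flatnonzero(diff)
    if len(brk) == 0:
        return np.full(S, S, dtype=np.int64), ~diff
    idx = np.searchsorted(brk, np.arange(S), side="left")
    left = np.where(idx > 0, brk[np.maximum(idx - 1, 0)], -1)
    right = np.where(idx < len(brk), brk[np.minimum(idx, max(len(brk) - 1, 0))], S)
    lengths = right - left - 1
    return lengths, ~diff


def nsl_scores(
    matrix: HaplotypeMatrix,
    calls: AncestralCalls,
    rows,
) -> pd.DataFrame:
    """Per-site nSL for the haplotypes in `rows` (one population).

    Only polarized sites get scores; a site needs >= 2 haplotypes in both
    allele classes. Scaffolds are scanned independently.
    """
    rows = np.asarray(rows)
    dval = calls.derived_value()
    out = pd.DataFrame(
        {
            "scaffold": matrix.scaffold,
            "pos": matrix.positions,
            "daf": np.nan,
            "sl_a": np.nan,
            "sl_d": np.nan,
            "nsl_raw": np.nan,
        }
    )
    for scaf in matrix.scaffolds():
        sites = np.flatnonzero(matrix.scaffold == scaf)
        sub = matrix.alleles[np.ix_(rows, sites)]
        dv = dval[sites]
        H, S = sub.shape
        sum_a = np.zeros(S)
        cnt_a = np.zeros(S)
        sum_d = np.zeros(S)
        cnt_d = np.zeros(S)
        for i, j in combinations(range(H), 2):
            lengths, valid = _pair_interval_lengths(sub[i], sub[j])
            anc = valid & (dv >= 0) & (sub[i] == (1 - dv)) & (sub[j] == (1 - dv))
            der = valid & (dv >= 0) & (sub[i] == dv) & (sub[j] == dv)
            sum_a[anc] += lengths[anc]
            cnt_a[anc] += 1
            sum_d[der] += lengths[der]
            cnt_d[der] += 1
        ok_missing = sub != MISSING
        n_obs = ok_missing.sum(axis=0)
        n_der = ((sub == dv[None, :]) & ok_missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            daf = np.where((dv >= 0) & (n_obs > 0), n_der / np.maximum(n_obs, 1), np.nan)
            sl_a = np.where(cnt_a > 0, sum_a / np.maximum(cnt_a, 1), np.nan)
            sl_d = np.where(cnt_d > 0, sum_d / np.maximum(cnt_d, 1), np.nan)
            raw = np.where(
                (n_der >= 2) & (n_obs - n_der >= 2) & (cnt_a > 0) & (cnt_d > 0),
                np.log(sl_a / sl_d),
                np.nan,
            )
        out.loc[sites, "daf"] = daf
        out.loc[sites, "sl_a"] = sl_a
        out.loc[sites, "sl_d"] = sl_d
        out.loc[sites, "nsl_raw"] = raw
    return out


def standardize_nsl(
    scores: pd.DataFrame, bin_width: float = 0.02, min_sites: int = 50
) -> pd.DataFrame:
    """Standardize raw nSL within derived-frequency bins (mean 0, sd 1).

    Bins with fewer than `min_sites` scored sites are merged with their
    right neighbour (leftover tail merges leftward). Zero-variance bins
    yield missing scores with a warning.
    """
    out = scores.copy()
    out["nsl_std"] = np.nan
    ok = out["nsl_raw"].notna() & out["daf"].notna()
    if not ok.any():
        return out
    daf = out.loc[ok, "daf"].to_numpy()
    raw = out.loc[ok, "nsl_raw"].to_numpy()
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    bin_id = np.clip(np.digitize(daf, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins rightward
    ids = np.unique(bin_id)
    merged = {}
    group, size = [], 0
    gid = 0
    for b in ids:
        group.append(b)
        size += int(np.sum(bin_id == b))
        if size >= min_sites:
            for g in group:
                merged[g] = gid
            gid += 1
            group, size = [], 0
    if group:  # leftover tail joins the previous group
        tail_gid = max(gid - 1, 0)
        for g in group:
            merged[g] = tail_gid
    grp = np.array([merged[b] for b in bin_id])
    z = np.full(len(raw), np.nan)
    for g in np.unique(grp):
        sel = grp == g
        mu = raw[sel].mean()
        sd = raw[sel].std()
        if sd == 0:
            warnings.warn("zero-variance nSL frequency bin: scores set missing")
            continue
        z[sel] = (raw[sel] - mu) / sd
    out.loc[ok, "nsl_std"] = z
    return out


def window_summarize_nsl(
    scores: pd.DataFrame, windows: WindowTable, reduction: str = "max_abs"
) -> np.ndarray:
    """Per-window summary of standardized nSL (default: max |score|)."""
    vals = np.full(len(windows), np.nan)
    key = {
        (row.scaffold, row.start): i
        for i, row in enumerate(windows.table.itertuples(index=False))
    }
    width = windows.width
    ok = scores["nsl_std"].notna()
    for scaf, pos, z in zip(
        scores.loc[ok, "scaffold"], scores.loc[ok, "pos"], scores.loc[ok, "nsl_std"]
    ):
        start = ((int(pos) - 1) // width) * width
        i = key.get((scaf, start))
        if i is None:
            continue
        v = abs(z) if reduction == "max_abs" else z
        if reduction == "max_abs":
            if np.isnan(vals[i]) or v > vals[i]:
                vals[i] = v
        elif reduction == "mean":
            vals[i] = v if np.isnan(vals[i]) else vals[i] + v
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
    if reduction == "mean":
        counts = np.zeros(len(windows))
        for scaf, pos in zip(scores.loc[ok, "scaffold"], scores.loc[ok, "pos"]):
            i = key.get((scaf, ((int(pos) - 1) // width) * width))
            if i is not None:
                counts[i] += 1
        vals = np.where(counts > 0, vals / np.maximum(counts, 1), np.nan)
    return vals
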