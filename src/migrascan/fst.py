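"""Windowed Hudson F_ST, generalized PBS, the dPBS linked-selection
correction, top-quantile region calling and island-replacement validation.

PBS here is the branch-length statistic built from log-transformed pairwise
F_ST, T = -ln(1 - F_ST). Two generalizations beyond three populations are
provided:

``as_printed``
    PBS = [sum_j T(focal, j) - sum of consecutive-pair T(j, j+1) over the
    non-focal list in its given order] / m, the published 4-population form
    (which omits the first-to-last cross term).
``mean_triplet``
    mean over all non-focal pairs {j, k} of the classic
    (T_fj + T_fk - T_jk)/2.

Both reduce to the classic 3-population PBS when there are two non-focal
populations.

dPBS subtracts, window by window, the maximum (optionally standardized) PBS
among the non-focal populations from the focal population's PBS: linked
selection elevates PBS in every population and cancels; population-specific
selection does not.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import (
    HaplotypeMatrix,
    RegionCall,
    WindowTable,
    allele_frequencies,
)

log = logging.getLogger(__name__)

T_EPS = 1e-6


def hudson_site_components(matrix: HaplotypeMatrix, rows_a, rows_b):
    """Per-site Hudson estimator numerator/denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites with fewer than 2 non-missing haplotypes in either population get
    NaN components.
    """
    p1, n1 = allele_frequencies(matrix, rows_a)
    p2, n2 = allele_frequencies(matrix, rows_b)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def window_fst(
    matrix: HaplotypeMatrix,
    hidx: dict,
    pop_a: str,
    pop_b: str,
    windows: WindowTable,
) -> pd.DataFrame:
    """Hudson F_ST per window, ratio of sums across the window's sites."""
    for p in (pop_a, pop_b):
        if p not in hidx:
            raise KeyError(f"unknown population label {p!r}")
    num, den = hudson_site_components(matrix, hidx[pop_a], hidx[pop_b])
    wix = windows.site_window(matrix)
    nwin = len(windows)
    num_sum = np.zeros(nwin)
    den_sum = np.zeros(nwin)
    ok = (wix >= 0) & ~np.isnan(num)
    np.add.at(num_sum, wix[ok], num[ok])
    np.add.at(den_sum, wix[ok], den[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den_sum > 0, num_sum / np.where(den_sum > 0, den_sum, 1), np.nan)
    out = windows.table.copy()
    out["num_sum"], out["den_sum"], out["fst"] = num_sum, den_sum, fst
    return out


def log_transform_T(fst):
    """T = -ln(1 - F_ST), with F_ST clamped to [0, 1-1e-6] first."""
    fst = np.asarray(fst, dtype=float)
    return -np.log1p(-np.clip(fst, 0.0, 1.0 - T_EPS))


def _pair_key(a, b):
    return (a, b) if a <= b else (b, a)


def pairwise_T(
    matrix: HaplotypeMatrix, hidx: dict, populations, windows: WindowTable
) -> dict:
    """T = -ln(1-F_ST) per window for every pair of the given populations."""
    out = {}
    for a, b in combinations(populations, 2):
        out[_pair_key(a, b)] = log_transform_T(
            window_fst(matrix, hidx, a, b, windows)["fst"].to_numpy()
        )
    return out


def pbs(T: dict, focal: str, nonfocal, mode: str = "as_printed") -> np.ndarray:
    """Per-window PBS for `focal` against the `nonfocal` list (order matters
    for `as_printed`: its omitted cross terms are keyed to consecutive pairs)."""
    nonfocal = list(nonfocal)
    m = len(nonfocal)
    if m < 2:
        raise ValueError("PBS needs at least two non-focal populations")
    if mode == "as_printed":
        acc = sum(T[_pair_key(focal, j)] for j in nonfocal)
        acc = acc - sum(
            T[_pair_key(nonfocal[k], nonfocal[k + 1])] for k in range(m - 1)
        )
        return acc / m
    if mode == "mean_triplet":
        vals = [
            (T[_pair_key(focal, j)] + T[_pair_key(focal, k)] - T[_pair_key(j, k)]) / 2
            for j, k in combinations(nonfocal, 2)
        ]
        return np.mean(vals, axis=0)
    raise ValueError(f"unknown PBS mode {mode!r}")


def _robust_z(x):
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0:
        raise ValueError("zero MAD: cannot robustly standardize PBS")
    return (x - med) / (mad / 0.6745)


def delta_pbs(pbs_by_pop: dict, focal: str, scaling: str = "none") -> np.ndarray:
    """dPBS = scaled PBS of focal minus max scaled PBS among the others.

    All populations' PBS vectors must be on identical (orthologous) windows.
    scaling: 'none' or 'zscore' (robust per-population standardization).
    """
    lengths = {len(np.asarray(v)) for v in pbs_by_pop.values()}
    if len(lengths) != 1:
        raise ValueError("PBS window sets differ across populations")
    if focal not in pbs_by_pop:
        raise KeyError(f"focal population {focal!r} has no PBS vector")
    if scaling == "none":
        scaled = {p: np.asarray(v, dtype=float) for p, v in pbs_by_pop.items()}
    elif scaling == "zscore":
        scaled = {p: _robust_z(np.asarray(v, dtype=float)) for p, v in pbs_by_pop.items()}
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    others = [scaled[p] for p in pbs_by_pop if p != focal]
    if not others:
        raise ValueError("dPBS needs at least one non-focal population")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        other_max = np.nanmax(np.stack(others), axis=0)
    return scaled[focal] - other_max


def pbs_scan(
    matrix: HaplotypeMatrix,
    hidx: dict,
    windows: WindowTable,
    focal: str,
    nonfocal,
    mode: str = "as_printed",
    scaling: str = "none",
) -> pd.DataFrame:
    """Full scan: PBS for focal and for each non-focal population as focal
    in turn (on identical windows), plus dPBS for the focal population."""
    nonfocal = list(nonfocal)
    pops = [focal] + nonfocal
    T = pairwise_T(matrix, hidx, pops, windows)
    pbs_by_pop = {
        p: pbs(T, p, [q for q in pops if q != p], mode=mode) for p in pops
    }
    out = windows.table.copy()
    for p in pops:
        out[f"pbs_{p}"] = pbs_by_pop[p]
    out["delta_pbs"] = delta_pbs(pbs_by_pop, focal, scaling=scaling)
    return out


def call_regions(
    windows: WindowTable,
    values,
    statistic: str,
    population: str,
    quantile: float = 0.99,
) -> list:
    """Merge adjacent windows above the empirical `quantile` threshold.

    Windows must strictly exceed the threshold (at quantile 0 the bound is
    inclusive so the degenerate call spans each scaffold). Each region
    reports its peak window value.
    """
    values = np.asarray(values, dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("statistic is missing in every window")
    if np.sum(~np.isnan(values)) < 100:
        warnings.warn("fewer than 100 windows: quantile threshold is unstable")
    thr = float(np.nanquantile(values, quantile))
    above = values >= thr if quantile == 0 else values > thr
    above &= ~np.isnan(values)
    tbl = windows.table
    regions = []
    i = 0
    while i < len(tbl):
        if not above[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(tbl)
            and above[j + 1]
            and tbl.scaffold.iloc[j + 1] == tbl.scaffold.iloc[i]
            and tbl.start.iloc[j + 1] == tbl.end.iloc[j]
        ):
            j += 1
        member = list(range(i, j + 1))
        regions.append(
            RegionCall(
                scaffold=tbl.scaffold.iloc[i],
                start=int(tbl.start.iloc[i]),
                end=int(tbl.end.iloc[j]),
                statistic=statistic,
                population=population,
                peak_value=float(np.nanmax(values[member])),
                windows=member,
            )
        )
        i = j + 1
    return regions


def island_replacement_pbs(
    matrix: HaplotypeMatrix,
    hidx: dict,
    windows: WindowTable,
    island: str,
    nonfocal,
    regions,
    mode: str = "as_printed",
    scaling: str = "none",
    quantile: float = 0.99,
):
    """Re-run the PBS scan with an island population as focal and report
    which previously called regions fall in the island's top quantile.

    Returns (scan table, {region index: recaptured bool}).
    """
    tbl = pbs_scan(matrix, hidx, windows, island, nonfocal, mode=mode, scaling=scaling)
    vals = tbl[f"pbs_{island}"].to_numpy()
    thr = float(np.nanquantile(vals, quantile))
    recaptured = {}
    for k, reg in enumerate(regions):
        recaptured[k] = bool(np.any(vals[reg.windows] > thr))
    return tbl, recaptured
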