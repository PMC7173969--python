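"""Relative cross-coalescence rate (rCCR) from recorded genealogies.

For two populations, per time bin, the coalescence rate is the span-weighted
number of sample-pair coalescences in the bin divided by the pair mass still
uncoalesced at the bin's start (a discrete hazard). The relative
cross-coalescence rate divides the between-population rate by the average of
the two within-population rates: ~1 under panmixia, ~0 long after a clean
split. The 0.5-crossing dates the population separation; the most recent
rise above the curve's minimum dates secondary contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


def default_time_bins(t_min: float = 200.0, t_max: float = 1.2e6, n: int = 21):
    """Log-spaced bin edges in generations, padded with [0, .) and (., inf)."""
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n), [np.inf]])


@dataclass
class CcrCurve:
    """Binned within/between coalescence rates and their ratio."""

    bin_edges: np.ndarray  # generations, length B+1
    rate_within_a: np.ndarray
    rate_within_b: np.ndarray
    rate_between: np.ndarray
    rccr: np.ndarray  # NaN where under-populated
    generation_time: float
    pop_a: str
    pop_b: str

    @property
    def bin_edges_years(self) -> np.ndarray:
        return self.bin_edges * self.generation_time


def _hazard(counts: np.ndarray, widths: np.ndarray, min_at_risk: float):
    total = counts.sum()
    at_risk = total - np.concatenate([[0.0], np.cumsum(counts)[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(at_risk > min_at_risk * total, counts / at_risk, np.nan)
    return h / widths


def relative_ccr(
    bundle,
    pop_a: str,
    pop_b: str,
    bin_edges: np.ndarray | None = None,
    min_at_risk: float = 0.01,
    samples_a=None,
    samples_b=None,
) -> CcrCurve:
    """rCCR between two populations from the bundle's tree sequences.

    Pair-coalescence counts are pooled over scaffolds (span-weighted).
    Bins where the surviving pair mass falls below `min_at_risk` of the
    total are reported as missing. Sample nodes are looked up by population
    name unless explicit node-id lists `samples_a`/`samples_b` (shared
    across scaffolds) are given.
    """
    if bin_edges is None:
        bin_edges = default_time_bins()
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros((3, len(bin_edges) - 1))
    for ts in bundle.tree_sequences:
        if samples_a is not None and samples_b is not None:
            sets = [list(samples_a), list(samples_b)]
        else:
            name_to_id = {
                p.metadata.get("name", str(p.id)): p.id for p in ts.populations()
            }
            sets = []
            for pop in (pop_a, pop_b):
                if pop not in name_to_id:
                    raise KeyError(f"population {pop!r} not in tree sequence")
                s = ts.samples(population=name_to_id[pop])
                if len(s) == 0:
                    raise ValueError(f"no samples recorded for population {pop!r}")
                sets.append(list(s))
        c = ts.pair_coalescence_counts(
            sample_sets=sets,
            indexes=[(0, 0), (1, 1), (0, 1)],
            time_windows=bin_edges,
            span_normalise=False,
            pair_normalise=False,
        )
        counts += np.asarray(c)
    widths = np.diff(bin_edges)
    h_a = _hazard(counts[0], widths, min_at_risk)
    h_b = _hazard(counts[1], widths, min_at_risk)
    h_ab = _hazard(counts[2], widths, min_at_risk)
    with np.errstate(invalid="ignore", divide="ignore"):
        rccr = h_ab / (0.5 * (h_a + h_b))
    return CcrCurve(
        bin_edges=bin_edges,
        rate_within_a=h_a,
        rate_within_b=h_b,
        rate_between=h_ab,
        rccr=rccr,
        generation_time=bundle.params.generation_time,
        pop_a=pop_a,
        pop_b=pop_b,
    )


def estimate_split_time(curve: CcrCurve):
    """Date of population separation: the most ancient upward 0.5-crossing.

    Scanning from the present to the past, the crossing is placed at the
    recent edge of the first bin at or above 0.5 (so a step curve that
    jumps at a bin edge is dated exactly at that edge).

    Returns (generations, years); None if the curve never crosses 0.5.
    """
    r = curve.rccr
    edges = curve.bin_edges
    crossing = None
    for i in range(1, len(r)):
        if np.isnan(r[i]) or np.isnan(r[i - 1]):
            continue
        if r[i - 1] < 0.5 <= r[i]:
            crossing = edges[i]
    if crossing is None:
        log.warning("rCCR never crosses 0.5: split time undefined")
        return None
    return float(crossing), float(crossing * curve.generation_time)


def estimate_rise_onset(curve: CcrCurve, delta: float = 0.1):
    """Date of secondary contact: the most recent bin whose rCCR exceeds
    the curve's minimum by more than `delta` (its recent edge, scaled to
    years as well). Returns None when no bin qualifies."""
    r = curve.rccr
    finite = np.isfinite(r)
    if not finite.any():
        return None
    base = np.nanmin(r[finite])
    for i in range(len(r)):
        if finite[i] and r[i] > base + delta:
            t = curve.bin_edges[i]
            return float(t), float(t * curve.generation_time)
    return None
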