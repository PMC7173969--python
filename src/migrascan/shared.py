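"""Shared-variation diagnostics.

Three small tools used to ask whether a swept region draws on standing
variation: the count of derived alleles a haplotype carries relative to the
polarized ancestral sequence, a comparison of a region's unfolded SFS
against same-length random regions (selection on standing variation leaves
an excess of mid-frequency derived alleles), and exact IUPAC-degenerate
motif scanning on both strands.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, HaplotypeMatrix
from .polarize import AncestralCalls, unfolded_sfs

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def haplotype_ancestral_distance(matrix: HaplotypeMatrix, calls: AncestralCalls,
                                 haplotype: int, region_sites):
    """Number of derived alleles the haplotype carries over the region.

    Returns (distance, n_skipped) where n_skipped counts region sites that
    were undetermined or missing in the haplotype.
    """
    region_sites = np.asarray(region_sites)
    dval = calls.derived_value()[region_sites]
    h = matrix.alleles[haplotype, region_sites]
    usable = (dval >= 0) & (h != MISSING)
    distance = int(np.sum(h[usable] == dval[usable]))
    return distance, int(np.sum(~usable))


def region_sites(matrix: HaplotypeMatrix, scaffold: str, start: int, end: int):
    """Site indices whose 0-based position falls in [start, end)."""
    pos0 = matrix.positions - 1
    return np.flatnonzero((matrix.scaffold == scaffold) & (pos0 >= start) & (pos0 < end))


@dataclass
class RegionSfsNull:
    focal_stat: float
    null_stats: np.ndarray
    empirical_p: float
    percentile: float  # focal stat's percentile within the null ensemble


def region_sfs_comparison(
    matrix: HaplotypeMatrix,
    calls: AncestralCalls,
    rows,
    scaffold: str,
    start: int,
    end: int,
    n_random: int = 1000,
    seed: int | None = None,
    scaffold_lengths: dict | None = None,
    masks=(),
) -> RegionSfsNull:
    """Mid-frequency SFS mass of a region vs same-length random regions.

    Random regions are placed uniformly over the scaffolds (excluding the
    focal region and any (scaffold, start, end) masks); the summary per SFS
    is the fraction of polarized segregating sites at derived count in
    [0.25*2N, 0.75*2N]. The empirical p is the focal statistic's rank among
    the ensemble: p = (1 + #{null >= focal}) / (n_random + 1).
    """
    rng = np.random.default_rng(seed)
    rows = np.asarray(rows)
    length = end - start
    lengths = {}
    for scaf in matrix.scaffolds():
        L = (
            int(scaffold_lengths[scaf])
            if scaffold_lengths
            else int(matrix.positions[matrix.scaffold == scaf].max())
        )
        if L >= length:
            lengths[scaf] = L
    if not lengths:
        raise ValueError("no scaffold is long enough to place random regions")
    exclude = [(scaffold, start, end)] + list(masks)

    def overlaps(scaf, s, e):
        return any(scaf == m[0] and s < m[2] and e > m[1] for m in exclude)

    focal = unfolded_sfs(matrix, calls, rows, region_sites(matrix, scaffold, start, end))
    focal_stat = focal.mid_frequency_mass()
    scafs = list(lengths)
    weights = np.array([lengths[s] - length + 1 for s in scafs], dtype=float)
    weights /= weights.sum()
    null = []
    attempts = 0
    while len(null) < n_random:
        attempts += 1
        if attempts > 50 * n_random:
            raise ValueError("genome too short to place the random regions")
        scaf = scafs[rng.choice(len(scafs), p=weights)]
        s = int(rng.integers(0, lengths[scaf] - length + 1))
        if overlaps(scaf, s, s + length):
            continue
        sfs = unfolded_sfs(matrix, calls, rows, region_sites(matrix, scaf, s, s + length))
        stat = sfs.mid_frequency_mass()
        null.append(stat if np.isfinite(stat) else 0.0)
    null = np.array(null)
    emp_p = (1 + np.sum(null >= focal_stat)) / (n_random + 1)
    pct = 100.0 * np.mean(null < focal_stat)
    return RegionSfsNull(
        focal_stat=float(focal_stat),
        null_stats=null,
        empirical_p=float(emp_p),
        percentile=float(pct),
    )


def _motif_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_iupac_motif(sequence: str, motif: str):
    """Exact IUPAC-degenerate matches on both strands.

    Returns a list of (start, strand) with 0-based forward-strand start
    coordinates; overlapping matches are reported.
    """
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in _motif_regex(motif).finditer(seq)]
    rc = _motif_regex(reverse_complement(motif))
    hits += [(m.start(), "-") for m in rc.finditer(seq)]
    return sorted(hits)
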