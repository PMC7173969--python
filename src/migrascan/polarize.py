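"""Ancestral-allele calling from two outgroup species and unfolded SFS.

The polarization rule: an allele is ancestral when both outgroup species are
homozygous for it and it matches REF or ALT; every other configuration
(heterozygous outgroup, third allele, disagreeing homozygotes, missing
outgroup) leaves the site undetermined with a recorded reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .datamodel import MISSING, HaplotypeMatrix, PopulationMap, haplotype_index

log = logging.getLogger(__name__)

REASONS = ("none", "outgroup_heterozygous", "triallelic", "outgroup_missing")


@dataclass
class AncestralCalls:
    """Per-site ancestral allele ('ref', 'alt' or 'undetermined') + reason."""

    ancestral: np.ndarray
    reason: np.ndarray

    def __post_init__(self):
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        self.reason = np.asarray(self.reason, dtype=object)
        und = self.ancestral == "undetermined"
        if not np.array_equal(und, self.reason != "none"):
            raise ValueError("undetermined iff exclusion reason is set")

    @property
    def determined(self) -> np.ndarray:
        return self.ancestral != "undetermined"

    def take(self, index) -> "AncestralCalls":
        index = np.asarray(index)
        return AncestralCalls(self.ancestral[index], self.reason[index])

    def derived_value(self) -> np.ndarray:
        """Per-site 0/1 value of the *derived* allele (-1 where undetermined)."""
        out = np.full(len(self.ancestral), -1, dtype=np.int8)
        out[self.ancestral == "ref"] = 1  # ALT is derived
        out[self.ancestral == "alt"] = 0
        return out


def call_ancestral_site(outgroup1, outgroup2, ref, alt):
    """Call one site from the base-space alleles of two outgroup species.

    `outgroup1`/`outgroup2` are iterables of non-missing base strings (any
    number of individuals per species; a species is homozygous iff all its
    non-missing alleles are identical). Returns (ancestral, reason).
    """
    a1 = {str(b).upper() for b in outgroup1 if b not in (None, ".", "N", "")}
    a2 = {str(b).upper() for b in outgroup2 if b not in (None, ".", "N", "")}
    if not a1 or not a2:
        return "undetermined", "outgroup_missing"
    if len(a1) > 1 or len(a2) > 1:
        return "undetermined", "outgroup_heterozygous"
    b1, b2 = next(iter(a1)), next(iter(a2))
    if b1 != b2 or b1 not in (str(ref).upper(), str(alt).upper()):
        # disagreeing homozygotes or a third base both count as triallelic
        return "undetermined", "triallelic"
    return ("ref" if b1 == str(ref).upper() else "alt"), "none"


def call_ancestral(matrix: HaplotypeMatrix, popmap: PopulationMap) -> AncestralCalls:
    """Polarize every site using outgroup samples carried in the matrix.

    Each outgroup *population* in the map is treated as one species; exactly
    two are required. Outgroup alleles are read off the 0/1 matrix through
    ref_alt, so the possible outcomes here are ref/alt homozygosity,
    heterozygosity or missingness (a genuinely triallelic record would have
    been skipped on read).
    """
    og_pops = popmap.outgroup_populations()
    if len(og_pops) != 2:
        raise ValueError(
            f"need exactly two outgroup species (populations), got {og_pops}"
        )
    hidx = haplotype_index(matrix, popmap)
    anc = np.empty(matrix.n_sites, dtype=object)
    reason = np.empty(matrix.n_sites, dtype=object)
    sub = [matrix.alleles[hidx[p]] for p in og_pops]
    for j in range(matrix.n_sites):
        ref, alt = matrix.ref_alt[j]
        base = {0: str(ref), 1: str(alt)}
        species = [
            [base[int(a)] for a in s[:, j] if a != MISSING] for s in sub
        ]
        anc[j], reason[j] = call_ancestral_site(species[0], species[1], ref, alt)
    return AncestralCalls(anc, reason)


def call_ancestral_from_fasta(matrix: HaplotypeMatrix, seqs1: dict, seqs2: dict):
    """Polarize from per-species consensus sequences (scaffold -> sequence).

    Each FASTA base is treated as homozygous; 'N' as missing. Positions are
    1-based into the given sequences.
    """
    anc = np.empty(matrix.n_sites, dtype=object)
    reason = np.empty(matrix.n_sites, dtype=object)
    for j in range(matrix.n_sites):
        scaf, pos = matrix.scaffold[j], int(matrix.positions[j])
        ref, alt = matrix.ref_alt[j]
        picks = []
        for seqs in (seqs1, seqs2):
            s = seqs.get(scaf, "")
            picks.append([s[pos - 1]] if pos <= len(s) else [])
        anc[j], reason[j] = call_ancestral_site(picks[0], picks[1], ref, alt)
    return AncestralCalls(anc, reason)


@dataclass
class SFS:
    """Unfolded site-frequency spectrum: counts for derived classes 1..2N-1."""

    counts: np.ndarray
    n_haplotypes: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n_haplotypes - 1:
            raise ValueError("counts must cover derived classes 1..2N-1")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def n_segregating(self) -> float:
        return float(self.counts.sum())

    def mid_frequency_mass(self, lo: float = 0.25, hi: float = 0.75) -> float:
        """Fraction of segregating sites with derived count in [lo*2N, hi*2N]."""
        if self.n_segregating == 0:
            return np.nan
        i = np.arange(1, self.n_haplotypes)
        sel = (i >= lo * self.n_haplotypes) & (i <= hi * self.n_haplotypes)
        return float(self.counts[sel].sum() / self.n_segregating)


def unfolded_sfs(
    matrix: HaplotypeMatrix,
    calls: AncestralCalls,
    rows,
    site_index=None,
    project_to: int | None = None,
) -> SFS:
    """Unfolded SFS of the haplotypes in `rows` over `site_index` sites.

    Only polarized sites enter. Sites with missing haplotypes are dropped
    by default or projected down to `project_to` haplotypes by
    hypergeometric projection.
    """
    rows = np.asarray(rows)
    n = project_to if project_to is not None else len(rows)
    if site_index is None:
        site_index = np.arange(matrix.n_sites)
    site_index = np.asarray(site_index)
    if len(site_index) == 0:
        warnings.warn("unfolded_sfs: empty site set; returning all-zero SFS")
        return SFS(np.zeros(n - 1), n)
    dval = calls.derived_value()[site_index]
    sub = matrix.alleles[np.ix_(rows, site_index)]
    ok = sub != MISSING
    m = ok.sum(axis=0)
    alt_count = np.where(ok, sub, 0).sum(axis=0)
    # derived count depends on which allele is ancestral at the site
    d = np.where(dval == 1, alt_count, m - alt_count)
    counts = np.zeros(n - 1)
    for j in range(len(site_index)):
        if dval[j] < 0:
            continue
        if project_to is None:
            if m[j] < len(rows):
                continue
            if 0 < d[j] < n:
                counts[d[j] - 1] += 1
        else:
            if m[j] < project_to:
                continue
            # E[# derived in subsample of size n] spread hypergeometrically
            i = np.arange(1, n)
            counts += hypergeom.pmf(i, m[j], d[j], n)
    return SFS(counts, n)
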