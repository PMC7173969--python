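"""Coalescent generator for a blackcap-like study design.

Default demography: six populations (a constant-size continental resident,
three migrant populations growing two-fold since the split, two bottlenecked
island populations) splitting from a common ancestor 15,000 generations ago,
with one recent admixture pulse from the migrants into the residents
(backwards: resident lineages move into the first migrant population), plus
an optional distant outgroup used for ancestral-allele polarization. Rates:
mu = 3e-9 /gen/site, r = 1e-8, generation time 2 years. The outgroup split
is placed so that the *expected* ingroup-outgroup per-site divergence equals
`outgroup_divergence` (the ancestral-coalescence term 2*Ne_anc is subtracted
from d/(2*mu)).

Selective sweeps are injected by haplotype-block transplantation on the
simulated matrix: exactly controllable, fast, and it produces the
differentiation and haplotype-homozygosity signatures the scan statistics
target (the package tests detectors, not selection dynamics). A sweep never
fixes the region: at least one non-carrier haplotype always remains.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .datamodel import HaplotypeMatrix, PopulationMap
from .polarize import AncestralCalls

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass
class DemographyParams:
    """Parameters of the simulated study design (times in generations)."""

    samples_per_population: int = 5  # diploids
    ancestral_ne: float = 250_000
    resident_ne: float = 250_000
    migrant_ne_initial: float = 250_000
    migrant_ne_final: float = 500_000
    island_ne: float = 10_000
    split_time: float = 15_000
    admixture_time: float = 2_500
    admixture_fraction: float = 0.2
    mutation_rate: float = 3e-9
    recombination_rate: float = 1e-8
    generation_time: float = 2.0
    outgroup_divergence: float = 0.026
    include_outgroup: bool = True
    outgroup_samples: int = 1  # diploids per outgroup species
    outgroup2_split_factor: float = 2.0  # second species splits this much deeper
    scaffold_count: int = 10
    scaffold_length: int = 1_000_000
    resident_population: str = "resident_continent"
    migrant_populations: tuple = ("med_NW", "med_SW", "med_SE")
    island_populations: tuple = ("island_azores", "island_canary")
    seed: int | None = None

    def __post_init__(self):
        if self.split_time <= 0 or self.admixture_time <= 0:
            raise ValueError("all times must be positive")
        if self.admixture_time >= self.split_time:
            raise ValueError("admixture pulse must postdate the split")
        if not 0 < self.admixture_fraction < 1:
            raise ValueError("admixture fraction must be in (0,1)")
        if self.outgroup_split_time <= self.split_time:
            raise ValueError("outgroup split must predate the ingroup split")

    @property
    def outgroup_split_time(self) -> float:
        """Outgroup split placed so E[divergence] = outgroup_divergence."""
        return self.outgroup_divergence / (2 * self.mutation_rate) - 2 * self.ancestral_ne

    @property
    def populations(self):
        return (
            [self.resident_population]
            + list(self.migrant_populations)
            + list(self.island_populations)
        )

    def phenotype_class(self, pop: str) -> str:
        if pop == self.resident_population:
            return "resident_continent"
        if pop in self.migrant_populations:
            return pop
        if pop in self.island_populations:
            return pop
        return "outgroup"


@dataclass
class SimulationBundle:
    """Simulated haplotypes + truth record, the oracle for every scan."""

    matrix: HaplotypeMatrix
    popmap: PopulationMap
    ancestral: AncestralCalls
    tree_sequences: list
    params: DemographyParams
    truth: dict

    def write(self, prefix):
        """Export VCF + population map TSV + ancestral TSV + truth JSON."""
        from .vcfio import write_ancestral_table, write_vcf

        lengths = {s: self.params.scaffold_length for s in self.matrix.scaffolds()}
        write_vcf(self.matrix, f"{prefix}.vcf", scaffold_lengths=lengths)
        self.popmap.write_tsv(f"{prefix}.popmap.tsv")
        write_ancestral_table(self.matrix, self.ancestral, f"{prefix}.ancestral.tsv")
        with open(f"{prefix}.truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


def build_demography(params: DemographyParams) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name=params.resident_population, initial_size=params.resident_ne)
    growth = (
        np.log(params.migrant_ne_final / params.migrant_ne_initial) / params.split_time
    )
    for pop in params.migrant_populations:
        dem.add_population(
            name=pop, initial_size=params.migrant_ne_final, growth_rate=growth
        )
    for pop in params.island_populations:
        dem.add_population(name=pop, initial_size=params.island_ne)
    dem.add_population(name="anc_ingroup", initial_size=params.ancestral_ne)
    if params.include_outgroup:
        # two outgroup species: a sister (outgroup_sp1, the divergence
        # reference) and a deeper second species (outgroup_sp2), so the
        # double-homozygous polarization rule is robust to lineage sorting
        dem.add_population(name="outgroup_sp1", initial_size=params.ancestral_ne)
        dem.add_population(name="outgroup_sp2", initial_size=params.ancestral_ne)
        dem.add_population(name="anc_sister", initial_size=params.ancestral_ne)
        dem.add_population(name="root", initial_size=params.ancestral_ne)
    # the admixture pulse: forward-time migrant -> resident
    dem.add_mass_migration(
        time=params.admixture_time,
        source=params.resident_population,
        dest=params.migrant_populations[0],
        proportion=params.admixture_fraction,
    )
    dem.add_population_split(
        time=params.split_time, derived=params.populations, ancestral="anc_ingroup"
    )
    if params.include_outgroup:
        dem.add_population_split(
            time=params.outgroup_split_time,
            derived=["anc_ingroup", "outgroup_sp1"],
            ancestral="anc_sister",
        )
        dem.add_population_split(
            time=params.outgroup2_split_factor * params.outgroup_split_time,
            derived=["anc_sister", "outgroup_sp2"],
            ancestral="root",
        )
    dem.sort_events()
    return dem


def _population_map(params: DemographyParams, sample_ids) -> PopulationMap:
    records = []
    for sid in sample_ids:
        pop = sid.rsplit("_", 1)[0]
        if pop.startswith("outgroup"):
            records.append((sid, pop, "outgroup", None))
        else:
            code = {"short_SW": 1, "long_SE": 3}.get(params.phenotype_class(pop))
            records.append(
                (sid, pop, params.phenotype_class(pop), code if code else 2)
            )
    return PopulationMap.from_records(records)


def simulate(params: DemographyParams, mutate: bool = True) -> SimulationBundle:
    """Seeded, reproducible simulation of the full study design.

    Exports nothing by itself; use SimulationBundle.write(). With
    mutate=False only genealogies are generated (enough for coalescence-rate
    work) and the haplotype matrix is empty.
    """
    rng = np.random.default_rng(params.seed)
    dem = build_demography(params)
    samples = {p: params.samples_per_population for p in params.populations}
    if params.include_outgroup:
        samples["outgroup_sp1"] = params.outgroup_samples
        samples["outgroup_sp2"] = params.outgroup_samples

    sample_ids = []
    for pop, n in samples.items():
        sample_ids += [f"{pop}_{i}" for i in range(n)]

    tree_seqs = []
    all_alleles, all_pos, all_scaf, all_ref_alt, all_anc = [], [], [], [], []
    for k in range(params.scaffold_count):
        a_seed, m_seed = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=params.scaffold_length,
            recombination_rate=params.recombination_rate,
            random_seed=int(a_seed),
        )
        if mutate:
            ts = msprime.sim_mutations(
                ts,
                rate=params.mutation_rate,
                model=msprime.BinaryMutationModel(),
                random_seed=int(m_seed),
            )
            scaf = f"scaffold_{k+1}"
            G = ts.genotype_matrix()  # sites x haplotypes, 0 = ancestral
            pos = ts.sites_position.astype(np.int64) + 1
            # unique integer positions only (finite-sites collisions dropped)
            keep = np.flatnonzero(np.concatenate([[True], np.diff(pos) > 0]))
            G, pos = G[keep], pos[keep]
            S = len(pos)
            anc_base = BASES[rng.integers(0, 4, size=S)]
            der_base = np.array(
                [rng.choice([b for b in "ACGT" if b != a]) for a in anc_base]
            )
            anc_is_ref = rng.random(S) < 0.5
            ref = np.where(anc_is_ref, anc_base, der_base)
            alt = np.where(anc_is_ref, der_base, anc_base)
            alleles = np.where(anc_is_ref[None, :], G.T, 1 - G.T).astype(np.int8)
            all_alleles.append(alleles)
            all_pos.append(pos)
            all_scaf.append(np.array([scaf] * S, dtype=object))
            all_ref_alt.append(np.stack([ref, alt], axis=1).astype(object))
            all_anc.append(np.where(anc_is_ref, "ref", "alt").astype(object))
        tree_seqs.append(ts)

    if mutate:
        matrix = HaplotypeMatrix(
            alleles=np.concatenate(all_alleles, axis=1),
            positions=np.concatenate(all_pos),
            scaffold=np.concatenate(all_scaf),
            ref_alt=np.concatenate(all_ref_alt),
            sample_ids=sample_ids,
        )
        anc = np.concatenate(all_anc)
        calls = AncestralCalls(anc, np.full(len(anc), "none", dtype=object))
    else:
        matrix = HaplotypeMatrix(
            alleles=np.zeros((2 * len(sample_ids), 0), dtype=np.int8),
            positions=np.zeros(0, dtype=np.int64),
            scaffold=np.zeros(0, dtype=object),
            ref_alt=np.zeros((0, 2), dtype=object),
            sample_ids=sample_ids,
        )
        calls = AncestralCalls(np.zeros(0, dtype=object), np.zeros(0, dtype=object))

    truth = {
        "split_time": params.split_time,
        "admixture_time": params.admixture_time,
        "admixture_fraction": params.admixture_fraction,
        "outgroup_split_time": params.outgroup_split_time if params.include_outgroup else None,
        "seed": params.seed,
        "sweep": None,
    }
    return SimulationBundle(
        matrix=matrix,
        popmap=_population_map(params, sample_ids),
        ancestral=calls,
        tree_sequences=tree_seqs,
        params=params,
        truth=truth,
    )


def inject_sweep(
    bundle: SimulationBundle,
    population: str,
    mode: str = "hard",
    target_frequency: float = 0.9,
    width: int = 50_000,
    scaffold: str | None = None,
    center: int | None = None,
    seed: int | None = None,
    n_backgrounds: int = 2,
) -> SimulationBundle:
    """Transplant haplotype blocks to emulate a sweep in one population.

    hard: the block around one carrier haplotype is copied onto focal
    haplotypes until the carrier background reaches `target_frequency`.
    standing: carrier blocks are drawn from `n_backgrounds` (>= 2) distinct
    carrier backgrounds in different populations, leaving several haplotype
    backgrounds segregating at intermediate frequency among carriers — the
    shared-variation signature. Fixation (target_frequency = 1) is
    disallowed.
    """
    if not 0 < target_frequency < 1:
        raise ValueError("target_frequency must be in (0,1); fixation is disallowed")
    if mode not in ("hard", "standing"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    rng = np.random.default_rng(seed)
    m = bundle.matrix
    from .datamodel import haplotype_index

    hidx = haplotype_index(m, bundle.popmap)
    if population not in hidx:
        raise KeyError(f"unknown population {population!r}")
    focal_rows = hidx[population]
    scaffold = scaffold or m.scaffolds()[0]
    on_scaf = np.flatnonzero(m.scaffold == scaffold)
    if center is None:
        center = int(m.positions[on_scaf].max() // 2)
    start, end = center - width // 2, center + width // 2
    sites = on_scaf[
        (m.positions[on_scaf] - 1 >= start) & (m.positions[on_scaf] - 1 < end)
    ]
    if len(sites) == 0:
        raise ValueError("no segregating sites inside the sweep interval")
    dval = bundle.ancestral.derived_value()

    # target site: nearest polarized site to the center that is segregating
    # appropriately for the mode
    ingroup_rows = np.concatenate(
        [hidx[p] for p in bundle.popmap.populations(include_outgroup=False)]
    )
    cand = []
    for j in sites:
        if dval[j] < 0:
            continue
        der = m.alleles[:, j] == dval[j]
        n_focal = der[focal_rows].sum()
        pools = [
            der[hidx[p]].sum() > 0
            for p in bundle.popmap.populations(include_outgroup=False)
        ]
        freq = der[ingroup_rows].mean()
        if mode == "hard" and 1 <= n_focal <= 0.5 * len(focal_rows):
            cand.append((abs(m.positions[j] - center), j))
        elif (
            mode == "standing"
            and sum(pools) >= 2
            and 0.1 <= freq <= 0.9
            and n_focal <= 0.5 * len(focal_rows)
        ):
            cand.append((abs(m.positions[j] - center), j))
    if not cand:
        raise ValueError(f"no usable target site for a {mode} sweep in the interval")
    if mode == "hard":
        target = min(cand)[1]
    else:
        # standing variation: among the candidate sites nearest the center,
        # target the one whose carriers span the deepest pair of
        # cross-population haplotype backgrounds over the region
        cand = sorted(cand)[:30]
        best_score, target = -1, cand[0][1]
        for _, j in cand:
            der_rows = [
                int(r) for r in ingroup_rows if m.alleles[r, j] == dval[j]
            ][:16]
            pops_of = {}
            for p, rr in hidx.items():
                for r in der_rows:
                    if r in set(rr):
                        pops_of[r] = p
            score = -1
            blocks = m.alleles[np.ix_(der_rows, sites)]
            for a in range(len(der_rows)):
                for bb in range(a + 1, len(der_rows)):
                    if pops_of.get(der_rows[a]) == pops_of.get(der_rows[bb]):
                        continue
                    score = max(score, int(np.sum(blocks[a] != blocks[bb])))
            if score > best_score:
                best_score, target = score, j

    der_focal = np.flatnonzero(m.alleles[focal_rows, target] == dval[target])
    n_target = int(round(target_frequency * len(focal_rows)))
    n_target = min(n_target, len(focal_rows) - 1)  # never fix the region
    if n_target <= len(der_focal):
        return replace(bundle)  # already at or above the target: no-op

    if mode == "hard":
        carriers = [focal_rows[rng.choice(der_focal)]]
    else:
        all_der = np.flatnonzero(m.alleles[:, target] == dval[target])
        all_der = np.array([r for r in all_der if r in set(ingroup_rows)])
        by_pop = {}
        for r in all_der:
            for p, rr in hidx.items():
                if r in set(rr):
                    by_pop.setdefault(p, []).append(r)
        pops_with = [p for p in by_pop if by_pop[p]]
        if len(pops_with) < 2:
            raise ValueError("standing sweep needs carriers in >= 2 populations")
        # among all carriers, keep the most divergent cross-population pair
        # over the region (deeply split haplogroups are the shared-variation
        # scenario this mode emulates), then fill up to n_backgrounds
        pop_of = {int(r): p for p in by_pop for r in by_pop[p]}
        cand_rows = sorted(pop_of)
        if len(cand_rows) > 24:
            cand_rows = sorted(rng.choice(cand_rows, size=24, replace=False))
        blocks = m.alleles[np.ix_(cand_rows, sites)]
        best, pair = -1, (0, 1)
        for i in range(len(cand_rows)):
            for j in range(i + 1, len(cand_rows)):
                if pop_of[cand_rows[i]] == pop_of[cand_rows[j]]:
                    continue
                nd = int(np.sum(blocks[i] != blocks[j]))
                if nd > best:
                    best, pair = nd, (i, j)
        order = list(pair) + [k for k in range(len(cand_rows)) if k not in pair]
        carriers = [cand_rows[k] for k in order[: max(2, n_backgrounds)]]

    recipients = np.array([r for r in focal_rows if r not in set(focal_rows[der_focal])])
    rng.shuffle(recipients)
    recipients = recipients[: n_target - len(der_focal)]
    alleles = m.alleles.copy()
    for r in recipients:
        src = carriers[int(rng.integers(len(carriers)))]
        alleles[r, sites] = m.alleles[src, sites]
    new_matrix = replace(m, alleles=alleles)
    truth = dict(bundle.truth)
    truth["sweep"] = {
        "population": population,
        "mode": mode,
        "scaffold": scaffold,
        "start": int(start),
        "end": int(end),
        "target_position": int(m.positions[target]),
        "target_frequency": target_frequency,
        "n_carrier_backgrounds": len(carriers),
    }
    return replace(bundle, matrix=new_matrix, truth=truth)


def simulate_neutral_panel(
    n_pops: int = 4,
    samples_per_population: int = 25,
    ne: float = 10_000,
    split_time: float = 1_000,
    sequence_length: int = 1_000_000,
    mutation_rate: float = 1e-8,
    recombination_rate: float = 1e-8,
    seed: int | None = None,
    include_outgroup: bool = False,
    outgroup_split_factor: float = 10.0,
):
    """Neutral star-split panel for null-calibration experiments.

    `n_pops` equally sized populations split `split_time` generations ago
    from one ancestor, all at constant size `ne`; no admixture, no
    selection. Optionally an outgroup population (split
    `outgroup_split_factor` times deeper) provides tree rooting. Returns
    (HaplotypeMatrix, PopulationMap).
    """
    rng = np.random.default_rng(seed)
    dem = msprime.Demography()
    pops = [f"pop{i+1}" for i in range(n_pops)]
    for p in pops:
        dem.add_population(name=p, initial_size=ne)
    dem.add_population(name="anc", initial_size=ne)
    dem.add_population_split(time=split_time, derived=pops, ancestral="anc")
    samples = {p: samples_per_population for p in pops}
    if include_outgroup:
        dem.add_population(name="og", initial_size=ne)
        dem.add_population(name="root", initial_size=ne)
        dem.add_population_split(
            time=split_time * outgroup_split_factor,
            derived=["anc", "og"],
            ancestral="root",
        )
        samples["og"] = max(2, samples_per_population // 2)
    a_seed, m_seed = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=sequence_length,
        recombination_rate=recombination_rate,
        random_seed=int(a_seed),
    )
    ts = msprime.sim_mutations(
        ts, rate=mutation_rate, model=msprime.BinaryMutationModel(),
        random_seed=int(m_seed),
    )
    G = ts.genotype_matrix()
    pos = ts.sites_position.astype(np.int64) + 1
    keep = np.flatnonzero(np.concatenate([[True], np.diff(pos) > 0]))
    G, pos = G[keep], pos[keep]
    S = len(pos)
    sample_ids = [f"{p}_{i}" for p, n in samples.items() for i in range(n)]
    matrix = HaplotypeMatrix(
        alleles=G.T.astype(np.int8),
        positions=pos,
        scaffold=np.array(["scaffold_1"] * S, dtype=object),
        ref_alt=np.array([("A", "G")] * S, dtype=object),
        sample_ids=sample_ids,
    )
    # every ingroup population shares the phenotype class: labels carry no signal
    popmap = PopulationMap.from_records(
        [
            (sid, sid.rsplit("_", 1)[0],
             "outgroup" if sid.startswith("og_") else "med_NW",
             None if sid.startswith("og_") else 2)
            for sid in sample_ids
        ]
    )
    return matrix, popmap


def outgroup_consensus(bundle: SimulationBundle, species: str | None = None) -> np.ndarray:
    """Majority 0/1 allele per site of one outgroup species (default: the
    sister species, the divergence reference)."""
    from .datamodel import MISSING, haplotype_index

    hidx = haplotype_index(bundle.matrix, bundle.popmap)
    og_pops = bundle.popmap.outgroup_populations()
    if not og_pops:
        raise ValueError("bundle has no outgroup samples")
    rows = hidx[species or og_pops[0]]
    sub = bundle.matrix.alleles[rows]
    ok = sub != MISSING
    ones = np.where(ok, sub, 0).sum(axis=0)
    return (ones * 2 >= ok.sum(axis=0)).astype(np.int8)


def ingroup_outgroup_divergence(bundle: SimulationBundle) -> float:
    """Mean per-site divergence of ingroup haplotypes from the outgroup
    consensus, over the full simulated sequence length."""
    from .datamodel import haplotype_index

    hidx = haplotype_index(bundle.matrix, bundle.popmap)
    cons = outgroup_consensus(bundle)
    total_bp = bundle.params.scaffold_count * bundle.params.scaffold_length
    rows = np.concatenate(
        [hidx[p] for p in bundle.popmap.populations(include_outgroup=False)]
    )
    diffs = (bundle.matrix.alleles[rows] != cons[None, :]).sum(axis=1)
    return float(diffs.mean() / total_bp)
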