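import numpy as np
import pytest

from migrascan.datamodel import HaplotypeMatrix, PopulationMap
from migrascan.polarize import AncestralCalls


def toy_matrix(alleles, positions=None, scaffold="s1", sample_prefix="x"):
    """Small HaplotypeMatrix from a 2-D 0/1/-1 array (haplotypes x sites)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    H, S = alleles.shape
    if positions is None:
        positions = np.arange(1, S + 1) * 100
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions),
        scaffold=np.array([scaffold] * S, dtype=object),
        ref_alt=np.array([("A", "G")] * S, dtype=object),
        sample_ids=[f"{sample_prefix}{i}" for i in range(H // 2)],
    )


def toy_popmap(assignments):
    """{population: [sample ids]} -> PopulationMap (outgroup_* -> outgroup)."""
    recs = []
    for pop, samples in assignments.items():
        cls = "outgroup" if pop.startswith("outgroup") else "med_NW"
        for s in samples:
            recs.append((s, pop, cls, None if cls == "outgroup" else 2))
    return PopulationMap.from_records(recs)


def all_determined(matrix, ancestral="ref"):
    """AncestralCalls marking every site determined."""
    S = matrix.n_sites
    return AncestralCalls(
        np.full(S, ancestral, dtype=object), np.full(S, "none", dtype=object)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    """Default-roster simulation, small genome, reused across tests."""
    from migrascan.simulate import DemographyParams, simulate

    params = DemographyParams(
        seed=77, scaffold_count=2, scaffold_length=300_000, samples_per_population=5
    )
    return simulate(params)


@pytest.fixture(scope="session")
def neutral_panel():
    """Neutral 4-population panel with outgroup rooting, session-cached."""
    from migrascan.datamodel import filter_sites
    from migrascan.simulate import simulate_neutral_panel

    m, pm = simulate_neutral_panel(samples_per_population=10, seed=7, include_outgroup=True)
    return filter_sites(m, pm, 0.05, 5), pm
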