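import numpy as np
import pytest

from migrascan.ccr import (
    CcrCurve,
    estimate_rise_onset,
    estimate_split_time,
    relative_ccr,
)
from migrascan.datamodel import haplotype_index
from migrascan.simulate import (
    DemographyParams,
    inject_sweep,
    simulate,
    simulate_neutral_panel,
)


class TestParams:
    def test_pulse_after_split_rejected(self):
        with pytest.raises(ValueError, match="postdate"):
            DemographyParams(split_time=1000, admixture_time=2000)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            DemographyParams(admixture_fraction=1.5)

    def test_outgroup_split_accounts_for_ancestral_coalescence(self):
        p = DemographyParams()
        assert p.outgroup_split_time == pytest.approx(
            p.outgroup_divergence / (2 * p.mutation_rate) - 2 * p.ancestral_ne
        )


class TestSimulate:
    def test_same_seed_identical_export(self, tmp_path):
        kw = dict(seed=9, scaffold_count=1, scaffold_length=120_000)
        b1 = simulate(DemographyParams(**kw))
        b2 = simulate(DemographyParams(**kw))
        b1.write(tmp_path / "a")
        b2.write(tmp_path / "b")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_exported_vcf_roundtrips(self, small_bundle, tmp_path):
        from migrascan.datamodel import PopulationMap
        from migrascan.vcfio import read_vcf

        small_bundle.write(tmp_path / "sim")
        pm = PopulationMap.read_tsv(tmp_path / "sim.popmap.tsv")
        m, _ = read_vcf(str(tmp_path / "sim.vcf"), pm)
        np.testing.assert_array_equal(m.alleles, small_bundle.matrix.alleles)
        np.testing.assert_array_equal(m.positions, small_bundle.matrix.positions)

    def test_constant_size_diversity_matches_theta(self):
        # pi ~ 4 Ne mu in a constant-size population
        ne, mu, L = 20_000, 1e-8, 8_000_000
        m, pm = simulate_neutral_panel(
            n_pops=1, samples_per_population=5, ne=ne, split_time=10,
            sequence_length=L, mutation_rate=mu, seed=12,
        )
        a = m.alleles
        pi = 0.0
        n = a.shape[0]
        p = a.mean(axis=0)
        pi = float(np.sum(2 * p * (1 - p) * n / (n - 1))) / L
        assert pi == pytest.approx(4 * ne * mu, rel=0.10)

    def test_fst_monotone_in_split_time(self):
        from migrascan.datamodel import filter_sites, make_windows
        from migrascan.fst import window_fst

        fsts = []
        for t in (500, 2000, 8000):
            m, pm = simulate_neutral_panel(
                n_pops=2, samples_per_population=10, ne=10_000, split_time=t,
                sequence_length=400_000, seed=40 + t,
            )
            hidx = haplotype_index(m, pm)
            w = make_windows(m, width=500_000)
            out = window_fst(m, hidx, "pop1", "pop2", w)
            fsts.append(out["fst"].iloc[0])
        assert fsts[0] < fsts[1] < fsts[2]
        assert fsts[2] > 0.2

    def test_ingroup_outgroup_divergence_matches_target(self):
        from migrascan.simulate import ingroup_outgroup_divergence

        p = DemographyParams(seed=3, scaffold_count=5, scaffold_length=1_000_000,
                             recombination_rate=1e-9)
        b = simulate(p)
        d = ingroup_outgroup_divergence(b)
        assert d == pytest.approx(p.outgroup_divergence, rel=0.10)


@pytest.fixture(scope="module")
def base():
    return simulate(DemographyParams(
        seed=101, scaffold_count=2, scaffold_length=400_000,
        samples_per_population=10, island_populations=(), include_outgroup=False))


class TestInjectSweep:

    def test_fixation_disallowed(self, base):
        with pytest.raises(ValueError, match="fixation"):
            inject_sweep(base, "resident_continent", target_frequency=1.0)

    def test_no_sites_changed_outside_interval(self, base):
        swept = inject_sweep(base, "resident_continent", mode="hard",
                             target_frequency=0.9, width=30_000, seed=1)
        sw = swept.truth["sweep"]
        outside = ~(
            (base.matrix.scaffold == sw["scaffold"])
            & (base.matrix.positions - 1 >= sw["start"])
            & (base.matrix.positions - 1 < sw["end"])
        )
        np.testing.assert_array_equal(
            base.matrix.alleles[:, outside], swept.matrix.alleles[:, outside]
        )

    def test_hard_sweep_raises_haplotype_homozygosity(self, base):
        swept = inject_sweep(base, "resident_continent", mode="hard",
                             target_frequency=0.9, width=30_000, seed=2)
        sw = swept.truth["sweep"]
        hidx = haplotype_index(swept.matrix, swept.popmap)
        rows = hidx["resident_continent"]
        inside = (
            (swept.matrix.scaffold == sw["scaffold"])
            & (swept.matrix.positions - 1 >= sw["start"])
            & (swept.matrix.positions - 1 < sw["end"])
        )

        def hom(matrix, cols):
            sub = matrix.alleles[np.ix_(rows, np.flatnonzero(cols))]
            p = sub.mean(axis=0)
            return float(np.mean(p ** 2 + (1 - p) ** 2))

        assert hom(swept.matrix, inside) > hom(base.matrix, inside) + 0.05

    def test_hard_one_background_standing_several(self, base):
        hard = inject_sweep(base, "resident_continent", mode="hard",
                            target_frequency=0.9, width=30_000, seed=3)
        standing = inject_sweep(base, "resident_continent", mode="standing",
                                target_frequency=0.8, width=30_000, seed=3)
        assert hard.truth["sweep"]["n_carrier_backgrounds"] == 1
        assert standing.truth["sweep"]["n_carrier_backgrounds"] >= 2
        # standing: carriers retain >= 2 distinct backgrounds in the region
        sw = standing.truth["sweep"]
        hidx = haplotype_index(standing.matrix, standing.popmap)
        rows = hidx["resident_continent"]
        inside = np.flatnonzero(
            (standing.matrix.scaffold == sw["scaffold"])
            & (standing.matrix.positions - 1 >= sw["start"])
            & (standing.matrix.positions - 1 < sw["end"])
        )
        dval = standing.ancestral.derived_value()
        tcol = np.flatnonzero(standing.matrix.positions == sw["target_position"])[0]
        carriers = rows[standing.matrix.alleles[rows, tcol] == dval[tcol]]
        blocks = {tuple(standing.matrix.alleles[r, inside]) for r in carriers}
        assert len(blocks) >= 2

    def test_noop_when_target_already_reached(self, base):
        hidx = haplotype_index(base.matrix, base.popmap)
        rows = hidx["resident_continent"]
        # find a site frequency and ask for exactly that frequency
        dval = base.ancestral.derived_value()
        j = next(
            j for j in range(base.matrix.n_sites)
            if dval[j] >= 0 and 2 <= (base.matrix.alleles[rows, j] == dval[j]).sum() <= 6
        )
        f = (base.matrix.alleles[rows, j] == dval[j]).mean()
        swept = inject_sweep(
            base, "resident_continent", mode="hard", target_frequency=float(f),
            width=10_000, center=int(base.matrix.positions[j]), seed=4)
        np.testing.assert_array_equal(swept.matrix.alleles, base.matrix.alleles)
        assert swept.truth["sweep"] is None


def step_curve(edges, rccr_values, gen_time=2.0):
    return CcrCurve(
        bin_edges=np.asarray(edges, dtype=float),
        rate_within_a=np.ones(len(rccr_values)),
        rate_within_b=np.ones(len(rccr_values)),
        rate_between=np.asarray(rccr_values, dtype=float),
        rccr=np.asarray(rccr_values, dtype=float),
        generation_time=gen_time,
        pop_a="a", pop_b="b",
    )


class TestCcr:
    def test_step_curve_crossing_at_exact_edge(self):
        c = step_curve([0, 100, 200, 400, np.inf], [0.0, 0.0, 1.0, 1.0])
        gens, years = estimate_split_time(c)
        assert gens == 200 and years == 400

    def test_no_crossing_returns_none(self):
        c = step_curve([0, 100, 200, np.inf], [0.0, 0.1, 0.2])
        assert estimate_split_time(c) is None

    def test_most_ancient_crossing_wins(self):
        c = step_curve([0, 1, 2, 3, 4, np.inf], [0.0, 0.8, 0.2, 0.9, 1.0])
        gens, _ = estimate_split_time(c)
        assert gens == 3

    def test_rise_onset_at_first_bin_above_minimum(self):
        c = step_curve([0, 10, 20, 40, np.inf], [0.0, 0.05, 0.3, 1.0])
        gens, years = estimate_rise_onset(c, delta=0.1)
        assert gens == 20 and years == 40

    def test_panmictic_labels_give_unit_rccr(self):
        # one panmictic population, arbitrarily split into two label sets
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="p", initial_size=10_000)
        ts = msprime.sim_ancestry(samples={"p": 10}, demography=dem,
                                  sequence_length=2_000_000,
                                  recombination_rate=1e-8, random_seed=3)

        class FakeBundle:
            tree_sequences = [ts]
            class params:
                generation_time = 2.0

        nodes = list(range(20))
        curve = relative_ccr(FakeBundle, "a", "b",
                             bin_edges=np.concatenate([[0], np.geomspace(2e3, 2e5, 8), [np.inf]]),
                             samples_a=nodes[:10], samples_b=nodes[10:])
        ok = np.isfinite(curve.rccr)
        assert np.all(np.abs(curve.rccr[ok] - 1.0) < 0.25)

    def test_clean_ancient_split_structural_zero(self):
        import msprime

        dem = msprime.Demography()
        for name in ("A", "B"):
            dem.add_population(name=name, initial_size=10_000)
        dem.add_population(name="anc", initial_size=10_000)
        dem.add_population_split(time=50_000, derived=["A", "B"], ancestral="anc")
        ts = msprime.sim_ancestry(samples={"A": 5, "B": 5}, demography=dem,
                                  sequence_length=2_000_000,
                                  recombination_rate=1e-8, random_seed=8)

        class FakeBundle:
            tree_sequences = [ts]
            class params:
                generation_time = 2.0

        curve = relative_ccr(FakeBundle, "A", "B")
        recent = (curve.bin_edges[1:] < 10_000) & np.isfinite(curve.rccr)
        assert np.all(curve.rccr[recent] < 0.05)

    def test_split_recovery_within_tolerance(self):
        """0.5-crossing recovers the simulated split across seeds."""
        ests = []
        for seed in (1, 2):
            p = DemographyParams(seed=seed, scaffold_count=3,
                                 scaffold_length=1_000_000, include_outgroup=False)
            b = simulate(p, mutate=False)
            curve = relative_ccr(b, "med_NW", "resident_continent")
            gens, years = estimate_split_time(curve)
            ests.append(gens)
        est = np.mean(ests)
        assert abs(est - 15_000) / 15_000 < 0.25
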