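import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migrascan.datamodel import haplotype_index, make_windows
from migrascan.fst import (
    call_regions,
    delta_pbs,
    hudson_site_components,
    island_replacement_pbs,
    log_transform_T,
    pbs,
    pbs_scan,
    window_fst,
)

from conftest import toy_matrix, toy_popmap


def hudson_oracle(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestWindowFst:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.alleles = rng.integers(0, 2, size=(16, 10)).astype(np.int8)
        self.m = toy_matrix(self.alleles, positions=np.arange(1, 11) * 50)
        self.pm = toy_popmap({"popA": [f"x{i}" for i in range(4)],
                              "popB": [f"x{i}" for i in range(4, 8)]})
        self.hidx = haplotype_index(self.m, self.pm)

    def test_equal_frequencies_give_nonpositive_fst(self):
        alleles = np.tile(np.array([[0], [1]]), (4, 5)).astype(np.int8)  # p=0.5 everywhere
        m = toy_matrix(alleles, sample_prefix="x")
        pm = toy_popmap({"popA": ["x0", "x1"], "popB": ["x2", "x3"]})
        w = make_windows(m, width=10_000)
        out = window_fst(m, haplotype_index(m, pm), "popA", "popB", w)
        assert out["fst"].iloc[0] <= 0

    def test_fixed_difference_approaches_one(self):
        alleles = np.zeros((40, 5), dtype=np.int8)
        alleles[20:] = 1
        m = toy_matrix(alleles, sample_prefix="x")
        pm = toy_popmap({"popA": [f"x{i}" for i in range(10)],
                         "popB": [f"x{i}" for i in range(10, 20)]})
        w = make_windows(m, width=10_000)
        out = window_fst(m, haplotype_index(m, pm), "popA", "popB", w)
        assert out["fst"].iloc[0] > 0.9

    def test_window_equals_per_site_oracle_sum(self):
        w = make_windows(self.m, width=10_000)
        out = window_fst(self.m, self.hidx, "popA", "popB", w)
        nums, dens = [], []
        for j in range(10):
            p1 = self.alleles[:8, j].mean()
            p2 = self.alleles[8:, j].mean()
            num, den = hudson_oracle(p1, 8, p2, 8)
            nums.append(num)
            dens.append(den)
        assert out["fst"].iloc[0] == pytest.approx(sum(nums) / sum(dens), rel=1e-12)

    def test_unknown_population_errors(self):
        w = make_windows(self.m, width=10_000)
        with pytest.raises(KeyError):
            window_fst(self.m, self.hidx, "popA", "nope", w)

    def test_sites_with_too_few_haplotypes_are_nan(self):
        alleles = self.alleles.copy()
        alleles[:7, 0] = -1  # popA has 1 haplotype left at site 0
        m = toy_matrix(alleles, positions=np.arange(1, 11) * 50, sample_prefix="x")
        num, den = hudson_site_components(m, self.hidx["popA"], self.hidx["popB"])
        assert np.isnan(num[0]) and not np.isnan(num[1])


class TestLogTransform:
    @pytest.mark.parametrize("fst,expected", [(0.0, 0.0), (-0.3, 0.0), (0.5, np.log(2))])
    def test_values(self, fst, expected):
        assert log_transform_T(fst) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_clamped(self):
        x = np.linspace(-0.5, 1.5, 50)
        t = log_transform_T(x)
        assert (np.diff(t) >= 0).all() and np.isfinite(t).all()


class TestPbs:
    def T_const(self, t, pops):
        from itertools import combinations

        return {tuple(sorted(p)): np.array([t]) for p in combinations(pops, 2)}

    def test_all_T_equal_as_printed_gives_t_over_3(self):
        T = self.T_const(0.9, "RABC")
        out = pbs(T, "R", ["A", "B", "C"], mode="as_printed")
        assert out[0] == pytest.approx(0.9 / 3)

    def test_all_fst_zero_gives_zero(self):
        T = self.T_const(0.0, "RABC")
        assert pbs(T, "R", ["A", "B", "C"])[0] == 0.0

    @pytest.mark.parametrize("mode", ["as_printed", "mean_triplet"])
    def test_two_nonfocal_reduces_to_classic(self, mode, rng):
        pops = ["R", "A", "B"]
        from itertools import combinations

        T = {tuple(sorted(p)): rng.random(5) for p in combinations(pops, 2)}
        out = pbs(T, "R", ["A", "B"], mode=mode)
        classic = (T[("A", "R")] + T[("B", "R")] - T[("A", "B")]) / 2
        np.testing.assert_allclose(out, classic)

    def test_modes_agree_only_generally_for_two_nonfocal(self, rng):
        from itertools import combinations

        pops = "RABC"
        T = {tuple(sorted(p)): rng.random(4) for p in combinations(pops, 2)}
        a = pbs(T, "R", ["A", "B", "C"], mode="as_printed")
        b = pbs(T, "R", ["A", "B", "C"], mode="mean_triplet")
        assert not np.allclose(a, b)  # the printed form omits one cross term

    def test_fewer_than_two_nonfocal_errors(self):
        with pytest.raises(ValueError):
            pbs({}, "R", ["A"])


class TestDeltaPbs:
    def test_identical_vectors_give_zero(self, rng):
        v = rng.random(20)
        out = delta_pbs({"R": v, "A": v.copy(), "B": v.copy()}, "R")
        np.testing.assert_allclose(out, 0.0)

    def test_arithmetic(self):
        out = delta_pbs(
            {"R": np.array([0.5]), "A": np.array([0.1]), "B": np.array([0.3])}, "R"
        )
        assert out[0] == pytest.approx(0.2)

    def test_shift_invariance_per_window(self, rng):
        vals = {p: rng.random(10) for p in "RAB"}
        base = delta_pbs(vals, "R")
        shift = rng.random(10)
        shifted = {p: v + shift for p, v in vals.items()}
        np.testing.assert_allclose(base, delta_pbs(shifted, "R"))

    def test_mismatched_windows_error(self):
        with pytest.raises(ValueError, match="differ"):
            delta_pbs({"R": np.zeros(3), "A": np.zeros(4)}, "R")

    def test_robust_zscore_scaling(self, rng):
        vals = {p: rng.random(200) for p in "RAB"}
        out = delta_pbs(vals, "R", scaling="zscore")
        assert np.isfinite(out).all()


class TestCallRegions:
    def make_windows_table(self, n):
        m = toy_matrix(np.zeros((2, n), dtype=np.int8),
                       positions=np.arange(1, n + 1) * 2500 - 1000)
        return make_windows(m, width=2500)

    def test_constant_statistic_yields_no_regions(self):
        w = self.make_windows_table(120)
        assert call_regions(w, np.ones(120), "s", "p") == []

    def test_three_adjacent_windows_merge(self):
        w = self.make_windows_table(200)
        v = np.zeros(200)
        v[50:53] = [4.0, 5.0, 4.5]
        regions = call_regions(w, v, "s", "p", quantile=0.95)
        assert len(regions) == 1
        r = regions[0]
        assert r.end - r.start == 7500 and r.peak_value == 5.0
        assert r.windows == [50, 51, 52]

    def test_quantile_zero_spans_each_scaffold(self, rng):
        w = self.make_windows_table(150)
        regions = call_regions(w, rng.random(150), "s", "p", quantile=0.0)
        assert len(regions) == 1
        assert regions[0].start == 0 and regions[0].end == w.table.end.iloc[-1]

    def test_all_missing_errors(self):
        w = self.make_windows_table(120)
        with pytest.raises(ValueError):
            call_regions(w, np.full(120, np.nan), "s", "p")


class TestScanProperties:
    @pytest.fixture(scope="class")
    def star_scan(self):
        """Neutral star phylogeny: symmetric drift, no selection."""
        from migrascan.simulate import simulate_neutral_panel
        from migrascan.datamodel import PopulationMap, filter_sites

        m, pm = simulate_neutral_panel(
            n_pops=4, samples_per_population=8, seed=13, sequence_length=1_500_000
        )
        m = filter_sites(m, pm, 0.05, 5)
        hidx = haplotype_index(m, pm)
        w = make_windows(m, width=2500, scaffold_lengths={"scaffold_1": 1_500_000})
        return m, pm, hidx, w

    def test_neutral_symmetric_drift_mean_delta_pbs_near_zero(self, star_scan):
        m, pm, hidx, w = star_scan
        pops = pm.populations()
        means = []
        for focal in pops:
            tbl = pbs_scan(m, hidx, w, focal, [p for p in pops if p != focal])
            means.append(np.nanmean(tbl["delta_pbs"]))
        # symmetric drift: no population systematically elevated
        assert max(abs(x) for x in means) < 0.15

    def test_top_windows_spread_across_populations(self, star_scan):
        m, pm, hidx, w = star_scan
        pops = pm.populations()
        top_counts = {}
        for focal in pops:
            tbl = pbs_scan(m, hidx, w, focal, [p for p in pops if p != focal])
            v = tbl["delta_pbs"].to_numpy()
            top_counts[focal] = int(np.sum(v > np.nanquantile(v, 0.99)))
        counts = np.array(list(top_counts.values()))
        assert counts.max() <= 3 * max(counts.min(), 1)

    def test_island_replacement_identity_when_focal_unchanged(self, small_bundle):
        from migrascan.datamodel import filter_sites

        b = small_bundle
        mf = filter_sites(b.matrix, b.popmap)
        hidx = haplotype_index(mf, b.popmap)
        w = make_windows(mf, 2500, {s: 300_000 for s in mf.scaffolds()})
        migr = list(b.params.migrant_populations)
        base = pbs_scan(mf, hidx, w, "resident_continent", migr)
        # "substituting" the identical population reproduces the table
        tbl, _ = island_replacement_pbs(mf, hidx, w, "resident_continent", migr, [])
        np.testing.assert_allclose(
            base["pbs_resident_continent"], tbl["pbs_resident_continent"]
        )

    def test_island_replacement_recaptures_shared_signal(self, small_bundle):
        from dataclasses import replace
        from migrascan.simulate import inject_sweep
        from migrascan.datamodel import filter_site_index

        # sweep in the resident population, then transplant the same carrier
        # block into most island haplotypes (a shared selected haplotype)
        b1 = inject_sweep(small_bundle, "resident_continent", mode="hard",
                          target_frequency=0.9, width=40_000, seed=4)
        sw = b1.truth["sweep"]
        hidx0 = haplotype_index(b1.matrix, b1.popmap)
        sites = np.flatnonzero(
            (b1.matrix.scaffold == sw["scaffold"])
            & (b1.matrix.positions - 1 >= sw["start"])
            & (b1.matrix.positions - 1 < sw["end"])
        )
        dval = b1.ancestral.derived_value()
        tcol = np.flatnonzero(b1.matrix.positions == sw["target_position"])[0]
        res_rows = hidx0["resident_continent"]
        carrier = res_rows[b1.matrix.alleles[res_rows, tcol] == dval[tcol]][0]
        alleles = b1.matrix.alleles.copy()
        island_rows = hidx0["island_azores"]
        for r in island_rows[:-1]:
            alleles[r, sites] = alleles[carrier, sites]
        b2 = replace(b1, matrix=replace(b1.matrix, alleles=alleles))
        keep = filter_site_index(b2.matrix, b2.popmap)
        mf = b2.matrix.take_sites(keep)
        hidx = haplotype_index(mf, b2.popmap)
        w = make_windows(mf, 2500, {s: 300_000 for s in mf.scaffolds()})
        migr = list(b2.params.migrant_populations)
        tbl = pbs_scan(mf, hidx, w, "resident_continent", migr)
        regions = call_regions(w, tbl["delta_pbs"].to_numpy(), "delta_pbs",
                               "resident_continent")
        regions = [r for r in regions if r.scaffold == sw["scaffold"]
                   and r.start < sw["end"] and r.end > sw["start"]]
        assert regions, "sweep region not called in the resident scan"
        _, recaptured = island_replacement_pbs(
            mf, hidx, w, "island_azores", migr, regions)
        assert any(recaptured.values())
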