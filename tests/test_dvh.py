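import numpy as np
import pytest

import sfrtplan as sp
from sfrtplan.dose import DoseGrid

from oracles import brute_force_gamma, sort_dose_at_volume, sort_volume_at_dose


def make_dose_mask(values, name="s"):
    """A flat structure whose voxels carry the given dose values (1 mm^3)."""
    values = np.asarray(values, float)
    grid = sp.VoxelGrid((values.size, 1, 1))
    mask = sp.StructureMask(grid, name, np.ones(grid.shape, bool))
    return DoseGrid(grid, values.reshape(grid.shape)), mask


def two_level(n_low=6000, n_high=4000, low=4.0, high=19.0):
    return make_dose_mask(np.r_[np.full(n_low, low), np.full(n_high, high)])


class TestCurve:
    def test_uniform_dose_is_step_curve(self):
        dose, mask = make_dose_mask(np.full(10000, 10.0))  # 10 cc at 10 Gy
        c = sp.compute_dvh(dose, mask)
        assert c.total_cc == pytest.approx(10.0)
        assert sp.volume_at_dose(c, 10.0) == (pytest.approx(100.0), pytest.approx(10.0))
        assert sp.volume_at_dose(c, 10.01)[0] == 0.0
        assert (np.diff(c.volume_cc) <= 0).all()
        assert c.volume_pct[0] == 100.0 and c.volume_cc[-1] == 0.0

    def test_two_level_dose_percentiles(self):
        dose, mask = two_level()
        c = sp.compute_dvh(dose, mask)
        assert sp.volume_at_dose(c, 10.0)[0] == pytest.approx(40.0)
        assert sp.dose_at_volume(c, pct=5.0) == pytest.approx(19.0, abs=0.01)
        assert sp.dose_at_volume(c, pct=95.0) == pytest.approx(4.0, abs=0.01)

    def test_bin_refinement_stability(self):
        dose, mask = two_level()
        coarse = sp.compute_dvh(dose, mask, bin_width=0.02)
        fine = sp.compute_dvh(dose, mask, bin_width=0.01)
        for pct in (5.0, 50.0, 95.0):
            assert abs(sp.dose_at_volume(coarse, pct=pct)
                       - sp.dose_at_volume(fine, pct=pct)) <= 0.02
        for d in (4.0, 10.0, 19.0):
            assert sp.volume_at_dose(coarse, d) == sp.volume_at_dose(fine, d)

    def test_empty_structure_rejected(self, small_grid):
        dose = DoseGrid(small_grid, np.zeros(small_grid.shape))
        empty = sp.StructureMask(small_grid, "e", np.zeros(small_grid.shape, bool))
        with pytest.raises(ValueError):
            sp.compute_dvh(dose, empty)

    def test_out_of_range_queries_rejected(self):
        dose, mask = two_level()
        c = sp.compute_dvh(dose, mask)
        for bad in ({"pct": 0.0}, {"pct": 101.0}, {"cc": 0.0}, {"cc": 11.0}):
            with pytest.raises(ValueError):
                sp.dose_at_volume(c, **bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_percentiles_match_sort_oracle(self, seed, rng):
        values = np.random.default_rng(seed).gamma(2.0, 4.0, 40 ** 3)
        dose, mask = make_dose_mask(values)
        c = sp.compute_dvh(dose, mask)
        voxel_cc = 1e-3
        for pct in (2.0, 5.0, 50.0, 95.0, 99.9):
            ours = sp.dose_at_volume(c, pct=pct)
            ref = sort_dose_at_volume(values, voxel_cc, pct / 100.0 * values.size * voxel_cc)
            assert abs(ours - ref) <= 0.01  # one bin width
        for d in (1.0, 5.0, 20.0):
            assert sp.volume_at_dose(c, d)[1] == pytest.approx(
                sort_volume_at_dose(values, voxel_cc, d), abs=1e-12)

    def test_hot_spot_dose_matches_sort_and_count(self, rng):
        values = rng.normal(10.0, 3.0, 50 ** 3).clip(0)
        dose, mask = make_dose_mask(values)
        c = sp.compute_dvh(dose, mask)
        # D0.03cc = dose exceeded by the hottest 30 voxels at 1 mm^3;
        # binned vs order-statistic interpolation differ by <= 2 bins
        ref = sort_dose_at_volume(values, 1e-3, 0.03)
        assert sp.dose_at_volume(c, cc=0.03) == pytest.approx(ref, abs=0.02)


class TestPVDR:
    def test_uniform_dose_gives_unity(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 8.0, "GTV")
        ptv = sp.expand(gtv, 3.0).with_name("PTV")
        dose = DoseGrid(small_grid, np.full(small_grid.shape, 10.0))
        res = sp.pvdr(dose, gtv, ptv, "LATTICE")
        assert res.value == pytest.approx(1.0, abs=0.01)

    def test_two_level_dose(self):
        dose, mask = two_level()
        res = sp.pvdr(dose, mask, mask, "LATTICE")
        assert res.value == pytest.approx(4.75, abs=0.02)

    def test_scart_uses_ptv(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 8.0, "GTV")
        ptv = sp.expand(gtv, 3.0).with_name("PTV")
        dose = DoseGrid(small_grid, np.full(small_grid.shape, 10.0))
        assert sp.pvdr(dose, gtv, ptv, "SCART").structure == "PTV"

    def test_zero_valley_marked_undefined(self):
        dose, mask = two_level(low=0.0)
        res = sp.pvdr(dose, mask, mask, "LATTICE")
        assert not res.defined and res.value is None


class TestCoverage:
    def test_full_and_zero_coverage(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 8.0, "GTV")
        dose = DoseGrid(small_grid, np.full(small_grid.shape, 4.0))
        assert sp.coverage(dose, gtv, 4.0) == 100.0
        assert sp.coverage(dose, gtv, 4.01) == 0.0


class TestGamma:
    def test_identical_curves_pass_fully(self):
        dose, mask = two_level()
        c = sp.compute_dvh(dose, mask)
        assert sp.dvh_gamma(c, c, dose_criterion=0.19, volume_criterion=0.1) == 100.0

    def test_half_criterion_dose_shift_passes(self):
        delta_d = 1.0
        dose, mask = two_level()
        ref = sp.compute_dvh(dose, mask)
        shifted, _ = two_level(low=4.0 + 0.5 * delta_d, high=19.0 + 0.5 * delta_d)
        ev = sp.compute_dvh(shifted, mask)
        assert sp.dvh_gamma(ref, ev, delta_d, 0.1) == 100.0

    def test_step_curves_hand_enumeration(self):
        # reference: 10 cc up to 10 Gy; evaluated: 10 cc up to 13 Gy;
        # criteria 1 Gy / 0.1 cc; samples at 1 Gy steps plus the terminal
        # point: 12 of 15 samples pass
        ref_dose, mask = make_dose_mask(np.full(10000, 10.0))
        ev_dose, _ = make_dose_mask(np.full(10000, 13.0))
        ref = sp.compute_dvh(ref_dose, mask)
        ev = sp.compute_dvh(ev_dose, mask)
        rate = sp.dvh_gamma(ref, ev, dose_criterion=1.0, volume_criterion=0.1)
        assert rate == pytest.approx(80.0, abs=0.5)

    def test_matches_brute_force_minimization(self):
        ref_dose, mask = make_dose_mask(np.full(10000, 10.0))
        ev_dose, _ = make_dose_mask(np.full(10000, 13.0))
        ref = sp.compute_dvh(ref_dose, mask)
        ev = sp.compute_dvh(ev_dose, mask)
        ours = sp.dvh_gamma(ref, ev, 1.0, 0.1)
        ref_pts = np.column_stack([ref.edges, ref.volume_cc])
        samples = [(d, sp.volume_at_dose(ev, d)[1]) for d in np.arange(0.0, 13.5, 1.0)]
        samples.append((13.0, 0.0))
        assert ours == pytest.approx(brute_force_gamma(ref_pts, samples, 1.0, 0.1), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_self_gamma_always_full_under_fuzzing(self, seed):
        values = np.random.default_rng(seed).gamma(3.0, 3.0, 8000)
        dose, mask = make_dose_mask(values)
        c = sp.compute_dvh(dose, mask)
        d_max = c.max_dose
        assert sp.dvh_gamma(c, c, d_max / 100.0, c.total_cc / 100.0) == 100.0

    def test_sub_criterion_uniform_shift_passes_flat_regions(self):
        values = np.r_[np.full(5000, 5.0), np.full(5000, 12.0)]
        dose, mask = make_dose_mask(values)
        ref = sp.compute_dvh(dose, mask)
        shift_dose, _ = make_dose_mask(values + 0.8)
        ev = sp.compute_dvh(shift_dose, mask)
        assert sp.dvh_gamma(ref, ev, dose_criterion=1.0,
                            volume_criterion=0.1) == 100.0

    def test_invalid_criteria_rejected(self):
        dose, mask = two_level()
        c = sp.compute_dvh(dose, mask)
        with pytest.raises(ValueError):
            sp.dvh_gamma(c, c, 0.0, 0.1)
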