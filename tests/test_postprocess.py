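import numpy as np
import pytest

from mdfps.geometry import GridSpec, make_admin_grid
from mdfps.geostat import PosteriorSurface
from mdfps.postprocess import (
    ChangeSummary,
    aggregate_area,
    change_analysis,
    classify_progress,
    exceedance,
    summarize_area,
)


def surface_from(samples, nx=6, ny=6, pixel=10.0, mask=None):
    grid = GridSpec(0.0, 0.0, pixel, nx, ny)
    mask = np.ones((ny, nx), bool) if mask is None else mask
    return PosteriorSurface(grid=grid, mask=mask, samples=np.asarray(samples, float))


class TestExceedance:
    def test_all_samples_above_threshold(self):
        assert exceedance(np.array([0.8, 0.8, 0.9]), 0.75) == 1.0

    def test_symmetric_split(self):
        assert exceedance(np.array([0.1, 0.9]), 0.5) == 0.5

    def test_uniform_draws_quarter_above_075(self):
        rng = np.random.default_rng(12)
        u = rng.uniform(size=1000)
        se = np.sqrt(0.25 * 0.75 / 1000)
        assert abs(exceedance(u, 0.75) - 0.25) <= 3 * se

    def test_strict_inequality(self):
        assert exceedance(np.array([0.75, 0.75]), 0.75) == 0.0

    def test_monotone_in_threshold_and_boundary_values(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(size=500)
        eps = 1e-12
        assert exceedance(s, s.min() - eps) == 1.0
        assert exceedance(s, s.max()) == 0.0
        thresholds = np.sort(rng.uniform(size=20))
        eps_values = [exceedance(s, t) for t in thresholds]
        assert all(a >= b for a, b in zip(eps_values, eps_values[1:]))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            exceedance(np.array([]), 0.5)


class TestAggregateArea:
    def test_constant_surface_constant_areas(self):
        admin = make_admin_grid(4, 60.0)
        surf = surface_from(np.full((10, 36), 0.4))
        areas, national = aggregate_area(surf, admin)
        for draws in areas.values():
            np.testing.assert_allclose(draws, 0.4)
        np.testing.assert_allclose(national, 0.4)

    def test_single_polygon_equals_national(self):
        admin = make_admin_grid(1, 60.0)
        rng = np.random.default_rng(2)
        surf = surface_from(rng.uniform(size=(20, 36)))
        areas, national = aggregate_area(surf, admin)
        np.testing.assert_allclose(areas[1], national, atol=1e-15)

    def test_hand_computed_weighted_means(self):
        """2 areas x 8 pixels with a hand-set cube and weight layer."""
        admin = make_admin_grid(2, 60.0)  # two 30x60 strips (left/right)
        grid = GridSpec(0.0, 0.0, 15.0, 4, 2)  # centres x=7.5..52.5, y=7.5,22.5
        samples = np.array(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
             [0.2, 0.4, 0.6, 0.8, 1.0, 0.0, 0.5, 0.3]]
        )
        surf = PosteriorSurface(grid=grid, mask=np.ones((2, 4), bool), samples=samples)
        w = np.array([[1.0, 2.0, 1.0, 1.0], [3.0, 1.0, 1.0, 2.0]])
        areas, national = aggregate_area(surf, admin, weights=w)
        # area 1 = columns 0-1 (weights 1,2,3,1); area 2 = columns 2-3 (1,1,1,2)
        np.testing.assert_allclose(areas[1], [2.6 / 7, 4.0 / 7])
        np.testing.assert_allclose(areas[2], [3.0 / 5, 2.5 / 5])
        np.testing.assert_allclose(national, (samples * w.ravel()).sum(axis=1) / w.sum())

    def test_partition_conservation_to_1e12(self):
        """National draw equals the pixel-count-weighted mean of area draws."""
        admin = make_admin_grid(9, 60.0)
        rng = np.random.default_rng(7)
        surf = surface_from(rng.uniform(size=(25, 36)))
        areas, national = aggregate_area(surf, admin)
        centers = surf.pixel_centers()
        member = admin.locate(centers[:, 0], centers[:, 1])
        weights = np.array([np.sum(member == i) for i in admin.ids], float)
        recombined = sum(w * areas[i] for w, i in zip(weights, admin.ids)) / weights.sum()
        np.testing.assert_allclose(recombined, national, atol=1e-12)

    def test_empty_polygon_reported(self):
        admin = make_admin_grid(4, 200.0)  # polygons beyond the 60 km grid
        surf = surface_from(np.full((3, 36), 0.5))
        with pytest.raises(ValueError, match="polygon"):
            aggregate_area(surf, admin)


class TestSummarizeArea:
    def test_degenerate_draws(self):
        with pytest.warns(UserWarning, match="draws"):
            (s,) = summarize_area({1: np.full(50, 0.46)}, t=0.75)
        assert s.posterior_mean == pytest.approx(0.46, abs=1e-15)
        assert s.ci_low == pytest.approx(0.46, abs=1e-15)
        assert s.ci_high == pytest.approx(0.46, abs=1e-15)
        assert s.ep == 0.0

    def test_sorted_grid_exceedance(self):
        draws = np.arange(0.01, 1.005, 0.01)  # 0.01 .. 1.00
        (s,) = summarize_area({1: draws}, t=0.75)
        assert s.ep == pytest.approx(0.25)

    def test_ep_at_zero_on_positive_draws_is_one(self):
        (s,) = summarize_area({1: np.random.default_rng(1).uniform(0.01, 1, 200)}, t=0.0)
        assert s.ep == 1.0


class TestChangeAnalysis:
    def make_pair(self, shift=0.0, n_draws=400, seed=5):
        admin = make_admin_grid(4, 60.0)
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.5, size=(n_draws, 36))
        s1 = surface_from(base)
        s2 = surface_from(np.clip(base + shift, 0, 1))
        return admin, s1, s2

    def test_identical_surfaces_null_change(self):
        admin, s1, _ = self.make_pair()
        summaries, national = change_analysis(s1, s1, admin, seed=3)
        assert abs(national.mpc) < 1.0  # percentage points
        assert 0.35 < national.ep_increase < 0.65  # independent pairing -> ~0.5
        for s in summaries:
            assert 0.3 < s.ep_increase < 0.7

    def test_constant_shift_of_ten_points(self):
        admin, s1, s2 = self.make_pair(shift=0.10)
        summaries, national = change_analysis(s1, s2, admin, seed=3)
        assert national.mpc == pytest.approx(10.0, abs=0.35)
        assert national.ep_increase == 1.0
        for s in summaries:
            assert s.ep_increase == 1.0

    def test_indexed_pairing_is_exact_for_paired_draws(self):
        admin, s1, s2 = self.make_pair(shift=0.10)
        summaries, national = change_analysis(s1, s2, admin, pairing="indexed")
        assert national.mpc == pytest.approx(10.0, abs=1e-9)
        assert national.ci_low == pytest.approx(10.0, abs=1e-6)

    def test_mpc_linearity_under_indexed_pairing(self):
        admin, s1, s2 = self.make_pair(shift=0.07)
        _, national = change_analysis(s1, s2, admin, pairing="indexed")
        a1, n1 = aggregate_area(s1, admin)
        a2, n2 = aggregate_area(s2, admin)
        assert national.mpc == pytest.approx(100 * (n2.mean() - n1.mean()), abs=1e-9)

    def test_grid_mismatch_rejected(self):
        admin, s1, _ = self.make_pair()
        other = surface_from(np.full((5, 16), 0.5), nx=4, ny=4)
        with pytest.raises(ValueError, match="grids"):
            change_analysis(s1, other, admin)


class TestClassifyProgress:
    def make(self, ep):
        return ChangeSummary(area_id=1, mpc=0.0, ci_low=-1.0, ci_high=1.0, ep_increase=ep)

    @pytest.mark.parametrize(
        "ep,label",
        [(0.95, "improving"), (0.9, "improving"), (0.05, "reversing"), (0.1, "reversing"),
         (0.5, "indeterminate"), (0.89, "indeterminate")],
    )
    def test_threshold_rules(self, ep, label):
        assert classify_progress([self.make(ep)])[1] == label

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_progress([self.make(0.5)], hi=0.1, lo=0.9)
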