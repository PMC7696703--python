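"""Grid construction, subset selection, ellipses, densities and the scan."""

import numpy as np
import pytest
from scipy import stats

from smartscan.data_model import PairedCohort, PairedObservation
from smartscan.errors import SampleSizeError, SmartError
from smartscan.scan import (
    DensityMap,
    Ellipse,
    ScanSettings,
    build_grid,
    hotelling_ellipse,
    observation_density,
    roi_model,
    run_scan,
    select_subset,
    variable_density,
)


def _cohort_from(coords, D, rng=None):
    obs = [
        PairedObservation(pair_id=f"p{i:03d}", ttd=float(c[0]), tbs=float(c[1]), d=D[i])
        for i, c in enumerate(coords)
    ]
    return PairedCohort(observations=obs, variable_ids=[f"v{j}" for j in range(D.shape[1])])


class TestBuildGrid:
    def test_counting_example(self):
        coords = np.array([[1.0, 1.0], [2.0, 1.5]])
        grid = build_grid(coords, step=0.25)
        assert len(grid) == 5 * 3

    def test_single_observation_one_point(self):
        grid = build_grid(np.array([[1.0, 2.0]]), step=0.25)
        assert len(grid) == 1

    def test_step_larger_than_range_corners_only(self):
        coords = np.array([[1.1, 1.1], [1.4, 1.3]])
        grid = build_grid(coords, step=10.0)
        assert len(grid) == 4  # floor/ceil corners at multiples of the step

    def test_grid_aligned_to_step_multiples(self):
        grid = build_grid(np.array([[1.13, 2.27], [3.9, 4.1]]), step=0.25)
        np.testing.assert_allclose(np.round(grid / 0.25) * 0.25, grid, atol=1e-9)


class TestSelectSubset:
    def test_k_equals_n_returns_all(self, rng):
        coords = rng.uniform(0, 10, size=(15, 2))
        idx = select_subset((100.0, -5.0), 1.0, coords, k=15)
        np.testing.assert_array_equal(np.sort(idx), np.arange(15))

    def test_matches_brute_force_sort(self, rng):
        coords = rng.uniform(0, 10, size=(30, 2))
        anchor = coords.mean(axis=0)
        idx = select_subset(anchor, 1.0, coords, k=10)
        d = np.hypot(*(coords - anchor).T)
        expected = np.sort(np.argsort(d, kind="stable")[:10])
        np.testing.assert_array_equal(idx, expected)

    @pytest.mark.parametrize("weight", [0.125, 0.5, 2.0, 8.0])
    def test_weighted_matches_brute_force(self, rng, weight):
        coords = rng.uniform(0, 12, size=(64, 2))
        for anchor in rng.uniform(0, 12, size=(10, 2)):
            idx = select_subset(anchor, weight, coords, k=20)
            d2 = (weight * (coords[:, 0] - anchor[0])) ** 2 + (coords[:, 1] - anchor[1]) ** 2
            expected = np.sort(np.argsort(d2, kind="stable")[:20])
            np.testing.assert_array_equal(idx, expected)

    def test_weight_stretches_ttd_axis(self):
        # cross of points: with weight 8, ttd distance dominates, so the
        # subset elongates along tbs; with weight 1/8 the converse
        coords = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 3.0], [0.0, -3.0]])
        heavy = select_subset((0.0, 0.0), 8.0, coords, k=2)
        light = select_subset((0.0, 0.0), 0.125, coords, k=2)
        np.testing.assert_array_equal(heavy, [2, 3])  # tbs arm kept
        np.testing.assert_array_equal(light, [0, 1])  # ttd arm kept


class TestHotellingEllipse:
    def test_large_n_isotropic_radius_approaches_chi2(self, rng):
        pts = rng.standard_normal((20000, 2))
        ell = hotelling_ellipse(pts)
        assert ell.semi_axes[0] == pytest.approx(np.sqrt(stats.chi2.ppf(0.95, 2)), rel=0.05)
        assert ell.semi_axes[1] == pytest.approx(np.sqrt(stats.chi2.ppf(0.95, 2)), rel=0.05)

    def test_collinear_degenerate_sentinel(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        ell = hotelling_ellipse(pts)
        assert ell.degenerate and ell.semi_axes[1] == 0.0
        assert not ell.covers(pts).any()

    def test_rotation_equivariance(self, rng):
        pts = rng.standard_normal((50, 2)) @ np.diag([3.0, 1.0])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = hotelling_ellipse(pts)
        e2 = hotelling_ellipse(pts @ R.T)
        np.testing.assert_allclose(e2.center, R @ e1.center, atol=1e-8)
        np.testing.assert_allclose(e2.semi_axes, e1.semi_axes, atol=1e-8)
        assert ((e2.angle - e1.angle - theta + np.pi) % np.pi) == pytest.approx(0, abs=1e-6) or \
               ((e2.angle - e1.angle - theta) % np.pi) == pytest.approx(0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(SampleSizeError):
            hotelling_ellipse(np.zeros((2, 2)))


class TestDensities:
    def _scan_result(self, rng, effect=4.0):
        coords = rng.uniform(0.5, 6, size=(24, 2))
        D = rng.standard_normal((24, 8))
        inside = coords[:, 0] < 3
        D[inside, :3] += effect
        cohort = _cohort_from(coords, D)
        return run_scan(cohort, ScanSettings(step=2.0, k=8, k_folds=4))

    def test_no_significant_subsets_zero_map(self, rng):
        coords = rng.uniform(0.5, 6, size=(15, 2))
        cohort = _cohort_from(coords, rng.standard_normal((15, 4)))
        scan = run_scan(cohort, ScanSettings(step=3.0, k=6, k_folds=3, alpha=1e-9))
        dmap = observation_density(scan, raster_step=1.0)
        np.testing.assert_array_equal(dmap.counts, 0)

    def test_single_ellipse_indicator(self, rng):
        scan = self._scan_result(rng)
        sig = scan.significant_subsets()
        if not sig:
            pytest.skip("no significant subset in this draw")
        # rebuild a scan with exactly one significant subset
        for s in scan.subsets:
            s.significant = False
        sig[0].significant = True
        dmap = observation_density(scan, raster_step=0.5)
        expected = sig[0].ellipse.covers(dmap.cell_centers).reshape(dmap.counts.shape)
        np.testing.assert_array_equal(dmap.counts, expected.astype(float))

    def test_two_ellipse_overlap_counts(self):
        e1 = hotelling_ellipse(np.array([[0, 0], [2, 0], [0, 2], [2, 2.0]]))
        e2 = hotelling_ellipse(np.array([[10, 10], [12, 10], [10, 12], [12, 12.0]]))
        cells = np.array([[1.0, 1.0], [11.0, 11.0], [100.0, 100.0]])
        total = e1.covers(cells).astype(int) + e2.covers(cells).astype(int)
        np.testing.assert_array_equal(total, [1, 1, 0])  # disjoint: max 1
        # overlapping copy counts twice
        total2 = e1.covers(cells).astype(int) * 2
        assert total2[0] == 2

    def test_variable_density_nesting_and_sign(self, rng):
        scan = self._scan_result(rng)
        mv = variable_density(scan, "v0", criterion="multivariate", raster_step=1.0)
        tt = variable_density(scan, "v0", criterion="ttest", raster_step=1.0)
        assert np.all(np.abs(mv.counts) <= np.abs(tt.counts))
        assert np.all(mv.counts >= 0)  # planted increase: never negative

    def test_unknown_variable_raises(self, rng):
        scan = self._scan_result(rng)
        with pytest.raises(SmartError):
            variable_density(scan, "nope")


class TestRunScan:
    def test_dedup_and_bounds(self, rng):
        coords = rng.uniform(0, 5, size=(20, 2))
        cohort = _cohort_from(coords, rng.normal(size=(20, 5)))
        settings = ScanSettings(step=1.0, k=8, k_folds=4)
        scan = run_scan(cohort, settings)
        keys = [s.pair_ids for s in scan.subsets]
        assert len(keys) == len(set(keys))
        assert scan.n_subsets <= len(scan.grid) * len(settings.weights)

    def test_deterministic_rerun(self, small_cohort):
        cohort, _ = small_cohort
        settings = ScanSettings(step=2.0, k=8, k_folds=4)
        s1 = run_scan(cohort, settings)
        s2 = run_scan(cohort, settings)
        assert [s.pair_ids for s in s1.subsets] == [s.pair_ids for s in s2.subsets]
        np.testing.assert_array_equal(
            [s.p_cvanova for s in s1.subsets], [s.p_cvanova for s in s2.subsets]
        )

    def test_position_inside_member_bounding_box(self, small_cohort):
        cohort, _ = small_cohort
        scan = run_scan(cohort, ScanSettings(step=3.0, k=6, k_folds=3))
        for s in scan.subsets:
            members = scan.coords[s.member_idx]
            assert members[:, 0].min() <= s.position[0] <= members[:, 0].max()
            assert members[:, 1].min() <= s.position[1] <= members[:, 1].max()


class TestRoiModel:
    def test_planted_panel_gives_positive_q2(self, small_cohort):
        cohort, truth = small_cohort
        cv = roi_model(cohort, truth.roi, variables=truth.panel, k_folds=5)
        assert cv.computable and cv.Q2 > 0.2

    def test_null_cohort_q2_nonpositive_median(self, rng):
        q2 = []
        for _ in range(15):
            coords = rng.uniform(0.5, 6, size=(12, 2))
            cohort = _cohort_from(coords, rng.standard_normal((12, 6)))
            cv = roi_model(cohort, (7.0, 7.0), k_folds=4, select_vars=False)
            q2.append(cv.Q2)
        assert np.median(q2) <= 0.0

    def test_empty_roi_raises(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(SmartError):
            roi_model(cohort, (0.01, 0.01))
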