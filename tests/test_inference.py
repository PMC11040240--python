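import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import ConvexHull, Delaunay

from roostfinder.diffusion import DiffusionParams, expected_proportions
from roostfinder.inference import (
    GridSpec,
    build_rho_surface,
    centre_of_calls,
    confidence_heuristic,
    rho_metric,
    search_statistics,
)

from conftest import make_survey

P = DiffusionParams()


class TestRhoMetric:
    def test_identity_is_zero(self):
        C = np.array([0.2, 0.3, 0.5])
        assert rho_metric(C, C) == 0.0

    def test_hand_sum(self):
        assert rho_metric([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            rho_metric([0.5, 0.5], [1.0])

    def test_exponent_two_emphasises_busy_detectors(self):
        # two model candidates with the same total L1 mismatch: one errs on
        # the detector holding most calls, the other spreads the error.
        # squaring penalises the concentrated mismatch more; exponent 1
        # cannot tell them apart.
        C = np.array([0.7, 0.2, 0.1])
        F_busy = np.array([0.5, 0.3, 0.2])  # 0.2 error on the busy detector
        F_spread = np.array([0.6, 0.25, 0.15])  # 0.1 spread errors... same L1
        assert rho_metric(C, F_busy, 1) == pytest.approx(
            rho_metric(C, F_spread, 1) * 2
        )
        # concentrated error costs relatively more under exponent 2
        r2 = rho_metric(C, F_busy, 2) / rho_metric(C, F_spread, 2)
        r1 = rho_metric(C, F_busy, 1) / rho_metric(C, F_spread, 1)
        assert r2 > r1


class TestGridSpec:
    def test_centres_and_cell_lookup(self):
        g = GridSpec(0, 100, 0, 50, n_x=10, n_y=5)
        assert g.cell_size == (10.0, 10.0)
        np.testing.assert_allclose(g.x_centres()[0], 5.0)
        np.testing.assert_allclose(g.y_centres()[0], 45.0)  # row 0 = north
        assert g.cell_of((5.0, 45.0)) == (0, 0)
        assert g.cell_of((99.9, 0.1)) == (4, 9)
        assert g.cell_of((100.0, 50.0)) == (0, 9)  # boundary snaps inside
        assert g.cell_of((150.0, 0.0)) is None

    def test_padding_expands_bounds(self):
        g = GridSpec.from_positions(np.array([[0, 0], [100, 50]]), 10, 10, padding=25)
        assert g.bounds == (-25.0, 125.0, -25.0, 75.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, 0, 1)
        with pytest.raises(ValueError):
            GridSpec(0, 1, 0, 1, n_x=1)
        with pytest.raises(ValueError):
            GridSpec(0, 1, 0, 1, padding=-1)


class TestBuildRhoSurface:
    def test_self_consistent_ring(self, ring_survey):
        # counts equal by symmetry = forward model at the ring centre, so the
        # argmin cell should be (one of) the central cells with rho ~ 0
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=21, n_y=21)
        surf = build_rho_surface(ring_survey, grid, P)
        assert surf.argmin_cell == (10, 10)  # centre cell of 21 x 21
        assert surf.rho[10, 10] < 1e-4
        assert surf.rho.max() == 1.0
        assert surf.rho.min() >= 0.0

    def test_count_scaling_invariance(self, ring_positions):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 40, size=20)
        grid = GridSpec.from_positions(ring_positions, 15, 15)
        s1 = build_rho_surface(make_survey(ring_positions, counts), grid, P)
        s2 = build_rho_surface(make_survey(ring_positions, counts * 10), grid, P)
        np.testing.assert_allclose(s1.rho, s2.rho, rtol=1e-12)

    def test_scene_translation_invariance(self, ring_positions):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 40, size=20)
        shift = np.array([250_000.0, 65_000.0])
        g1 = GridSpec.from_positions(ring_positions, 15, 15)
        g2 = GridSpec.from_positions(ring_positions + shift, 15, 15)
        s1 = build_rho_surface(make_survey(ring_positions, counts), g1, P)
        s2 = build_rho_surface(make_survey(ring_positions + shift, counts), g2, P)
        np.testing.assert_allclose(s1.rho, s2.rho, rtol=1e-6)
        np.testing.assert_allclose(np.array(s2.zp) - shift, s1.zp, atol=1e-6)

    def test_matches_per_cell_brute_force(self, ring_positions):
        # oracle: recompute rho cell by cell via expected_proportions
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 40, size=20)
        survey = make_survey(ring_positions, counts)
        grid = GridSpec.from_positions(ring_positions, 12, 9)
        surf = build_rho_surface(survey, grid, P)
        xs, ys = grid.x_centres(), grid.y_centres()
        raw = np.empty((9, 12))
        for i, y in enumerate(ys):
            for j, x in enumerate(xs):
                F = expected_proportions(survey.positions, (x, y), P)
                raw[i, j] = rho_metric(survey.proportions, F)
        np.testing.assert_allclose(surf.rho, raw / raw.max(), rtol=1e-10)

    def test_approx_close_to_exact_quadrature_away_from_detectors(self):
        # detectors >= 200 m from every cell centre: approx-mode rho matches
        # an exact-disk-quadrature surface within 2% per cell
        dets = np.array([[-1200.0, -1300.0], [1250.0, -1200.0], [0.0, 1400.0]])
        survey = make_survey(dets, [30, 12, 5])
        grid = GridSpec(-500, 500, -500, 500, n_x=8, n_y=8)
        sa = build_rho_surface(survey, grid, P, mode="approx")
        se = build_rho_surface(survey, grid, P, mode="exact")
        np.testing.assert_allclose(sa.rho, se.rho, rtol=0.02)

    def test_grid_order_independence(self, ring_survey):
        # cells are independent: evaluating a row-reversed grid must give the
        # mirrored surface exactly
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=9, n_y=9)
        surf = build_rho_surface(ring_survey, grid, P)
        flipped = GridSpec(-1500, 1500, -1500, 1500, n_x=9, n_y=9)
        # mirror the survey north-south instead of the grid
        mirrored = make_survey(
            ring_survey.positions * np.array([1.0, -1.0]),
            [d.total_calls for d in ring_survey.detectors],
        )
        surf2 = build_rho_surface(mirrored, flipped, P)
        np.testing.assert_allclose(surf.rho, surf2.rho[::-1], rtol=1e-9)

    def test_normalisation_max_exactly_one(self, ring_positions):
        rng = np.random.default_rng(6)
        for seed in range(3):
            counts = np.random.default_rng(seed).integers(0, 30, size=20)
            if counts.sum() == 0:
                continue
            surf = build_rho_surface(
                make_survey(ring_positions, counts),
                GridSpec.from_positions(ring_positions, 7, 7),
                P,
            )
            assert surf.rho.max() == 1.0
            assert np.all((surf.rho >= 0) & (surf.rho <= 1))


class TestCentreOfCalls:
    def test_all_calls_at_one_detector(self):
        s = make_survey([[0, 0], [100, 200], [-50, 30]], [0, 25, 0])
        assert centre_of_calls(s) == (100.0, 200.0)

    def test_square_symmetry(self):
        s = make_survey([[0, 0], [100, 0], [100, 100], [0, 100]], [7, 7, 7, 7])
        assert centre_of_calls(s) == (50.0, 50.0)

    @given(seed=st.integers(0, 10_000))
    def test_inside_convex_hull(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 15)
        pos = rng.uniform(-1000, 1000, size=(n, 2))
        counts = rng.integers(0, 50, size=n)
        if counts.sum() == 0:
            counts[0] = 1
        cc = np.array(centre_of_calls(make_survey(pos, counts)))
        tri = Delaunay(pos)
        assert tri.find_simplex(cc + 0.0) >= 0 or np.min(
            np.linalg.norm(pos - cc, axis=1)
        ) < 1e-6


class TestSearchStatistics:
    def test_threshold_tables(self, ring_survey):
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=20, n_y=20)
        surf = build_rho_surface(ring_survey, grid, P)
        est = search_statistics(surf, survey=ring_survey, thresholds=(0.0, 0.5, 1.0))
        assert est.percent_below[1.0] == 100.0
        assert est.area_below[1.0] == pytest.approx(est.total_area_km2)
        assert (
            est.percent_below[0.0]
            <= est.percent_below[0.5]
            <= est.percent_below[1.0]
        )
        # roost cell is inside the rho <= rho_c region by construction
        assert est.rho_c is not None
        assert est.percent_below_rho_c < 100.0
        assert est.area_below_rho_c >= grid.cell_area_km2

    def test_distances(self, ring_survey):
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=21, n_y=21)
        surf = build_rho_surface(ring_survey, grid, P)
        est = search_statistics(surf, survey=ring_survey)
        assert est.dist_zp_roost == pytest.approx(0.0, abs=1.0)  # centre cell
        assert est.dist_cc_roost == pytest.approx(0.0, abs=1e-9)  # symmetry
        assert est.dist_zp_cc == pytest.approx(est.dist_zp_roost, abs=1e-6)

    def test_roost_outside_grid_warns(self, ring_survey):
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=10, n_y=10)
        surf = build_rho_surface(ring_survey, grid, P)
        with pytest.warns(UserWarning, match="outside the evaluated grid"):
            est = search_statistics(surf, survey=ring_survey, roost=(9000.0, 0.0))
        assert est.rho_c is None

    def test_uniform_surface_degenerate(self, ring_survey):
        grid = GridSpec(-1500, 1500, -1500, 1500, n_x=10, n_y=10)
        surf = build_rho_surface(ring_survey, grid, P)
        surf.rho[:] = 1.0  # degenerate: every cell equally bad
        est = search_statistics(surf, survey=ring_survey, thresholds=(0.999, 1.0))
        assert est.percent_below[1.0] == 100.0
        assert est.percent_below[0.999] == 0.0


class TestConfidenceHeuristic:
    @pytest.mark.parametrize(
        "sep, expected",
        [(280.0, "high"), (0.0, "high"), (750.0, "moderate"), (5000.0, "low")],
    )
    def test_thresholds(self, sep, expected):
        assert confidence_heuristic(sep) == expected

    def test_configurable(self):
        assert confidence_heuristic(280.0, high=100.0, moderate=200.0) == "low"
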