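"""Coded variables, DoE construction, quadratic fitting and optimization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asnase import reference as ref
from asnase.response_surface import (
    CodedFactor, DesirabilitySpec, DegenerateSpecError, DimensionError,
    QuadraticSurface, SingularDesignError, code_point, composite_desirability,
    decode_point, default_desirability_specs, desirability, fit_quadratic,
    make_design, maximize_composite, optimize_on_cube, read_design_csv,
    write_design_csv)


# ---------------------------------------------------------------------------
# coded factors
# ---------------------------------------------------------------------------

class TestCoding:
    @pytest.mark.parametrize("factor, actual, expected", [
        (CodedFactor("peg_mw", 4500, 1500), 6000.0, 1.0),
        (CodedFactor("citrate_pct", 20.8, 5.0), 15.8, -1.0),
        (CodedFactor("pH", 7.8, 1.0), 7.8, 0.0),
    ])
    def test_study_factor_codings(self, factor, actual, expected):
        assert factor.code(actual) == pytest.approx(expected)

    def test_center_point_codes_to_origin(self):
        factors = list(ref.ATPS_FACTORS)
        centers = [f.center for f in factors]
        assert np.allclose(code_point(factors, centers), 0.0)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_exact(self, coded):
        factors = [CodedFactor("a", 72, 36), CodedFactor("b", 6, 2),
                   CodedFactor("c", 4, 2)]
        actual = decode_point(factors, coded)
        assert np.allclose(code_point(factors, actual), coded, atol=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(DimensionError):
            code_point([CodedFactor("a", 0, 1)], [1.0, 2.0])

    def test_nonpositive_half_range_rejected(self):
        with pytest.raises(ValueError):
            CodedFactor("bad", 0.0, 0.0)


# ---------------------------------------------------------------------------
# surface evaluation
# ---------------------------------------------------------------------------

class TestEvaluate:
    @pytest.mark.parametrize("surface_name, b0", [
        ("PROTOPLAST_SURFACE", 5.53),
        ("ATPS_YIELD_SURFACE", 66.29),
        ("ATPS_PURIFICATION_SURFACE", 29.58),
    ])
    def test_origin_returns_intercept(self, surface_name, b0):
        surface = getattr(ref, surface_name)
        assert surface.evaluate(np.zeros(surface.k)) == pytest.approx(b0)

    def test_yield_surface_at_selected_point(self, yield_surface):
        # independent term-by-term sum over the 21 coefficients
        x = np.array([1.0, -1.0, 1.0, 1.0, -1.0])
        expected = yield_surface.b0 + yield_surface.linear @ x
        for b, (i, j) in zip(yield_surface.interactions,
                             itertools.combinations(range(5), 2)):
            expected += b * x[i] * x[j]
        expected += yield_surface.squares @ x ** 2
        assert expected == pytest.approx(44.64)
        assert yield_surface.evaluate(x) == pytest.approx(expected)

    def test_vectorized_matches_pointwise(self, yield_surface):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(20, 5))
        batch = yield_surface.evaluate(pts)
        assert np.allclose(batch, [yield_surface.evaluate(p) for p in pts])

    def test_dimension_mismatch(self, yield_surface):
        with pytest.raises(DimensionError):
            yield_surface.evaluate([0.0, 0.0])

    def test_json_round_trip(self, purification_surface):
        clone = QuadraticSurface.from_json(purification_surface.to_json())
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, size=(10, 5))
        assert np.allclose(clone.evaluate(pts),
                           purification_surface.evaluate(pts))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitQuadratic:
    def test_noiseless_recovery_is_exact(self, protoplast_surface, bbd3):
        y = protoplast_surface.evaluate(bbd3)
        fitted, stats = fit_quadratic(bbd3, y)
        assert fitted.b0 == pytest.approx(protoplast_surface.b0, abs=1e-9)
        assert np.allclose(fitted.linear, protoplast_surface.linear, atol=1e-9)
        assert np.allclose(fitted.interactions,
                           protoplast_surface.interactions, atol=1e-9)
        assert np.allclose(fitted.squares, protoplast_surface.squares,
                           atol=1e-9)
        assert stats.adj_r2 == pytest.approx(1.0)

    def test_constant_responses_give_intercept_only(self, bbd3):
        fitted, _ = fit_quadratic(bbd3, np.full(len(bbd3), 3.7))
        assert fitted.b0 == pytest.approx(3.7)
        assert np.allclose(fitted.linear, 0, atol=1e-9)
        assert np.allclose(fitted.interactions, 0, atol=1e-9)
        assert np.allclose(fitted.squares, 0, atol=1e-9)

    def test_noisy_coefficients_within_three_se(self, protoplast_surface,
                                                bbd3):
        """Across 200 seeded refits with sd = 0.05 noise, per-coefficient
        3-standard-error coverage should sit near its t-distribution value
        (~98% with 7 residual df), comfortably above 95%."""
        truth = np.concatenate((
            [protoplast_surface.b0], protoplast_surface.linear,
            protoplast_surface.interactions, protoplast_surface.squares))
        clean = protoplast_surface.evaluate(bbd3)
        rng = np.random.default_rng(42)
        covered = total = 0
        for _ in range(200):
            y = clean + rng.normal(0, 0.05, clean.shape)
            fitted, stats = fit_quadratic(bbd3, y)
            est = np.concatenate((
                [fitted.b0], fitted.linear, fitted.interactions,
                fitted.squares))
            covered += int(np.sum(np.abs(est - truth) <= 3 * stats.param_se))
            total += truth.size
        assert covered / total >= 0.95

    def test_rmse_at_least_mae(self, protoplast_surface, bbd3):
        rng = np.random.default_rng(7)
        y = protoplast_surface.evaluate(bbd3) + rng.normal(0, 0.1, len(bbd3))
        _, stats = fit_quadratic(bbd3, y)
        assert stats.rmse >= stats.mae

    def test_lack_of_fit_needs_replicates(self, protoplast_surface, bbd3):
        rng = np.random.default_rng(3)
        y = protoplast_surface.evaluate(bbd3) + rng.normal(0, 0.05, len(bbd3))
        _, with_reps = fit_quadratic(bbd3, y)  # 5 center replicates
        assert with_reps.lof_f is not None and with_reps.lof_f >= 0
        assert 0 <= with_reps.lof_p <= 1

    def test_aliased_design_raises_named_error(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-1, 1, size=(30, 3))
        d[:, 2] = d[:, 1]  # x3 aliased with x2
        with pytest.raises(SingularDesignError, match="aliased"):
            fit_quadratic(d, rng.normal(size=30))


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

class TestMakeDesign:
    def test_box_behnken_3_structure(self, bbd3):
        assert bbd3.shape == (17, 3)
        edges = bbd3[:12]
        assert np.all(np.isin(edges, (-1.0, 0.0, 1.0)))
        assert np.all((edges != 0).sum(axis=1) == 2)
        assert np.all(bbd3[12:] == 0)

    def test_face_centred_ccd_5(self, ccd5):
        assert len(ccd5) == 32 + 10 + 5
        assert ccd5.min() >= -1 and ccd5.max() <= 1
        axial = ccd5[32:42]
        assert np.all((axial != 0).sum(axis=1) == 1)

    def test_rotatable_alpha(self):
        d = make_design("central_composite", 2, center_points=0,
                        alpha="rotatable")
        assert np.max(np.abs(d)) == pytest.approx(2 ** 0.5)

    @pytest.mark.parametrize("k, n_runs", [(11, 12), (7, 8), (4, 8)])
    def test_plackett_burman_balance_and_orthogonality(self, k, n_runs):
        d = make_design("plackett_burman", k)
        assert d.shape == (n_runs, k)
        assert np.all(np.isin(d, (-1.0, 1.0)))
        assert np.allclose(d.sum(axis=0), 0)
        # brute-force inner products of all column pairs
        for i, j in itertools.combinations(range(k), 2):
            assert d[:, i] @ d[:, j] == pytest.approx(0)

    def test_bbd_requires_three_factors(self):
        with pytest.raises(ValueError):
            make_design("box_behnken", 2)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_design("latin_square", 3)


# ---------------------------------------------------------------------------
# optimization on the cube
# ---------------------------------------------------------------------------

def _surface(k, b0=0.0, linear=None, interactions=None, squares=None):
    m = k * (k - 1) // 2
    return QuadraticSurface(
        factors=tuple(CodedFactor(f"x{i}", 0, 1) for i in range(k)),
        b0=b0,
        linear=np.zeros(k) if linear is None else np.asarray(linear, float),
        interactions=(np.zeros(m) if interactions is None
                      else np.asarray(interactions, float)),
        squares=np.zeros(k) if squares is None else np.asarray(squares, float),
    )


class TestOptimizeOnCube:
    def test_linear_surface_hits_corner(self):
        s = _surface(2, b0=1.0, linear=[1.0, 1.0])
        x, v = optimize_on_cube(s, "maximize")
        assert np.allclose(x, [1, 1], atol=1e-6)
        assert v == pytest.approx(3.0)

    def test_concave_vertex(self):
        # y = -(x1 - 0.2)^2 peaks at the stationary point -b/(2a) = 0.2
        s = _surface(1, b0=-0.04, linear=[0.4], squares=[-1.0])
        x, v = optimize_on_cube(s, "maximize")
        assert x[0] == pytest.approx(0.2, abs=1e-6)
        assert v == pytest.approx(0.0, abs=1e-10)

    def test_minimize_mirrors_maximize(self):
        s = _surface(2, linear=[1.0, -2.0])
        x, _ = optimize_on_cube(s, "minimize")
        assert np.allclose(x, [-1, 1], atol=1e-6)

    def test_protoplast_surface_dominates_grid(self, protoplast_surface):
        x, v = optimize_on_cube(protoplast_surface, "maximize")
        axes = [np.arange(-1, 1.01, 0.05)] * 3
        grid = np.column_stack(
            [m.ravel() for m in np.meshgrid(*axes, indexing="ij")])
        assert v >= protoplast_surface.evaluate(grid).max() - 1e-9

    def test_multistart_path_reproducible(self, yield_surface):
        x1, v1 = optimize_on_cube(yield_surface, "maximize", seed=11)
        x2, v2 = optimize_on_cube(yield_surface, "maximize", seed=11)
        assert np.array_equal(x1, x2) and v1 == v2
        # quadratic bounded on the cube: optimum beats random probes
        rng = np.random.default_rng(0)
        probes = rng.uniform(-1, 1, size=(2000, 5))
        assert v1 >= yield_surface.evaluate(probes).max() - 1e-6


# ---------------------------------------------------------------------------
# desirability
# ---------------------------------------------------------------------------

class TestDesirability:
    spec = DesirabilitySpec("y", "maximize", low=10.0, target=20.0)

    @pytest.mark.parametrize("y, d", [(20.0, 1.0), (10.0, 0.0), (15.0, 0.5),
                                      (25.0, 1.0), (0.0, 0.0)])
    def test_one_sided_ramp(self, y, d):
        assert desirability(y, self.spec) == pytest.approx(d)

    def test_minimize_mirrored(self):
        spec = DesirabilitySpec("y", "minimize", low=20.0, target=10.0)
        assert desirability(10.0, spec) == pytest.approx(1.0)
        assert desirability(20.0, spec) == pytest.approx(0.0)
        assert desirability(15.0, spec) == pytest.approx(0.5)

    def test_weight_curves_ramp(self):
        spec = DesirabilitySpec("y", "maximize", 0.0, 1.0, weight=2.0)
        assert desirability(0.5, spec) == pytest.approx(0.25)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(DegenerateSpecError):
            DesirabilitySpec("y", "maximize", 5.0, 5.0)


class TestCompositeDesirability:
    def test_all_at_target_gives_one(self, yield_surface,
                                     purification_surface, ccd5):
        surfaces = [yield_surface, purification_surface]
        x = np.zeros(5)
        specs = [DesirabilitySpec(s.response_name, "maximize",
                                  s.evaluate(x) - 5, s.evaluate(x))
                 for s in surfaces]
        assert composite_desirability(surfaces, specs, x) == pytest.approx(1.0)

    def test_one_zero_annihilates(self, yield_surface, purification_surface):
        x = np.zeros(5)
        specs = [
            DesirabilitySpec("a", "maximize", yield_surface.evaluate(x) - 1,
                             yield_surface.evaluate(x)),
            DesirabilitySpec("b", "maximize",
                             purification_surface.evaluate(x) + 1,
                             purification_surface.evaluate(x) + 2),
        ]
        assert composite_desirability(
            [yield_surface, purification_surface], specs, x) == 0.0

    def test_order_invariance(self, yield_surface, purification_surface,
                              ccd5):
        surfaces = [yield_surface, purification_surface]
        specs = default_desirability_specs(surfaces, ccd5,
                                           ["maximize", "maximize"])
        rng = np.random.default_rng(5)
        for x in rng.uniform(-1, 1, size=(10, 5)):
            d1 = composite_desirability(surfaces, specs, x)
            d2 = composite_desirability(surfaces[::-1], specs[::-1], x)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 1.0

    def test_maximizer_dominates_grid(self, yield_surface,
                                      purification_surface, ccd5):
        """Multi-objective optimum of the two extraction models beats a
        0.25-step lattice over the coded cube."""
        surfaces = [yield_surface, purification_surface]
        specs = default_desirability_specs(surfaces, ccd5,
                                           ["maximize", "maximize"])
        x, d = maximize_composite(surfaces, specs, seed=99)
        assert 0.0 <= d <= 1.0
        axes = [np.arange(-1, 1.01, 0.25)] * 5
        grid = np.column_stack(
            [m.ravel() for m in np.meshgrid(*axes, indexing="ij")])
        grid_d = max(composite_desirability(surfaces, specs, p) for p in grid)
        assert d >= grid_d - 1e-9


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_design_csv_round_trip(tmp_path, protoplast_surface, bbd3):
    y = protoplast_surface.evaluate(bbd3)
    path = tmp_path / "design.csv"
    write_design_csv(path, bbd3, y,
                     factor_names=protoplast_surface.factor_names)
    design, responses, names = read_design_csv(path)
    assert np.allclose(design, bbd3)
    assert np.allclose(responses, y)
    assert names == list(protoplast_surface.factor_names)
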