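"""Response-surface screening: design geometry, quadratic fits,
hierarchy-respecting backward elimination and desirability search."""

import numpy as np
import pytest

import ivtwin as iv
from ivtwin.doe import FULL_TERMS, _model_matrix
from ivtwin.synthetic import gen_doe_dataset


@pytest.fixture(scope="module")
def design():
    return iv.generate_design()


class TestDesign:
    def test_fifteen_runs_three_centers(self, design):
        assert design.n_runs == 15
        assert int(design.runs["is_center"].sum()) == 3

    def test_center_maps_to_range_midpoints(self, design):
        center = design.runs[design.runs["is_center"]].iloc[0]
        assert center["temperature"] == pytest.approx(38.5)
        assert center["urea"] == pytest.approx(0.8)
        assert center["additive"] == pytest.approx(0.55)

    def test_coded_columns_sum_to_zero(self, design):
        np.testing.assert_allclose(design.coded.sum(axis=0), 0.0, atol=1e-12)

    def test_quadratic_terms_estimable(self, design):
        X = _model_matrix(design.coded, FULL_TERMS)
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_coded_physical_round_trip(self, design):
        for i, f in enumerate(design.factors, start=1):
            coded = design.runs[f"x{i}"].to_numpy()
            back = f.to_coded(f.to_physical(coded))
            np.testing.assert_allclose(back, coded, atol=1e-12)

    def test_run_order_shuffle_is_seeded(self):
        a = iv.generate_design(seed=5)
        b = iv.generate_design(seed=5)
        assert a.runs.equals(b.runs)

    def test_requires_three_factors(self):
        with pytest.raises(ValueError):
            iv.generate_design(factors=[iv.FactorSpec("x", 0.0, 1.0)])


class TestFitQuadratic:
    def test_exact_coefficient_recovery(self, design):
        y, _ = gen_doe_dataset({"Intercept": 2.0, "x1": 3.0, "x2^2": -1.0}, design)
        m = iv.fit_quadratic(design, y)
        assert m.coef["Intercept"] == pytest.approx(2.0, abs=1e-9)
        assert m.coef["x1"] == pytest.approx(3.0, abs=1e-9)
        assert m.coef["x2^2"] == pytest.approx(-1.0, abs=1e-9)
        for t in set(FULL_TERMS) - {"x1", "x2^2"}:
            assert m.coef[t] == pytest.approx(0.0, abs=1e-9)

    def test_constant_response(self, design):
        m = iv.fit_quadratic(design, np.full(design.n_runs, 7.0))
        for t in FULL_TERMS:
            assert m.coef[t] == pytest.approx(0.0, abs=1e-9)
        assert m.adj_R2 == pytest.approx(0.0, abs=1e-6)
        assert all(m.pvalues[t] == pytest.approx(1.0) for t in FULL_TERMS)

    def test_noisy_recovery_within_3_se(self, design):
        truth = {"Intercept": 5.0, "x1": 2.0, "x3": -1.5, "x1:x3": 1.0, "x2^2": -2.0}
        y, _ = gen_doe_dataset(truth, design, noise_sd=0.1, seed=17)
        m = iv.fit_quadratic(design, y)
        for term in FULL_TERMS:
            err = abs(m.coef[term] - truth.get(term, 0.0))
            assert err < 3 * m.se[term] + 1e-12

    def test_length_mismatch_rejected(self, design):
        with pytest.raises(ValueError):
            iv.fit_quadratic(design, np.zeros(10))

    def test_rank_deficient_design_names_aliased_terms(self):
        d = iv.generate_design(template="factorial")  # corners + centers
        with pytest.raises(ValueError, match="aliased"):
            iv.fit_quadratic(d, np.arange(d.n_runs, dtype=float))


class TestStepwiseReduce:
    def test_recovers_true_support_at_vanishing_noise(self, design):
        truth = {"Intercept": 4.0, "x3": 2.5, "x3^2": -1.8, "x1:x3": 1.2}
        y, _ = gen_doe_dataset(truth, design, noise_sd=0.0, seed=3)
        reduced = iv.stepwise_reduce(iv.fit_quadratic(design, y), alpha=0.05)
        # hierarchy keeps x1 (parent of x1:x3) even if tiny
        assert set(reduced.terms) == {"x1", "x3", "x3^2", "x1:x3"}

    def test_single_strong_main_effect_survives(self, design):
        y, _ = gen_doe_dataset({"Intercept": 1.0, "x2": 5.0}, design,
                               noise_sd=0.5, seed=9)
        reduced = iv.stepwise_reduce(iv.fit_quadratic(design, y))
        assert "x2" in reduced.terms
        assert set(reduced.terms) <= {"x2"} or reduced.pvalues.drop(
            ["Intercept", "x2"], errors="ignore").le(0.05).all()

    def test_all_significant_model_unchanged(self, design):
        truth = {t: 3.0 for t in FULL_TERMS}
        truth["Intercept"] = 1.0
        y, _ = gen_doe_dataset(truth, design, noise_sd=0.01, seed=2)
        full = iv.fit_quadratic(design, y)
        reduced = iv.stepwise_reduce(full)
        assert reduced.terms == full.terms

    def test_hierarchy_keeps_parent_of_retained_interaction(self, design):
        # x1:x2 strong, x1 and x2 truly zero -> both parents retained
        y, _ = gen_doe_dataset({"Intercept": 1.0, "x1:x2": 4.0}, design,
                               noise_sd=0.05, seed=6)
        reduced = iv.stepwise_reduce(iv.fit_quadratic(design, y))
        assert "x1:x2" in reduced.terms
        assert {"x1", "x2"} <= set(reduced.terms)

    def test_refit_is_idempotent(self, design):
        y, _ = gen_doe_dataset({"Intercept": 2.0, "x1": 1.0}, design,
                               noise_sd=0.2, seed=12)
        reduced = iv.stepwise_reduce(iv.fit_quadratic(design, y))
        refit = iv.stepwise_reduce(reduced)
        assert refit.terms == reduced.terms
        np.testing.assert_allclose(refit.coef, reduced.coef, rtol=1e-12)


class TestDesirability:
    def test_monotone_response_pushes_to_boundary(self, design):
        y, _ = gen_doe_dataset({"Intercept": 0.0, "x1": 1.0}, design)
        m = iv.fit_quadratic(design, y)
        opt = iv.desirability_optimize({"y": m}, {"y": "maximize"}, n_grid=11)
        assert opt["coded"][0] == pytest.approx(1.0)

    def test_concave_response_peaks_at_center(self, design):
        truth = {"Intercept": 5.0, "x1^2": -1.0, "x2^2": -1.0, "x3^2": -1.0}
        y, _ = gen_doe_dataset(truth, design)
        m = iv.fit_quadratic(design, y)
        opt = iv.desirability_optimize({"y": m}, {"y": "maximize"}, n_grid=11)
        np.testing.assert_allclose(opt["coded"], 0.0, atol=1e-12)

    def test_trade_off_matches_fine_grid_oracle(self, design):
        y1, _ = gen_doe_dataset(
            {"Intercept": 3.0, "x1": 2.0, "x1^2": -1.0, "x2": 0.5}, design)
        y2, _ = gen_doe_dataset(
            {"Intercept": 1.0, "x1": -1.5, "x2^2": 2.0}, design)
        m1 = iv.fit_quadratic(design, y1, response="yield")
        m2 = iv.fit_quadratic(design, y2, response="truncated")
        goals = {"yield": "maximize", "truncated": "minimize"}
        coarse = iv.desirability_optimize({"yield": m1, "truncated": m2},
                                          goals, n_grid=21)
        fine = iv.desirability_optimize({"yield": m1, "truncated": m2},
                                        goals, n_grid=81)
        step = 2.0 / 20
        assert np.all(np.abs(coarse["coded"] - fine["coded"]) <= step + 1e-9)


class TestContour:
    def test_constant_model_gives_constant_matrix(self, design):
        y, _ = gen_doe_dataset({"Intercept": 4.2}, design)
        m = iv.fit_quadratic(design, y)
        out = iv.contour_eval(m, ("temperature", "additive"), {"urea": 0.8}, n_grid=8)
        np.testing.assert_allclose(out["z"], 4.2, atol=1e-9)

    def test_pure_x1_model_varies_only_along_x1(self, design):
        y, _ = gen_doe_dataset({"Intercept": 1.0, "x1": 2.0}, design)
        m = iv.fit_quadratic(design, y)
        out = iv.contour_eval(m, ("temperature", "urea"), {"additive": 0.55}, n_grid=6)
        # temperature is x1 -> rows identical, columns vary
        np.testing.assert_allclose(out["z"] - out["z"][0], 0.0, atol=1e-9)
        assert np.ptp(out["z"][0]) > 0

    def test_matches_direct_model_evaluation(self, design):
        y, _ = gen_doe_dataset(
            {"Intercept": 1.0, "x1": 0.7, "x2:x3": -0.4, "x3^2": 0.9}, design)
        m = iv.fit_quadratic(design, y)
        out = iv.contour_eval(m, ("urea", "additive"), {"temperature": 39.0}, n_grid=5)
        for i, av in enumerate(out["y"]):
            for j, uv in enumerate(out["x"]):
                direct = m.predict_physical(np.array([[39.0, uv, av]]))[0]
                assert out["z"][i, j] == pytest.approx(direct, rel=1e-12)
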