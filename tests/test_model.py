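import math

import numpy as np
import pytest
from scipy.stats import norm

from proclens import (
    Dataset,
    DegenerateGridError,
    EstimationError,
    Event,
    Grid,
    LandmarkTable,
    ModelParams,
    ProcessRecord,
    build_landmark_table,
    fit,
    fit_duration,
    fit_outcome,
    load_model,
    log_pseudo_likelihood,
    log_pseudo_likelihood_parts,
    save_model,
    select_grid,
    SimConfig,
    simulate_dataset,
)

from oracles import duration_bfgs, probit_grid_search


def make_table(X, y, z, names=None):
    names = names or [f"x{k}" for k in range(np.asarray(X).shape[1])]
    return LandmarkTable.from_arrays(np.asarray(X, float), y, z, names)


class TestSelectGrid:
    def test_levels_are_equally_spaced_quantiles(self):
        grid = select_grid(np.arange(1, 101), J=9)
        assert grid.points.tolist() == [10, 20, 30, 40, 50, 60, 70, 80, 90]

    def test_single_point_is_median(self):
        grid = select_grid([10, 20, 30], J=1)
        assert grid.points.tolist() == [20.0]

    def test_constant_durations_degenerate(self):
        with pytest.raises(DegenerateGridError):
            select_grid([5.0, 5.0, 5.0], J=1)

    def test_duplicate_quantiles_collapse(self, caplog):
        durations = [1.0] * 90 + list(range(2, 12))  # heavy atom at 1.0
        import logging

        with caplog.at_level(logging.WARNING, logger="proclens.model"):
            grid = select_grid(durations, J=3)
        assert grid.points.tolist() == [1.0]  # 25/50/75% quantiles coincide
        assert any("collapsed" in m for m in caplog.messages)

    def test_too_many_points_rejected(self):
        with pytest.raises(DegenerateGridError):
            select_grid([1.0, 2.0, 3.0], J=3)


class TestFitOutcome:
    def test_intercept_only_balanced(self):
        lt = make_table(np.ones((40, 1)), [0, 1] * 20, np.zeros(40))
        res = fit_outcome(lt)
        assert res.converged
        assert res.b1[0] == pytest.approx(0.0, abs=1e-8)  # Phi(0) = 1/2

    def test_two_cell_design_matches_probit_quantiles(self):
        # success rates 0.25 (x=0) and 0.75 (x=1), perfectly balanced cells
        X = np.column_stack([np.ones(80), np.repeat([0.0, 1.0], 40)])
        y = np.concatenate([np.tile([1, 0, 0, 0], 10), np.tile([1, 1, 1, 0], 10)])
        z = np.zeros(80)
        res = fit_outcome(make_table(X, y, z))
        q25, q75 = norm.ppf(0.25), norm.ppf(0.75)
        assert res.b1[0] == pytest.approx(q25, abs=1e-6)
        assert res.b1[0] + res.b1[1] == pytest.approx(q75, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(30, 51))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = (rng.random(n) < norm.cdf(X @ [0.3, 0.8])).astype(int)
            if len(np.unique(y)) < 2:
                continue
            res = fit_outcome(make_table(X, y, np.zeros(n)))
            _, ll_oracle = probit_grid_search(X, y)
            assert res.loglik == pytest.approx(ll_oracle, abs=1e-4)

    def test_single_class_rejected(self):
        lt = make_table(np.ones((10, 1)), np.ones(10, dtype=int), np.zeros(10))
        with pytest.raises(EstimationError, match="both classes"):
            fit_outcome(lt)

    def test_separation_reported_not_raised(self):
        X = np.column_stack([np.ones(20), np.concatenate([-np.ones(10), np.ones(10)])])
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        res = fit_outcome(make_table(X, y, np.zeros(20)))
        assert not res.converged
        assert res.message != ""


class TestFitDuration:
    def test_constant_response_perfect_fit(self):
        lt = make_table(np.ones((5, 1)), [0, 1, 0, 1, 0], np.full(5, 2.5))
        res = fit_duration(lt)
        assert res.b2[0] == pytest.approx(2.5)
        assert res.sigma2 == 0.0
        assert res.loglik == math.inf

    def test_matches_numerical_maximizer(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(20, 51))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            z = X @ [1.0, -0.5, 0.3] + rng.normal(0, 0.8, size=n)
            res = fit_duration(make_table(X, [0, 1] * (n // 2) + [0] * (n % 2), z))
            b_o, s2_o, ll_o = duration_bfgs(X, z)
            np.testing.assert_allclose(res.b2, b_o, atol=1e-6)
            assert res.sigma2 == pytest.approx(s2_o, abs=1e-6)
            assert res.loglik == pytest.approx(ll_o, abs=1e-6)

    def test_sigma2_is_mean_squared_residual(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        z = rng.normal(size=30)
        res = fit_duration(make_table(X, [0, 1] * 15, z))
        resid = z - X @ res.b2
        assert res.sigma2 == pytest.approx(float(np.mean(resid**2)), rel=1e-12)

    def test_collinear_design_names_columns(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(EstimationError, match="collinear"):
            fit_duration(make_table(X, [0, 1] * 10, np.zeros(20), names=["a", "b"]))


@pytest.fixture(scope="module")
def fitted(sim_small, sim_small_cfg):
    cfg = sim_small_cfg
    return cfg, fit(sim_small, [cfg.anchor_time], cfg.feature_names)


class TestFitComposition:
    def test_total_is_sum_of_parts(self, fitted):
        _, res = fitted
        assert res.loglik_total == pytest.approx(
            res.loglik_outcome + res.loglik_duration, rel=1e-8
        )

    def test_single_landmark_equals_manual_stack(self, sim_small, fitted):
        cfg, res = fitted
        lt = build_landmark_table(sim_small, [cfg.anchor_time], cfg.feature_names)
        out = fit_outcome(lt)
        dur = fit_duration(lt)
        np.testing.assert_allclose(res.params.b1, out.b1, rtol=1e-12)
        np.testing.assert_allclose(res.params.b2, dur.b2, rtol=1e-12)
        assert res.params.sigma2 == dur.sigma2

    def test_grid_above_max_duration_fails(self, sim_small):
        top = float(sim_small.durations.max()) + 1
        with pytest.raises(EstimationError, match="empty"):
            fit(sim_small, [top], ["const", "N"])

    def test_factorization_parts_independent(self, sim_small, fitted):
        cfg, res = fitted
        p = res.params
        bumped_b1 = ModelParams(p.b1 + 0.3, p.b2, p.sigma2, p.spec_names)
        _, out0, dur0 = log_pseudo_likelihood_parts(p, sim_small, [cfg.anchor_time])
        _, out1, dur1 = log_pseudo_likelihood_parts(bumped_b1, sim_small, [cfg.anchor_time])
        assert dur0 == dur1
        assert out0 != out1

    def test_fitted_params_beat_perturbations(self, sim_small, fitted):
        cfg, res = fitted
        p = res.params
        base = log_pseudo_likelihood(p, sim_small, [cfg.anchor_time])
        rng = np.random.default_rng(3)
        for _ in range(5):
            delta = rng.normal(0, 0.05, size=p.b1.size)
            alt = ModelParams(p.b1 + delta, p.b2 - delta, p.sigma2 * 1.05, p.spec_names)
            assert log_pseudo_likelihood(alt, sim_small, [cfg.anchor_time]) <= base + 1e-8 * abs(base)

    def test_model_roundtrips_through_json(self, fitted, tmp_path):
        _, res = fitted
        save_model(res, tmp_path / "m.json")
        params, grid, diag = load_model(tmp_path / "m.json")
        np.testing.assert_allclose(params.b1, res.params.b1)
        np.testing.assert_allclose(params.b2, res.params.b2)
        assert params.sigma2 == res.params.sigma2
        assert params.spec_names == res.params.spec_names
        assert grid.points.tolist() == res.grid.points.tolist()
        assert diag["n_rows"] == res.n_rows


class TestLogPseudoLikelihood:
    def test_empty_product_is_zero(self, table1):
        params = ModelParams([0.0], [0.0], 1.0, ("const",))
        ds = Dataset((table1,))
        assert log_pseudo_likelihood(params, ds, [100.0]) == 0.0

    def test_hand_evaluated_single_row(self):
        # one at-risk row: y=1, eta1=0, zero residual, sigma2=1
        # contribution = log 1/2 - log(tau - t) - log sqrt(2 pi)
        tau, t = 8.0, 3.0
        rec = ProcessRecord("h", (Event(0.0, "start"),), tau, 1)
        params = ModelParams([0.0], [math.log(tau - t)], 1.0, ("const",))
        got = log_pseudo_likelihood(params, Dataset((rec,)), [t])
        expected = math.log(0.5) - math.log(tau - t) - 0.5 * math.log(2 * math.pi)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_sentinel(self):
        rec = ProcessRecord("h", (Event(0.0, "start"),), 8.0, 1)
        params = ModelParams([0.0], [0.0], 0.0, ("const",))  # residual log(5) != 0
        assert log_pseudo_likelihood(params, Dataset((rec,)), [3.0]) == -math.inf

    def test_mismatched_features_rejected(self, sim_small):
        params = ModelParams([0.0], [0.0], 1.0, ("const",))
        with pytest.raises(ValueError, match="mismatch"):
            log_pseudo_likelihood(params, sim_small, [30.0], specs=["N"])


class TestScaleEquivariance:
    def test_time_rescaling_shifts_intercept_only(self):
        cfg = SimConfig(n_individuals=150, seed=7, feature_names=("const",),
                        b1_true=(0.2,), b2_true=(4.0,))
        ds = simulate_dataset(cfg)
        c = 3.0
        scaled = Dataset(tuple(
            ProcessRecord(r.person_id, (Event(0.0, "start"),), r.duration * c, r.outcome)
            for r in ds
        ))
        base = Dataset(tuple(
            ProcessRecord(r.person_id, (Event(0.0, "start"),), r.duration, r.outcome)
            for r in ds
        ))
        t0 = cfg.anchor_time
        res = fit(base, [t0], ["const"])
        res_c = fit(scaled, [t0 * c], ["const"])
        assert res_c.params.b2[0] == pytest.approx(res.params.b2[0] + math.log(c), rel=1e-10)
        assert res_c.params.sigma2 == pytest.approx(res.params.sigma2, rel=1e-10)
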