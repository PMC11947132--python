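"""Method-of-moments weight solver: exactness, oracles, ESS behavior."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import anchormaic as am
from anchormaic.containers import AgDSummary, BaselineTarget
from anchormaic.exceptions import InfeasibleTargetError, MAICError


def _targets(**values):
    rows = []
    for name, v in values.items():
        kind = "binary" if name == "male" else "continuous"
        rows.append(
            BaselineTarget(
                name=name, kind=kind, value=v, sd=None if kind == "binary" else 1.0
            )
        )
    return AgDSummary(n_active=10, n_anchor=10, baseline_targets=rows)


class TestCentering:
    def test_symmetric_pair(self):
        ipd = pd.DataFrame({"x": [4.0, 6.0]})
        centered = am.center_covariates(ipd, _targets(x=5.0), ["x"])
        assert centered[:, 0].tolist() == [-1.0, 1.0]

    def test_published_baseline_differences(self):
        # patients placed so the sample means hit the XINDI pooled values
        # exactly; centering on the comparator's targets leaves the published
        # mean differences as column means
        n = 100
        ipd = pd.DataFrame(
            {
                "age": [61.6 - 1, 61.6 + 1] * (n // 2),
                "male": [1] * 58 + [0] * 42,  # proportion 0.58
                "bmi": [23.9 - 0.5, 23.9 + 0.5] * (n // 2),
                "off_baseline": [5.7 - 1, 5.7 + 1] * (n // 2),
            }
        )
        tg = _targets(age=62.2, bmi=23.1, off_baseline=6.1)
        tg.baseline_targets.append(BaselineTarget(name="male", kind="binary", value=0.66))
        centered = am.center_covariates(ipd, tg, ["age", "male", "bmi", "off_baseline"])
        np.testing.assert_allclose(
            centered.mean(axis=0), [-0.6, 0.58 - 0.66, 0.8, -0.4], atol=1e-12
        )

    def test_missing_covariate_is_named(self):
        ipd = pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 1.0]})
        # present in the IPD but absent from the aggregate targets
        with pytest.raises(KeyError, match="y"):
            am.center_covariates(ipd, _targets(x=1.5), ["x", "y"])
        # absent from the IPD altogether
        with pytest.raises(MAICError, match="z"):
            am.center_covariates(ipd, _targets(z=1.0), ["z"])

    def test_constant_covariate_off_target_is_infeasible(self):
        ipd = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(InfeasibleTargetError):
            am.center_covariates(ipd, _targets(x=3.0), ["x"])


class TestSolver:
    def test_identity_when_targets_equal_means(self, rng):
        X = rng.normal(size=(40, 3))
        centered = X - X.mean(axis=0)
        ws = am.estimate_weights(centered)
        assert ws.converged and ws.iterations == 0
        np.testing.assert_array_equal(ws.beta, np.zeros(3))
        np.testing.assert_array_equal(ws.weights, np.ones(40))
        assert ws.ess_total == 40.0

    def test_one_covariate_matches_bisection_oracle(self):
        centered = np.array([[-1.0], [-1.0], [1.0]])
        ws = am.estimate_weights(centered)
        # independent oracle: root of the tilting gradient in one dimension
        beta_oracle = optimize.brentq(
            lambda b: -2.0 * np.exp(-b) + np.exp(b), -5, 5, xtol=1e-14
        )
        assert beta_oracle == pytest.approx(0.5 * np.log(2.0), abs=1e-12)
        assert ws.beta[0] == pytest.approx(beta_oracle, abs=1e-10)
        np.testing.assert_allclose(
            ws.weights / ws.weights[0], [1.0, 1.0, 2.0], atol=1e-10
        )
        # matched mean: weighted mean of centered values is zero
        assert (ws.weights @ centered[:, 0]) / ws.weights.sum() == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_covariates_match_grid_search_oracle(self, rng):
        X = rng.normal(size=(30, 2))
        lam = rng.dirichlet(np.ones(30))
        target = lam @ X
        centered = X - target
        ws = am.estimate_weights(centered)

        def q(b):
            return np.exp(centered @ b).sum()

        # coarse-to-fine grid search, independent of the Newton path
        best = np.zeros(2)
        width = 4.0
        for _ in range(8):
            g0 = np.linspace(best[0] - width, best[0] + width, 41)
            g1 = np.linspace(best[1] - width, best[1] + width, 41)
            vals = np.array([[q(np.array([a, b])) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            best = np.array([g0[i], g1[j]])
            width /= 8.0
        np.testing.assert_allclose(ws.beta, best, atol=1e-4)

    def test_exact_balance_on_feasible_instance(self, rng):
        X = rng.normal(size=(80, 4)) * [10, 1, 3, 2] + [60, 0.5, 24, 6]
        lam = rng.dirichlet(np.ones(80))
        target = lam @ X
        ws = am.estimate_weights(X - target)
        assert ws.converged
        achieved = (ws.weights @ X) / ws.weights.sum()
        np.testing.assert_allclose(achieved, target, rtol=1e-8)
        # convexity sanity: the optimum is no worse than β = 0
        assert ws.objective_value <= X.shape[0] + 1e-9

    def test_target_outside_hull_is_infeasible(self, rng):
        x = rng.normal(size=(20, 1))
        with pytest.raises(InfeasibleTargetError, match="x0"):
            am.estimate_weights(x - (x.max() + 1.0))

    def test_collinear_covariates_are_rejected(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(MAICError, match="collinear"):
            am.estimate_weights(X - X.mean(axis=0))

    def test_more_covariates_than_patients_rejected(self):
        with pytest.raises(MAICError):
            am.estimate_weights(np.zeros((2, 3)))


class TestESS:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            (np.ones(10), 10.0),
            (np.array([3.0, 1.0]), 1.6),
            (np.array([1.0, 1.0, 2.0]), 16.0 / 6.0),
        ],
    )
    def test_hand_values(self, weights, expected):
        assert am.effective_sample_size(weights) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_weights_error(self):
        with pytest.raises(MAICError):
            am.effective_sample_size(np.zeros(5))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=50)
    )
    def test_bounds_and_scale_invariance(self, ws):
        w = np.asarray(ws)
        ess = am.effective_sample_size(w)
        assert 1.0 - 1e-9 <= ess <= len(w) + 1e-9
        assert am.effective_sample_size(17.3 * w) == pytest.approx(ess, rel=1e-12)
        if len(set(ws)) > 1:
            assert ess < len(w) - 1e-12 or np.allclose(w, w[0])

    def test_ess_decreases_with_increasing_shift(self, rng):
        """Pushing the target further from the sample mean never increases ESS."""
        x = rng.normal(size=(200, 1))
        ess_grid = []
        for delta in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            ws = am.estimate_weights(x - (x.mean() + delta))
            ess_grid.append(ws.ess_total)
        assert all(a >= b - 1e-9 for a, b in zip(ess_grid, ess_grid[1:]))

    def test_ess_shrinks_under_published_magnitude_shift(self, fitted, ipd):
        assert fitted.ess < len(ipd)
        assert fitted.ess > 1.0


class TestRescale:
    def test_mean_one_on_equal_weights(self, rng):
        centered = rng.normal(size=(15, 1))
        ws = am.estimate_weights(centered - centered.mean())
        out = am.rescale_weights(ws, "mean_one")
        np.testing.assert_allclose(out.weights, np.ones(15))

    def test_invariants_under_rescale(self, ipd, agd):
        centered = am.center_covariates(ipd, agd, ["age", "bmi"])
        ws = am.estimate_weights(centered, ["age", "bmi"])
        for mode in ("raw", "sum_to_n", "mean_one"):
            out = am.rescale_weights(ws, mode)
            assert out.ess_total == pytest.approx(ws.ess_total, rel=1e-12)
            m0 = (ws.weights @ ipd["age"]) / ws.weights.sum()
            m1 = (out.weights @ ipd["age"]) / out.weights.sum()
            assert m1 == pytest.approx(m0, abs=1e-12)

    def test_unknown_mode_and_unconverged_rejected(self, rng):
        centered = rng.normal(size=(15, 1))
        ws = am.estimate_weights(centered - centered.mean())
        with pytest.raises(MAICError):
            am.rescale_weights(ws, "normalize")
        ws.converged = False
        with pytest.raises(MAICError):
            am.rescale_weights(ws, "mean_one")
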