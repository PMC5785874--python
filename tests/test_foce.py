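"""FOCE-I engine against linear-Gaussian closed forms.

For a linear structural model with additive error the FOCE linearisation
is exact, so the engine must reproduce textbook mixed-model results:
ridge-style posterior modes, the marginal Gaussian -2 log likelihood, and
analytically standardized residuals.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fenofed.foce import (LOG, SHIFTED_LOG, SubjectProblem, conditional_mode,
                          interval, linearized_residuals, subject_ofv,
                          total_ofv)

LOG2PI = np.log(2 * np.pi)


def linear_subject(y, theta, omega, sigma, label="s"):
    """y_j = theta + eta + eps_j with additive error (identity model)."""
    y = np.asarray(y, dtype=float)

    def predict(b):
        return np.full(len(y), theta + b[0])

    def predict_jac(b):
        return predict(b), np.ones((len(y), 1))

    return SubjectProblem(label=label, y=y, predict=predict,
                          predict_jac=predict_jac,
                          sd_b=np.array([omega]), sigma=sigma,
                          error="additive")


def exact_marginal_m2ll(y, theta, omega, sigma):
    """Closed-form -2 log N(y | theta*1, omega^2*J + sigma^2*I)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = omega ** 2 * np.ones((n, n)) + sigma ** 2 * np.eye(n)
    r = y - theta
    sign, logdet = np.linalg.slogdet(C)
    return float(r @ np.linalg.solve(C, r) + logdet + n * LOG2PI)


class TestConditionalMode:
    def test_single_observation_matches_ridge_solution(self):
        # posterior mode: eta = omega^2 (y - theta) / (omega^2 + sigma^2)
        y, theta, omega, sigma = 2.0, 0.5, 0.7, 0.3
        prob = linear_subject([y], theta, omega, sigma)
        inner = conditional_mode(prob)
        expected = omega ** 2 * (y - theta) / (omega ** 2 + sigma ** 2)
        assert inner.b[0] == pytest.approx(expected, abs=1e-8)

    def test_vanishing_omega_pins_mode_at_zero(self):
        prob = linear_subject([2.0, 1.5], 1.0, 1e-8, 0.3)
        inner = conditional_mode(prob)
        assert abs(inner.b[0]) < 1e-6

    def test_two_starts_agree_on_convex_problem(self):
        prob = linear_subject([1.2], 1.0, 0.5, 0.2)
        a = conditional_mode(prob, b0=np.array([0.0]))
        b = conditional_mode(prob, b0=np.array([0.1]))
        assert abs(a.b[0] - b.b[0]) < 1e-6

    def test_shrinkage_to_zero_for_large_residual_error(self):
        # as sigma grows the data stop informing eta: EBE -> 0
        prev = np.inf
        for sigma in (0.5, 5.0, 50.0):
            prob = linear_subject([3.0, 2.0], 1.0, 0.8, sigma)
            mode = abs(conditional_mode(prob).b[0])
            assert mode < prev
            prev = mode
        assert prev < 1e-3


class TestObjective:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_linear_gaussian_marginal(self, seed):
        rng = np.random.default_rng(seed)
        theta, omega, sigma = 1.3, 0.6, 0.25
        problems, exact = [], 0.0
        for i in range(5):
            n = rng.integers(1, 6)
            y = theta + rng.normal(0, omega) + rng.normal(0, sigma, n)
            problems.append(linear_subject(y, theta, omega, sigma, label=i))
            exact += exact_marginal_m2ll(y, theta, omega, sigma)
        assert total_ofv(problems) == pytest.approx(exact, abs=1e-4)

    def test_degenerate_hierarchy_equals_naive_pooled(self):
        # Omega -> 0: OFV collapses to the pooled additive-error -2LL
        y = np.array([1.1, 0.8, 1.4])
        theta, sigma = 1.0, 0.3
        prob = linear_subject(y, theta, 0.0, sigma)
        inner = conditional_mode(prob)
        ofv = subject_ofv(prob, inner)
        r = y - theta
        pooled = float(np.sum(r ** 2) / sigma ** 2
                       + len(y) * np.log(sigma ** 2) + len(y) * LOG2PI)
        assert ofv == pytest.approx(pooled, abs=1e-10)

    def test_subject_without_observations_contributes_nothing(self):
        empty = linear_subject([], 1.0, 0.5, 0.3)
        inner = conditional_mode(empty)
        assert subject_ofv(empty, inner) == 0.0

    def test_cwres_matches_analytic_standardization(self):
        rng = np.random.default_rng(4)
        theta, omega, sigma = 2.0, 0.5, 0.4
        y = theta + rng.normal(0, omega) + rng.normal(0, sigma, 6)
        prob = linear_subject(y, theta, omega, sigma)
        inner = conditional_mode(prob)
        cwres = linearized_residuals(prob, inner)
        C = omega ** 2 * np.ones((6, 6)) + sigma ** 2 * np.eye(6)
        expected = np.linalg.solve(np.linalg.cholesky(C), y - theta)
        assert np.allclose(cwres, expected, atol=1e-8)


class TestTransforms:
    @settings(deadline=None, max_examples=100)
    @given(x=st.floats(1e-6, 1e4))
    def test_log_round_trip(self, x):
        assert LOG.to_natural(LOG.to_unconstrained(x)) == pytest.approx(x)

    @settings(deadline=None, max_examples=100)
    @given(x=st.floats(-0.999, 100.0))
    def test_shifted_log_round_trip(self, x):
        t = SHIFTED_LOG.to_unconstrained(x)
        assert SHIFTED_LOG.to_natural(t) == pytest.approx(x, abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(x=st.floats(-0.99, 9.99))
    def test_interval_round_trip_and_bounds(self, x):
        tr = interval(-1.0, 10.0)
        t = tr.to_unconstrained(x)
        back = tr.to_natural(t)
        assert back == pytest.approx(x, abs=1e-9)
        assert -1.0 < tr.to_natural(-50.0) < tr.to_natural(50.0) < 10.0
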