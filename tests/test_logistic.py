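"""Four-parameter logistic curve, its derivative and the self-start routine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares

from lfmcdyn import LogisticParams, evaluate_logistic, logistic_rate, self_start
from lfmcdyn.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
)

P = LogisticParams(A=100.0, w=20.0, m=30.0, s=-16.0)


class TestEvaluate:
    def test_midpoint_is_mean_of_asymptotes(self):
        assert evaluate_logistic(P, 30.0) == pytest.approx(60.0, abs=1e-12)

    def test_known_value(self):
        # direct scalar evaluation: 20 + 80 / (1 + exp((30-10)/-16))
        assert evaluate_logistic(P, 10.0) == pytest.approx(82.184, abs=5e-4)

    def test_lower_asymptote_far_future(self):
        gw = LogisticParams(A=54.3, w=29.1, m=30.9, s=-16.1)
        assert evaluate_logistic(gw, 1e6) == pytest.approx(29.1, abs=1e-9)

    def test_upper_asymptote_far_past(self):
        assert evaluate_logistic(P, -1e6) == pytest.approx(100.0, abs=1e-9)

    def test_vectorised(self):
        t = np.array([0.0, 30.0, 60.0])
        y = evaluate_logistic(P, t)
        assert y.shape == (3,)
        assert np.all(np.diff(y) < 0)  # declining curve

    def test_zero_s_rejected(self):
        with pytest.raises(InvalidParameterError):
            LogisticParams(A=100, w=20, m=30, s=0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            LogisticParams(A=np.nan, w=20, m=30, s=-16)
        with pytest.raises(InvalidParameterError):
            evaluate_logistic(P, np.inf)


class TestRate:
    def test_peak_rate_closed_form(self):
        # at the inflection: (A - w) / (4 s)
        assert logistic_rate(P, 30.0) == pytest.approx(-1.25, abs=1e-12)

    def test_rate_vanishes_at_asymptotes(self):
        far = 30.0 + 1e4 * 16.0
        assert abs(logistic_rate(P, far)) < 1e-12
        assert abs(logistic_rate(P, -far)) < 1e-12

    def test_everywhere_negative_for_declining_curve(self):
        t = np.linspace(-50, 150, 201)
        assert np.all(logistic_rate(P, t) < 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        A=st.floats(30, 400), w=st.floats(1, 29), m=st.floats(0, 90),
        s=st.floats(-40, -2), t=st.floats(-20, 110),
    )
    def test_matches_finite_differences(self, A, w, m, s, t):
        p = LogisticParams(A=A, w=w, m=m, s=s)
        h = 1e-6 * max(1.0, abs(t))
        fd = (evaluate_logistic(p, t + h) - evaluate_logistic(p, t - h)) / (2 * h)
        assert logistic_rate(p, t) == pytest.approx(fd, rel=1e-6, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(delta=st.floats(0, 200), s=st.floats(-40, -2))
    def test_symmetric_about_inflection(self, delta, s):
        p = LogisticParams(A=100, w=20, m=30, s=s)
        assert logistic_rate(p, 30 + delta) == pytest.approx(
            logistic_rate(p, 30 - delta), rel=1e-12, abs=1e-300
        )

    @settings(derandomize=True, max_examples=50)
    @given(A=st.floats(30, 400), w=st.floats(1, 29), m=st.floats(0, 90),
           s=st.floats(-40, -2))
    def test_midpoint_identity_holds_for_all_params(self, A, w, m, s):
        p = LogisticParams(A=A, w=w, m=m, s=s)
        assert evaluate_logistic(p, m) == pytest.approx((A + w) / 2, rel=1e-14)


def _refit(t, y, start):
    def resid(x):
        return evaluate_logistic(LogisticParams(*x), t) - y

    return least_squares(resid, [start.A, start.w, start.m, start.s])


class TestSelfStart:
    def test_noiseless_curve_recovered_via_refit(self):
        t = np.linspace(0, 90, 50)
        y = evaluate_logistic(P, t)
        start = self_start(t, y)
        sol = _refit(t, y, start)
        assert sol.success
        np.testing.assert_allclose(sol.x, [100, 20, 30, -16], rtol=1e-4)

    def test_declining_data_give_negative_s(self):
        t = np.linspace(0, 90, 30)
        assert self_start(t, evaluate_logistic(P, t)).s < 0

    def test_increasing_data_give_positive_s(self):
        t = np.linspace(0, 90, 30)
        y = evaluate_logistic(P, t)[::-1]
        assert self_start(t, y).s > 0

    def test_constant_response_rejected(self):
        t = np.linspace(0, 90, 10)
        with pytest.raises(DegenerateDataError):
            self_start(t, np.full(10, 50.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            self_start([0, 1, 2, 3], [5, 4, 3, 2])
        with pytest.raises(InsufficientDataError):
            self_start([0, 0, 1, 1, 1], [5, 5, 3, 3, 3])

    def test_bounds_contain_all_observations(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 90, 40)
        y = evaluate_logistic(P, t) + rng.normal(0, 4, 40)
        start = self_start(t, y)
        assert start.w < y.min() and start.A > y.max()

    def test_adequate_for_noisy_refits(self):
        """Least squares started from self_start converges on >= 95% of
        noisy replicates (noise SD = 5% of the curve range)."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 90, 40)
        clean = evaluate_logistic(P, t)
        sd = 0.05 * np.ptp(clean)
        ok = 0
        for _ in range(100):
            y = clean + rng.normal(0, sd, t.size)
            try:
                sol = _refit(t, y, self_start(t, y))
            except Exception:
                continue
            if sol.success and abs(sol.x[0] - 100) < 25:
                ok += 1
        assert ok >= 95
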