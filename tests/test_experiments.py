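"""Diagnostic experiments: step responses, kernel fits, tracking, 3D traversal."""

import math

import numpy as np
import pytest

from chemoevolve.experiments import (
    GaussianWorldResult,
    TimeSeries,
    autocorrelation,
    circular_mean,
    circular_std,
    departure_theta,
    fit_step_response,
    step_alpha_closed_form,
    step_response_timecourse,
    traverse_3d,
    tumble_probability,
    two_gaussian_experiment,
)
from chemoevolve.field import Field3D, FieldParams, concentration_3d, make_field_3d
from chemoevolve.fixtures import RSPH_FIT_PARAMS, synthetic_step_series
from chemoevolve.response import ResponseParams

OPTIMIZED = {
    # strategies optimized for slowly-varying, wide-peaked conditions
    "adaptive": ResponseParams(0.0084, 54.0, -1500.0, 1500.0, 0.020, "adaptive"),
    "inverted": ResponseParams(0.0063, 0.3, 4.4, 0.0, 5.0, "inverted"),
    "speculator": ResponseParams(0.0089, 0.056, 74.0, -67.0, 33.0, "speculator"),
}


class TestStepResponse:
    def test_recursion_matches_closed_form(
        self, adaptive_demo, inverted_demo, speculator_demo
    ):
        for p in (adaptive_demo, inverted_demo, speculator_demo):
            ts = step_response_timecourse(p, 1.0, 50.0, 350.0, 600.0, dt=0.25)
            exact = step_alpha_closed_form(p, 1.0, 50.0, 350.0, ts.t)
            assert np.allclose(ts.y, exact, rtol=1e-9, atol=1e-9)

    def test_plateau_rates_by_strategy(
        self, adaptive_demo, inverted_demo, speculator_demo
    ):
        # steady state under c0 = 1: alpha0 + (A + B)
        for p, expected in ((adaptive_demo, 10.0), (speculator_demo, 12.0), (inverted_demo, 30.0)):
            ts = step_response_timecourse(p, 1.0, 50.0, 350.0, 400.0, dt=0.25)
            alpha_300 = ts.y[np.searchsorted(ts.t, 300.0)]
            assert alpha_300 == pytest.approx(expected, abs=1e-6)

    def test_optimized_responses_move_in_observed_directions(self):
        # on attractant removal the adaptive rate spikes above basal;
        # inverted and speculator rates rise on addition instead
        for name, p in OPTIMIZED.items():
            ts = step_response_timecourse(p, 1.0, 50.0, 350.0, 420.0)
            after_on = ts.y[(ts.t > 55.0) & (ts.t < 80.0)].max()
            after_off = ts.y[(ts.t > 350.0) & (ts.t < 400.0)].max()
            if name == "adaptive":
                assert after_off > 10 * p.alpha0
            else:
                assert after_on > 10 * p.alpha0

    def test_time_step_capped_at_memory_resolution(self, adaptive_demo):
        with pytest.raises(ValueError):
            step_response_timecourse(adaptive_demo, dt=adaptive_demo.tau)


class TestTumbleProbability:
    def test_quasi_steady_occupancy(self):
        assert tumble_probability(1.0, 3.0) == pytest.approx(0.25)

    def test_dynamic_occupancy_relaxes_to_quasi_steady(self):
        t = np.linspace(0, 400, 2001)
        alpha = np.where(t < 100, 0.1, 0.4)
        p = tumble_probability(alpha, 0.1, t)
        assert p[0] == pytest.approx(0.5)
        assert p[-1] == pytest.approx(0.8, abs=1e-6)
        # the transition is gradual: halfway point reached after ~1/(a+b)
        k = np.searchsorted(t, 100.0)
        assert p[k + 1] < 0.75

    def test_rate_rescaling_changes_dynamics_not_plateaus(self):
        # the quasi-steady occupancy is scale invariant; the lag is not
        t = np.linspace(0, 400, 2001)
        alpha = np.where(t < 100, 0.1, 0.4)
        p1 = tumble_probability(alpha, 0.1, t)
        p2 = tumble_probability(10 * alpha, 1.0, t)
        assert p1[-1] == pytest.approx(p2[-1], abs=1e-9)
        assert not np.allclose(p1, p2, atol=1e-3)


class TestKernelFit:
    def test_noiseless_recovery_is_exact(self):
        series = synthetic_step_series(noise=0.0)
        res = fit_step_response(series, 1.0, 100.0, 400.0, rng=0)
        truth = RSPH_FIT_PARAMS
        for name in ("alpha0", "beta", "A", "B", "tau"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            ), name
        assert res.ssr < 1e-12
        assert not res.degenerate

    def test_flat_series_flagged_degenerate(self):
        t = np.arange(0.0, 500.0, 1.0)
        series = TimeSeries(t=t, y=np.full_like(t, 0.4))
        res = fit_step_response(series, 1.0, 100.0, 400.0, n_starts=3, rng=1)
        assert res.degenerate


class TestTwoGaussianWorld:
    def test_result_geometry_and_spread(self):
        p = OPTIMIZED["speculator"]
        res = two_gaussian_experiment(p, n_agents=4, n_periods=1, rng=3, n_bins=20)
        assert res.theta.shape == res.mean_x.shape == res.std_x.shape == (20,)
        assert np.all((res.mean_x >= 0) & (res.mean_x < 100.0))
        assert np.all(res.std_x >= 0)
        assert res.per_agent_mean.shape == (4, 20)

    def test_departure_detection(self):
        theta = np.arange(0.0, 5000.0, 100.0)
        mean_x = np.where(theta < 2000.0, 25.0, 75.0)
        res = GaussianWorldResult(
            theta=theta, mean_x=mean_x, std_x=np.zeros_like(theta),
            per_agent_mean=np.zeros((1, len(theta))), ell=100.0, period=5000.0,
        )
        assert departure_theta(res) == 2000.0
        res.mean_x = np.full_like(theta, 25.0)
        assert departure_theta(res) == math.inf

    def test_circular_statistics_wrap(self):
        xs = np.array([98.0, 2.0])  # straddling the periodic boundary
        assert circular_mean(xs, 100.0) == pytest.approx(0.0, abs=1e-9)
        assert circular_std(xs, 100.0) < 3.0


class TestTraverse3D:
    def test_zero_field_gives_zero_series(self):
        fld = Field3D(X3=np.zeros((3, 3, 3)), Y3=np.zeros((3, 3, 3)), ell=100.0)
        ts = traverse_3d(fld, n_segments=3, dt=1.0, rng=0)
        assert np.all(ts.y == 0.0)
        assert len(ts.y) == 3 * 200

    def test_fixed_direction_matches_field_slice(self):
        fp = FieldParams(T=100.0, L=20.0)
        fld = make_field_3d(fp, 5)

        class AxisRng:
            def __init__(self):
                self._u = np.random.default_rng(1)

            def uniform(self, lo, hi, size=None):
                return self._u.uniform(lo, hi, size)

            def standard_normal(self, n):
                return np.array([1.0, 0.0, 0.0])

        ts = traverse_3d(fld, n_segments=1, dt=0.5, rng=AxisRng())
        # reconstruct the same straight-line path and evaluate directly
        rng = np.random.default_rng(1)
        start = rng.uniform(0.0, 100.0, size=3)
        path = np.mod(start + np.outer(np.arange(1, 401) * 0.5, [1.0, 0, 0]), 100.0)
        assert np.allclose(ts.y, concentration_3d(fld, path))


class TestAutocorrelation:
    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        n = 20_000
        ts = TimeSeries(t=np.arange(n, dtype=float), y=rng.standard_normal(n))
        r = autocorrelation(ts, 20)
        assert r.y[0] == pytest.approx(1.0)
        assert np.all(np.abs(r.y[1:]) < 3.0 / np.sqrt(n))

    def test_pure_cosine(self):
        lam = 50.0
        t = np.arange(0.0, 5000.0)
        ts = TimeSeries(t=t, y=np.cos(2 * np.pi * t / lam))
        r = autocorrelation(ts, 100)
        assert np.allclose(r.y, np.cos(2 * np.pi * np.arange(101) / lam), atol=0.05)

    def test_lag_must_fit_series(self):
        ts = TimeSeries(t=np.arange(10.0), y=np.zeros(10))
        with pytest.raises(ValueError):
            autocorrelation(ts, 10)
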