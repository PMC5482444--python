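"""Stochastic field: AR(1) weight dynamics, spectra, deterministic environments."""

import numpy as np
import pytest

from chemoevolve.field import (
    Field3D,
    FieldParams,
    FieldState,
    concentration,
    concentration_3d,
    constant_environment,
    init_field,
    make_field_3d,
    spatial_covariance,
    stationary_weight_variance,
    step_environment,
    stochastic_environment,
    two_gaussian_environment,
    update_field,
)


class TestFieldParams:
    def test_highest_mode_is_world_length_over_correlation_length(self):
        assert FieldParams(T=100.0, L=20.0).p_star == 5
        assert FieldParams(T=100.0, L=100.0).p_star == 1

    def test_update_interval_is_hundredth_of_correlation_time(self):
        assert FieldParams(T=250.0, L=50.0).dt_c == 2.5

    @pytest.mark.parametrize("kw", [dict(T=-1, L=20), dict(T=100, L=0), dict(T=100, L=101)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            FieldParams(**kw)

    def test_non_integer_mode_ratio_warns_and_rounds(self):
        with pytest.warns(UserWarning, match="rounding"):
            fp = FieldParams(T=100.0, L=30.0)
        assert fp.p_star == 3


class TestWeightDynamics:
    def test_unequilibrated_field_is_zero_everywhere(self):
        fp = FieldParams(T=100.0, L=20.0)
        state = init_field(fp, seed=0, t_eq=0.0)
        x = np.linspace(0, 100, 50)
        assert np.all(concentration(state, fp, x) == 0.0)

    def test_single_update_from_zero_is_scaled_noise(self):
        # with zero weights the decay term vanishes: X_p = eta_p * scale
        fp = FieldParams(T=100.0, L=20.0)

        class OnesRng:
            def standard_normal(self, shape):
                return np.ones(shape)

        state = FieldState(X=np.zeros(5), Y=np.zeros(5), t=0.0)
        new = update_field(state, fp, OnesRng())
        assert np.allclose(new.X, fp.noise_scale)
        assert np.allclose(new.Y, fp.noise_scale)
        assert new.t == fp.dt_c

    def test_equilibration_matches_sequential_updates(self, rng):
        # the vectorized equilibration consumes the same draws as stepping
        fp = FieldParams(T=50.0, L=25.0)
        fast = init_field(fp, seed=77)
        slow = FieldState(X=np.zeros(fp.p_star), Y=np.zeros(fp.p_star), t=0.0)
        g = np.random.default_rng(77)
        for _ in range(200):  # t_eq = 2T -> 200 updates
            slow = update_field(slow, fp, g)
        assert np.allclose(fast.X, slow.X)
        assert np.allclose(fast.Y, slow.Y)

    def test_stationary_variance_near_inverse_mode_count(self):
        fp = FieldParams(T=100.0, L=20.0)
        rng = np.random.default_rng(3)
        state = init_field(fp, rng)
        n = 10_000
        w = np.empty((n, 2, fp.p_star))
        for k in range(n):
            state = update_field(state, fp, rng)
            w[k, 0] = state.X
            w[k, 1] = state.Y
        var = w.reshape(n, -1).var(axis=0, ddof=1)
        expected = stationary_weight_variance(fp)
        assert expected == pytest.approx(1.0 / fp.p_star, rel=0.01)
        # mean over the 10 weights within 5%; individual weights are noisier
        assert var.mean() == pytest.approx(expected, rel=0.05)
        assert np.all(np.abs(var - expected) < 0.3 * expected)

    def test_weight_autocorrelation_time_is_T(self):
        fp = FieldParams(T=100.0, L=100.0)
        rng = np.random.default_rng(4)
        state = init_field(fp, rng)
        n = 40_000
        w = np.empty((n, 2))
        for k in range(n):
            state = update_field(state, fp, rng)
            w[k] = state.X[0], state.Y[0]
        lags = np.arange(1, 51)
        rho = np.array(
            [np.mean([np.corrcoef(s[:-k], s[k:])[0, 1] for s in w.T]) for k in lags]
        )
        slope = np.polyfit(lags * fp.dt_c, np.log(rho), 1)[0]
        assert -1.0 / slope == pytest.approx(fp.T, rel=0.10)

    def test_distinct_mode_noise_uncorrelated(self):
        fp = FieldParams(T=100.0, L=20.0)
        rng = np.random.default_rng(5)
        state = init_field(fp, rng)
        n = 5000
        w = np.empty((n, fp.p_star))
        for k in range(n):
            state = update_field(state, fp, rng)
            w[k] = state.X
        corr = np.corrcoef(w.T)
        off = corr[~np.eye(fp.p_star, dtype=bool)]
        assert np.all(np.abs(off) < 5.0 / np.sqrt(n / (2 * fp.T / fp.dt_c)))


class TestConcentration:
    def test_single_mode_evaluation_and_clipping(self):
        fp = FieldParams(T=100.0, L=20.0)
        state = FieldState(X=np.array([1.0, 0, 0, 0, 0]), Y=np.zeros(5), t=0.0)
        assert concentration(state, fp, 0.0) == pytest.approx(1.0)
        # cos(pi) = -1 is clipped to zero
        assert concentration(state, fp, 50.0) == 0.0

    def test_positions_wrap_periodically(self):
        fp = FieldParams(T=100.0, L=20.0)
        state = init_field(fp, seed=1)
        x = np.array([10.0, 110.0, -90.0])
        c = concentration(state, fp, x)
        assert c[0] == pytest.approx(c[1]) == pytest.approx(c[2])

    def test_spatial_covariance_matches_mode_sum_closed_form(self):
        # C(d) = var_w * sum_p cos(2 pi p d / ell), modes independent
        fp = FieldParams(T=100.0, L=20.0)
        rng = np.random.default_rng(6)
        state = init_field(fp, rng)
        d_grid = np.array([0.0, 5.0, 10.0, 20.0, 35.0, 50.0])
        n_snap, spacing = 3000, 100  # snapshots 1 T apart
        prods = np.zeros((n_snap, d_grid.size))
        p = np.arange(1, fp.p_star + 1)

        def unclipped(xs):
            ph = 2 * np.pi * np.multiply.outer(xs, p) / fp.ell
            return np.cos(ph) @ state.X + np.sin(ph) @ state.Y

        xs0 = np.array([0.0])
        for k in range(n_snap):
            for _ in range(spacing):
                state = update_field(state, fp, rng)
            vals = unclipped(np.concatenate([xs0, xs0 + d_grid]))
            prods[k] = vals[0] * vals[1:]
        emp = prods.mean(axis=0)
        assert np.allclose(emp, spatial_covariance(fp, d_grid), atol=0.12)

    def test_clipped_field_mean_is_clipped_gaussian_mean(self):
        # E max(0, N(0,1)) = 1/sqrt(2 pi), independent of T and L
        for T, L, seed in [(100.0, 20.0, 7), (200.0, 50.0, 8)]:
            fp = FieldParams(T=T, L=L)
            rng = np.random.default_rng(seed)
            state = init_field(fp, rng)
            xs = np.linspace(0, fp.ell, 200, endpoint=False)
            means = []
            for _ in range(600):
                for _ in range(100):  # snapshots one correlation time apart
                    state = update_field(state, fp, rng)
                means.append(concentration(state, fp, xs).mean())
            assert np.mean(means) == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=0.03)


class TestField3D:
    def test_zero_weights_give_zero_everywhere(self):
        fld = Field3D(X3=np.zeros((3, 3, 3)), Y3=np.zeros((3, 3, 3)), ell=100.0)
        pos = np.random.default_rng(0).uniform(0, 100, (10, 3))
        assert np.all(concentration_3d(fld, pos) == 0.0)

    def test_single_mode_constant_on_diagonal_planes(self):
        # one (1,1,1) weight -> field depends on x+y+z only
        X3 = np.zeros((2, 2, 2))
        X3[0, 0, 0] = 1.0
        fld = Field3D(X3=X3, Y3=np.zeros((2, 2, 2)), ell=100.0)
        base = np.array([[10.0, 20.0, 30.0]])
        shifted = np.array([[15.0, 25.0, 20.0]])  # same x+y+z = 60
        assert concentration_3d(fld, base) == pytest.approx(concentration_3d(fld, shifted))

    def test_axis_covariance_matches_1d_closed_form_and_isotropy(self):
        fp = FieldParams(T=100.0, L=20.0)
        rng = np.random.default_rng(9)
        d = np.array([5.0, 10.0])
        cov = {0: [], 1: [], 2: []}
        for _ in range(200):
            fld = make_field_3d(fp, rng)
            base = rng.uniform(0, 100, (40, 3))
            v0 = concentration_3d(fld, base)
            for ax in range(3):
                for dd in d:
                    shift = base.copy()
                    shift[:, ax] += dd
                    cov[ax].append(np.mean(v0 * concentration_3d(fld, shift)))
        expected = (1.0 / fp.p_star) * np.cos(2 * np.pi * np.arange(1, 6)[:, None] * d / 100).sum(0)
        for ax in range(3):
            emp = np.mean(np.reshape(cov[ax], (-1, 2)), axis=0)
            assert np.allclose(emp, expected, atol=0.08)


class TestDeterministicEnvironments:
    def test_step_environment_window(self):
        env = step_environment(1.0, 50.0, 350.0)
        assert env(0.0, 49.0) == 0.0
        assert env(0.0, 50.0) == 1.0
        assert env(0.0, 349.9) == 1.0
        assert env(0.0, 350.0) == 0.0

    def test_zero_step_is_identically_zero(self):
        env = step_environment(0.0, 10.0, 20.0)
        assert env(3.0, 15.0) == 0.0

    def test_step_environment_requires_ordered_times(self):
        with pytest.raises(ValueError):
            step_environment(1.0, 350.0, 50.0)

    def test_two_gaussian_antiphase_amplitudes(self):
        env = two_gaussian_environment()
        # full left amplitude at phase 0; right bump extinguished
        assert env(25.0, 0.0) == pytest.approx(1.0)
        assert env(75.0, 0.0) == pytest.approx(0.0, abs=1e-12)
        # quarter period: both amplitudes 1/2 under the cosine waveform
        assert env(25.0, 1250.0) == pytest.approx(0.5)
        assert env(75.0, 1250.0) == pytest.approx(0.5)

    def test_two_gaussian_periodicity(self):
        env = two_gaussian_environment()
        x = np.linspace(0, 100, 17)
        assert np.allclose(env(x, 777.0), env(x, 777.0 + 5000.0))

    def test_environments_never_negative(self):
        envs = [
            two_gaussian_environment(),
            step_environment(2.0, 0.0, 10.0),
            constant_environment(0.5),
        ]
        xs = np.linspace(-50, 150, 31)
        for env in envs:
            for t in (0.0, 5.0, 2600.0):
                assert np.all(env(xs, t) >= 0.0)


class TestStochasticEnvironment:
    def test_seeded_realization_is_reproducible(self):
        fp = FieldParams(T=100.0, L=20.0)
        e1 = stochastic_environment(fp, 42)
        e2 = stochastic_environment(fp, 42)
        e1.advance_to(57.0)
        e2.advance_to(57.0)
        assert np.array_equal(e1.state.X, e2.state.X)

    def test_advance_schedule_independent_of_call_pattern(self):
        fp = FieldParams(T=100.0, L=20.0)
        e1 = stochastic_environment(fp, 11)
        e2 = stochastic_environment(fp, 11)
        for t in np.arange(0, 60.0, 0.7):
            e1.advance_to(t)
        e2.advance_to(59.5)
        assert np.array_equal(e1.state.X, e2.state.X)
        assert np.array_equal(e1.state.Y, e2.state.Y)
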