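"""Neural dynamics, hemodynamic observation and integration accuracy."""

import numpy as np
import pytest

from facedcm.design import build_stimulus_design
from facedcm.forward import (ForwardModel, bold_from_states,
                             neural_derivative, neural_timeseries)
from facedcm.network import DCMParams


def brute_force_derivative(z, u, spec, params):
    """Independent oracle: assemble dz/dt entry by entry with explicit loops
    over the allowed connections, never forming the Jacobian."""
    n = spec.n_regions
    dz = np.zeros(n)
    for i in range(n):
        # self term: -0.5 exp(x_A + sum_j u_j x_Bj)
        x = params[f"A:{spec.regions[i]}->{spec.regions[i]}"]
        for k, inp in enumerate(spec.inputs):
            nm = f"B({inp}):{spec.regions[i]}->{spec.regions[i]}"
            if spec.b_masks[inp][i, i]:
                x += u[k] * params[nm]
        dz[i] += -0.5 * np.exp(x) * z[i]
        for j in range(n):
            if j == i:
                continue
            c = 0.0
            if spec.a_mask[i, j]:
                c += params[f"A:{spec.regions[j]}->{spec.regions[i]}"]
            for k, inp in enumerate(spec.inputs):
                if spec.b_masks[inp][i, j]:
                    c += u[k] * params[f"B({inp}):{spec.regions[j]}->{spec.regions[i]}"]
            dz[i] += c * z[j]
        for k, inp in enumerate(spec.inputs):
            if spec.c_mask[i, k]:
                dz[i] += params[f"C({inp}):{spec.regions[i]}"] * u[k]
    return dz


class TestNeuralDerivative:
    def test_prior_mean_is_pure_decay(self, spec):
        p = DCMParams.zeros(spec)
        z = np.array([1.0, -2.0, 0.5, 0.0, 3.0, -1.0])
        dz = neural_derivative(z, np.zeros(2), spec, p)
        assert np.allclose(dz, -0.5 * z)

    def test_driving_term_enters_lEVC_only(self, spec):
        p = DCMParams.zeros(spec)
        p["C(visual):lEVC"] = 0.7
        dz = neural_derivative(np.zeros(6), np.array([1.0, 0.0]), spec, p)
        expected = np.zeros(6)
        expected[spec.regions.index("lEVC")] = 0.7
        assert np.allclose(dz, expected)

    def test_matches_brute_force_oracle(self, spec):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = DCMParams(spec, rng.normal(0, 0.3, spec.n_parameters()))
            z = rng.normal(size=6)
            u = rng.uniform(0, 1, 2)
            got = neural_derivative(z, u, spec, p)
            want = brute_force_derivative(z, u, spec, p)
            assert np.allclose(got, want, atol=1e-12)

    def test_dimension_mismatch_rejected(self, spec):
        with pytest.raises(ValueError):
            neural_derivative(np.zeros(4), np.zeros(2), spec,
                              DCMParams.zeros(spec))


def _stage_series(short_design, n_seconds, z_fun):
    """Neural stage samples (spacing dt/2, starting at t=0) of ``z_fun``."""
    dt = short_design.dt
    spsc = 2 * short_design.microtime_bins
    n_scans = int(n_seconds / short_design.tr_s)
    m = n_scans * spsc
    t = np.arange(m + 1) * (dt / 2.0)
    neural = np.zeros((m + 1, 6))
    neural[:, 0] = z_fun(t)
    return neural, dt / 2.0, spsc, n_scans


class TestHemodynamics:
    def test_rest_gives_flat_bold(self, spec, short_design):
        p = DCMParams.zeros(spec)
        neural, dt2, spsc, _ = _stage_series(short_design, 20.0,
                                             lambda t: 0.0 * t)
        bold = bold_from_states(neural, p, dt2, spsc)
        assert np.allclose(bold, 0.0, atol=1e-12)

    def test_impulse_response_shape(self, spec, short_design):
        """A brief neural burst produces a positive transient peaking a few
        seconds later and relaxing back toward baseline."""
        p = DCMParams.zeros(spec)
        neural, dt2, spsc, n_scans = _stage_series(
            short_design, 30.0, lambda t: (t < 1.0).astype(float))
        bold = bold_from_states(neural, p, dt2, spsc)[:, 0]
        t = (1 + np.arange(n_scans)) * short_design.tr_s
        peak = np.argmax(bold)
        assert bold[peak] > 0
        assert 2.0 < t[peak] < 9.0
        assert bold[-1] < 0.25 * bold[peak]

    def test_matches_adaptive_ode_oracle(self, spec, short_design):
        """Fixed-step RK4 agrees with scipy's adaptive integrator on the
        same balloon equations driven by the same smooth input."""
        from scipy.integrate import solve_ivp

        from facedcm.forward import ALPHA, E0, GAMMA, K1, K2, K3, KAPPA, TAU0, V0

        z_fun = lambda t: np.exp(-0.5 * (t - 3.0) ** 2)  # noqa: E731

        def rhs(t, x):
            s, f, v, q = x
            fv = max(v, 1e-9) ** (1.0 / ALPHA)
            return [z_fun(t) - KAPPA * s - GAMMA * (f - 1.0), s,
                    (f - fv) / TAU0,
                    (f * (1.0 - (1.0 - E0) ** (1.0 / max(f, 1e-9))) / E0
                     - fv * q / max(v, 1e-9)) / TAU0]

        neural, dt2, spsc, n_scans = _stage_series(short_design, 24.0, z_fun)
        p = DCMParams.zeros(spec)
        bold = bold_from_states(neural, p, dt2, spsc)[:, 0]
        scan_t = (1 + np.arange(n_scans)) * short_design.tr_s
        sol = solve_ivp(rhs, (0, scan_t[-1]), [0, 1, 1, 1], rtol=1e-11,
                        atol=1e-13, dense_output=True)
        s_, f_, v_, q_ = sol.sol(scan_t)
        oracle = V0 * (K1 * (1 - q_) + K2 * (1 - q_ / v_) + K3 * (1 - v_))
        assert np.max(np.abs(bold - oracle)) < 1e-5 * np.abs(oracle).max()

    def test_efficacy_scales_small_signal_response(self, spec, short_design):
        p = DCMParams.zeros(spec)
        neural, dt2, spsc, _ = _stage_series(
            short_design, 30.0, lambda t: 1e-3 * (t < 1.0))
        base = bold_from_states(neural, p, dt2, spsc)
        p2 = p.copy()
        for r in spec.regions:
            p2[f"efficacy:{r}"] = np.log(2.0)
        doubled = bold_from_states(neural, p2, dt2, spsc)
        ratio = np.abs(doubled).max() / np.abs(base).max()
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestPredictTimeseries:
    def test_zero_input_gives_zero_prediction(self, spec, short_design):
        p = DCMParams.zeros(spec)  # C = 0
        y = ForwardModel(spec, short_design).predict(p)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_deterministic_across_runs(self, spec, short_design, active_params):
        y1 = ForwardModel(spec, short_design).predict(active_params)
        y2 = ForwardModel(spec, short_design).predict(active_params)
        assert np.max(np.abs(y1 - y2)) < 1e-10

    def test_response_monotone_in_drive(self, spec, short_design, active_params):
        fm = ForwardModel(spec, short_design)
        amps = []
        for scale in (0.25, 0.5, 1.0):
            p = active_params.copy()
            p["C(visual):lEVC"] = 0.6 * scale
            p["C(visual):rEVC"] = 0.6 * scale
            amps.append(np.abs(fm.predict(p)).max())
        assert amps[0] < amps[1] < amps[2]

    def test_numba_and_numpy_kernels_agree(self, spec, short_design,
                                           active_params):
        import facedcm.forward as fwd

        if not fwd.HAVE_NUMBA:
            pytest.skip("numba unavailable; single-kernel build")
        y_fast = ForwardModel(spec, short_design, use_numba=True).predict(active_params)
        y_ref = ForwardModel(spec, short_design, use_numba=False).predict(active_params)
        assert np.max(np.abs(y_fast - y_ref)) < 1e-10

    def test_step_halving_convergence(self, spec, active_params):
        """Integrating at twice the microtime resolution changes the
        prediction by a negligible amount."""
        design = build_stimulus_design(n_blocks_per_condition=1, rng=0,
                                       microtime_bins=16)
        y16 = ForwardModel(spec, design, microtime_bins=16).predict(active_params)
        y32 = ForwardModel(spec, design, microtime_bins=32).predict(active_params)
        rms = np.sqrt(np.mean((y16 - y32) ** 2))
        assert rms < 1e-6

    def test_default_decay_returns_any_state_to_rest(self, spec):
        p = DCMParams.zeros(spec)
        z = np.array([2.0, -1.0, 0.7, 0.1, -3.0, 1.5])
        J = p.effective_connectivity(np.zeros(2))
        from scipy.linalg import expm

        z_late = expm(J * 30.0) @ z
        assert np.max(np.abs(z_late)) < 1e-6


def test_neural_and_fused_paths_consistent(spec, short_design, active_params):
    """predict_timeseries equals the neural-integration + hemodynamic
    composition, the dual-route internal cross-check."""
    y_fused = ForwardModel(spec, short_design).predict(active_params)
    nz = neural_timeseries(spec, active_params, short_design)
    y_comp = bold_from_states(nz, active_params, short_design.dt / 2.0,
                              2 * short_design.microtime_bins)
    y_comp = y_comp - y_comp.mean(axis=0)
    assert np.max(np.abs(y_fused - y_comp)) < 1e-10
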