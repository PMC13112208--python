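"""Deterministic generative model: bilinear neural dynamics + balloon model.

Neural states z (Hz) evolve as dz/dt = (A~ + sum_j u_j B~_j) z + C u, where
the effective diagonal is -0.5 * exp(x_A + sum_j u_j x_Bj) and off-diagonals
combine additively.  Because the box-car inputs are piecewise constant at
microtime resolution, the neural update over one microtime bin is computed
exactly with a matrix exponential (augmented to include the constant drive).

Each region's neural activity feeds a balloon-Windkessel hemodynamic
cascade (vasodilatory signal s, blood flow f, volume v, deoxyhemoglobin q)
integrated with classic RK4 at the same microtime step, and the static BOLD
observation equation (3 T coefficients) is sampled once per scan.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .design import StimulusDesign
from .network import DCMParams, DCMSpec, effective_self  # noqa: F401  (re-export)

# Fixed hemodynamic constants (per-region transit time and neurovascular
# efficacy are free parameters, as log-scalings around tau0 and 1).
KAPPA = 0.64   # signal decay (1/s)
GAMMA = 0.32   # autoregulation (1/s)
TAU0 = 2.0     # mean transit time (s)
ALPHA = 0.32   # vessel stiffness
E0 = 0.4       # resting oxygen extraction
V0 = 4.0       # resting venous volume fraction (percent signal units)
TE = 0.025     # echo time (s)
THETA0 = 40.3  # frequency offset at the outer surface of magnetized vessels (1/s)
R0 = 25.0      # intravascular relaxation slope (1/s)

K1 = 4.3 * THETA0 * E0 * TE
K2 = R0 * E0 * TE
K3 = 0.0       # epsilon = 1 (intra/extravascular ratio)

# saturation of the log-hemodynamic states: derivative evaluations clamp to
# the physiological range (inactive for any sane parameter regime) and the
# states themselves are bounded so pathological trial parameters yield
# large-but-finite predictions instead of overflow
LOG_STATE_CLAMP = 3.5   # |ln f|, |ln v|, |ln q| inside derivatives
LOG_STATE_BOUND = 6.0   # hard bound on the integrated log states


class IntegrationError(RuntimeError):
    """Hemodynamic or neural state became non-finite during integration."""

    def __init__(self, scan_index: int):
        self.scan_index = int(scan_index)
        super().__init__(f"non-finite state while integrating scan {scan_index}")


def neural_derivative(z, u, spec: DCMSpec, params: DCMParams) -> np.ndarray:
    """dz/dt (Hz/s) of the bilinear neural state equation."""
    z = np.asarray(z, dtype=float)
    if z.shape != (spec.n_regions,):
        raise ValueError(f"state has shape {z.shape}, expected ({spec.n_regions},)")
    J = params.effective_connectivity(u)
    return J @ z + params.c_matrix() @ np.asarray(u, dtype=float)


# ----------------------------------------------------------------------
# parameter decoding (vector batch -> structured arrays)
# ----------------------------------------------------------------------
class _Coding:
    """Precomputed positions of each structural block in the flat vector."""

    def __init__(self, spec: DCMSpec):
        self.spec = spec
        idx = spec.name_index()
        n = spec.n_regions
        self.a_entries = [(idx[f"A:{spec.regions[j]}->{spec.regions[i]}"], i, j)
                          for i in range(n) for j in range(n)
                          if i != j and spec.a_mask[i, j]]
        self.x_a = np.array([idx[f"A:{r}->{r}"] for r in spec.regions])
        self.b_entries = {}
        self.x_b = {}
        for inp in spec.inputs:
            m = spec.b_masks[inp]
            self.b_entries[inp] = [
                (idx[f"B({inp}):{spec.regions[j]}->{spec.regions[i]}"], i, j)
                for i in range(n) for j in range(n) if i != j and m[i, j]]
            xb = np.full(n, -1)
            for r_i, r in enumerate(spec.regions):
                nm = f"B({inp}):{r}->{r}"
                if nm in idx:
                    xb[r_i] = idx[nm]
            self.x_b[inp] = xb
        self.c_entries = [(idx[f"C({inp}):{spec.regions[i]}"], i, k)
                          for k, inp in enumerate(spec.inputs)
                          for i in range(n) if spec.c_mask[i, k]]
        self.transit = np.array([idx[f"transit:{r}"] for r in spec.regions])
        self.efficacy = np.array([idx[f"efficacy:{r}"] for r in spec.regions])

    def decode(self, theta: np.ndarray, patterns: np.ndarray):
        """Per input pattern: exact one-step propagators and drive terms.

        Parameters
        ----------
        theta : (B, p) batch of parameter vectors
        patterns : (P, k) distinct input rows

        Returns
        -------
        jac : (B, P, n, n) effective connectivity per pattern
        drive : (B, P, n) C @ u per pattern
        tau, eff : (B, n) transit times (s) and efficacies
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        B = theta.shape[0]
        n = self.spec.n_regions
        P = patterns.shape[0]
        jac = np.zeros((B, P, n, n))
        drive = np.zeros((B, P, n))
        A_off = np.zeros((B, n, n))
        for pos, i, j in self.a_entries:
            A_off[:, i, j] = theta[:, pos]
        C = np.zeros((B, n, patterns.shape[1]))
        for pos, i, k in self.c_entries:
            C[:, i, k] = theta[:, pos]
        for p in range(P):
            u = patterns[p]
            J = A_off.copy()
            x = theta[:, self.x_a].copy()
            for k, inp in enumerate(self.spec.inputs):
                if u[k] == 0.0:
                    continue
                for pos, i, j in self.b_entries[inp]:
                    J[:, i, j] += u[k] * theta[:, pos]
                sel = self.x_b[inp] >= 0
                x[:, sel] += u[k] * theta[:, self.x_b[inp][sel]]
            J[:, np.arange(n), np.arange(n)] = -0.5 * np.exp(x)
            jac[:, p] = J
            drive[:, p] = np.einsum("bik,k->bi", C, u)
        # clamp the log-scalings so extreme trial parameters cannot drive
        # the transit time or efficacy to 0/inf
        tau = TAU0 * np.exp(np.clip(theta[:, self.transit], -8.0, 8.0))
        eff = np.exp(np.clip(theta[:, self.efficacy], -8.0, 8.0))
        return jac, drive, tau, eff


def _propagators(jac: np.ndarray, drive: np.ndarray, dt: float):
    """Exact half-bin update z' = E z + d from J and constant drive.

    Uses the augmented matrix exponential exp((dt/2) [[J, Cu], [0, 0]]),
    which avoids inverting J.  Two applications advance one microtime bin;
    the intermediate state feeds the RK4 mid-stages of the hemodynamic
    integration exactly.
    """
    B, P, n, _ = jac.shape
    E = np.empty((B, P, n, n))
    d = np.empty((B, P, n))
    M = np.zeros((n + 1, n + 1))
    h = 0.5 * dt
    for b in range(B):
        for p in range(P):
            M[:n, :n] = jac[b, p] * h
            M[:n, n] = drive[b, p] * h
            Em = expm(M)
            E[b, p] = Em[:n, :n]
            d[b, p] = Em[:n, n]
    return E, d


# ----------------------------------------------------------------------
# hemodynamic integration kernels
# ----------------------------------------------------------------------
def _hemo_deriv_np(z, s, lf, lv, lq, tau, eff):
    """Balloon-model derivatives with log-transformed f, v, q.

    Integrating ln f, ln v, ln q keeps flow, volume and deoxyhemoglobin
    strictly positive for any neural input, so sustained inhibition cannot
    collapse the states through zero.  Derivatives are evaluated with the
    log states clamped to the physiological range, so extreme trial
    parameters (for instance during inversion) saturate instead of making
    the system stiff beyond the fixed step's stability.
    """
    lf = np.clip(lf, -LOG_STATE_CLAMP, LOG_STATE_CLAMP)
    lv = np.clip(lv, -LOG_STATE_CLAMP, LOG_STATE_CLAMP)
    lq = np.clip(lq, -LOG_STATE_CLAMP, LOG_STATE_CLAMP)
    f = np.exp(lf)
    v = np.exp(lv)
    fv = np.exp(lv / ALPHA)  # v ** (1/alpha)
    ds = eff * z - KAPPA * s - GAMMA * (f - 1.0)
    dlf = s / f
    dlv = (f - fv) / (tau * v)
    dlq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 / np.exp(lq) - fv / v) / tau
    return ds, dlf, dlv, dlq


def _integrate_numpy(E, d, pat_idx, tau, eff, dt, n_scans, steps_per_scan):
    B, P, n, _ = E.shape
    z = np.zeros((B, n))
    s = np.zeros((B, n))
    lf = np.zeros((B, n))
    lv = np.zeros((B, n))
    lq = np.zeros((B, n))
    bold = np.empty((B, n_scans, n))
    t = 0
    for scan in range(n_scans):
        for _ in range(steps_per_scan):
            p = pat_idx[t]
            zm = np.einsum("bij,bj->bi", E[:, p], z) + d[:, p]
            z_new = np.einsum("bij,bj->bi", E[:, p], zm) + d[:, p]
            k1 = _hemo_deriv_np(z, s, lf, lv, lq, tau, eff)
            k2 = _hemo_deriv_np(zm, s + 0.5 * dt * k1[0], lf + 0.5 * dt * k1[1],
                                lv + 0.5 * dt * k1[2], lq + 0.5 * dt * k1[3], tau, eff)
            k3 = _hemo_deriv_np(zm, s + 0.5 * dt * k2[0], lf + 0.5 * dt * k2[1],
                                lv + 0.5 * dt * k2[2], lq + 0.5 * dt * k2[3], tau, eff)
            k4 = _hemo_deriv_np(z_new, s + dt * k3[0], lf + dt * k3[1],
                                lv + dt * k3[2], lq + dt * k3[3], tau, eff)
            s = s + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            lf = np.clip(lf + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            lv = np.clip(lv + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            lq = np.clip(lq + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            z = z_new
            t += 1
        q = np.exp(lq)
        v = np.exp(lv)
        bold[:, scan] = V0 * (K1 * (1.0 - q) + K2 * (1.0 - q / v)
                              + K3 * (1.0 - v))
    return bold


try:  # optional numba acceleration; the numpy kernel is the reference
    import math

    from numba import njit

    @njit(cache=True, inline="always")
    def _hemo_scalar(zc, s, lf, lv, lq, ti, ei):  # pragma: no cover
        lf = min(max(lf, -LOG_STATE_CLAMP), LOG_STATE_CLAMP)
        lv = min(max(lv, -LOG_STATE_CLAMP), LOG_STATE_CLAMP)
        lq = min(max(lq, -LOG_STATE_CLAMP), LOG_STATE_CLAMP)
        f = math.exp(lf)
        v = math.exp(lv)
        fv = math.exp(lv / ALPHA)
        ds = ei * zc - KAPPA * s - GAMMA * (f - 1.0)
        dlf = s / f
        dlv = (f - fv) / (ti * v)
        dlq = (f * (1.0 - (1.0 - E0) ** (1.0 / f)) / E0 / math.exp(lq)
               - fv / v) / ti
        return ds, dlf, dlv, dlq

    @njit(cache=True)
    def _integrate_numba(E, d, pat_idx, tau, eff, dt, n_scans, steps_per_scan):  # pragma: no cover - exercised via equivalence test
        B = E.shape[0]
        n = E.shape[2]
        bold = np.empty((B, n_scans, n))
        for b in range(B):
            z = np.zeros(n)
            s = np.zeros(n)
            lf = np.zeros(n)
            lv = np.zeros(n)
            lq = np.zeros(n)
            z_half = np.empty(n)
            z_new = np.empty(n)
            t = 0
            for scan in range(n_scans):
                for _ in range(steps_per_scan):
                    p = pat_idx[t]
                    for i in range(n):
                        acc = d[b, p, i]
                        for j in range(n):
                            acc += E[b, p, i, j] * z[j]
                        z_half[i] = acc
                    for i in range(n):
                        acc = d[b, p, i]
                        for j in range(n):
                            acc += E[b, p, i, j] * z_half[j]
                        z_new[i] = acc
                    for i in range(n):
                        ti = tau[b, i]
                        ei = eff[b, i]
                        s1, f1, v1, q1 = _hemo_scalar(
                            z[i], s[i], lf[i], lv[i], lq[i], ti, ei)
                        s2, f2, v2, q2 = _hemo_scalar(
                            z_half[i], s[i] + 0.5 * dt * s1,
                            lf[i] + 0.5 * dt * f1, lv[i] + 0.5 * dt * v1,
                            lq[i] + 0.5 * dt * q1, ti, ei)
                        s3, f3, v3, q3 = _hemo_scalar(
                            z_half[i], s[i] + 0.5 * dt * s2,
                            lf[i] + 0.5 * dt * f2, lv[i] + 0.5 * dt * v2,
                            lq[i] + 0.5 * dt * q2, ti, ei)
                        s4, f4, v4, q4 = _hemo_scalar(
                            z_new[i], s[i] + dt * s3, lf[i] + dt * f3,
                            lv[i] + dt * v3, lq[i] + dt * q3, ti, ei)
                        s[i] += dt / 6.0 * (s1 + 2 * s2 + 2 * s3 + s4)
                        lf[i] = min(max(lf[i] + dt / 6.0 * (f1 + 2 * f2 + 2 * f3 + f4),
                                        -LOG_STATE_BOUND), LOG_STATE_BOUND)
                        lv[i] = min(max(lv[i] + dt / 6.0 * (v1 + 2 * v2 + 2 * v3 + v4),
                                        -LOG_STATE_BOUND), LOG_STATE_BOUND)
                        lq[i] = min(max(lq[i] + dt / 6.0 * (q1 + 2 * q2 + 2 * q3 + q4),
                                        -LOG_STATE_BOUND), LOG_STATE_BOUND)
                    for i in range(n):
                        z[i] = z_new[i]
                    t += 1
                for i in range(n):
                    q = math.exp(lq[i])
                    v = math.exp(lv[i])
                    bold[b, scan, i] = V0 * (K1 * (1.0 - q)
                                             + K2 * (1.0 - q / v)
                                             + K3 * (1.0 - v))
        return bold

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _integrate(E, d, pat_idx, tau, eff, dt, n_scans, steps_per_scan,
               use_numba=None):
    use = HAVE_NUMBA if use_numba is None else (use_numba and HAVE_NUMBA)
    kern = _integrate_numba if use else _integrate_numpy
    return kern(np.ascontiguousarray(E), np.ascontiguousarray(d),
                np.ascontiguousarray(pat_idx), np.ascontiguousarray(tau),
                np.ascontiguousarray(eff), float(dt), int(n_scans),
                int(steps_per_scan))


# ----------------------------------------------------------------------
# public forward model
# ----------------------------------------------------------------------
class ForwardModel:
    """Predicted BOLD (scans x regions) as a function of the parameter vector.

    Caches the input patterns of a design; ``predict_batch`` evaluates many
    parameter vectors in one call, which is what the finite-difference
    Jacobian in the inversion scheme uses.
    """

    def __init__(self, spec: DCMSpec, design: StimulusDesign,
                 microtime_bins: int | None = None, use_numba: bool | None = None):
        if tuple(design.input_names) != tuple(spec.inputs):
            raise ValueError("design input names do not match spec inputs")
        self.spec = spec
        self.design = design
        self.bins = design.microtime_bins if microtime_bins is None else int(microtime_bins)
        self.use_numba = use_numba
        self._coding = _Coding(spec)
        U = design.regressors(self.bins)
        self.patterns, self.pattern_idx = np.unique(U, axis=0, return_inverse=True)
        self.pattern_idx = self.pattern_idx.astype(np.int64)
        self.dt = design.tr_s / self.bins

    def predict_batch(self, theta: np.ndarray, center: bool = True) -> np.ndarray:
        """Predicted BOLD for a batch of parameter vectors, (B, scans, regions)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        jac, drive, tau, eff = self._coding.decode(theta, self.patterns)
        E, d = _propagators(jac, drive, self.dt)
        bold = _integrate(E, d, self.pattern_idx, tau, eff, self.dt,
                          self.design.n_scans, self.bins, self.use_numba)
        if not np.all(np.isfinite(bold)):
            bad = np.argwhere(~np.isfinite(bold))
            raise IntegrationError(int(bad[0, 1]))
        if center:
            bold = bold - bold.mean(axis=1, keepdims=True)
        return bold

    def predict(self, params, center: bool = True) -> np.ndarray:
        """Predicted BOLD (scans x regions) for one parameter vector."""
        values = params.values if isinstance(params, DCMParams) else np.asarray(params)
        return self.predict_batch(values[None, :], center=center)[0]


def neural_timeseries(spec: DCMSpec, params: DCMParams,
                      design: StimulusDesign) -> np.ndarray:
    """Neural states at half-microtime resolution, (2 T_micro + 1, n).

    Row 0 is the resting initial state at t = 0; subsequent rows advance
    by half a microtime bin.  This sampling carries exactly the stage
    values that the hemodynamic RK4 integration consumes, so composing it
    with :func:`bold_from_states` reproduces the fused forward model to
    machine precision.
    """
    U = design.regressors()
    patterns, idx = np.unique(U, axis=0, return_inverse=True)
    jac, drive, _, _ = _Coding(spec).decode(params.values[None, :], patterns)
    E, d = _propagators(jac, drive, design.dt)
    n = spec.n_regions
    z = np.zeros(n)
    out = np.empty((2 * U.shape[0] + 1, n))
    out[0] = z
    for t in range(U.shape[0]):
        p = idx[t]
        z = E[0, p] @ z + d[0, p]
        out[2 * t + 1] = z
        z = E[0, p] @ z + d[0, p]
        out[2 * t + 2] = z
    return out


def bold_from_states(neural: np.ndarray, params: DCMParams, dt: float,
                     samples_per_scan: int) -> np.ndarray:
    """Hemodynamic observation of a given neural time series.

    ``neural`` holds the states at a spacing of ``dt`` seconds starting at
    t = 0 (odd length: begin/mid/end samples of each RK4 step of length
    2 dt), as produced by :func:`neural_timeseries`.  Integrates the
    balloon-model ODEs and samples the static BOLD equation once every
    ``samples_per_scan`` samples.  Returned BOLD is uncentered (zero at
    rest).
    """
    neural = np.asarray(neural, dtype=float)
    T, n = neural.shape
    if (T - 1) % samples_per_scan or samples_per_scan % 2:
        raise ValueError("need an even number of samples per scan plus the "
                         "initial state")
    h = 2.0 * dt  # RK4 step spans two neural samples
    tau = TAU0 * np.exp(np.clip(params.transit_log(), -8.0, 8.0))[None, :]
    eff = np.exp(np.clip(params.efficacy_log(), -8.0, 8.0))[None, :]
    n_scans = (T - 1) // samples_per_scan
    s = np.zeros((1, n))
    lf = np.zeros((1, n))
    lv = np.zeros((1, n))
    lq = np.zeros((1, n))
    bold = np.empty((n_scans, n))
    t = 0
    for scan in range(n_scans):
        for _ in range(samples_per_scan // 2):
            z0 = neural[t][None, :]
            zm = neural[t + 1][None, :]
            z1 = neural[t + 2][None, :]
            k1 = _hemo_deriv_np(z0, s, lf, lv, lq, tau, eff)
            k2 = _hemo_deriv_np(zm, s + 0.5 * h * k1[0], lf + 0.5 * h * k1[1],
                                lv + 0.5 * h * k1[2], lq + 0.5 * h * k1[3], tau, eff)
            k3 = _hemo_deriv_np(zm, s + 0.5 * h * k2[0], lf + 0.5 * h * k2[1],
                                lv + 0.5 * h * k2[2], lq + 0.5 * h * k2[3], tau, eff)
            k4 = _hemo_deriv_np(z1, s + h * k3[0], lf + h * k3[1],
                                lv + h * k3[2], lq + h * k3[3], tau, eff)
            s = s + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            lf = np.clip(lf + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            lv = np.clip(lv + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            lq = np.clip(lq + h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
                         -LOG_STATE_BOUND, LOG_STATE_BOUND)
            t += 2
        q = np.exp(lq)
        v = np.exp(lv)
        bold[scan] = (V0 * (K1 * (1.0 - q) + K2 * (1.0 - q / v)
                            + K3 * (1.0 - v)))[0]
        if not np.all(np.isfinite(bold[scan])):
            raise IntegrationError(scan)
    return bold


def predict_timeseries(spec: DCMSpec, params: DCMParams,
                       design: StimulusDesign) -> np.ndarray:
    """Predicted BOLD (scans x regions), mean-centered per region."""
    return ForwardModel(spec, design).predict(params)
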