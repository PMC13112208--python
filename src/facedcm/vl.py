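"""Variational Laplace: Gaussian posterior and free energy by Gauss-Newton.

The scheme maximizes the negative variational free energy

    F = <log p(y | theta, lambda)>_q - KL(q(theta) || p(theta)) + log p(lambda)

over a Gaussian posterior q with mean at the current estimate and covariance
from the local curvature.  Observation noise is i.i.d. Gaussian within each
noise group (here: one group per region) with log-precision hyperparameters
lambda updated by Newton steps between Gauss-Newton parameter updates.

Steps use Levenberg-style regularization of the Gauss-Newton system and are
accepted only if they increase F, so the accepted-step F trace is
non-decreasing by construction.  Gradients of the forward model come from
central finite differences evaluated in one batched call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import PriorSpec

LAMBDA_CLAMP = 32.0


class InversionError(RuntimeError):
    """Numerical failure (non-finite quantities, indefinite curvature)."""


@dataclass
class VLSettings:
    """Tolerances and iteration controls for variational Laplace."""

    tol: float = 1e-2          # nats; convergence when dF < tol ...
    converge_window: int = 4   # ... for this many consecutive accepted steps
    max_iter: int = 128
    fd_step: float = 1e-4      # central-difference step, natural scale
    lambda_prior_mean: float = 0.0
    lambda_prior_var: float = 32.0
    init_damping: float = 1e-4
    max_damping: float = 1e8


@dataclass
class PosteriorDensity:
    """Gaussian posterior over a parameter vector plus its free energy."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    f_trace: list = field(default_factory=list)
    noise_log_precision: np.ndarray = None
    converged: bool = True
    names: list = None

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def marginal(self, names) -> "PosteriorDensity":
        """Marginal posterior over a named subset of parameters."""
        idx = [self.names.index(nm) for nm in names]
        return PosteriorDensity(
            mean=self.mean[idx], cov=self.cov[np.ix_(idx, idx)],
            free_energy=self.free_energy, f_trace=list(self.f_trace),
            noise_log_precision=self.noise_log_precision,
            converged=self.converged, names=list(names))


def _logdet_chol(M: np.ndarray) -> tuple:
    """(log determinant, cholesky factor); raises InversionError if not PD."""
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as err:
        raise InversionError("posterior precision is not positive definite") from err
    return 2.0 * float(np.sum(np.log(np.diag(L)))), L


def _free_energy(r, J, pi_vec, log_pi_sum, eps, p0, s0_logdet, k_free,
                 lam, lam_fixed, settings):
    """F and posterior covariance at the current (theta, lambda, J).

    With Sigma_q = (J' Pi J + P0)^-1 the expected-log-likelihood trace term
    and the prior trace term of the KL sum to k_free and cancel, leaving

        F = -0.5 r'Pi r + 0.5 sum(log pi) - n/2 log 2pi
            - 0.5 eps'P0 eps + 0.5 (log|Sigma_q| - log|S0|)  [+ hyperprior]
    """
    n = r.size
    Pq = (J * pi_vec[:, None]).T @ J + np.diag(p0)
    logdet_pq, L = _logdet_chol(Pq)
    F = (-0.5 * float(r @ (pi_vec * r)) + 0.5 * log_pi_sum
         - 0.5 * n * np.log(2 * np.pi)
         - 0.5 * float(eps @ (p0 * eps))
         + 0.5 * (-logdet_pq - s0_logdet))
    if not lam_fixed:
        F += -0.5 * float(np.sum((lam - settings.lambda_prior_mean) ** 2
                                 / settings.lambda_prior_var))
    Sq = np.linalg.inv(L.T) @ np.linalg.inv(L)
    return F, Sq, Pq


def variational_laplace(predict_batch, y, prior: PriorSpec, noise_groups=None,
                        settings: VLSettings | None = None,
                        fixed_noise_log_precision=None) -> PosteriorDensity:
    """Invert a nonlinear-Gaussian observation model.

    Parameters
    ----------
    predict_batch : callable
        Maps a (B, p) batch of parameter vectors to (B, n) predictions.
    y : ndarray, (n,)
        Data vector.
    prior : PriorSpec
        Diagonal Gaussian prior; zero-variance entries stay fixed.
    noise_groups : ndarray of int or None
        Noise-group label per data point (one log-precision per group);
        None pools everything into a single group.
    fixed_noise_log_precision : ndarray or None
        If given, noise hyperparameters are clamped (no hyperprior terms);
        used by the conjugate linear-Gaussian cross-checks.
    """
    settings = settings or VLSettings()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    groups = (np.zeros(n, dtype=int) if noise_groups is None
              else np.asarray(noise_groups, dtype=int).ravel())
    n_groups = int(groups.max()) + 1
    group_masks = [groups == g for g in range(n_groups)]
    group_n = np.array([m.sum() for m in group_masks], dtype=float)

    free = prior.free
    k_free = int(free.sum())
    if k_free == 0:
        raise InversionError("no free parameters to estimate")
    p0 = 1.0 / prior.variance[free]
    s0_logdet = float(np.sum(np.log(prior.variance[free])))
    theta = prior.mean.copy()

    lam_fixed = fixed_noise_log_precision is not None
    if lam_fixed:
        lam = np.asarray(fixed_noise_log_precision, dtype=float).ravel()
        if lam.size == 1:
            lam = np.full(n_groups, float(lam[0]))
    else:
        lam = np.array([-np.log(max(float(np.var(y[m])), 1e-12))
                        for m in group_masks])

    def pi_of(lam_):
        pi = np.empty(n)
        for g, m in enumerate(group_masks):
            pi[m] = np.exp(lam_[g])
        return pi

    def batched_eval(th):
        """Prediction and central-difference Jacobian in one batched call."""
        h = settings.fd_step
        batch = [th]
        for i in np.flatnonzero(free):
            up = th.copy(); up[i] += h
            dn = th.copy(); dn[i] -= h
            batch.append(up); batch.append(dn)
        out = np.asarray(predict_batch(np.array(batch)))
        out = out.reshape(out.shape[0], -1)
        g0 = out[0]
        J = (out[1::2] - out[2::2]).T / (2.0 * h)
        return g0, J

    def update_lambda(r, J, Sq, lam_):
        if lam_fixed:
            return lam_
        lam_ = lam_.copy()
        for g, m in enumerate(group_masks):
            Jg = J[m]
            S = float(r[m] @ r[m]) + float(np.sum((Jg @ Sq) * Jg))
            for _ in range(8):
                e = np.exp(np.clip(lam_[g], -LAMBDA_CLAMP, LAMBDA_CLAMP))
                grad = 0.5 * group_n[g] - 0.5 * e * S \
                    - (lam_[g] - settings.lambda_prior_mean) / settings.lambda_prior_var
                hess = -0.5 * e * S - 1.0 / settings.lambda_prior_var
                step = np.clip(-grad / hess, -4.0, 4.0)
                lam_[g] = np.clip(lam_[g] + step, -LAMBDA_CLAMP, LAMBDA_CLAMP)
        return lam_

    def objective(th, lam_):
        g0, J = batched_eval(th)
        r = y - g0
        if not np.all(np.isfinite(r)):
            raise InversionError("non-finite prediction during inversion")
        pi_vec = pi_of(lam_)
        eps = (th - prior.mean)[free]
        F, Sq, Pq = _free_energy(r, J, pi_vec, float(group_n @ lam_), eps, p0,
                                 s0_logdet, k_free, lam_, lam_fixed, settings)
        return F, r, J, Sq, Pq

    def screen(th, lam_, J, Pq):
        """Cheap trial score: data fit and prior terms at a frozen Jacobian."""
        try:
            g0 = np.asarray(predict_batch(th[None, :])).reshape(-1)
        except Exception:
            return -np.inf
        r = y - g0
        if not np.all(np.isfinite(r)):
            return -np.inf
        pi_vec = pi_of(lam_)
        eps = (th - prior.mean)[free]
        logdet_pq, _ = _logdet_chol(Pq)
        F = (-0.5 * float(r @ (pi_vec * r)) + 0.5 * float(group_n @ lam_)
             - 0.5 * n * np.log(2 * np.pi)
             - 0.5 * float(eps @ (p0 * eps))
             + 0.5 * (-logdet_pq - s0_logdet))
        if not lam_fixed:
            F += -0.5 * float(np.sum((lam_ - settings.lambda_prior_mean) ** 2
                                     / settings.lambda_prior_var))
        return F

    F, r, J, Sq, Pq = objective(theta, lam)
    # one hyperparameter pass before the first recorded F
    lam = update_lambda(r, J, Sq, lam)
    F, r, J, Sq, Pq = objective(theta, lam)
    f_trace = [F]
    damping = settings.init_damping
    consecutive_small = 0
    converged = False

    for _ in range(settings.max_iter):
        pi_vec = pi_of(lam)
        grad = J.T @ (pi_vec * r) - p0 * (theta - prior.mean)[free]
        stepped = False
        while damping <= settings.max_damping:
            H = Pq + damping * np.diag(np.diag(Pq))
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as err:
                raise InversionError("singular Gauss-Newton system") from err
            trial = theta.copy()
            trial[free] += delta
            if screen(trial, lam, J, Pq) <= F:
                damping *= 10.0
                continue
            try:
                F_t, r_t, J_t, Sq_t, Pq_t = objective(trial, lam)
            except (InversionError, RuntimeError):
                F_t = -np.inf  # diverging trial: reject and raise damping
            if F_t > F:
                lam_t = update_lambda(r_t, J_t, Sq_t, lam)
                if not lam_fixed and np.any(lam_t != lam):
                    F_t2, r_t2, J_t2, Sq_t2, Pq_t2 = objective(trial, lam_t)
                    if F_t2 >= F_t:  # keep the hyperparameter update
                        F_t, r_t, J_t, Sq_t, Pq_t, lam = \
                            F_t2, r_t2, J_t2, Sq_t2, Pq_t2, lam_t
                dF = F_t - F
                theta, F, r, J, Sq, Pq = trial, F_t, r_t, J_t, Sq_t, Pq_t
                f_trace.append(F)
                damping = max(damping / 2.0, 1e-8)
                consecutive_small = consecutive_small + 1 if dF < settings.tol else 0
                stepped = True
                break
            damping *= 10.0
        if not stepped:
            # cannot improve further at maximum damping: treat as converged
            converged = True
            break
        if consecutive_small >= settings.converge_window:
            converged = True
            break

    cov = np.zeros((prior.n, prior.n))
    cov[np.ix_(free, free)] = Sq
    return PosteriorDensity(
        mean=theta, cov=cov, free_energy=float(F), f_trace=f_trace,
        noise_log_precision=lam, converged=converged, names=list(prior.names))
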