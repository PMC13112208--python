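"""Bayesian model reduction and model averaging over Gaussian posteriors.

Given a full model's Gaussian prior and posterior, the evidence and
posterior of any model that differs only in its prior follow analytically
from

    Z_r / Z = integral  q(theta) pi_r(theta) / pi(theta)  dtheta .

Parameters are switched off by a reduced prior variance of exactly zero
(a delta at zero), handled by conditioning rather than by limits of the
precision formula, so switched-off parameters have posterior mean and
variance exactly zero.
"""

from __future__ import annotations

import numpy as np


class DegenerateReductionError(RuntimeError):
    """The reduced-model precision combination is singular."""


def reduce_gaussian(post_mean, post_cov, prior_mean, prior_var,
                    red_mean, red_var, return_cov: bool = True):
    """Log-evidence change and reduced posterior under a new prior.

    Parameters
    ----------
    post_mean, post_cov : full-model posterior (mean vector, covariance).
    prior_mean, prior_var : full-model prior (mean, diagonal variances; all > 0
        over the carried parameters).
    red_mean, red_var : reduced prior; entries with ``red_var == 0`` are
        clamped to ``red_mean`` (switched off when the mean is zero).

    Returns
    -------
    dF : float
        log Z_reduced - log Z_full.
    r_mean : ndarray
        Reduced posterior mean (clamped entries at ``red_mean``).
    r_cov : ndarray or None
        Reduced posterior covariance (zero rows/columns for clamped
        entries); None when ``return_cov`` is False.
    """
    mu = np.asarray(post_mean, dtype=float)
    Sq = np.asarray(post_cov, dtype=float)
    m0 = np.asarray(prior_mean, dtype=float)
    v0 = np.asarray(prior_var, dtype=float)
    mr = np.asarray(red_mean, dtype=float)
    vr = np.asarray(red_var, dtype=float)
    k = mu.size

    if np.any(v0 <= 0):
        raise ValueError("full prior variances must be positive")

    try:
        Lq = np.linalg.cholesky(Sq)
    except np.linalg.LinAlgError as err:
        raise DegenerateReductionError("posterior covariance not PD") from err
    Lam_q = np.linalg.inv(Lq.T) @ np.linalg.inv(Lq)
    logdet_Sq = 2.0 * float(np.sum(np.log(np.diag(Lq))))

    lam0 = 1.0 / v0
    # log(q/pi) = -0.5 th' D th + th' dvec + e
    D = Lam_q - np.diag(lam0)
    dvec = Lam_q @ mu - lam0 * m0
    e = (-0.5 * float(mu @ Lam_q @ mu) + 0.5 * float(m0 @ (lam0 * m0))
         - 0.5 * logdet_Sq + 0.5 * float(np.sum(np.log(v0))))

    on = vr > 0
    off = ~on
    c = mr[off]

    r_mean = np.empty(k)
    r_mean[off] = c
    if not np.any(on):
        # all parameters clamped: point-mass reduced model
        dF = e - 0.5 * float(c @ D[np.ix_(off, off)] @ c) + float(c @ dvec[off])
        r_cov = np.zeros((k, k)) if return_cov else None
        return float(dF), r_mean, r_cov

    n_on = int(on.sum())
    lam_r = 1.0 / vr[on]
    A = D[np.ix_(on, on)] + np.diag(lam_r)
    b = dvec[on] - D[np.ix_(on, off)] @ c + lam_r * mr[on]
    try:
        La = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as err:
        raise DegenerateReductionError(
            "reduced posterior precision not positive definite") from err
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(La))))
    w = np.linalg.solve(La, b)
    quad = float(w @ w)  # b' A^-1 b

    dF = (e - 0.5 * float(c @ D[np.ix_(off, off)] @ c) + float(c @ dvec[off])
          + 0.5 * quad - 0.5 * float(mr[on] @ (lam_r * mr[on]))
          - 0.5 * logdet_A - 0.5 * float(np.sum(np.log(vr[on]))))

    mean_on = np.linalg.solve(La.T, w)
    r_mean[on] = mean_on
    r_cov = None
    if return_cov:
        A_inv = np.linalg.inv(La.T) @ np.linalg.inv(La)
        r_cov = np.zeros((k, k))
        r_cov[np.ix_(on, on)] = A_inv
    return float(dF), r_mean, r_cov


def bayesian_model_reduction(full_prior, full_posterior, reduced_prior):
    """BMR on PriorSpec/PosteriorDensity objects; see :func:`reduce_gaussian`.

    Returns ``(dF, reduced PosteriorDensity)`` where the reduced free
    energy is ``full.free_energy + dF``.
    """
    from .vl import PosteriorDensity

    if list(reduced_prior.names) != list(full_prior.names):
        raise ValueError("reduced prior must cover the same parameters")
    free = full_prior.free
    if np.any(reduced_prior.variance[~free] > 0):
        raise ValueError("cannot free a parameter that the full prior fixes")
    idx = np.flatnonzero(free)
    dF, r_mean_f, r_cov_f = reduce_gaussian(
        full_posterior.mean[idx], full_posterior.cov[np.ix_(idx, idx)],
        full_prior.mean[idx], full_prior.variance[idx],
        reduced_prior.mean[idx], reduced_prior.variance[idx])
    r_mean = full_posterior.mean.copy()
    r_mean[idx] = r_mean_f
    r_cov = np.zeros_like(full_posterior.cov)
    r_cov[np.ix_(idx, idx)] = r_cov_f
    reduced = PosteriorDensity(
        mean=r_mean, cov=r_cov, free_energy=full_posterior.free_energy + dF,
        f_trace=list(full_posterior.f_trace),
        noise_log_precision=full_posterior.noise_log_precision,
        converged=full_posterior.converged, names=list(full_posterior.names))
    return dF, reduced


def bma_moments(means, variances, weights):
    """Moment-matched mean and variance of a Gaussian mixture.

    ``means`` and ``variances`` are (M, k) per-model marginal moments,
    ``weights`` the model posterior probabilities.  Returns (mean (k,),
    variance (k,)) of the mixture: var = E[S + m m'] - mbar mbar' on the
    diagonal.
    """
    m = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mbar = w @ m
    second = w @ (v + m ** 2)
    return mbar, np.clip(second - mbar ** 2, 0.0, None)


def log_evidence_to_pp(log_evidence) -> np.ndarray:
    """Posterior probabilities from log evidences (softmax, overflow-safe)."""
    le = np.asarray(log_evidence, dtype=float)
    le = le - le.max()
    w = np.exp(le)
    return w / w.sum()
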