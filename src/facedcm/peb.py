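"""Parametric empirical Bayes over subject-level DCM posteriors.

The hierarchical GLM is theta_i = beta' x_i + eps_i: subject parameters are
a group-level linear model over covariates plus i.i.d. between-subject
Gaussian deviations.  Subject-level evidence enters through the posterior /
prior density ratio of each subject's inversion, so conditional on the
between-subject log-precision hyperparameter the beta posterior is an exact
conjugate Gaussian; the hyperparameter is then optimized on the group free
energy (empirical Bayes).

Model comparison over reduced beta priors (cells switched off) uses
Bayesian model reduction on the group posterior: the factorial space is
scored per covariate over all 37^3 joint assignments, pooled into factor
families, and summarized by Bayesian model averaging.  A greedy automatic
search prunes the 132 cells without factorial constraints and averages the
256 models of its final iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .bmr import bma_moments, log_evidence_to_pp
from .modelspace import ModelSpace, build_factorial_space  # noqa: F401
from .vl import PosteriorDensity

REGRESSORS = ("commonality", "LI_FFA", "LI_OFA", "handedness", "age", "gender")

#: group-level prior variance per beta cell
BETA_PRIOR_VAR = 1.0 / 16.0
#: baseline between-subject variance (scaled by exp(-gamma))
BETWEEN_VAR0 = 1.0 / 16.0
#: hyperprior on the between-subject log-precision gamma
GAMMA_PRIOR_MEAN = 0.0
GAMMA_PRIOR_VAR = 1.0


class InvalidDesignError(ValueError):
    """The group design matrix violates its invariants."""


@dataclass
class GroupDesign:
    """Second-level design matrix: commonality column plus centered covariates."""

    X: np.ndarray
    names: tuple = REGRESSORS

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.names = tuple(self.names)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise InvalidDesignError("X must be subjects x regressors")
        if not np.allclose(self.X[:, 0], 1.0):
            raise InvalidDesignError("first regressor must be the all-ones "
                                     "commonality column")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise InvalidDesignError("design matrix is rank deficient")

    @classmethod
    def from_covariates(cls, df: pd.DataFrame, names=REGRESSORS) -> "GroupDesign":
        """Build X from a covariate table, mean-centering every covariate."""
        cols = [np.ones(len(df))]
        for nm in names[1:]:
            col = np.asarray(df[nm.lower()], dtype=float)
            cols.append(col - col.mean())
        return cls(np.column_stack(cols), names)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass
class _GaussianReducer:
    """Precomputed quantities for repeated BMR on one Gaussian posterior."""

    mu: np.ndarray
    dvec: np.ndarray
    D: np.ndarray
    e: float
    prior_var: np.ndarray

    @classmethod
    def from_posterior(cls, mu, cov, prior_mean, prior_var):
        lam0 = 1.0 / prior_var
        Lq = np.linalg.cholesky(cov)
        Lam_q = np.linalg.inv(Lq.T) @ np.linalg.inv(Lq)
        logdet_Sq = 2.0 * float(np.sum(np.log(np.diag(Lq))))
        D = Lam_q - np.diag(lam0)
        dvec = Lam_q @ mu - lam0 * prior_mean
        e = (-0.5 * float(mu @ Lam_q @ mu)
             + 0.5 * float(prior_mean @ (lam0 * prior_mean))
             - 0.5 * logdet_Sq + 0.5 * float(np.sum(np.log(prior_var))))
        return cls(mu=mu, dvec=dvec, D=D, e=e, prior_var=prior_var)

    def score(self, on: np.ndarray, moments: bool = False):
        """dF of the reduced model keeping only ``on`` cells (others at 0).

        With ``moments`` also returns the reduced posterior mean and
        marginal variances over all cells (zeros where off).
        """
        on = np.asarray(on, dtype=bool)
        k = self.mu.size
        if not on.any():
            dF = self.e
            return (dF, np.zeros(k), np.zeros(k)) if moments else dF
        lam_r = 1.0 / self.prior_var[on]
        A = self.D[np.ix_(on, on)] + np.diag(lam_r)
        b = self.dvec[on]
        La = np.linalg.cholesky(A)
        w = np.linalg.solve(La, b)
        dF = (self.e + 0.5 * float(w @ w)
              - 0.5 * 2.0 * float(np.sum(np.log(np.diag(La))))
              - 0.5 * float(np.sum(np.log(self.prior_var[on]))))
        if not moments:
            return dF
        mean = np.zeros(k)
        mean[on] = np.linalg.solve(La.T, w)
        Ainv = np.linalg.inv(La.T) @ np.linalg.inv(La)
        var = np.zeros(k)
        var[on] = np.diag(Ainv)
        return dF, mean, var


# ----------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------
@dataclass
class BMAResult:
    """Moment-matched Bayesian model average over beta cells."""

    cell_names: list
    mean: np.ndarray
    sd: np.ndarray
    pp_nonzero: np.ndarray
    n_models: int

    def flagged(self, threshold: float = 0.75) -> np.ndarray:
        """Cells whose posterior probability of being non-zero exceeds
        ``threshold`` (strictly)."""
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        return np.asarray(self.pp_nonzero) > threshold

    def table(self, threshold: float = 0.75) -> pd.DataFrame:
        flags = self.flagged(threshold)
        return pd.DataFrame({"cell": self.cell_names, "mean": self.mean,
                             "sd": self.sd, "pp_nonzero": self.pp_nonzero,
                             "flagged": flags})


def threshold_parameters(bma: BMAResult, threshold: float = 0.75) -> pd.DataFrame:
    """All cells with their flags; flagged = Pp(nonzero) strictly above
    threshold."""
    return bma.table(threshold)


@dataclass
class ComparisonResult:
    """Factorial comparison over joint per-covariate model assignments."""

    space: ModelSpace
    covariates: tuple
    joint_log_evidence: np.ndarray   # shape (37,) * len(covariates)
    marginal_pp: dict                # covariate -> (37,)
    best_combination: tuple          # model index per covariate
    best_joint_pp: float
    bma: BMAResult | None = None

    @property
    def joint_pp(self) -> np.ndarray:
        le = self.joint_log_evidence
        return np.exp(le - logsumexp(le))

    def winner(self, covariate: str):
        i = int(np.argmax(self.marginal_pp[covariate]))
        return self.space[i], float(self.marginal_pp[covariate][i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.space.models):
            row = {"model": i + 1, "name": m.name, "hemisphere": m.hemisphere,
                   "region": m.region, "type": m.ctype}
            for cov in self.covariates:
                row[f"pp_{cov}"] = self.marginal_pp[cov][i]
            rows.append(row)
        return pd.DataFrame(rows)


def family_inference(result: ComparisonResult, factor: str) -> pd.DataFrame:
    """Pooled posterior probability per family of one factor.

    Family probability is the sum of the member models' marginal Pp; the
    null model forms the NONE family.  Returns families x covariates.
    """
    fams = result.space.families(factor)
    out = {}
    for fam, idx in fams.items():
        out[fam] = {cov: float(np.sum(result.marginal_pp[cov][idx]))
                    for cov in result.covariates}
    return pd.DataFrame(out).T


@dataclass
class SearchResult:
    """Greedy-search outcome: retained cells and final-iteration BMA."""

    cell_names: list
    retained: np.ndarray
    bma: BMAResult
    free_energy_path: list = field(default_factory=list)

    @property
    def n_final_models(self) -> int:
        return self.bma.n_models


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------
class PEB:
    """Group-level parametric-empirical-Bayes model.

    Parameters
    ----------
    posteriors : list of PosteriorDensity
        Subject-level posteriors; each must carry the selected parameters.
    design : GroupDesign
    field_names : list of str
        Subject-level parameters taken to the group (default: all
        modulatory parameters present in the first posterior).
    within_prior : PriorSpec-like (mean, variance arrays) or None
        Subject-level prior over the selected parameters; defaults to
        zero mean, unit variance (the modulatory default).
    """

    def __init__(self, posteriors, design: GroupDesign, field_names=None,
                 within_prior=None):
        if len(posteriors) < 2:
            raise ValueError("PEB needs at least two subjects")
        if len(posteriors) != design.n_subjects:
            raise InvalidDesignError("number of posteriors does not match "
                                     "design rows")
        if field_names is None:
            field_names = [nm for nm in posteriors[0].names
                           if nm.startswith("B(")]
        for post in posteriors:
            missing = [nm for nm in field_names if nm not in post.names]
            if missing:
                raise ValueError(f"posterior lacks parameters {missing[:3]}...")
        self.posteriors = list(posteriors)
        self.design = design
        self.field_names = list(field_names)
        if within_prior is None:
            self.within_mean = np.zeros(len(field_names))
            self.within_var = np.ones(len(field_names))
        else:
            sub = within_prior.subset(field_names)
            self.within_mean = sub.mean
            self.within_var = sub.variance
        self.cell_names = [f"{reg}:{nm}" for reg in design.names
                           for nm in field_names]

    # -- internal: subject likelihood factors --------------------------
    def _likelihood_factors(self):
        """Each subject's implied likelihood over theta_i in natural form.

        The inversion's posterior/prior ratio is an unnormalized Gaussian
        factor exp(kappa - 0.5 theta'H theta + theta'b) with H = Pq - P0.
        H is kept in precision form (clipped to PSD) so directions in
        which the data added no information contribute exactly nothing,
        with no ill-conditioned inversion.
        """
        k = len(self.field_names)
        P0 = 1.0 / self.within_var
        m0 = self.within_mean
        factors = []
        for post in self.posteriors:
            marg = post.marginal(self.field_names)
            Sq = marg.cov + 1e-12 * np.eye(k)
            Pq = np.linalg.inv(Sq)
            H = Pq - np.diag(P0)
            w, U = np.linalg.eigh(H)
            H = (U * np.clip(w, 0.0, None)) @ U.T
            b = Pq @ marg.mean - P0 * m0
            sign, logdet_Sq = np.linalg.slogdet(Sq)
            kappa = (-0.5 * float(marg.mean @ Pq @ marg.mean)
                     + 0.5 * float(m0 @ (P0 * m0))
                     - 0.5 * logdet_Sq
                     + 0.5 * float(np.sum(np.log(self.within_var))))
            factors.append((H, b, kappa))
        return factors

    def _beta_posterior(self, gamma, factors):
        k = len(self.field_names)
        nreg = len(self.design.names)
        m = nreg * k
        p_b = np.exp(gamma) / BETWEEN_VAR0  # between-subject precision
        P_beta = np.eye(m) / BETA_PRIOR_VAR
        h = np.zeros(m)
        log_lik = 0.0
        eye = np.eye(k)
        for i, (H, b, kappa) in enumerate(factors):
            A = H + p_b * eye
            La = np.linalg.cholesky(A)
            A_inv = np.linalg.inv(La.T) @ np.linalg.inv(La)
            logdet_A = 2.0 * float(np.sum(np.log(np.diag(La))))
            # W = P_b - P_b A^-1 P_b  (Woodbury form of (Sigma_b + H^+)^-1)
            W = p_b * eye - (p_b ** 2) * A_inv
            w_vec = p_b * (A_inv @ b)
            x = self.design.X[i]
            P_beta += np.kron(np.outer(x, x), W)
            h += np.kron(x, w_vec)
            log_lik += (kappa + 0.5 * float(b @ A_inv @ b)
                        + 0.5 * k * np.log(p_b) - 0.5 * logdet_A)
        Lb = np.linalg.cholesky(P_beta)
        u = np.linalg.solve(Lb, h)
        mu_beta = np.linalg.solve(Lb.T, u)
        logdet_P = 2.0 * float(np.sum(np.log(np.diag(Lb))))
        log_z = (log_lik + 0.5 * float(u @ u)
                 - 0.5 * (m * np.log(BETA_PRIOR_VAR) + logdet_P))
        return mu_beta, Lb, log_z

    def fit(self, gamma_bounds=(-8.0, 8.0)) -> "PEBResults":
        """Empirical-Bayes fit: optimize the between-subject log-precision,
        then return the conjugate Gaussian posterior over beta."""
        factors = self._likelihood_factors()

        def neg_f(gamma):
            _, _, log_z = self._beta_posterior(gamma, factors)
            return -(log_z
                     - 0.5 * (gamma - GAMMA_PRIOR_MEAN) ** 2 / GAMMA_PRIOR_VAR)

        opt = minimize_scalar(neg_f, bounds=gamma_bounds, method="bounded",
                              options={"xatol": 1e-4})
        gamma = float(opt.x)
        mu_beta, Lb, _ = self._beta_posterior(gamma, factors)
        Linv = np.linalg.inv(Lb)
        cov_beta = Linv.T @ Linv
        return PEBResults(model=self, beta_mean=mu_beta, beta_cov=cov_beta,
                          free_energy=float(-opt.fun), gamma=gamma)


@dataclass
class PEBResults:
    """Estimated group-level posterior over the (regressor x parameter)
    beta cells, plus the group free energy."""

    model: PEB
    beta_mean: np.ndarray
    beta_cov: np.ndarray
    free_energy: float
    gamma: float

    @property
    def cell_names(self) -> list:
        return self.model.cell_names

    @property
    def n_cells(self) -> int:
        return self.beta_mean.size

    def beta_table(self) -> pd.DataFrame:
        sd = np.sqrt(np.diag(self.beta_cov))
        reg = [c.split(":", 1)[0] for c in self.cell_names]
        par = [c.split(":", 1)[1] for c in self.cell_names]
        return pd.DataFrame({"regressor": reg, "parameter": par,
                             "mean": self.beta_mean, "sd": sd})

    def between_subject_sd(self) -> float:
        return float(np.sqrt(BETWEEN_VAR0 * np.exp(-self.gamma)))

    def _reducer(self) -> _GaussianReducer:
        m = self.n_cells
        return _GaussianReducer.from_posterior(
            self.beta_mean, self.beta_cov, np.zeros(m),
            np.full(m, BETA_PRIOR_VAR))

    def _cell_grid(self):
        """(n_regressors, k) index grid into the flat cell vector."""
        nreg = len(self.model.design.names)
        k = len(self.model.field_names)
        return np.arange(nreg * k).reshape(nreg, k)

    # ------------------------------------------------------------------
    # factorial comparison
    # ------------------------------------------------------------------
    def compare(self, space: ModelSpace | None = None,
                covariates=("commonality", "LI_FFA", "LI_OFA"),
                compute_bma: bool = True,
                bma_weight_floor: float = 1e-8) -> ComparisonResult:
        """Score every joint assignment of one candidate model per covariate.

        Each covariate of interest independently receives one of the
        candidate masks (applied to its beta row via BMR); nuisance
        regressor rows are never reduced.  Marginal Pp per covariate sums
        the joint Pp over the other covariates' assignments.
        """
        from .network import DCMSpec

        if space is None:
            space = build_factorial_space(DCMSpec.face_network())
        for cov in covariates:
            if cov not in self.model.design.names:
                raise InvalidDesignError(f"covariate {cov!r} not in design")
        if space.parameter_names != self.model.field_names:
            raise ValueError("model space does not match the PEB parameters")

        red = self._reducer()
        grid = self._cell_grid()
        cov_rows = [self.model.design.names.index(c) for c in covariates]
        n_models = len(space)
        masks = np.array([m.mask for m in space.models])  # (37, k)

        shape = (n_models,) * len(covariates)
        log_z = np.empty(shape)
        base_on = np.ones(self.n_cells, dtype=bool)
        for combo in np.ndindex(shape):
            on = base_on.copy()
            for cov_i, model_i in enumerate(combo):
                on[grid[cov_rows[cov_i]]] = masks[model_i]
            log_z[combo] = red.score(on)

        flat_pp = log_evidence_to_pp(log_z.ravel())
        joint_pp = flat_pp.reshape(shape)
        best = np.unravel_index(int(np.argmax(joint_pp)), shape)
        marginal = {}
        for cov_i, cov in enumerate(covariates):
            axes = tuple(a for a in range(len(covariates)) if a != cov_i)
            marginal[cov] = joint_pp.sum(axis=axes)

        bma = None
        if compute_bma:
            # moment-match over the models that carry essentially all the
            # posterior mass (capped, so flat-evidence cases stay tractable)
            order = np.argsort(-flat_pp)
            cum = np.cumsum(flat_pp[order])
            n_keep = int(np.searchsorted(cum, 1.0 - 1e-9) + 1)
            keep = order[:min(max(n_keep, 1), 4096)]
            keep = keep[flat_pp[keep] > bma_weight_floor * flat_pp[keep[0]]]
            weights = flat_pp[keep] / flat_pp[keep].sum()
            means = np.empty((keep.size, self.n_cells))
            vars_ = np.empty((keep.size, self.n_cells))
            for j, flat_i in enumerate(keep):
                combo = np.unravel_index(int(flat_i), shape)
                on = base_on.copy()
                for cov_i, model_i in enumerate(combo):
                    on[grid[cov_rows[cov_i]]] = masks[model_i]
                _, means[j], vars_[j] = red.score(on, moments=True)
            mean, var = bma_moments(means, vars_, weights)
            pp_nonzero = np.ones(self.n_cells)
            for cov_i, cov in enumerate(covariates):
                for p in range(masks.shape[1]):
                    on_models = masks[:, p]
                    pp_nonzero[grid[cov_rows[cov_i], p]] = float(
                        np.sum(marginal[cov][on_models]))
            bma = BMAResult(cell_names=self.cell_names, mean=mean,
                            sd=np.sqrt(var), pp_nonzero=pp_nonzero,
                            n_models=int(np.prod(shape)))

        return ComparisonResult(
            space=space, covariates=tuple(covariates),
            joint_log_evidence=log_z, marginal_pp=marginal,
            best_combination=tuple(int(b) for b in best),
            best_joint_pp=float(joint_pp[best]), bma=bma)

    # ------------------------------------------------------------------
    # greedy automatic search
    # ------------------------------------------------------------------
    def search(self, n_final: int = 8) -> SearchResult:
        """Greedy pruning of beta cells by Bayesian model reduction.

        Each iteration scores the removal of every currently-on cell,
        collects the cells whose individual removal does not reduce the
        evidence, exhaustively scores all on/off combinations of the (up
        to) ``n_final`` most dispensable of them, and jumps to the best
        combination.  When no removal improves the evidence, Bayesian
        model averaging is performed over the ``2 ** n_final`` models of
        the final iteration.
        """
        red = self._reducer()
        m = self.n_cells
        on = np.ones(m, dtype=bool)
        f_path = [red.score(on)]
        recently_pruned: list = []

        for _ in range(m):
            current = f_path[-1]
            on_idx = np.flatnonzero(on)
            deltas = np.empty(on_idx.size)
            for j, c in enumerate(on_idx):
                trial = on.copy()
                trial[c] = False
                deltas[j] = red.score(trial) - current
            candidates = on_idx[deltas >= 0]
            if candidates.size == 0:
                break
            order = np.argsort(-deltas[deltas >= 0])
            chosen = candidates[order[:n_final]]
            # exhaustive scoring over the chosen subset
            best_f, best_pattern = -np.inf, None
            for pattern in range(2 ** chosen.size):
                trial = on.copy()
                for bit, c in enumerate(chosen):
                    trial[c] = bool((pattern >> bit) & 1)
                f = red.score(trial)
                if f > best_f:
                    best_f, best_pattern = f, pattern
            if best_f <= current:
                break
            for bit, c in enumerate(chosen):
                keep = bool((best_pattern >> bit) & 1)
                on[c] = keep
                if not keep:
                    recently_pruned.append(int(c))
            f_path.append(best_f)

        # final iteration: exhaustive BMA over the last n_final undecided cells
        undecided = list(np.flatnonzero(on)[np.argsort(
            [abs(red.score(self._toggle(on, c)) - f_path[-1])
             for c in np.flatnonzero(on)])][:n_final])
        for c in reversed(recently_pruned):
            if len(undecided) >= n_final:
                break
            if c not in undecided:
                undecided.append(c)
        undecided = undecided[:n_final]

        n_models = 2 ** len(undecided)
        log_e = np.empty(n_models)
        means = np.empty((n_models, m))
        vars_ = np.empty((n_models, m))
        on_masks = np.empty((n_models, m), dtype=bool)
        for pattern in range(n_models):
            trial = on.copy()
            for bit, c in enumerate(undecided):
                trial[c] = bool((pattern >> bit) & 1)
            log_e[pattern], means[pattern], vars_[pattern] = \
                red.score(trial, moments=True)
            on_masks[pattern] = trial
        weights = log_evidence_to_pp(log_e)
        mean, var = bma_moments(means, vars_, weights)
        pp_nonzero = weights @ on_masks
        bma = BMAResult(cell_names=self.cell_names, mean=mean,
                        sd=np.sqrt(var), pp_nonzero=pp_nonzero,
                        n_models=n_models)
        best_pattern = int(np.argmax(log_e))
        retained = on_masks[best_pattern]
        return SearchResult(cell_names=self.cell_names, retained=retained,
                            bma=bma, free_energy_path=f_path)

    @staticmethod
    def _toggle(on: np.ndarray, c: int) -> np.ndarray:
        trial = on.copy()
        trial[c] = not trial[c]
        return trial

    def summary(self) -> str:
        lines = [
            "Parametric Empirical Bayes results",
            "==================================",
            f"subjects:            {self.model.design.n_subjects}",
            f"regressors:          {', '.join(self.model.design.names)}",
            f"parameters carried:  {len(self.model.field_names)}",
            f"beta cells:          {self.n_cells}",
            f"group free energy:   {self.free_energy:.2f}",
            f"between-subject SD:  {self.between_subject_sd():.4f}",
        ]
        tab = self.beta_table()
        strongest = tab.reindex(tab["mean"].abs().sort_values(ascending=False)
                                .index[:8])
        lines.append("largest |beta| cells:")
        for _, r in strongest.iterrows():
            lines.append(f"  {r.regressor:>12s} {r.parameter:<28s} "
                         f"{r['mean']:+7.3f} (sd {r.sd:.3f})")
        return "\n".join(lines)


def fit_peb(posteriors, design: GroupDesign, field_names=None,
            within_prior=None) -> PEBResults:
    """Convenience wrapper: build and fit the PEB model in one call."""
    return PEB(posteriors, design, field_names=field_names,
               within_prior=within_prior).fit()
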