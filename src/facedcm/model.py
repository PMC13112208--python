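"""Subject-level DCM as a fittable model object.

``FaceDCM`` couples one subject's mean-centered region time series with
the stimulus design, the network structure and the shrinkage priors;
``fit()`` runs variational Laplace and returns ``DCMResults`` carrying the
Gaussian posterior, the free energy and fit diagnostics.
"""

from __future__ import annotations

import numpy as np

from .data import SubjectTimeSeries
from .design import StimulusDesign
from .forward import ForwardModel
from .network import DCMParams, DCMSpec
from .priors import PriorSpec, default_priors
from .vl import PosteriorDensity, VLSettings, variational_laplace


class FaceDCM:
    """One subject's generative model of the face network.

    Parameters
    ----------
    data : SubjectTimeSeries or ndarray (scans x regions)
        Mean-centered BOLD; region order must match the spec.
    design : StimulusDesign
    spec : DCMSpec, optional
        Defaults to the canonical 6-region face network.
    priors : PriorSpec, optional
        Defaults to :func:`facedcm.priors.default_priors`.
    """

    def __init__(self, data, design: StimulusDesign, spec: DCMSpec | None = None,
                 priors: PriorSpec | None = None):
        self.spec = spec or DCMSpec.face_network()
        if isinstance(data, SubjectTimeSeries):
            if tuple(data.regions) != tuple(self.spec.regions):
                raise ValueError("region labels do not match the spec order")
            if abs(data.tr_s - design.tr_s) > 1e-9:
                raise ValueError("time-series TR does not match the design")
            self.subject_id = data.subject_id
            y = data.bold
        else:
            self.subject_id = "subject"
            y = np.asarray(data, dtype=float)
        if y.shape != (design.n_scans, self.spec.n_regions):
            raise ValueError(
                f"data shape {y.shape} does not match design "
                f"({design.n_scans} scans x {self.spec.n_regions} regions)")
        self.bold = y - y.mean(axis=0, keepdims=True)
        self.design = design
        self.priors = priors or default_priors(self.spec)
        self.forward = ForwardModel(self.spec, design)
        # data points grouped by region for the noise hyperparameters
        self._groups = np.tile(np.arange(self.spec.n_regions),
                               (design.n_scans, 1)).ravel()

    def _predict_flat(self, theta_batch: np.ndarray) -> np.ndarray:
        bold = self.forward.predict_batch(theta_batch)
        return bold.reshape(bold.shape[0], -1)

    def fit(self, settings: VLSettings | None = None) -> "DCMResults":
        """Invert the model by variational Laplace."""
        posterior = variational_laplace(
            self._predict_flat, self.bold.ravel(), self.priors,
            noise_groups=self._groups, settings=settings)
        return DCMResults(self, posterior)


class DCMResults:
    """Posterior density, free energy and diagnostics of one inversion."""

    def __init__(self, model: FaceDCM, posterior: PosteriorDensity):
        self.model = model
        self.posterior = posterior

    @property
    def free_energy(self) -> float:
        return self.posterior.free_energy

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def params(self) -> DCMParams:
        return DCMParams(self.model.spec, self.posterior.mean.copy())

    def fitted_values(self) -> np.ndarray:
        return self.model.forward.predict(self.posterior.mean)

    def explained_variance(self) -> float:
        """Percent variance of the data explained by the posterior-mean
        prediction: 100 * (1 - RSS / TSS).  Can be negative for
        pathological fits."""
        return explained_variance(self.posterior, self.model.bold,
                                  self.model.spec, self.model.design,
                                  forward=self.model.forward)

    def modulatory_posterior(self) -> PosteriorDensity:
        """Marginal posterior over the modulatory (B) parameters, the
        subvector carried to the group level."""
        return self.posterior.marginal(self.model.spec.modulatory_names())

    def summary(self) -> str:
        sd = self.posterior.sd()
        names = self.posterior.names
        lines = [
            f"DCM inversion: {self.model.subject_id}",
            "-" * 40,
            f"free energy:        {self.free_energy:.2f}",
            f"explained variance: {self.explained_variance():.1f}%",
            f"converged:          {self.converged} "
            f"({len(self.posterior.f_trace)} accepted steps)",
            "modulatory parameters (posterior mean +/- sd):",
        ]
        for nm in self.model.spec.modulatory_names():
            i = names.index(nm)
            lines.append(f"  {nm:<28s} {self.posterior.mean[i]:+7.3f} "
                         f"+/- {sd[i]:.3f}")
        return "\n".join(lines)

    def plot_fit(self, axes=None):
        """Observed vs fitted time series per region."""
        import matplotlib.pyplot as plt

        fitted = self.fitted_values()
        if axes is None:
            _, axes = plt.subplots(self.model.spec.n_regions, 1, sharex=True,
                                   figsize=(8, 10))
        t = np.arange(self.model.design.n_scans) * self.model.design.tr_s
        for i, (ax, region) in enumerate(zip(axes, self.model.spec.regions)):
            ax.plot(t, self.model.bold[:, i], lw=0.6, label="observed")
            ax.plot(t, fitted[:, i], lw=1.2, label="fitted")
            ax.set_ylabel(region)
        axes[0].legend(loc="upper right")
        axes[-1].set_xlabel("time (s)")
        return axes


def explained_variance(posterior, data, spec: DCMSpec | None = None,
                       design: StimulusDesign | None = None,
                       forward: ForwardModel | None = None) -> float:
    """Percent explained variance of a posterior-mean prediction.

    ``data`` may be a SubjectTimeSeries or an array (scans x regions).
    """
    y = data.bold if isinstance(data, SubjectTimeSeries) else np.asarray(data)
    y = y - y.mean(axis=0, keepdims=True)
    tss = float(np.sum(y ** 2))
    if tss <= 0:
        raise ValueError("zero-variance data: explained variance undefined")
    fm = forward if forward is not None else ForwardModel(spec, design)
    if isinstance(posterior, (np.ndarray, list, DCMParams)):
        mean = posterior.values if isinstance(posterior, DCMParams) else np.asarray(posterior)
    else:
        mean = posterior.mean
    pred = fm.predict(mean)
    rss = float(np.sum((y - pred) ** 2))
    return 100.0 * (1.0 - rss / tss)
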