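"""In-memory containers for region time series and their HDF5 round trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np


@dataclass
class SubjectTimeSeries:
    """Mean-centered BOLD of one subject, scans x regions.

    Attributes
    ----------
    subject_id : str
    regions : tuple of str
    bold : ndarray, (n_scans, n_regions)
        Mean-centered per region, arbitrary units.
    tr_s : float
    """

    subject_id: str
    regions: tuple
    bold: np.ndarray
    tr_s: float

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        self.regions = tuple(self.regions)
        if self.bold.ndim != 2 or self.bold.shape[1] != len(self.regions):
            raise ValueError("bold must be scans x regions")
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("bold contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.bold.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("bold", data=self.bold)
            h5.attrs["subject_id"] = self.subject_id
            h5.attrs["tr_s"] = self.tr_s
            h5.attrs["regions"] = ",".join(self.regions)

    @classmethod
    def load(cls, path) -> "SubjectTimeSeries":
        with h5py.File(path, "r") as h5:
            return cls(subject_id=str(h5.attrs["subject_id"]),
                       regions=tuple(str(h5.attrs["regions"]).split(",")),
                       bold=h5["bold"][()], tr_s=float(h5.attrs["tr_s"]))


def save_posterior(path, posterior, extra: dict | None = None) -> None:
    """Write a PosteriorDensity to an HDF5 file with a JSON-able attr set."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("mean", data=posterior.mean)
        h5.create_dataset("cov", data=posterior.cov)
        h5.create_dataset("f_trace", data=np.asarray(posterior.f_trace))
        h5.create_dataset("noise_log_precision",
                          data=np.asarray(posterior.noise_log_precision))
        h5.attrs["free_energy"] = posterior.free_energy
        h5.attrs["converged"] = bool(posterior.converged)
        h5.attrs["names"] = "\n".join(posterior.names)
        for k, v in (extra or {}).items():
            h5.attrs[k] = v


def load_posterior(path):
    from .vl import PosteriorDensity

    with h5py.File(path, "r") as h5:
        return PosteriorDensity(
            mean=h5["mean"][()], cov=h5["cov"][()],
            free_energy=float(h5.attrs["free_energy"]),
            f_trace=list(h5["f_trace"][()]),
            noise_log_precision=h5["noise_log_precision"][()],
            converged=bool(h5.attrs["converged"]),
            names=str(h5.attrs["names"]).split("\n"))


def posterior_files(directory) -> list:
    return sorted(Path(directory).glob("posterior_*.h5"))
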