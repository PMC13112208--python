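"""Shrinkage priors over the DCM parameter vector.

Zero-mean Gaussian priors throughout; a zero prior variance fixes the
parameter at its prior mean (used both for structurally absent entries and
for switching parameters off during model reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DCMSpec

# prior variances by parameter block
VAR_A_OFFDIAG = 1.0 / 64.0
VAR_SELF = 1.0 / 256.0
VAR_B = 1.0
VAR_C = 1.0
VAR_HEMO = 1.0 / 256.0


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior: mean, variance and name -> index map."""

    mean: np.ndarray
    variance: np.ndarray
    names: list

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean and variance shapes differ")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")
        self.index = {nm: i for i, nm in enumerate(self.names)}

    @property
    def n(self) -> int:
        return self.mean.size

    @property
    def free(self) -> np.ndarray:
        """Boolean mask of parameters with non-zero prior variance."""
        return self.variance > 0

    def copy(self) -> "PriorSpec":
        return PriorSpec(self.mean.copy(), self.variance.copy(), list(self.names))

    def switched_off(self, names) -> "PriorSpec":
        """Reduced prior with the given parameters fixed at zero."""
        out = self.copy()
        for nm in names:
            i = out.index[nm]
            out.mean[i] = 0.0
            out.variance[i] = 0.0
        return out

    def subset(self, names) -> "PriorSpec":
        idx = [self.index[nm] for nm in names]
        return PriorSpec(self.mean[idx], self.variance[idx], list(names))


def default_priors(spec: DCMSpec) -> PriorSpec:
    """Default zero-mean priors for the face-network DCM.

    Enabled A off-diagonals get variance 1/64, self log-scalings 1/256,
    B and C entries 1, and the hemodynamic log-scalings (transit,
    efficacy) 1/256.
    """
    names = spec.parameter_names()
    var = np.empty(len(names))
    for i, nm in enumerate(names):
        if nm.startswith("A:"):
            src, tgt = nm[2:].split("->")
            var[i] = VAR_SELF if src == tgt else VAR_A_OFFDIAG
        elif nm.startswith("B("):
            var[i] = VAR_B
        elif nm.startswith("C("):
            var[i] = VAR_C
        else:  # transit / efficacy log-scalings
            var[i] = VAR_HEMO
    return PriorSpec(np.zeros(len(names)), var, names)
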