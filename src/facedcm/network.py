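"""Six-region face-network graph and its parameterization.

The network comprises early visual cortex (EVC), occipital face area (OFA)
and fusiform face area (FFA) in both hemispheres.  Directed baseline
connectivity (the A matrix), input-dependent modulations (one B matrix per
input) and driving inputs (the C matrix) follow the standard bilinear DCM
convention: entry ``(i, j)`` is the influence of region ``j`` on region
``i``.  Self-connections are parameterized as log-scalings ``x`` of a fixed
-0.5 Hz decay, so the effective self-connection ``-0.5 * exp(x)`` is
negative for every finite ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

REGIONS = ("lEVC", "rEVC", "lOFA", "rOFA", "lFFA", "rFFA")
INPUTS = ("visual", "faces")

#: directed off-diagonal baseline connections, as (source, target) pairs
A_CONNECTIONS = (
    # intra-hemispheric OFA <-> FFA
    ("lOFA", "lFFA"), ("lFFA", "lOFA"),
    ("rOFA", "rFFA"), ("rFFA", "rOFA"),
    # homotopic inter-hemispheric
    ("lOFA", "rOFA"), ("rOFA", "lOFA"),
    ("lFFA", "rFFA"), ("rFFA", "lFFA"),
    # unidirectional forward input connections
    ("lEVC", "lOFA"), ("lEVC", "lFFA"),
    ("rEVC", "rOFA"), ("rEVC", "rFFA"),
)

#: regions whose self-connections the face input may modulate
FACE_SELF_REGIONS = ("lOFA", "rOFA", "lFFA", "rFFA")

#: between-region connections the face input may modulate (all of them)
FACE_CONNECTIONS = A_CONNECTIONS

#: driving input targets
C_TARGETS = ("lEVC", "rEVC")


def _index(region: str) -> int:
    try:
        return REGIONS.index(region)
    except ValueError as err:
        raise ValueError(f"unknown region {region!r}") from err


def effective_self(x: float) -> float:
    """Effective self-connection rate (Hz) for log-scaling parameter ``x``.

    The self-connection downregulates a region's activity by a factor of
    ``-0.5 * exp(x)``, where -0.5 Hz is the default level of self-inhibition;
    the exponential keeps the rate strictly negative.
    """
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"self-connection log-scaling must be finite, got {x}")
    return -0.5 * float(np.exp(x))


@dataclass(frozen=True)
class DCMSpec:
    """Sparsity structure (allowed A/B/C entries) of the face-network DCM.

    Attributes
    ----------
    regions : tuple of str
        Ordered region labels.
    inputs : tuple of str
        Ordered input labels; the first drives the system via C.
    a_mask : ndarray of bool, (n, n)
        Allowed baseline connections; diagonal always True.
    b_masks : dict of str -> ndarray of bool, (n, n)
        Allowed modulations per input (diagonal entries modulate the
        self log-scaling).
    c_mask : ndarray of bool, (n, k)
        Allowed driving inputs.
    """

    regions: tuple = REGIONS
    inputs: tuple = INPUTS
    a_mask: np.ndarray = field(default=None)
    b_masks: dict = field(default=None)
    c_mask: np.ndarray = field(default=None)

    @classmethod
    def face_network(cls) -> "DCMSpec":
        """The canonical 6-region bilateral face network."""
        n = len(REGIONS)
        a = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(a, True)
        for src, tgt in A_CONNECTIONS:
            a[_index(tgt), _index(src)] = True

        b_visual = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(b_visual, True)  # visual modulates all 6 selfs

        b_faces = np.zeros((n, n), dtype=bool)
        for r in FACE_SELF_REGIONS:
            b_faces[_index(r), _index(r)] = True
        for src, tgt in FACE_CONNECTIONS:
            b_faces[_index(tgt), _index(src)] = True

        c = np.zeros((n, len(INPUTS)), dtype=bool)
        for r in C_TARGETS:
            c[_index(r), 0] = True  # visual input only

        return cls(a_mask=a, b_masks={"visual": b_visual, "faces": b_faces},
                   c_mask=c)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def n_modulatory(self) -> int:
        """Number of modulatory (B) parameters across all inputs."""
        return int(sum(int(m.sum()) for m in self.b_masks.values()))

    # ------------------------------------------------------------------
    # parameter vector layout
    # ------------------------------------------------------------------
    def parameter_names(self) -> list:
        """Ordered names of the free parameters of one subject's DCM.

        Layout: A off-diagonals, A self log-scalings, B entries per input
        (diagonal entries are log-scaling increments), C gains, then the
        per-region hemodynamic log-scalings (transit time, neurovascular
        efficacy).
        """
        names = []
        n = self.n_regions
        for i in range(n):
            for j in range(n):
                if i != j and self.a_mask[i, j]:
                    names.append(f"A:{self.regions[j]}->{self.regions[i]}")
        for r in self.regions:
            names.append(f"A:{r}->{r}")
        for inp in self.inputs:
            m = self.b_masks[inp]
            for r_i, r in enumerate(self.regions):
                if m[r_i, r_i]:
                    names.append(f"B({inp}):{r}->{r}")
            for i in range(n):
                for j in range(n):
                    if i != j and m[i, j]:
                        names.append(f"B({inp}):{self.regions[j]}->{self.regions[i]}")
        for k, inp in enumerate(self.inputs):
            for i in range(n):
                if self.c_mask[i, k]:
                    names.append(f"C({inp}):{self.regions[i]}")
        for r in self.regions:
            names.append(f"transit:{r}")
        for r in self.regions:
            names.append(f"efficacy:{r}")
        return names

    def modulatory_names(self) -> list:
        """Names of the modulatory (B) parameters, in vector order."""
        return [nm for nm in self.parameter_names() if nm.startswith("B(")]

    def name_index(self) -> dict:
        return {nm: i for i, nm in enumerate(self.parameter_names())}

    def n_parameters(self) -> int:
        return len(self.parameter_names())

    def to_json(self) -> str:
        payload = {
            "regions": list(self.regions),
            "inputs": list(self.inputs),
            "a_mask": self.a_mask.astype(int).tolist(),
            "b_masks": {k: v.astype(int).tolist() for k, v in self.b_masks.items()},
            "c_mask": self.c_mask.astype(int).tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DCMSpec":
        d = json.loads(text)
        return cls(
            regions=tuple(d["regions"]),
            inputs=tuple(d["inputs"]),
            a_mask=np.asarray(d["a_mask"], dtype=bool),
            b_masks={k: np.asarray(v, dtype=bool) for k, v in d["b_masks"].items()},
            c_mask=np.asarray(d["c_mask"], dtype=bool),
        )


class DCMParams:
    """Numeric parameters of one subject's DCM, as a flat vector plus spec.

    The vector follows :meth:`DCMSpec.parameter_names`.  Convenience
    accessors materialize the A/B/C matrices; entries outside the spec
    masks do not exist in the vector.
    """

    def __init__(self, spec: DCMSpec, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (spec.n_parameters(),):
            raise ValueError(
                f"parameter vector has shape {values.shape}, expected "
                f"({spec.n_parameters()},)")
        self.spec = spec
        self.values = values
        self._idx = spec.name_index()

    @classmethod
    def zeros(cls, spec: DCMSpec) -> "DCMParams":
        return cls(spec, np.zeros(spec.n_parameters()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._idx[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[self._idx[name]] = value

    def copy(self) -> "DCMParams":
        return DCMParams(self.spec, self.values.copy())

    # -- matrix views ---------------------------------------------------
    def a_offdiag(self) -> np.ndarray:
        """Baseline off-diagonal connections (Hz); zeros where masked out."""
        n = self.spec.n_regions
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and self.spec.a_mask[i, j]:
                    A[i, j] = self[f"A:{self.spec.regions[j]}->{self.spec.regions[i]}"]
        return A

    def self_log_scaling(self, input_name: str | None = None) -> np.ndarray:
        """Self log-scalings x per region, for A or for one input's B."""
        prefix = "A" if input_name is None else f"B({input_name})"
        out = np.zeros(self.spec.n_regions)
        for r_i, r in enumerate(self.spec.regions):
            nm = f"{prefix}:{r}->{r}"
            if nm in self._idx:
                out[r_i] = self[nm]
        return out

    def b_offdiag(self, input_name: str) -> np.ndarray:
        n = self.spec.n_regions
        B = np.zeros((n, n))
        m = self.spec.b_masks[input_name]
        for i in range(n):
            for j in range(n):
                if i != j and m[i, j]:
                    B[i, j] = self[f"B({input_name}):{self.spec.regions[j]}->{self.spec.regions[i]}"]
        return B

    def c_matrix(self) -> np.ndarray:
        n = self.spec.n_regions
        C = np.zeros((n, len(self.spec.inputs)))
        for k, inp in enumerate(self.spec.inputs):
            for i in range(n):
                if self.spec.c_mask[i, k]:
                    C[i, k] = self[f"C({inp}):{self.spec.regions[i]}"]
        return C

    def transit_log(self) -> np.ndarray:
        return np.array([self[f"transit:{r}"] for r in self.spec.regions])

    def efficacy_log(self) -> np.ndarray:
        return np.array([self[f"efficacy:{r}"] for r in self.spec.regions])

    def effective_connectivity(self, u: np.ndarray) -> np.ndarray:
        """Jacobian of the neural state equation at input values ``u``.

        Off-diagonals combine additively (A plus active B terms scaled by
        ``u``); the diagonal is ``-0.5 * exp(x_A + sum_j u_j x_Bj)``.
        """
        u = np.asarray(u, dtype=float)
        if u.shape != (len(self.spec.inputs),):
            raise ValueError(f"input vector has shape {u.shape}, expected "
                             f"({len(self.spec.inputs)},)")
        J = self.a_offdiag().copy()
        x = self.self_log_scaling(None).copy()
        for k, inp in enumerate(self.spec.inputs):
            J += u[k] * self.b_offdiag(inp)
            x = x + u[k] * self.self_log_scaling(inp)
        J[np.diag_indices_from(J)] = -0.5 * np.exp(x)
        return J

    def to_json(self) -> str:
        return json.dumps(
            {"names": self.spec.parameter_names(),
             "values": self.values.tolist()}, indent=1)

    @classmethod
    def from_json(cls, spec: DCMSpec, text: str) -> "DCMParams":
        d = json.loads(text)
        if d["names"] != spec.parameter_names():
            raise ValueError("parameter names do not match the spec layout")
        return cls(spec, np.asarray(d["values"], dtype=float))
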