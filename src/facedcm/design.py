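"""Block-design stimulus timing and box-car input regressors.

The experiment alternates 14.5 s stimulus blocks (faces, houses or
scrambled images) with 14.5 s fixation baselines; nine blocks per
category at TR 1.45 s give a run of roughly 13 minutes.  Two inputs drive
the network model: "visual" (any stimulus block) and "faces" (face blocks
only), represented as 0/1 box-cars at microtime resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("faces", "houses", "scrambled")


@dataclass(frozen=True)
class StimulusDesign:
    """Timing of one run plus its input regressors.

    Attributes
    ----------
    tr_s : float
        Repetition time (s).
    microtime_bins : int
        Microtime bins per scan used for neural integration.
    n_scans : int
        Number of volumes in the run.
    onsets : dict of str -> ndarray
        Block onsets (s) per condition.
    block_s : float
        Block duration (s).
    input_names : tuple of str
        Names of the model inputs, ``("visual", "faces")``.
    """

    tr_s: float
    microtime_bins: int
    n_scans: int
    onsets: dict
    block_s: float
    input_names: tuple = ("visual", "faces")
    conditions: tuple = CONDITIONS

    @property
    def dt(self) -> float:
        """Microtime step (s)."""
        return self.tr_s / self.microtime_bins

    @property
    def duration_s(self) -> float:
        return self.n_scans * self.tr_s

    def to_json(self) -> str:
        import json

        return json.dumps({
            "tr_s": self.tr_s, "microtime_bins": self.microtime_bins,
            "n_scans": self.n_scans, "block_s": self.block_s,
            "input_names": list(self.input_names),
            "conditions": list(self.conditions),
            "onsets": {c: np.asarray(v).tolist()
                       for c, v in self.onsets.items()}}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StimulusDesign":
        import json

        d = json.loads(text)
        return cls(tr_s=d["tr_s"], microtime_bins=d["microtime_bins"],
                   n_scans=d["n_scans"], block_s=d["block_s"],
                   input_names=tuple(d["input_names"]),
                   conditions=tuple(d["conditions"]),
                   onsets={c: np.asarray(v, dtype=float)
                           for c, v in d["onsets"].items()})

    def regressors(self, microtime_bins: int | None = None) -> np.ndarray:
        """Box-car input matrix, shape ``(n_scans * bins, n_inputs)``.

        The "visual" regressor is 1 during any stimulus block, the
        "faces" regressor only during face blocks, so the face box-cars
        are a subset of the visual ones.
        """
        bins = self.microtime_bins if microtime_bins is None else int(microtime_bins)
        dt = self.tr_s / bins
        t = np.arange(self.n_scans * bins) * dt
        u = np.zeros((t.size, len(self.input_names)))
        for cond, ons in self.onsets.items():
            for onset in np.atleast_1d(ons):
                box = (t >= onset) & (t < onset + self.block_s)
                u[box, 0] = 1.0
                if cond == "faces":
                    u[box, 1] = 1.0
        return u


def build_stimulus_design(n_blocks_per_condition: int = 9,
                          block_s: float = 14.5,
                          isi_s: float = 14.5,
                          tr_s: float = 1.45,
                          microtime_bins: int = 16,
                          rng=None,
                          conditions: tuple = CONDITIONS) -> StimulusDesign:
    """Build a pseudo-randomized block design.

    Stimulus blocks are separated by fixation baselines of ``isi_s``
    seconds.  Condition order is a pseudo-random permutation within each
    cycle of ``len(conditions)`` consecutive stimulus blocks, which
    balances conditions over the run.

    Parameters
    ----------
    n_blocks_per_condition : int
        Blocks per stimulus category (default 9).
    block_s, isi_s : float
        Stimulus-block and baseline durations (s); must be positive.
    tr_s : float
        Repetition time (s).
    microtime_bins : int
        Microtime bins per scan for neural integration.
    rng : int, numpy Generator or None
        Seeds the condition order.
    """
    if block_s <= 0 or isi_s <= 0 or tr_s <= 0:
        raise ValueError("block, baseline and TR durations must be positive")
    if n_blocks_per_condition < 1:
        raise ValueError("need at least one block per condition")
    if microtime_bins < 1:
        raise ValueError("microtime_bins must be >= 1")
    rng = np.random.default_rng(rng)

    order = []
    for _ in range(n_blocks_per_condition):
        order.extend(rng.permutation(len(conditions)))
    onsets = {c: [] for c in conditions}
    t = 0.0
    for cond_i in order:
        onsets[conditions[cond_i]].append(t)
        t += block_s + isi_s
    total_s = t  # trailing baseline included
    n_scans = int(round(total_s / tr_s))
    return StimulusDesign(
        tr_s=tr_s, microtime_bins=microtime_bins, n_scans=n_scans,
        onsets={c: np.asarray(v, dtype=float) for c, v in onsets.items()},
        block_s=block_s, conditions=tuple(conditions))
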