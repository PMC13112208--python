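"""Factorial hypothesis space over face-specific modulations.

Candidate models differ in which face modulations they allow, crossed over
three factors: hemisphere (LEFT / RIGHT / BOTH), region (OFA / FFA / BOTH)
and connection type (INPUT = forward EVC projections, SELF =
self-connections, BASE = intra- plus interhemispheric OFA/FFA connections,
ALL = their union), giving 3 x 3 x 4 = 36 models plus a null model with no
face modulations.  A face-modulation parameter belongs to a model iff the
TARGET region and TARGET hemisphere of its connection match the model's
levels (inferred convention; emitted in reports).  Visual self-modulations
are always on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DCMSpec

HEMI_LEVELS = ("BOTH", "LEFT", "RIGHT")
REGION_LEVELS = ("BOTH", "OFA", "FFA")
TYPE_LEVELS = ("ALL", "INPUT", "SELF", "BASE")


def _classify(name: str) -> dict | None:
    """Target hemisphere/region and connection type of a B parameter."""
    if not name.startswith("B("):
        return None
    inp, arrow = name[2:].split("):")
    src, tgt = arrow.split("->")
    hemi = "LEFT" if tgt.startswith("l") else "RIGHT"
    region = tgt[1:]
    if src == tgt:
        ctype = "SELF"
    elif src[1:] == "EVC":
        ctype = "INPUT"
    else:
        ctype = "BASE"
    return {"input": inp, "src": src, "tgt": tgt,
            "hemisphere": hemi, "region": region, "type": ctype}


@dataclass(frozen=True)
class CandidateModel:
    """One factorial model: a mask over the modulatory parameter names."""

    name: str
    hemisphere: str | None
    region: str | None
    ctype: str | None
    mask: np.ndarray          # over the modulatory parameter list
    is_null: bool = False

    def family(self, factor: str) -> str:
        if self.is_null:
            return "NONE"
        return {"hemisphere": self.hemisphere, "region": self.region,
                "type": self.ctype}[factor]


@dataclass
class ModelSpace:
    """Ordered candidate models over the modulatory parameters."""

    parameter_names: list
    models: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i) -> CandidateModel:
        return self.models[i]

    def by_levels(self, hemisphere: str, region: str, ctype: str) -> CandidateModel:
        for m in self.models:
            if (m.hemisphere, m.region, m.ctype) == (hemisphere, region, ctype):
                return m
        raise KeyError((hemisphere, region, ctype))

    @property
    def null_index(self) -> int:
        return next(i for i, m in enumerate(self.models) if m.is_null)

    def families(self, factor: str) -> dict:
        """Partition of model indices into families for one factor."""
        if factor not in ("hemisphere", "region", "type"):
            raise ValueError(f"unknown factor {factor!r}")
        fams: dict = {}
        for i, m in enumerate(self.models):
            fams.setdefault(m.family(factor), []).append(i)
        return fams

    def membership_table(self):
        """Long-format mapping of models to their active face parameters."""
        import pandas as pd

        rows = []
        for i, m in enumerate(self.models):
            for nm, on in zip(self.parameter_names, m.mask):
                rows.append({"model": i + 1, "name": m.name,
                             "hemisphere": m.hemisphere, "region": m.region,
                             "type": m.ctype, "parameter": nm, "on": bool(on)})
        return pd.DataFrame(rows)


def build_factorial_space(spec: DCMSpec) -> ModelSpace:
    """The 36 factorial models plus the null model, full model first.

    Enumeration is lexicographic over (type, region, hemisphere) with level
    orders (ALL, INPUT, SELF, BASE), (BOTH, OFA, FFA), (BOTH, LEFT, RIGHT),
    so model 1 is the full model (ALL, BOTH, BOTH); the null model is last.
    """
    names = spec.modulatory_names()
    info = [_classify(nm) for nm in names]
    if not any(d and d["type"] == "INPUT" for d in info):
        raise ValueError("spec lacks the EVC forward modulations of the "
                         "6-region face network")
    always_on = np.array([d["input"] != "faces" for d in info])

    def mask_for(hemi, region, ctype):
        m = always_on.copy()
        for j, d in enumerate(info):
            if d["input"] != "faces":
                continue
            ok_h = hemi == "BOTH" or d["hemisphere"] == hemi
            ok_r = region == "BOTH" or d["region"] == region
            ok_t = ctype == "ALL" or d["type"] == ctype
            m[j] = ok_h and ok_r and ok_t
        return m

    models = []
    for ctype in TYPE_LEVELS:
        for region in REGION_LEVELS:
            for hemi in HEMI_LEVELS:
                models.append(CandidateModel(
                    name=f"{ctype}/{region}/{hemi}", hemisphere=hemi,
                    region=region, ctype=ctype,
                    mask=mask_for(hemi, region, ctype)))
    models.append(CandidateModel(name="null", hemisphere=None, region=None,
                                 ctype=None, mask=always_on.copy(),
                                 is_null=True))
    return ModelSpace(parameter_names=names, models=models)
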