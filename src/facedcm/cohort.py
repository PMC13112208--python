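"""Synthetic cohorts with planted group-level connectivity effects.

Every downstream stage is testable without access to human data: the
generator draws per-subject DCM parameters from the group-level GLM
theta_i = beta' x_i + eps_i, simulates region-level BOLD through the
forward model with additive Gaussian observation noise, and can emulate
the statistic-map inputs of the laterality module.

The planted default effects mirror the study conditions the pipeline is
meant to recover: a commonality effect on all face modulations, an effect
of FFA lateralization on the left-OFA self-modulation, and opposite-signed
effects of OFA lateralization on the two interhemispheric FFA connections.
Nuisance covariates (handedness, age, gender) carry no true effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SubjectTimeSeries
from .design import StimulusDesign, build_stimulus_design
from .forward import ForwardModel
from .laterality import ROIMask, StatMap
from .network import DCMParams, DCMSpec
from .peb import REGRESSORS, GroupDesign
from .vl import PosteriorDensity

# default generator settings (the study conditions; see docs/methods.md)
NOISE_SD = 1.0            # BOLD observation noise, percent-signal units
BETWEEN_SD = 0.1          # between-subject SD, between-region parameters
BETWEEN_SD_SELF = 0.05    # between-subject SD, self log-scalings
EFFECT_COMMON_SELF = 0.5   # commonality on face self-modulations
EFFECT_COMMON_CROSS = 0.1  # commonality on face between-region modulations
EFFECT_LIFFA_LOFA_SELF = -2.0
EFFECT_LIOFA_LFFA_RFFA = -1.0
EFFECT_LIOFA_RFFA_LFFA = 1.0
A_FORWARD = 0.2           # EVC -> ipsilateral OFA/FFA
A_INTRA = 0.10            # OFA <-> FFA within hemisphere
A_INTER = 0.05            # homotopic interhemispheric
B_VISUAL_SELF = 0.15
C_VISUAL = 1.2
STABILITY_MARGIN = -0.01  # required max real eigenvalue of the neural Jacobian


@dataclass
class GroundTruth:
    """Group GLM that generates a cohort: design, effects and noise levels."""

    X: np.ndarray                  # subjects x regressors, col 0 all ones
    regressor_names: tuple
    beta: np.ndarray               # regressors x free parameters
    between_sd: np.ndarray         # per free parameter
    noise_sd: float
    seed: int
    parameter_names: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.between_sd = np.asarray(self.between_sd, dtype=float)
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be all ones")
        if self.X.shape[0] > 1 and np.abs(self.X[:, 1:].mean(axis=0)).max() > 1e-9:
            raise ValueError("covariate columns must be mean-centered")
        if self.beta.shape[0] != self.X.shape[1]:
            raise ValueError("beta rows must align with design regressors")

    def nonzero_covariate_cells(self) -> list:
        """(regressor, parameter) pairs with planted non-zero effects."""
        out = []
        for j, reg in enumerate(self.regressor_names):
            for p, nm in enumerate(self.parameter_names):
                if j > 0 and self.beta[j, p] != 0:
                    out.append((reg, nm))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "regressor_names": list(self.regressor_names),
            "parameter_names": self.parameter_names,
            "beta": self.beta.tolist(),
            "between_sd": self.between_sd.tolist(),
            "noise_sd": self.noise_sd, "seed": self.seed,
            "X": self.X.tolist()}, indent=1)


def sample_covariates(n_subjects: int, rng=None) -> pd.DataFrame:
    """Realistic covariate table: mostly left-lateralized LIs, a
    right-handed majority, a young adult age range."""
    rng = np.random.default_rng(rng)
    li_ffa = np.clip(rng.normal(0.35, 0.30, n_subjects), -1, 1)
    li_ofa = np.clip(rng.normal(0.25, 0.35, n_subjects), -1, 1)
    right_handed = rng.random(n_subjects) < 0.9
    handed = np.where(right_handed, rng.normal(0.8, 0.15, n_subjects),
                      rng.normal(-0.5, 0.3, n_subjects))
    handed = np.clip(handed, -1, 1)
    age = np.clip(rng.normal(24.0, 4.0, n_subjects), 18, 60)
    # balanced genders (permuted), so small cohorts keep a full-rank design
    gender = rng.permutation(np.resize([0.5, -0.5], n_subjects))
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
        "li_ffa": li_ffa, "li_ofa": li_ofa, "handedness": handed,
        "age": age, "gender": gender})


def default_beta(spec: DCMSpec,
                 regressor_names=REGRESSORS) -> np.ndarray:
    """Ground-truth effect matrix (regressors x free parameters)."""
    names = spec.parameter_names()
    idx = {nm: i for i, nm in enumerate(names)}
    beta = np.zeros((len(regressor_names), len(names)))
    common = beta[0]
    for nm in names:
        if nm.startswith("A:"):
            src, tgt = nm[2:].split("->")
            if src == tgt:
                continue
            if src.endswith("EVC"):
                common[idx[nm]] = A_FORWARD
            elif src[0] == tgt[0]:
                common[idx[nm]] = A_INTRA
            else:
                common[idx[nm]] = A_INTER
        elif nm.startswith("B(visual)"):
            common[idx[nm]] = B_VISUAL_SELF
        elif nm.startswith("B(faces)"):
            src, tgt = nm.split(":")[1].split("->")
            common[idx[nm]] = (EFFECT_COMMON_SELF if src == tgt
                               else EFFECT_COMMON_CROSS)
        elif nm.startswith("C("):
            common[idx[nm]] = C_VISUAL
    r = list(regressor_names)
    beta[r.index("LI_FFA"), idx["B(faces):lOFA->lOFA"]] = EFFECT_LIFFA_LOFA_SELF
    beta[r.index("LI_OFA"), idx["B(faces):lFFA->rFFA"]] = EFFECT_LIOFA_LFFA_RFFA
    beta[r.index("LI_OFA"), idx["B(faces):rFFA->lFFA"]] = EFFECT_LIOFA_RFFA_LFFA
    return beta


def default_between_sd(spec: DCMSpec, sd: float = BETWEEN_SD,
                       sd_self: float = BETWEEN_SD_SELF) -> np.ndarray:
    """Between-subject SDs: ``sd`` on between-region parameters, a smaller
    ``sd_self`` on self log-scalings, hemodynamics shared across subjects."""
    out = []
    for nm in spec.parameter_names():
        if nm.startswith(("transit:", "efficacy:")):
            out.append(0.0)
        elif "->" in nm:
            src, tgt = nm.split(":")[1].split("->")
            out.append(sd_self if src == tgt else sd)
        else:
            out.append(sd)
    return np.array(out)


def is_stable(params: DCMParams, margin: float = STABILITY_MARGIN,
              min_steady_z: float = -0.29) -> bool:
    """Whether the system is well posed under every input condition.

    Checks (i) the largest real eigenvalue of the effective connectivity
    at rest, during visual stimulation and during face blocks, and
    (ii) that the steady-state neural activity keeps the balloon model's
    blood flow positive (f* = 1 + z*/gamma > 0 requires z* > -0.32 Hz at
    the default autoregulation; sustained stronger inhibition drives flow
    to zero and has no physical interpretation).
    """
    n_inputs = len(params.spec.inputs)
    C = params.c_matrix()
    for u in (np.zeros(n_inputs),
              np.eye(n_inputs)[0],
              np.ones(n_inputs)):
        J = params.effective_connectivity(u)
        if np.linalg.eigvals(J).real.max() > margin:
            return False
        z_ss = np.linalg.solve(J, -C @ u)
        if z_ss.min() < min_steady_z:
            return False
    return True


def make_ground_truth(spec: DCMSpec, covariates: pd.DataFrame, seed: int,
                      noise_sd: float = NOISE_SD,
                      between_sd: float = BETWEEN_SD,
                      beta: np.ndarray | None = None) -> GroundTruth:
    design = GroupDesign.from_covariates(covariates)
    return GroundTruth(
        X=design.X, regressor_names=design.names,
        beta=default_beta(spec) if beta is None else beta,
        between_sd=default_between_sd(spec, between_sd),
        noise_sd=noise_sd, seed=int(seed),
        parameter_names=spec.parameter_names())


def sample_group_parameters(gt: GroundTruth, spec: DCMSpec,
                            rng=None) -> list:
    """Per-subject DCM parameters theta_i = (X beta)_i + Gaussian deviate."""
    if gt.beta.shape[1] != spec.n_parameters():
        raise ValueError(
            f"beta has {gt.beta.shape[1]} parameter columns, spec has "
            f"{spec.n_parameters()}")
    rng = np.random.default_rng(gt.seed if rng is None else rng)
    mean = gt.X @ gt.beta
    eps = rng.normal(size=mean.shape) * gt.between_sd[None, :]
    return [DCMParams(spec, mean[i] + eps[i]) for i in range(mean.shape[0])]


def simulate_subject_bold(spec: DCMSpec, params: DCMParams,
                          design: StimulusDesign, noise_sd: float = NOISE_SD,
                          rng=None, subject_id: str = "sub-001",
                          forward: ForwardModel | None = None) -> SubjectTimeSeries:
    """Predicted BOLD plus i.i.d. Gaussian noise, mean-centered per region."""
    fm = forward if forward is not None else ForwardModel(spec, design)
    rng = np.random.default_rng(rng)
    bold = fm.predict(params, center=False)
    bold = bold + rng.normal(0.0, noise_sd, size=bold.shape)
    bold = bold - bold.mean(axis=0, keepdims=True)
    return SubjectTimeSeries(subject_id=subject_id, regions=spec.regions,
                             bold=bold, tr_s=design.tr_s)


@dataclass
class Cohort:
    """A complete synthetic data set: covariates, truth, series."""

    spec: DCMSpec
    design: StimulusDesign
    covariates: pd.DataFrame
    ground_truth: GroundTruth
    subject_params: list
    timeseries: list
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.timeseries)

    def group_design(self) -> GroupDesign:
        return GroupDesign.from_covariates(self.covariates)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        (out / "ground_truth.json").write_text(self.ground_truth.to_json())
        (out / "spec.json").write_text(self.spec.to_json())
        (out / "design.json").write_text(self.design.to_json())
        for ts in self.timeseries:
            ts.save(out / f"timeseries_{ts.subject_id}.h5")


def simulate_cohort(n_subjects: int = 30, seed: int = 0,
                    spec: DCMSpec | None = None,
                    design: StimulusDesign | None = None,
                    noise_sd: float = NOISE_SD,
                    between_sd: float = BETWEEN_SD,
                    beta: np.ndarray | None = None) -> Cohort:
    """Generate a full cohort under the default study conditions.

    All randomness derives from ``seed``; the same seed reproduces the
    cohort bit-for-bit.
    """
    spec = spec or DCMSpec.face_network()
    root = np.random.SeedSequence(seed)
    s_design, s_cov, s_params, s_noise = root.spawn(4)
    design = design or build_stimulus_design(rng=np.random.default_rng(s_design))
    covariates = sample_covariates(n_subjects, np.random.default_rng(s_cov))
    gt = make_ground_truth(spec, covariates, seed, noise_sd, between_sd, beta)
    rng_params = np.random.default_rng(s_params)
    params = sample_group_parameters(gt, spec, rng_params)
    # redraw the between-subject deviate of the rare subject whose sampled
    # dynamics are unstable (the population model is truncated to the
    # stable regime; see docs/methods.md)
    for i, p in enumerate(params):
        tries = 0
        while not is_stable(p):
            mean_i = gt.X[i] @ gt.beta
            p = DCMParams(spec, mean_i
                          + rng_params.normal(size=mean_i.shape) * gt.between_sd)
            tries += 1
            if tries > 200:
                raise RuntimeError("could not sample stable dynamics; "
                                   "ground-truth effects are too strong")
        params[i] = p
    fm = ForwardModel(spec, design)
    noise_rngs = [np.random.default_rng(s) for s in s_noise.spawn(n_subjects)]
    series = [simulate_subject_bold(spec, params[i], design, noise_sd,
                                    noise_rngs[i],
                                    subject_id=f"sub-{i + 1:03d}", forward=fm)
              for i in range(n_subjects)]
    return Cohort(spec=spec, design=design, covariates=covariates,
                  ground_truth=gt, subject_params=params, timeseries=series,
                  seed=seed)


def simulate_subject_posteriors(gt: GroundTruth, spec: DCMSpec,
                                obs_sd: float = 0.15, rng=None,
                                field_names=None) -> list:
    """Emulated subject-level posteriors for group-level recovery studies.

    Bypasses BOLD simulation and inversion: each subject's posterior mean
    is the true parameter subvector plus measurement noise of scale
    ``obs_sd``, with an isotropic posterior covariance of the same scale.
    This isolates the group-level machinery (PEB, BMR, search) from the
    cost of subject-level inversion; end-to-end behaviour including
    inversion is exercised by the pipeline at smaller cohort sizes.
    """
    rng = np.random.default_rng(rng)
    params = sample_group_parameters(gt, spec, rng)
    names = field_names or spec.modulatory_names()
    idx = [spec.parameter_names().index(nm) for nm in names]
    k = len(idx)
    out = []
    for i, p in enumerate(params):
        mean = p.values[idx] + rng.normal(0.0, obs_sd, size=k)
        cov = obs_sd ** 2 * np.eye(k)
        out.append(PosteriorDensity(mean=mean, cov=cov, free_energy=0.0,
                                    noise_log_precision=np.zeros(1),
                                    names=list(names)))
    return out


def generate_stat_map_pair(target_li: float, voxels_per_roi: int = 150,
                           t_scale: float = 4.0, rng=None,
                           shape=(24, 24, 12), voxel_mm: float = 2.0):
    """Synthetic t-map with mirrored ROIs whose suprathreshold t mass
    approximates a target lateralization index.

    The two ROIs hold ``voxels_per_roi`` voxels each; the count of active
    (suprathreshold-scale) voxels is split in proportion (1 + LI) : (1 - LI)
    while active values are i.i.d. across hemispheres, so the expected
    mass ratio, and hence the LI, is approximately threshold-invariant.

    Returns ``(StatMap, left ROIMask, right ROIMask)``.
    """
    target_li = float(target_li)
    if not -1.0 <= target_li <= 1.0:
        raise ValueError("target LI must lie in [-1, 1]")
    if voxels_per_roi < 20:
        raise ValueError("need at least 20 voxels per ROI")
    rng = np.random.default_rng(rng)
    nx, ny, nz = shape
    if nx % 2:
        raise ValueError("x extent must be even (hemispheric symmetry)")
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0  # centered grid

    data = rng.normal(0.0, 0.1, size=shape)

    # mirrored boxes, one per hemisphere
    box = int(np.ceil(voxels_per_roi ** (1 / 3)))
    while box ** 2 * min(box, nz) < voxels_per_roi:
        box += 1
    x0_r = nx // 2 + 2
    y0 = (ny - box) // 2
    z0 = (nz - min(box, nz)) // 2
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    flat = []
    for dx in range(box):
        for dy in range(box):
            for dz in range(min(box, nz)):
                flat.append((dx, dy, dz))
    flat = flat[:voxels_per_roi]
    for dx, dy, dz in flat:
        right[x0_r + dx, y0 + dy, z0 + dz] = True
        left[nx - 1 - (x0_r + dx), y0 + dy, z0 + dz] = True

    # choose active counts so that the LI implied by the bootstrap resample
    # sizes ceil(k * n) matches the target (calibrates away the rounding
    # bias of small resamples; k = 0.25 is the default resampling ratio)
    k_cal = 0.25
    best, best_err = None, np.inf
    for n_l in range(voxels_per_roi + 1):
        n_r = voxels_per_roi - n_l
        c_l = np.ceil(k_cal * n_l)
        c_r = np.ceil(k_cal * n_r)
        if c_l + c_r == 0:
            continue
        err = abs((c_l - c_r) / (c_l + c_r) - target_li)
        if err < best_err:
            best, best_err = n_l, err
    n_active_l = int(best)
    n_active_r = voxels_per_roi - n_active_l
    # active t-values concentrate near t_scale so the left:right count ratio
    # (and hence the LI) is approximately threshold-invariant
    active_vals = lambda n: np.clip(  # noqa: E731
        t_scale * (1.0 + 0.04 * rng.normal(size=n)), 0.5 * t_scale, None)
    li_idx = np.flatnonzero(left.ravel(order="C"))
    ri_idx = np.flatnonzero(right.ravel(order="C"))
    rng.shuffle(li_idx)
    rng.shuffle(ri_idx)
    d = data.ravel()
    d[li_idx[:n_active_l]] = active_vals(n_active_l)
    d[ri_idx[:n_active_r]] = active_vals(n_active_r)
    data = d.reshape(shape)

    smap = StatMap(data, affine, label=f"synthetic LI={target_li:+.2f}")
    l_center = smap.world_coords(np.argwhere(left).mean(axis=0))[0]
    r_center = smap.world_coords(np.argwhere(right).mean(axis=0))[0]
    return (smap,
            ROIMask(left, "left", l_center, "box"),
            ROIMask(right, "right", r_center, "box"))
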