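"""Hemispheric lateralization indices from statistic maps.

The lateralization index LI = (A_L - A_R) / (A_L + A_R) compares activity
between homologous left/right regions of interest; positive values mean
left-hemispheric dominance, |LI| <= 0.2 is conventionally called bilateral.
Activity A is the sum of suprathreshold t-values within the ROI.

The bootstrap procedure resamples suprathreshold voxels within each
hemisphere (ratio k, with replacement), forms all pairwise LI combinations
of the resampled activity masses, and keeps the trimmed mean of the central
fraction; this is repeated over a grid of regularly spaced t-thresholds and
combined into an overall LI weighted by threshold (more conservative
thresholds count more).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DOMINANCE_CUTOFF = 0.2


class UndefinedLIError(ValueError):
    """No activity mass available to form a lateralization index."""


@dataclass
class StatMap:
    """A 3-D t-statistic volume with its world-space affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("statistic map must be 3-D")

    @classmethod
    def from_nifti(cls, path, label: str = "") -> "StatMap":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine, label)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(path))

    def same_grid(self, other: "StatMap") -> bool:
        return (self.data.shape == other.data.shape
                and np.allclose(self.affine, other.affine))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ hom.T).T[:, :3]


@dataclass
class ROIMask:
    """Boolean voxel mask tagged with its hemisphere and center."""

    mask: np.ndarray
    hemisphere: str
    center_mm: np.ndarray = None
    shape: str = "box"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.center_mm is not None:
            self.center_mm = np.asarray(self.center_mm, dtype=float)
            x = self.center_mm[0]
            if (self.hemisphere == "left") != (x < 0):
                raise ValueError("hemisphere tag inconsistent with the world "
                                 "x-sign of the center (negative x = left)")

    def values(self, stat_map: StatMap) -> np.ndarray:
        return stat_map.data[self.mask]


def conjunction_map(map1: StatMap, map2: StatMap) -> StatMap:
    """Voxelwise minimum of two t-maps: a voxel survives only if it is
    significant in both contrasts."""
    if not map1.same_grid(map2):
        raise ValueError("conjunction requires identical grids")
    return StatMap(np.minimum(map1.data, map2.data), map1.affine,
                   label=f"min({map1.label},{map2.label})")


def compute_li(a_left: float, a_right: float) -> float:
    """(A_L - A_R) / (A_L + A_R), in [-1, 1]; positive = left dominant."""
    a_left = float(a_left)
    a_right = float(a_right)
    if a_left < 0 or a_right < 0:
        raise ValueError("activity masses must be non-negative")
    denom = a_left + a_right
    if denom <= 0:
        raise UndefinedLIError("zero total activity mass")
    return (a_left - a_right) / denom


def classify_dominance(li: float) -> str:
    """Dominance class by the conventional +/-0.2 rule (boundaries are
    bilateral)."""
    if li > DOMINANCE_CUTOFF:
        return "left"
    if li < -DOMINANCE_CUTOFF:
        return "right"
    return "bilateral"


def select_subject_roi(subject_map: StatMap, anat_box: ROIMask,
                       group_peak_mm, t_min: float = 3.1,
                       group_peak_t: float | None = None) -> np.ndarray:
    """Subject-specific ROI center: the qualifying local maximum nearest
    to the group peak.

    Local maxima of the subject map are eligible if they (i) fall within
    the anatomical box, (ii) reach ``t_min`` and (iii) are at least as
    high as the map value at the group peak coordinate.  If none
    qualifies, the group peak itself is returned.
    """
    group_peak_mm = np.asarray(group_peak_mm, dtype=float)
    inv = np.linalg.inv(subject_map.affine)
    ijk = (inv @ np.append(group_peak_mm, 1.0))[:3]
    ijk = np.clip(np.round(ijk).astype(int), 0,
                  np.array(subject_map.data.shape) - 1)
    if group_peak_t is None:
        group_peak_t = float(subject_map.data[tuple(ijk)])

    data = subject_map.data
    local_max = (data == ndimage.maximum_filter(data, size=3))
    eligible = local_max & anat_box.mask & (data >= t_min) & (data >= group_peak_t)
    coords = np.argwhere(eligible)
    if coords.size == 0:
        return group_peak_mm
    world = subject_map.world_coords(coords)
    dists = np.linalg.norm(world - group_peak_mm, axis=1)
    return world[int(np.argmin(dists))]


def _resample_sums(vals: np.ndarray, k: float, n_samples: int,
                   base_seed: int) -> np.ndarray:
    """Bootstrap sums of one hemisphere's suprathreshold values.

    The resampling indices are seeded from the side's voxel count (plus
    the caller's seed), not from which argument slot the hemisphere
    occupies.  Swapping the left/right inputs therefore reproduces the
    same resamples per side (negating every pairwise LI exactly), and
    scaling all values by a common factor scales the sums exactly.
    """
    v = np.sort(np.asarray(vals, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, v.size]))
    n = int(np.ceil(k * v.size))
    idx = rng.integers(0, v.size, size=(n_samples, n))
    return v[idx].sum(axis=1)


def bootstrap_li_samples(left_vals, right_vals, k: float = 0.25,
                         n_samples: int = 100, rng=None) -> np.ndarray:
    """All pairwise LI combinations of bootstrap-resampled activity masses.

    Draws ``n_samples`` resamples of size ``ceil(k * N)`` (with
    replacement) per hemisphere, sums the t-values of each resample, and
    returns the ``n_samples ** 2`` pairwise LIs.
    """
    left_vals = np.asarray(left_vals, dtype=float)
    right_vals = np.asarray(right_vals, dtype=float)
    if left_vals.size == 0 or right_vals.size == 0:
        raise UndefinedLIError("one hemisphere has no suprathreshold voxels")
    if not 0.0 < k <= 1.0:
        raise ValueError("resampling ratio k must be in (0, 1]")
    base = int(np.random.default_rng(rng).integers(0, 2 ** 31))
    sums_l = _resample_sums(left_vals, k, n_samples, base)
    sums_r = _resample_sums(right_vals, k, n_samples, base)
    li = (sums_l[:, None] - sums_r[None, :]) / (sums_l[:, None] + sums_r[None, :])
    return li.ravel()


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean of the central ``trim`` fraction by order statistics."""
    if not 0.0 < trim <= 1.0:
        raise ValueError("trim fraction must be in (0, 1]")
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    drop = int(round(n * (1.0 - trim) / 2.0))
    kept = v[drop:n - drop] if drop > 0 else v
    return float(kept.mean())


def bootstrap_li(left_vals, right_vals, k: float = 0.25,
                 n_samples: int = 100, trim: float = 0.5,
                 rng=None) -> float:
    """Trimmed-mean LI over all pairwise bootstrap combinations."""
    return trimmed_mean(
        bootstrap_li_samples(left_vals, right_vals, k, n_samples, rng), trim)


@dataclass
class LIResult:
    """Threshold-weighted overall LI with per-threshold trajectories."""

    li: float
    thresholds: np.ndarray
    li_per_threshold: np.ndarray
    a_left: np.ndarray
    a_right: np.ndarray
    dominance: str
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "li": self.li, "dominance": self.dominance,
            "thresholds": np.asarray(self.thresholds).tolist(),
            "li_per_threshold": np.asarray(self.li_per_threshold).tolist(),
            "a_left": np.asarray(self.a_left).tolist(),
            "a_right": np.asarray(self.a_right).tolist(),
            "settings": self.settings}, indent=1)

    def plot(self, ax=None):
        """Per-threshold LI trajectory with the overall weighted LI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.thresholds, self.li_per_threshold, "o-",
                label="trimmed-mean LI")
        ax.axhline(self.li, color="k", ls="--",
                   label=f"weighted LI = {self.li:.2f}")
        ax.axhspan(-DOMINANCE_CUTOFF, DOMINANCE_CUTOFF, alpha=0.1, color="gray")
        ax.set_xlabel("t threshold")
        ax.set_ylabel("LI")
        ax.set_ylim(-1.05, 1.05)
        ax.legend()
        return ax


def weighted_li(stat_map: StatMap, left_roi: ROIMask, right_roi: ROIMask,
                n_thresholds: int = 20, k: float = 0.25,
                n_samples: int = 100, trim: float = 0.5,
                rng=None) -> LIResult:
    """Threshold-weighted bootstrap LI for one statistic map.

    Thresholds are ``n_thresholds`` regularly spaced values from just
    above 0 to the smaller of the two ROI maxima; each threshold
    contributes its trimmed-mean bootstrap LI with weight equal to the
    threshold itself, so conservative thresholds weigh more.  Thresholds
    where either ROI is empty are skipped.
    """
    if n_thresholds < 2:
        raise ValueError("need at least two threshold steps")
    if np.any(left_roi.mask & right_roi.mask):
        raise ValueError("left and right ROIs overlap")
    lv = left_roi.values(stat_map)
    rv = right_roi.values(stat_map)
    top = min(lv.max(), rv.max())
    if top <= 0:
        raise UndefinedLIError("no positive t-values in both ROIs")
    thresholds = np.linspace(0.0, top, n_thresholds + 1)[1:]

    seeds = np.random.default_rng(rng).integers(0, 2 ** 31, size=n_thresholds)
    lis, a_l, a_r, used = [], [], [], []
    for t, seed in zip(thresholds, seeds):
        lvals = lv[lv >= t]
        rvals = rv[rv >= t]
        if lvals.size == 0 or rvals.size == 0:
            continue
        lis.append(bootstrap_li(lvals, rvals, k, n_samples, trim, seed))
        a_l.append(float(lvals.sum()))
        a_r.append(float(rvals.sum()))
        used.append(t)
    if not used:
        raise UndefinedLIError("no threshold step with voxels in both ROIs")
    used = np.asarray(used)
    lis = np.asarray(lis)
    overall = float(np.sum(used * lis) / np.sum(used))
    return LIResult(
        li=overall, thresholds=used, li_per_threshold=lis,
        a_left=np.asarray(a_l), a_right=np.asarray(a_r),
        dominance=classify_dominance(overall),
        settings={"n_thresholds": int(n_thresholds), "k": float(k),
                  "n_samples": int(n_samples), "trim": float(trim),
                  "activity_measure": "sum of suprathreshold t-values"})
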