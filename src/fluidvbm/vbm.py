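"""Minimal voxel-based morphometry statistics stage.

Pipeline: Gaussian smoothing (FWHM in mm), relative-threshold masking, a
voxelwise two-group GLM with TIV as nuisance covariate, and thresholding at
either uncorrected p < 0.001 or a family-wise-error level obtained by
max-statistic permutation of the group labels.  Permutation replaces
random-field theory deliberately: it is exact under exchangeability and
needs no smoothness estimate.

``VBMModel`` is the model object (per-subject maps + design); ``fit()``
returns ``VBMResults`` holding the t map, the mask and the thresholds.
The GLM contrast is one-sided control > patient (atrophy direction), so
positive t means less tissue in patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter, label

from .volumes import ScalarVolume, _check_same_shape

GROUP_CONTROL = "control"
GROUP_PATIENT = "patient"


@dataclass
class GroupDesign:
    """Per-subject group labels and TIV covariate for the two-group GLM."""

    subject_ids: list
    group_labels: list
    tiv: np.ndarray

    def __post_init__(self):
        self.subject_ids = list(self.subject_ids)
        self.group_labels = list(self.group_labels)
        self.tiv = np.asarray(self.tiv, dtype=np.float64)
        n = len(self.subject_ids)
        if len(self.group_labels) != n or self.tiv.shape != (n,):
            raise ValueError("design columns must have one entry per subject")
        bad = set(self.group_labels) - {GROUP_CONTROL, GROUP_PATIENT}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for g in (GROUP_CONTROL, GROUP_PATIENT):
            if self.group_labels.count(g) < 2:
                raise ValueError(f"need >= 2 subjects in group {g!r}")
        if np.any(self.tiv <= 0):
            raise ValueError("tiv must be positive for all subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def patient_indicator(self) -> np.ndarray:
        return np.array([g == GROUP_PATIENT for g in self.group_labels], float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroupDesign":
        """Build from a CSV-style table with columns subject_id, group, tiv_mm3."""
        return cls(df["subject_id"].tolist(), df["group"].tolist(),
                   df["tiv_mm3"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "group": self.group_labels,
                             "tiv_mm3": self.tiv})


@dataclass
class StatMap:
    """Voxelwise t map with its mask and threshold metadata.

    t values are defined inside the mask; outside they are 0 and flagged by
    the mask itself.  Zero-variance voxels get t = 0 (flagged in
    ``zero_variance``) so downstream thresholding is total.
    """

    t_values: ScalarVolume
    dof: int
    mask: ScalarVolume
    threshold_used: float = np.nan
    correction: str = "uncorrected"
    zero_variance: np.ndarray | None = None


def smooth_fwhm(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Gaussian smoothing specified as FWHM in mm.

    sigma_voxels = fwhm_mm / (voxel_size * sqrt(8 ln 2)) per axis;
    boundaries are zero-padded (background).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma = fwhm_mm / (vol.voxel_size * math.sqrt(8.0 * math.log(2.0)))
    return vol.with_data(gaussian_filter(vol.data, sigma, mode="constant", cval=0.0))


def relative_threshold_mask(images: list[ScalarVolume],
                            fraction: float) -> ScalarVolume:
    """Intersection mask: every image exceeds fraction x its positive-voxel mean.

    The per-image global value is the mean over strictly positive voxels (an
    SPM-like global proxy); a voxel survives only if it passes in every image.
    """
    if not images:
        raise ValueError("need at least one image")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    first = images[0]
    mask = np.ones(first.shape, bool)
    for img in images:
        _check_same_shape(first.shape, img.shape, "relative_threshold_mask")
        pos = img.data[img.data > 0]
        global_mean = pos.mean() if pos.size else 0.0
        mask &= img.data > fraction * global_mean
    return first.with_data(mask.astype(np.float64))


def _design_matrix(design: GroupDesign):
    """Intercept + patient indicator + centered TIV; drops collinear TIV."""
    n = design.n_subjects
    tiv = design.tiv - design.tiv.mean()
    cols = [np.ones(n), design.patient_indicator, tiv]
    names = ["intercept", "patient", "tiv"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("TIV column is collinear with the design; dropping it",
                      RuntimeWarning, stacklevel=3)
        X = X[:, :2]
        names = names[:2]
    return X, names


def _t_from_data(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized OLS t for the contrast control - patient.

    Y is (n_subjects, n_voxels).  Returns (t, dof, zero_variance_flags).
    """
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    contrast = np.zeros(p)
    contrast[1] = -1.0  # control - patient: atrophy gives positive t
    cvar = float(contrast @ (pinv @ pinv.T) @ contrast)
    var = cvar * sigma2
    # zero-variance voxels: residual variance at round-off scale relative to
    # the data magnitude (identical values across subjects)
    scale = np.maximum((Y ** 2).mean(axis=0), 1.0)
    zero_var = sigma2 <= 1e-14 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (contrast @ beta) / np.sqrt(var)
    t[zero_var] = 0.0
    return t, dof, zero_var


def glm_two_group_t(maps: list[ScalarVolume], design: GroupDesign,
                    mask: ScalarVolume) -> StatMap:
    """Voxelwise two-group t test with TIV nuisance covariate.

    Fits value ~ intercept + group + TIV by OLS at every in-mask voxel and
    returns the t statistic for control - patient.  dof = n - rank(design).
    """
    if len(maps) != design.n_subjects:
        raise ValueError("need exactly one map per subject")
    shape = maps[0].shape
    for m in maps:
        _check_same_shape(shape, m.shape, "glm_two_group_t")
    _check_same_shape(shape, mask.shape, "glm_two_group_t mask")
    in_mask = mask.data > 0
    Y = np.stack([m.data[in_mask] for m in maps])
    X, _ = _design_matrix(design)
    t, dof, zero_var = _t_from_data(Y, X)
    t_vol = np.zeros(shape)
    t_vol[in_mask] = t
    zv = np.zeros(shape, bool)
    zv[in_mask] = zero_var
    return StatMap(t_values=maps[0].with_data(t_vol), dof=dof, mask=mask,
                   zero_variance=zv)


def _n_distinct_assignments(n_control: int, n_patient: int) -> int:
    return math.comb(n_control + n_patient, n_patient)


def permutation_fwe_threshold(maps: list[ScalarVolume], design: GroupDesign,
                              mask: ScalarVolume, n_perm: int = 1000,
                              alpha: float = 0.05, seed: int = 0) -> float:
    """Max-statistic permutation threshold controlling family-wise error.

    Permutes the group labels (the TIV column stays fixed), recomputes the
    maximum in-mask t per permutation, and returns the (1 - alpha) quantile
    of that null distribution (upper order statistic, conservative).  Falls
    back to exact enumeration when fewer distinct label assignments exist
    than permutations requested.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    in_mask = mask.data > 0
    Y = np.stack([m.data[in_mask] for m in maps])
    X, _ = _design_matrix(design)
    n = design.n_subjects
    g = design.patient_indicator
    n_pat = int(g.sum())

    n_exact = _n_distinct_assignments(n - n_pat, n_pat)
    max_ts = []
    if n_exact <= n_perm:
        from itertools import combinations
        for pat_idx in combinations(range(n), n_pat):
            Xp = X.copy()
            Xp[:, 1] = 0.0
            Xp[list(pat_idx), 1] = 1.0
            t, _, _ = _t_from_data(Y, Xp)
            max_ts.append(t.max())
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, 1] = g[perm]
            t, _, _ = _t_from_data(Y, Xp)
            max_ts.append(t.max())
    max_ts = np.asarray(max_ts)
    return float(np.quantile(max_ts, 1.0 - alpha, method="higher"))


def threshold_map(stat: StatMap, mode: str = "uncorrected_p001",
                  extent_k: int = 0,
                  fwe_threshold: float | None = None) -> ScalarVolume:
    """Binary suprathreshold map at p_unc < 0.001 or a permutation FWE level.

    ``extent_k`` removes connected clusters smaller than k voxels
    (6-connectivity); k = 0 keeps everything, down to single voxels.
    For mode "fwe05_permutation" pass the threshold from
    :func:`permutation_fwe_threshold`.
    """
    if mode == "uncorrected_p001":
        thresh = float(stats.t.ppf(1.0 - 0.001, stat.dof))
    elif mode == "fwe05_permutation":
        if fwe_threshold is None:
            raise ValueError("fwe mode needs fwe_threshold from permutation")
        thresh = float(fwe_threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sig = (stat.t_values.data > thresh) & (stat.mask.data > 0)
    if extent_k > 0 and sig.any():
        labels, n_lab = label(sig)
        counts = np.bincount(labels.ravel())
        keep = np.zeros_like(counts, bool)
        keep[1:] = counts[1:] >= extent_k
        sig = keep[labels]
    stat.threshold_used = thresh
    stat.correction = ("uncorrected" if mode == "uncorrected_p001"
                       else "permutation_fwe")
    return stat.t_values.with_data(sig.astype(np.float64))


@dataclass
class VBMResults:
    """Fitted VBM stage: smoothed maps' t statistics and thresholded maps."""

    stat_map: StatMap
    significant: ScalarVolume
    mode: str
    fwe_threshold: float | None = None
    model: "VBMModel | None" = None

    def summary(self) -> str:
        n_sig = int(self.significant.data.sum())
        n_mask = int(self.stat_map.mask.data.sum())
        lines = [
            "VBM two-group analysis",
            "----------------------",
            f"degrees of freedom    : {self.stat_map.dof}",
            f"in-mask voxels        : {n_mask}",
            f"threshold mode        : {self.mode}",
            f"t threshold           : {self.stat_map.threshold_used:.3f}",
            f"suprathreshold voxels : {n_sig}",
            f"max t (in mask)       : {self.stat_map.t_values.data.max():.3f}",
        ]
        return "\n".join(lines)


class VBMModel:
    """Two-group VBM comparison of modulated gray-matter maps.

    Parameters
    ----------
    maps : list of ScalarVolume
        One (typically warped + modulated) probability map per subject.
    design : GroupDesign
        Group labels and TIV covariate.
    fwhm_mm : float
        Smoothing kernel FWHM in mm (default 8).
    mask_fraction : float
        Relative threshold for the analysis mask (default 0.2).
    """

    def __init__(self, maps: list[ScalarVolume], design: GroupDesign,
                 fwhm_mm: float = 8.0, mask_fraction: float = 0.2):
        if len(maps) != design.n_subjects:
            raise ValueError("need one map per design row")
        self.maps = maps
        self.design = design
        self.fwhm_mm = fwhm_mm
        self.mask_fraction = mask_fraction

    def fit(self, mode: str = "uncorrected_p001", extent_k: int = 0,
            n_perm: int = 1000, alpha: float = 0.05, seed: int = 0) -> VBMResults:
        smoothed = [smooth_fwhm(m, self.fwhm_mm) for m in self.maps]
        # mask from the unsmoothed maps, so it tracks tissue support rather
        # than the smoothing halo
        mask = relative_threshold_mask(self.maps, self.mask_fraction)
        stat = glm_two_group_t(smoothed, self.design, mask)
        fwe_thr = None
        if mode == "fwe05_permutation":
            fwe_thr = permutation_fwe_threshold(smoothed, self.design, mask,
                                                n_perm=n_perm, alpha=alpha,
                                                seed=seed)
        sig = threshold_map(stat, mode=mode, extent_k=extent_k,
                            fwe_threshold=fwe_thr)
        return VBMResults(stat_map=stat, significant=sig, mode=mode,
                          fwe_threshold=fwe_thr, model=self)
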