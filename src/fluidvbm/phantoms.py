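"""Synthetic gray-matter phantoms, cohorts with ground-truth atrophy, and
fiducial dispersion metrics.

The generators stand in for unified-segmentation GM probability maps: smooth
ellipsoidal structures on a zero background, optionally degraded by Gaussian
noise, plus cohorts in which the patient group carries a known analytic
contraction ("atrophy") of a target region.  Every generator is a pure
function of its seed.

Registration consistency is scored with the dispersion of warped fiducial
clusters: lambda1, the standard-deviation-like spread along the direction of
greatest positional uncertainty (mm), and R1, the fraction of total
dispersion carried by that direction (1/3 = isotropic, 1 = collinear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .vbm import GroupDesign
from .volumes import DisplacementField, ScalarVolume, sample_warped


@dataclass
class PhantomSpec:
    """Recipe for a synthetic GM probability map.

    structures is a list of (center_mm, radii_mm, peak) ellipsoids; the map
    is their (clipped) superposition, smoothed by ``smoothness_mm`` and
    degraded by clipped Gaussian noise of sd ``noise_sd``.
    """

    shape: tuple = (32, 32, 32)
    voxel_mm: float = 2.0
    structures: list = dc_field(default_factory=list)
    smoothness_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for _, _, peak in self.structures:
            if not (0.0 < peak <= 1.0):
                raise ValueError(f"peak probability must be in (0, 1], got {peak}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")


@dataclass
class FiducialCluster:
    """One landmark location with one warped position per subject (mm)."""

    location_id: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.points.shape[0] < 3:
            raise ValueError("need >= 3 points per cluster to estimate covariance")


@dataclass
class DispersionMetrics:
    """lambda1 (mm) and R1 anisotropy ratio for a fiducial cluster."""

    lambda1: float
    r1: float


def make_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Build the probability map described by ``spec``; deterministic in seed."""
    data = np.zeros(spec.shape)
    idx = np.indices(spec.shape, dtype=np.float64) * spec.voxel_mm
    for center, radii, peak in spec.structures:
        center = np.asarray(center, float)
        radii = np.broadcast_to(np.asarray(radii, float), (3,))
        r2 = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
        data += peak * (r2 <= 1.0)
    if data.max() > 1.0:
        warnings.warn("overlapping structures exceed probability 1; clipping",
                      RuntimeWarning, stacklevel=2)
        data = np.clip(data, 0.0, 1.0)
    if spec.smoothness_mm > 0:
        data = gaussian_filter(data, spec.smoothness_mm / spec.voxel_mm,
                               mode="constant", cval=0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    data = np.clip(data, 0.0, 1.0)
    return ScalarVolume(data, (spec.voxel_mm,) * 3)


def _radial_contraction_field(shape, center_vox, core_radius_vox,
                              taper_vox, scale) -> DisplacementField:
    """Eulerian field whose warp samples radially outward by ``scale`` in the
    core, relaxing linearly to identity across a taper shell.

    The outward sampling displacement is D(r) = (scale-1) r inside the core
    and decays linearly to 0 over the taper; u(x) = -D(r) rhat.  The radial
    sampling map r + D(r) has derivative scale in the core and
    1 - (scale-1) core/taper in the shell, so the Jacobian determinant stays
    positive whenever (scale - 1) < taper / core."""
    idx = np.indices(shape, dtype=np.float64)
    d = idx - np.asarray(center_vox).reshape(3, 1, 1, 1)
    r = np.sqrt((d ** 2).sum(axis=0))
    D = np.zeros(shape)
    core = r <= core_radius_vox
    D[core] = (scale - 1.0) * r[core]
    ring = (r > core_radius_vox) & (r < core_radius_vox + taper_vox)
    D[ring] = (scale - 1.0) * core_radius_vox * (
        1.0 - (r[ring] - core_radius_vox) / taper_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r > 0, d / r, 0.0)
    u = -D * unit
    return DisplacementField(u)


def apply_synthetic_atrophy(phantom: ScalarVolume, region: ScalarVolume,
                            fraction: float,
                            calibrate: bool = True
                            ) -> tuple[ScalarVolume, DisplacementField]:
    """Shrink the tissue inside ``region`` by ``fraction`` of its mass.

    A known analytic radial contraction centered on the region is applied by
    warping: sampling outward by factor c contracts the structure, and
    c = (1 - fraction)^(-1/3) is then refined by bisection until the
    probability mass inside the region drops by the requested fraction.
    Returns the atrophied phantom and the ground-truth field, whose Jacobian
    determinant is positive by construction.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    reg = region.data > 0
    if not reg.any():
        raise ValueError("region is empty")
    center = np.array([c.mean() for c in np.nonzero(reg)])
    vol_vox = reg.sum()
    core_r = (3.0 * vol_vox / (4.0 * np.pi)) ** (1.0 / 3.0)
    taper = min(max(core_r, 3.0), 5.0)
    mass0 = phantom.data[reg].sum()
    target = (1.0 - fraction) * mass0

    def regional_mass(scale):
        u = _radial_contraction_field(phantom.shape, center, core_r, taper, scale)
        return sample_warped(phantom, u).data[reg].sum(), u

    # largest contraction whose analytic Jacobian stays safely positive:
    # the taper-shell radial derivative is 1 - (c-1) core/taper
    c_max = 1.0 + 0.9 * taper / core_r
    c = min((1.0 - fraction) ** (-1.0 / 3.0), c_max)
    if calibrate:
        mass_floor, _ = regional_mass(c_max)
        if mass_floor > target:
            warnings.warn(
                "requested regional mass reduction not reachable while "
                "preserving topology; applying the maximal contraction",
                RuntimeWarning, stacklevel=2)
            c = c_max
        else:
            lo, hi = 1.0, c_max
            for _ in range(30):
                c = 0.5 * (lo + hi)
                mass, _ = regional_mass(c)
                if mass > target:
                    lo = c
                else:
                    hi = c
                if abs(mass - target) <= 1e-3 * mass0:
                    break
    u = _radial_contraction_field(phantom.shape, center, core_r, taper, c)
    return sample_warped(phantom, u), u


def random_jitter_field(shape, rms_vox: float, seed: int,
                        smooth_vox: float = 3.0) -> DisplacementField:
    """Smooth random displacement field with the given RMS vector norm."""
    rng = np.random.default_rng(seed)
    f = np.stack([gaussian_filter(rng.normal(size=shape), smooth_vox)
                  for _ in range(3)])
    rms = np.sqrt((f ** 2).sum(axis=0).mean())
    if rms > 0 and rms_vox > 0:
        f *= rms_vox / rms
    else:
        f[:] = 0.0
    return DisplacementField(f)


def default_brain_spec(shape=(32, 32, 32), voxel_mm=2.0,
                       smoothness_mm=2.0, noise_sd=0.0, seed=0) -> PhantomSpec:
    """A brain-like phantom: a large cortical ellipsoid plus a distinct
    off-center inner structure (a hippocampus stand-in) whose boundary gives
    a simulated atrophy something to move."""
    fov = np.asarray(shape) * voxel_mm
    center = fov / 2.0
    inner_center = center + np.array([0.08, 0.0, 0.0]) * fov
    inner_radius = 0.2 * float(fov.min())
    return PhantomSpec(
        shape=tuple(shape), voxel_mm=voxel_mm,
        structures=[
            (tuple(center), tuple(0.42 * fov), 0.25),
            (tuple(inner_center), (inner_radius,) * 3, 0.65),
        ],
        smoothness_mm=smoothness_mm, noise_sd=noise_sd, seed=seed,
    )


def default_atrophy_region(shape=(32, 32, 32), voxel_mm=2.0,
                           radius_mm=None) -> ScalarVolume:
    """Spherical target region covering the inner structure of the default
    brain phantom (slightly larger, to include its moving boundary)."""
    fov = np.asarray(shape) * voxel_mm
    center = fov / 2.0 + np.array([0.08, 0.0, 0.0]) * fov
    if radius_mm is None:
        radius_mm = 0.2 * float(fov.min()) + voxel_mm
    idx = np.indices(shape, dtype=np.float64) * voxel_mm
    r2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return ScalarVolume((r2 <= radius_mm ** 2).astype(float), (voxel_mm,) * 3)


def make_cohort(n_controls: int, n_patients: int, atrophy_fraction: float,
                inter_subject_jitter_mm: float = 2.0, seed: int = 0,
                shape=(32, 32, 32), voxel_mm: float = 2.0,
                noise_sd: float = 0.05, smoothness_mm: float = 2.0,
                tiv_mean_mm3: float = 1.5e6, tiv_cv: float = 0.1,
                ) -> tuple[list[ScalarVolume], GroupDesign, ScalarVolume]:
    """Simulated two-group study with ground-truth regional atrophy.

    Controls are jittered copies of a template phantom (random smooth warps
    of RMS ``inter_subject_jitter_mm`` plus voxel noise); patients
    additionally carry the analytic contraction of the truth region by
    ``atrophy_fraction`` (0 disables it, making the groups exchangeable).
    TIVs are drawn independently of the maps.  Deterministic given ``seed``.
    """
    if min(n_controls, n_patients) < 3:
        raise ValueError("need >= 3 subjects per group")
    template = make_phantom(default_brain_spec(shape, voxel_mm, smoothness_mm))
    region = default_atrophy_region(shape, voxel_mm)
    if atrophy_fraction > 0:
        atrophied, _ = apply_synthetic_atrophy(template, region, atrophy_fraction)
    else:
        atrophied = template
    rng = np.random.default_rng(seed)
    jit_vox = inter_subject_jitter_mm / voxel_mm
    maps, ids, labels = [], [], []
    for i in range(n_controls + n_patients):
        base = template if i < n_controls else atrophied
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        jitter = random_jitter_field(shape, jit_vox, sub_seed)
        data = sample_warped(base, jitter).data
        if noise_sd > 0:
            data = np.clip(data + rng.normal(0, noise_sd, size=shape), 0.0, 1.0)
        maps.append(ScalarVolume(data, (voxel_mm,) * 3))
        if i < n_controls:
            ids.append(f"ctl{i:03d}")
            labels.append("control")
        else:
            ids.append(f"pat{i - n_controls:03d}")
            labels.append("patient")
    tiv = rng.normal(tiv_mean_mm3, tiv_cv * tiv_mean_mm3, size=len(maps))
    tiv = np.clip(tiv, 0.5 * tiv_mean_mm3, None)
    design = GroupDesign(ids, labels, tiv)
    return maps, design, region


def fibonacci_fiducials(center_mm, radius_mm, n: int = 20) -> np.ndarray:
    """n landmark locations spread over a sphere surface (structure boundary)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - z ** 2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return np.asarray(center_mm) + radius_mm * pts


def warp_points(points_mm, u: DisplacementField, voxel_mm: float,
                n_fixed_point: int = 5) -> np.ndarray:
    """Post-warp locations of material points under the x - u(x) convention.

    A feature at original location q appears in the warped image at the x
    solving x - u(x) = q; this is found by fixed-point iteration
    x <- q + u(x) with trilinear interpolation of the field.  Points outside
    the field's domain are excluded with a warning.
    """
    pts = np.asarray(points_mm, dtype=np.float64).reshape(-1, 3)
    shape = np.asarray(u.grid_shape)
    vox = pts / voxel_mm
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    if not inside.all():
        warnings.warn(f"{(~inside).sum()} point(s) outside the field domain; "
                      "excluded", RuntimeWarning, stacklevel=2)
    vox = vox[inside]
    x = vox.copy()
    for _ in range(n_fixed_point):
        disp = np.stack([
            map_coordinates(u.field[c], x.T, order=1, mode="constant", cval=0.0)
            for c in range(3)
        ], axis=1)
        x = vox + disp
    return x * voxel_mm


def fiducial_dispersion(cluster: FiducialCluster) -> DispersionMetrics:
    """Covariance-eigenvalue dispersion of one fiducial cluster.

    With eigenvalues e1 >= e2 >= e3 of the 3x3 covariance of the points
    about their mean: lambda1 = sqrt(e1) (mm, a standard deviation along the
    main error direction) and R1 = e1 / (e1 + e2 + e3).  A cluster of
    identical points reports lambda1 = 0 and R1 = 1/3 (no preferred
    direction).
    """
    cov = np.cov(cluster.points.T, ddof=1)
    evals = np.linalg.eigvalsh(cov)[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 1e-30:
        return DispersionMetrics(lambda1=0.0, r1=1.0 / 3.0)
    return DispersionMetrics(lambda1=float(np.sqrt(evals[0])),
                             r1=float(evals[0] / total))
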