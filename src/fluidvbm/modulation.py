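"""Jacobian modulation, TIV estimation and group-volume arithmetic.

Warping alone changes tissue *concentration*; multiplying the warped
probability map by the Jacobian determinant of the warp restores the local
tissue *amount*, so that total probability mass is conserved and group
comparisons read as volume differences.  Total intracranial volume (TIV) is
estimated as the probability mass of the native-space GM + WM + CSF segments
and used both as a GLM nuisance covariate and to normalize regional volumes
to a control-cohort mean head size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ScalarVolume, _check_same_shape


class TopologyViolationError(ValueError):
    """A Jacobian map contains non-positive values (folded warp)."""


@dataclass
class SegmentTriple:
    """Native-space GM, WM and CSF probability maps on one grid."""

    gm: ScalarVolume
    wm: ScalarVolume
    csf: ScalarVolume

    def __post_init__(self):
        _check_same_shape(self.gm.shape, self.wm.shape, "SegmentTriple gm/wm")
        _check_same_shape(self.gm.shape, self.csf.shape, "SegmentTriple gm/csf")


def modulate(warped: ScalarVolume, jac: ScalarVolume) -> ScalarVolume:
    """Voxelwise product of a warped probability map and its Jacobian map."""
    _check_same_shape(warped.shape, jac.shape, "modulate")
    if np.any(jac.data <= 0):
        raise TopologyViolationError(
            f"Jacobian determinant must be positive everywhere; min = {jac.data.min():.4g}"
        )
    return warped.with_data(warped.data * jac.data)


def estimate_tiv(seg: SegmentTriple) -> float:
    """TIV in mm^3: (sum of gm + wm + csf probabilities) x voxel volume."""
    total = seg.gm.data.sum() + seg.wm.data.sum() + seg.csf.data.sum()
    return float(total * seg.gm.voxel_volume_mm3)


def normalize_to_mean_tiv(raw_volume: float, subject_tiv: float,
                          mean_control_tiv: float) -> float:
    """Scale a regional volume to the mean control head size.

    raw_volume * mean_control_tiv / subject_tiv, all in mm^3.
    """
    if subject_tiv <= 0 or mean_control_tiv <= 0:
        raise ValueError("TIV values must be positive")
    return raw_volume * mean_control_tiv / subject_tiv


def group_percent_change(control_mean: float, patient_mean: float) -> float:
    """Percent volume change of the patient group relative to controls.

    100 * (patient - control) / control, rounded to one decimal (atrophy
    reads as a negative percentage).
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return round(100.0 * (patient_mean - control_mean) / control_mean, 1)
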