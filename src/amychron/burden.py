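"""Amyloid burden metrics.

Global amyloid burden is expressed on two interchangeable scales: the amyloid
load metric (``abl``, unit Aβ_L), obtained by decomposing a PiB SUVR image into
an Aβ-carrying-capacity template and a nonspecific-binding template, and the
standardized Centiloid scale (``cl``).  The two are linearly related
(CL = 2.27·Aβ_L − 12.1), and amyloid positivity (A+) is defined by the early
cutoff of 13.3 Aβ_L ≈ 18.0 CL.

This module provides the scale conversions, the A+ classifier, and the
voxel-level two-template least-squares estimator of amyloid load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionConstants",
    "CONSTANTS",
    "abl_to_cl",
    "cl_to_abl",
    "classify_apositive",
    "VoxelFixture",
    "estimate_abl_voxelwise",
    "read_voxel_csv",
    "write_voxel_csv",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Coefficients of the Aβ_L → Centiloid linear map and the A+ cutoff."""

    slope: float = 2.27       # CL per Aβ_L
    intercept: float = -12.1  # CL at zero amyloid load
    cutoff_abl: float = 13.3  # A+ cutoff on the amyloid-load scale
    cutoff_cl: float = 18.0   # the same cutoff as printed on the CL scale

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InputError("conversion slope must be positive")
        # the printed CL cutoff is a rounded value; keep the two anchored
        if abs(self.slope * self.cutoff_abl + self.intercept - self.cutoff_cl) > 0.1:
            raise InputError("cutoff_cl inconsistent with the linear conversion")


CONSTANTS = ConversionConstants()


def _validate_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} must be finite")
    return arr


def abl_to_cl(abl, constants: ConversionConstants = CONSTANTS):
    """Convert amyloid load (Aβ_L) to equivalent Centiloids.

    Accepts scalars or array-likes; vectorizes elementwise.
    """
    arr = _validate_finite(abl, "abl")
    out = constants.slope * arr + constants.intercept
    return float(out) if np.isscalar(abl) or arr.ndim == 0 else out


def cl_to_abl(cl, constants: ConversionConstants = CONSTANTS):
    """Convert Centiloids back to amyloid load (inverse of :func:`abl_to_cl`)."""
    arr = _validate_finite(cl, "cl")
    out = (arr - constants.intercept) / constants.slope
    return float(out) if np.isscalar(cl) or arr.ndim == 0 else out


def classify_apositive(abl, constants: ConversionConstants = CONSTANTS):
    """A+ classification: amyloid load at or above the cutoff (boundary inclusive).

    The cutoff value itself is positive because a chronicity of 0 years is
    defined to coincide with the cutoff.
    """
    arr = _validate_finite(abl, "abl")
    out = arr >= constants.cutoff_abl
    return bool(out) if np.isscalar(abl) or arr.ndim == 0 else out


@dataclass
class VoxelFixture:
    """Flattened voxel data for the two-template amyloid-load fit.

    Attributes
    ----------
    suvr : (n_voxels,) SUVR image values.
    template_k : (n_voxels,) Aβ-carrying-capacity template.
    template_ns : (n_voxels,) nonspecific-binding template.
    mask : (n_voxels,) bool, which voxels enter the fit (Aβ-carrying voxels).
    """

    suvr: np.ndarray
    template_k: np.ndarray
    template_ns: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.suvr = _validate_finite(self.suvr, "suvr")
        self.template_k = _validate_finite(self.template_k, "template_k")
        self.template_ns = _validate_finite(self.template_ns, "template_ns")
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.suvr.size
        if not (self.template_k.size == n == self.template_ns.size == self.mask.size):
            raise InputError("voxel vectors must all have the same length")
        if self.mask.sum() < 2:
            raise InputError("mask must select at least 2 voxels")


def estimate_abl_voxelwise(fix: VoxelFixture) -> tuple[float, float]:
    """Estimate amyloid load from an SUVR image by two-template least squares.

    Solves ``min ||suvr − abl·template_k − ns·template_ns||²`` over the masked
    voxels (ordinary, unconstrained least squares).  Returns ``(abl, ns_coeff)``.
    A negative fitted load is physically implausible but reported as-is with a
    warning.
    """
    m = fix.mask
    design = np.column_stack([fix.template_k[m], fix.template_ns[m]])
    if np.linalg.matrix_rank(design) < 2:
        raise InputError("templates are collinear within the mask; fit is singular")
    coef, *_ = np.linalg.lstsq(design, fix.suvr[m], rcond=None)
    abl, ns_coeff = float(coef[0]), float(coef[1])
    if abl < 0:
        logger.warning("voxelwise fit produced negative amyloid load %.3f", abl)
    return abl, ns_coeff


def read_voxel_csv(path) -> VoxelFixture:
    """Read a flat voxel fixture CSV (voxel_id, suvr, template_k, template_ns, mask)."""
    df = pd.read_csv(path, comment="#")
    required = {"suvr", "template_k", "template_ns", "mask"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"voxel CSV missing columns: {sorted(missing)}")
    return VoxelFixture(
        suvr=df["suvr"].to_numpy(float),
        template_k=df["template_k"].to_numpy(float),
        template_ns=df["template_ns"].to_numpy(float),
        mask=df["mask"].to_numpy(bool),
    )


def write_voxel_csv(fix: VoxelFixture, path) -> None:
    pd.DataFrame(
        {
            "voxel_id": np.arange(fix.suvr.size),
            "suvr": fix.suvr,
            "template_k": fix.template_k,
            "template_ns": fix.template_ns,
            "mask": fix.mask.astype(int),
        }
    ).to_csv(path, index=False)
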