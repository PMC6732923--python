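"""Landmark-based rigid registration of SPECT onto the planning grid.

Paired anatomical landmarks (lung apices, hila, tumour-associated
perfusion defect) define a least-squares rigid transform via the Kabsch
algorithm; the SPECT volume is then resampled trilinearly onto the
planning grid.  The RMS landmark residual serves as a misregistration
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import GridSpec, ImageVolume, RigidTransform, resample_to_grid

__all__ = [
    "KabschResult",
    "MisregistrationWarning",
    "kabsch_align",
    "register_spect",
    "read_landmarks_csv",
]


class MisregistrationWarning(UserWarning):
    """Landmark residual exceeds the configured ceiling."""


@dataclass
class KabschResult:
    transform: RigidTransform
    rms_residual_mm: float


def kabsch_align(source_points, target_points) -> KabschResult:
    """Least-squares rigid transform mapping source points onto targets.

    Solves ``argmin_{R,t} Σ ||R p_i + t - q_i||²`` over proper rotations
    (det +1, no scaling) via SVD of the cross-covariance.  Requires at
    least three non-collinear point pairs.

    Returns
    -------
    KabschResult
        The fitted :class:`RigidTransform` and the RMS residual in mm.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_points, dtype=float))
    if src.shape != tgt.shape or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("at least 3 landmark pairs are required")
    src_c = src - src.mean(axis=0)
    # Collinearity check: the centred source cloud must span a plane.
    if np.linalg.matrix_rank(src_c, tol=1e-8 * max(1.0, np.abs(src_c).max())) < 2:
        raise ValueError("landmarks are collinear; rotation is unconstrained")
    tgt_c = tgt - tgt.mean(axis=0)
    h = src_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, trans)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return KabschResult(transform=transform, rms_residual_mm=rms)


def register_spect(
    spect: ImageVolume,
    landmarks_spect,
    landmarks_ct,
    target_geometry: GridSpec,
    max_residual_mm: float = 15.0,
) -> tuple[ImageVolume, KabschResult]:
    """Align a SPECT volume onto the planning grid via paired landmarks.

    The Kabsch transform carries SPECT-world points into planning-world
    points; the volume is resampled trilinearly onto ``target_geometry``.
    A residual above ``max_residual_mm`` raises a
    :class:`MisregistrationWarning` but does not fail the registration.
    """
    result = kabsch_align(landmarks_spect, landmarks_ct)
    if result.rms_residual_mm > max_residual_mm:
        warnings.warn(
            f"landmark RMS residual {result.rms_residual_mm:.1f} mm exceeds "
            f"ceiling {max_residual_mm:.1f} mm; check the co-registration",
            MisregistrationWarning,
            stacklevel=2,
        )
    aligned = resample_to_grid(
        spect, target_geometry, transform=result.transform, interpolation="trilinear"
    )
    return aligned, result


def read_landmarks_csv(path: str | Path) -> np.ndarray:
    """Read landmarks as (n, 3) mm from a CSV with columns label, x_mm, y_mm, z_mm."""
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
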