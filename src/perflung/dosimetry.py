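"""Cumulative DVHs, fractional Vx metrics and mean lung dose.

Vx is the percentage of a structure's voxels receiving at least x Gy
(inclusive ≥, computed voxelwise, never from histogram bins); MLD is the
arithmetic mean dose over the structure, reported in cGy.  The canonical
reporting thresholds are 5, 10, 13, 20, 30, 40 and 50 Gy; the prefix
``a`` denotes the anatomic lung and ``p`` the perfused (p20) lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .perfusion import PerfusionVolumeSet
from .volume import ImageVolume, mask_volume_ml

__all__ = [
    "CANONICAL_THRESHOLDS_GY",
    "PLANNING_CONSTRAINTS",
    "DvhMetrics",
    "v_at_dose",
    "mean_dose",
    "cumulative_dvh",
    "patient_metrics",
    "metric_columns",
]

#: Dose thresholds (Gy) at which fractional volumes are reported.
CANONICAL_THRESHOLDS_GY = (5.0, 10.0, 13.0, 20.0, 30.0, 40.0, 50.0)

#: Planning dose-volume constraints: MLD < 20 Gy and V20 < 35%.
PLANNING_CONSTRAINTS = {"mld_max_gy": 20.0, "v20_max_pct": 35.0}


@dataclass
class DvhMetrics:
    """Cumulative DVH plus summary metrics for one structure."""

    structure: str
    total_volume_ml: float
    bin_edges_gy: np.ndarray
    cumulative_pct: np.ndarray
    vx: dict[float, float] = field(default_factory=dict)
    mean_dose_cgy: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_dose_cgy < 0:
            raise ValueError("mean dose cannot be negative")
        if np.any(np.diff(self.cumulative_pct) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")


def _check_pair(dose: ImageVolume, mask: ImageVolume) -> np.ndarray:
    if dose.role != "dose_gy":
        raise ValueError("dose volume must have role 'dose_gy'")
    if mask.role != "mask":
        raise ValueError("structure must have role 'mask'")
    if not dose.same_grid(mask):
        raise ValueError("dose and mask must share the planning grid")
    sel = mask.data.astype(bool)
    if not sel.any():
        raise ValueError("structure mask is empty")
    return sel


def v_at_dose(dose: ImageVolume, mask: ImageVolume, threshold_gy: float) -> float:
    """Fractional volume (%) of ``mask`` receiving ≥ ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValueError("dose threshold must be non-negative")
    sel = _check_pair(dose, mask)
    vals = dose.data[sel]
    return 100.0 * float(np.count_nonzero(vals >= threshold_gy)) / vals.size


def mean_dose(dose: ImageVolume, mask: ImageVolume) -> float:
    """Mean dose over the structure, in cGy."""
    sel = _check_pair(dose, mask)
    return float(dose.data[sel].mean()) * 100.0


def cumulative_dvh(
    dose: ImageVolume,
    mask: ImageVolume,
    bin_width_gy: float = 0.1,
    structure: str = "structure",
) -> DvhMetrics:
    """Cumulative DVH over [0, max dose] with exact Vx at the canonical thresholds.

    The binned curve is for plotting/export only; the ``vx`` map and mean
    dose are computed voxelwise, free of binning error.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    sel = _check_pair(dose, mask)
    vals = dose.data[sel].astype(float)
    top = max(float(vals.max()), bin_width_gy)
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    cum = 100.0 * (vals[None, :] >= edges[:, None]).mean(axis=1)
    cum[0] = 100.0  # every voxel receives >= 0 Gy
    return DvhMetrics(
        structure=structure,
        total_volume_ml=mask_volume_ml(mask),
        bin_edges_gy=edges,
        cumulative_pct=cum,
        vx={t: v_at_dose(dose, mask, t) for t in CANONICAL_THRESHOLDS_GY},
        mean_dose_cgy=float(vals.mean()) * 100.0,
    )


def check_planning_constraints(dose: ImageVolume, mask: ImageVolume) -> dict[str, bool]:
    """Flag violations of the lung planning rules MLD < 20 Gy and V20 < 35%."""
    mld_gy = mean_dose(dose, mask) / 100.0
    v20 = v_at_dose(dose, mask, 20.0)
    return {
        "mld_violated": mld_gy >= PLANNING_CONSTRAINTS["mld_max_gy"],
        "v20_violated": v20 >= PLANNING_CONSTRAINTS["v20_max_pct"],
    }


def metric_columns(extra_thresholds: bool = False) -> list[str]:
    """Canonical metric column names: aV5..aV50, aMLD_cGy, pV5..pV50, pMLD_cGy."""
    cols = [f"aV{int(t)}" for t in CANONICAL_THRESHOLDS_GY] + ["aMLD_cGy"]
    cols += [f"pV{int(t)}" for t in CANONICAL_THRESHOLDS_GY] + ["pMLD_cGy"]
    if extra_thresholds:
        for frac in (25, 30, 40, 50):
            cols += [f"p{frac}V{int(t)}" for t in CANONICAL_THRESHOLDS_GY]
            cols += [f"p{frac}MLD_cGy"]
    return cols


def patient_metrics(
    dose: ImageVolume,
    anatomic_mask: ImageVolume,
    perfusion_set: PerfusionVolumeSet,
    extra_thresholds: bool = False,
) -> dict[str, float]:
    """Per-patient dose-metric dictionary over anatomic and perfused lung.

    aVx/aMLD are computed on the anatomic mask; pVx/pMLD on the p20 mask
    treated as an independent organ-at-risk.  With ``extra_thresholds``
    the p25–p50 volumes get their own metric columns.  Absolute volumes
    (ml) of every structure are included for the volume-comparison table.
    """
    out: dict[str, float] = {}
    for t in CANONICAL_THRESHOLDS_GY:
        out[f"aV{int(t)}"] = v_at_dose(dose, anatomic_mask, t)
    out["aMLD_cGy"] = mean_dose(dose, anatomic_mask)
    p20 = perfusion_set.p20
    for t in CANONICAL_THRESHOLDS_GY:
        out[f"pV{int(t)}"] = v_at_dose(dose, p20, t)
    out["pMLD_cGy"] = mean_dose(dose, p20)
    out["anat_ml"] = mask_volume_ml(anatomic_mask)
    for frac, m in perfusion_set.masks.items():
        out[f"p{int(round(frac * 100))}_ml"] = mask_volume_ml(m)
    if extra_thresholds:
        for frac, m in perfusion_set.masks.items():
            tag = f"p{int(round(frac * 100))}"
            if tag == "p20":
                continue
            for t in CANONICAL_THRESHOLDS_GY:
                out[f"{tag}V{int(t)}"] = v_at_dose(dose, m, t)
            out[f"{tag}MLD_cGy"] = mean_dose(dose, m)
    out.update(check_planning_constraints(dose, anatomic_mask))
    return out
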