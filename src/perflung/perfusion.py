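"""Anatomic lung and SPECT perfusion-volume construction.

Perfused lung is defined in two steps: (1) a boundary contour around all
tracer-containing voxels in the lungs; (2) nested "perfusion volumes"
keeping only voxels with counts at or above a fraction of the maximum
voxel perfusion count inside that boundary (p20 ... p50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, StructureSet, mask_volume_ml

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PerfusionVolumeSet",
    "anatomic_lung_volume",
    "perfusion_boundary",
    "perfusion_volume",
    "build_perfusion_set",
]

#: Fractions of the maximum voxel perfusion count defining p20 ... p50.
DEFAULT_THRESHOLDS = (0.20, 0.25, 0.30, 0.40, 0.50)


@dataclass
class PerfusionVolumeSet:
    """Nested perfusion masks at fractional-max thresholds.

    Attributes
    ----------
    boundary : ImageVolume
        Mask of all tracer-containing lung voxels (step 1).
    thresholds : tuple of float
        Fractions of the maximum count, ascending.
    masks : dict
        Threshold fraction -> binary mask (step 2).  ``masks[0.20]`` is
        the p20 volume used as the perfused organ-at-risk.
    max_count : float
        Maximum voxel perfusion count within the boundary.
    """

    boundary: ImageVolume
    thresholds: tuple[float, ...]
    masks: dict[float, ImageVolume]
    max_count: float

    def __post_init__(self) -> None:
        if self.max_count <= 0:
            raise ValueError("max_count must be positive")
        b = self.boundary.data.astype(bool)
        prev = b
        for t in sorted(self.thresholds):
            m = self.masks[t].data.astype(bool)
            if np.any(m & ~b):
                raise ValueError(f"threshold mask {t} escapes the boundary")
            if np.any(m & ~prev):
                raise ValueError("threshold masks are not nested")
            prev = m

    def mask(self, threshold: float) -> ImageVolume:
        return self.masks[threshold]

    @property
    def p20(self) -> ImageVolume:
        return self.masks[0.20]

    def volumes_ml(self) -> dict[float, float]:
        return {t: mask_volume_ml(m) for t, m in self.masks.items()}


def anatomic_lung_volume(
    structures: StructureSet, subtract: str = "gtv"
) -> ImageVolume:
    """Anatomic lung mask: lungs minus target volume minus central airways.

    By default the GTV/ITV is subtracted (``subtract='gtv'``); pass
    ``subtract='ptv'`` to remove the full PTV instead.  The trachea and
    proximal bronchial tree are always excluded.
    """
    if subtract not in ("gtv", "ptv"):
        raise ValueError("subtract must be 'gtv' or 'ptv'")
    target = structures.gtv_itv if subtract == "gtv" else structures.ptv
    out = (
        structures.lungs.data.astype(bool)
        & ~target.data.astype(bool)
        & ~structures.central_airways.data.astype(bool)
    )
    if not out.any():
        raise ValueError("anatomic lung volume is empty after exclusions")
    return structures.lungs.with_data(out.astype(np.uint8))


def perfusion_boundary(
    spect: ImageVolume,
    lungs_hint: ImageVolume,
    floor_fraction: float = 0.01,
    closing_radius: int = 1,
) -> ImageVolume:
    """Contour all tracer-containing lung voxels into a single boundary.

    A reproducible surrogate for the manual step: voxels with counts
    above ``floor_fraction`` of the maximum count are kept, restricted to
    the (up to) two largest connected components that intersect the lung
    hint mask, then morphologically closed to form a contiguous boundary.
    """
    if spect.role != "spect_counts":
        raise ValueError("perfusion boundary requires a spect_counts volume")
    if not (0 <= floor_fraction < 0.2):
        raise ValueError("floor_fraction must lie in [0, 0.2)")
    if not spect.same_grid(lungs_hint):
        raise ValueError("spect must be resampled to the lung-mask grid first")
    max_count = float(spect.data.max())
    if max_count <= 0:
        raise ValueError("SPECT volume contains no counts")

    active = spect.data > floor_fraction * max_count
    labels, n = ndimage.label(active)
    if n == 0:
        raise ValueError("no voxels above the count floor")
    hint = lungs_hint.data.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    keep_ids = [lab for lab in order if (hint[labels == lab]).any()][:2]
    if not keep_ids:
        raise ValueError("no tracer-containing component intersects the lungs")
    boundary = np.isin(labels, keep_ids)
    if closing_radius > 0:
        struct = _ball(closing_radius)
        boundary = ndimage.binary_closing(boundary, structure=struct)
    return spect.with_data(boundary.astype(np.uint8), role="mask")


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= r * r


def perfusion_volume(
    spect: ImageVolume, boundary: ImageVolume, threshold: float
) -> ImageVolume:
    """Perfusion volume at one fractional-max threshold.

    Keeps boundary voxels whose counts are greater than or equal to
    ``threshold`` times the maximum voxel perfusion count within the
    boundary (inclusive comparison).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly in (0, 1)")
    b = boundary.data.astype(bool)
    if not b.any():
        raise ValueError("boundary mask is empty")
    max_count = float(spect.data[b].max())
    if max_count <= 0:
        raise ValueError("no counts within the boundary")
    mask = b & (spect.data >= threshold * max_count)
    return spect.with_data(mask.astype(np.uint8), role="mask")


def build_perfusion_set(
    spect: ImageVolume,
    lungs_hint: ImageVolume,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    floor_fraction: float = 0.01,
    max_count_percentile: float | None = None,
) -> PerfusionVolumeSet:
    """Run both steps for every threshold and collect the nested set.

    ``max_count_percentile`` optionally replaces the absolute maximum
    count with a robust percentile (e.g. 99.5) to guard against hot
    pixels; off by default.
    """
    thresholds = tuple(sorted(float(t) for t in thresholds))
    if not thresholds:
        raise ValueError("thresholds list must not be empty")
    boundary = perfusion_boundary(spect, lungs_hint, floor_fraction=floor_fraction)
    inside = spect.data[boundary.data.astype(bool)]
    if max_count_percentile is None:
        max_count = float(inside.max())
    else:
        max_count = float(np.percentile(inside, max_count_percentile))
    if max_count <= 0:
        raise ValueError("no counts within the boundary")
    masks = {}
    b = boundary.data.astype(bool)
    for t in thresholds:
        if not (0 < t < 1):
            raise ValueError("threshold must lie strictly in (0, 1)")
        m = b & (spect.data >= t * max_count)
        masks[t] = spect.with_data(m.astype(np.uint8), role="mask")
    return PerfusionVolumeSet(
        boundary=boundary, thresholds=thresholds, masks=masks, max_count=max_count
    )
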