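"""Shoot phenotyping from top-view colour images.

Rosettes are segmented by thresholding in HSV space (hue with wraparound,
saturation, value), the plate's plants are split by assigning connected
components to the nearest sowing position, and projected leaf area is the
mask pixel count times the squared pixel scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import disk, opening

from .errors import ConfigurationError
from .image_io import ColorImage
from .plate_model import PlateImageMeta

__all__ = [
    "HSVThresholds",
    "segment_leaves",
    "split_plants",
    "projected_leaf_area",
    "ROSETTE_DIAMETER_LIMIT_MM",
]

#: Rosettes larger than this diameter outgrow the plate; flagged in QC.
ROSETTE_DIAMETER_LIMIT_MM = 24.0


@dataclass
class HSVThresholds:
    """Hue/saturation/value windows defining "plant" pixels.

    Hue is in degrees and handled modulo 360: a window with ``hue_min >
    hue_max`` (e.g. 330..30) wraps around red.  Saturation and value are in
    [0, 1].  Defaults are green-vegetation calibration values, meant to be
    overridden per camera.
    """

    hue_min: float = 60.0
    hue_max: float = 180.0
    sat_min: float = 0.15
    sat_max: float = 1.0
    val_min: float = 0.15
    val_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.sat_min <= self.sat_max <= 1 and 0 <= self.val_min <= self.val_max <= 1):
            raise ValueError("saturation/value ranges must be ordered within [0, 1]")

    def hue_in_range(self, hue_deg: np.ndarray) -> np.ndarray:
        h = np.mod(hue_deg, 360.0)
        lo, hi = np.mod(self.hue_min, 360.0), np.mod(self.hue_max, 360.0)
        if lo <= hi:
            return (h >= lo) & (h <= hi)
        return (h >= lo) | (h <= hi)  # wraparound window


def segment_leaves(img: ColorImage, th: Optional[HSVThresholds] = None) -> np.ndarray:
    """Binary rosette mask: pixels whose HSV triplet lies in all three windows.

    A 1-px-radius morphological opening removes isolated speckle.
    """
    th = th or HSVThresholds()
    hsv = rgb2hsv(img.pixels)
    hue = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    val = hsv[:, :, 2]
    mask = (
        th.hue_in_range(hue)
        & (sat >= th.sat_min)
        & (sat <= th.sat_max)
        & (val >= th.val_min)
        & (val <= th.val_max)
    )
    return opening(mask, disk(1))


def split_plants(
    mask: np.ndarray,
    meta: PlateImageMeta,
    max_dist_mm: float = 15.0,
) -> tuple[list[np.ndarray], dict]:
    """Assign mask components to the plate's plant positions.

    Each connected component goes to the plant position nearest its centroid
    x-coordinate; components farther than ``max_dist_mm`` from every position
    are discarded as debris.  Returns one mask per position plus a QC dict
    with flags: ``overlap`` (a component spans more than one position's
    half-lane), ``discarded_px``, and ``oversize`` (rosette diameter beyond
    the tracking limit).
    """
    positions = list(meta.plant_positions)
    if not positions:
        positions = [mask.shape[1] * meta.px_scale / 1000.0 / 2.0]
    scale_mm = meta.px_scale / 1000.0
    labels, n = ndimage.label(mask)
    out = [np.zeros_like(mask, dtype=bool) for _ in positions]
    qc = {"overlap": [False] * len(positions), "oversize": [False] * len(positions), "discarded_px": 0}
    if n == 0:
        return out, qc
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    objects = ndimage.find_objects(labels)
    for comp, ((_cy, cx), slc) in enumerate(zip(centroids, objects), start=1):
        cx_mm = cx * scale_mm
        dists = [abs(cx_mm - p) for p in positions]
        j = int(np.argmin(dists))
        comp_mask = labels == comp
        if dists[j] > max_dist_mm:
            qc["discarded_px"] += int(comp_mask.sum())
            continue
        # a component whose x-extent reaches into a neighbour's half-lane
        # likely contains touching rosettes
        xs = np.nonzero(comp_mask.any(axis=0))[0] * scale_mm
        for jj, p in enumerate(positions):
            if jj != j and abs(xs - p).min() < max_dist_mm / 2.0:
                qc["overlap"][j] = True
        out[j] |= comp_mask
    for j, m in enumerate(out):
        if not m.any():
            continue
        ys, xs = np.nonzero(m)
        diam = max(np.ptp(ys), np.ptp(xs)) * scale_mm
        if diam > ROSETTE_DIAMETER_LIMIT_MM:
            qc["oversize"][j] = True
            warnings.warn(f"plant {j + 1}: rosette diameter {diam:.1f} mm exceeds the tracking limit")
    return out, qc


def projected_leaf_area(mask: np.ndarray, meta: PlateImageMeta) -> float:
    """Projected leaf area in mm^2: pixel count x (px_scale/1000)^2."""
    if meta.px_scale is None or meta.px_scale <= 0:
        raise ConfigurationError("px_scale is not set for leaf-area computation")
    return float(mask.sum()) * (meta.px_scale / 1000.0) ** 2
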