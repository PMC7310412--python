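"""Core domain types and geometric primitives for plate-based root phenotyping.

Coordinate convention
---------------------
All stored geometry is in plate millimetres with the origin at the image
top-left corner, x growing rightward and y growing *downward*, so that root
"depth" is positive y.  Upright 12 x 12 cm agar plates are imaged face-on,
which makes the image frame and the plate frame coincide up to the pixel
scale (default 39 um/px for root images, 83 um/px for top-view shoot
images).

A root system is a tree of :class:`RootAxis` records: exactly one order-0
(primary) axis, first-order laterals branched from it, and optionally
second-order laterals branched from those.  Every axis stores its centreline
as a :class:`Polyline`, a link to its parent, and the arc-length position on
the parent where it attaches.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError, ValidationError

__all__ = [
    "View",
    "PlateImageMeta",
    "Polyline",
    "RootAxis",
    "RootSystem",
    "TraitRecord",
    "DepthProfile",
    "TRAIT_FIELDS",
    "arc_length",
    "point_at_arclength",
    "tangent_at_arclength",
    "px_to_mm",
    "mm_to_px",
    "translate_system",
    "rotate_system",
]

#: Default pixel scales (um per pixel) by view.
DEFAULT_PX_SCALE = {"root": 39.0, "shoot": 83.0}

#: Default snap distance (mm) for lateral attachment checks (~5 px at 39 um/px).
DEFAULT_SNAP_MM = 0.2


class View(str, Enum):
    """Which camera produced an image: the root (side) or shoot (top) view."""

    ROOT = "root"
    SHOOT = "shoot"


@dataclass
class PlateImageMeta:
    """Metadata attached to one plate image.

    ``plant_positions`` are the x-coordinates (mm) of the sowing holes along
    the top edge of the plate; up to four plants per plate, strictly
    increasing.
    """

    plate_id: str
    view: View
    capture_time: Optional[datetime] = None
    plant_positions: Sequence[float] = ()
    px_scale: Optional[float] = None  # um per pixel
    image_width_px: Optional[int] = None
    image_height_px: Optional[int] = None

    def __post_init__(self) -> None:
        self.view = View(self.view)
        if self.px_scale is None:
            self.px_scale = DEFAULT_PX_SCALE[self.view.value]
        if self.px_scale <= 0:
            raise ValidationError("px_scale must be positive")
        pos = list(self.plant_positions)
        if len(pos) > 4:
            raise ValidationError("at most 4 plant positions per plate")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("plant_positions must be strictly increasing")
        self.plant_positions = tuple(pos)


class Polyline:
    """Ordered 2-D vertex chain in plate millimetres.

    Thin wrapper around an ``(n, 2)`` float array guaranteeing at least two
    vertices with no consecutive duplicates.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Iterable[Sequence[float]]):
        arr = np.asarray(list(vertices) if not isinstance(vertices, np.ndarray) else vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise GeometryError("a polyline needs at least 2 (x, y) vertices")
        seg = np.diff(arr, axis=0)
        keep = np.hypot(seg[:, 0], seg[:, 1]) > 0
        if not keep.any():
            raise GeometryError("polyline has no distinct consecutive vertices")
        arr = np.vstack([arr[:1], arr[1:][keep]])
        if arr.shape[0] < 2:
            raise GeometryError("a polyline needs at least 2 distinct vertices")
        self.vertices = arr

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __eq__(self, other) -> bool:
        return isinstance(other, Polyline) and np.array_equal(self.vertices, other.vertices)

    def __repr__(self) -> str:
        return f"Polyline({len(self)} vertices, {self.length():.3f} mm)"

    def segment_lengths(self) -> np.ndarray:
        d = np.diff(self.vertices, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def cumulative_lengths(self) -> np.ndarray:
        """Arc length from the first vertex to each vertex (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])

    def first(self) -> np.ndarray:
        return self.vertices[0].copy()

    def last(self) -> np.ndarray:
        return self.vertices[-1].copy()

    def reversed(self) -> "Polyline":
        return Polyline(self.vertices[::-1].copy())

    def transformed(self, fn) -> "Polyline":
        return Polyline(np.apply_along_axis(fn, 1, self.vertices))


def arc_length(path: Polyline) -> float:
    """Total arc length of a polyline in mm (sum of Euclidean segment lengths)."""
    if not isinstance(path, Polyline):
        path = Polyline(path)
    return path.length()


def point_at_arclength(path: Polyline, s: float) -> np.ndarray:
    """Point on ``path`` at arc-length position ``s`` (linear interpolation).

    ``s`` must lie in ``[0, arc_length(path)]``; small floating slack
    (1e-9 mm) at either end is tolerated.
    """
    if not isinstance(path, Polyline):
        path = Polyline(path)
    cum = path.cumulative_lengths()
    total = cum[-1]
    if s < -1e-9 or s > total + 1e-9:
        raise GeometryError(f"arc-length {s} outside [0, {total}]")
    s = min(max(s, 0.0), total)
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(cum) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    v = path.vertices
    return v[i] + t * (v[i + 1] - v[i])


def tangent_at_arclength(path: Polyline, s: float, half_window_mm: float = 0.2) -> np.ndarray:
    """Unit tangent (growth direction) at arc length ``s``.

    Estimated by central differencing over ``±half_window_mm`` (clipped at
    the path ends), which smooths pixel-level jitter of traced centrelines.
    """
    if not isinstance(path, Polyline):
        path = Polyline(path)
    total = path.length()
    a = max(0.0, s - half_window_mm)
    b = min(total, s + half_window_mm)
    if b - a < 1e-12:
        a, b = 0.0, total
    p0 = point_at_arclength(path, a)
    p1 = point_at_arclength(path, b)
    d = p1 - p0
    n = math.hypot(d[0], d[1])
    if n < 1e-12:
        raise GeometryError("degenerate tangent (closed or zero-extent window)")
    return d / n


def px_to_mm(px_coords, meta: PlateImageMeta) -> np.ndarray:
    """Convert pixel coordinates to mm: ``mm = px * px_scale / 1000``."""
    if meta.px_scale is None or meta.px_scale <= 0:
        raise ConfigurationError("px_scale is not set on the image metadata")
    return np.asarray(px_coords, dtype=float) * (meta.px_scale / 1000.0)


def mm_to_px(mm_coords, meta: PlateImageMeta) -> np.ndarray:
    """Inverse of :func:`px_to_mm` (exact up to floating round-off)."""
    if meta.px_scale is None or meta.px_scale <= 0:
        raise ConfigurationError("px_scale is not set on the image metadata")
    return np.asarray(mm_coords, dtype=float) * (1000.0 / meta.px_scale)


@dataclass
class RootAxis:
    """One root: order 0 = primary, 1 = first-order lateral, 2 = second-order.

    ``branch_pos_mm`` is the arc-length position on the parent axis where
    this axis attaches (``None`` for the primary).  ``deleted`` marks an axis
    removed by a manual correction.
    """

    axis_id: str
    order: int
    path: Polyline
    parent_id: Optional[str] = None
    branch_pos_mm: Optional[float] = None
    mean_diameter_um: Optional[float] = None
    deleted: bool = False

    def length_mm(self) -> float:
        return self.path.length()

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValidationError("axis order must be >= 0")
        if (self.order == 0) != (self.parent_id is None):
            raise ValidationError("order 0 iff no parent")
        if (self.parent_id is None) != (self.branch_pos_mm is None):
            raise ValidationError("branch_pos_mm set iff the axis has a parent")


@dataclass
class RootSystem:
    """Per-plant, per-timepoint tree of root axes anchored at a seed point.

    An "empty" system (no skeleton found in the plant's lane) carries no
    axes and ``empty=True``; trait computations treat it as all-zero lengths.
    """

    plant_id: str
    plate_id: str
    seed_point: tuple[float, float]
    axes: list[RootAxis] = field(default_factory=list)
    capture_time: Optional[datetime] = None
    empty: bool = False

    def axis(self, axis_id: str) -> RootAxis:
        for ax in self.axes:
            if ax.axis_id == axis_id:
                return ax
        raise KeyError(axis_id)

    def primary(self) -> RootAxis:
        prim = [ax for ax in self.axes if ax.order == 0]
        if len(prim) != 1:
            raise ValidationError(f"expected exactly one primary axis, found {len(prim)}")
        return prim[0]

    def laterals(self, order: int = 1) -> list[RootAxis]:
        return [ax for ax in self.axes if ax.order == order]

    def all_vertices(self) -> np.ndarray:
        if not self.axes:
            return np.empty((0, 2))
        return np.vstack([ax.path.vertices for ax in self.axes])

    def children_of(self, axis_id: str) -> list[RootAxis]:
        return [ax for ax in self.axes if ax.parent_id == axis_id]

    def validate(self, snap_mm: float = DEFAULT_SNAP_MM) -> None:
        """Check the structural invariants; raise :class:`ValidationError`."""
        if self.empty and not self.axes:
            return
        prim = self.primary()
        ids = {ax.axis_id for ax in self.axes}
        if len(ids) != len(self.axes):
            raise ValidationError("duplicate axis ids")
        seed = np.asarray(self.seed_point, dtype=float)
        if np.hypot(*(prim.path.first() - seed)) > snap_mm + 1e-9:
            raise ValidationError("seed_point is not within snap distance of the primary's first vertex")
        by_id = {ax.axis_id: ax for ax in self.axes}
        for ax in self.axes:
            if ax.order == 0:
                continue
            parent = by_id.get(ax.parent_id)
            if parent is None:
                raise ValidationError(f"axis {ax.axis_id}: unresolved parent {ax.parent_id}")
            if parent.order != ax.order - 1:
                raise ValidationError(f"axis {ax.axis_id}: parent order must be {ax.order - 1}")
            plen = parent.length_mm()
            if not (-1e-9 <= ax.branch_pos_mm <= plen + 1e-9):
                raise ValidationError(
                    f"axis {ax.axis_id}: branch_pos_mm {ax.branch_pos_mm} outside [0, {plen}]"
                )
            attach = point_at_arclength(parent.path, min(max(ax.branch_pos_mm, 0.0), plen))
            if np.hypot(*(ax.path.first() - attach)) > snap_mm + 1e-9:
                raise ValidationError(f"axis {ax.axis_id}: first vertex too far from its branch point")


def translate_system(system: RootSystem, dx: float, dy: float) -> RootSystem:
    """Rigidly translate every axis (and the seed point) of a root system."""
    shift = np.array([dx, dy])
    axes = [replace(ax, path=Polyline(ax.path.vertices + shift)) for ax in system.axes]
    return replace(system, axes=axes, seed_point=(system.seed_point[0] + dx, system.seed_point[1] + dy))


def rotate_system(system: RootSystem, angle_deg: float, center: tuple[float, float] = (0.0, 0.0)) -> RootSystem:
    """Rigidly rotate a root system about ``center`` by ``angle_deg``."""
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    c = np.asarray(center, dtype=float)

    def xf(v: np.ndarray) -> np.ndarray:
        return (v - c) @ rot.T + c

    axes = [replace(ax, path=Polyline(xf(ax.path.vertices))) for ax in system.axes]
    seed = xf(np.asarray(system.seed_point, dtype=float))
    return replace(system, axes=axes, seed_point=(float(seed[0]), float(seed[1])))


#: Trait fields, in CSV column order. These are exactly the header names of
#: the exported trait tables.
TRAIT_FIELDS = (
    "length_primary_mm",
    "length_lateral_mm",
    "length_total_mm",
    "n_lateral",
    "lateral_density_per_mm",
    "branching_angle_deg",
    "diam_primary_um",
    "diam_lateral_um",
    "depth_mm",
    "width_mm",
    "hull_area_mm2",
    "root_length_density_mm_per_mm2",
    "rgr_primary_pct_per_day",
    "rgr_lateral_pct_per_day",
    "rgr_total_pct_per_day",
    "ratio_lateral_primary",
    "ratio_primary_depth",
    "leaf_area_mm2",
)


@dataclass
class TraitRecord:
    """One plant x one timepoint row of the full trait catalogue.

    Ratio and rate fields are ``None`` when their denominator is zero or the
    quantity is undefined (e.g. growth rates at the first timepoint).
    """

    plant_id: str
    capture_time: Optional[datetime] = None
    length_primary_mm: float = 0.0
    length_lateral_mm: float = 0.0
    length_total_mm: float = 0.0
    n_lateral: int = 0
    lateral_density_per_mm: Optional[float] = None
    branching_angle_deg: Optional[float] = None
    diam_primary_um: Optional[float] = None
    diam_lateral_um: Optional[float] = None
    depth_mm: float = 0.0
    width_mm: float = 0.0
    hull_area_mm2: float = 0.0
    root_length_density_mm_per_mm2: Optional[float] = None
    rgr_primary_pct_per_day: Optional[float] = None
    rgr_lateral_pct_per_day: Optional[float] = None
    rgr_total_pct_per_day: Optional[float] = None
    ratio_lateral_primary: Optional[float] = None
    ratio_primary_depth: Optional[float] = None
    leaf_area_mm2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("length_primary_mm", "length_lateral_mm", "length_total_mm"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = {"plant_id": self.plant_id, "capture_time": self.capture_time}
        for name in TRAIT_FIELDS:
            d[name] = getattr(self, name)
        return d


@dataclass
class DepthProfile:
    """Root length summed in fixed-width horizontal depth bins.

    Depths are measured downward from the root-system base (bin edge 0);
    ``bin_edges`` has one more entry than ``length_per_bin_mm``.
    """

    bin_width_mm: float
    bin_edges: np.ndarray
    length_per_bin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.length_per_bin_mm = np.asarray(self.length_per_bin_mm, dtype=float)
        if self.bin_width_mm <= 0:
            raise ValidationError("bin_width_mm must be positive")
        if self.bin_edges.size != self.length_per_bin_mm.size + 1:
            raise ValidationError("bin_edges must have len(length_per_bin) + 1 entries")
        if (self.length_per_bin_mm < -1e-12).any():
            raise ValidationError("bin lengths must be non-negative")

    def total_length_mm(self) -> float:
        return float(self.length_per_bin_mm.sum())
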