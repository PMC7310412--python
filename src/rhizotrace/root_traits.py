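"""Root-trait catalogue computed from :class:`~rhizotrace.plate_model.RootSystem` trees.

The trait set covers single-timepoint geometry (lengths, counts, branching
angle, diameters, depth/width, convex-hull area, root length per agar area,
length/depth ratios), the depth-binned root-length-density profile, and
between-timepoint relative growth rates (RGR, % per day, natural-log form).

Conventions
-----------
* "Lateral" traits count first-order laterals (axes branched from the
  primary); ``total_length`` sums *all* orders, including second-order
  laterals where present.  ``include_second_order_in_lateral`` switches the
  lateral-length definition if desired.
* The branching angle is measured between the parent's growth direction at
  the branch point and the chord from the branch point to the point 0.4 mm
  along the lateral, reported in [0°, 180°] (90° = perpendicular).
* System depth is measured from the topmost root vertex by default
  (``depth_reference="system_top"``); ``"seed_point"`` is available.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint

from .errors import GeometryError, ValidationError
from .plate_model import (
    DepthProfile,
    Polyline,
    RootAxis,
    RootSystem,
    TraitRecord,
    arc_length,
    point_at_arclength,
    tangent_at_arclength,
)

__all__ = [
    "TraitConfig",
    "primary_length",
    "lateral_length",
    "total_length",
    "lateral_count",
    "lateral_density",
    "branching_angle",
    "system_depth",
    "system_width",
    "convex_hull_area",
    "depth_profile",
    "root_length_per_area",
    "relative_growth_rate",
    "curvature_ratio",
    "compute_all_traits",
]


@dataclass
class TraitConfig:
    """Parameters of the trait catalogue (lengths in mm, areas in mm^2)."""

    angle_offset_mm: float = 0.4
    profile_bin_mm: float = 2.0
    agar_area_mm2: float = 120.0 * 120.0
    depth_reference: str = "system_top"  # or "seed_point"
    include_second_order_in_lateral: bool = False

    def __post_init__(self) -> None:
        if self.angle_offset_mm <= 0 or self.profile_bin_mm <= 0 or self.agar_area_mm2 <= 0:
            raise ValueError("TraitConfig values must be positive")
        if self.depth_reference not in ("system_top", "seed_point"):
            raise ValueError("depth_reference must be 'system_top' or 'seed_point'")


def primary_length(system: RootSystem) -> float:
    """Arc length of the order-0 axis (mm); 0 for an empty system."""
    if system.empty and not system.axes:
        return 0.0
    return system.primary().length_mm()


def lateral_length(system: RootSystem, cfg: Optional[TraitConfig] = None) -> float:
    """Summed arc length of first-order laterals (mm).

    Second-order laterals are excluded unless the config says otherwise.
    """
    cfg = cfg or TraitConfig()
    orders = (1, 2) if cfg.include_second_order_in_lateral else (1,)
    return float(sum(ax.length_mm() for ax in system.axes if ax.order in orders))


def total_length(system: RootSystem) -> float:
    """Summed arc length over all axes of all orders (mm)."""
    return float(sum(ax.length_mm() for ax in system.axes))


def lateral_count(system: RootSystem) -> int:
    """Number of first-order laterals branched from the primary."""
    return len(system.laterals(order=1))


def lateral_density(system: RootSystem) -> Optional[float]:
    """Laterals per mm of primary root; ``None`` when the primary has zero length."""
    lp = primary_length(system)
    if lp <= 0:
        return None
    return lateral_count(system) / lp


def branching_angle(system: RootSystem, axis: RootAxis, cfg: Optional[TraitConfig] = None) -> Optional[float]:
    """Initial branching angle of a lateral, in degrees within [0, 180].

    Angle between (a) the parent's tangent at the branch position, pointing
    in the parent's growth direction, and (b) the chord from the branch point
    to the point ``angle_offset_mm`` (default 0.4 mm) along the lateral.  For
    laterals shorter than the offset the full lateral chord is used.
    Returns ``None`` for a degenerate (< 1e-6 mm) chord.
    """
    cfg = cfg or TraitConfig()
    if axis.order < 1:
        raise ValidationError("branching angle is defined for laterals only")
    parent = system.axis(axis.parent_id)
    s = min(max(axis.branch_pos_mm, 0.0), parent.length_mm())
    tang = tangent_at_arclength(parent.path, s)
    branch_pt = point_at_arclength(parent.path, s)
    off = min(cfg.angle_offset_mm, axis.length_mm())
    tip = point_at_arclength(axis.path, off)
    chord = tip - branch_pt
    n = math.hypot(chord[0], chord[1])
    if n < 1e-6:
        return None
    cosang = float(np.clip((tang @ chord) / n, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _depth_origin(system: RootSystem, cfg: TraitConfig) -> float:
    verts = system.all_vertices()
    if cfg.depth_reference == "seed_point" or verts.size == 0:
        return float(system.seed_point[1])
    return float(verts[:, 1].min())


def system_depth(system: RootSystem, cfg: Optional[TraitConfig] = None) -> float:
    """Maximum vertical extent of the whole root system (mm)."""
    cfg = cfg or TraitConfig()
    verts = system.all_vertices()
    if verts.size == 0:
        return 0.0
    return float(verts[:, 1].max() - _depth_origin(system, cfg))


def system_width(system: RootSystem) -> float:
    """Maximum horizontal extent of the whole root system (mm)."""
    verts = system.all_vertices()
    if verts.size == 0:
        return 0.0
    return float(verts[:, 0].max() - verts[:, 0].min())


def convex_hull_area(system: RootSystem) -> float:
    """Area of the convex hull of all axis vertices (mm^2); 0 if degenerate."""
    verts = system.all_vertices()
    if verts.shape[0] < 3:
        return 0.0
    return float(MultiPoint(verts).convex_hull.area)


def depth_profile(system: RootSystem, cfg: Optional[TraitConfig] = None) -> DepthProfile:
    """Root length per fixed-width depth bin below the root-system base.

    Every axis polyline is clipped against the horizontal bin boundaries so
    each segment's length is distributed exactly; the bin sums therefore add
    up to the total root length.
    """
    cfg = cfg or TraitConfig()
    bw = cfg.profile_bin_mm
    verts = system.all_vertices()
    if verts.size == 0:
        return DepthProfile(bw, np.array([0.0, bw]), np.array([0.0]))
    y0 = _depth_origin(system, cfg)
    max_depth = max(float(verts[:, 1].max() - y0), 0.0)
    n_bins = max(int(math.floor((max_depth - 1e-9) / bw)) + 1, 1)
    edges = np.arange(n_bins + 1, dtype=float) * bw
    acc = np.zeros(n_bins)
    for ax in system.axes:
        v = ax.path.vertices
        for (x1, y1), (x2, y2) in zip(v[:-1], v[1:]):
            seg_len = math.hypot(x2 - x1, y2 - y1)
            if seg_len == 0:
                continue
            d1, d2 = y1 - y0, y2 - y0
            if abs(d2 - d1) < 1e-12:
                idx = min(int(math.floor(d1 / bw)), n_bins - 1)
                acc[max(idx, 0)] += seg_len
                continue
            lo, hi = sorted((d1, d2))
            first = int(math.floor(lo / bw))
            last = int(math.floor(min(hi / bw, n_bins - 1e-12)))
            for b in range(max(first, 0), min(last, n_bins - 1) + 1):
                blo, bhi = b * bw, (b + 1) * bw
                ylo, yhi = max(lo, blo), min(hi, bhi)
                if yhi > ylo:
                    acc[b] += seg_len * (yhi - ylo) / (hi - lo)
    return DepthProfile(bw, edges, acc)


def root_length_per_area(system: RootSystem, cfg: Optional[TraitConfig] = None) -> float:
    """Total root length divided by the agar surface area (mm per mm^2)."""
    cfg = cfg or TraitConfig()
    return total_length(system) / cfg.agar_area_mm2


def relative_growth_rate(length1_mm: float, length2_mm: float, t1, t2) -> float:
    """Classical relative growth rate: ``100 * (ln L2 - ln L1) / dt_days``.

    ``t1``/``t2`` may be datetimes or numeric day values; dt must be > 0.
    """
    if length1_mm <= 0 or length2_mm <= 0:
        raise GeometryError("relative growth rate needs positive lengths")
    if hasattr(t2, "total_seconds") or hasattr(t1, "timestamp"):
        dt_days = (t2 - t1).total_seconds() / 86400.0
    else:
        dt_days = float(t2) - float(t1)
    if dt_days <= 0:
        raise GeometryError("relative growth rate needs t2 > t1")
    return 100.0 * (math.log(length2_mm) - math.log(length1_mm)) / dt_days


def curvature_ratio(system: RootSystem, cfg: Optional[TraitConfig] = None) -> Optional[float]:
    """Primary root length divided by the primary axis' vertical extent.

    Equals 1 for a perfectly straight, vertical primary and grows above 1
    with bending.  Uses the primary's own vertical extent (not whole-system
    depth) so a deep lateral cannot push the ratio below 1; ``None`` when
    the primary has no vertical extent.
    """
    if system.empty and not system.axes:
        return None
    prim = system.primary()
    ys = prim.path.vertices[:, 1]
    extent = float(ys.max() - ys.min())
    if extent <= 0:
        return None
    return prim.length_mm() / extent


def _mean_branching_angle(system: RootSystem, cfg: TraitConfig) -> Optional[float]:
    angles = []
    for ax in system.laterals(order=1):
        a = branching_angle(system, ax, cfg)
        if a is not None:
            angles.append(a)
    return float(np.mean(angles)) if angles else None


def _lateral_diameter(system: RootSystem) -> Optional[float]:
    """Length-weighted mean diameter over first-order laterals (um)."""
    pairs = [(ax.length_mm(), ax.mean_diameter_um) for ax in system.laterals(order=1) if ax.mean_diameter_um is not None]
    if not pairs:
        return None
    w = np.array([p[0] for p in pairs])
    d = np.array([p[1] for p in pairs])
    if w.sum() <= 0:
        return float(d.mean())
    return float((w * d).sum() / w.sum())


def _instantaneous_record(system: RootSystem, cfg: TraitConfig) -> TraitRecord:
    lp = primary_length(system)
    ll = lateral_length(system, cfg)
    lt = total_length(system)
    nl = lateral_count(system)
    depth = system_depth(system, cfg)
    prim_diam = None
    if system.axes:
        prim_diam = system.primary().mean_diameter_um
    return TraitRecord(
        plant_id=system.plant_id,
        capture_time=system.capture_time,
        length_primary_mm=lp,
        length_lateral_mm=ll,
        length_total_mm=lt,
        n_lateral=nl,
        lateral_density_per_mm=(nl / lp) if lp > 0 else None,
        branching_angle_deg=_mean_branching_angle(system, cfg),
        diam_primary_um=prim_diam,
        diam_lateral_um=_lateral_diameter(system),
        depth_mm=depth,
        width_mm=system_width(system),
        hull_area_mm2=convex_hull_area(system),
        root_length_density_mm_per_mm2=root_length_per_area(system, cfg),
        ratio_lateral_primary=(ll / lp) if lp > 0 else None,
        ratio_primary_depth=curvature_ratio(system, cfg),
    )


def compute_all_traits(systems: Sequence[RootSystem], cfg: Optional[TraitConfig] = None) -> list[TraitRecord]:
    """Full trait catalogue for one plant's time series of root systems.

    One :class:`TraitRecord` per timepoint; the three relative growth rates
    are computed between consecutive timepoints (unset at the first one, and
    whenever the earlier length is zero).
    """
    cfg = cfg or TraitConfig()
    if not systems:
        return []
    if len({s.plant_id for s in systems}) != 1:
        raise ValidationError("compute_all_traits expects a single plant's series")
    times = [s.capture_time for s in systems]
    if len(systems) > 1:
        if any(t is None for t in times):
            raise ValidationError("time series requires capture_time on every system")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("capture times must be strictly increasing (no duplicates)")
    records = [_instantaneous_record(s, cfg) for s in systems]
    for prev_sys, prev, cur_sys, cur in zip(systems, records, systems[1:], records[1:]):
        t1, t2 = prev_sys.capture_time, cur_sys.capture_time
        for field_name, getter in (
            ("rgr_primary_pct_per_day", "length_primary_mm"),
            ("rgr_lateral_pct_per_day", "length_lateral_mm"),
            ("rgr_total_pct_per_day", "length_total_mm"),
        ):
            l1, l2 = getattr(prev, getter), getattr(cur, getter)
            if l1 > 0 and l2 > 0:
                setattr(cur, field_name, relative_growth_rate(l1, l2, t1, t2))
    return records
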