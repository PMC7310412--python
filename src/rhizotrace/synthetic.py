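"""Ground-truthed synthetic root systems, growth series and plate images.

The generator produces everything needed to test the pipeline without real
data: root systems grown by a downward-biased random walk with Poisson
lateral initiation, nested growth series (later timepoints geometrically
extend earlier ones), rendered grayscale plate images with optional
condensation-droplet and scratch artifacts, calibration-rod images with a
truth table, and top-view shoot images of lobed green rosettes with analytic
truth areas.

Growth model
------------
The primary root starts at the sowing position heading straight down and
elongates at a constant rate; at each 0.5 mm step its heading receives a
Gaussian perturbation (sd ``curvature_sd_deg_per_mm`` x sqrt(step)) plus a
weak restoring pull toward vertical (gravitropism).  Lateral initiation is a
Poisson process along the primary (``lateral_rate_per_mm``); a lateral
appears when the primary tip passes its position, departs at a signed angle
~ Normal(mean, sd) from the local parent tangent, and elongates straight at
``lateral_rate_mm_per_day``.  Growth stops at the plate walls.

All randomness flows through one explicitly passed ``numpy.random.Generator``;
identical seed and parameters give bit-identical systems and images.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .image_io import ColorImage, GrayImage
from .plate_model import PlateImageMeta, Polyline, RootAxis, RootSystem, View

__all__ = [
    "GrowthParams",
    "RenderParams",
    "RenderedPlate",
    "RenderedShoot",
    "GROWTH_PRESETS",
    "sample_root_system",
    "sample_growth_series",
    "sample_plate",
    "render_root_image",
    "make_calibration_rods",
    "render_shoot_image",
]

_EPOCH = datetime(2020, 6, 1, 10, 0, 0)


@dataclass
class GrowthParams:
    """Parameters of the synthetic growth model (defaults: a typical
    *Arabidopsis* seedling on a 12 x 12 cm plate over three weeks)."""

    primary_rate_mm_per_day: float = 3.0
    curvature_sd_deg_per_mm: float = 5.0
    lateral_rate_per_mm: float = 0.4
    branch_angle_mean_deg: float = 53.0
    branch_angle_sd_deg: float = 8.0
    lateral_rate_mm_per_day: float = 1.0
    second_order_rate_per_mm: float = 0.0
    duration_days: float = 21.0
    imaging_interval_days: float = 7.0
    plants_per_plate: int = 1
    plate_mm: float = 120.0
    seed_depth_mm: float = 5.0
    step_mm: float = 0.5
    gravitropism: float = 0.05  # heading pull toward vertical per step

    def __post_init__(self) -> None:
        for name in (
            "primary_rate_mm_per_day",
            "lateral_rate_per_mm",
            "lateral_rate_mm_per_day",
            "second_order_rate_per_mm",
            "curvature_sd_deg_per_mm",
            "branch_angle_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.plants_per_plate <= 4):
            raise ValueError("plants_per_plate must be in 1..4")
        if self.imaging_interval_days > self.duration_days:
            raise ValueError("imaging interval must not exceed the experiment duration")


@dataclass
class _Lateral:
    arc_pos_mm: float  # position on parent where it attaches
    t_init_days: float
    angle_deg: float  # signed departure angle from the parent tangent
    children: list = field(default_factory=list)


@dataclass
class _Plan:
    """Whole-experiment growth plan; materialised by truncation at any t."""

    params: GrowthParams
    seed_xy: np.ndarray
    vertices: np.ndarray  # primary polyline out to the full duration
    cum: np.ndarray  # cumulative arc length at each vertex
    laterals: list[_Lateral]


def _clip_point(p: np.ndarray, plate: float, margin: float = 0.5) -> bool:
    return bool(margin <= p[0] <= plate - margin and margin <= p[1] <= plate - margin)


def _plan_plant(p: GrowthParams, seed_xy: np.ndarray, rng: np.random.Generator) -> _Plan:
    max_len = p.primary_rate_mm_per_day * p.duration_days
    n_steps = int(math.ceil(max_len / p.step_mm)) if max_len > 0 else 0
    heading = 90.0  # degrees; 90 = straight down (+y)
    pts = [seed_xy.copy()]
    sd_step = p.curvature_sd_deg_per_mm * math.sqrt(p.step_mm)
    for _ in range(n_steps):
        heading = heading + p.gravitropism * (90.0 - heading) + float(rng.normal(0.0, sd_step))
        th = math.radians(heading)
        nxt = pts[-1] + p.step_mm * np.array([math.cos(th), math.sin(th)])
        if not _clip_point(nxt, p.plate_mm):
            break
        pts.append(nxt)
    vertices = np.array(pts)
    seg = np.hypot(*np.diff(vertices, axis=0).T) if len(vertices) > 1 else np.array([])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    laterals: list[_Lateral] = []
    if p.lateral_rate_per_mm > 0 and total > 0:
        n_lat = rng.poisson(p.lateral_rate_per_mm * total)
        positions = np.sort(rng.uniform(0.0, total, size=n_lat))
        for s in positions:
            lat = _Lateral(
                arc_pos_mm=float(s),
                t_init_days=float(s) / p.primary_rate_mm_per_day,
                angle_deg=float(rng.choice([-1.0, 1.0]) * rng.normal(p.branch_angle_mean_deg, p.branch_angle_sd_deg)),
            )
            if p.second_order_rate_per_mm > 0:
                max_lat_len = p.lateral_rate_mm_per_day * (p.duration_days - lat.t_init_days)
                n2 = rng.poisson(p.second_order_rate_per_mm * max(max_lat_len, 0.0))
                for s2 in np.sort(rng.uniform(0.0, max(max_lat_len, 1e-9), size=n2)):
                    lat.children.append(
                        _Lateral(
                            arc_pos_mm=float(s2),
                            t_init_days=lat.t_init_days + float(s2) / p.lateral_rate_mm_per_day,
                            angle_deg=float(
                                rng.choice([-1.0, 1.0]) * rng.normal(p.branch_angle_mean_deg, p.branch_angle_sd_deg)
                            ),
                        )
                    )
            laterals.append(lat)
    return _Plan(params=p, seed_xy=seed_xy, vertices=vertices, cum=cum, laterals=laterals)


def _truncate_path(vertices: np.ndarray, cum: np.ndarray, length: float) -> np.ndarray:
    """First ``length`` mm of a polyline (>= 2 vertices guaranteed by caller)."""
    length = min(length, float(cum[-1]))
    i = int(np.searchsorted(cum, length, side="right")) - 1
    i = min(i, len(cum) - 2)
    out = [vertices[: i + 1]]
    seg = cum[i + 1] - cum[i]
    t = 1.0 if seg == 0 else (length - cum[i]) / seg
    out.append((vertices[i] + t * (vertices[i + 1] - vertices[i]))[None, :])
    return np.vstack(out)


def _tangent_at(vertices: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(cum, min(s, cum[-1]), side="right")) - 1
    i = min(max(i, 0), len(cum) - 2)
    d = vertices[i + 1] - vertices[i]
    return d / np.hypot(*d)


def _point_at(vertices: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(cum, min(s, cum[-1]), side="right")) - 1
    i = min(max(i, 0), len(cum) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (min(s, cum[-1]) - cum[i]) / seg
    return vertices[i] + t * (vertices[i + 1] - vertices[i])


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array(
        [v[0] * math.cos(th) - v[1] * math.sin(th), v[0] * math.sin(th) + v[1] * math.cos(th)]
    )


def _materialize(plan: _Plan, t_days: float, plant_id: str, plate_id: str) -> RootSystem:
    p = plan.params
    lp = min(p.primary_rate_mm_per_day * t_days, float(plan.cum[-1]))
    capture = _EPOCH + timedelta(days=t_days)
    if lp <= 0 or len(plan.vertices) < 2:
        return RootSystem(plant_id, plate_id, tuple(plan.seed_xy), axes=[], capture_time=capture, empty=True)
    prim_path = _truncate_path(plan.vertices, plan.cum, lp)
    axes = [RootAxis(axis_id=f"{plant_id}.000", order=0, path=Polyline(prim_path))]
    n = 0
    for lat in plan.laterals:
        if lat.arc_pos_mm > lp or lat.t_init_days >= t_days:
            continue
        llen = p.lateral_rate_mm_per_day * (t_days - lat.t_init_days)
        if llen < 1e-6:
            continue
        bp = _point_at(plan.vertices, plan.cum, lat.arc_pos_mm)
        direction = _rotate(_tangent_at(plan.vertices, plan.cum, lat.arc_pos_mm), lat.angle_deg)
        # shorten at plate walls
        end = bp + direction * llen
        scale = 1.0
        for dim in (0, 1):
            if direction[dim] != 0:
                for bound in (0.5, p.plate_mm - 0.5):
                    s_hit = (bound - bp[dim]) / (direction[dim] * llen)
                    if 0 < s_hit < scale and not _clip_point(bp + direction * llen * (s_hit + 1e-9), p.plate_mm):
                        scale = s_hit
        llen_eff = llen * scale
        if llen_eff < 1e-6:
            continue
        n += 1
        lat_id = f"{plant_id}.{n:03d}"
        lat_verts = np.vstack([bp, bp + direction * llen_eff])
        axes.append(
            RootAxis(
                axis_id=lat_id,
                order=1,
                path=Polyline(lat_verts),
                parent_id=f"{plant_id}.000",
                branch_pos_mm=lat.arc_pos_mm,
            )
        )
        lat_cum = np.array([0.0, llen_eff])
        for child in lat.children:
            if child.arc_pos_mm > llen_eff or child.t_init_days >= t_days:
                continue
            clen = p.lateral_rate_mm_per_day * (t_days - child.t_init_days) * 0.7
            if clen < 1e-6:
                continue
            cbp = _point_at(lat_verts, lat_cum, child.arc_pos_mm)
            cdir = _rotate(direction, child.angle_deg)
            cend = cbp + cdir * clen
            if not _clip_point(cend, p.plate_mm):
                continue
            n += 1
            axes.append(
                RootAxis(
                    axis_id=f"{plant_id}.{n:03d}",
                    order=2,
                    path=Polyline(np.vstack([cbp, cend])),
                    parent_id=lat_id,
                    branch_pos_mm=child.arc_pos_mm,
                )
            )
    system = RootSystem(plant_id, plate_id, tuple(plan.seed_xy), axes=axes, capture_time=capture)
    system.validate()
    return system


def sample_root_system(
    p: GrowthParams,
    t_days: float,
    rng: np.random.Generator,
    plant_id: str = "plant1",
    plate_id: str = "P01",
    seed_xy: Optional[Sequence[float]] = None,
) -> RootSystem:
    """One synthetic root system at age ``t_days`` (deterministic given rng state)."""
    if t_days > p.duration_days + 1e-9:
        raise ValueError("t_days exceeds the experiment duration")
    if seed_xy is None:
        seed_xy = np.array([p.plate_mm / 2.0, p.seed_depth_mm])
    plan = _plan_plant(p, np.asarray(seed_xy, dtype=float), rng)
    return _materialize(plan, t_days, plant_id, plate_id)


def sample_growth_series(
    p: GrowthParams,
    rng: np.random.Generator,
    plant_id: str = "plant1",
    plate_id: str = "P01",
    seed_xy: Optional[Sequence[float]] = None,
) -> list[RootSystem]:
    """Nested monotone time series: each timepoint extends the previous one."""
    if seed_xy is None:
        seed_xy = np.array([p.plate_mm / 2.0, p.seed_depth_mm])
    plan = _plan_plant(p, np.asarray(seed_xy, dtype=float), rng)
    n_frames = int(math.floor(p.duration_days / p.imaging_interval_days + 1e-9))
    times = [p.imaging_interval_days * (i + 1) for i in range(max(n_frames, 1))]
    return [_materialize(plan, t, plant_id, plate_id) for t in times]


def plant_positions(p: GrowthParams) -> list[float]:
    """Evenly distributed sowing-hole x-coordinates along the top edge."""
    n = p.plants_per_plate
    return [p.plate_mm * (i + 1) / (n + 1) for i in range(n)]


def sample_plate(
    p: GrowthParams, t_days: float, rng: np.random.Generator, plate_id: str = "P01"
) -> list[RootSystem]:
    """Up to four plants on one plate, seeded at evenly spaced holes."""
    return [
        sample_root_system(p, t_days, rng, plant_id=f"{plate_id}_p{i + 1}", plate_id=plate_id, seed_xy=(x, p.seed_depth_mm))
        for i, x in enumerate(plant_positions(p))
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderParams:
    """Appearance of rendered plate images."""

    px_scale_um: float = 39.0
    plate_mm: float = 120.0
    root_intensity: float = 200.0
    primary_width_px: float = 4.0
    lateral_width_px: float = 2.5
    background_level: float = 20.0
    noise_sd: float = 3.0
    droplet_count: int = 0
    droplet_radius_mm: tuple[float, float] = (0.5, 1.5)
    droplet_intensity: float = 120.0
    droplet_clearance_mm: float = 0.0  # if > 0, droplets avoid roots by this margin
    scratch_count: int = 0
    scratch_len_mm: float = 10.0
    scratch_intensity: float = 60.0
    # shoot rendering
    shoot_px_scale_um: float = 83.0
    lobe_amplitude: float = 0.12
    lobe_count: int = 8

    def __post_init__(self) -> None:
        if min(self.primary_width_px, self.lateral_width_px) < 1:
            raise ValueError("stroke widths must be >= 1 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RenderedPlate:
    image: GrayImage
    truth_mask: np.ndarray
    artifacts: list[dict]


@dataclass
class RenderedShoot:
    image: ColorImage
    truth_mask: np.ndarray
    truth_areas_mm2: list[float]
    truth_total_mm2: float


def _resample(path: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.hypot(*np.diff(path, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return path[:1]
    svals = np.arange(0.0, total, spacing)
    svals = np.append(svals, total)
    idx = np.clip(np.searchsorted(cum, svals, side="right") - 1, 0, len(cum) - 2)
    segl = np.where(seg[idx] == 0, 1.0, seg[idx])
    t = (svals - cum[idx]) / segl
    return path[idx] + t[:, None] * (path[idx + 1] - path[idx])


def _stamp(alpha: np.ndarray, centers: np.ndarray, width_px: float, value: float = 1.0) -> None:
    """Max-composite anti-aliased disks of diameter ``width_px`` at float centres (row, col)."""
    if len(centers) == 0:
        return
    h, w = alpha.shape
    radius = int(math.ceil(width_px / 2.0 + 1.0))
    cr, cc = centers[:, 0], centers[:, 1]
    br, bc = np.round(cr).astype(int), np.round(cc).astype(int)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr, cc2 = br + dr, bc + dc
            d = np.hypot(rr - cr, cc2 - cc)
            a = np.clip(width_px / 2.0 + 0.5 - d, 0.0, 1.0) * value
            ok = (rr >= 0) & (rr < h) & (cc2 >= 0) & (cc2 < w) & (a > 0)
            if ok.any():
                np.maximum.at(alpha, (rr[ok], cc2[ok]), a[ok])


def _axis_samples_px(ax: RootAxis, scale_mm: float) -> np.ndarray:
    path_px = ax.path.vertices[:, ::-1] / scale_mm  # (x, y) mm -> (row, col) px
    return _resample(path_px, spacing=0.4)


def render_root_image(
    systems: Sequence[RootSystem],
    r: RenderParams,
    rng: np.random.Generator,
    plate_id: str = "P01",
    capture_time: Optional[datetime] = None,
) -> RenderedPlate:
    """Render root systems as bright anti-aliased strokes on a dark plate.

    Returns the 8-bit grayscale image, the paired ground-truth mask (stroke
    coverage >= 0.5) and the artifact metadata (droplet rings, scratches).
    """
    scale_mm = r.px_scale_um / 1000.0
    size = int(round(r.plate_mm / scale_mm))
    alpha = np.zeros((size, size))
    root_samples = []
    for system in systems:
        for ax in system.axes:
            width = r.primary_width_px if ax.order == 0 else r.lateral_width_px * (0.8 if ax.order >= 2 else 1.0)
            pts = _axis_samples_px(ax, scale_mm)
            _stamp(alpha, pts, width)
            root_samples.append(pts)
    truth_mask = alpha >= 0.5
    root_pts = np.vstack(root_samples) if root_samples else np.empty((0, 2))

    artifact_alpha = np.zeros_like(alpha)
    artifacts: list[dict] = []
    for _ in range(r.droplet_count):
        rad_mm = float(rng.uniform(*r.droplet_radius_mm))
        rad_px = rad_mm / scale_mm
        for _try in range(100):
            center = rng.uniform(rad_px + 2, size - rad_px - 2, size=2)
            if r.droplet_clearance_mm <= 0 or len(root_pts) == 0:
                break
            clearance_px = (rad_mm + r.droplet_clearance_mm) / scale_mm
            if np.hypot(*(root_pts - center).T).min() > clearance_px:
                break
        th = np.linspace(0.0, 2.0 * math.pi, max(int(2.0 * math.pi * rad_px), 12), endpoint=False)
        ring = np.column_stack([center[0] + rad_px * np.sin(th), center[1] + rad_px * np.cos(th)])
        _stamp(artifact_alpha, ring, 1.5, value=r.droplet_intensity / max(r.root_intensity, 1.0))
        artifacts.append({"kind": "droplet", "center_px": tuple(center), "radius_mm": rad_mm})
    for _ in range(r.scratch_count):
        p0 = rng.uniform(2, size - 2, size=2)
        ang = rng.uniform(0, math.pi)
        length_px = r.scratch_len_mm / scale_mm
        p1 = np.clip(p0 + length_px * np.array([math.sin(ang), math.cos(ang)]), 2, size - 2)
        pts = _resample(np.vstack([p0, p1]), 0.4)
        _stamp(artifact_alpha, pts, 1.0, value=r.scratch_intensity / max(r.root_intensity, 1.0))
        artifacts.append({"kind": "scratch", "p0_px": tuple(p0), "p1_px": tuple(p1)})

    combined = np.maximum(alpha, artifact_alpha)
    img = r.background_level + combined * (r.root_intensity - r.background_level)
    if r.noise_sd > 0:
        img = img + rng.normal(0.0, r.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    meta = PlateImageMeta(
        plate_id=plate_id,
        view=View.ROOT,
        capture_time=capture_time or (systems[0].capture_time if systems else None),
        plant_positions=tuple(float(s.seed_point[0]) for s in systems),
        px_scale=r.px_scale_um,
        image_width_px=size,
        image_height_px=size,
    )
    return RenderedPlate(GrayImage(pixels, meta), truth_mask, artifacts)


def make_calibration_rods(
    lengths_mm: Sequence[float], r: RenderParams, rng: np.random.Generator
):
    """Straight reference rods of known lengths, one image per rod.

    Emulates the metal-rod accuracy check: returns the rendered plates, the
    underlying single-axis root systems, and a truth table (pandas DataFrame
    with the exact lengths and orientations).
    """
    import pandas as pd

    plates, systems, rows = [], [], []
    for i, length in enumerate(lengths_mm):
        if length <= 0 or length > r.plate_mm - 4:
            raise ValueError(f"rod length {length} does not fit the plate")
        ang = float(rng.uniform(0.0, 180.0))
        th = math.radians(ang)
        d = np.array([math.cos(th), abs(math.sin(th))])  # keep the rod heading downward
        center = np.array([r.plate_mm / 2.0, r.plate_mm / 2.0])
        a, b = center - d * length / 2.0, center + d * length / 2.0
        system = RootSystem(
            plant_id=f"rod{i + 1:02d}",
            plate_id=f"ROD{i + 1:02d}",
            seed_point=tuple(a),
            axes=[RootAxis(axis_id=f"rod{i + 1:02d}.000", order=0, path=Polyline(np.vstack([a, b])))],
            capture_time=_EPOCH,
        )
        plates.append(render_root_image([system], r, rng, plate_id=system.plate_id))
        systems.append(system)
        rows.append({"rod_id": system.plant_id, "length_mm": float(length), "angle_deg": ang})
    return plates, systems, pd.DataFrame(rows)


def render_shoot_image(
    rosette_radii_mm: Sequence[float],
    r: RenderParams,
    rng: np.random.Generator,
    plate_id: str = "P01",
) -> RenderedShoot:
    """Top-view colour image of lobed green rosettes on a dark background.

    The rosette boundary is ``rho(theta) = r0 (1 + a cos(k theta + phi))``
    with lobe amplitude ``a`` and ``k`` lobes; its exact area is
    ``pi r0^2 (1 + a^2/2)``, which is returned as the per-plant truth.  The
    whole-plate truth is the analytic sum when the rosettes do not overlap,
    otherwise the polygon-union area.
    """
    scale_mm = r.shoot_px_scale_um / 1000.0
    size = int(round(r.plate_mm / scale_mm))
    n = len(rosette_radii_mm)
    xs = [r.plate_mm * (i + 1) / (n + 1) for i in range(n)]
    y = r.plate_mm / 2.0
    mask = np.zeros((size, size), dtype=bool)
    rgb = np.zeros((size, size, 3), dtype=float)
    rgb[:] = (25.0, 25.0, 25.0)
    a = r.lobe_amplitude
    truth_areas = []
    boundaries = []
    for x0, r0 in zip(xs, rosette_radii_mm):
        truth_areas.append(math.pi * r0**2 * (1.0 + a**2 / 2.0) if r0 > 0 else 0.0)
        if r0 <= 0:
            continue
        phi = float(rng.uniform(0.0, 2.0 * math.pi))
        rmax_px = r0 * (1.0 + abs(a)) / scale_mm
        cr, cc = y / scale_mm, x0 / scale_mm
        r_lo = max(int(cr - rmax_px) - 1, 0)
        r_hi = min(int(cr + rmax_px) + 2, size)
        c_lo = max(int(cc - rmax_px) - 1, 0)
        c_hi = min(int(cc + rmax_px) + 2, size)
        rr, cc2 = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dy, dx = rr - cr, cc2 - cc
        dist = np.hypot(dx, dy) * scale_mm
        theta = np.arctan2(dy, dx)
        rho = r0 * (1.0 + a * np.cos(r.lobe_count * theta + phi))
        inside = dist <= rho
        mask[r_lo:r_hi, c_lo:c_hi] |= inside
        # greenish leaf colour with mild radial shading
        shade = 1.0 - 0.3 * np.clip(dist / max(r0, 1e-9), 0.0, 1.0)
        block = rgb[r_lo:r_hi, c_lo:c_hi]
        block[inside] = np.column_stack(
            [40.0 * shade[inside], 180.0 * shade[inside], 60.0 * shade[inside]]
        )
        th_samp = np.linspace(0.0, 2.0 * math.pi, 1024, endpoint=False)
        rho_s = r0 * (1.0 + a * np.cos(r.lobe_count * th_samp + phi))
        boundaries.append(np.column_stack([x0 + rho_s * np.cos(th_samp), y + rho_s * np.sin(th_samp)]))
    # whole-plate truth: analytic sum unless shapes overlap
    truth_total = float(sum(truth_areas))
    if len(boundaries) > 1:
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        polys = [Polygon(b) for b in boundaries]
        if any(p1.intersects(p2) for i, p1 in enumerate(polys) for p2 in polys[i + 1 :]):
            truth_total = float(unary_union(polys).area)
    if r.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, r.noise_sd, size=rgb.shape)
    pixels = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    meta = PlateImageMeta(
        plate_id=plate_id,
        view=View.SHOOT,
        plant_positions=tuple(xs),
        px_scale=r.shoot_px_scale_um,
        image_width_px=size,
        image_height_px=size,
    )
    return RenderedShoot(ColorImage(pixels, meta), mask, truth_areas, truth_total)


def prune_immature(system: RootSystem, min_lateral_mm: float = 1.0) -> RootSystem:
    """Copy of a system without laterals shorter than ``min_lateral_mm``.

    Useful for building fixtures in the well-separated regime where every
    lateral is long enough to be resolvable; children of removed axes are
    removed too.
    """
    keep = {ax.axis_id for ax in system.axes if ax.order == 0 or ax.length_mm() >= min_lateral_mm}
    changed = True
    while changed:
        changed = False
        for ax in system.axes:
            if ax.axis_id in keep and ax.parent_id is not None and ax.parent_id not in keep:
                keep.discard(ax.axis_id)
                changed = True
    out = RootSystem(
        plant_id=system.plant_id,
        plate_id=system.plate_id,
        seed_point=system.seed_point,
        axes=[ax for ax in system.axes if ax.axis_id in keep],
        capture_time=system.capture_time,
        empty=system.empty,
    )
    return out


#: Phenomenology presets: shoots grown inside the sealed plate develop
#: slower, denser-branching, wider-angled root systems than shoots grown
#: through the lid.
GROWTH_PRESETS = {
    "shoot_outside": GrowthParams(
        primary_rate_mm_per_day=3.0,
        lateral_rate_per_mm=0.4,
        branch_angle_mean_deg=53.0,
    ),
    "shoot_inside": GrowthParams(
        primary_rate_mm_per_day=1.25,
        lateral_rate_per_mm=0.72,
        branch_angle_mean_deg=63.0,
        curvature_sd_deg_per_mm=9.0,
        second_order_rate_per_mm=0.05,
    ),
}
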