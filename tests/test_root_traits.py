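"""Trait catalogue: lengths, angles, extents, hull, profiles, growth rates."""
import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from rhizotrace.errors import GeometryError, ValidationError
from rhizotrace.plate_model import Polyline, RootAxis, RootSystem
from rhizotrace.root_traits import (
    TraitConfig,
    branching_angle,
    compute_all_traits,
    convex_hull_area,
    curvature_ratio,
    depth_profile,
    lateral_count,
    lateral_density,
    lateral_length,
    primary_length,
    relative_growth_rate,
    root_length_per_area,
    system_depth,
    system_width,
    total_length,
)
from rhizotrace.synthetic import GrowthParams, sample_growth_series, sample_root_system

from conftest import make_tree


def random_tree(seed, **kw):
    rng = np.random.default_rng(seed)
    p = GrowthParams(plate_mm=60, duration_days=10, imaging_interval_days=10, lateral_rate_per_mm=0.4, **kw)
    return sample_root_system(p, 10.0, rng)


class TestLengthTraits:
    def test_fixture_lengths(self):
        sys_ = make_tree(primary_len=10.0, laterals=((3.0, 2.0, 90.0), (6.0, 3.0, -90.0)))
        assert primary_length(sys_) == pytest.approx(10.0)
        assert lateral_length(sys_) == pytest.approx(5.0)
        assert total_length(sys_) == pytest.approx(15.0)
        assert lateral_count(sys_) == 2
        assert lateral_density(sys_) == pytest.approx(0.2)

    def test_no_laterals(self):
        sys_ = make_tree(laterals=())
        assert lateral_length(sys_) == 0.0
        assert total_length(sys_) == primary_length(sys_)
        assert lateral_density(sys_) == 0.0

    def test_randomized_tree_matches_axis_walk_oracle(self):
        sys_ = random_tree(3, second_order_rate_per_mm=0.15)
        # oracle: independent walk over every axis summing pairwise distances
        def oracle_len(ax):
            v = ax.path.vertices
            return sum(math.dist(a, b) for a, b in zip(v[:-1], v[1:]))

        assert total_length(sys_) == pytest.approx(sum(oracle_len(a) for a in sys_.axes), abs=1e-9)
        assert lateral_length(sys_) == pytest.approx(
            sum(oracle_len(a) for a in sys_.axes if a.order == 1), abs=1e-9
        )
        assert lateral_count(sys_) == sum(1 for a in sys_.axes if a.order == 1)
        assert lateral_density(sys_) == pytest.approx(lateral_count(sys_) / primary_length(sys_))

    def test_second_order_excluded_by_default_included_on_request(self):
        sys_ = random_tree(5, second_order_rate_per_mm=0.3)
        assert any(ax.order == 2 for ax in sys_.axes)
        strict = lateral_length(sys_)
        loose = lateral_length(sys_, TraitConfig(include_second_order_in_lateral=True))
        second = sum(a.length_mm() for a in sys_.axes if a.order == 2)
        assert loose == pytest.approx(strict + second, abs=1e-9)


class TestBranchingAngle:
    def test_perpendicular_lateral(self):
        sys_ = make_tree(laterals=((5.0, 2.0, 90.0),))
        assert branching_angle(sys_, sys_.laterals()[0]) == pytest.approx(90.0, abs=1e-9)

    def test_45_degree_lateral(self):
        sys_ = make_tree(laterals=((5.0, 2.0, 45.0),))
        assert branching_angle(sys_, sys_.laterals()[0]) == pytest.approx(45.0, abs=1e-9)

    def test_quarter_circle_lateral_matches_chord_oracle(self):
        # lateral curving along a quarter circle of radius 0.5 mm from (0, 5)
        r = 0.5
        theta = np.linspace(0, math.pi / 2, 200)
        # starts heading +x, curls downward; center at (0, 5 + r)
        pts = np.column_stack([r * np.sin(theta), 5.0 + r * (1 - np.cos(theta))])
        axes = [
            RootAxis("p.000", 0, Polyline([(0, 0), (0, 10)])),
            RootAxis("p.001", 1, Polyline(pts), parent_id="p.000", branch_pos_mm=5.0),
        ]
        sys_ = RootSystem("p", "P", (0, 0), axes)
        got = branching_angle(sys_, sys_.axes[1])
        # oracle: dense resampling + cumulative-length bisection for the 0.4 mm point
        seg = np.hypot(*np.diff(pts, axis=0).T)
        cum = np.concatenate([[0], np.cumsum(seg)])
        i = np.searchsorted(cum, 0.4)
        chord = pts[i] - pts[0]
        expected = math.degrees(math.acos(chord @ np.array([0, 1]) / np.hypot(*chord)))
        assert got == pytest.approx(expected, abs=0.5)

    def test_angle_within_0_180_and_mirror_symmetric(self):
        sys_ = random_tree(11)
        from rhizotrace.plate_model import RootSystem as RS
        from dataclasses import replace

        mirrored = RS(
            sys_.plant_id,
            sys_.plate_id,
            (-sys_.seed_point[0], sys_.seed_point[1]),
            [replace(ax, path=Polyline(ax.path.vertices * np.array([-1, 1]))) for ax in sys_.axes],
            capture_time=sys_.capture_time,
        )
        for ax, axm in zip(sys_.laterals(), mirrored.laterals()):
            a = branching_angle(sys_, ax)
            am = branching_angle(mirrored, axm)
            assert 0.0 <= a <= 180.0
            assert am == pytest.approx(a, abs=1e-9)

    def test_short_lateral_uses_full_chord(self):
        sys_ = make_tree(laterals=((5.0, 0.2, 60.0),))  # shorter than the 0.4 mm offset
        assert branching_angle(sys_, sys_.laterals()[0]) == pytest.approx(60.0, abs=1e-9)


class TestExtents:
    def test_vertical_primary(self):
        sys_ = make_tree(laterals=())
        assert system_depth(sys_) == pytest.approx(10.0)
        assert system_width(sys_) == pytest.approx(0.0)

    def test_t_shape_width(self):
        sys_ = make_tree(primary_len=10.0, laterals=((5.0, 4.0, 90.0), (5.0001, 4.0, -90.0)))
        assert system_width(sys_) == pytest.approx(8.0, abs=1e-6)

    def test_random_tree_matches_vertex_scan_oracle(self):
        sys_ = random_tree(13)
        verts = np.vstack([ax.path.vertices for ax in sys_.axes])
        assert system_width(sys_) == pytest.approx(verts[:, 0].max() - verts[:, 0].min())
        assert system_depth(sys_) == pytest.approx(verts[:, 1].max() - verts[:, 1].min())
        assert system_depth(sys_, TraitConfig(depth_reference="seed_point")) == pytest.approx(
            verts[:, 1].max() - sys_.seed_point[1]
        )


def brute_force_hull_area(points):
    """O(n^3) oracle: a point is a hull vertex iff it is not strictly inside
    any triangle of other points; area by the shoelace formula on the sorted
    hull vertices."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    hull = []
    for p in pts:
        inside = False
        for a in pts:
            for b in pts:
                for c in pts:
                    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
                    if (d1 > 1e-12 and d2 > 1e-12 and d3 > 1e-12) or (
                        d1 < -1e-12 and d2 < -1e-12 and d3 < -1e-12
                    ):
                        inside = True
        if not inside:
            hull.append(p)
    if len(hull) < 3:
        return 0.0
    hull = np.array(hull)
    center = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - center[1], hull[:, 0] - center[0]))
    h = hull[order]
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestConvexHull:
    def test_unit_square(self):
        axes = [RootAxis("a", 0, Polyline([(0, 0), (0, 1), (1, 1), (1, 0)]))]
        assert convex_hull_area(RootSystem("p", "P", (0, 0), axes)) == pytest.approx(1.0)

    def test_collinear_points(self):
        axes = [RootAxis("a", 0, Polyline([(0, 0), (1, 1), (2, 2), (3, 3)]))]
        assert convex_hull_area(RootSystem("p", "P", (0, 0), axes)) == 0.0

    def test_12_random_points_match_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(12, 2))
        axes = [RootAxis("a", 0, Polyline(pts))]
        got = convex_hull_area(RootSystem("p", "P", tuple(pts[0]), axes))
        assert got == pytest.approx(brute_force_hull_area(pts), rel=1e-9)

    def test_hull_contains_every_vertex(self):
        from shapely.geometry import MultiPoint, Point

        sys_ = random_tree(17)
        verts = np.vstack([ax.path.vertices for ax in sys_.axes])
        hull = MultiPoint(verts).convex_hull
        assert all(hull.buffer(1e-9).contains(Point(v)) for v in verts)


class TestDepthProfile:
    def test_vertical_primary_five_even_bins(self):
        sys_ = make_tree(laterals=())
        prof = depth_profile(sys_, TraitConfig(profile_bin_mm=2.0))
        assert prof.length_per_bin_mm == pytest.approx([2.0] * 5)

    def test_horizontal_lateral_lands_in_one_bin(self):
        sys_ = make_tree(primary_len=10.0, laterals=((3.0, 4.0, 90.0),))
        prof = depth_profile(sys_, TraitConfig(profile_bin_mm=2.0))
        assert prof.length_per_bin_mm[1] == pytest.approx(4.0 + 2.0)  # lateral + primary share [2,4)

    def test_conservation_and_fine_resampling_oracle(self):
        sys_ = random_tree(19, second_order_rate_per_mm=0.1)
        prof = depth_profile(sys_)
        assert prof.total_length_mm() == pytest.approx(total_length(sys_), abs=1e-6)
        # oracle: 1 um resampling of every segment, histogram by midpoint depth
        y0 = min(v[1] for ax in sys_.axes for v in ax.path.vertices)
        acc = np.zeros_like(prof.length_per_bin_mm)
        for ax in sys_.axes:
            v = ax.path.vertices
            for a, b in zip(v[:-1], v[1:]):
                n = max(int(math.dist(a, b) / 0.001), 1)
                t = (np.arange(n) + 0.5) / n
                mids = a + t[:, None] * (b - a)
                piece = math.dist(a, b) / n
                idx = np.clip(((mids[:, 1] - y0) / prof.bin_width_mm).astype(int), 0, len(acc) - 1)
                np.add.at(acc, idx, piece)
        assert prof.length_per_bin_mm == pytest.approx(acc, rel=1e-3)


class TestRatesAndRatios:
    def test_root_length_per_area(self):
        sys_ = make_tree(primary_len=10.0, laterals=())
        cfg = TraitConfig(agar_area_mm2=14400.0)
        assert root_length_per_area(sys_, cfg) == pytest.approx(10.0 / 14400.0)

    @pytest.mark.parametrize(
        "l1,l2,dt,expected",
        [(10, 10, 1, 0.0), (10, 20, 1, 100 * math.log(2)), (10, 20, 2, 50 * math.log(2))],
    )
    def test_rgr_closed_forms(self, l1, l2, dt, expected):
        assert relative_growth_rate(l1, l2, 0.0, dt) == pytest.approx(expected)

    def test_rgr_domain_errors(self):
        with pytest.raises(GeometryError):
            relative_growth_rate(0.0, 10.0, 0, 1)
        with pytest.raises(GeometryError):
            relative_growth_rate(10.0, 20.0, 1, 1)

    def test_curvature_ratio_vertical_is_one(self):
        sys_ = make_tree(laterals=())
        assert curvature_ratio(sys_) == pytest.approx(1.0)

    def test_curvature_ratio_semicircle_is_pi(self):
        # rainbow-shaped primary: arc pi*r, vertical extent r
        theta = np.linspace(0.0, math.pi, 2000)
        r = 5.0
        pts = np.column_stack([r * np.cos(theta), r - r * np.sin(theta)])
        sys_ = RootSystem("p", "P", tuple(pts[0]), [RootAxis("a", 0, Polyline(pts))])
        assert curvature_ratio(sys_) == pytest.approx(math.pi, rel=1e-4)

    def test_curvature_ratio_45_degree_line(self):
        sys_ = RootSystem(
            "p", "P", (0, 0), [RootAxis("a", 0, Polyline([(0, 0), (10 / math.sqrt(2), 10 / math.sqrt(2))]))]
        )
        assert curvature_ratio(sys_) == pytest.approx(math.sqrt(2), rel=1e-12)


class TestComputeAllTraits:
    def test_single_timepoint_has_no_rgr(self, simple_tree):
        simple_tree.capture_time = datetime(2020, 6, 10)
        (rec,) = compute_all_traits([simple_tree])
        assert rec.length_total_mm > 0
        assert rec.rgr_primary_pct_per_day is None

    def test_doubling_series_gives_ln2_rates(self):
        t0 = datetime(2020, 6, 1)
        sys1 = make_tree(primary_len=10.0, laterals=((3.0, 2.0, 90.0),))
        sys2 = make_tree(primary_len=20.0, laterals=((3.0, 4.0, 90.0),))
        sys1.capture_time, sys2.capture_time = t0, t0 + timedelta(days=1)
        recs = compute_all_traits([sys1, sys2])
        for name in ("rgr_primary_pct_per_day", "rgr_lateral_pct_per_day", "rgr_total_pct_per_day"):
            assert getattr(recs[1], name) == pytest.approx(100 * math.log(2), rel=1e-9)

    def test_duplicate_timestamps_rejected(self, simple_tree):
        import copy

        simple_tree.capture_time = datetime(2020, 6, 10)
        with pytest.raises(ValidationError):
            compute_all_traits([simple_tree, copy.deepcopy(simple_tree)])

    def test_fixture_series_matches_scripted_oracle(self):
        """Every field recomputed independently from the raw geometry."""
        sys_ = make_tree(primary_len=10.0, laterals=((3.0, 2.0, 90.0), (6.0, 3.0, -45.0)))
        sys_.capture_time = datetime(2020, 6, 10)
        cfg = TraitConfig(agar_area_mm2=1600.0)
        (rec,) = compute_all_traits([sys_], cfg)
        assert rec.length_primary_mm == pytest.approx(10.0)
        assert rec.length_lateral_mm == pytest.approx(5.0)
        assert rec.length_total_mm == pytest.approx(15.0)
        assert rec.n_lateral == 2
        assert rec.lateral_density_per_mm == pytest.approx(0.2)
        assert rec.branching_angle_deg == pytest.approx((90.0 + 45.0) / 2)
        verts = np.vstack([a.path.vertices for a in sys_.axes])
        assert rec.depth_mm == pytest.approx(verts[:, 1].max() - verts[:, 1].min())
        assert rec.width_mm == pytest.approx(verts[:, 0].max() - verts[:, 0].min())
        assert rec.root_length_density_mm_per_mm2 == pytest.approx(15.0 / 1600.0)
        assert rec.ratio_lateral_primary == pytest.approx(0.5)
        assert rec.ratio_primary_depth == pytest.approx(1.0)

    def test_monotone_growth_series_non_negative_rgr(self):
        rng = np.random.default_rng(23)
        p = GrowthParams(plate_mm=60, duration_days=12, imaging_interval_days=4, lateral_rate_per_mm=0.3)
        series = sample_growth_series(p, rng)
        recs = compute_all_traits(series)
        lengths = [r.length_total_mm for r in recs]
        assert all(b >= a - 1e-9 for a, b in zip(lengths, lengths[1:]))
        for r in recs[1:]:
            if r.rgr_total_pct_per_day is not None:
                assert r.rgr_total_pct_per_day >= -1e-9
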