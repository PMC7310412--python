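"""Root-system extraction from grayscale plate images.

The pipeline turns an image into per-plant root-system trees:

1. ``segment_roots`` — flatten uneven background illumination, threshold,
   drop tiny components (condensation speckle, sensor noise).
2. ``skeletonize_mask`` — 1-px medial axis of the root mask.
3. ``build_graph`` — skeleton pixels to an undirected graph whose nodes are
   junctions/endpoints and whose edges carry the traced centreline polyline
   (chain-code length: 1 per orthogonal step, sqrt(2) per diagonal step) and
   the local root half-width sampled from the distance transform.
4. ``bridge_gaps`` — reconnect skeleton fragments split by droplets or
   scratches when the broken ends are close and roughly collinear.
5. ``extract_tree`` — carve a root tree out of the graph: the primary axis
   follows the straightest continuation from the seed point; everything that
   hangs off it becomes (recursively ordered) laterals.
6. ``estimate_diameters`` — mean width per axis from the Euclidean distance
   transform.
7. ``apply_corrections`` — merge a manually retraced architecture over the
   automatic one.

Everything here is deterministic; there is no random state in this module.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import approximate_polygon
from skimage.morphology import remove_small_objects, skeletonize

from .errors import MergeError
from .image_io import GrayImage
from .plate_model import PlateImageMeta, Polyline, RootAxis, RootSystem, point_at_arclength

__all__ = [
    "ExtractionParams",
    "SkeletonGraph",
    "segment_roots",
    "skeletonize_mask",
    "build_graph",
    "bridge_gaps",
    "resolve_crossings",
    "extract_tree",
    "estimate_diameters",
    "apply_corrections",
    "extract_root_systems",
]


@dataclass
class ExtractionParams:
    """Tunable parameters of the extraction pipeline (lengths in mm)."""

    background_flatten_radius_mm: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 20.0
    min_component_px: int = 20
    max_gap_mm: float = 1.0
    max_bridge_angle_deg: float = 30.0
    min_lateral_mm: float = 0.1
    snap_mm: float = 0.2
    simplify_tol_px: float = 0.5
    #: terminal skeleton edges shorter than this multiple of the local root
    #: diameter are treated as thinning spurs, not laterals
    spur_width_factor: float = 1.5

    def __post_init__(self) -> None:
        for name in (
            "background_flatten_radius_mm",
            "min_component_px",
            "max_gap_mm",
            "max_bridge_angle_deg",
            "min_lateral_mm",
            "snap_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class SkeletonGraph:
    """Undirected multigraph over skeleton junctions and endpoints.

    Node attribute ``xy`` is the node coordinate in mm.  Edge attributes:
    ``path`` (polyline vertices in mm, oriented from the lower to the higher
    node id), ``length`` (chain-code arc length in mm) and ``halfwidth``
    (mean distance-transform half-width along the edge in mm, 0 if no mask
    was supplied).
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    px_scale: float = 39.0  # um per px

    def node_xy(self, n) -> np.ndarray:
        return self.graph.nodes[n]["xy"]

    def endpoints(self) -> list:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 1]

    def total_length(self) -> float:
        return sum(d["length"] for *_e, d in self.graph.edges(data=True))

    def edge_path(self, u, v, key) -> np.ndarray:
        """Edge polyline oriented from u to v."""
        data = self.graph.edges[u, v, key]
        path = data["path"]
        start = self.node_xy(u)
        if np.allclose(path[0], start) and not np.allclose(path[-1], start):
            return path
        if np.allclose(path[-1], start) and not np.allclose(path[0], start):
            return path[::-1]
        # self-loop or ambiguous: fall back to stored orientation
        return path if data.get("u") == u else path[::-1]


# ---------------------------------------------------------------------------
# segmentation & skeleton
# ---------------------------------------------------------------------------


def segment_roots(img: GrayImage, params: Optional[ExtractionParams] = None) -> np.ndarray:
    """Segment root-candidate pixels from a grayscale plate image.

    Background illumination is flattened by subtracting a Gaussian-smoothed
    version of the image (radius ``background_flatten_radius_mm``) before
    thresholding, so slow intensity gradients across the agar do not bias
    the threshold.  Components smaller than ``min_component_px`` are removed.
    An image with no detectable foreground yields an empty mask and a
    warning, never an exception.
    """
    params = params or ExtractionParams()
    arr = img.pixels.astype(float)
    sigma_px = params.background_flatten_radius_mm * 1000.0 / img.meta.px_scale
    background = ndimage.gaussian_filter(arr, sigma=sigma_px)
    flat = np.clip(arr - background, 0.0, None)
    if flat.max() - flat.min() < 4.0:  # below ~2 LSB of contrast: nothing there
        warnings.warn("segment_roots: no foreground contrast; returning empty mask")
        return np.zeros(arr.shape, dtype=bool)
    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        thr = threshold_otsu(flat)
    mask = flat > thr
    mask = remove_small_objects(mask, max_size=params.min_component_px - 1)
    if not mask.any():
        warnings.warn("segment_roots: empty mask after component filtering")
    return mask


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, topology-preserving skeleton."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask.astype(bool))


# ---------------------------------------------------------------------------
# skeleton -> graph
# ---------------------------------------------------------------------------

_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of interior vertices (endpoints pinned).

    Damps the +-0.5 px staircase wiggle of traced skeleton centrelines that
    survives polygon simplification and would otherwise bias arc lengths up.
    """
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.vstack([path[0][None, :].repeat(pad, 0), path, path[-1][None, :].repeat(pad, 0)])
    sm = np.column_stack([np.convolve(padded[:, i], kernel, mode="valid") for i in (0, 1)])
    sm[0], sm[-1] = path[0], path[-1]
    return sm


def _px_path_to_mm(path_px: np.ndarray, scale_mm: float, tol_px: float) -> tuple[np.ndarray, float]:
    """Simplified mm polyline + chain-code length for a (row, col) pixel path."""
    steps = np.abs(np.diff(path_px, axis=0))
    chain = np.where((steps == 1).all(axis=1), math.sqrt(2.0), 1.0).sum() if len(path_px) > 1 else 0.0
    smoothed = _smooth_path(path_px.astype(float))
    simplified = approximate_polygon(smoothed, tolerance=tol_px) if len(path_px) > 2 else path_px.astype(float)
    xy = np.column_stack([simplified[:, 1], simplified[:, 0]]) * scale_mm  # (col, row) -> (x, y)
    return xy, float(chain) * scale_mm


def build_graph(
    skeleton: np.ndarray,
    meta: PlateImageMeta,
    mask: Optional[np.ndarray] = None,
    simplify_tol_px: float = 0.5,
) -> SkeletonGraph:
    """Trace a skeleton into a junction/endpoint graph.

    Nodes are connected clusters of skeleton pixels with a neighbour count
    other than 2 (junction clusters may span a few pixels; their coordinate
    is the cluster centroid).  Edge arc length uses chain-code weights
    (1 px orthogonal, sqrt(2) px diagonal) converted to mm; edge polylines
    are Douglas-Peucker simplified at ``simplify_tol_px`` to suppress
    staircase bias before trait computation.  If ``mask`` is given, the mean
    distance-transform half-width along each edge is stored.
    """
    scale_mm = meta.px_scale / 1000.0
    sg = SkeletonGraph(px_scale=meta.px_scale)
    G = sg.graph
    skel = skeleton.astype(bool)
    if not skel.any():
        return sg
    deg = _neighbor_count(skel)
    node_mask = skel & (deg != 2)
    node_labels, n_nodes = ndimage.label(node_mask, structure=np.ones((3, 3)))
    edt = ndimage.distance_transform_edt(mask.astype(bool)) if mask is not None else None

    # node centroids (row, col)
    if n_nodes:
        centroids = ndimage.center_of_mass(node_mask, node_labels, range(1, n_nodes + 1))
    else:
        centroids = []
    for i, (r, c) in enumerate(centroids, start=1):
        G.add_node(i, xy=np.array([c * scale_mm, r * scale_mm]), px=(r, c))

    def add_edge(u: int, v: int, path_px: list) -> None:
        arr = np.asarray(path_px)
        # splice node centroids onto the ends so edge endpoints == node coords
        start = np.array(G.nodes[u]["px"], dtype=float)
        end = np.array(G.nodes[v]["px"], dtype=float)
        full = np.vstack([start[None, :], arr, end[None, :]])
        # drop duplicated consecutive points
        keep = np.ones(len(full), dtype=bool)
        keep[1:] = np.abs(np.diff(full, axis=0)).max(axis=1) > 1e-9
        full = full[keep]
        if len(full) < 2:
            return
        xy, chain = _px_path_to_mm(full, scale_mm, simplify_tol_px)
        hw = 0.0
        if edt is not None and len(arr):
            hw = float(np.mean([edt[int(r), int(c)] for r, c in arr])) * scale_mm
        elif edt is not None:
            hw = float(edt[int(start[0]), int(start[1])]) * scale_mm
        G.add_edge(u, v, path=xy, length=chain, halfwidth=hw, u=u)

    visited = np.zeros(skel.shape, dtype=bool)
    rows, cols = np.nonzero(node_mask)
    shape = skel.shape

    def neighbors(r: int, c: int):
        for dr, dc in _NBR:
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1] and skel[rr, cc]:
                yield rr, cc

    # trace edges between node clusters through degree-2 corridors
    for r0, c0 in zip(rows, cols):
        u = int(node_labels[r0, c0])
        for r1, c1 in neighbors(r0, c0):
            if node_labels[r1, c1]:
                # directly adjacent node pixels: same cluster -> internal, skip;
                # different clusters -> zero-corridor edge (dedup by ordering)
                v = int(node_labels[r1, c1])
                if v != u and (u < v or (u == v and (r0, c0) < (r1, c1))):
                    add_edge(u, v, [(r0, c0), (r1, c1)])
                continue
            if visited[r1, c1]:
                continue
            path = [(r0, c0), (r1, c1)]
            visited[r1, c1] = True
            prev, cur = (r0, c0), (r1, c1)
            while True:
                nxt = [p for p in neighbors(*cur) if p != prev and not (len(path) > 2 and p == path[-3])]
                # prefer an unvisited degree-2 continuation or a node pixel
                node_next = [p for p in nxt if node_labels[p]]
                corridor = [p for p in nxt if not node_labels[p] and not visited[p]]
                if node_next:
                    end = node_next[0]
                    path.append(end)
                    add_edge(u, int(node_labels[end]), path)
                    break
                if not corridor:
                    # dead end without a node pixel (shouldn't happen) — endpoint
                    add_edge(u, u, path)
                    break
                prev, cur = cur, corridor[0]
                visited[cur] = True
                path.append(cur)

    # pure cycles: degree-2 pixels never visited and not nodes
    remaining = skel & ~visited & ~node_mask
    lbl, n_cyc = ndimage.label(remaining, structure=np.ones((3, 3)))
    for i in range(1, n_cyc + 1):
        rs, cs = np.nonzero(lbl == i)
        start = (int(rs[0]), int(cs[0]))
        nid = G.number_of_nodes() + 1
        G.add_node(nid, xy=np.array([start[1] * scale_mm, start[0] * scale_mm]), px=start)
        path = [start]
        visited[start] = True
        prev, cur = None, start
        while True:
            nxt = [p for p in neighbors(*cur) if p != prev]
            nxt = [p for p in nxt if not visited[p]]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited[cur] = True
            path.append(cur)
        path.append(start)  # close the loop
        add_edge(nid, nid, path)
    return sg


# ---------------------------------------------------------------------------
# gap bridging
# ---------------------------------------------------------------------------


def _endpoint_tangent(sg: SkeletonGraph, node) -> Optional[np.ndarray]:
    """Outward unit tangent at a degree-1 node (direction pointing away from the root body)."""
    edges = list(sg.graph.edges(node, keys=True))
    if len(edges) != 1:
        return None
    u, v, k = edges[0]
    other = v if u == node else u
    path = sg.edge_path(other, node, k)  # oriented towards the endpoint
    tip = path[-1]
    # walk back ~0.5 mm for a stable direction estimate
    back = len(path) - 2
    acc = 0.0
    while back > 0 and acc < 0.5:
        acc += float(np.hypot(*(path[back + 1] - path[back])))
        back -= 1
    d = tip - path[max(back, 0)]
    n = np.hypot(*d)
    return None if n < 1e-9 else d / n


def bridge_gaps(sg: SkeletonGraph, params: Optional[ExtractionParams] = None) -> SkeletonGraph:
    """Join broken skeleton fragments across droplet/scratch gaps.

    Endpoint pairs closer than ``max_gap_mm`` whose outward tangents each
    align with the connecting segment within ``max_bridge_angle_deg`` are
    joined by a straight connector edge; pairs are matched greedily by
    increasing gap distance and each endpoint is used at most once.
    """
    params = params or ExtractionParams()
    ends = sg.endpoints()
    tangents = {n: _endpoint_tangent(sg, n) for n in ends}
    cos_max = math.cos(math.radians(params.max_bridge_angle_deg))
    candidates = []
    for i, a in enumerate(ends):
        for b in ends[i + 1 :]:
            pa, pb = sg.node_xy(a), sg.node_xy(b)
            gap = float(np.hypot(*(pb - pa)))
            if gap > params.max_gap_mm or gap < 1e-9:
                continue
            ta, tb = tangents[a], tangents[b]
            if ta is None or tb is None:
                continue
            d = (pb - pa) / gap
            if float(ta @ d) >= cos_max and float(tb @ -d) >= cos_max:
                candidates.append((gap, a, b))
    used: set = set()
    for gap, a, b in sorted(candidates, key=lambda t: t[0]):
        if a in used or b in used:
            continue
        used.update((a, b))
        pa, pb = sg.node_xy(a), sg.node_xy(b)
        sg.graph.add_edge(a, b, path=np.vstack([pa, pb]), length=gap, halfwidth=0.0, u=a, bridged=True)
    return sg


# ---------------------------------------------------------------------------
# crossing resolution
# ---------------------------------------------------------------------------


def _fuse_edges(G: nx.MultiGraph, node, e1, e2, sg: "SkeletonGraph") -> None:
    """Replace two edges meeting at ``node`` by one through-going edge."""
    (u1, v1, k1), (u2, v2, k2) = e1, e2
    a = v1 if u1 == node else u1
    b = v2 if u2 == node else u2
    p1 = sg.edge_path(a, node, k1)
    p2 = sg.edge_path(node, b, k2)
    path = np.vstack([p1, p2[1:]])
    d1, d2 = G.edges[u1, v1, k1], G.edges[u2, v2, k2]
    G.remove_edge(u1, v1, k1)
    G.remove_edge(u2, v2, k2)
    G.add_edge(
        a,
        b,
        path=path,
        length=d1["length"] + d2["length"],
        halfwidth=(d1.get("halfwidth", 0.0) + d2.get("halfwidth", 0.0)) / 2.0,
        u=a,
    )


def resolve_crossings(sg: SkeletonGraph, merge_len_mm: float = 0.5, min_opposition_deg: float = 135.0) -> SkeletonGraph:
    """Resolve root crossings in the skeleton graph.

    Two roots crossing in the 2-D projection appear either as one 4-way
    junction or - when their strokes merge tangentially - as two 3-way
    junctions joined by a short shared stretch.  In both cases the four
    outer edges are matched into two anti-parallel pairs (opposition angle
    above ``min_opposition_deg``) and each pair is fused into a single
    through-going edge, so downstream tree extraction sees two roots crossing
    rather than a junction.  Genuine branch points (3-way, or 4-way without a
    consistent anti-parallel pairing) are left untouched.
    """
    G = sg.graph
    cos_gate = math.cos(math.radians(min_opposition_deg))

    def outgoing(node, other, key):
        return _outgoing_dir(sg.edge_path(node, other, key))

    # tangentially merged crossings: short edge between two 3-way junctions
    changed = True
    while changed:
        changed = False
        for u, v, k in list(G.edges(keys=True)):
            if u == v or not G.has_edge(u, v, k):
                continue
            if G.edges[u, v, k]["length"] >= merge_len_mm:
                continue
            if G.degree(u) != 3 or G.degree(v) != 3:
                continue
            outer_u = [(a, b, kk) for a, b, kk in G.edges(u, keys=True) if not ({a, b} == {u, v} and kk == k)]
            outer_v = [(a, b, kk) for a, b, kk in G.edges(v, keys=True) if not ({a, b} == {u, v} and kk == k)]
            if len(outer_u) != 2 or len(outer_v) != 2:
                continue
            if any(a == b for a, b, _kk in outer_u + outer_v):
                continue
            shared = sg.edge_path(u, v, k)
            shared_len = G.edges[u, v, k]["length"]
            du = [outgoing(u, (b if a == u else a), kk) for a, b, kk in outer_u]
            dv = [outgoing(v, (b if a == v else a), kk) for a, b, kk in outer_v]
            pairings = [((0, 0), (1, 1)), ((0, 1), (1, 0))]
            score = [sum(float(du[i] @ dv[j]) for i, j in pr) for pr in pairings]
            pairing = pairings[int(np.argmin(score))]
            if not all(float(du[i] @ dv[j]) < cos_gate for i, j in pairing):
                continue
            new_edges = []
            for i, j in pairing:
                au, bu, ku = outer_u[i]
                av, bv, kv = outer_v[j]
                a = bu if au == u else au
                b = bv if av == v else av
                path = np.vstack(
                    [sg.edge_path(a, u, ku), shared[1:], sg.edge_path(v, b, kv)[1:]]
                )
                length = G.edges[au, bu, ku]["length"] + shared_len + G.edges[av, bv, kv]["length"]
                hw = (G.edges[au, bu, ku].get("halfwidth", 0.0) + G.edges[av, bv, kv].get("halfwidth", 0.0)) / 2.0
                new_edges.append((a, b, path, length, hw))
            G.remove_node(u)
            G.remove_node(v)
            for a, b, path, length, hw in new_edges:
                G.add_edge(a, b, path=path, length=length, halfwidth=hw, u=a)
            changed = True
            break

    # clean 4-way crossings
    for node in list(G.nodes):
        if node not in G or G.degree(node) != 4:
            continue
        edges = list(G.edges(node, keys=True))
        if len(edges) != 4 or any(a == b for a, b, _kk in edges):
            continue
        dirs = [outgoing(node, (b if a == node else a), kk) for a, b, kk in edges]
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        score = [sum(float(dirs[i] @ dirs[j]) for i, j in pr) for pr in pairings]
        best = pairings[int(np.argmin(score))]
        if all(float(dirs[i] @ dirs[j]) < cos_gate for i, j in best):
            for i, j in best:
                _fuse_edges(G, node, edges[i], edges[j], sg)
            G.remove_node(node)
    return sg


# ---------------------------------------------------------------------------
# tree extraction
# ---------------------------------------------------------------------------


def _outgoing_dir(path: np.ndarray, reach_mm: float = 1.0) -> np.ndarray:
    """Unit direction of the first ~reach_mm of an oriented polyline."""
    start = path[0]
    acc = 0.0
    for i in range(1, len(path)):
        acc += float(np.hypot(*(path[i] - path[i - 1])))
        if acc >= reach_mm:
            d = path[i] - start
            break
    else:
        d = path[-1] - start
    n = np.hypot(*d)
    return d / n if n > 1e-12 else np.array([0.0, 1.0])


def _incoming_dir(path: np.ndarray, reach_mm: float = 1.0) -> np.ndarray:
    return -_outgoing_dir(path[::-1], reach_mm)  # direction of travel at arrival


def _walk_straightest(sg: SkeletonGraph, start, start_dir: np.ndarray, unused: set) -> tuple[np.ndarray, list]:
    """Greedy straightest-continuation walk from ``start``.

    Returns the concatenated polyline and the list of (node, arc_pos,
    incoming_dir) visited along the way (including the start at arc 0).
    ``unused`` is the set of available edge keys (u, v, k); traversed edges
    are removed from it.
    """
    G = sg.graph
    pts = [sg.node_xy(start)[None, :]]
    visited_nodes = [(start, 0.0)]
    arc = 0.0
    cur, cur_dir = start, start_dir
    while True:
        best, best_cos = None, -2.0
        for u, v, k in G.edges(cur, keys=True):
            if (min(u, v), max(u, v), k) not in unused:
                continue
            path = sg.edge_path(cur, v if u == cur else u, k)
            out = _outgoing_dir(path)
            c = float(cur_dir @ out)
            if c > best_cos:
                best_cos = c
                best = (u, v, k, path)
        if best is None:
            break
        u, v, k, path = best
        unused.discard((min(u, v), max(u, v), k))
        pts.append(path[1:])
        seglen = float(np.hypot(*np.diff(path, axis=0).T).sum()) if len(path) > 1 else 0.0
        arc += seglen
        cur = v if u == cur else u
        cur_dir = _incoming_dir(path)
        visited_nodes.append((cur, arc))
    return np.vstack(pts), visited_nodes


def _reanchor_lateral(
    parent: Polyline, child_pts: np.ndarray, branch_pos: float, clear_mm: float
) -> tuple[np.ndarray, float, float]:
    """Correct the junction-distorted start of a lateral path.

    Skeletonization pulls the branch point along the parent and bends the
    first ~root-width of the lateral's centreline, which biases branching
    angles.  The fix: drop child path points within ``clear_mm`` of the
    junction, fit the lateral's clean initial direction just beyond, and
    re-intersect that line with the parent path to recover the true branch
    point.  Falls back to the original geometry when the path is too short
    or no nearby intersection exists.
    """
    start = child_pts[0]
    d = np.hypot(*(child_pts - start).T)
    idx = np.nonzero(d >= clear_mm)[0]
    if len(idx) == 0:
        return child_pts, branch_pos, 0.0
    i0 = int(idx[0])
    trimmed_arc = float(np.hypot(*np.diff(child_pts[: i0 + 1], axis=0).T).sum()) if i0 > 0 else 0.0
    rest = child_pts[i0:]
    if len(rest) < 2:
        rest = np.vstack([child_pts[i0 - 1], child_pts[-1]])
        trimmed_arc = max(trimmed_arc - float(np.hypot(*(child_pts[i0] - child_pts[i0 - 1]))), 0.0)
    # clean initial direction of the lateral: first ~0.6 mm beyond the junction
    seg = np.hypot(*np.diff(rest, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    j = int(np.searchsorted(cum, 0.6, side="right"))
    q0, q1 = rest[0], rest[min(max(j, 1), len(rest) - 1)]
    ddir = q1 - q0
    if np.hypot(*ddir) < 1e-9:
        return child_pts, branch_pos, 0.0
    # intersect the line q0 + t*ddir (t <= 0 side) with parent segments near branch_pos
    pverts = parent.vertices
    pcum = parent.cumulative_lengths()
    best = None
    for k in range(len(pverts) - 1):
        if pcum[k + 1] < branch_pos - 2.0 or pcum[k] > branch_pos + 2.0:
            continue
        a, b = pverts[k], pverts[k + 1]
        m = np.array([[b[0] - a[0], -ddir[0]], [b[1] - a[1], -ddir[1]]])
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) < 1e-12:
            continue
        rhs = q0 - a
        u = (rhs[0] * m[1, 1] - rhs[1] * m[0, 1]) / det
        t = (m[0, 0] * rhs[1] - m[1, 0] * rhs[0]) / det
        if -1e-9 <= u <= 1 + 1e-9 and t <= 0.2:
            pos = pcum[k] + u * (pcum[k + 1] - pcum[k])
            if best is None or abs(pos - branch_pos) < abs(best[1] - branch_pos):
                best = (a + u * (b - a), float(pos))
    if best is None:
        return child_pts, branch_pos, 0.0
    anchor, pos = best
    if np.hypot(*(anchor - q0)) > 3.0 * max(clear_mm, 0.1):  # implausible, keep original
        return child_pts, branch_pos, 0.0
    connector = float(np.hypot(*(anchor - rest[0])))
    new_pts = np.vstack([anchor[None, :], rest]) if connector > 1e-9 else rest
    # children of this axis sit on ``rest``; their arc positions shift by
    # (new connector length - trimmed original arc)
    return new_pts, float(min(max(pos, 0.0), parent.length())), connector - trimmed_arc


def extract_tree(
    sg: SkeletonGraph,
    seed_point: tuple[float, float],
    params: Optional[ExtractionParams] = None,
    plant_id: str = "plant",
    plate_id: str = "",
    capture_time=None,
) -> RootSystem:
    """Carve a root-system tree out of a skeleton graph.

    The primary axis starts at the node nearest ``seed_point`` and follows,
    at every junction, the edge that least changes direction (initial
    direction: straight down).  Edges left over at junctions on the primary
    become first-order laterals (recursively: second order, ...), each again
    traced by straightest continuation.  Roots that cross (an X junction, or
    a lateral growing back over another axis) are handled as traversals:
    every skeleton edge is consumed exactly once, so graph cycles resolve
    into two crossing paths rather than a broken tree.  Terminal spur edges
    shorter than the local root diameter x ``spur_width_factor`` and laterals
    shorter than ``min_lateral_mm`` are discarded.
    """
    params = params or ExtractionParams()
    seed = np.asarray(seed_point, dtype=float)
    if sg.graph.number_of_nodes() == 0:
        return RootSystem(plant_id, plate_id, tuple(seed), axes=[], capture_time=capture_time, empty=True)
    start = min(sg.graph.nodes, key=lambda n: float(np.hypot(*(sg.node_xy(n) - seed))))
    comp = nx.node_connected_component(sg.graph, start)
    G = sg.graph.subgraph(comp).copy()
    sub = SkeletonGraph(graph=G, px_scale=sg.px_scale)

    unused = {(min(u, v), max(u, v), k) for u, v, k in G.edges(keys=True)}
    axes: list[RootAxis] = []
    counter = [0]

    from collections import deque

    # breadth-first over orders: every first-order lateral claims its edges
    # before any second-order tracing starts, so a crossing lateral cannot be
    # stolen as a deeper child of the axis it merely crosses
    queue: deque = deque([(start, np.array([0.0, 1.0]), 0, None, None, None)])
    while queue:
        start_node, start_dir, order, parent_id, branch_pos, parent_path = queue.popleft()
        pts, visited = _walk_straightest(sub, start_node, start_dir, unused)
        if len(pts) < 2:
            continue
        path = Polyline(pts)
        length = path.length()
        arc_delta = 0.0
        # spur / minimum-length filters, then junction re-anchoring, for laterals
        if order > 0:
            hw = max(
                (G.edges[u, v, k].get("halfwidth", 0.0) for u, v, k in G.edges(start_node, keys=True)),
                default=0.0,
            )
            min_len = max(params.min_lateral_mm, params.spur_width_factor * 2.0 * hw)
            has_children = any(
                (min(u, v), max(u, v), k) in unused
                for n, _arc in visited
                for u, v, k in G.edges(n, keys=True)
            )
            if length < min_len and not has_children:
                continue
            if length < params.min_lateral_mm:
                continue
            if parent_path is not None:
                clear = max(2.0 * hw, 3.0 * sg.px_scale / 1000.0)
                new_pts, branch_pos, arc_delta = _reanchor_lateral(parent_path, pts, branch_pos, clear)
                path = Polyline(new_pts)
        counter[0] += 1
        axis_id = f"{plant_id}.{counter[0]:03d}"
        axes.append(
            RootAxis(
                axis_id=axis_id,
                order=order,
                path=path,
                parent_id=parent_id,
                branch_pos_mm=branch_pos,
            )
        )
        # any edge still unused at a node of this axis starts a child axis
        own_len = path.length()
        for node, arc_pos in visited:
            for u, v, k in list(G.edges(node, keys=True)):
                if (min(u, v), max(u, v), k) not in unused:
                    continue
                other = v if u == node else u
                child_dir = _outgoing_dir(sub.edge_path(node, other, k))
                child_pos = float(min(max(arc_pos + arc_delta, 0.0), own_len))
                queue.append((node, child_dir, order + 1, axis_id, child_pos, path))
    if not axes:
        return RootSystem(plant_id, plate_id, tuple(seed), axes=[], capture_time=capture_time, empty=True)
    system = RootSystem(
        plant_id=plant_id,
        plate_id=plate_id,
        seed_point=(float(axes[0].path.first()[0]), float(axes[0].path.first()[1])),
        axes=axes,
        capture_time=capture_time,
    )
    system.validate(snap_mm=max(params.snap_mm, 1e-6))
    return system


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------


def estimate_diameters(mask: np.ndarray, system: RootSystem, meta: PlateImageMeta) -> RootSystem:
    """Estimate per-axis mean diameter from the distance transform.

    Diameter = mean over samples along the axis path of 2 x the Euclidean
    distance to background, in um, corrected for the half-pixel offset of the
    distance transform (the EDT of a 1-px line is 1 at the centre, so the raw
    2 x EDT overestimates width by one pixel).  Samples within 2 px of a
    junction (the axis' own attachment point or a child's branch point) are
    excluded since widths there reflect the junction blob, not the root.
    """
    scale_mm = meta.px_scale / 1000.0
    edt = ndimage.distance_transform_edt(mask.astype(bool))
    h, w = mask.shape
    new_axes = []
    for ax in system.axes:
        junctions = [ax.path.first()] if ax.order > 0 else []
        junctions += [
            point_at_arclength(ax.path, min(ch.branch_pos_mm, ax.length_mm()))
            for ch in system.children_of(ax.axis_id)
        ]
        total = ax.length_mm()
        n_samples = max(int(total / scale_mm), 2)
        svals = np.linspace(0.0, total, n_samples)
        widths = []
        for s in svals:
            p = point_at_arclength(ax.path, s)
            if junctions and min(np.hypot(*(p - j)) for j in junctions) < 2.0 * scale_mm:
                continue
            r = int(round(p[1] / scale_mm))
            c = int(round(p[0] / scale_mm))
            if 0 <= r < h and 0 <= c < w:
                widths.append(edt[r, c])
        widths = [v for v in widths if v > 0]
        if not widths:
            warnings.warn(f"axis {ax.axis_id}: path lies outside the mask; diameter unset")
            new_axes.append(replace(ax, mean_diameter_um=None))
        else:
            diam_px = max(2.0 * float(np.mean(widths)) - 1.0, 1.0)
            new_axes.append(replace(ax, mean_diameter_um=diam_px * meta.px_scale))
    return replace(system, axes=new_axes)


# ---------------------------------------------------------------------------
# manual corrections
# ---------------------------------------------------------------------------


def _project_on_path(path: Polyline, point: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(arc position, distance, foot point) of the projection of ``point``."""
    v = path.vertices
    cum = path.cumulative_lengths()
    best = (0.0, float("inf"), v[0])
    for k in range(len(v) - 1):
        a, b = v[k], v[k + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        foot = a + t * ab
        d = float(np.hypot(*(point - foot)))
        if d < best[1]:
            best = (float(cum[k] + t * (cum[k + 1] - cum[k])), d, foot)
    return best


def apply_corrections(auto: RootSystem, corrected: RootSystem) -> RootSystem:
    """Merge a manually retraced architecture over the automatic extraction.

    Axes in ``corrected`` replace automatic axes with the same id; axes only
    present in ``corrected`` are added; axes flagged ``deleted`` are removed
    (with their descendants).  The merged system is revalidated.
    """
    if auto.plant_id != corrected.plant_id:
        raise MergeError(f"plant id mismatch: {auto.plant_id!r} vs {corrected.plant_id!r}")
    if (
        auto.capture_time is not None
        and corrected.capture_time is not None
        and auto.capture_time != corrected.capture_time
    ):
        raise MergeError("capture time mismatch between automatic and corrected systems")
    merged: dict[str, RootAxis] = {ax.axis_id: ax for ax in auto.axes}
    deleted = set()
    for ax in corrected.axes:
        if ax.deleted:
            deleted.add(ax.axis_id)
            merged.pop(ax.axis_id, None)
        else:
            merged[ax.axis_id] = replace(ax, deleted=False)
    # cascade deletions to orphaned descendants
    changed = True
    while changed:
        changed = False
        for aid, ax in list(merged.items()):
            if ax.parent_id is not None and ax.parent_id not in merged:
                del merged[aid]
                deleted.add(aid)
                changed = True
    axes = list(merged.values())
    # retracing a parent can move it away from its children's old attachment
    # points: re-anchor every child on its (possibly new) parent geometry
    by_id = {ax.axis_id: ax for ax in axes}
    for i, ax in enumerate(axes):
        if ax.parent_id is None:
            continue
        parent = by_id[ax.parent_id]
        pos, dist, proj = _project_on_path(parent.path, ax.path.first())
        new_path = ax.path
        if dist > 1e-9:
            new_path = Polyline(np.vstack([proj[None, :], ax.path.vertices]))
        axes[i] = replace(ax, branch_pos_mm=pos, path=new_path)
        by_id[ax.axis_id] = axes[i]
    prim = [ax for ax in axes if ax.order == 0]
    seed = tuple(prim[0].path.first()) if prim else auto.seed_point
    out = RootSystem(
        plant_id=auto.plant_id,
        plate_id=auto.plate_id,
        seed_point=seed,
        axes=axes,
        capture_time=auto.capture_time or corrected.capture_time,
        empty=not axes,
    )
    if axes:
        out.validate()
    return out


# ---------------------------------------------------------------------------
# whole-image convenience pipeline
# ---------------------------------------------------------------------------


def extract_root_systems(
    img: GrayImage,
    params: Optional[ExtractionParams] = None,
    plant_positions: Optional[Sequence[float]] = None,
) -> list[RootSystem]:
    """Full pipeline: segment, skeletonize, graph, bridge, per-plant trees.

    The image is divided into vertical lanes centred on the plant positions
    (mm along the top edge); each lane is seeded at its topmost skeleton
    pixel near the hole x-coordinate and processed independently.
    """
    params = params or ExtractionParams()
    meta = img.meta
    positions = list(plant_positions if plant_positions is not None else meta.plant_positions)
    if not positions:
        positions = [img.pixels.shape[1] * meta.px_scale / 1000.0 / 2.0]
    mask = segment_roots(img, params)
    skel = skeletonize_mask(mask)
    sg = bridge_gaps(build_graph(skel, meta, mask=mask, simplify_tol_px=params.simplify_tol_px), params)
    sg = resolve_crossings(sg)
    width_mm = img.pixels.shape[1] * meta.px_scale / 1000.0
    bounds = [0.0] + [(a + b) / 2.0 for a, b in zip(positions, positions[1:])] + [width_mm]
    systems = []
    used_components: set = set()
    for i, x0 in enumerate(positions):
        lo, hi = bounds[i], bounds[i + 1]
        lane_nodes = [
            n for n in sg.graph.nodes if lo <= sg.node_xy(n)[0] < hi and frozenset(nx.node_connected_component(sg.graph, n)) not in used_components
        ]
        pid = f"{meta.plate_id}_p{i + 1}"
        if not lane_nodes:
            systems.append(RootSystem(pid, meta.plate_id, (x0, 0.0), axes=[], capture_time=meta.capture_time, empty=True))
            continue
        top = min(lane_nodes, key=lambda n: (sg.node_xy(n)[1], abs(sg.node_xy(n)[0] - x0)))
        seed = (x0, float(sg.node_xy(top)[1]))
        # seed on the actual topmost point so the nearest-node rule picks this lane's plant
        seed = (float(sg.node_xy(top)[0]), float(sg.node_xy(top)[1]))
        system = extract_tree(sg, seed, params, plant_id=pid, plate_id=meta.plate_id, capture_time=meta.capture_time)
        used_components.add(frozenset(nx.node_connected_component(sg.graph, top)))
        systems.append(estimate_diameters(mask, system, meta) if not system.empty else system)
    return systems
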