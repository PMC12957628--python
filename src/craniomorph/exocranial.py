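"""Automated exocranial (exterior) surface extraction by visibility culling.

The exterior surface of a skull mesh is recovered without manual editing by
surrounding the mesh with a huge axis-aligned cube — side length 100 times
the maximum pairwise vertex distance, centred on the vertex centroid — and
probing visibility from the 26 distinguished points of that cube (8 corners,
12 edge midpoints, 6 face centres).  A face is kept when it is visible from
at least ``min_views`` (default 2) of those points; endocranial structure,
sinus walls and other internal geometry are occluded from every viewpoint
and removed.

A point is visible from a viewpoint when no other triangle intersects the
open segment between them.  Two interchangeable engines answer that query:
an exhaustive vectorised segment/triangle scan (the oracle) and an
axis-aligned BVH with batched traversal.  They are required to agree
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse

from .exceptions import DegenerateInputError, EmptyExteriorError, ParameterError
from .mesh_core import TriangleMesh, face_normals_areas, max_pairwise_distance

#: Relative offset of the probe point along the face normal, as a fraction
#: of the viewpoint-cube side.
PROBE_EPS_FRAC = 1e-5

#: Relative tolerance of the segment/triangle test; grazing edge hits count
#: as occlusion (conservative).
RAY_EPS = 1e-9

N_VIEWPOINTS = 26


@dataclass(frozen=True)
class ViewpointSet:
    """The 26 probe points on the enclosing cube."""

    points: np.ndarray  # (26, 3)
    center: np.ndarray  # (3,)
    side: float

    def __post_init__(self) -> None:
        if self.points.shape != (N_VIEWPOINTS, 3):
            raise ParameterError("a viewpoint set must contain exactly 26 points")


@dataclass
class VisibilityResult:
    """Per-face visibility counts and the derived keep decision."""

    counts: np.ndarray          # (n_faces,) ints in [0, 26]
    keep: np.ndarray            # (n_faces,) bool, counts >= min_views
    min_views: int
    face_map: np.ndarray | None = None  # kept output face -> input face index


def build_viewpoint_set(mesh: TriangleMesh) -> ViewpointSet:
    """Cube viewpoints: centre at the vertex centroid, side 100 x diameter."""
    if mesh.n_vertices < 2:
        raise DegenerateInputError("viewpoint cube needs at least 2 vertices")
    center = mesh.vertices.mean(axis=0)
    side = 100.0 * max_pairwise_distance(mesh)
    if side <= 0:
        raise DegenerateInputError("mesh has zero extent")
    offsets = np.array([o for o in product((-1, 0, 1), repeat=3)
                        if o != (0, 0, 0)], dtype=np.float64)
    points = center + offsets * (side / 2.0)
    return ViewpointSet(points=points, center=center, side=side)


# ---------------------------------------------------------------------------
# segment / triangle intersection
# ---------------------------------------------------------------------------


def _segment_hits(origins: np.ndarray, ends: np.ndarray,
                  tri: np.ndarray) -> np.ndarray:
    """Moller-Trumbore for open segments.

    Parameters: origins/ends (s, 3); tri (t, 3, 3).  Returns (s, t) bool.
    Barycentric tolerances are slightly permissive so grazing edge hits
    register as occlusion.
    """
    d = ends - origins                      # (s, 3)
    e1 = tri[:, 1] - tri[:, 0]              # (t, 3)
    e2 = tri[:, 2] - tri[:, 0]
    p = np.cross(d[:, None, :], e2[None, :, :])       # (s, t, 3)
    det = (p * e1[None, :, :]).sum(-1)                # (s, t)
    # parallel/degenerate threshold is per (segment, triangle) pair so the
    # answer is independent of how pairs are batched (BVH leaves vs full scan)
    det_scale = (np.linalg.norm(d, axis=1)[:, None]
                 * np.linalg.norm(e1, axis=1)[None, :]
                 * np.linalg.norm(e2, axis=1)[None, :])
    near_zero = np.abs(det) < RAY_EPS * np.maximum(det_scale, 1e-300)
    inv = np.where(near_zero, 1.0, 1.0 / np.where(near_zero, 1.0, det))
    tvec = origins[:, None, :] - tri[None, :, 0, :]   # (s, t, 3)
    u = (tvec * p).sum(-1) * inv
    q = np.cross(tvec, e1[None, :, :])
    v = (q * d[:, None, :]).sum(-1) * inv
    t = (q * e2[None, :, :]).sum(-1) * inv
    bar_tol = 1e-12
    hits = (~near_zero
            & (u >= -bar_tol) & (v >= -bar_tol) & (u + v <= 1.0 + bar_tol)
            & (t > RAY_EPS) & (t < 1.0 - RAY_EPS))
    return hits


class BruteForceOcclusion:
    """Exhaustive all-triangle occlusion oracle."""

    def __init__(self, mesh: TriangleMesh, chunk: int = 256):
        self.tri = mesh.vertices[mesh.faces]
        self.chunk = chunk

    def any_hit(self, origins, ends, excluded=None) -> np.ndarray:
        """For each segment, does any non-excluded triangle intersect it?

        ``excluded`` is an optional callable ``excluded(seg_indices) ->
        (len(seg_indices), n_tri) bool`` marking triangles to ignore.
        """
        origins = np.atleast_2d(origins)
        ends = np.atleast_2d(ends)
        out = np.zeros(len(origins), dtype=bool)
        for lo in range(0, len(origins), self.chunk):
            sl = slice(lo, min(lo + self.chunk, len(origins)))
            hits = _segment_hits(origins[sl], ends[sl], self.tri)
            if excluded is not None:
                hits &= ~excluded(np.arange(sl.start, sl.stop))
            out[sl] = hits.any(axis=1)
        return out


class TriangleBVH:
    """Axis-aligned median-split BVH over mesh faces.

    Traversal is batched: a frontier of (node, active segments) pairs is
    processed with vectorised segment/AABB slab tests, and leaves run the
    same Moller-Trumbore kernel as the exhaustive oracle, so answers are
    bit-identical to the brute-force scan.
    """

    def __init__(self, mesh: TriangleMesh, leaf_size: int = 8):
        self.tri = mesh.vertices[mesh.faces]
        lo = self.tri.min(axis=1)
        hi = self.tri.max(axis=1)
        centers = self.tri.mean(axis=1)
        n = len(self.tri)
        # arrays of nodes: box_lo, box_hi, left, right, start, count
        self.box_lo: list[np.ndarray] = []
        self.box_hi: list[np.ndarray] = []
        self.children: list[tuple[int, int]] = []
        self.leaf_faces: list[np.ndarray | None] = []
        order = np.arange(n)

        def build(idx: np.ndarray) -> int:
            node = len(self.box_lo)
            self.box_lo.append(lo[idx].min(axis=0))
            self.box_hi.append(hi[idx].max(axis=0))
            self.children.append((-1, -1))
            self.leaf_faces.append(None)
            if len(idx) <= leaf_size:
                self.leaf_faces[node] = idx
                return node
            axis = int(np.argmax(self.box_hi[node] - self.box_lo[node]))
            med = np.median(centers[idx, axis])
            left_mask = centers[idx, axis] <= med
            if left_mask.all() or not left_mask.any():
                left_mask = np.zeros(len(idx), dtype=bool)
                left_mask[: len(idx) // 2] = True
                idx = idx[np.argsort(centers[idx, axis])]
            l = build(idx[left_mask])
            r = build(idx[~left_mask])
            self.children[node] = (l, r)
            return node

        import sys
        depth = max(2 * int(np.ceil(np.log2(max(n, 2)))) + 20, 64)
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * depth + 1000))
        try:
            build(order)
        finally:
            sys.setrecursionlimit(old)
        self.box_lo = np.asarray(self.box_lo)
        self.box_hi = np.asarray(self.box_hi)

    def _segment_box_overlap(self, o, d, inv_d, node) -> np.ndarray:
        """Slab test of segments (param t in [0,1]) against one node box."""
        with np.errstate(invalid="ignore"):  # 0 * inf lanes overwritten below
            lo = (self.box_lo[node] - o) * inv_d
            hi = (self.box_hi[node] - o) * inv_d
        tmin = np.minimum(lo, hi)
        tmax = np.maximum(lo, hi)
        # axes with zero direction: inside-slab check
        zero = d == 0
        inside = (o >= self.box_lo[node] - 1e-12) & (o <= self.box_hi[node] + 1e-12)
        tmin = np.where(zero, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(zero, np.where(inside, np.inf, -np.inf), tmax)
        enter = tmin.max(axis=1)
        exit_ = tmax.min(axis=1)
        return (enter <= exit_ + 1e-12) & (exit_ >= 0.0) & (enter <= 1.0)

    def any_hit(self, origins, ends, excluded=None) -> np.ndarray:
        origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
        ends = np.atleast_2d(np.asarray(ends, dtype=np.float64))
        d = ends - origins
        with np.errstate(divide="ignore"):
            inv_d = np.where(d != 0, 1.0 / np.where(d == 0, 1.0, d), np.inf)
        hit = np.zeros(len(origins), dtype=bool)
        stack = [(0, np.arange(len(origins)))]
        while stack:
            node, active = stack.pop()
            active = active[~hit[active]]
            if not len(active):
                continue
            mask = self._segment_box_overlap(origins[active], d[active],
                                             inv_d[active], node)
            active = active[mask]
            if not len(active):
                continue
            faces = self.leaf_faces[node]
            if faces is not None:
                hits = _segment_hits(origins[active], ends[active],
                                     self.tri[faces])
                if excluded is not None:
                    hits &= ~excluded(active)[:, faces]
                hit[active] |= hits.any(axis=1)
            else:
                l, r = self.children[node]
                stack.append((l, active))
                stack.append((r, active))
        return hit


# ---------------------------------------------------------------------------
# visibility
# ---------------------------------------------------------------------------


def _face_adjacency(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Boolean face x face matrix: faces sharing at least one vertex."""
    m = len(mesh.faces)
    rows = np.repeat(np.arange(m), 3)
    cols = mesh.faces.ravel()
    inc = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(m, mesh.n_vertices))
    adj = (inc @ inc.T).tocsr()
    return adj


def segment_occluded(a, b, mesh: TriangleMesh,
                     excluded_face: int | None = None,
                     engine=None) -> bool:
    """True iff some mesh triangle other than ``excluded_face`` intersects
    the open segment ab."""
    a = np.asarray(a, dtype=np.float64).reshape(3)
    b = np.asarray(b, dtype=np.float64).reshape(3)
    if np.array_equal(a, b):
        raise ParameterError("segment endpoints coincide")
    if engine is None:
        engine = BruteForceOcclusion(mesh)
    if excluded_face is None:
        exc = None
    else:
        def exc(idx):
            mask = np.zeros((len(idx), len(mesh.faces)), dtype=bool)
            mask[:, excluded_face] = True
            return mask
    return bool(engine.any_hit(a[None], b[None], excluded=exc)[0])


def visibility_counts(mesh: TriangleMesh, viewpoints: ViewpointSet,
                      probe_rule: str = "centroid",
                      method: str = "bvh",
                      min_views: int = 2) -> VisibilityResult:
    """Count, per face, from how many of the 26 viewpoints it is visible.

    probe_rule ``centroid``: the face is probed at its centroid offset by
    eps along its normal toward the viewpoint's side.  ``any-vertex``: the
    face is visible if any of its three (offset) vertices is.
    """
    if probe_rule not in {"centroid", "any-vertex"}:
        raise ParameterError(f"unknown probe_rule {probe_rule!r}")
    if method not in {"bvh", "brute"}:
        raise ParameterError(f"unknown method {method!r}")
    if min_views < 1 or min_views > N_VIEWPOINTS:
        raise ParameterError("min_views must be in [1, 26]")
    engine = (TriangleBVH(mesh) if method == "bvh"
              else BruteForceOcclusion(mesh))
    adj = _face_adjacency(mesh)
    fnormals, _ = face_normals_areas(mesh)
    eps = PROBE_EPS_FRAC * viewpoints.side
    n_faces = len(mesh.faces)
    counts = np.zeros(n_faces, dtype=np.int64)

    if probe_rule == "centroid":
        base_pts = mesh.vertices[mesh.faces].mean(axis=1)   # (m, 3)
        probe_face = np.arange(n_faces)
    else:
        base_pts = mesh.vertices[mesh.faces].reshape(-1, 3)  # (3m, 3)
        probe_face = np.repeat(np.arange(n_faces), 3)
        fnormals = np.repeat(fnormals, 3, axis=0)

    def excluded(active_idx):
        # ignore the probed face and its vertex-adjacent faces
        return adj[probe_face[active_idx]].toarray()

    for q in viewpoints.points:
        side = np.sign(((q - base_pts) * fnormals).sum(axis=1))
        side = np.where(side == 0, 1.0, side)
        origins = base_pts + eps * fnormals * side[:, None]
        ends = np.broadcast_to(q, origins.shape)
        occluded = engine.any_hit(origins, ends, excluded=excluded)
        visible = ~occluded
        if probe_rule == "centroid":
            counts += visible
        else:
            counts += np.logical_or.reduce(visible.reshape(-1, 3), axis=1)

    keep = counts >= min_views
    return VisibilityResult(counts=counts, keep=keep, min_views=min_views)


def extract_exterior(mesh: TriangleMesh,
                     viewpoints: ViewpointSet | None = None,
                     probe_rule: str = "centroid",
                     min_views: int = 2,
                     method: str = "bvh"):
    """Remove faces not visible from at least ``min_views`` viewpoints.

    Returns ``(exterior_mesh, VisibilityResult)``; the result's
    ``face_map`` maps output faces back to input face indices.
    Unreferenced vertices are dropped.
    """
    if viewpoints is None:
        viewpoints = build_viewpoint_set(mesh)
    result = visibility_counts(mesh, viewpoints, probe_rule=probe_rule,
                               method=method, min_views=min_views)
    keep_idx = np.flatnonzero(result.keep)
    if not len(keep_idx):
        raise EmptyExteriorError(
            "no face visible from >= %d viewpoints; check face winding"
            % min_views)
    faces = mesh.faces[keep_idx]
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[faces.ravel()] = True
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    out = TriangleMesh(mesh.vertices[used], remap[faces],
                       vertex_scalar=None if mesh.vertex_scalar is None
                       else mesh.vertex_scalar[used])
    result.face_map = keep_idx
    return out, result
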