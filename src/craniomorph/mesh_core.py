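"""Mesh and landmark data model, file I/O and elementary geometry.

Crania are represented as triangle meshes in millimetres.  Eight standard
craniometric landmarks (glabella, inion, opisthion, nasospinale and the
paired mastoidale / zygomaticofrontale points) accompany each specimen and
drive the initial rigid alignment; all downstream statistics run on dense
quasi-landmarks instead, so landmark placement error has limited influence.

STL files carry no vertex sharing, so meshes are welded on load: vertices
closer than ``1e-6`` times the bounding-box diagonal are merged to rebuild
the connectivity needed by visibility culling and dense correspondence.
"""

from __future__ import annotations

import heapq
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .exceptions import DegenerateInputError, MeshFormatError, ParameterError

logger = logging.getLogger(__name__)

#: Face count the pipeline simplifies raw surfaces to before extraction.
DEFAULT_TARGET_FACES = 50_000

#: Relative tolerance (fraction of bounding-box diagonal) for vertex welding.
WELD_TOLERANCE = 1e-6

#: Canonical landmark vocabulary (order fixed for matrix layouts).
LANDMARK_NAMES = (
    "glabella",
    "inion",
    "opisthion",
    "nasospinale",
    "mastoidale_dx",
    "mastoidale_sin",
    "zygomaticofrontale_dx",
    "zygomaticofrontale_sin",
)


def _canonical_landmark_name(raw: str) -> str:
    name = raw.strip().lower().replace(",", " ").replace("-", " ")
    name = "_".join(name.split())
    if name not in LANDMARK_NAMES:
        raise MeshFormatError(
            f"unknown landmark name {raw!r}; expected one of {LANDMARK_NAMES}"
        )
    return name


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """A triangle surface in mm with optional per-vertex scalar channel.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    vertex_scalar : optional (n,) float array, e.g. a dimorphism map value
        exported to the PLY ``quality`` property.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalar: np.ndarray | None = None
    n_dropped_faces: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("non-finite vertex coordinate")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError("face index out of range")
            if (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ).any():
                raise MeshFormatError("face with repeated vertex index")
        if self.vertex_scalar is not None:
            self.vertex_scalar = np.asarray(self.vertex_scalar, dtype=np.float64)
            if self.vertex_scalar.shape != (len(self.vertices),):
                raise MeshFormatError("vertex_scalar must be one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounding_box_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_scalar is None else self.vertex_scalar.copy(),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "TriangleMesh":
        """Return a rigidly (or similarity) transformed copy: ``s * v @ R + t``."""
        v = self.vertices * float(scale)
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=np.float64)
        if translation is not None:
            v = v + np.asarray(translation, dtype=np.float64)
        return TriangleMesh(v, self.faces.copy(),
                            None if self.vertex_scalar is None
                            else self.vertex_scalar.copy())


@dataclass
class LandmarkSet:
    """The eight named craniometric landmarks of one specimen (mm)."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        cleaned: dict[str, np.ndarray] = {}
        for raw, xyz in self.points.items():
            name = _canonical_landmark_name(raw)
            arr = np.asarray(xyz, dtype=np.float64).reshape(3)
            if not np.isfinite(arr).all():
                raise MeshFormatError(f"non-finite coordinate for landmark {name}")
            cleaned[name] = arr
        missing = set(LANDMARK_NAMES) - set(cleaned)
        if missing:
            raise MeshFormatError(f"missing landmarks: {sorted(missing)}")
        if len(cleaned) != len(LANDMARK_NAMES):
            raise MeshFormatError("landmark set must contain exactly 8 entries")
        self.points = {name: cleaned[name] for name in LANDMARK_NAMES}

    def as_array(self) -> np.ndarray:
        """Landmark coordinates as an (8, 3) array in canonical order."""
        return np.stack([self.points[name] for name in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, coords: np.ndarray) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (8, 3):
            raise MeshFormatError("landmark array must have shape (8, 3)")
        return cls({name: coords[i] for i, name in enumerate(LANDMARK_NAMES)})

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Specimen:
    """One cranium: mesh + landmarks + study metadata."""

    id: str
    population: str
    sex: str  # "F", "M" or "unknown"
    mesh: TriangleMesh
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        if self.sex not in {"F", "M", "unknown"}:
            raise ParameterError(f"sex must be F, M or unknown, got {self.sex!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray):
    """Remove faces with repeated indices or (numerically) zero area."""
    if not len(faces):
        return faces, 0
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    scale = max(float(np.ptp(vertices, axis=0).max()), 1.0) if len(vertices) else 1.0
    zero_area = area2 <= (1e-14 * scale * scale)
    bad = repeated | zero_area
    return faces[~bad], int(bad.sum())


def weld_vertices(vertices: np.ndarray, faces: np.ndarray,
                  tolerance: float | None = None):
    """Merge vertices closer than ``tolerance`` (default 1e-6 x bbox diagonal).

    Returns (vertices, faces, n_dropped_faces); faces that become degenerate
    after merging are removed.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if tolerance is None:
        diag = float(np.linalg.norm(np.ptp(vertices, axis=0))) if len(vertices) else 0.0
        tolerance = WELD_TOLERANCE * diag
    parent = np.arange(len(vertices))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tolerance > 0 and len(vertices) > 1:
        tree = cKDTree(vertices)
        for i, j in tree.query_pairs(tolerance):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(vertices))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    new_vertices = vertices[uniq]
    new_faces = inverse[faces]
    new_faces, dropped = _drop_degenerate_faces(new_vertices, new_faces)
    # drop unreferenced vertices
    used = np.zeros(len(new_vertices), dtype=bool)
    if len(new_faces):
        used[new_faces.ravel()] = True
    remap = -np.ones(len(new_vertices), dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    return new_vertices[used], remap[new_faces], dropped


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in {"stl", "ply"}:
        raise MeshFormatError(f"unknown mesh format {fmt!r} (expected stl or ply)")
    return fmt


def read_mesh(path, fmt: str | None = None, weld: bool = True) -> TriangleMesh:
    """Load an STL or PLY mesh (binary or ASCII) into a validated TriangleMesh.

    Degenerate faces are dropped (count logged and recorded on the mesh);
    STL soups are welded to recover vertex connectivity.  A per-vertex
    ``quality`` property in PLY files is loaded into ``vertex_scalar``.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    fmt = _infer_format(path, fmt)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no geometry")
        loaded = trimesh.util.concatenate(geoms)
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(faces) == 0:
        raise MeshFormatError(f"{path}: mesh has no faces")
    scalar = None
    raw = loaded.metadata.get("_ply_raw") if hasattr(loaded, "metadata") else None
    if raw and "vertex" in raw:
        vdata = raw["vertex"].get("data")
        names = (vdata.dtype.names if isinstance(vdata, np.ndarray)
                 and vdata.dtype.names else
                 tuple(vdata.keys()) if isinstance(vdata, dict) else ())
        if "quality" in names:
            scalar = np.asarray(vdata["quality"], dtype=np.float64).ravel()
    dropped = 0
    if weld and scalar is None:
        vertices, faces, dropped = weld_vertices(vertices, faces)
    else:
        faces, dropped = _drop_degenerate_faces(vertices, faces)
    if len(faces) == 0:
        raise MeshFormatError(f"{path}: no valid faces after cleaning")
    if dropped:
        logger.info("%s: dropped %d degenerate face(s)", path.name, dropped)
    mesh = TriangleMesh(vertices, faces, vertex_scalar=scalar)
    mesh.n_dropped_faces = dropped
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None,
               binary: bool = False) -> None:
    """Write STL or PLY; a vertex_scalar channel goes to PLY ``quality``."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply" and mesh.vertex_scalar is not None:
        tm.vertex_attributes["quality"] = mesh.vertex_scalar.astype(np.float32)
    if fmt == "ply":
        data = tm.export(file_type="ply",
                         encoding="binary" if binary else "ascii")
    else:
        data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_landmarks(path) -> LandmarkSet:
    """Read one specimen's landmarks from a ``name,x,y,z`` CSV file."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"landmark file not found: {path}")
    df = pd.read_csv(path, header=None, comment="#",
                     names=["name", "x", "y", "z"], skipinitialspace=True)
    if len(df) and str(df.iloc[0]["name"]).strip().lower() == "name":
        df = df.iloc[1:]
    points = {}
    for _, row in df.iterrows():
        try:
            xyz = np.array([float(row.x), float(row.y), float(row.z)])
        except (TypeError, ValueError) as exc:
            raise MeshFormatError(
                f"{path}: bad coordinate in row {row.tolist()!r}") from exc
        points[str(row["name"])] = xyz
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("name,x,y,z\n")
        for name, xyz in landmarks.points.items():
            fh.write(f"{name},{xyz[0]:.9g},{xyz[1]:.9g},{xyz[2]:.9g}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the study metadata table (columns id, population, sex)."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "population", "sex"}
    if not required.issubset(df.columns):
        raise MeshFormatError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise MeshFormatError(f"duplicate specimen ids in metadata: {dupes}")
    return df


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------


def face_normals_areas(mesh: TriangleMesh):
    """Unit face normals (winding orientation) and face areas."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norm
    normals = np.zeros_like(cross)
    ok = norm > 0
    normals[ok] = cross[ok] / norm[ok, None]
    return normals, areas


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex unit normals: area-weighted mean of incident face normals.

    Orientation follows the face winding (consistently outward for closed,
    correctly wound surfaces).  Isolated vertices get a zero vector.
    """
    fnormals, areas = face_normals_areas(mesh)
    weighted = fnormals * areas[:, None]
    out = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(out, mesh.faces[:, c], weighted)
    norm = np.linalg.norm(out, axis=1)
    ok = norm > 0
    out[ok] /= norm[ok, None]
    if not ok.all():
        logger.warning("vertex_normals: %d isolated/degenerate vertex normals "
                       "set to zero", int((~ok).sum()))
    return out


def max_pairwise_distance(mesh_or_points) -> float:
    """Diameter of the vertex set (max pairwise Euclidean distance, mm).

    Uses the convex hull to restrict the O(N^2) scan; falls back to the full
    scan for degenerate (flat / collinear) inputs, so the result always
    equals brute force.
    """
    pts = (mesh_or_points.vertices
           if isinstance(mesh_or_points, TriangleMesh) else
           np.asarray(mesh_or_points, dtype=np.float64))
    if pts.ndim != 2 or len(pts) < 2:
        raise DegenerateInputError("need at least 2 points for a diameter")
    candidates = pts
    if len(pts) > 16:
        try:
            hull = ConvexHull(pts)
            candidates = pts[hull.vertices]
        except QhullError:
            candidates = np.unique(pts, axis=0)
            if len(candidates) < 2:
                raise DegenerateInputError("all points coincide")
    diff = candidates[:, None, :] - candidates[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


# ---------------------------------------------------------------------------
# quadric-error simplification
# ---------------------------------------------------------------------------


def _vertex_quadrics(vertices, faces):
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    area = 0.5 * norm
    n = np.zeros_like(cross)
    ok = norm > 0
    n[ok] = cross[ok] / norm[ok, None]
    d = -(n * tri[:, 0]).sum(axis=1)
    plane = np.concatenate([n, d[:, None]], axis=1)  # (m, 4)
    K = plane[:, :, None] * plane[:, None, :] * area[:, None, None]
    Q = np.zeros((len(vertices), 4, 4))
    for c in range(3):
        np.add.at(Q, faces[:, c], K)
    return Q


def _collapse_target(Q: np.ndarray, pu: np.ndarray, pv: np.ndarray):
    """Optimal position and cost for contracting an edge with joint quadric Q."""
    A = Q[:3, :3]
    b = Q[:3, 3]
    candidates = [pu, pv, 0.5 * (pu + pv)]
    try:
        x = np.linalg.solve(A, -b)
        if np.isfinite(x).all() and np.linalg.norm(x - 0.5 * (pu + pv)) < 10 * (
                np.linalg.norm(pu - pv) + 1e-12):
            candidates.insert(0, x)
    except np.linalg.LinAlgError:
        pass
    best, best_cost = None, np.inf
    for p in candidates:
        h = np.append(p, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = p, cost
    return best, max(best_cost, 0.0)


def simplify_mesh(mesh: TriangleMesh, target_faces: int,
                  max_deviation: float | None = None) -> TriangleMesh:
    """Quadric-error edge-collapse decimation to approximately target_faces.

    Preserves topology via a link condition and rejects collapses that flip
    face normals.  If ``max_deviation`` is given (fraction of the input
    bounding-box diagonal), the symmetric sampled surface deviation is
    verified and a DegenerateInputError raised when exceeded.
    """
    if target_faces < 4:
        raise ParameterError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return mesh.copy()

    V = mesh.vertices.copy()
    alive_v = np.ones(len(V), dtype=bool)
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    v_faces: list[set[int]] = [set() for _ in range(len(V))]
    for fi, f in faces.items():
        for v in f:
            v_faces[v].add(fi)
    Q = _vertex_quadrics(V, mesh.faces)

    stamp = np.zeros(len(V), dtype=np.int64)
    heap: list[tuple] = []

    def neighbours(u):
        out = set()
        for fi in v_faces[u]:
            out.update(faces[fi])
        out.discard(u)
        return out

    def push_edge(u, v):
        if u > v:
            u, v = v, u
        p, cost = _collapse_target(Q[u] + Q[v], V[u], V[v])
        heapq.heappush(heap, (cost, u, v, stamp[u], stamp[v], p))

    edges = set()
    for f in faces.values():
        edges.update({tuple(sorted(e)) for e in
                      ((f[0], f[1]), (f[1], f[2]), (f[0], f[2]))})
    for u, v in edges:
        push_edge(u, v)

    n_faces = len(faces)
    while n_faces > target_faces and heap:
        cost, u, v, su, sv, p = heapq.heappop(heap)
        if not (alive_v[u] and alive_v[v]):
            continue
        if stamp[u] != su or stamp[v] != sv:
            continue
        shared = v_faces[u] & v_faces[v]
        if not shared:
            continue
        # link condition: common neighbours must be exactly those opposite
        # the shared faces, else the collapse pinches the surface
        common = neighbours(u) & neighbours(v)
        opposite = set()
        for fi in shared:
            opposite.update(set(faces[fi]) - {u, v})
        if common != opposite or len(shared) > 2:
            continue
        # normal-flip check over surviving faces around u and v
        flip = False
        for fi in (v_faces[u] | v_faces[v]) - shared:
            f = faces[fi]
            tri_old = V[list(f)]
            tri_new = np.array([p if w in (u, v) else V[w] for w in f])
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if n_old @ n_new <= 0:
                flip = True
                break
        if flip:
            continue
        # collapse v into u at position p
        V[u] = p
        Q[u] = Q[u] + Q[v]
        alive_v[v] = False
        for fi in shared:
            for w in faces[fi]:
                v_faces[w].discard(fi)
            del faces[fi]
            n_faces -= 1
        for fi in list(v_faces[v]):
            f = faces[fi]
            faces[fi] = tuple(u if w == v else w for w in f)
            v_faces[u].add(fi)
        v_faces[v] = set()
        stamp[u] += 1
        for w in neighbours(u):
            push_edge(u, w)

    if n_faces > int(np.ceil(1.05 * target_faces)):
        raise DegenerateInputError(
            f"simplification stalled at {n_faces} faces (target {target_faces})")

    remap = -np.ones(len(V), dtype=np.int64)
    used = sorted({w for f in faces.values() for w in f})
    remap[used] = np.arange(len(used))
    new_faces = np.array([[remap[w] for w in f] for f in faces.values()],
                         dtype=np.int64)
    out = TriangleMesh(V[used], new_faces)
    if max_deviation is not None:
        dev = symmetric_surface_deviation(mesh, out)
        limit = max_deviation * mesh.bounding_box_diagonal()
        if dev > limit:
            raise DegenerateInputError(
                f"simplified surface deviates {dev:.4g} mm > limit {limit:.4g} mm")
    return out


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point to ``p`` on each triangle (Voronoi-region walk)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    out = np.empty_like(tri[:, 0])
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done = m.copy()
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    # edge AC
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    # edge BC
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def _point_triangle_distances(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Distance from each point to the nearest point on the mesh surface."""
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        closest = closest_point_on_triangles(p, tri)
        out[i] = np.linalg.norm(p - closest, axis=1).min()
    return out


def symmetric_surface_deviation(a: TriangleMesh, b: TriangleMesh,
                                n_samples: int = 500, seed: int = 0) -> float:
    """Sampled symmetric (max of both directions) surface deviation in mm."""
    rng = np.random.default_rng(seed)

    def sample(mesh):
        _, areas = face_normals_areas(mesh)
        p = areas / areas.sum()
        idx = rng.choice(len(mesh.faces), size=n_samples, p=p)
        u = rng.random((n_samples, 1))
        v = rng.random((n_samples, 1))
        flip = (u + v) > 1
        u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
        tri = mesh.vertices[mesh.faces[idx]]
        return tri[:, 0] + u * (tri[:, 1] - tri[:, 0]) + v * (tri[:, 2] - tri[:, 0])

    d_ab = _point_triangle_distances(sample(a), b).max()
    d_ba = _point_triangle_distances(sample(b), a).max()
    return float(max(d_ab, d_ba))
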