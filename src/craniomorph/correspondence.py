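"""Dense correspondence across crania (CPD-DCA).

Vertex-wise homology between specimens is established in four steps:

1. generalized Procrustes analysis (GPA) of the eight anatomical landmarks
   gives each specimen a rigid transform into a common frame;
2. coherent point drift (CPD) non-rigidly deforms each rigidly aligned
   specimen surface onto a template ("base") mesh;
3. a closest-point search from every base vertex into the deformed specimen
   yields quasi-landmarks — the matched specimen vertices read off in the
   *rigid* (pre-deformation) frame, so real specimen geometry rather than
   the smoothed CPD field enters the statistics; matches farther than
   ``prune_factor`` times the median match distance are masked out;
4. a second GPA over all surviving quasi-landmarks removes the residual
   influence of landmark placement error.

Form space keeps each specimen's scale during the second GPA; shape space
normalises centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DegenerateInputError, ParameterError, RegistrationError
from .mesh_core import Specimen, TriangleMesh

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesAlignment:
    """Result of a GPA run: per-configuration similarity parameters.

    ``aligned[i] = scales[i] * (configs[i] - translations[i]) @ rotations[i]``
    Rotations are proper (det +1); the consensus centroid is at the origin
    and, with scaling enabled, the consensus has unit centroid size.
    """

    rotations: np.ndarray      # (n, 3, 3)
    translations: np.ndarray   # (n, 3) centroids removed from each config
    scales: np.ndarray         # (n,) 1.0 when with_scaling=False
    consensus: np.ndarray      # (k, 3)
    aligned: np.ndarray        # (n, k, 3)
    rmsd: float
    n_iterations: int
    with_scaling: bool

    def apply(self, index: int, points: np.ndarray) -> np.ndarray:
        """Map arbitrary points of configuration ``index`` into the
        consensus frame."""
        return (self.scales[index]
                * (np.asarray(points) - self.translations[index])
                @ self.rotations[index])


def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimising ||source @ R - target||_F."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def centroid_size(config: np.ndarray) -> float:
    """sqrt of summed squared distances of points from their centroid."""
    config = np.asarray(config, dtype=np.float64)
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum()))


def _canonical_frame(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation sending the consensus to principal-axis orientation.

    Eigenvectors of the 3x3 consensus covariance, eigenvalues descending;
    each axis's sign is fixed by making its largest-magnitude component
    positive, and the determinant is forced to +1.
    """
    C = consensus.T @ consensus
    evals, vecs = np.linalg.eigh(C)
    vecs = vecs[:, ::-1]
    for j in range(3):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def gpa(configurations, with_scaling: bool = False,
        tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> ProcrustesAlignment:
    """Iterative generalized Procrustes superimposition.

    Configurations are centred, optionally scaled to unit centroid size,
    and rotated to the evolving consensus until the consensus moves less
    than ``tol`` (RMS) or ``max_iter`` iterations.  Reflections are never
    permitted.
    """
    X = np.asarray(configurations, dtype=np.float64)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ParameterError("configurations must be an (n, k, 3) array")
    n, k, _ = X.shape
    if n < 2:
        raise ParameterError("GPA needs at least 2 configurations")
    if k < 3:
        raise ParameterError("GPA needs at least 3 points per configuration")
    translations = X.mean(axis=1)
    centered = X - translations[:, None, :]
    for i in range(n):
        if np.linalg.matrix_rank(centered[i], tol=1e-9 * max(
                1.0, np.abs(centered[i]).max())) < 2:
            raise DegenerateInputError(
                f"configuration {i} is collinear or degenerate")
    sizes = np.sqrt((centered ** 2).sum(axis=(1, 2)))
    if with_scaling:
        working = centered / sizes[:, None, None]
        scales = 1.0 / sizes
    else:
        working = centered.copy()
        scales = np.ones(n)

    rotations = np.tile(np.eye(3), (n, 1, 1))
    # initialise at the mean: re-running GPA on already-aligned input then
    # starts at its own fixed point instead of a rotated frame
    consensus = working.mean(axis=0)
    if with_scaling:
        cs0 = centroid_size(consensus)
        if cs0 > 0:
            consensus = consensus / cs0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            R = kabsch_rotation(working[i], consensus)
            rotations[i] = R
        aligned = np.einsum("nkj,njm->nkm", working, rotations)
        new_consensus = aligned.mean(axis=0)
        if with_scaling:
            cs = centroid_size(new_consensus)
            if cs > 0:
                new_consensus = new_consensus / cs
        shift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if shift < tol:
            break
    aligned = np.einsum("nkj,njm->nkm", working, rotations)
    # canonicalise the (otherwise arbitrary) global frame: consensus
    # principal axes -> coordinate axes, deterministic signs, det +1;
    # output rows then do not depend on the inputs' initial orientations
    V = _canonical_frame(consensus)
    consensus = consensus @ V
    aligned = aligned @ V
    rotations = rotations @ V
    rmsd = float(np.sqrt(((aligned - consensus) ** 2).sum(axis=(1, 2)).mean()))
    return ProcrustesAlignment(
        rotations=rotations, translations=translations, scales=scales,
        consensus=consensus - consensus.mean(axis=0), aligned=aligned,
        rmsd=rmsd, n_iterations=n_iter, with_scaling=with_scaling)


# ---------------------------------------------------------------------------
# coherent point drift (non-rigid)
# ---------------------------------------------------------------------------


@dataclass
class CPDParams:
    """Free parameters of non-rigid CPD.

    beta is the Gaussian kernel width as a fraction of the moving cloud's
    RMS scale (motion smoothness length); lam weights the coherence
    regulariser; w is the uniform-outlier mixture weight.  Clouds larger
    than ``low_rank_threshold`` points use a rank-``low_rank_modes``
    eigendecomposition of the kernel.
    """

    beta: float = 0.5
    lam: float = 2.0
    w: float = 0.1
    max_iter: int = 150
    tol: float = 1e-6
    low_rank_modes: int = 100
    low_rank_threshold: int = 5000

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ParameterError("beta must be > 0")
        if self.lam <= 0:
            raise ParameterError("lambda must be > 0")
        if not 0 <= self.w < 1:
            raise ParameterError("w must be in [0, 1)")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


@dataclass
class CPDResult:
    displaced: np.ndarray      # moving cloud after deformation (M, 3)
    sigma2_trace: list = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0


def cpd_nonrigid(source_points: np.ndarray, target_points: np.ndarray,
                 params: CPDParams | None = None) -> CPDResult:
    """Deform ``source_points`` toward ``target_points`` with non-rigid CPD.

    The moving cloud is treated as Gaussian-mixture centroids displaced by
    a motion-coherent field T(Y) = Y + G W, G the Gaussian kernel of width
    beta; EM alternates soft assignments with a regularised solve for W.
    """
    params = params or CPDParams()
    Y = np.asarray(source_points, dtype=np.float64)
    X = np.asarray(target_points, dtype=np.float64)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[1] != 3 or X.shape[1] != 3:
        raise ParameterError("point clouds must be (n, 3) arrays")
    M, N = len(Y), len(X)
    if M < 10 or N < 10:
        raise ParameterError("CPD needs at least 10 points per cloud")

    scale = np.sqrt(((Y - Y.mean(axis=0)) ** 2).sum(axis=1).mean())
    beta = params.beta * max(scale, 1e-12)
    diff = Y[:, None, :] - Y[None, :, :]
    G = np.exp(-(diff ** 2).sum(-1) / (2.0 * beta ** 2))

    low_rank = M > params.low_rank_threshold
    if low_rank:
        from scipy.sparse.linalg import eigsh
        kmodes = min(params.low_rank_modes, M - 2)
        lam_G, Qg = eigsh(G, k=kmodes, which="LM")
        order = np.argsort(lam_G)[::-1]
        lam_G, Qg = lam_G[order], Qg[:, order]

    sigma2 = ((Y[:, None, :] - X[None, :, :]) ** 2).sum() / (3.0 * M * N) \
        if M * N <= 4_000_000 else _initial_sigma2(Y, X)
    W = np.zeros((M, 3))
    T = Y.copy()
    trace = [float(sigma2)]
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # E-step
        d2 = ((T[:, None, :] - X[None, :, :]) ** 2).sum(-1)  # (M, N)
        P = np.exp(-d2 / (2.0 * sigma2))
        c = ((2 * np.pi * sigma2) ** 1.5) * params.w / (1 - params.w) * M / N
        denom = P.sum(axis=0) + c
        P = P / denom[None, :]
        P1 = P.sum(axis=1)          # (M,)
        Pt1 = P.sum(axis=0)         # (N,)
        Np = P1.sum()
        PX = P @ X
        # M-step: (diag(P1) G + lam sigma2 I) W = PX - diag(P1) Y
        rhs = PX - P1[:, None] * Y
        reg = params.lam * sigma2
        if low_rank:
            # Woodbury with G ~ Qg diag(lam_G) Qg'
            dP1 = P1[:, None]
            A = Qg * dP1                       # diag(P1) Qg
            inner = np.diag(1.0 / lam_G) + (Qg.T @ A)
            W = (rhs - A @ np.linalg.solve(inner, Qg.T @ rhs)) / reg
        else:
            lhs = G * P1[:, None] + reg * np.eye(M)
            W = np.linalg.solve(lhs, rhs)
        if not np.isfinite(W).all():
            raise RegistrationError(f"non-finite CPD update at iteration {it}")
        T = Y + G @ W
        # sigma2 update
        xPx = (Pt1 * (X ** 2).sum(axis=1)).sum()
        trPXT = (PX * T).sum()
        tPt = (P1 * (T ** 2).sum(axis=1)).sum()
        sigma2_new = (xPx - 2.0 * trPXT + tPt) / (3.0 * Np)
        sigma2_new = max(float(sigma2_new), 1e-12 * scale ** 2)
        trace.append(sigma2_new)
        if abs(sigma2 - sigma2_new) < params.tol * max(sigma2, 1e-300):
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new
    return CPDResult(displaced=T, sigma2_trace=trace,
                     converged=converged, n_iterations=it)


def _initial_sigma2(Y: np.ndarray, X: np.ndarray) -> float:
    """Memory-light initial variance for very large clouds."""
    total = 0.0
    for chunk in np.array_split(Y, max(1, len(Y) // 512)):
        total += ((chunk[:, None, :] - X[None, :, :]) ** 2).sum()
    return total / (3.0 * len(Y) * len(X))


# ---------------------------------------------------------------------------
# quasi-landmark matching and assembly
# ---------------------------------------------------------------------------


@dataclass
class QuasiLandmarkMatch:
    """One specimen matched to the base: coordinates in its rigid frame."""

    coordinates: np.ndarray   # (k_base, 3)
    mask: np.ndarray          # (k_base,) bool
    distances: np.ndarray     # (k_base,) match distances (deformed frame)


@dataclass
class CorrespondedSample:
    """Homologous quasi-landmark coordinates across specimens."""

    base_mesh: TriangleMesh
    mask: np.ndarray            # (k_base,) bool, identical across specimens
    coordinates: np.ndarray     # (n_specimens, 3 * k) flattened rows
    specimen_ids: list
    space: str                  # "form" or "shape"
    alignment: ProcrustesAlignment | None = None
    distances: np.ndarray | None = None  # (n_specimens, k_base)

    @property
    def k(self) -> int:
        return int(self.mask.sum())

    def rows_as_configs(self) -> np.ndarray:
        return self.coordinates.reshape(len(self.coordinates), -1, 3)

    def save(self, path) -> None:
        np.savez(path,
                 base_vertices=self.base_mesh.vertices,
                 base_faces=self.base_mesh.faces,
                 mask=self.mask,
                 coordinates=self.coordinates,
                 specimen_ids=np.array(self.specimen_ids, dtype=object),
                 space=np.array(self.space),
                 distances=(np.zeros((0, 0)) if self.distances is None
                            else self.distances),
                 allow_pickle=True)

    @classmethod
    def load(cls, path) -> "CorrespondedSample":
        data = np.load(path, allow_pickle=True)
        distances = data["distances"]
        return cls(
            base_mesh=TriangleMesh(data["base_vertices"], data["base_faces"]),
            mask=data["mask"].astype(bool),
            coordinates=data["coordinates"],
            specimen_ids=[str(s) for s in data["specimen_ids"]],
            space=str(data["space"]),
            distances=None if distances.size == 0 else distances)


def match_quasi_landmarks(base_vertices: np.ndarray,
                          specimen_deformed: np.ndarray,
                          specimen_rigid: np.ndarray,
                          prune_factor: float = 3.0) -> QuasiLandmarkMatch:
    """Closest-point matching from base vertices into the deformed specimen.

    For every base vertex the nearest deformed-specimen vertex is found;
    the quasi-landmark records that vertex's position in the specimen's
    rigidly aligned (pre-deformation) frame.  Matches with distance above
    ``prune_factor`` x median are masked out.
    """
    base_vertices = np.asarray(base_vertices, dtype=np.float64)
    specimen_deformed = np.asarray(specimen_deformed, dtype=np.float64)
    specimen_rigid = np.asarray(specimen_rigid, dtype=np.float64)
    if specimen_deformed.shape != specimen_rigid.shape:
        raise ParameterError("deformed and rigid specimen shapes differ")
    tree = cKDTree(specimen_deformed)
    distances, idx = tree.query(base_vertices)
    coords = specimen_rigid[idx]
    median = float(np.median(distances))
    mask = distances <= prune_factor * median if median > 0 \
        else np.ones(len(distances), dtype=bool)
    if mask.sum() < 3:
        raise RegistrationError(
            f"only {int(mask.sum())} quasi-landmarks survive pruning")
    return QuasiLandmarkMatch(coordinates=coords, mask=mask,
                              distances=distances)


def assemble_corresponded(matches: list[QuasiLandmarkMatch],
                          base_mesh: TriangleMesh,
                          specimen_ids: list,
                          space: str = "form") -> CorrespondedSample:
    """Intersect per-specimen masks and re-align via a second GPA."""
    if space not in {"form", "shape"}:
        raise ParameterError("space must be 'form' or 'shape'")
    if len(matches) < 2:
        raise ParameterError("need at least 2 matched specimens")
    mask = np.logical_and.reduce([m.mask for m in matches])
    if int(mask.sum()) < 3:
        raise RegistrationError("empty (or too small) mask intersection")
    configs = np.stack([m.coordinates[mask] for m in matches])
    alignment = gpa(configs, with_scaling=(space == "shape"))
    coords = alignment.aligned.reshape(len(matches), -1)
    return CorrespondedSample(
        base_mesh=base_mesh, mask=mask, coordinates=coords,
        specimen_ids=list(specimen_ids), space=space, alignment=alignment,
        distances=np.stack([m.distances for m in matches]))


# ---------------------------------------------------------------------------
# study-level drivers
# ---------------------------------------------------------------------------


def select_base_specimen(landmark_configs: np.ndarray) -> int:
    """Index of the configuration closest to the landmark GPA consensus."""
    fit = gpa(landmark_configs, with_scaling=False)
    resid = ((fit.aligned - fit.consensus) ** 2).sum(axis=(1, 2))
    return int(np.argmin(resid))


def correspond_study(specimens: list[Specimen],
                     base: int | str = "auto",
                     cpd_params: CPDParams | None = None,
                     prune_factor: float = 3.0,
                     space: str = "form") -> CorrespondedSample:
    """Full CPD-DCA over a list of specimens.

    ``base`` selects the template specimen: ``"auto"`` picks the specimen
    whose landmark configuration is closest to the landmark GPA consensus,
    otherwise pass a specimen id or index.
    """
    if len(specimens) < 2:
        raise ParameterError("need at least 2 specimens")
    cpd_params = cpd_params or CPDParams()
    lm = np.stack([s.landmarks.as_array() for s in specimens])
    lm_fit = gpa(lm, with_scaling=False)

    if base == "auto":
        base_idx = select_base_specimen(lm)
    elif isinstance(base, str):
        ids = [s.id for s in specimens]
        if base not in ids:
            raise ParameterError(f"unknown base specimen id {base!r}")
        base_idx = ids.index(base)
    else:
        base_idx = int(base)

    rigid = [lm_fit.apply(i, s.mesh.vertices)
             for i, s in enumerate(specimens)]
    base_vertices = rigid[base_idx]
    base_mesh = TriangleMesh(base_vertices, specimens[base_idx].mesh.faces)

    matches = []
    for i, spec in enumerate(specimens):
        if i == base_idx:
            deformed = rigid[i]
        else:
            deformed = cpd_nonrigid(rigid[i], base_vertices,
                                    cpd_params).displaced
        matches.append(match_quasi_landmarks(
            base_vertices, deformed, rigid[i], prune_factor=prune_factor))
    return assemble_corresponded(matches, base_mesh,
                                 [s.id for s in specimens], space=space)


def correspond_homologous(specimens: list[Specimen],
                          space: str = "form") -> CorrespondedSample:
    """Correspondence shortcut for vertex-homologous meshes.

    Meshes produced by the synthetic generator share the base-mesh topology,
    so every vertex is already its own quasi-landmark: the CPD/closest-point
    steps reduce to the identity and only the final GPA is needed.  Raises
    if vertex counts differ (real scans must go through
    :func:`correspond_study`).
    """
    if len(specimens) < 2:
        raise ParameterError("need at least 2 specimens")
    counts = {s.mesh.n_vertices for s in specimens}
    if len(counts) != 1:
        raise ParameterError(
            "specimens are not vertex-homologous; use correspond_study")
    configs = np.stack([s.mesh.vertices for s in specimens])
    alignment = gpa(configs, with_scaling=(space == "shape"))
    k = specimens[0].mesh.n_vertices
    base_mesh = TriangleMesh(alignment.consensus.copy(),
                             specimens[0].mesh.faces.copy())
    return CorrespondedSample(
        base_mesh=base_mesh,
        mask=np.ones(k, dtype=bool),
        coordinates=alignment.aligned.reshape(len(specimens), -1),
        specimen_ids=[s.id for s in specimens],
        space=space,
        alignment=alignment)
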