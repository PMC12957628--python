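"""Variability and dimorphism statistics on corresponded crania.

Centroid size, high-dimensional PCA (the quasi-landmark matrix has ~100k
columns for real scans, so the principal components are computed through
the n x n Gram matrix rather than the 3k x 3k covariance), normal-projected
male-female difference maps, and two-way ANOVA / Tukey HSD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correspondence import CorrespondedSample, centroid_size  # noqa: F401
from .exceptions import DegenerateInputError, ParameterError
from .mesh_core import TriangleMesh, vertex_normals


# ---------------------------------------------------------------------------
# high-dimensional PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Principal components of a corresponded coordinate matrix.

    ``components`` rows are orthonormal directions in the 3k-dimensional
    coordinate space; ``scores[i, j]`` is specimen i's coordinate on
    component j.  ``space`` records whether rows came from form (size
    retained) or shape (size removed) superimposition.
    """

    mean: np.ndarray                    # (3k,)
    components: np.ndarray              # (c, 3k)
    scores: np.ndarray                  # (n, c)
    explained_variance: np.ndarray      # (c,)
    explained_variance_ratio: np.ndarray
    space: str = "form"

    @property
    def n_components(self) -> int:
        return len(self.components)

    def transform(self, rows: np.ndarray) -> np.ndarray:
        """Project new coordinate rows into the component space."""
        rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
        if rows.shape[1] != len(self.mean):
            raise ParameterError(
                f"row length {rows.shape[1]} != model dimension {len(self.mean)}")
        return (rows - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(scores)
        return self.mean + scores @ self.components[: scores.shape[1]]


def hd_pca(coordinates: np.ndarray, space: str = "form",
           rank_tol: float = 1e-12) -> PCAModel:
    """PCA via the dual (Gram) route: memory scales with n, not 3k.

    Eigendecomposition of the n x n inner-product matrix of centred rows
    gives scores and variances identical (up to component sign) to the
    direct covariance eigendecomposition.
    """
    X = np.asarray(coordinates, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("coordinate matrix must be 2-D")
    n = len(X)
    if n < 3:
        raise ParameterError("need at least 3 specimens for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    G = Xc @ Xc.T
    total = float(np.trace(G))
    if total <= 0:
        raise DegenerateInputError("all rows identical: zero total variance")
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * evals[0]
    keep[min(n - 1, len(keep)):] = False  # at most n-1 non-trivial components
    evals, evecs = evals[keep], evecs[:, keep]
    svals = np.sqrt(evals)
    scores = evecs * svals[None, :]
    components = (Xc.T @ evecs) / svals[None, :]   # (3k, c)
    return PCAModel(
        mean=mean,
        components=components.T,
        scores=scores,
        explained_variance=evals / (n - 1),
        explained_variance_ratio=evals / total,
        space=space)


def pc_size_correlation(model: PCAModel, sizes: np.ndarray,
                        component: int = 0) -> float:
    """Pearson correlation between a PC's scores and centroid size.

    Reported rather than assumed: on cranial data PC1 typically tracks
    size, but this quantifies it for the sample at hand.
    """
    return float(np.corrcoef(model.scores[:, component], sizes)[0, 1])


# ---------------------------------------------------------------------------
# difference maps
# ---------------------------------------------------------------------------


@dataclass
class DifferenceMap:
    """Signed per-vertex dimorphism map on the consensus surface.

    Positive values mean group A (first label) is more prominent along the
    outward surface normal; units are mm in form space, dimensionless in
    shape space.  Values are defined only on unmasked vertices.
    """

    values: np.ndarray          # (k,) on unmasked vertices
    mask: np.ndarray            # (k_base,) bool
    group_a: str
    group_b: str
    space: str

    def to_mesh(self, consensus_mesh: TriangleMesh) -> TriangleMesh:
        """Attach the map as a vertex scalar channel (PLY quality export)."""
        out = consensus_mesh.copy()
        out.vertex_scalar = self.values.copy()
        return out


def _consensus_submesh(sample: CorrespondedSample) -> TriangleMesh:
    """Grand-mean surface over the unmasked vertices of the base topology."""
    mean_config = sample.rows_as_configs().mean(axis=0)
    mask = sample.mask
    remap = -np.ones(len(mask), dtype=np.int64)
    remap[mask] = np.arange(int(mask.sum()))
    faces = sample.base_mesh.faces
    keep_faces = mask[faces].all(axis=1)
    return TriangleMesh(mean_config, remap[faces[keep_faces]])


def difference_map(sample: CorrespondedSample, group_labels,
                   group_a: str = "M", group_b: str = "F") -> DifferenceMap:
    """Mean group-A minus group-B surface, projected on consensus normals.

    Normals are taken on the grand-mean (consensus) surface so that
    swapping groups exactly negates the map.
    """
    labels = np.asarray(group_labels)
    if len(labels) != len(sample.coordinates):
        raise ParameterError("one label per specimen required")
    in_a = labels == group_a
    in_b = labels == group_b
    if not in_a.any() or not in_b.any():
        raise ParameterError(
            f"both groups must be non-empty (A={int(in_a.sum())}, "
            f"B={int(in_b.sum())})")
    configs = sample.rows_as_configs()
    delta = configs[in_a].mean(axis=0) - configs[in_b].mean(axis=0)  # (k, 3)
    consensus = _consensus_submesh(sample)
    normals = vertex_normals(consensus)
    values = (delta * normals).sum(axis=1)
    return DifferenceMap(values=values, mask=sample.mask.copy(),
                         group_a=group_a, group_b=group_b, space=sample.space)


# ---------------------------------------------------------------------------
# ANOVA and Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Two-way fixed-effects ANOVA summary for sex x population."""

    p_values: dict          # keys: sex, sample, sex:sample
    f_statistics: dict
    df: dict                # includes 'residual'
    ss_type: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("sex", "sample", "sex:sample"):
            rows.append({"source": key, "F": self.f_statistics[key],
                         "p": self.p_values[key], "df": self.df[key]})
        rows.append({"source": "residual", "F": np.nan, "p": np.nan,
                     "df": self.df["residual"]})
        return pd.DataFrame(rows)


def anova_sex_sample(dv, sex_labels, population_labels,
                     ss_type: int = 2) -> AnovaTable:
    """Two-way ANOVA with interaction on a per-specimen scalar.

    The default dependent variable in the pipeline is centroid size.
    Unbalanced designs use Type II sums of squares by default (Type III
    available, computed with sum-to-zero contrasts).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    dv = np.asarray(dv, dtype=np.float64)
    sex = np.asarray(sex_labels).astype(str)
    pop = np.asarray(population_labels).astype(str)
    if not (len(dv) == len(sex) == len(pop)):
        raise ParameterError("dv, sex and population must have equal length")
    if len(np.unique(sex)) < 2 or len(np.unique(pop)) < 2:
        raise ParameterError("each factor needs at least 2 levels")
    cells = pd.crosstab(sex, pop)
    if (cells.values == 0).any():
        raise DegenerateInputError(
            "empty sex x population cell: interaction not estimable")
    if np.ptp(dv) == 0:
        raise DegenerateInputError("dependent variable is constant")
    if ss_type not in (2, 3):
        raise ParameterError("ss_type must be 2 or 3")

    df = pd.DataFrame({"dv": dv, "sex": sex, "pop": pop})
    contrast = "Sum" if ss_type == 3 else "Treatment"
    model = ols(f"dv ~ C(sex, {contrast}) * C(pop, {contrast})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)

    def row(name_frag):
        idx = [i for i in table.index if name_frag in i]
        return table.loc[idx[0]]

    sex_row = row("C(sex")
    pop_row = [i for i in table.index if "C(pop" in i and ":" not in i][0]
    inter_row = [i for i in table.index if ":" in i][0]
    return AnovaTable(
        p_values={"sex": float(sex_row["PR(>F)"]),
                  "sample": float(table.loc[pop_row, "PR(>F)"]),
                  "sex:sample": float(table.loc[inter_row, "PR(>F)"])},
        f_statistics={"sex": float(sex_row["F"]),
                      "sample": float(table.loc[pop_row, "F"]),
                      "sex:sample": float(table.loc[inter_row, "F"])},
        df={"sex": int(sex_row["df"]),
            "sample": int(table.loc[pop_row, "df"]),
            "sex:sample": int(table.loc[inter_row, "df"]),
            "residual": int(table.loc["Residual", "df"])},
        ss_type=ss_type)


def tukey_hsd(dv, group_labels) -> pd.DataFrame:
    """Pairwise Tukey HSD p-values (Tukey-Kramer for unbalanced groups).

    Returns a symmetric DataFrame with a unit diagonal, indexed by group
    label, suitable for the population-by-population comparison tables.
    """
    dv = np.asarray(dv, dtype=np.float64)
    labels = np.asarray(group_labels).astype(str)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    samples = [dv[labels == g] for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 observations")
    res = stats.tukey_hsd(*samples)
    mat = np.array(res.pvalue, dtype=np.float64)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=groups, columns=groups)
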