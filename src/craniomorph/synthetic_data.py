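"""Synthetic cranial populations for exercising the full pipeline.

Real study material (CT-derived crania from five populations) is not
redistributable, so this module grows skull-like meshes with controllable
population structure: per-population smooth mean-form offset fields, sexual
dimorphism applied along outward normals on designated "dimorphic" patches
(glabellar and occipital prominences), male-larger size allometry, global
population scale, and i.i.d. vertex noise.  All specimens of a study share
the base-mesh topology, so generated cohorts are vertex-homologous by
construction — convenient for fast statistical tests — while the optional
nested internal shell exercises exterior extraction, and the meshes can be
pushed through the full CPD-DCA path like real scans.

Generation is bit-reproducible from (specs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .exceptions import ParameterError
from .mesh_core import (LANDMARK_NAMES, LandmarkSet, Specimen, TriangleMesh,
                        vertex_normals, write_landmarks, write_mesh)

#: Semi-axes of the base cranial ellipsoid (mm): anterior-posterior,
#: lateral, vertical — adult neurocranium-like proportions.
SEMI_AXES = (90.0, 70.0, 65.0)

#: Unit directions (before scaling) whose nearest surface vertices play the
#: roles of the eight standard landmarks.  x: anterior, y: left, z: superior.
_LANDMARK_DIRECTIONS = {
    "glabella": (1.0, 0.0, 0.25),
    "inion": (-1.0, 0.0, 0.05),
    "opisthion": (-0.6, 0.0, -0.8),
    "nasospinale": (1.0, 0.0, -0.45),
    "mastoidale_dx": (0.05, -0.75, -0.70),
    "mastoidale_sin": (0.05, 0.75, -0.70),
    "zygomaticofrontale_dx": (0.80, -0.55, 0.20),
    "zygomaticofrontale_sin": (0.80, 0.55, 0.20),
}

#: Centres and widths of the dimorphic patches (glabellar + occipital).
_DIMORPHIC_PATCHES = (((1.0, 0.0, 0.25), 0.15), ((-1.0, 0.0, 0.05), 0.15))


@dataclass
class PopulationSpec:
    """Generating parameters of one synthetic population.

    offset_amplitude: RMS amplitude (mm) of the population's smooth
    mean-form offset field.  dimorphism: displacement (mm) added along the
    outward normal on the dimorphic patches for males.  male_size: male /
    female centroid-size ratio (>1 = males larger).  scale: global
    population size factor.  noise: per-coordinate i.i.d. vertex noise SD
    (mm).  individual_amplitude: RMS amplitude (mm) of each specimen's own
    smooth variation field — the within-sex morphological variation real
    samples show.  size_sd: SD of the log of each specimen's individual
    size factor (~2.5% centroid-size CV).
    """

    label: str
    n_female: int
    n_male: int
    offset_amplitude: float = 1.2
    dimorphism: float = 2.5
    male_size: float = 1.06
    scale: float = 1.0
    noise: float = 0.5
    individual_amplitude: float = 0.6
    size_sd: float = 0.025

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ParameterError("counts must be >= 0")
        if min(self.dimorphism, self.noise, self.offset_amplitude,
               self.individual_amplitude, self.size_sd) < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.male_size <= 0 or self.scale <= 0:
            raise ParameterError("size factors must be > 0")


@dataclass
class BaseCranium:
    """Template mesh, its landmarks and bookkeeping for deformation."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    landmark_indices: dict
    n_outer_vertices: int
    unit_directions: np.ndarray   # (n_vertices, 3) unit radial directions
    patch: np.ndarray             # (n_vertices,) dimorphic patch weight

    def __iter__(self):
        # allow (mesh, landmarks) unpacking
        return iter((self.mesh, self.landmarks))


@dataclass
class StudyFixture:
    """A generated multi-population study."""

    specimens: list
    metadata: pd.DataFrame
    parameters: dict
    seed: int


def _smooth_sphere_field(directions: np.ndarray, rng: np.random.Generator,
                         l_max: int = 6) -> np.ndarray:
    """Smooth random scalar field on the sphere, unit RMS.

    Spectral synthesis: random spherical-harmonic coefficients with
    exponentially decaying power, evaluated at the vertex directions.
    """
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(directions[:, 1], directions[:, 0])      # azimuth
    out = np.zeros(len(directions))
    for ell in range(1, l_max + 1):
        decay = np.exp(-0.5 * ell)
        for m in range(0, ell + 1):
            coef = rng.normal() * decay
            Y = sph_harm_y(ell, m, theta, phi)
            if m == 0:
                out += coef * Y.real
            else:
                coef2 = rng.normal() * decay
                out += np.sqrt(2) * (coef * Y.real + coef2 * Y.imag)
    rms = np.sqrt((out ** 2).mean())
    return out / rms if rms > 0 else out


def _patch_weight(directions: np.ndarray) -> np.ndarray:
    """Dimorphic patch mask in [0, 1] (smooth bumps, glabella + inion)."""
    w = np.zeros(len(directions))
    for center, width in _DIMORPHIC_PATCHES:
        c = np.asarray(center) / np.linalg.norm(center)
        w += np.exp((directions @ c - 1.0) / width)
    return np.clip(w, 0.0, 1.0)


def make_base_cranium(resolution: int = 3, with_internal_shell: bool = False,
                      seed: int = 0) -> BaseCranium:
    """Construct the skull-like template surface and its eight landmarks.

    ``resolution`` is the icosphere subdivision level; level 3 gives 1280
    faces (the desk-scale default).  Levels below 3 fall under 500 faces
    and are rejected.  ``with_internal_shell`` adds a disjoint nested
    shell emulating endocranial structure.
    """
    n_faces = 20 * 4 ** resolution
    if n_faces < 500:
        raise ParameterError(
            f"resolution {resolution} gives only {n_faces} faces (< 500)")
    rng = np.random.default_rng(seed)
    ico = trimesh.creation.icosphere(subdivisions=resolution)
    dirs = np.asarray(ico.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    radius = np.ones(len(dirs))
    # frontal (glabellar) and occipital prominences on the unit sphere
    for center, width, amp in (((1.0, 0.0, 0.15), 0.25, 0.07),
                               ((-1.0, 0.0, 0.05), 0.20, 0.06)):
        c = np.asarray(center) / np.linalg.norm(center)
        radius += amp * np.exp((dirs @ c - 1.0) / width)
    # slight individual texture so base crania are seed-distinguishable
    radius += 0.004 * _smooth_sphere_field(dirs, rng)
    vertices = dirs * radius[:, None] * np.asarray(SEMI_AXES)
    faces = np.asarray(ico.faces, dtype=np.int64)

    lmk_indices = {}
    for name, direction in _LANDMARK_DIRECTIONS.items():
        d = np.asarray(direction) / np.linalg.norm(direction)
        lmk_indices[name] = int(np.argmax(dirs @ d))

    if with_internal_shell:
        inner_vertices = 0.55 * vertices
        inner_faces = faces + len(vertices)
        vertices = np.vstack([vertices, inner_vertices])
        all_faces = np.vstack([faces, inner_faces])
        unit = np.vstack([dirs, dirs])
    else:
        all_faces = faces
        unit = dirs

    mesh = TriangleMesh(vertices, all_faces)
    landmarks = LandmarkSet({name: vertices[idx]
                             for name, idx in lmk_indices.items()})
    return BaseCranium(mesh=mesh, landmarks=landmarks,
                       landmark_indices=lmk_indices,
                       n_outer_vertices=len(dirs) if not with_internal_shell
                       else len(dirs),
                       unit_directions=unit,
                       patch=_patch_weight(unit))


def population_offset_field(base: BaseCranium,
                            spec: PopulationSpec,
                            rng: np.random.Generator) -> np.ndarray:
    """The population's shared mean-form offset (mm, along normals)."""
    return spec.offset_amplitude * _smooth_sphere_field(
        base.unit_directions, rng)


def generate_specimen(base: BaseCranium, spec: PopulationSpec, sex: str,
                      rng: np.random.Generator,
                      population_field: np.ndarray | None = None,
                      specimen_id: str = "") -> Specimen:
    """Deform the base into one individual of the given sex.

    Vertex displacement = population offset field + the specimen's own
    smooth individual field + (male only) dimorphism x patch weight, all
    along the outward vertex normal, plus i.i.d. 3-D noise; the whole mesh
    (and its landmarks) is then scaled by
    scale x male_size**is_male x exp(N(0, size_sd)).
    """
    if sex not in {"F", "M"}:
        raise ParameterError("sex must be F or M")
    if population_field is None:
        population_field = np.zeros(base.mesh.n_vertices)
    normals = vertex_normals(base.mesh)
    # fixed draw order keeps generation bit-reproducible per stream
    size_jitter = float(np.exp(rng.normal(0.0, spec.size_sd))) \
        if spec.size_sd > 0 else 1.0
    along = population_field.copy()
    if spec.individual_amplitude > 0:
        along = along + spec.individual_amplitude * _smooth_sphere_field(
            base.unit_directions, rng)
    if sex == "M":
        along = along + spec.dimorphism * base.patch
    displacement = along[:, None] * normals
    displacement += rng.normal(0.0, spec.noise, size=base.mesh.vertices.shape)
    factor = spec.scale * (spec.male_size if sex == "M" else 1.0) * size_jitter
    vertices = (base.mesh.vertices + displacement) * factor
    mesh = TriangleMesh(vertices, base.mesh.faces.copy())
    landmarks = LandmarkSet({name: vertices[idx]
                             for name, idx in base.landmark_indices.items()})
    return Specimen(id=specimen_id or f"{spec.label}_{sex}",
                    population=spec.label, sex=sex, mesh=mesh,
                    landmarks=landmarks)


def generate_study(specs: list[PopulationSpec], seed: int = 0,
                   resolution: int = 3,
                   with_internal_shell: bool = False) -> StudyFixture:
    """Generate all specimens of a multi-population study.

    Per population, a single offset field is drawn and shared by both
    sexes (isolating the dimorphism term); every specimen then gets its
    own noise stream.  Streams are keyed by (seed, population index,
    specimen index) so regeneration is bit-identical.
    """
    if not specs:
        raise ParameterError("need at least one population spec")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate population labels in {labels}")
    base = make_base_cranium(resolution=resolution,
                             with_internal_shell=with_internal_shell,
                             seed=seed)
    specimens = []
    rows = []
    for p_idx, spec in enumerate(specs):
        field_rng = np.random.default_rng([seed, p_idx, 0])
        pop_field = population_offset_field(base, spec, field_rng)
        counter = 0
        for sex, count in (("F", spec.n_female), ("M", spec.n_male)):
            for j in range(count):
                counter += 1
                rng = np.random.default_rng([seed, p_idx, counter])
                sid = f"{spec.label}_{sex}{j + 1:03d}"
                specimens.append(generate_specimen(
                    base, spec, sex, rng, population_field=pop_field,
                    specimen_id=sid))
                rows.append({"id": sid, "population": spec.label, "sex": sex})
    metadata = pd.DataFrame(rows)
    parameters = {"seed": seed, "resolution": resolution,
                  "with_internal_shell": with_internal_shell,
                  "populations": [vars(s).copy() for s in specs]}
    return StudyFixture(specimens=specimens, metadata=metadata,
                        parameters=parameters, seed=seed)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Study sample sizes: (females, males) per population.
STUDY_COUNTS = {
    "CZE": (59, 84),
    "SVK": (55, 37),
    "FRA": (51, 52),
    "DEN": (89, 90),
    "EGY": (50, 51),
}

#: Population contrasts: Danes weakly dimorphic; Egyptians smaller overall
#: with the most distinct mean form.  (offset, dimorphism, male_size, scale)
_POPULATION_PARAMS = {
    "CZE": (1.2, 3.5, 1.07, 1.00),
    "SVK": (1.2, 3.2, 1.07, 1.00),
    "FRA": (1.4, 3.0, 1.06, 1.00),
    "DEN": (1.4, 1.2, 1.03, 1.00),
    "EGY": (2.0, 3.0, 1.06, 0.93),
}


def preset_specs(name: str = "table1") -> list[PopulationSpec]:
    """Population specs for the packaged presets.

    ``table1``: the study's published sample sizes (618 specimens: 304 F,
    314 M).  ``mini``: the same five populations at one fifth the counts
    for fast runs.
    """
    if name not in {"table1", "mini"}:
        raise ParameterError(f"unknown preset {name!r}")
    divisor = 5 if name == "mini" else 1
    specs = []
    for label, (nf, nm) in STUDY_COUNTS.items():
        off, delta, s, g = _POPULATION_PARAMS[label]
        specs.append(PopulationSpec(
            label=label,
            n_female=int(round(nf / divisor)),
            n_male=int(round(nm / divisor)),
            offset_amplitude=off, dimorphism=delta,
            male_size=s, scale=g))
    return specs


def generate_preset(name: str = "table1", seed: int = 0,
                    resolution: int = 3,
                    with_internal_shell: bool = False) -> StudyFixture:
    return generate_study(preset_specs(name), seed=seed,
                          resolution=resolution,
                          with_internal_shell=with_internal_shell)


def write_study(fixture: StudyFixture, out_dir) -> list[Path]:
    """Write STL meshes, landmark CSVs and the metadata table to a folder."""
    out_dir = Path(out_dir)
    (out_dir / "meshes").mkdir(parents=True, exist_ok=True)
    (out_dir / "landmarks").mkdir(parents=True, exist_ok=True)
    written = []
    for s in fixture.specimens:
        mesh_path = out_dir / "meshes" / f"{s.id}.stl"
        write_mesh(s.mesh, mesh_path)
        lmk_path = out_dir / "landmarks" / f"{s.id}.csv"
        write_landmarks(s.landmarks, lmk_path)
        written += [mesh_path, lmk_path]
    meta_path = out_dir / "metadata.csv"
    fixture.metadata.to_csv(meta_path, index=False)
    written.append(meta_path)
    return written
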