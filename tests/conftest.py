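"""Shared fixtures: small meshes and a fully analysed mini study."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
import trimesh

from craniomorph.classification import cross_population_apply, sweep_and_train
from craniomorph.correspondence import correspond_homologous
from craniomorph.mesh_core import TriangleMesh
from craniomorph.morphometrics import hd_pca
from craniomorph.synthetic_data import generate_preset, generate_study, preset_specs

warnings.filterwarnings("ignore", category=FutureWarning)

TRAIN_POPS = ("CZE", "SVK", "FRA")


def icosphere(subdivisions: int = 2, radius: float = 1.0) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def nested_spheres(subdivisions: int = 2, r_outer: float = 10.0,
                   r_inner: float = 5.0):
    """One mesh holding two disjoint shells; returns (mesh, n_outer_faces)."""
    outer = trimesh.creation.icosphere(subdivisions=subdivisions,
                                       radius=r_outer)
    inner = trimesh.creation.icosphere(subdivisions=subdivisions,
                                       radius=r_inner)
    vertices = np.vstack([outer.vertices, inner.vertices])
    faces = np.vstack([outer.faces, inner.faces + len(outer.vertices)])
    return TriangleMesh(vertices, faces), len(outer.faces)


@pytest.fixture(scope="session")
def mini_analysis():
    """Mini-preset study analysed end to end in form space.

    Generated cohorts are vertex-homologous, so correspondence reduces to
    the final GPA; the classifier is trained on the three European-analogue
    populations and applied to the weakly dimorphic (DEN) and size-shifted
    (EGY) analogues.
    """
    fixture = generate_preset("mini", seed=1)
    specimens = fixture.specimens
    pops = np.array([s.population for s in specimens])
    sexes = np.array([s.sex for s in specimens])
    n_mini = len(specimens)

    # same-distribution control: fresh specimens from the training
    # populations' generating distribution (different seed), corresponded
    # in the same frame as the study
    control_specs = [s for s in preset_specs("mini")
                     if s.label in TRAIN_POPS]
    control = generate_study(control_specs, seed=2)
    control_sexes = np.array([s.sex for s in control.specimens])
    corr = correspond_homologous(specimens + control.specimens, space="form")
    rows = corr.coordinates

    train_mask = np.isin(pops, TRAIN_POPS)
    pca = hd_pca(rows[:n_mini][train_mask], space="form")
    curve, model = sweep_and_train(
        pca.transform(rows[:n_mini][train_mask]), sexes[train_mask],
        pca=pca, training_populations=TRAIN_POPS)

    reports = {}
    for pop in ("DEN", "EGY"):
        sel = pops == pop
        for t in (0.5, 0.9):
            reports[(pop, t)] = cross_population_apply(
                model, rows[:n_mini][sel], sexes[sel], threshold=t,
                population=pop)
    for t in (0.5, 0.9):
        reports[("control", t)] = cross_population_apply(
            model, rows[n_mini:], control_sexes, threshold=t,
            population="control")
    return {
        "fixture": fixture, "specimens": specimens, "pops": pops,
        "sexes": sexes, "corr": corr, "train_mask": train_mask,
        "pca": pca, "curve": curve, "model": model, "reports": reports,
    }
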