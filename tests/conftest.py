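"""Shared fixtures: toy meshes, single-mesh scenes, reference skies."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from canophot.canopy import CanopyLayout, build_canopy
from canophot.light import SkyCondition
from canophot.plant_model import PlantMesh


def flat_square_mesh(z_cm: float, half_cm: float = 50.0, tilt_deg: float = 0.0,
                     leaf: int = 1) -> PlantMesh:
    """A single square leaf of side 2*half at height z, tilted about y."""
    v = np.array([
        [-half_cm, -half_cm, 0.0], [half_cm, -half_cm, 0.0],
        [half_cm, half_cm, 0.0], [-half_cm, half_cm, 0.0],
    ])
    th = np.radians(tilt_deg)
    rot = np.array([
        [np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]
    ])
    v = v @ rot.T
    v[:, 2] += z_cm
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    areas = 0.5 * np.linalg.norm(
        np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]]), axis=1
    )
    return PlantMesh(
        vertices=v, triangles=tris,
        facet_leaf=np.full(2, leaf), facet_layer=np.full(2, 2), facet_area=areas,
    )


def merge_meshes(meshes: list[PlantMesh]) -> PlantMesh:
    vs, ts, leaf, layer, area = [], [], [], [], []
    off = 0
    for m in meshes:
        vs.append(m.vertices)
        ts.append(m.triangles + off)
        off += len(m.vertices)
        leaf.append(m.facet_leaf)
        layer.append(m.facet_layer)
        area.append(m.facet_area)
    return PlantMesh(
        np.concatenate(vs), np.concatenate(ts), np.concatenate(leaf),
        np.concatenate(layer), np.concatenate(area),
    )


def single_mesh_scene(mesh: PlantMesh, box_cm: float = 100.0):
    """Scene with one origin-centered mesh filling a periodic box."""
    layout = CanopyLayout(
        rows=1, plants_per_row=1, row_spacing_cm=box_cm, plant_spacing_cm=box_cm,
        scoring_width_cm=box_cm, scoring_length_cm=box_cm, randomize_azimuth=False,
    )
    return build_canopy([mesh], layout, rng_seed=0)


def overhead_sky(direct: float = 1000.0, diffuse: float = 0.0) -> SkyCondition:
    return SkyCondition(
        datetime=dt.datetime(2020, 8, 27, 12), latitude=30.933, longitude=121.133,
        direct_ppfd=direct, diffuse_ppfd=diffuse,
        solar_zenith=0.0, solar_azimuth=180.0,
    )


def turbid_scene(lai: float, n_facets: int = 4000, box_cm: float = 100.0,
                 height_cm: float = 100.0, seed: int = 0):
    """Homogeneous random-facet 'turbid medium' canopy of given LAI.

    Small equilateral triangles with uniformly random positions and
    uniformly random orientations (normals uniform on the sphere), total
    one-sided area = LAI x ground area.
    """
    rng = np.random.default_rng(seed)
    area_per = lai * box_cm * box_cm / n_facets
    s = np.sqrt(area_per * 4 / np.sqrt(3))
    base = np.array([
        [0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]
    ]) - np.array([s / 2, s * np.sqrt(3) / 6, 0])
    vs, ts = [], []
    for i in range(n_facets):
        zax = rng.normal(size=3)
        zax /= np.linalg.norm(zax)
        xax = np.cross(zax, [0.3, 0.5, 0.9])
        xax /= np.linalg.norm(xax)
        yax = np.cross(zax, xax)
        rot = np.stack([xax, yax, zax], axis=1)
        pos = rng.uniform(
            [-box_cm / 2, -box_cm / 2, 5], [box_cm / 2, box_cm / 2, 5 + height_cm]
        )
        vs.append(base @ rot.T + pos)
        ts.append([3 * i, 3 * i + 1, 3 * i + 2])
    mesh = PlantMesh(
        np.concatenate(vs), np.array(ts), np.ones(n_facets, np.int64),
        np.full(n_facets, 2, np.int64), np.full(n_facets, area_per),
    )
    return single_mesh_scene(mesh, box_cm)


@pytest.fixture(scope="session")
def erect_plant():
    from canophot.plant_model import generate_synthetic_plant

    return generate_synthetic_plant("erect", rng_seed=2)
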