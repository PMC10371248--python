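"""Field canopy assembly: replicated plants on a row grid plus scoring region.

The default planting geometry is 4 rows spaced 55 cm apart with 13 plants
per row spaced 15 cm; the central 110 x 75 cm rectangle (2 rows x 5 plants)
is the scoring region over which light absorption and photosynthesis are
accounted, keeping the guard plants as a boundary buffer. Rows run
north-south by default (plants spaced along y, rows along x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant_model import PlantMesh, _rotation_matrix

__all__ = ["CanopyLayout", "Rect", "CanopyScene", "build_canopy", "compute_lai"]

Z = np.array([0.0, 0.0, 1.0])


@dataclass
class Rect:
    """Axis-aligned ground rectangle (cm)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @property
    def area_cm2(self) -> float:
        return max(self.x_max - self.x_min, 0.0) * max(self.y_max - self.y_min, 0.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass
class CanopyLayout:
    rows: int = 4
    plants_per_row: int = 13
    row_spacing_cm: float = 55.0
    plant_spacing_cm: float = 15.0
    scoring_width_cm: float = 110.0   # across rows (x)
    scoring_length_cm: float = 75.0   # along rows (y)
    randomize_azimuth: bool = True
    domain_ceiling_cm: float = 400.0

    def validate(self) -> None:
        if self.rows < 1 or self.plants_per_row < 1:
            raise ValueError("layout: rows and plants_per_row must be >= 1")
        if self.row_spacing_cm <= 0 or self.plant_spacing_cm <= 0:
            raise ValueError("spacings must be > 0")


@dataclass
class PlantInstance:
    mesh_index: int
    translation: np.ndarray   # (2,) ground-plane offset, cm
    azimuth_deg: float
    scored: bool


@dataclass
class CanopyScene:
    """Flattened canopy geometry ready for ray tracing.

    Per-facet arrays concatenate every plant instance; ``facet_instance``
    indexes into ``instances``, ``facet_scored`` marks facets of plants
    whose base lies inside the scoring region.
    """

    meshes: list[PlantMesh]
    instances: list[PlantInstance]
    layout: CanopyLayout
    scoring_region: Rect
    vertices: np.ndarray
    triangles: np.ndarray
    facet_instance: np.ndarray
    facet_leaf: np.ndarray
    facet_layer: np.ndarray
    facet_area: np.ndarray
    facet_scored: np.ndarray
    domain: Rect = field(default=None)  # lateral periodic domain
    rng_seed: int = 0

    @property
    def n_facets(self) -> int:
        return self.triangles.shape[0]

    @property
    def height_cm(self) -> float:
        return float(self.vertices[:, 2].max()) if len(self.vertices) else 0.0


def build_canopy(
    plants: list[PlantMesh],
    layout: CanopyLayout | None = None,
    rng_seed: int = 0,
) -> CanopyScene:
    """Place plant meshes on the row grid and flatten the scene.

    The supplied plants are cycled over the grid in row-major order; the
    seed draws each instance's azimuth from {0, 90, 180, 270} degrees when
    ``layout.randomize_azimuth`` is on. The same inputs and seed always
    produce an identical scene.
    """
    if not plants:
        raise ValueError("need at least one plant mesh")
    layout = layout or CanopyLayout()
    layout.validate()
    rng = np.random.default_rng(rng_seed)

    width = layout.rows * layout.row_spacing_cm
    length = layout.plants_per_row * layout.plant_spacing_cm
    domain = Rect(0.0, width, 0.0, length)
    cx, cy = width / 2.0, length / 2.0
    region = Rect(
        cx - layout.scoring_width_cm / 2.0, cx + layout.scoring_width_cm / 2.0,
        cy - layout.scoring_length_cm / 2.0, cy + layout.scoring_length_cm / 2.0,
    )

    instances: list[PlantInstance] = []
    vert_chunks, tri_chunks = [], []
    inst_ids, leafs, layers, areas, scored_flags = [], [], [], [], []
    v_offset = 0
    k = 0
    warned = False
    for r in range(layout.rows):
        x = (r + 0.5) * layout.row_spacing_cm
        for p in range(layout.plants_per_row):
            y = (p + 0.5) * layout.plant_spacing_cm
            mesh_i = k % len(plants)
            az = float(rng.choice([0.0, 90.0, 180.0, 270.0])) if layout.randomize_azimuth else 0.0
            scored = region.contains(x, y)
            inst = PlantInstance(
                mesh_index=mesh_i,
                translation=np.array([x, y]),
                azimuth_deg=az,
                scored=scored,
            )
            mesh = plants[mesh_i]
            R = _rotation_matrix(Z, np.radians(az))
            v = mesh.vertices @ R.T
            v = v + np.array([x, y, 0.0])
            if not warned and v[:, 2].max() > layout.domain_ceiling_cm:
                import warnings

                warnings.warn("plant exceeds the domain ceiling", stacklevel=2)
                warned = True
            vert_chunks.append(v)
            tri_chunks.append(mesh.triangles + v_offset)
            n_f = mesh.n_facets
            inst_ids.append(np.full(n_f, len(instances), dtype=np.int64))
            leafs.append(mesh.facet_leaf)
            layers.append(mesh.facet_layer)
            areas.append(mesh.facet_area)
            scored_flags.append(np.full(n_f, scored))
            v_offset += v.shape[0]
            instances.append(inst)
            k += 1

    return CanopyScene(
        meshes=list(plants),
        instances=instances,
        layout=layout,
        scoring_region=region,
        vertices=np.concatenate(vert_chunks),
        triangles=np.concatenate(tri_chunks),
        facet_instance=np.concatenate(inst_ids),
        facet_leaf=np.concatenate(leafs),
        facet_layer=np.concatenate(layers),
        facet_area=np.concatenate(areas),
        facet_scored=np.concatenate(scored_flags),
        domain=domain,
        rng_seed=rng_seed,
    )


def compute_lai(scene: CanopyScene, scope: str = "scored") -> float:
    """Leaf area index: one-sided leaf area over ground area (dimensionless).

    ``scope="scored"`` uses the scoring-region plants over the scoring-region
    area; ``scope="all"`` uses every plant over the full planted footprint.
    """
    if scope == "scored":
        mask = scene.facet_scored & (scene.facet_leaf > 0)
        ground = scene.scoring_region.area_cm2
    elif scope == "all":
        mask = scene.facet_leaf > 0
        ground = scene.domain.area_cm2
    else:
        raise ValueError("scope must be 'scored' or 'all'")
    if ground <= 0:
        raise ValueError("zero ground area")
    return float(scene.facet_area[mask].sum() / ground)
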