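"""Editable plant geometry: leaf vector models, trait adjustment, meshing.

A maize plant is represented as a stem polyline plus one *vector model* per
leaf: an ordered midrib axis (base to tip) with, at each axis station, a
pair of half-width vectors reaching from the midrib to the left and right
blade edge. This representation makes the architectural traits of interest
(leaf length, width, insertion angle, curvature, leaf number) directly
editable, and lofts exactly into a triangle mesh for ray tracing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .pointcloud import LabeledPointCloud

__all__ = [
    "LeafVectorModel",
    "PlantVectorModel",
    "TraitAdjustment",
    "PlantMesh",
    "ArchitectureParams",
    "PRESETS",
    "generate_synthetic_plant",
    "sample_point_cloud",
    "extract_vector_model",
    "measure_traits",
    "apply_adjustment",
    "mesh_plant",
    "write_obj",
]

Z = np.array([0.0, 0.0, 1.0])


@dataclass
class LeafVectorModel:
    """One leaf: midrib axis points plus per-station edge vectors (cm)."""

    axis: np.ndarray          # (S, 3) base -> tip
    half_left: np.ndarray     # (S, 3) midrib -> left edge
    half_right: np.ndarray    # (S, 3) midrib -> right edge
    layer: int = 2            # 1 = bottom, 2 = up
    leaf_index: int = 1

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(-1, 3)
        self.half_left = np.asarray(self.half_left, dtype=float).reshape(-1, 3)
        self.half_right = np.asarray(self.half_right, dtype=float).reshape(-1, 3)
        if self.axis.shape[0] < 3:
            raise ValueError("leaf axis needs >= 3 stations")
        if not (self.axis.shape == self.half_left.shape == self.half_right.shape):
            raise ValueError("axis and half-width arrays must have equal shapes")

    @property
    def n_stations(self) -> int:
        return self.axis.shape[0]

    @property
    def base(self) -> np.ndarray:
        return self.axis[0]

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.axis, axis=0), axis=1).sum())

    @property
    def width(self) -> float:
        return float(
            (np.linalg.norm(self.half_left, axis=1)
             + np.linalg.norm(self.half_right, axis=1)).max()
        )

    def copy(self) -> "LeafVectorModel":
        return LeafVectorModel(
            self.axis.copy(), self.half_left.copy(), self.half_right.copy(),
            self.layer, self.leaf_index,
        )


@dataclass
class PlantVectorModel:
    leaves: list[LeafVectorModel]
    stem: np.ndarray                 # (M, 3) polyline base -> top
    stem_radius: float = 1.0

    def __post_init__(self) -> None:
        self.stem = np.asarray(self.stem, dtype=float).reshape(-1, 3)
        idx = [leaf.leaf_index for leaf in self.leaves]
        if len(idx) != len(set(idx)):
            raise ValueError("leaf_index values must be unique")

    @property
    def stem_height(self) -> float:
        return float(self.stem[:, 2].max() - self.stem[:, 2].min())

    def copy(self) -> "PlantVectorModel":
        return PlantVectorModel(
            [leaf.copy() for leaf in self.leaves], self.stem.copy(), self.stem_radius
        )


@dataclass
class TraitAdjustment:
    """Architectural edit: multiplicative LL/LW, additive LN/LC/LA.

    Sign conventions (documented in docs/methods.md): positive
    ``leaf_angle_delta_deg`` rotates leaves toward vertical (more erect);
    positive ``leaf_curvature_delta_deg`` adds droop (cumulative bending
    away from vertical along the blade).
    """

    leaf_length_factor: float = 1.0
    leaf_width_factor: float = 1.0
    leaf_number_delta: int = 0
    leaf_curvature_delta_deg: float = 0.0
    leaf_angle_delta_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.leaf_length_factor <= 0 or self.leaf_width_factor <= 0:
            raise ValueError("length/width factors must be > 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.leaf_length_factor == 1.0 and self.leaf_width_factor == 1.0
            and self.leaf_number_delta == 0
            and self.leaf_curvature_delta_deg == 0.0
            and self.leaf_angle_delta_deg == 0.0
        )


@dataclass
class PlantMesh:
    """Triangle mesh with per-facet organ attributes.

    ``facet_leaf`` is 0 for stem facets and the leaf index otherwise;
    ``facet_layer`` is 0 (stem), 1 (bottom) or 2 (up); areas are cm^2.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    facet_leaf: np.ndarray
    facet_layer: np.ndarray
    facet_area: np.ndarray

    @property
    def n_facets(self) -> int:
        return self.triangles.shape[0]

    @property
    def leaf_area_cm2(self) -> float:
        return float(self.facet_area[self.facet_leaf > 0].sum())


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return np.eye(3)
    x, y, z = axis / n
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


# --------------------------------------------------------------------------
# Synthetic plant generation

@dataclass
class ArchitectureParams:
    """Parametric description of a maize-like plant.

    Angles are degrees; ``insertion_angle_deg`` is measured from vertical
    (0 = fully erect blade), ``curvature_deg`` is the additional droop
    accumulated from base to tip. Jitters are relative (lengths/widths) or
    absolute degrees (angles) 1-sigma magnitudes applied per leaf.
    """

    n_leaves: int = 12
    leaf_length_cm: float = 60.0
    leaf_width_cm: float = 8.0
    stem_height_cm: float = 120.0
    stem_radius_cm: float = 1.2
    insertion_angle_deg: float = 30.0
    curvature_deg: float = 50.0
    lowest_leaf_height_cm: float = 10.0
    length_jitter: float = 0.10
    width_jitter: float = 0.08
    angle_jitter_deg: float = 5.0
    azimuth_jitter_deg: float = 10.0
    phyllotaxis: str = "alternate"     # "alternate" | "spiral"
    width_profile: str = "maize"       # "maize" | "rect"
    length_profile: str = "maize"      # "maize" | "uniform"
    stations: int = 31

    def validate(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("invalid parameters: n_leaves must be >= 1")
        for name in ("leaf_length_cm", "leaf_width_cm", "stem_height_cm",
                     "stem_radius_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid parameters: {name} must be > 0")
        if self.stations < 3:
            raise ValueError("invalid parameters: stations must be >= 3")


#: Qualitative architecture presets. "erect" mimics a compact upright line
#: (W64A-like), "spread" a planophile line with longer, droopier leaves
#: (A619-like); parameter values are synthetic, not measured data.
PRESETS: dict[str, ArchitectureParams] = {
    "erect": ArchitectureParams(
        n_leaves=12, leaf_length_cm=60.0, leaf_width_cm=8.0,
        stem_height_cm=120.0, insertion_angle_deg=18.0, curvature_deg=25.0,
        angle_jitter_deg=4.0,
    ),
    "spread": ArchitectureParams(
        n_leaves=10, leaf_length_cm=75.0, leaf_width_cm=8.5,
        stem_height_cm=115.0, insertion_angle_deg=50.0, curvature_deg=60.0,
        angle_jitter_deg=6.0,
    ),
    "toy-flat": ArchitectureParams(
        n_leaves=4, leaf_length_cm=40.0, leaf_width_cm=10.0,
        stem_height_cm=60.0, insertion_angle_deg=85.0, curvature_deg=0.0,
        length_jitter=0.0, width_jitter=0.0, angle_jitter_deg=0.0,
        azimuth_jitter_deg=0.0, width_profile="rect", length_profile="uniform",
        stations=9,
    ),
}


def _width_profile(s: np.ndarray, kind: str) -> np.ndarray:
    """Relative blade width along the normalized arc length s in [0, 1]."""
    if kind == "rect":
        return np.ones_like(s)
    # maize-like: widest ~1/3 from the base, tapering to a pointed tip
    return np.sin(np.pi * np.clip(s, 0, 1) ** 0.7) ** 0.8


def _length_profile(rank: np.ndarray, kind: str) -> np.ndarray:
    """Relative leaf length by position on the stem (0 = lowest)."""
    if kind == "uniform":
        return np.ones_like(rank)
    # mid-canopy leaves are the longest
    return 0.7 + 0.3 * np.sin(np.pi * (0.15 + 0.7 * rank))


def generate_synthetic_plant(
    params: ArchitectureParams | str, rng_seed: int = 0
) -> PlantVectorModel:
    """Deterministically generate a maize-like plant vector model.

    Leaves are inserted along the stem with alternating (or spiral)
    phyllotaxis; each blade leaves the stem at the insertion angle and bends
    progressively by the curvature; half-width vectors follow a maize-like
    blade outline. The same (params, seed) pair always yields the same
    plant.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    params.validate()
    rng = np.random.default_rng(rng_seed)
    n = params.n_leaves
    ranks = (np.arange(n) + 0.5) / n
    base_heights = params.lowest_leaf_height_cm + ranks * (
        params.stem_height_cm - params.lowest_leaf_height_cm
    )
    lengths = params.leaf_length_cm * _length_profile(ranks, params.length_profile)
    lengths = lengths * (1.0 + params.length_jitter * rng.standard_normal(n))
    widths = params.leaf_width_cm * (1.0 + params.width_jitter * rng.standard_normal(n))
    lengths = np.maximum(lengths, 5.0)
    widths = np.maximum(widths, 0.5)
    if params.phyllotaxis == "spiral":
        azimuths = (137.5 * np.arange(n)) % 360.0
    else:
        azimuths = np.where(np.arange(n) % 2 == 0, 0.0, 180.0)
    azimuths = azimuths + params.azimuth_jitter_deg * rng.standard_normal(n)
    angles = params.insertion_angle_deg + params.angle_jitter_deg * rng.standard_normal(n)
    angles = np.clip(angles, 1.0, 95.0)

    leaves = []
    s_grid = np.linspace(0.0, 1.0, params.stations)
    for i in range(n):
        az = math.radians(azimuths[i])
        h = np.array([math.sin(az), math.cos(az), 0.0])        # outward
        lat = np.array([math.cos(az), -math.sin(az), 0.0])     # lateral
        base = np.array([0.0, 0.0, base_heights[i]]) + params.stem_radius_cm * h
        # tangent angle from vertical grows linearly base -> tip
        seg = lengths[i] / (params.stations - 1)
        ang0 = math.radians(angles[i])
        dang = math.radians(params.curvature_deg) / (params.stations - 1)
        axis = np.empty((params.stations, 3))
        axis[0] = base
        a = ang0
        for j in range(1, params.stations):
            t = math.sin(a) * h + math.cos(a) * Z
            axis[j] = axis[j - 1] + seg * t
            a += dang
        w = 0.5 * widths[i] * _width_profile(s_grid, params.width_profile)
        half = w[:, None] * lat[None, :]
        leaves.append(
            LeafVectorModel(
                axis=axis, half_left=half, half_right=-half,
                layer=2, leaf_index=i + 1,
            )
        )
    stem = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, params.stem_height_cm]])
    plant = PlantVectorModel(leaves=leaves, stem=stem,
                             stem_radius=params.stem_radius_cm)
    _assign_leaf_layers(plant)
    return plant


def _assign_leaf_layers(plant: PlantVectorModel) -> None:
    """Layer by base height vs. the plant's mid-height (ground to top)."""
    top = max(
        [plant.stem[:, 2].max()] + [leaf.axis[:, 2].max() for leaf in plant.leaves]
    )
    mid = top / 2.0
    for leaf in plant.leaves:
        leaf.layer = 1 if leaf.base[2] < mid else 2


# --------------------------------------------------------------------------
# Meshing

def mesh_plant(plant: PlantVectorModel, stem_sides: int = 8) -> PlantMesh:
    """Loft the vector model into a triangle mesh.

    Each leaf becomes two triangle strips (left and right of the midrib)
    between consecutive station cross-sections; the stem becomes a closed
    triangulated tube. Degenerate facets (area < 1e-4 cm^2 or aspect ratio
    > 100) are removed.
    """
    verts: list[np.ndarray] = []
    tris: list[list[int]] = []
    f_leaf: list[int] = []
    f_layer: list[int] = []
    offset = 0

    for leaf in plant.leaves:
        S = leaf.n_stations
        left = leaf.axis + leaf.half_left
        right = leaf.axis + leaf.half_right
        # vertex layout per station: [left, mid, right]
        v = np.concatenate([left, leaf.axis, right], axis=0)
        verts.append(v)
        iL, iM, iR = 0, S, 2 * S
        for j in range(S - 1):
            quads = [
                (iL + j, iM + j, iM + j + 1, iL + j + 1),   # left strip
                (iM + j, iR + j, iR + j + 1, iM + j + 1),   # right strip
            ]
            for a, b, c, d in quads:
                tris.append([offset + a, offset + b, offset + c])
                tris.append([offset + a, offset + c, offset + d])
                f_leaf += [leaf.leaf_index] * 2
                f_layer += [leaf.layer] * 2
        offset += v.shape[0]

    # stem tube
    r = plant.stem_radius
    if r > 0 and plant.stem.shape[0] >= 2:
        theta = 2.0 * np.pi * np.arange(stem_sides) / stem_sides
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(stem_sides)])
        rings = []
        for p in plant.stem:
            rings.append(p[None, :] + r * ring)
        v = np.concatenate(rings, axis=0)
        verts.append(v)
        for j in range(plant.stem.shape[0] - 1):
            for k in range(stem_sides):
                k2 = (k + 1) % stem_sides
                a = offset + j * stem_sides + k
                b = offset + j * stem_sides + k2
                c = offset + (j + 1) * stem_sides + k2
                d = offset + (j + 1) * stem_sides + k
                tris.append([a, b, c])
                tris.append([a, c, d])
                f_leaf += [0, 0]
                f_layer += [0, 0]
        offset += v.shape[0]

    vertices = np.concatenate(verts, axis=0)
    triangles = np.asarray(tris, dtype=np.int64)
    facet_leaf = np.asarray(f_leaf, dtype=np.int64)
    facet_layer = np.asarray(f_layer, dtype=np.int64)
    areas = _triangle_areas(vertices, triangles)

    # degenerate-facet cleaning
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    edges = np.stack([
        np.linalg.norm(b - a, axis=1),
        np.linalg.norm(c - b, axis=1),
        np.linalg.norm(a - c, axis=1),
    ])
    longest = edges.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # inradius-based aspect ratio proxy: longest edge / (2 area / perimeter)
        aspect = np.where(areas > 0, longest * edges.sum(axis=0) / (2.0 * areas), np.inf)
    keep = (areas >= 1e-4) & (aspect <= 100.0 * 3.0)
    return PlantMesh(
        vertices=vertices,
        triangles=triangles[keep],
        facet_leaf=facet_leaf[keep],
        facet_layer=facet_layer[keep],
        facet_area=areas[keep],
    )


def write_obj(path, mesh: PlantMesh) -> None:
    """Write the mesh as OBJ with facet attributes in a sidecar CSV."""
    from pathlib import Path

    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# canophot plant mesh (cm)\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    side = pd.DataFrame({
        "facet": np.arange(mesh.n_facets),
        "leaf": mesh.facet_leaf,
        "layer": mesh.facet_layer,
        "area_cm2": mesh.facet_area,
    })
    side.to_csv(path.with_suffix(".facets.csv"), index=False)


# --------------------------------------------------------------------------
# Point-cloud sampling (the forward model for the extraction round trip)

def sample_point_cloud(
    plant: PlantVectorModel,
    points_per_cm2: float = 4.0,
    noise_sigma_cm: float = 0.0,
    rng_seed: int = 0,
) -> LabeledPointCloud:
    """Sample a labeled point cloud from the plant surface.

    Points are drawn uniformly by area from the lofted mesh facets, labeled
    with the facet's organ (0 = stem, k = leaf k), optionally perturbed with
    isotropic Gaussian noise — the synthetic stand-in for a segmented
    multi-view-stereo scan.
    """
    rng = np.random.default_rng(rng_seed)
    mesh = mesh_plant(plant)
    counts = rng.poisson(mesh.facet_area * points_per_cm2)
    total = int(counts.sum())
    pts = np.empty((total, 3))
    labels = np.empty(total, dtype=np.int64)
    pos = 0
    tri = mesh.triangles
    V = mesh.vertices
    for f in np.nonzero(counts)[0]:
        k = counts[f]
        u = rng.random(k)
        v = rng.random(k)
        flip = u + v > 1
        u[flip] = 1 - u[flip]
        v[flip] = 1 - v[flip]
        a, b, c = V[tri[f, 0]], V[tri[f, 1]], V[tri[f, 2]]
        pts[pos:pos + k] = a + u[:, None] * (b - a) + v[:, None] * (c - a)
        labels[pos:pos + k] = mesh.facet_leaf[f]
        pos += k
    if noise_sigma_cm > 0:
        pts = pts + rng.normal(0.0, noise_sigma_cm, size=pts.shape)
    layer = {leaf.leaf_index: leaf.layer for leaf in plant.leaves}
    return LabeledPointCloud(points=pts, labels=labels, layer=layer)


# --------------------------------------------------------------------------
# Vector-model extraction from labeled clouds

def _knn_graph(pts: np.ndarray, k: int = 10):
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=k + 1)
    n = pts.shape[0]
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dists[:, 1:].ravel()
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _resample_polyline(path: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate leaf: zero-length main path")
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, path[:, d])
    return out


def _smooth_polyline(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing with edge replication; endpoints pinned."""
    if window < 2 or path.shape[0] <= window:
        return path
    window |= 1  # odd window so 'valid' output length matches the input
    pad = window // 2
    padded = np.vstack([
        np.repeat(path[:1], pad, axis=0), path, np.repeat(path[-1:], pad, axis=0)
    ])
    kernel = np.ones(window) / window
    out = np.empty_like(path)
    for d in range(3):
        out[:, d] = np.convolve(padded[:, d], kernel, mode="valid")
    out[0] = path[0]
    out[-1] = path[-1]
    return out


def _cut_cross_sections(pts: np.ndarray, tree: cKDTree, axis: np.ndarray,
                        recenter: bool):
    """Slab-cut half widths at each station; optionally re-center the midrib."""
    stations = axis.shape[0]
    tangents = np.gradient(axis, axis=0)
    # end stations inherit their neighbor's tangent: the graph endpoints sit
    # on the blade edge (e.g. a tip corner) and would tilt the cut plane
    tangents[0] = tangents[1]
    tangents[-1] = tangents[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    seg_len = np.linalg.norm(np.diff(axis, axis=0), axis=1).mean()
    slab = max(seg_len * 0.75, 0.3)
    half_left = np.zeros_like(axis)
    half_right = np.zeros_like(axis)
    new_axis = axis.copy()
    for j in range(stations):
        t = tangents[j]
        lat = np.cross(t, Z)
        norm = np.linalg.norm(lat)
        if norm < 1e-6:
            lat = np.cross(t, np.array([1.0, 0.0, 0.0]))
            norm = np.linalg.norm(lat)
        lat /= norm
        cand = tree.query_ball_point(axis[j], r=max(slab * 6, 3.0))
        if not cand:
            continue
        rel = pts[cand] - axis[j]
        in_slab = np.abs(rel @ t) <= slab
        if not np.any(in_slab):
            continue
        u = rel[in_slab] @ lat
        u_min, u_max = float(u.min()), float(u.max())
        if recenter:
            new_axis[j] = axis[j] + 0.5 * (u_min + u_max) * lat
        half_left[j] = lat * max(u_max, 0.0)
        half_right[j] = lat * min(u_min, 0.0)
    return new_axis, half_left, half_right


def extract_vector_model(
    cloud: LabeledPointCloud, stations: int = 31, knn: int = 10
) -> PlantVectorModel:
    """Extract a plant vector model from a labeled point cloud.

    Per leaf: a k-NN graph over the leaf's points is built; the main path
    runs from the base point (leaf point nearest the stem, lowest first) to
    the graph-farthest point (tip) via Dijkstra shortest paths; the path is
    resampled to ``stations`` stations, and at each station the points in a
    thin slab perpendicular to the local tangent give the midrib-to-edge
    half-width vectors.
    """
    leaf_ids = cloud.leaf_indices
    if leaf_ids.size == 0:
        raise ValueError("cloud has no leaf labels")
    stem_pts = cloud.points[cloud.labels == 0]
    stem_tree = cKDTree(stem_pts) if stem_pts.shape[0] else None

    leaves = []
    for leaf_id in leaf_ids:
        pts = cloud.points[cloud.labels == leaf_id]
        if pts.shape[0] < 200:
            raise ValueError(f"degenerate leaf {leaf_id}: fewer than 200 points")
        if stem_tree is not None:
            d_stem, _ = stem_tree.query(pts)
            score = d_stem + 0.25 * (pts[:, 2] - pts[:, 2].min())
        else:
            score = pts[:, 2]
        base_i = int(np.argmin(score))
        graph = _knn_graph(pts, k=knn)
        dist, pred = dijkstra(graph, directed=False, indices=base_i,
                              return_predecessors=True)
        if not np.all(np.isfinite(dist)):
            raise ValueError(f"fragmented leaf {leaf_id}: disconnected point graph")
        tip_i = int(np.argmax(dist))
        # walk predecessors tip -> base
        chain = [tip_i]
        while chain[-1] != base_i:
            chain.append(int(pred[chain[-1]]))
        path = pts[chain[::-1]]
        if path.shape[0] < 3:
            raise ValueError(f"degenerate leaf {leaf_id}: main path too short")
        # smooth out graph zigzag, then resample to stations
        dense = _resample_polyline(path, max(4 * stations, 64))
        dense = _smooth_polyline(dense, window=7)
        axis = _resample_polyline(dense, stations)

        tree = cKDTree(pts)
        # two passes: the first midrib estimate is the graph path, which can
        # drift laterally (e.g. toward a square tip corner); re-centering each
        # station at the cross-section midpoint straightens the axis before
        # the final width cut
        for _ in range(2):
            axis, _, _ = _cut_cross_sections(pts, tree, axis, recenter=True)
        # the graph tip sits on the blade edge (a corner for truncate-tipped
        # blades); rebuild the outermost stations from the interior midline
        # trend before the final width cut
        t_hat = axis[-3] - axis[-4]
        t_hat /= max(np.linalg.norm(t_hat), 1e-12)
        reach = float((axis[-1] - axis[-3]) @ t_hat)
        axis[-1] = axis[-3] + reach * t_hat
        axis[-2] = axis[-3] + 0.5 * reach * t_hat
        axis, half_left, half_right = _cut_cross_sections(
            pts, tree, axis, recenter=False
        )
        layer = cloud.layer.get(int(leaf_id), 2)
        leaves.append(
            LeafVectorModel(axis=axis, half_left=half_left, half_right=half_right,
                            layer=layer, leaf_index=int(leaf_id))
        )

    if stem_pts.shape[0] >= 10:
        order = np.argsort(stem_pts[:, 2])
        sp = stem_pts[order]
        nbins = max(int(sp.shape[0] // 50), 2)
        bins = np.array_split(np.arange(sp.shape[0]), nbins)
        stem = np.array([sp[b].mean(axis=0) for b in bins if b.size])
        radial = stem_pts[:, :2] - stem[:, :2].mean(axis=0)
        stem_radius = float(np.median(np.linalg.norm(radial, axis=1)))
    else:
        bases = np.array([leaf.base for leaf in leaves])
        center = bases.mean(axis=0)
        stem = np.array([
            [center[0], center[1], 0.0],
            [center[0], center[1], float(bases[:, 2].max())],
        ])
        stem_radius = 1.0
    plant = PlantVectorModel(leaves=leaves, stem=stem, stem_radius=stem_radius)
    if not cloud.layer:
        _assign_leaf_layers(plant)
    return plant


# --------------------------------------------------------------------------
# Trait measurement and adjustment

def measure_traits(plant: PlantVectorModel) -> tuple[pd.DataFrame, dict]:
    """Per-leaf trait table and plant-level summary.

    Leaf length is the midrib arc length, width the maximum across stations
    of left+right half widths, base height the z of the first axis point,
    and area the sum of lofted facet areas.
    """
    mesh = mesh_plant(plant)
    rows = []
    for leaf in plant.leaves:
        area = float(mesh.facet_area[mesh.facet_leaf == leaf.leaf_index].sum())
        rows.append({
            "leaf": leaf.leaf_index,
            "layer": leaf.layer,
            "length_cm": leaf.length,
            "width_cm": leaf.width,
            "base_height_cm": float(leaf.base[2]),
            "area_cm2": area,
        })
    table = pd.DataFrame(rows).sort_values("leaf").reset_index(drop=True)
    summary = {
        "leaf_count": len(plant.leaves),
        "stem_height_cm": plant.stem_height,
        "mean_leaf_length_cm": float(table["length_cm"].mean()),
        "max_leaf_length_cm": float(table["length_cm"].max()),
        "mean_leaf_width_cm": float(table["width_cm"].mean()),
        "max_leaf_width_cm": float(table["width_cm"].max()),
        "total_leaf_area_cm2": float(table["area_cm2"].sum()),
    }
    return table, summary


def _leaf_vertical_frame(leaf: LeafVectorModel) -> tuple[np.ndarray, np.ndarray]:
    """(outward horizontal, lateral) unit vectors of the leaf's vertical plane."""
    chord = leaf.axis[-1] - leaf.axis[0]
    h = chord - chord[2] * Z
    if np.linalg.norm(h) < 1e-9:
        # vertical leaf: derive the plane from the half-width direction
        hw = leaf.half_left[np.argmax(np.linalg.norm(leaf.half_left, axis=1))]
        lat = hw / max(np.linalg.norm(hw), 1e-12)
        h = np.cross(Z, lat)
    h = h / np.linalg.norm(h)
    lat = np.cross(h, Z)
    lat = lat / np.linalg.norm(lat)
    return h, lat


def _rotate_leaf(leaf: LeafVectorModel, R: np.ndarray, about: np.ndarray) -> None:
    leaf.axis = (leaf.axis - about) @ R.T + about
    leaf.half_left = leaf.half_left @ R.T
    leaf.half_right = leaf.half_right @ R.T


def _bend_leaf(leaf: LeafVectorModel, delta_deg: float) -> None:
    """Distribute ``delta_deg`` of extra droop progressively along the axis."""
    S = leaf.n_stations
    h, lat = _leaf_vertical_frame(leaf)
    # rotation about +lat erects the tangent (toward +Z); droop is the
    # opposite sense, hence the negative step for positive delta
    step = -math.radians(delta_deg) / (S - 1)
    seg = np.diff(leaf.axis, axis=0)
    new_axis = leaf.axis.copy()
    hl = leaf.half_left.copy()
    hr = leaf.half_right.copy()
    for j in range(1, S):
        R = _rotation_matrix(lat, step * (j - 0.5))
        new_axis[j] = new_axis[j - 1] + R @ seg[j - 1]
        Rs = _rotation_matrix(lat, step * j)
        hl[j] = Rs @ leaf.half_left[j]
        hr[j] = Rs @ leaf.half_right[j]
    leaf.axis = new_axis
    leaf.half_left = hl
    leaf.half_right = hr


def apply_adjustment(
    plant: PlantVectorModel, adj: TraitAdjustment, rng_seed: int = 0
) -> PlantVectorModel:
    """Return a new plant with the architectural adjustment applied.

    Order of operations: length and width scaling, then leaf-angle rigid
    rotation about the base, then progressive curvature bending, then leaf
    count changes (clones inserted above the top with 180-degree phyllotaxis
    rotation; removal proceeds from the bottom). The identity adjustment
    returns a geometrically identical plant.
    """
    out = plant.copy()
    if adj.leaf_number_delta <= -len(out.leaves):
        raise ValueError("no leaves left: leaf_number_delta removes every leaf")

    for leaf in out.leaves:
        if adj.leaf_length_factor != 1.0:
            base = leaf.axis[0].copy()
            leaf.axis = base + adj.leaf_length_factor * (leaf.axis - base)
        if adj.leaf_width_factor != 1.0:
            leaf.half_left = leaf.half_left * adj.leaf_width_factor
            leaf.half_right = leaf.half_right * adj.leaf_width_factor
        if adj.leaf_angle_delta_deg != 0.0:
            h, lat = _leaf_vertical_frame(leaf)
            # positive delta -> more erect: rotate about +lat (= h x Z)
            R = _rotation_matrix(lat, math.radians(adj.leaf_angle_delta_deg))
            _rotate_leaf(leaf, R, leaf.axis[0].copy())
        if adj.leaf_curvature_delta_deg != 0.0:
            _bend_leaf(leaf, adj.leaf_curvature_delta_deg)

    if adj.leaf_number_delta < 0:
        order = np.argsort([leaf.base[2] for leaf in out.leaves])
        drop = set(order[: -adj.leaf_number_delta])
        out.leaves = [lf for i, lf in enumerate(out.leaves) if i not in drop]
    elif adj.leaf_number_delta > 0:
        by_height = sorted(out.leaves, key=lambda lf: lf.base[2], reverse=True)
        bases = sorted(leaf.base[2] for leaf in out.leaves)
        spacing = (
            float(np.mean(np.diff(bases))) if len(bases) > 1 else 10.0
        )
        spacing = max(spacing, 2.0)
        top_z = by_height[0].base[2]
        next_index = max(leaf.leaf_index for leaf in out.leaves) + 1
        Rz = _rotation_matrix(Z, math.pi)
        for j in range(adj.leaf_number_delta):
            src = by_height[j % len(by_height)]
            clone = src.copy()
            base = clone.axis[0].copy()
            # rotate azimuth 180 degrees about the stem axis through the base
            stem_xy = np.array([out.stem[0, 0], out.stem[0, 1], 0.0])
            about = np.array([stem_xy[0], stem_xy[1], base[2]])
            _rotate_leaf(clone, Rz, about)
            new_z = top_z + (j + 1) * spacing
            clone.axis = clone.axis + (new_z - clone.axis[0, 2]) * Z
            clone.leaf_index = next_index
            next_index += 1
            out.leaves.append(clone)
        top_needed = max(leaf.base[2] for leaf in out.leaves)
        if out.stem[-1, 2] < top_needed:
            out.stem[-1, 2] = top_needed
    _assign_leaf_layers(out)
    return out
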