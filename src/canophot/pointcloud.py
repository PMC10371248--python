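"""Labeled plant point clouds: I/O, ground-plane removal, denoising.

Clouds carry per-point organ labels (0 = stem, k >= 1 = leaf k) so that leaf
vector models can be extracted without re-running organ segmentation, which
is assumed to have been done upstream (or comes for free from the synthetic
plant generator). Coordinates are centimeters, Z up, ground near z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "LabeledPointCloud",
    "remove_ground_plane",
    "denoise",
    "assign_layers",
    "read_ply",
    "write_ply",
    "read_xyz",
    "write_xyz",
]


@dataclass
class LabeledPointCloud:
    """Points (N,3 float, cm), integer organ labels, optional RGB colors."""

    points: np.ndarray
    labels: np.ndarray
    colors: np.ndarray | None = None
    #: per-leaf canopy layer tag: {leaf index: 1 (bottom) | 2 (up)}
    layer: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def leaf_indices(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def select(self, mask: np.ndarray) -> "LabeledPointCloud":
        return LabeledPointCloud(
            points=self.points[mask],
            labels=self.labels[mask],
            colors=None if self.colors is None else self.colors[mask],
            layer=dict(self.layer),
        )

    def reindex_leaves(self) -> "LabeledPointCloud":
        """Renumber surviving leaf labels to a contiguous 1..N set."""
        new = self.labels.copy()
        mapping = {}
        for i, old in enumerate(sorted(self.leaf_indices), start=1):
            mapping[int(old)] = i
            new[self.labels == old] = i
        layer = {mapping[k]: v for k, v in self.layer.items() if k in mapping}
        return LabeledPointCloud(self.points, new, self.colors, layer)


def remove_ground_plane(
    cloud: LabeledPointCloud,
    max_distance_cm: float = 5.0,
    n_iterations: int = 200,
    rng_seed: int = 0,
) -> LabeledPointCloud:
    """Drop points within ``max_distance_cm`` of the dominant RANSAC plane.

    The plane is fit robustly: random 3-point hypotheses, best inlier count
    wins, followed by a least-squares refit on the inliers. Raises if no
    plane with at least 3 inliers exists.
    """
    if max_distance_cm <= 0:
        raise ValueError("max_distance_cm must be > 0")
    pts = cloud.points
    if pts.shape[0] < 3:
        raise ValueError("no ground plane: fewer than 3 points")
    rng = np.random.default_rng(rng_seed)
    best_inliers = None
    best_count = -1
    n = pts.shape[0]
    for _ in range(n_iterations):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        dist = np.abs((pts - p0) @ normal)
        inliers = dist <= max_distance_cm
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_inliers is None or best_count < 3:
        raise ValueError("no ground plane: RANSAC found no plane with >= 3 inliers")
    # Least-squares refit on the inliers for a stable final plane.
    sub = pts[best_inliers]
    centroid = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
    normal = vt[-1]
    dist = np.abs((pts - centroid) @ normal)
    keep = dist > max_distance_cm
    return cloud.select(keep).reindex_leaves()


def _largest_component(pts: np.ndarray, eps: float) -> np.ndarray:
    """Boolean mask of the largest eps-connected Euclidean cluster."""
    tree = cKDTree(pts)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    n = pts.shape[0]
    if pairs.size == 0:
        # every point is its own cluster; keep an arbitrary single point
        mask = np.zeros(n, dtype=bool)
        mask[0] = True
        return mask
    data = np.ones(pairs.shape[0], dtype=np.int8)
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    counts = np.bincount(comp, minlength=n_comp)
    return comp == counts.argmax()


def denoise(
    cloud: LabeledPointCloud,
    cluster_eps_cm: float = 0.5,
    sd_threshold: float = 0.3,
    k_neighbors: int = 50,
) -> LabeledPointCloud:
    """Euclidean-cluster filtering followed by statistical outlier removal.

    Clusters not connected (at distance ``cluster_eps_cm``) to the largest
    component are dropped; then a point is dropped when its mean distance to
    its ``k_neighbors`` nearest neighbors exceeds the global mean of that
    statistic by more than ``sd_threshold`` global standard deviations.
    """
    if k_neighbors >= len(cloud):
        raise ValueError("too few points: k_neighbors >= point count")
    cloud = cloud.select(_largest_component(cloud.points, cluster_eps_cm))
    if k_neighbors >= len(cloud):
        raise ValueError("too few points after clustering")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    keep = mean_d <= mean_d.mean() + sd_threshold * mean_d.std()
    return cloud.select(keep)


def assign_layers(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Tag each leaf as bottom (1) or up (2) layer.

    The plant center is the midpoint between the ground (z = 0) and the
    highest point of the cloud; a leaf whose base point (lowest point of the
    leaf) sits below the center is a bottom-layer leaf.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    center_z = cloud.points[:, 2].max() / 2.0
    layer = {}
    for leaf in cloud.leaf_indices:
        base_z = cloud.points[cloud.labels == leaf][:, 2].min()
        layer[int(leaf)] = 1 if base_z < center_z else 2
    out = cloud.select(np.ones(len(cloud), dtype=bool))
    out.layer = layer
    return out


# --------------------------------------------------------------------------
# PLY / XYZ I/O (custom: PLY with a per-vertex integer `label` property)

def write_ply(path: str | Path, cloud: LabeledPointCloud, binary: bool = True) -> None:
    path = Path(path)
    n = len(cloud)
    has_color = cloud.colors is not None
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {n}")
    header += ["property float x", "property float y", "property float z"]
    if has_color:
        header += [
            "property uchar red", "property uchar green", "property uchar blue"
        ]
    header.append("property int label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if has_color:
                rec = np.zeros(
                    n,
                    dtype=[("xyz", "<f4", 3), ("rgb", "u1", 3), ("label", "<i4")],
                )
                rec["rgb"] = cloud.colors
            else:
                rec = np.zeros(n, dtype=[("xyz", "<f4", 3), ("label", "<i4")])
            rec["xyz"] = cloud.points
            rec["label"] = cloud.labels
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                x, y, z = cloud.points[i]
                parts = [f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]
                if has_color:
                    parts += [str(int(c)) for c in cloud.colors[i]]
                parts.append(str(int(cloud.labels[i])))
                fh.write((" ".join(parts) + "\n").encode("ascii"))


_PLY_TYPES = {
    "char": ("i1", 1), "uchar": ("u1", 1), "short": ("<i2", 2), "ushort": ("<u2", 2),
    "int": ("<i4", 4), "uint": ("<u4", 4), "float": ("<f4", 4), "double": ("<f8", 8),
    "int8": ("i1", 1), "uint8": ("u1", 1), "int16": ("<i2", 2), "uint16": ("<u2", 2),
    "int32": ("<i4", 4), "uint32": ("<u4", 4), "float32": ("<f4", 4),
    "float64": ("<f8", 8),
}


def read_ply(path: str | Path) -> LabeledPointCloud:
    """Read an ASCII or binary little-endian PLY vertex cloud.

    Recognizes x/y/z, optional red/green/blue, and an integer ``label``
    property (missing labels default to 0)."""
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError("list properties not supported on vertices")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"unsupported PLY format {fmt!r}")
        names = [p[0] for p in props]
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertex):
                rows.append(fh.readline().split())
            arr = np.array(rows, dtype=float)
            data = {name: arr[:, i] for i, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, _PLY_TYPES[t][0]) for name, t in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            data = {name: rec[name].astype(float) for name in names}
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    labels = data.get("label", np.zeros(n_vertex)).astype(np.int64)
    colors = None
    if all(c in data for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.uint8)
    return LabeledPointCloud(points=pts, labels=labels, colors=colors)


def write_xyz(path: str | Path, cloud: LabeledPointCloud) -> None:
    """Write x,y,z,label as CSV."""
    arr = np.column_stack([cloud.points, cloud.labels.astype(float)])
    np.savetxt(path, arr, delimiter=",", header="x,y,z,label", comments="")


def read_xyz(path: str | Path) -> LabeledPointCloud:
    """Read x,y,z[,label] CSV or whitespace-separated point lists."""
    try:
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
    except ValueError:
        arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    labels = arr[:, 3].astype(np.int64) if arr.shape[1] > 3 else np.zeros(len(arr), np.int64)
    return LabeledPointCloud(points=arr[:, :3], labels=labels)
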