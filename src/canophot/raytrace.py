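"""Monte-Carlo light transport through the canopy mesh.

Forward path tracing of the direct solar beam and the diffuse sky through
the triangle soup of a :class:`~canophot.canopy.CanopyScene`. Rays are
launched from the top of the domain (stratified grid for the beam,
cosine-weighted hemisphere for the uniform-overcast diffuse sky), traverse
a uniform voxel grid with 3D DDA, and scatter at leaf facets by
Russian-roulette survival: reflect with probability R, transmit with
probability T, otherwise terminate and deposit the full ray weight on the
facet (unbiased, and exactly energy conserving per ray). Lateral domain
boundaries are periodic to emulate the surrounding field; the ground is
absorbing. Random numbers come from a counter-based hash of
(seed, ray, bounce), so results are deterministic and independent of
evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .light import SkyCondition, LeafOpticalProperties

__all__ = ["FacetAbsorption", "trace", "diurnal_trace", "resolve_optics"]


@dataclass
class FacetAbsorption:
    """Per-facet absorbed PPFD plus scene-level flux accounting.

    ``absorbed_ppfd`` is per unit one-sided facet area (umol m-2 s-1);
    power totals are umol s-1 over the whole (periodic) domain.
    """

    absorbed_ppfd: np.ndarray
    absorbed_power: np.ndarray
    emitted: float
    absorbed_facets: float
    absorbed_ground: float
    escaped: float
    ray_count: int
    rng_seed: int

    @property
    def balance_error(self) -> float:
        """Relative energy-balance defect |emitted - sinks| / emitted."""
        if self.emitted <= 0:
            return 0.0
        sinks = self.absorbed_facets + self.absorbed_ground + self.escaped
        return abs(self.emitted - sinks) / self.emitted

    @classmethod
    def zeros(cls, n_facets: int, rng_seed: int = 0) -> "FacetAbsorption":
        return cls(
            absorbed_ppfd=np.zeros(n_facets),
            absorbed_power=np.zeros(n_facets),
            emitted=0.0, absorbed_facets=0.0, absorbed_ground=0.0,
            escaped=0.0, ray_count=0, rng_seed=rng_seed,
        )


# --------------------------------------------------------------------------
# Counter-based RNG (splitmix64 over a mixed key)

@njit(cache=True, inline="always")
def _mix64(x):
    x = np.uint64(x)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand(seed, ray, bounce, dim):
    key = (
        np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
        + np.uint64(ray) * np.uint64(0xD1B54A32D192ED03)
        + np.uint64(bounce) * np.uint64(0x8CB92BA72F3D8DD7)
        + np.uint64(dim) * np.uint64(0xABCC5167CCAD925F)
    )
    z = _mix64(_mix64(key))
    return float(z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# --------------------------------------------------------------------------
# Voxel grid construction (numpy)

def _build_grid(v0, e1, e2, domain_w, domain_l, z_top, target_per_cell=8):
    n_tri = v0.shape[0]
    lo = np.minimum(np.minimum(v0, v0 + e1), v0 + e2)
    hi = np.maximum(np.maximum(v0, v0 + e1), v0 + e2)
    n_cells = max(int((n_tri / target_per_cell) ** (1.0 / 3.0)), 1)
    vol = domain_w * domain_l * z_top
    h = (vol / max(n_tri / target_per_cell, 1.0)) ** (1.0 / 3.0)
    nx = int(np.clip(math.ceil(domain_w / h), 1, 192))
    ny = int(np.clip(math.ceil(domain_l / h), 1, 192))
    nz = int(np.clip(math.ceil(z_top / h), 1, 192))
    hx, hy, hz = domain_w / nx, domain_l / ny, z_top / nz
    eps = 1e-9
    ix0 = np.clip((lo[:, 0] / hx - eps).astype(np.int64), 0, nx - 1)
    ix1 = np.clip((hi[:, 0] / hx + eps).astype(np.int64), 0, nx - 1)
    iy0 = np.clip((lo[:, 1] / hy - eps).astype(np.int64), 0, ny - 1)
    iy1 = np.clip((hi[:, 1] / hy + eps).astype(np.int64), 0, ny - 1)
    iz0 = np.clip((lo[:, 2] / hz - eps).astype(np.int64), 0, nz - 1)
    iz1 = np.clip((hi[:, 2] / hz + eps).astype(np.int64), 0, nz - 1)
    counts = np.zeros(nx * ny * nz, dtype=np.int64)
    spans = []
    for t in range(n_tri):
        xs = np.arange(ix0[t], ix1[t] + 1)
        ys = np.arange(iy0[t], iy1[t] + 1)
        zs = np.arange(iz0[t], iz1[t] + 1)
        cells = (
            (xs[:, None, None] * ny + ys[None, :, None]) * nz + zs[None, None, :]
        ).ravel()
        spans.append(cells)
        counts[cells] += 1
    cell_start = np.zeros(nx * ny * nz + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    cell_tris = np.empty(int(cell_start[-1]), dtype=np.int64)
    cursor = cell_start[:-1].copy()
    for t in range(n_tri):
        cells = spans[t]
        cell_tris[cursor[cells]] = t
        cursor[cells] += 1
    return (nx, ny, nz, hx, hy, hz), cell_start, cell_tris


# --------------------------------------------------------------------------
# Core kernel

@njit(cache=True)
def _trace_kernel(
    v0, e1, e2, normal, refl, trans,
    nx, ny, nz, hx, hy, hz,
    cell_start, cell_tris,
    n_direct, gx, gy, sun_dx, sun_dy, sun_dz, w_direct,
    n_diffuse, w_diffuse,
    max_bounces, seed,
    absorbed, totals,
):
    W = nx * hx
    L = ny * hy
    z_top = nz * hz
    z_launch = z_top - 0.5  # domain carries a 2 cm headroom margin
    eps_t = 1e-7
    max_steps = 8 * (nx + ny + nz) + 64
    n_rays = n_direct + n_diffuse

    for ray in range(n_rays):
        if ray < n_direct:
            # stratified jittered grid on the top plane, beam direction
            cell = ray
            jx = _rand(seed, ray, 0, 100)
            jy = _rand(seed, ray, 0, 101)
            px = ((cell % gx) + jx) / gx * W
            py = ((cell // gx) + jy) / gy * L
            dx, dy, dz = sun_dx, sun_dy, sun_dz
            w = w_direct
        else:
            jx = _rand(seed, ray, 0, 100)
            jy = _rand(seed, ray, 0, 101)
            px = jx * W
            py = jy * L
            u1 = _rand(seed, ray, 0, 102)
            u2 = _rand(seed, ray, 0, 103)
            r = math.sqrt(u1)
            phi = 2.0 * math.pi * u2
            dx = r * math.cos(phi)
            dy = r * math.sin(phi)
            dz = -math.sqrt(max(1.0 - u1, 0.0))
            w = w_diffuse
        pz = z_launch
        totals[0] += w

        bounce = 0
        alive = True
        steps = 0
        while alive:
            # ---- DDA traversal from (px,py,pz) along (dx,dy,dz)
            ix = int(px / hx)
            iy = int(py / hy)
            iz = int(pz / hz)
            if ix < 0: ix = 0
            if ix >= nx: ix = nx - 1
            if iy < 0: iy = 0
            if iy >= ny: iy = ny - 1
            if iz < 0: iz = 0
            if iz >= nz: iz = nz - 1
            step_x = 1 if dx > 0 else -1
            step_y = 1 if dy > 0 else -1
            step_z = 1 if dz > 0 else -1
            inv_dx = 1e30 if dx == 0.0 else 1.0 / dx
            inv_dy = 1e30 if dy == 0.0 else 1.0 / dy
            inv_dz = 1e30 if dz == 0.0 else 1.0 / dz
            t_max_x = ((ix + (1 if step_x > 0 else 0)) * hx - px) * inv_dx if dx != 0.0 else 1e30
            t_max_y = ((iy + (1 if step_y > 0 else 0)) * hy - py) * inv_dy if dy != 0.0 else 1e30
            t_max_z = ((iz + (1 if step_z > 0 else 0)) * hz - pz) * inv_dz if dz != 0.0 else 1e30
            t_dx = abs(hx * inv_dx)
            t_dy = abs(hy * inv_dy)
            t_dz = abs(hz * inv_dz)

            hit_tri = -1
            hit_t = 1e30
            segment_done = False
            exit_code = 0  # 1 = lateral wrap, 2 = ground, 3 = top/escape

            while not segment_done:
                steps += 1
                if steps > max_steps:
                    exit_code = 3
                    break
                t_exit = min(t_max_x, min(t_max_y, t_max_z))
                # test triangles in this cell
                c = (ix * ny + iy) * nz + iz
                for k in range(cell_start[c], cell_start[c + 1]):
                    tr = cell_tris[k]
                    # Moller-Trumbore
                    e1x = e1[tr, 0]; e1y = e1[tr, 1]; e1z = e1[tr, 2]
                    e2x = e2[tr, 0]; e2y = e2[tr, 1]; e2z = e2[tr, 2]
                    px_ = dy * e2z - dz * e2y
                    py_ = dz * e2x - dx * e2z
                    pz_ = dx * e2y - dy * e2x
                    det = e1x * px_ + e1y * py_ + e1z * pz_
                    if abs(det) < 1e-14:
                        continue
                    inv_det = 1.0 / det
                    tx = px - v0[tr, 0]
                    ty = py - v0[tr, 1]
                    tz = pz - v0[tr, 2]
                    u = (tx * px_ + ty * py_ + tz * pz_) * inv_det
                    if u < -1e-9 or u > 1.0 + 1e-9:
                        continue
                    qx = ty * e1z - tz * e1y
                    qy = tz * e1x - tx * e1z
                    qz = tx * e1y - ty * e1x
                    v = (dx * qx + dy * qy + dz * qz) * inv_det
                    if v < -1e-9 or u + v > 1.0 + 1e-9:
                        continue
                    t = (e2x * qx + e2y * qy + e2z * qz) * inv_det
                    if t > eps_t and t < hit_t:
                        hit_t = t
                        hit_tri = tr
                if hit_tri >= 0 and hit_t <= t_exit + 1e-9:
                    segment_done = True
                    break
                # advance to neighbor cell
                if t_max_x <= t_max_y and t_max_x <= t_max_z:
                    ix += step_x
                    t_max_x += t_dx
                    if ix < 0 or ix >= nx:
                        exit_code = 1
                        break
                elif t_max_y <= t_max_z:
                    iy += step_y
                    t_max_y += t_dy
                    if iy < 0 or iy >= ny:
                        exit_code = 1
                        break
                else:
                    iz += step_z
                    t_max_z += t_dz
                    if iz < 0:
                        exit_code = 2
                        break
                    if iz >= nz:
                        exit_code = 3
                        break

            if segment_done and hit_tri >= 0:
                # scatter or absorb at the facet
                px += dx * hit_t
                py += dy * hit_t
                pz += dz * hit_t
                u = _rand(seed, ray, bounce + 1, 0)
                R = refl[hit_tri]
                T = trans[hit_tri]
                if bounce >= max_bounces or u >= R + T:
                    absorbed[hit_tri] += w
                    totals[1] += w
                    alive = False
                else:
                    # incident-side sign of the facet normal
                    ndotd = (
                        normal[hit_tri, 0] * dx
                        + normal[hit_tri, 1] * dy
                        + normal[hit_tri, 2] * dz
                    )
                    side = -1.0 if ndotd > 0 else 1.0
                    if u < R:
                        ax = normal[hit_tri, 0] * side
                        ay = normal[hit_tri, 1] * side
                        az = normal[hit_tri, 2] * side
                    else:
                        ax = -normal[hit_tri, 0] * side
                        ay = -normal[hit_tri, 1] * side
                        az = -normal[hit_tri, 2] * side
                    # cosine-weighted direction about (ax, ay, az)
                    u1 = _rand(seed, ray, bounce + 1, 1)
                    u2 = _rand(seed, ray, bounce + 1, 2)
                    r = math.sqrt(u1)
                    phi = 2.0 * math.pi * u2
                    lx = r * math.cos(phi)
                    ly = r * math.sin(phi)
                    lz = math.sqrt(max(1.0 - u1, 0.0))
                    # orthonormal basis around the axis
                    if abs(ax) < 0.9:
                        bx, by, bz = 1.0, 0.0, 0.0
                    else:
                        bx, by, bz = 0.0, 1.0, 0.0
                    t1x = ay * bz - az * by
                    t1y = az * bx - ax * bz
                    t1z = ax * by - ay * bx
                    tn = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
                    t1x /= tn; t1y /= tn; t1z /= tn
                    t2x = ay * t1z - az * t1y
                    t2y = az * t1x - ax * t1z
                    t2z = ax * t1y - ay * t1x
                    dx = lx * t1x + ly * t2x + lz * ax
                    dy = lx * t1y + ly * t2y + lz * ay
                    dz = lx * t1z + ly * t2z + lz * az
                    px += 1e-6 * ax
                    py += 1e-6 * ay
                    pz += 1e-6 * az
                    bounce += 1
                    steps = 0
                continue

            if exit_code == 1:
                # periodic lateral wrap: move to the boundary and re-enter
                t_exit = min(t_max_x, min(t_max_y, t_max_z))
                # recompute the actual boundary crossing distance
                t_cross = 1e30
                if dx > 0:
                    t_cross = min(t_cross, (W - px) * inv_dx)
                elif dx < 0:
                    t_cross = min(t_cross, (0.0 - px) * inv_dx)
                if dy > 0:
                    t_cross = min(t_cross, (L - py) * inv_dy)
                elif dy < 0:
                    t_cross = min(t_cross, (0.0 - py) * inv_dy)
                if t_cross >= 1e29:
                    totals[3] += w
                    alive = False
                    continue
                px += dx * (t_cross + 1e-7)
                py += dy * (t_cross + 1e-7)
                pz += dz * (t_cross + 1e-7)
                if px < 0.0:
                    px += W
                elif px >= W:
                    px -= W
                if py < 0.0:
                    py += L
                elif py >= L:
                    py -= L
                if pz <= 0.0:
                    totals[2] += w
                    alive = False
                elif pz >= z_top:
                    totals[3] += w
                    alive = False
                continue
            elif exit_code == 2:
                totals[2] += w
                alive = False
            else:
                totals[3] += w
                alive = False


# --------------------------------------------------------------------------
# Public API

def resolve_optics(scene, optics) -> tuple[np.ndarray, np.ndarray]:
    """Per-facet reflectance/transmittance arrays from an optics spec.

    ``optics`` may be a single :class:`LeafOpticalProperties` applied to all
    leaves, a mapping ``{leaf_index: props}``, or a callable
    ``f(instance, leaf_index) -> props``. Stem facets are absorbing.
    """
    n = scene.n_facets
    refl = np.zeros(n)
    trans = np.zeros(n)
    leaf_mask = scene.facet_leaf > 0
    if isinstance(optics, LeafOpticalProperties):
        refl[leaf_mask] = optics.reflectance
        trans[leaf_mask] = optics.transmittance
    elif isinstance(optics, dict):
        for leaf_id, props in optics.items():
            m = scene.facet_leaf == leaf_id
            refl[m] = props.reflectance
            trans[m] = props.transmittance
    elif callable(optics):
        pairs = np.unique(
            np.column_stack([scene.facet_instance, scene.facet_leaf]), axis=0
        )
        for inst, leaf_id in pairs:
            if leaf_id == 0:
                continue
            props = optics(int(inst), int(leaf_id))
            m = (scene.facet_instance == inst) & (scene.facet_leaf == leaf_id)
            refl[m] = props.reflectance
            trans[m] = props.transmittance
    else:
        raise TypeError("optics must be LeafOpticalProperties, dict, or callable")
    if np.any(refl + trans > 1.0 + 1e-12):
        raise ValueError("reflectance + transmittance > 1 on some facet")
    return refl, trans


def trace(
    scene,
    sky: SkyCondition,
    optics,
    rays_per_m2: float = 1e4,
    max_bounces: int = 5,
    rng_seed: int = 0,
) -> FacetAbsorption:
    """Trace one sky condition through the canopy scene.

    ``rays_per_m2`` is the launch density (per horizontal m^2 of domain) for
    each of the direct and diffuse components. Per-facet absorbed flux is
    normalized by one-sided facet area. Deterministic for a fixed seed.
    """
    if scene.n_facets == 0:
        raise ValueError("scene is empty")
    if rays_per_m2 <= 0:
        raise ValueError("rays_per_m2 must be > 0")
    out = FacetAbsorption.zeros(scene.n_facets, rng_seed)
    if not sky.sun_up or (sky.direct_ppfd <= 0 and sky.diffuse_ppfd <= 0):
        return out

    refl, trans = resolve_optics(scene, optics)
    tri = scene.triangles
    V = scene.vertices
    v0 = np.ascontiguousarray(V[tri[:, 0]])
    e1 = np.ascontiguousarray(V[tri[:, 1]] - V[tri[:, 0]])
    e2 = np.ascontiguousarray(V[tri[:, 2]] - V[tri[:, 0]])
    nrm = np.cross(e1, e2)
    nlen = np.linalg.norm(nrm, axis=1, keepdims=True)
    nlen[nlen == 0] = 1.0
    nrm = np.ascontiguousarray(nrm / nlen)

    W = scene.domain.x_max - scene.domain.x_min
    L = scene.domain.y_max - scene.domain.y_min
    z_top = float(V[:, 2].max()) + 2.0
    # shift scene so the domain starts at the origin (grid convention)
    shift = np.array([scene.domain.x_min, scene.domain.y_min, 0.0])
    v0 = v0 - shift

    grid, cell_start, cell_tris = _build_grid(v0, e1, e2, W, L, z_top)
    nx, ny, nz, hx, hy, hz = grid
    area_m2 = W * L / 1e4

    sun = sky.sun_direction
    d = -sun  # from sky toward the ground
    if d[2] >= -1e-6:
        d = np.array([0.0, 0.0, -1.0])

    n_direct = 0
    gx = gy = 1
    w_direct = 0.0
    if sky.direct_ppfd > 0:
        n_target = max(int(rays_per_m2 * area_m2), 16)
        gx = max(int(round(math.sqrt(n_target * W / max(L, 1e-9)))), 1)
        gy = max(int(math.ceil(n_target / gx)), 1)
        n_direct = gx * gy
        w_direct = sky.direct_ppfd * area_m2 / n_direct
    n_diffuse = 0
    w_diffuse = 0.0
    if sky.diffuse_ppfd > 0:
        n_diffuse = max(int(rays_per_m2 * area_m2), 16)
        w_diffuse = sky.diffuse_ppfd * area_m2 / n_diffuse

    absorbed = np.zeros(scene.n_facets)
    totals = np.zeros(4)
    _trace_kernel(
        v0, e1, e2, nrm, refl, trans,
        nx, ny, nz, hx, hy, hz,
        cell_start, cell_tris,
        n_direct, gx, gy, float(d[0]), float(d[1]), float(d[2]), w_direct,
        n_diffuse, w_diffuse,
        max_bounces, np.uint64(rng_seed & 0x7FFFFFFFFFFFFFFF),
        absorbed, totals,
    )
    area_f_m2 = scene.facet_area / 1e4
    with np.errstate(divide="ignore", invalid="ignore"):
        ppfd = np.where(area_f_m2 > 0, absorbed / np.where(area_f_m2 > 0, area_f_m2, 1.0), 0.0)
    return FacetAbsorption(
        absorbed_ppfd=ppfd,
        absorbed_power=absorbed,
        emitted=float(totals[0]),
        absorbed_facets=float(totals[1]),
        absorbed_ground=float(totals[2]),
        escaped=float(totals[3]),
        ray_count=n_direct + n_diffuse,
        rng_seed=rng_seed,
    )


def diurnal_trace(
    scene,
    date,
    latitude: float,
    optics,
    hours=None,
    longitude: float = 0.0,
    atmospheric_transmittance: float = 0.7,
    rays_per_m2: float = 1e4,
    max_bounces: int = 5,
    rng_seed: int = 0,
) -> dict[float, FacetAbsorption]:
    """One trace per hour of the day (default 05:00-20:00 local solar time).

    Night hours yield zero absorption fields without tracing. The per-hour
    RNG stream is derived from ``rng_seed`` and the hour so that hours are
    independent yet reproducible.
    """
    from .light import incident_ppfd

    if hours is None:
        hours = list(range(5, 21))
    out: dict[float, FacetAbsorption] = {}
    for hour in hours:
        sky = incident_ppfd(date, float(hour), latitude, longitude,
                            atmospheric_transmittance)
        if not sky.sun_up or (sky.direct_ppfd <= 0 and sky.diffuse_ppfd <= 0):
            out[float(hour)] = FacetAbsorption.zeros(scene.n_facets, rng_seed)
            continue
        hour_seed = (rng_seed * 1000003 + int(round(hour * 4))) & 0x7FFFFFFF
        out[float(hour)] = trace(
            scene, sky, optics, rays_per_m2=rays_per_m2,
            max_bounces=max_bounces, rng_seed=hour_seed,
        )
    return out
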