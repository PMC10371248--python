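"""Leaf and canopy CO2 assimilation via the non-rectangular hyperbola (NRH).

The leaf light response is the classic four-parameter NRH: net assimilation
A(I) is the lower root of

    theta * A'**2 - (phi*I + P_max) * A' + phi*I*P_max = 0,   A = A' - R_d

with capacity ``P_max`` (umol CO2 m-2 s-1), initial quantum yield ``phi``
(mol CO2 mol-1 photons), convexity ``theta`` in (0, 1], and dark respiration
``R_d``. Canopy assimilation sums the facet-level responses to ray-traced
absorbed PPFD over the scoring region, and the diurnal total integrates the
hourly canopy rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LightResponseParams",
    "FitDiagnostics",
    "CanopyPhotosynthesis",
    "leaf_A",
    "fit_light_response",
    "quantum_yield_slope",
    "canopy_A",
    "diurnal_canopy_A",
]

#: PPFD levels of the standard gas-exchange measurement sequence.
MEASUREMENT_PPFD_GRID = (2000, 1500, 1000, 800, 600, 400, 300, 200, 150, 100, 50, 0)


@dataclass
class LightResponseParams:
    """NRH parameters for one (variety, canopy layer) combination."""

    P_max: float
    phi: float
    theta: float
    R_d: float
    layer: str = "up"  # "up" | "bottom"
    variety: str = ""

    def validate(self) -> None:
        if not self.P_max > 0:
            raise ValueError("P_max must be > 0")
        if not (0.0 < self.phi < 0.125):
            raise ValueError("phi must be in (0, 0.125)")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if self.R_d < 0:
            raise ValueError("R_d must be >= 0")

    def scaled(self, P_max: float = 1.0, phi: float = 1.0, theta: float = 1.0,
               R_d: float = 1.0) -> "LightResponseParams":
        """Return a copy with parameters multiplied by the given factors.

        ``theta`` is clipped to 1 (with the caller expected to have warned);
        used by the sensitivity sweeps.
        """
        return LightResponseParams(
            P_max=self.P_max * P_max,
            phi=self.phi * phi,
            theta=min(self.theta * theta, 1.0),
            R_d=self.R_d * R_d,
            layer=self.layer,
            variety=self.variety,
        )


@dataclass
class FitDiagnostics:
    rmse: float
    converged: bool
    n_points: int
    message: str = ""


@dataclass
class CanopyPhotosynthesis:
    """Canopy assimilation per unit ground area of the scoring region.

    ``A_c`` holds hourly rates (umol CO2 m-2 ground s-1); ``A_c_day`` is the
    diurnal integral (mol CO2 m-2 ground day-1, hourly sum x 3600 / 1e6).
    """

    A_c: dict[float, float] = field(default_factory=dict)
    A_c_day: float | None = None
    per_layer: dict[str, float] = field(default_factory=dict)
    per_leaf: dict[tuple[int, int], float] = field(default_factory=dict)
    ground_area_m2: float = 0.0


def leaf_A(I, params: LightResponseParams):
    """Net leaf assimilation (umol CO2 m-2 s-1) at PPFD ``I`` (scalar or array).

    Lower root of the NRH quadratic minus dark respiration; the theta -> 0
    degenerate case falls back to the rectangular hyperbola.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("PPFD must be >= 0")
    p, phi, th, rd = params.P_max, params.phi, params.theta, params.R_d
    s = phi * I + p
    if th < 1e-12:
        with np.errstate(divide="ignore", invalid="ignore"):
            gross = np.where(s > 0, phi * I * p / np.where(s > 0, s, 1.0), 0.0)
    else:
        disc = s * s - 4.0 * th * phi * I * p
        gross = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * th)
    out = gross - rd
    return float(out) if out.ndim == 0 else out


def _nrh(I, p, phi, th, rd):
    s = phi * I + p
    th = max(th, 1e-9)
    disc = np.maximum(s * s - 4.0 * th * phi * I * p, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * th) - rd


def fit_light_response(
    ppfd: np.ndarray,
    A: np.ndarray,
    layer: str = "up",
    variety: str = "",
    bounds: tuple | None = None,
) -> tuple[LightResponseParams, FitDiagnostics]:
    """Nonlinear least-squares fit of the NRH to a measured light response.

    Initial values follow the usual gas-exchange heuristics: R_d from the
    dark point, phi from the low-light slope, P_max from the high-light
    plateau, theta mid-range. Non-convergence is reported in the
    diagnostics, not raised.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    A = np.asarray(A, dtype=float)
    if ppfd.shape != A.shape:
        raise ValueError("ppfd and A must have the same shape")
    levels = np.unique(ppfd)
    if levels.size < 6:
        raise ValueError("need >= 6 distinct PPFD levels")
    if levels.min() > 1e-9:
        raise ValueError("need a dark (PPFD = 0) point")

    rd0 = max(-float(A[ppfd <= 1e-9].mean()), 0.01)
    low = (ppfd > 0) & (ppfd <= 250)
    if low.sum() >= 2:
        slope = np.polyfit(ppfd[low], A[low], 1)[0]
        phi0 = float(np.clip(slope, 1e-3, 0.12))
    else:
        phi0 = 0.05
    pmax0 = max(float(A.max()) + rd0, 1.0)
    x0 = np.array([pmax0, phi0, 0.7, rd0])
    if bounds is None:
        lo = np.array([1e-3, 1e-4, 1e-3, 0.0])
        hi = np.array([200.0, 0.125, 1.0, 20.0])
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def resid(x):
        return _nrh(ppfd, *x) - A

    try:
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=2000)
        ok = bool(res.success) and res.cost < 1e6
        x = res.x
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        msg = res.message
    except Exception as exc:  # pragma: no cover - scipy failures are rare
        ok, x, rmse, msg = False, x0, float("nan"), str(exc)
    # A flat/degenerate response is not a meaningful fit even if the solver
    # technically converged.
    if np.ptp(A) < 1e-6:
        ok = False
        msg = "degenerate (constant) response"
    params = LightResponseParams(
        P_max=float(x[0]), phi=float(x[1]), theta=float(x[2]), R_d=float(x[3]),
        layer=layer, variety=variety,
    )
    return params, FitDiagnostics(rmse=rmse, converged=ok, n_points=ppfd.size, message=msg)


def quantum_yield_slope(ppfd: np.ndarray, A: np.ndarray) -> float:
    """Apparent quantum yield: OLS slope of A vs PPFD at 50/100/150/200.

    This mirrors the standard low-light linear fit of gas-exchange practice;
    it underestimates phi slightly when theta < 1 (curvature bias).
    """
    ppfd = np.asarray(ppfd, dtype=float)
    A = np.asarray(A, dtype=float)
    required = (50.0, 100.0, 150.0, 200.0)
    missing = [lv for lv in required if not np.any(np.isclose(ppfd, lv))]
    if missing:
        raise ValueError(f"missing required PPFD levels: {missing}")
    mask = np.isclose(ppfd[:, None], np.array(required)[None, :]).any(axis=1)
    return float(np.polyfit(ppfd[mask], A[mask], 1)[0])


def canopy_A(absorption, params_by_layer: dict[str, LightResponseParams], scene,
             hour: float | None = None) -> CanopyPhotosynthesis:
    """One-hour canopy assimilation from per-facet absorbed PPFD.

    A_c = sum over scored leaf facets of leaf_A(absorbed, params[layer]) *
    facet_area / scoring_region_area, in umol CO2 m-2 ground s-1.
    """
    region_m2 = scene.scoring_region.area_cm2 / 1e4
    if region_m2 <= 0:
        raise ValueError("scoring region has zero area")
    out = CanopyPhotosynthesis(ground_area_m2=region_m2)
    mask = scene.facet_scored & (scene.facet_leaf > 0)
    layers = scene.facet_layer[mask]
    areas_m2 = scene.facet_area[mask] / 1e4
    ppfd = absorption.absorbed_ppfd[mask]
    leaves = scene.facet_leaf[mask]
    plants = scene.facet_instance[mask]
    total = 0.0
    for layer_code, layer_name in ((1, "bottom"), (2, "up")):
        sel = layers == layer_code
        if not np.any(sel):
            out.per_layer[layer_name] = 0.0
            continue
        if layer_name not in params_by_layer:
            raise ValueError(f"no light-response parameters for layer {layer_name!r}")
        a = leaf_A(ppfd[sel], params_by_layer[layer_name])
        contrib = a * areas_m2[sel]
        out.per_layer[layer_name] = float(contrib.sum() / region_m2)
        total += float(contrib.sum())
        for pl, lf, c in zip(plants[sel], leaves[sel], contrib):
            key = (int(pl), int(lf))
            out.per_leaf[key] = out.per_leaf.get(key, 0.0) + float(c / region_m2)
    ac = total / region_m2
    if hour is not None:
        out.A_c[hour] = ac
    else:
        out.A_c[0.0] = ac
    return out


def diurnal_canopy_A(
    hourly_absorptions: dict[float, object],
    params_by_layer: dict[str, LightResponseParams],
    scene,
    include_night: bool = False,
    night_hours: list[float] | None = None,
) -> CanopyPhotosynthesis:
    """Diurnal canopy assimilation A_c,d (mol CO2 m-2 ground day-1).

    Sums hourly A_c x 3600 s / 1e6 over the supplied daylight hours. With
    ``include_night``, night hours contribute dark respiration scaled by the
    scored leaf-area index.
    """
    out = CanopyPhotosynthesis(ground_area_m2=0.0)
    total = 0.0
    for hour in sorted(hourly_absorptions):
        res = canopy_A(hourly_absorptions[hour], params_by_layer, scene, hour=hour)
        out.A_c[hour] = res.A_c[hour]
        out.ground_area_m2 = res.ground_area_m2
        for k, v in res.per_layer.items():
            out.per_layer[k] = out.per_layer.get(k, 0.0) + v * 3600.0 / 1e6
        total += res.A_c[hour] * 3600.0 / 1e6
    if include_night and night_hours:
        from .canopy import compute_lai  # local import to avoid a cycle

        lai = compute_lai(scene, scope="scored")
        # layer-weighted dark respiration per ground area
        mask = scene.facet_scored & (scene.facet_leaf > 0)
        region_m2 = scene.scoring_region.area_cm2 / 1e4
        resp = 0.0
        for layer_code, layer_name in ((1, "bottom"), (2, "up")):
            sel = mask & (scene.facet_layer == layer_code)
            area_m2 = scene.facet_area[sel].sum() / 1e4
            resp += params_by_layer[layer_name].R_d * area_m2 / region_m2
        for hour in night_hours:
            out.A_c[hour] = -resp
            total += -resp * 3600.0 / 1e6
    out.A_c_day = total
    return out
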