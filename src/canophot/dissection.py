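"""Factorial dissection of canopy-photosynthesis differences, plus sweeps.

Two varieties differ in three trait groups: canopy structure (S), leaf
photosynthesis (P), and chlorophyll-driven leaf optics (C). Building the
eight canopies that combine each group from either variety and computing
the daily canopy assimilation A_c,d of each yields, by inclusion-exclusion,
the main-effect contributions c(S), c(P), c(C) and their interactions
c(SP), c(SC), c(PC), c(SPC):

    c(S)   = A(S) - A(O)
    c(SP)  = A(SP) - A(S) - A(P) + A(O)
    c(SPC) = A(SPC) - A(SP) - A(SC) - A(PC) + A(S) + A(P) + A(C) - A(O)

so that A(SPC) - A(O) equals the sum of all seven contributions exactly.
Sensitivity sweeps scale one photosynthetic parameter (0.6-1.4) or one
architectural trait (LW/LL factors, LN count, LC/LA degrees) at a time.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy import CanopyLayout, build_canopy, compute_lai
from .light import spad_to_optics
from .photosynthesis import LightResponseParams, diurnal_canopy_A
from .plant_model import PlantVectorModel, TraitAdjustment, apply_adjustment, mesh_plant
from .raytrace import diurnal_trace

__all__ = [
    "VarietyBundle",
    "SimulationConfig",
    "DissectionResult",
    "run_dissection",
    "simulate_bundle_Acd",
    "sweep_photosynthesis",
    "sweep_architecture",
]

SCENARIOS: dict[str, tuple[str, str, str]] = {
    # scenario -> source of (S=architecture, P=photosynthesis, C=chlorophyll)
    "O": ("base", "base", "base"),
    "S": ("donor", "base", "base"),
    "P": ("base", "donor", "base"),
    "C": ("base", "base", "donor"),
    "SP": ("donor", "donor", "base"),
    "SC": ("donor", "base", "donor"),
    "PC": ("base", "donor", "donor"),
    "SPC": ("donor", "donor", "donor"),
}


@dataclass
class VarietyBundle:
    """The three trait groups of one variety.

    ``spad`` is a mean SPAD reading (or ``{leaf_index: SPAD}``) converted to
    leaf optics through the variety's reflectance regression; set
    ``variety`` explicitly when the label is not one of the calibrated
    lines.
    """

    label: str
    architecture: list[PlantVectorModel]
    photosynthesis: dict[str, LightResponseParams]
    spad: float | dict[int, float] = 45.0
    variety: str | None = None

    def __post_init__(self) -> None:
        if not self.architecture:
            raise ValueError(f"bundle {self.label!r}: missing architecture")
        if not ({"up", "bottom"} <= set(self.photosynthesis)):
            raise ValueError(
                f"bundle {self.label!r}: photosynthesis params need 'up' and 'bottom'"
            )
        if self.variety is None:
            self.variety = self.label if self.label in ("W64A", "A619") else "W64A"

    def optics_map(self):
        """Per-leaf optics dict (or single props) from the SPAD values."""
        if isinstance(self.spad, dict):
            return {
                leaf: spad_to_optics(v, self.variety) for leaf, v in self.spad.items()
            }
        return spad_to_optics(float(self.spad), self.variety)


@dataclass
class SimulationConfig:
    """Shared settings for the diurnal canopy simulations."""

    date: _dt.date = _dt.date(2020, 8, 27)
    latitude: float = 30.933
    longitude: float = 121.133
    atmospheric_transmittance: float = 0.7
    hours: list[float] = field(default_factory=lambda: list(range(5, 21)))
    layout: CanopyLayout = field(default_factory=CanopyLayout)
    rays_per_m2: float = 1e4
    max_bounces: int = 5
    include_night: bool = False
    vary_placement: bool = True
    vary_rays: bool = True


@dataclass
class DissectionResult:
    A_cd: dict[str, float]
    per_replicate: dict[str, list[float]]
    contributions: dict[str, float]
    relative_contributions: dict[str, float]
    replicates: int

    def identity_residual(self) -> float:
        """Relative defect of the inclusion-exclusion identity."""
        total = sum(self.contributions.values())
        lhs = self.A_cd["SPC"] - self.A_cd["O"]
        scale = max(abs(lhs), abs(self.A_cd["O"]), 1e-12)
        return abs(lhs - total) / scale


def simulate_bundle_Acd(
    architecture: list[PlantVectorModel],
    photosynthesis: dict[str, LightResponseParams],
    optics,
    sim: SimulationConfig,
    rng_seed: int = 0,
    scene=None,
    absorptions=None,
):
    """Full pipeline for one trait combination: mesh -> canopy -> trace -> A_c,d.

    Returns (A_cd, scene, hourly absorptions); pass ``scene``/``absorptions``
    back in to reuse cached geometry or light fields when only the
    photosynthetic parameters change.
    """
    if scene is None:
        meshes = [mesh_plant(p) for p in architecture]
        scene = build_canopy(meshes, sim.layout, rng_seed=rng_seed)
    if absorptions is None:
        absorptions = diurnal_trace(
            scene, sim.date, sim.latitude, optics,
            hours=sim.hours, longitude=sim.longitude,
            atmospheric_transmittance=sim.atmospheric_transmittance,
            rays_per_m2=sim.rays_per_m2, max_bounces=sim.max_bounces,
            rng_seed=rng_seed,
        )
    result = diurnal_canopy_A(
        absorptions, photosynthesis, scene, include_night=sim.include_night
    )
    return result.A_c_day, scene, absorptions


def run_dissection(
    base: VarietyBundle,
    donor: VarietyBundle,
    sim: SimulationConfig | None = None,
    replicates: int = 5,
    rng_seed: int = 0,
    backend=None,
) -> DissectionResult:
    """Eight-scenario factorial dissection of A_c,d(base -> donor).

    All eight scenarios within one replicate share a single RNG seed so that
    Monte-Carlo noise differences out of the contributions; replicates vary
    the seed (plant placement and ray streams). ``backend`` may replace the
    full simulator with any callable
    ``f(architecture, photosynthesis, optics, replicate_seed) -> A_cd``
    (used by tests and by single-parameter dissections).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sim = sim or SimulationConfig()
    bundles = {"base": base, "donor": donor}

    if backend is None:
        cache: dict[tuple[str, str, int], tuple] = {}

        def backend(arch_src, photo_src, chl_src, seed):  # noqa: F811
            key = (arch_src, chl_src, seed)
            arch = bundles[arch_src]
            chl = bundles[chl_src]
            if key not in cache:
                a_cd, scene, absorptions = simulate_bundle_Acd(
                    arch.architecture, bundles[photo_src].photosynthesis,
                    chl.optics_map(), sim, rng_seed=seed,
                )
                cache[key] = (scene, absorptions)
                return a_cd
            scene, absorptions = cache[key]
            a_cd, _, _ = simulate_bundle_Acd(
                arch.architecture, bundles[photo_src].photosynthesis,
                chl.optics_map(), sim, rng_seed=seed,
                scene=scene, absorptions=absorptions,
            )
            return a_cd

        def call_backend(srcs, seed):
            return backend(srcs[0], srcs[1], srcs[2], seed)
    else:
        user_backend = backend

        def call_backend(srcs, seed):
            return user_backend(
                bundles[srcs[0]].architecture,
                bundles[srcs[1]].photosynthesis,
                bundles[srcs[2]].optics_map(),
                seed,
            )

    per_rep: dict[str, list[float]] = {k: [] for k in SCENARIOS}
    for rep in range(replicates):
        seed = (rng_seed * 10007 + rep) & 0x7FFFFFFF
        for key, srcs in SCENARIOS.items():
            per_rep[key].append(float(call_backend(srcs, seed)))

    A = {k: float(np.mean(v)) for k, v in per_rep.items()}
    c = {
        "S": A["S"] - A["O"],
        "P": A["P"] - A["O"],
        "C": A["C"] - A["O"],
        "SP": A["SP"] - A["S"] - A["P"] + A["O"],
        "SC": A["SC"] - A["S"] - A["C"] + A["O"],
        "PC": A["PC"] - A["P"] - A["C"] + A["O"],
    }
    c["SPC"] = (
        A["SPC"] - A["SP"] - A["SC"] - A["PC"]
        + A["S"] + A["P"] + A["C"] - A["O"]
    )
    denom = A["O"] if abs(A["O"]) > 1e-15 else np.nan
    rel = {k: 100.0 * v / denom for k, v in c.items()}
    return DissectionResult(
        A_cd=A, per_replicate=per_rep, contributions=c,
        relative_contributions=rel, replicates=replicates,
    )


def sweep_photosynthesis(
    bundle: VarietyBundle,
    parameter: str,
    layer: str = "up",
    factors=None,
    sim: SimulationConfig | None = None,
    replicates: int = 1,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """A_c,d response to proportional scaling of one NRH parameter.

    Geometry and traced light fields are computed once per replicate and
    reused across factors, since leaf optics do not change. ``theta``
    scalings that would exceed 1 are clipped with a warning.
    """
    if parameter not in ("P_max", "phi", "theta", "R_d"):
        raise ValueError("parameter must be one of P_max, phi, theta, R_d")
    factors = list(factors) if factors is not None else list(np.round(np.arange(0.6, 1.41, 0.1), 2))
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be > 0")
    sim = sim or SimulationConfig()
    rows = []
    fields_cache = []
    for rep in range(replicates):
        seed = (rng_seed * 10007 + rep) & 0x7FFFFFFF
        _, scene, absorptions = simulate_bundle_Acd(
            bundle.architecture, bundle.photosynthesis, bundle.optics_map(),
            sim, rng_seed=seed,
        )
        fields_cache.append((scene, absorptions))
    for f in factors:
        values = []
        for rep in range(replicates):
            scene, absorptions = fields_cache[rep]
            params = dict(bundle.photosynthesis)
            p = params[layer]
            if parameter == "theta" and p.theta * f > 1.0:
                warnings.warn("theta scaling clipped to 1", stacklevel=2)
            params[layer] = p.scaled(**{parameter: f})
            res = diurnal_canopy_A(absorptions, params, scene,
                                   include_night=sim.include_night)
            values.append(res.A_c_day)
        rows.append({
            "factor": f,
            "A_cd": float(np.mean(values)),
            "A_cd_sd": float(np.std(values)) if replicates > 1 else 0.0,
        })
    return pd.DataFrame(rows)


_TRAIT_FIELD = {
    "LW": "leaf_width_factor",
    "LL": "leaf_length_factor",
    "LN": "leaf_number_delta",
    "LC": "leaf_curvature_delta_deg",
    "LA": "leaf_angle_delta_deg",
}
_TRAIT_RANGE = {
    "LW": (0.6, 2.0), "LL": (0.6, 2.0), "LN": (-4, 8),
    "LC": (-180.0, 180.0), "LA": (-20.0, 40.0),
}


def sweep_architecture(
    bundle: VarietyBundle,
    trait: str,
    values,
    sim: SimulationConfig | None = None,
    replicates: int = 1,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, float | None]:
    """A_c,d (and LAI) response to one architectural trait adjustment.

    Each value rebuilds the plants with the corresponding
    :class:`TraitAdjustment`, re-meshes, re-traces, and reports mean A_c,d
    with replicate SD plus the scored-region LAI; the returned optimum is
    the value maximizing mean A_c,d. Failed adjustments are recorded as NaN
    rows and the sweep continues.
    """
    if trait not in _TRAIT_FIELD:
        raise ValueError(f"trait must be one of {sorted(_TRAIT_FIELD)}")
    lo, hi = _TRAIT_RANGE[trait]
    sim = sim or SimulationConfig()
    rows = []
    for v in values:
        if not (lo <= v <= hi):
            warnings.warn(f"{trait} value {v} outside the usual range [{lo}, {hi}]",
                          stacklevel=2)
        adj = TraitAdjustment(**{_TRAIT_FIELD[trait]: v})
        acds, lais = [], []
        error = ""
        try:
            plants = [apply_adjustment(p, adj) for p in bundle.architecture]
            for rep in range(replicates):
                seed = (rng_seed * 10007 + rep) & 0x7FFFFFFF
                a_cd, scene, _ = simulate_bundle_Acd(
                    plants, bundle.photosynthesis, bundle.optics_map(),
                    sim, rng_seed=seed,
                )
                acds.append(a_cd)
                lais.append(compute_lai(scene, scope="scored"))
        except ValueError as exc:
            error = str(exc)
        rows.append({
            "value": v,
            "A_cd": float(np.mean(acds)) if acds else float("nan"),
            "A_cd_sd": float(np.std(acds)) if len(acds) > 1 else 0.0,
            "LAI": float(np.mean(lais)) if lais else float("nan"),
            "error": error,
        })
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["A_cd"])
    optimum = float(valid.loc[valid["A_cd"].idxmax(), "value"]) if len(valid) else None
    return table, optimum
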