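"""Run configuration, presets, and the end-to-end pipeline.

A :class:`RunConfig` (loadable from YAML or JSON) fixes every input of one
simulation — site, date, planting layout, optics source, photosynthetic
parameters, ray settings, seeds — and :func:`run_pipeline` executes
generate/load plants -> canopy -> diurnal trace -> canopy photosynthesis,
writing CSV outputs and a manifest sufficient to reproduce the run
bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .canopy import CanopyLayout, build_canopy, compute_lai
from .dissection import SimulationConfig, VarietyBundle
from .light import LeafOpticalProperties, spad_to_optics
from .photosynthesis import LightResponseParams, diurnal_canopy_A
from .plant_model import PRESETS, generate_synthetic_plant, mesh_plant
from .raytrace import diurnal_trace

__all__ = ["RunConfig", "run_pipeline", "load_config", "default_params", "make_bundle"]


#: Synthetic default NRH parameter sets per canopy layer (clearly not the
#: unpublished measured values; chosen as typical maize magnitudes). The
#: "A619" entry carries the qualitatively higher capacity and quantum yield
#: of the planophile line so that variety swaps have a photosynthetic
#: signal to dissect.
DEFAULT_NRH = {
    "up": dict(P_max=35.0, phi=0.055, theta=0.75, R_d=1.8),
    "bottom": dict(P_max=22.0, phi=0.045, theta=0.70, R_d=1.2),
}
DEFAULT_NRH_BY_VARIETY = {
    "W64A": DEFAULT_NRH,
    "A619": {
        "up": dict(P_max=40.0, phi=0.062, theta=0.80, R_d=1.9),
        "bottom": dict(P_max=23.0, phi=0.052, theta=0.72, R_d=1.2),
    },
}


def default_params(variety: str = "") -> dict[str, LightResponseParams]:
    table = DEFAULT_NRH_BY_VARIETY.get(variety, DEFAULT_NRH)
    return {
        layer: LightResponseParams(layer=layer, variety=variety, **vals)
        for layer, vals in table.items()
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce one canopy simulation."""

    preset: str = "erect"                 # architecture preset or "file"
    plant_files: list[str] = field(default_factory=list)
    n_plants: int = 4
    date: str = "2020-08-27"
    latitude: float = 30.933
    longitude: float = 121.133
    atmospheric_transmittance: float = 0.7
    hours: list[float] = field(default_factory=lambda: list(range(5, 21)))
    rows: int = 4
    plants_per_row: int = 13
    row_spacing_cm: float = 55.0
    plant_spacing_cm: float = 15.0
    scoring_width_cm: float = 110.0
    scoring_length_cm: float = 75.0
    randomize_azimuth: bool = True
    spad: float | None = 45.0
    reflectance: float | None = None
    transmittance: float | None = None
    variety: str = "W64A"
    nrh: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_NRH.items()})
    rays_per_m2: float = 1e4
    max_bounces: int = 5
    rng_seed: int = 1
    include_night: bool = False
    output_dir: str = "outputs"

    def validate(self) -> None:
        if self.rows < 1 or self.plants_per_row < 1:
            raise ValueError("layout: rows and plants_per_row must be >= 1")
        if not (0.0 < self.atmospheric_transmittance <= 1.0):
            raise ValueError("atmospheric_transmittance must be in (0, 1]")
        if self.rays_per_m2 <= 0:
            raise ValueError("rays_per_m2 must be > 0")
        if self.preset != "file" and self.preset not in PRESETS:
            raise ValueError(
                f"preset must be 'file' or one of {sorted(PRESETS)}"
            )
        if self.spad is None and (self.reflectance is None or self.transmittance is None):
            raise ValueError("need either spad or reflectance+transmittance")
        for layer in ("up", "bottom"):
            if layer not in self.nrh:
                raise ValueError(f"nrh missing layer {layer!r}")

    @property
    def layout(self) -> CanopyLayout:
        return CanopyLayout(
            rows=self.rows, plants_per_row=self.plants_per_row,
            row_spacing_cm=self.row_spacing_cm,
            plant_spacing_cm=self.plant_spacing_cm,
            scoring_width_cm=self.scoring_width_cm,
            scoring_length_cm=self.scoring_length_cm,
            randomize_azimuth=self.randomize_azimuth,
        )

    @property
    def sim(self) -> SimulationConfig:
        return SimulationConfig(
            date=_dt.date.fromisoformat(self.date),
            latitude=self.latitude, longitude=self.longitude,
            atmospheric_transmittance=self.atmospheric_transmittance,
            hours=list(self.hours), layout=self.layout,
            rays_per_m2=self.rays_per_m2, max_bounces=self.max_bounces,
            include_night=self.include_night,
        )

    def optics(self) -> LeafOpticalProperties:
        if self.spad is not None:
            return spad_to_optics(self.spad, self.variety)
        return LeafOpticalProperties(
            reflectance=self.reflectance, transmittance=self.transmittance
        )

    def params(self) -> dict[str, LightResponseParams]:
        return {
            layer: LightResponseParams(layer=layer, variety=self.variety, **vals)
            for layer, vals in self.nrh.items()
        }


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def make_bundle(
    label: str,
    preset: str,
    n_plants: int = 4,
    spad: float = 45.0,
    rng_seed: int = 0,
    nrh: dict | None = None,
) -> VarietyBundle:
    """Convenience: a VarietyBundle of synthetic plants from a preset."""
    plants = [
        generate_synthetic_plant(preset, rng_seed=rng_seed * 100 + i)
        for i in range(n_plants)
    ]
    params = (
        {layer: LightResponseParams(layer=layer, variety=label, **vals)
         for layer, vals in nrh.items()}
        if nrh else default_params(label)
    )
    return VarietyBundle(
        label=label, architecture=plants, photosynthesis=params, spad=spad,
        variety=label if label in ("W64A", "A619") else "W64A",
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full simulation described by ``config``.

    Writes hourly canopy rates, per-facet absorption of the brightest hour,
    a one-row summary, and a reproduction manifest to the output directory;
    returns the summary dict.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "plant generation"
    try:
        if config.preset == "file":
            from .pointcloud import read_ply
            from .plant_model import extract_vector_model

            plants = [
                extract_vector_model(read_ply(f)) for f in config.plant_files
            ]
            if not plants:
                raise ValueError("preset 'file' requires plant_files")
        else:
            plants = [
                generate_synthetic_plant(config.preset,
                                         rng_seed=config.rng_seed * 100 + i)
                for i in range(config.n_plants)
            ]
        stage = "meshing"
        meshes = [mesh_plant(p) for p in plants]
        stage = "canopy assembly"
        scene = build_canopy(meshes, config.layout, rng_seed=config.rng_seed)
        stage = "ray tracing"
        sim = config.sim
        absorptions = diurnal_trace(
            scene, sim.date, sim.latitude, config.optics(),
            hours=sim.hours, longitude=sim.longitude,
            atmospheric_transmittance=sim.atmospheric_transmittance,
            rays_per_m2=sim.rays_per_m2, max_bounces=sim.max_bounces,
            rng_seed=config.rng_seed,
        )
        stage = "canopy photosynthesis"
        result = diurnal_canopy_A(
            absorptions, config.params(), scene, include_night=sim.include_night
        )
    except ValueError as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    hourly = pd.DataFrame(
        {"hour": list(result.A_c), "A_c_umol_m2_s": list(result.A_c.values())}
    )
    hourly.to_csv(out / "hourly_canopy_A.csv", index=False, float_format="%.8g")

    peak_hour = max(result.A_c, key=result.A_c.get)
    ab = absorptions[peak_hour]
    facets = pd.DataFrame({
        "facet": np.arange(scene.n_facets),
        "instance": scene.facet_instance,
        "leaf": scene.facet_leaf,
        "layer": scene.facet_layer,
        "area_cm2": scene.facet_area,
        "scored": scene.facet_scored.astype(int),
        "absorbed_umol_m2_s": ab.absorbed_ppfd,
    })
    facets.to_csv(out / f"facet_absorption_h{int(peak_hour):02d}.csv",
                  index=False, float_format="%.8g")

    summary = {
        "A_cd_mol_m2_day": result.A_c_day,
        "LAI_scored": compute_lai(scene, "scored"),
        "LAI_all": compute_lai(scene, "all"),
        "n_facets": int(scene.n_facets),
        "n_instances": len(scene.instances),
        "n_scored": int(sum(i.scored for i in scene.instances)),
        "peak_hour": float(peak_hour),
        "peak_A_c_umol_m2_s": result.A_c[peak_hour],
    }
    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False,
                                   float_format="%.10g")
    manifest = {
        "canophot_version": __version__,
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
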