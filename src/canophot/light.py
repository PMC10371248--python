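"""Incident-light boundary conditions and leaf optical properties.

Solar geometry and the clear-sky direct/diffuse partition provide the
radiation input for canopy ray tracing; leaf reflectance/transmittance in
the PAR band (400-700 nm) come either from measured spectra weighted by the
incident solar spectrum or from SPAD (chlorophyll-meter) regressions
calibrated for the maize inbred lines W64A and A619.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SkyCondition",
    "LeafOpticalProperties",
    "solar_position",
    "incident_ppfd",
    "weighted_optics",
    "spad_to_optics",
    "SOLAR_CONSTANT_W_M2",
    "PAR_ENERGY_FRACTION",
    "PAR_UMOL_PER_J",
]

# Clear-sky radiation constants (documented in docs/methods.md).
SOLAR_CONSTANT_W_M2 = 1367.0
PAR_ENERGY_FRACTION = 0.45
PAR_UMOL_PER_J = 4.57
#: Extraterrestrial PPFD on a plane normal to the beam, umol m-2 s-1.
EXTRATERRESTRIAL_PPFD = SOLAR_CONSTANT_W_M2 * PAR_ENERGY_FRACTION * PAR_UMOL_PER_J


@dataclass
class SkyCondition:
    """Radiation boundary condition for one instant.

    ``direct_ppfd`` is the direct-beam photon flux through a *horizontal*
    plane; ``diffuse_ppfd`` is the diffuse flux on the same plane. Zenith and
    azimuth are in degrees (zenith 0 = sun overhead; azimuth measured
    clockwise from north).
    """

    datetime: _dt.datetime
    latitude: float
    longitude: float
    atmospheric_transmittance: float = 0.7
    direct_ppfd: float = 0.0
    diffuse_ppfd: float = 0.0
    solar_zenith: float = 0.0
    solar_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.atmospheric_transmittance <= 1.0):
            raise ValueError("atmospheric_transmittance must be in (0, 1]")
        if self.direct_ppfd < 0 or self.diffuse_ppfd < 0:
            raise ValueError("PPFD values must be >= 0")
        if not (0.0 <= self.solar_zenith <= 180.0):
            raise ValueError("solar_zenith must be in [0, 180] degrees")

    @property
    def sun_up(self) -> bool:
        return self.solar_zenith < 90.0

    @property
    def sun_direction(self) -> np.ndarray:
        """Unit vector pointing from the scene *toward* the sun (Z up)."""
        z = math.radians(self.solar_zenith)
        a = math.radians(self.solar_azimuth)
        # x = east, y = north, z = up
        return np.array(
            [math.sin(z) * math.sin(a), math.sin(z) * math.cos(a), math.cos(z)]
        )


@dataclass
class LeafOpticalProperties:
    """Broadband PAR reflectance and transmittance of one leaf (fractions)."""

    reflectance: float
    transmittance: float
    spad: float | None = None
    source: str = "direct"

    def __post_init__(self) -> None:
        if self.reflectance < 0 or self.transmittance < 0:
            raise ValueError("reflectance and transmittance must be >= 0")
        if self.reflectance + self.transmittance > 1.0 + 1e-12:
            raise ValueError("reflectance + transmittance must be <= 1")

    @property
    def absorptance(self) -> float:
        return 1.0 - self.reflectance - self.transmittance


def solar_position(
    date: _dt.date, hour: float, latitude: float, longitude: float = 0.0
) -> tuple[float, float]:
    """Solar zenith and azimuth (degrees) at local *solar* time ``hour``.

    Declination follows the Cooper formula from day of year; the hour angle
    is 15 deg per hour from solar noon. Accuracy is well within 1 degree of
    ephemeris values, sufficient for canopy radiation modeling.
    """
    n = date.timetuple().tm_yday
    decl = math.radians(23.44) * math.sin(2.0 * math.pi * (284 + n) / 365.0)
    lat = math.radians(latitude)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(
        hour_angle
    )
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    # Azimuth from north, clockwise (east = 90).
    sin_zen = math.sqrt(max(0.0, 1.0 - cos_zen * cos_zen))
    if sin_zen < 1e-9:
        azimuth = 180.0
    else:
        cos_az = (math.sin(decl) - math.sin(lat) * cos_zen) / (math.cos(lat) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        azimuth = math.degrees(math.acos(cos_az))
        if hour_angle > 0:  # afternoon: sun in the west
            azimuth = 360.0 - azimuth
    return zenith, azimuth


def incident_ppfd(
    date: _dt.date,
    hour: float,
    latitude: float,
    longitude: float = 0.0,
    atmospheric_transmittance: float = 0.7,
) -> SkyCondition:
    """Clear-sky direct and diffuse PPFD for one local-solar-time instant.

    The direct beam is the extraterrestrial PAR flux attenuated by
    ``transmittance ** air_mass`` with air mass 1/cos(zenith); half of the
    scattered flux is assumed to reach the ground as diffuse light. Both
    components are reported on a horizontal plane; both are zero when the
    sun is at or below the horizon.
    """
    zenith, azimuth = solar_position(date, hour, latitude, longitude)
    when = _dt.datetime.combine(date, _dt.time()) + _dt.timedelta(hours=hour)
    sky = SkyCondition(
        datetime=when,
        latitude=latitude,
        longitude=longitude,
        atmospheric_transmittance=atmospheric_transmittance,
        solar_zenith=zenith,
        solar_azimuth=azimuth,
    )
    if zenith >= 90.0:
        return sky
    cos_zen = math.cos(math.radians(zenith))
    air_mass = 1.0 / cos_zen
    tau = atmospheric_transmittance
    beam_normal = EXTRATERRESTRIAL_PPFD * tau**air_mass
    sky.direct_ppfd = beam_normal * cos_zen
    sky.diffuse_ppfd = 0.5 * (1.0 - tau**air_mass) * EXTRATERRESTRIAL_PPFD * cos_zen
    return sky


def weighted_optics(
    wavelengths_nm: np.ndarray,
    reflectance_spectrum: np.ndarray,
    transmittance_spectrum: np.ndarray,
    solar_spectrum: np.ndarray,
) -> LeafOpticalProperties:
    """Solar-spectrum-weighted broadband PAR reflectance and transmittance.

    R = sum(R_i * I_i) / sum(I_i) and T = sum(T_i * I_i) / sum(I_i), with
    the sums running over the samples inside [400, 700] nm (plain sums over
    the given grid, no quadrature weighting).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    r = np.asarray(reflectance_spectrum, dtype=float)
    t = np.asarray(transmittance_spectrum, dtype=float)
    i = np.asarray(solar_spectrum, dtype=float)
    if not (wl.shape == r.shape == t.shape == i.shape):
        raise ValueError("spectra must share one wavelength grid")
    if wl.min() > 400.0 or wl.max() < 700.0:
        raise ValueError("wavelength grid must cover 400-700 nm")
    band = (wl >= 400.0) & (wl <= 700.0)
    total = i[band].sum()
    if total <= 0:
        raise ValueError("solar spectrum must have positive energy in the PAR band")
    return LeafOpticalProperties(
        reflectance=float((r[band] * i[band]).sum() / total),
        transmittance=float((t[band] * i[band]).sum() / total),
        source="spectrum",
    )


# SPAD regressions (percent units): transmittance shared by both lines,
# reflectance per line.
_SPAD_T = (0.006319, -0.8241, 29.49)
_SPAD_R = {
    "A619": (0.002478, -0.3554, 16.66),
    "W64A": (0.0, -0.04863, 8.856),
}


def spad_to_optics(spad: float, variety: str = "W64A") -> LeafOpticalProperties:
    """Leaf PAR optics predicted from a SPAD chlorophyll-meter reading.

    Empirical regressions (percent, converted to fractions): a quadratic in
    SPAD for transmittance shared by both maize lines, a quadratic for A619
    reflectance and a linear model for W64A reflectance. Values outside the
    calibration window or outside [0, 1] trigger a warning / clamp.
    """
    if variety not in _SPAD_R:
        raise ValueError(f"unknown variety {variety!r}; expected one of {sorted(_SPAD_R)}")
    if not (0.0 <= spad <= 80.0):
        warnings.warn(f"SPAD {spad} outside the calibration window [0, 80]", stacklevel=2)
    a, b, c = _SPAD_T
    t_pct = a * spad**2 + b * spad + c
    a, b, c = _SPAD_R[variety]
    r_pct = a * spad**2 + b * spad + c
    t = t_pct / 100.0
    r = r_pct / 100.0
    if not (0.0 <= t <= 1.0) or not (0.0 <= r <= 1.0) or r + t > 1.0:
        warnings.warn("SPAD-predicted optics clamped to physical range", stacklevel=2)
        t = min(max(t, 0.0), 1.0)
        r = min(max(r, 0.0), 1.0 - t)
    return LeafOpticalProperties(reflectance=r, transmittance=t, spad=spad, source="spad")
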