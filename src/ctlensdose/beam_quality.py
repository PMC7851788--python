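"""Beam-quality chain: tube spectrum, Al half-value layer, effective energy.

The chain mirrors how a CT beam is characterised in practice: a
semi-empirical tungsten-anode spectrum (Kramers-type bremsstrahlung
continuum hardened by anode self-filtration, plus tungsten K characteristic
lines above the 69.525 keV K-edge) is filtered by the tube's Al-equivalent
filtration; the polyenergetic aluminum half-value layer (HVL) is the Al
thickness halving the beam's air kerma; the *effective energy* is the
monoenergetic photon energy with that same HVL.  The effective energy then
indexes the Hp(3)/air-kerma conversion coefficient.

The added Al-equivalent filtration per (scanner, field of view) is a
*calibration* parameter: scanners do not publish their total filtration, so
the shipped defaults are chosen such that the computed 120 kVp effective
energies reproduce the measured per-FOV values (55.74, 57.97, 54.87 and
57.30 keV).  ``calibrate_added_filtration`` reproduces that fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .reference_data import (
    AL_DENSITY,
    AIR_DENSITY,
    W_DENSITY,
    TableRangeError,
    load_table,
)

__all__ = [
    "TubeSetting",
    "Spectrum",
    "BeamQuality",
    "simulate_spectrum",
    "apply_filtration",
    "air_kerma_of",
    "hvl_al",
    "hvl_monoenergetic",
    "effective_energy_from_hvl",
    "effective_energy_of_spectrum",
    "summarize_effective_energy",
    "calibrate_added_filtration",
    "default_beam_qualities",
    "W_K_EDGE_KEV",
    "DEFAULT_FILTRATION_MM_AL",
    "TABLE3_EFFECTIVE_ENERGIES_KEV",
]

#: tungsten K-edge; characteristic K lines appear only above this tube voltage
W_K_EDGE_KEV = 69.525

#: W K-line energies (keV) and relative intensities (Ka1 = 1)
_K_LINES = ((59.32, 1.00), (57.98, 0.58), (67.24, 0.22), (69.07, 0.08))

#: effective tungsten self-filtration path at the reference 7 deg anode angle [mm]
_W_SELF_FILTRATION_MM = 0.005

#: fraction scale of K-line fluence relative to the self-filtered continuum
_K_LINE_SCALE = 0.35

_DENSITIES = {"Al": AL_DENSITY, "air": AIR_DENSITY, "W": W_DENSITY}
_MU_TABLES = {"Al": "al_mu_rho", "air": "air_mu_rho", "W": "w_mu_rho"}

#: measured per-FOV effective energies at 120 kVp used as calibration anchors
TABLE3_EFFECTIVE_ENERGIES_KEV = {
    ("80-MDCT", "S-size (24 cm)"): 55.74,
    ("80-MDCT", "L-size (40 cm)"): 57.97,
    ("320-MDCT", "S-size (24 cm)"): 54.87,
    ("320-MDCT", "L-size (40 cm)"): 57.30,
}

# Calibrated total added Al-equivalent filtration [mm] per (scanner, FOV):
# brentq solutions of effective_energy(120 kVp, t) = anchor (see
# calibrate_added_filtration); values are calibrated, not measured.
DEFAULT_FILTRATION_MM_AL = {
    ("80-MDCT", "S-size (24 cm)"): 12.558541,
    ("80-MDCT", "L-size (40 cm)"): 15.244635,
    ("320-MDCT", "S-size (24 cm)"): 11.678684,
    ("320-MDCT", "L-size (40 cm)"): 14.364315,
}


@dataclass(frozen=True)
class TubeSetting:
    """X-ray tube configuration.

    ``filtration`` lists added (material, thickness-mm) pairs on top of the
    model's anode self-filtration.
    """

    tube_voltage: float
    anode_angle: float = 7.0
    filtration: tuple = ()
    fov_label: str = ""

    def __post_init__(self) -> None:
        if not 40 <= self.tube_voltage <= 150:
            raise ValueError(f"tube_voltage {self.tube_voltage} kVp outside [40, 150]")
        if self.anode_angle <= 0:
            raise ValueError("anode_angle must be positive")
        object.__setattr__(self, "filtration", tuple(self.filtration))
        for mat, t in self.filtration:
            if t < 0:
                raise ValueError(f"negative filtration thickness for {mat!r}")


@dataclass(frozen=True)
class Spectrum:
    """Relative photon-fluence spectrum on a uniform energy grid (keV)."""

    energies: np.ndarray
    fluence: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)
        if e.shape != f.shape or e.ndim != 1 or e.size < 2:
            raise ValueError("energies and fluence must be matched 1-D arrays")
        step = np.diff(e)
        if np.any(step <= 0) or not np.allclose(step, step[0], rtol=1e-9):
            raise ValueError("energies must be strictly increasing with uniform step")
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if not np.any(f > 0):
            raise ValueError("spectrum has no positive fluence")

    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.fluence) / np.sum(self.fluence))


@dataclass(frozen=True)
class BeamQuality:
    """A tube configuration with its Al-HVL and derived effective energy."""

    setting: TubeSetting
    hvl_al: float
    effective_energy: float

    def __post_init__(self) -> None:
        if self.hvl_al <= 0:
            raise ValueError("hvl_al must be > 0")
        if not 10 < self.effective_energy < self.setting.tube_voltage:
            raise ValueError("effective_energy must lie in (10 keV, tube voltage)")


def _mu_linear(material: str, energies: np.ndarray) -> np.ndarray:
    """Linear attenuation coefficient mu [1/cm] for a supported material."""
    if material not in _MU_TABLES:
        raise ValueError(
            f"unknown filtration material {material!r}; supported: {sorted(_MU_TABLES)}"
        )
    table = load_table(_MU_TABLES[material])
    return np.asarray(table(energies)) * _DENSITIES[material]


def simulate_spectrum(setting: TubeSetting, bin_width: float = 0.5) -> Spectrum:
    """Semi-empirical tungsten-anode spectrum for ``setting``.

    Kramers-type continuum ``(E0 - E)/E`` hardened by an effective tungsten
    self-filtration path (scaled with anode angle), with W K characteristic
    lines added when the tube voltage exceeds the K-edge, then attenuated by
    the setting's added filtration.  Fluence is in relative units.
    """
    if not 0 < bin_width <= 2:
        raise ValueError("bin_width must be in (0, 2] keV")
    e0 = setting.tube_voltage
    top = max(150.0, e0)
    energies = np.arange(10.0 + bin_width / 2.0, top, bin_width)
    fluence = np.zeros_like(energies)
    below = energies < e0
    fluence[below] = (e0 - energies[below]) / energies[below]

    # anode self-filtration: path scales as 1/sin(angle), normalised at 7 deg
    t_w_mm = _W_SELF_FILTRATION_MM * math.sin(math.radians(7.0)) / math.sin(
        math.radians(setting.anode_angle)
    )
    mu_w = _mu_linear("W", energies)
    fluence = fluence * np.exp(-mu_w * t_w_mm / 10.0)

    if e0 > W_K_EDGE_KEV:
        total = fluence.sum()
        line_budget = _K_LINE_SCALE * total * ((e0 - W_K_EDGE_KEV) / e0) ** 1.5
        weight = sum(w for _, w in _K_LINES)
        for line_e, w in _K_LINES:
            idx = int(np.argmin(np.abs(energies - line_e)))
            fluence[idx] += line_budget * w / weight

    spec = Spectrum(energies=energies, fluence=fluence)
    for mat, t in setting.filtration:
        spec = apply_filtration(spec, mat, t)
    return spec


def apply_filtration(spectrum: Spectrum, material: str, thickness_mm: float) -> Spectrum:
    """Attenuate ``spectrum`` by ``thickness_mm`` of ``material`` (Beer-Lambert per bin)."""
    if thickness_mm < 0:
        raise ValueError("filtration thickness must be >= 0")
    if thickness_mm == 0:
        return spectrum
    mu = _mu_linear(material, spectrum.energies)
    return Spectrum(
        energies=spectrum.energies,
        fluence=spectrum.fluence * np.exp(-mu * thickness_mm / 10.0),
    )


def air_kerma_of(spectrum: Spectrum) -> float:
    """Relative air kerma: sum over bins of fluence * E * (mu_en/rho)_air."""
    muen = np.asarray(load_table("air_mu_en_rho")(spectrum.energies))
    return float(np.sum(spectrum.fluence * spectrum.energies * muen))


def hvl_al(spectrum: Spectrum, tol_mm: float = 1e-5) -> float:
    """Polyenergetic Al half-value layer [mm] by bisection on the kerma ratio."""
    k0 = air_kerma_of(spectrum)

    def transmitted(t: float) -> float:
        return air_kerma_of(apply_filtration(spectrum, "Al", t)) / k0 - 0.5

    lo, hi = 0.0, 1.0
    while transmitted(hi) > 0:
        hi *= 2.0
        if hi > 200.0:
            raise RuntimeError(
                f"HVL bracketing failed: kerma ratio at {hi / 2:.0f} mm Al still "
                f"{transmitted(hi / 2) + 0.5:.3f} (> 0.5); non-physical spectrum?"
            )
    return float(brentq(transmitted, lo, hi, xtol=tol_mm))


def hvl_monoenergetic(energy_keV: float) -> float:
    """Closed-form Al HVL [mm] of a monoenergetic beam: ln2 / mu_Al(E)."""
    mu = float(load_table("al_mu_rho")(energy_keV)) * AL_DENSITY  # 1/cm
    return math.log(2.0) / mu * 10.0


_INVERT_LO_KEV = 30.0
_INVERT_HI_KEV = 150.0


def effective_energy_from_hvl(hvl_mm: float, tol_keV: float = 1e-4) -> float:
    """Monoenergetic energy [keV] whose Al HVL equals ``hvl_mm``.

    Inverts the strictly monotone 30-150 keV branch of the Al attenuation
    table by bisection.
    """
    if hvl_mm <= 0:
        raise ValueError("hvl must be > 0")
    lo_hvl = hvl_monoenergetic(_INVERT_LO_KEV)
    hi_hvl = hvl_monoenergetic(_INVERT_HI_KEV)
    if not lo_hvl <= hvl_mm <= hi_hvl:
        raise TableRangeError(
            f"HVL {hvl_mm:.4g} mm Al outside invertible range "
            f"[{lo_hvl:.3f}, {hi_hvl:.3f}] mm (30-150 keV branch)"
        )
    return float(
        brentq(
            lambda e: hvl_monoenergetic(e) - hvl_mm,
            _INVERT_LO_KEV,
            _INVERT_HI_KEV,
            xtol=tol_keV,
        )
    )


def effective_energy_of_spectrum(spectrum: Spectrum) -> float:
    """Effective energy [keV] of a polyenergetic spectrum via its Al HVL."""
    return effective_energy_from_hvl(hvl_al(spectrum))


def summarize_effective_energy(values) -> tuple[float, float]:
    """Mean and *population* SD (divisor n) of effective energies, 2 decimals.

    The population convention is deliberate for this summary: it is the one
    under which the four per-FOV anchors (55.74, 57.97, 54.87, 57.30 keV)
    summarise to 56.47 +/- 1.23 keV.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two effective-energy values")
    return round(float(v.mean()), 2), round(float(v.std(ddof=0)), 2)


def calibrate_added_filtration(
    target_effective_energy: float, tube_voltage: float = 120.0, **setting_kwargs
) -> float:
    """Al filtration [mm] making the simulated beam hit a target effective energy."""

    def objective(t: float) -> float:
        setting = TubeSetting(
            tube_voltage=tube_voltage, filtration=(("Al", t),), **setting_kwargs
        )
        return effective_energy_of_spectrum(simulate_spectrum(setting)) - target_effective_energy

    return float(brentq(objective, 2.0, 40.0, xtol=1e-3))


def default_beam_qualities(bin_width: float = 0.5) -> dict:
    """Compute :class:`BeamQuality` for each shipped (scanner, FOV) calibration."""
    out = {}
    for key, t_al in DEFAULT_FILTRATION_MM_AL.items():
        scanner, fov = key
        setting = TubeSetting(
            tube_voltage=120.0, filtration=(("Al", t_al),), fov_label=fov
        )
        spec = simulate_spectrum(setting, bin_width=bin_width)
        hvl = hvl_al(spec)
        out[key] = BeamQuality(
            setting=setting, hvl_al=hvl, effective_energy=effective_energy_from_hvl(hvl)
        )
    return out
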