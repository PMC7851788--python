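"""Bundled energy-indexed physics tables and the interpolation contract.

The package ships small plain-text tables of mass attenuation (mu/rho) and
mass energy-absorption (mu_en/rho) coefficients for aluminum and air, plus a
table of Hp(3)/air-kerma conversion coefficients for photons at normal
incidence on a cylinder head phantom.  The conversion-coefficient table is a
*synthetic* reconstruction of a Behrens-type cylinder-phantom tabulation
(no machine-readable original is bundled); it is anchored so that
interpolation at 56.47 keV yields K = 1.650 Sv/Gy.

Attenuation-type tables are interpolated log-log (exact for power-law
segments, the standard convention for photon cross sections); the smooth,
peaked conversion-coefficient curve is interpolated linearly.  Queries at a
tabulated node return the node value bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ReferenceTable",
    "TableRangeError",
    "load_table",
    "interpolate",
    "AL_DENSITY",
    "AIR_DENSITY",
    "W_DENSITY",
]

#: elemental densities carried with the tables [g/cm^3]; air at 20 degC
AL_DENSITY = 2.699
AIR_DENSITY = 1.205e-3
W_DENSITY = 19.3


class TableRangeError(ValueError):
    """Raised when a query energy falls outside a table's tabulated range."""


@dataclass(frozen=True)
class ReferenceTable:
    """An energy-indexed physics coefficient table.

    Parameters
    ----------
    name
        Label for the material or quantity (used in error messages).
    energies
        Photon energies in keV, strictly increasing, all positive.
    values
        Coefficient per energy: cm^2/g for mu/rho-type tables, Sv/Gy for
        conversion coefficients.  All positive.
    kind
        ``"attenuation"`` (log-log interpolation) or ``"conversion"``
        (linear interpolation).
    source_citation
        Free-text provenance.
    """

    name: str
    energies: np.ndarray
    values: np.ndarray
    kind: str = "attenuation"
    source_citation: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)
        if e.ndim != 1 or e.shape != v.shape or e.size < 2:
            raise ValueError(f"table {self.name!r}: need matched 1-D arrays of >= 2 nodes")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError(f"table {self.name!r}: energies must be positive and strictly increasing")
        if np.any(v <= 0):
            raise ValueError(f"table {self.name!r}: all values must be > 0")
        if self.kind not in ("attenuation", "conversion"):
            raise ValueError(f"table {self.name!r}: unknown kind {self.kind!r}")

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])

    def __call__(self, energy):
        return interpolate(self, energy)


def interpolate(table: ReferenceTable, energy):
    """Interpolate ``table`` at ``energy`` (keV; scalar or array).

    Log-log linear for attenuation-type tables, linear-linear for
    conversion-coefficient tables.  Tabulated node energies reproduce the
    stored node value exactly.

    Raises
    ------
    TableRangeError
        If any query energy lies outside the tabulated range.
    """
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    eq = np.atleast_1d(e)
    if np.any(eq < table.emin) or np.any(eq > table.emax):
        raise TableRangeError(
            f"energy {energy} keV outside range [{table.emin}, {table.emax}] keV "
            f"of table {table.name!r}"
        )
    if table.kind == "attenuation":
        out = np.exp(
            np.interp(np.log(eq), np.log(table.energies), np.log(table.values))
        )
    else:
        out = np.interp(eq, table.energies, table.values)
    # bit-exact at nodes (log/exp round trips can perturb the last ulp)
    idx = np.searchsorted(table.energies, eq)
    idx = np.clip(idx, 0, table.energies.size - 1)
    hit = table.energies[idx] == eq
    out[hit] = table.values[idx[hit]]
    return float(out[0]) if scalar else out


_TABLE_FILES = {
    "al_mu_rho": ("al_mass_attenuation.csv", "attenuation"),
    "al_mu_en_rho": ("al_mass_energy_absorption.csv", "attenuation"),
    "air_mu_rho": ("air_mass_attenuation.csv", "attenuation"),
    "air_mu_en_rho": ("air_mass_energy_absorption.csv", "attenuation"),
    "hp3_ka": ("hp3_ka_cylinder0_synthetic.csv", "conversion"),
    "w_mu_rho": ("w_mass_attenuation_approx.csv", "attenuation"),
}

_CACHE: dict[str, ReferenceTable] = {}


def _read_manifest() -> dict:
    with resources.files("ctlensdose.data").joinpath("manifest.json").open() as fh:
        return json.load(fh)


def load_table(key: str) -> ReferenceTable:
    """Load a bundled table by key.

    Keys: ``al_mu_rho``, ``al_mu_en_rho``, ``air_mu_rho``, ``air_mu_en_rho``,
    ``hp3_ka`` (conversion coefficients), ``w_mu_rho`` (internal, spectrum
    model only).
    """
    if key in _CACHE:
        return _CACHE[key]
    try:
        fname, kind = _TABLE_FILES[key]
    except KeyError:
        raise KeyError(f"unknown table {key!r}; available: {sorted(_TABLE_FILES)}") from None
    raw = resources.files("ctlensdose.data").joinpath(fname).read_text()
    rows = [line.split(",") for line in raw.strip().splitlines()[1:]]
    e = np.array([float(r[0]) for r in rows])
    v = np.array([float(r[1]) for r in rows])
    citation = _read_manifest().get(fname, {}).get("source", "")
    tab = ReferenceTable(name=key, energies=e, values=v, kind=kind, source_citation=citation)
    _CACHE[key] = tab
    return tab
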