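"""Seedable synthetic cohorts with the structure the analysis assumes.

The generator emulates a stratified occupational-dosimetry campaign:
procedures are assigned a working practice (assisted ventilation with
bag-valve-mask / head holding / observation), a standing area relative to
the gantry, and a profession; per-procedure DLP and true outside-glasses
Hp(3) are lognormal with practice-specific medians; a latent glasses
transmission links inside to outside readings, and a latent extension-tube
transmission separates the with/without-tube strata.  Six dosimeter
readings per procedure are synthesised with multiplicative side and
orientation noise and stored as air kerma (dose / K), so the forward
pipeline (x K) recovers the intended dose scale exactly.

True dose is coupled to DLP with unit elasticity (staff scatter dose scales
with the photon output the DLP measures); the residual lognormal noise is
sized so the *total* dose spread matches the configured geometric SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dose_analysis import AREAS, PRACTICES, PROFESSIONS, ProcedureRecord
from .hp3_conversion import DosimeterReading

__all__ = ["SyntheticConfig", "generate_cohort", "degenerate_cohort", "generate_curtain_experiment"]

#: default mix observed in a 91-procedure campaign: 65/12/14
_PRACTICE_MIX = {"assisted_ventilation": 65 / 91, "head_holding": 12 / 91, "observation": 14 / 91}

#: ventilation and head holding happen at the patient's head near the
#: gantry (areas I/II); observation is mostly distant (area III)
_AREA_MIX = {
    "assisted_ventilation": {"I": 0.50, "II": 0.45, "III": 0.05},
    "head_holding": {"I": 0.40, "II": 0.50, "III": 0.10},
    "observation": {"I": 0.10, "II": 0.20, "III": 0.70},
}

#: profession split per practice (ventilation is a physician task; head
#: holding splits 5/7 pediatrician/technologist; observation is mixed)
_PROFESSION_MIX = {
    "assisted_ventilation": {"intensive_care_physician": 1.0},
    "head_holding": {"pediatrician": 5 / 12, "radiological_technologist": 7 / 12},
    "observation": {
        "intensive_care_physician": 7 / 14,
        "pediatrician": 1 / 14,
        "radiological_technologist": 6 / 14,
    },
}

#: per-practice (median mSv, geometric SD) of the true outside-glasses dose
_DOSE_MODEL = {
    "assisted_ventilation": (0.51, 1.8),
    "head_holding": (0.36, 1.7),
    "observation": (0.19, 1.9),
}

#: per-practice (median mGy.cm, geometric SD) of DLP; ventilation is
#: calibrated to the observed 1,561 median, the others are pragmatic
#: placeholders (no per-practice DLP distributions are published)
_DLP_MODEL = {
    "assisted_ventilation": (1561.0, 1.7),
    "head_holding": (360.0, 1.8),
    "observation": (863.0, 1.8),
}


def _check_mix(name: str, mix: dict) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generator configuration; defaults are the study conditions."""

    n_procedures: int = 91
    seed: int = 0
    practice_mix: dict = field(default_factory=lambda: dict(_PRACTICE_MIX))
    area_mix_by_practice: dict = field(default_factory=lambda: {k: dict(v) for k, v in _AREA_MIX.items()})
    profession_by_practice: dict = field(default_factory=lambda: {k: dict(v) for k, v in _PROFESSION_MIX.items()})
    dose_model: dict = field(default_factory=lambda: dict(_DOSE_MODEL))
    dlp_model: dict = field(default_factory=lambda: dict(_DLP_MODEL))
    glasses_transmission: float = 0.49
    tube_use_probability: float = 62 / 65
    tube_transmission: float = 0.69
    orientation_noise_gsd: float = 1.15
    side_noise_gsd: float = 1.15
    dose_dlp_coupling: float = 1.0
    k_coefficient: float = 1.650

    def __post_init__(self) -> None:
        if self.n_procedures < 1:
            raise ValueError("n_procedures must be >= 1")
        _check_mix("practice_mix", self.practice_mix)
        for practice, mix in self.area_mix_by_practice.items():
            _check_mix(f"area_mix[{practice}]", mix)
        for practice, mix in self.profession_by_practice.items():
            _check_mix(f"profession_by_practice[{practice}]", mix)
        for name, model in (("dose_model", self.dose_model), ("dlp_model", self.dlp_model)):
            for practice, (median, gsd) in model.items():
                if median <= 0 or gsd < 1:
                    raise ValueError(f"{name}[{practice}]: need median > 0 and gsd >= 1")
        for name, t in (
            ("glasses_transmission", self.glasses_transmission),
            ("tube_transmission", self.tube_transmission),
        ):
            if not 0 < t <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {t}")
        if not 0 <= self.tube_use_probability <= 1:
            raise ValueError("tube_use_probability must be in [0, 1]")
        if self.k_coefficient <= 0:
            raise ValueError("k_coefficient must be > 0")


def _choice(rng: np.random.Generator, mix: dict, size: int) -> np.ndarray:
    labels = list(mix)
    probs = np.array([mix[l] for l in labels], dtype=float)
    probs /= probs.sum()
    return rng.choice(labels, size=size, p=probs)


def _lognormal(rng: np.random.Generator, median: float, gsd: float, size: int) -> np.ndarray:
    return median * np.exp(math.log(gsd) * rng.standard_normal(size))


def _median_of_pair_max(gsd: float) -> float:
    """Median of max(X1, X2) for iid lognormal(median 1, gsd) pairs."""
    from scipy.stats import norm

    return math.exp(math.log(gsd) * norm.ppf(2.0**-0.5))


# plausible CT acquisition settings per profession (shape only; the
# nonparametric tests exercise them, no quantitative anchor exists)
_CT_SETTINGS = {
    "intensive_care_physician": {"kvp": (120, 4), "ma": (3800, 1.6), "ctdi": (45, 1.6)},
    "pediatrician": {"kvp": (103, 6), "ma": (400, 1.9), "ctdi": (21, 1.8)},
    "radiological_technologist": {"kvp": (117, 5), "ma": (1200, 1.9), "ctdi": (45, 1.7)},
}


def generate_cohort(config: SyntheticConfig | None = None) -> list[ProcedureRecord]:
    """Draw a cohort of :class:`ProcedureRecord`; deterministic given the seed.

    One root seed is split into independent substreams (assignment, DLP,
    dose residual, tube use, reading noise, CT settings) so adding a stream
    never perturbs earlier draws.
    """
    cfg = config or SyntheticConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_assign, rng_dlp, rng_dose, rng_tube, rng_noise, rng_ct = (
        np.random.default_rng(s) for s in streams
    )
    n = cfg.n_procedures

    practices = _choice(rng_assign, cfg.practice_mix, n)
    areas = np.array(
        [_choice(rng_assign, cfg.area_mix_by_practice[p], 1)[0] for p in practices]
    )
    professions = np.array(
        [_choice(rng_assign, cfg.profession_by_practice[p], 1)[0] for p in practices]
    )

    dlp = np.empty(n)
    dose = np.empty(n)
    for practice in PRACTICES:
        mask = practices == practice
        m = int(mask.sum())
        if m == 0:
            continue
        dlp_median, dlp_gsd = cfg.dlp_model[practice]
        dose_median, dose_gsd = cfg.dose_model[practice]
        dlp[mask] = _lognormal(rng_dlp, dlp_median, dlp_gsd, m)
        sigma_dose = math.log(dose_gsd)
        sigma_dlp_part = cfg.dose_dlp_coupling * math.log(dlp_gsd)
        sigma_resid = math.sqrt(max(sigma_dose**2 - sigma_dlp_part**2, 0.0))
        resid = np.exp(sigma_resid * rng_dose.standard_normal(m))
        dose[mask] = dose_median * (dlp[mask] / dlp_median) ** cfg.dose_dlp_coupling * resid

    # extension tube: drawn only for assisted ventilation; configured dose
    # medians describe the predominant with-tube condition, so the no-tube
    # minority sits higher by 1/transmission
    vent = practices == "assisted_ventilation"
    tube = np.zeros(n, dtype=bool)
    tube[vent] = rng_tube.random(int(vent.sum())) < cfg.tube_use_probability
    dose[vent & ~tube] /= cfg.tube_transmission

    # Pairwise noise is centered so the *maximum* of each pair has median 1:
    # the configured medians describe the aggregated (pair-max) quantities the
    # campaign reports, so the aggregation itself must not shift them.
    side_noise = _lognormal(rng_noise, 1.0, cfg.side_noise_gsd, (n, 2))
    side_noise /= _median_of_pair_max(cfg.side_noise_gsd)
    orient_noise = _lognormal(rng_noise, 1.0, cfg.orientation_noise_gsd, (n, 2, 2))
    orient_noise /= _median_of_pair_max(cfg.orientation_noise_gsd)

    records = []
    for i in range(n):
        prof = professions[i]
        kvp_mu, kvp_sd = _CT_SETTINGS[prof]["kvp"]
        kvp = float(np.clip(rng_ct.normal(kvp_mu, kvp_sd), 80, 140))
        ma = float(_lognormal(rng_ct, *_CT_SETTINGS[prof]["ma"], 1)[0])
        ctdi = float(_lognormal(rng_ct, *_CT_SETTINGS[prof]["ctdi"], 1)[0])
        readings = []
        for s_idx, side in enumerate(("left", "right")):
            out_kerma = dose[i] * side_noise[i, s_idx] / cfg.k_coefficient
            readings.append(
                DosimeterReading(placement="outside", side=side, orientation="none", air_kerma=out_kerma)
            )
            for o_idx, orientation in enumerate(("vertical", "horizontal")):
                readings.append(
                    DosimeterReading(
                        placement="inside",
                        side=side,
                        orientation=orientation,
                        air_kerma=out_kerma
                        * cfg.glasses_transmission
                        * orient_noise[i, s_idx, o_idx],
                    )
                )
        records.append(
            ProcedureRecord(
                procedure_id=f"P{i + 1:04d}",
                profession=prof,
                practice=practices[i],
                area=areas[i],
                tube_voltage=kvp,
                tube_current=ma,
                ctdi_vol=ctdi,
                dlp=float(dlp[i]),
                extension_tube=bool(tube[i]),
                readings=readings,
            )
        )
    return records


def _fixed_record(pid, practice, profession, area, dose_kermas, *, dlp=1000.0, tube=False):
    oL, oR, iLV, iLH, iRV, iRH = dose_kermas
    readings = [
        DosimeterReading("outside", "left", "none", oL),
        DosimeterReading("outside", "right", "none", oR),
        DosimeterReading("inside", "left", "vertical", iLV),
        DosimeterReading("inside", "left", "horizontal", iLH),
        DosimeterReading("inside", "right", "vertical", iRV),
        DosimeterReading("inside", "right", "horizontal", iRH),
    ]
    return ProcedureRecord(
        procedure_id=pid,
        profession=profession,
        practice=practice,
        area=area,
        tube_voltage=120.0,
        tube_current=3000.0,
        ctdi_vol=40.0,
        dlp=dlp,
        extension_tube=tube,
        readings=readings,
    )


def degenerate_cohort(kind: str) -> list[ProcedureRecord]:
    """Deterministic edge-case fixtures.

    Kinds: ``all_zero_doses``, ``single_procedure``, ``missing_stratum``
    (every ventilation record uses the tube), ``constant_doses``.
    """
    icp = "intensive_care_physician"
    if kind == "all_zero_doses":
        return [
            _fixed_record(f"Z{i}", "assisted_ventilation", icp, "I", [0.0] * 6, tube=(i % 2 == 0))
            for i in range(4)
        ]
    if kind == "single_procedure":
        return [_fixed_record("S1", "assisted_ventilation", icp, "I", [0.30, 0.28, 0.15, 0.14, 0.13, 0.12])]
    if kind == "missing_stratum":
        return [
            _fixed_record(
                f"M{i}", "assisted_ventilation", icp, "I",
                [0.30, 0.28, 0.15, 0.14, 0.13, 0.12], tube=True,
            )
            for i in range(5)
        ]
    if kind == "constant_doses":
        return [
            _fixed_record(
                f"C{i}", practice, icp, "I", [0.20, 0.20, 0.10, 0.10, 0.10, 0.10],
                tube=(practice == "assisted_ventilation" and i % 2 == 0),
            )
            for i, practice in enumerate(
                ["assisted_ventilation", "assisted_ventilation", "head_holding", "observation"] * 2
            )
        ]
    raise ValueError(
        f"unknown degenerate cohort kind {kind!r}; choose from "
        "all_zero_doses, single_procedure, missing_stratum, constant_doses"
    )


def generate_curtain_experiment(
    seed: int = 0,
    n: int = 5,
    mean_without: float = 0.31,
    sd_without: float = 0.04,
    transmission: float = 0.39,
    sd_with: float = 0.03,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired phantom measurements without/with the protective curtain [mSv].

    Emulates the forehead-dosimeter experiment: n repeats of the unshielded
    dose, and n repeats shielded by a curtain of the given transmission.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    without = np.clip(rng.normal(mean_without, sd_without, n), 1e-6, None)
    with_ = np.clip(rng.normal(mean_without * transmission, sd_with, n), 1e-6, None)
    return without, with_
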