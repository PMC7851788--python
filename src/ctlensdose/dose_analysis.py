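"""Result computations: ratio analyses, protection efficiencies, compliance.

Conventions adopted throughout (documented in docs/methods.md):

* percent reductions are rounded half-up to whole percent, and the raw
  fraction is kept alongside so chained calculations never compound
  rounding;
* group summaries use the *sample* SD (divisor n-1) and type-7 linear
  interpolation for quantiles; the beam-quality summary is the single
  deliberate exception (population SD, see ``beam_quality``);
* zero denominators in ratio analyses are excluded with a logged warning
  rather than propagated as infinities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .hp3_conversion import DosimeterReading, Hp3Result, procedure_hp3

__all__ = [
    "ProcedureRecord",
    "ProtectionMeasure",
    "GroupSummary",
    "ComplianceReport",
    "DrlEntry",
    "PROFESSIONS",
    "PRACTICES",
    "AREAS",
    "round_half_up",
    "group_summary",
    "paired_ratio_summary",
    "reduction_from_ratio",
    "reduction_from_pair",
    "glasses_efficiency",
    "dlp_normalize",
    "tube_efficiency",
    "combine_measures",
    "max_procedures",
    "drl_compare",
]

logger = logging.getLogger(__name__)

PROFESSIONS = ("intensive_care_physician", "pediatrician", "radiological_technologist")
PRACTICES = ("assisted_ventilation", "head_holding", "observation")
AREAS = ("I", "II", "III")


@dataclass(frozen=True)
class ProcedureRecord:
    """One CT-assist event: acquisition metadata plus six dosimeter readings."""

    procedure_id: str
    profession: str
    practice: str
    area: str
    tube_voltage: float
    tube_current: float
    ctdi_vol: float
    dlp: float
    extension_tube: bool
    readings: tuple

    def __post_init__(self) -> None:
        if self.profession not in PROFESSIONS:
            raise ValueError(f"profession must be one of {PROFESSIONS}, got {self.profession!r}")
        if self.practice not in PRACTICES:
            raise ValueError(f"practice must be one of {PRACTICES}, got {self.practice!r}")
        if self.area not in AREAS:
            raise ValueError(f"area must be one of {AREAS}, got {self.area!r}")
        if self.dlp < 0 or self.ctdi_vol < 0:
            raise ValueError("dlp and ctdi_vol must be >= 0")
        object.__setattr__(self, "readings", tuple(self.readings))
        for r in self.readings:
            if not isinstance(r, DosimeterReading):
                raise TypeError("readings must be DosimeterReading instances")

    def hp3(self, k: float) -> Hp3Result:
        return procedure_hp3(self.readings, k)


@dataclass(frozen=True)
class ProtectionMeasure:
    """A protective measure characterised by its dose-reduction fraction."""

    name: str
    reduction_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.reduction_fraction < 1:
            raise ValueError(
                f"reduction_fraction must be in [0, 1), got {self.reduction_fraction}"
            )


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    q25: float
    q75: float
    ci95: tuple

    def __post_init__(self) -> None:
        if not (self.min <= self.q25 <= self.median <= self.q75 <= self.max):
            raise ValueError("order statistics out of order")


@dataclass(frozen=True)
class ComplianceReport:
    annual_limit: float
    median_dose: float
    max_procedures: int

    def __post_init__(self) -> None:
        if self.max_procedures < 0:
            raise ValueError("max_procedures must be >= 0")


@dataclass(frozen=True)
class DrlEntry:
    """One facility-median vs diagnostic-reference-level comparison."""

    exam_label: str
    metric: str
    facility_median: float
    drl_value: float
    exceeds: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.metric not in ("CTDIvol", "DLP"):
            raise ValueError("metric must be 'CTDIvol' or 'DLP'")
        object.__setattr__(
            self, "exceeds", drl_compare(self.facility_median, self.drl_value)
        )


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (printed-rate convention)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def group_summary(values) -> GroupSummary:
    """Descriptive summary: mean, sample SD, median, range, quartiles, 95% CI.

    Quartiles use linear interpolation between order statistics (numpy's
    default, type-7).  The CI is mean +/- t(0.975, n-1) * sd / sqrt(n); for
    n = 1 the SD and CI are degenerate (0 and the point itself).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("group_summary requires at least one value")
    n = int(v.size)
    mean = float(v.mean())
    if n >= 2:
        sd = float(v.std(ddof=1))
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        sd = 0.0
        ci = (mean, mean)
    return GroupSummary(
        n=n,
        mean=mean,
        sd=sd,
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        q25=float(np.quantile(v, 0.25)),
        q75=float(np.quantile(v, 0.75)),
        ci95=ci,
    )


def paired_ratio_summary(pairs) -> tuple[GroupSummary, int]:
    """Summary of per-pair numerator/denominator ratios.

    Pairs with zero denominator are excluded with a warning; the second
    return value is the exclusion count.
    """
    ratios = []
    excluded = 0
    for num, den in pairs:
        if den == 0:
            excluded += 1
            continue
        ratios.append(num / den)
    if excluded:
        logger.warning("paired_ratio_summary: excluded %d pair(s) with zero denominator", excluded)
    if not ratios:
        raise ValueError("no valid pairs (all denominators zero or empty input)")
    return group_summary(ratios), excluded


def reduction_from_ratio(median_ratio: float) -> int:
    """Percent reduction implied by an unprotected/protected dose ratio R.

    (R - 1)/R x 100, rounded half-up; negative when R < 1.
    """
    if median_ratio <= 0:
        raise ValueError("median_ratio must be > 0")
    return round_half_up((median_ratio - 1.0) / median_ratio * 100.0)


def reduction_from_pair(without: float, with_: float) -> int:
    """Percent reduction from an unprotected/protected value pair.

    {1 - with/without} x 100, rounded half-up.
    """
    if without <= 0:
        raise ValueError("'without' value must be > 0")
    if with_ < 0:
        raise ValueError("'with' value must be >= 0")
    return round_half_up((1.0 - with_ / without) * 100.0)


def glasses_efficiency(records, k: float) -> tuple[float, int]:
    """Safety-glasses efficiency from per-procedure outside/inside ratios.

    Each record is aggregated with the standard conventions; records with
    zero inside dose are excluded with a warning.  Returns the median ratio
    and its percent reduction.
    """
    ratios = []
    excluded = 0
    for rec in records:
        res = rec.hp3(k)
        if res.hp3_inside == 0:
            excluded += 1
            continue
        ratios.append(res.hp3_outside / res.hp3_inside)
    if excluded:
        logger.warning("glasses_efficiency: excluded %d record(s) with zero inside dose", excluded)
    if not ratios:
        raise ValueError("no records with nonzero inside dose")
    med = float(np.median(ratios))
    return med, reduction_from_ratio(med)


def dlp_normalize(hp3: float, dlp: float) -> float:
    """Hp(3)/DLP in units of mSv/(mGy.cm) x 1e-4 (the reporting scale)."""
    if dlp <= 0:
        raise ValueError("dlp must be > 0")
    return hp3 / dlp * 1.0e4


def tube_efficiency(records, k: float) -> tuple[int, int]:
    """Bag-valve-mask extension-tube efficiency, outside and inside.

    Restricted to assisted-ventilation procedures; per record the aggregated
    Hp(3) is normalized to DLP, stratum medians (with/without tube) are
    compared with :func:`reduction_from_pair` per placement.
    """
    strata = {True: {"outside": [], "inside": []}, False: {"outside": [], "inside": []}}
    skipped = 0
    for rec in records:
        if rec.practice != "assisted_ventilation":
            continue
        if rec.dlp == 0:
            skipped += 1
            continue
        res = rec.hp3(k)
        strata[rec.extension_tube]["outside"].append(dlp_normalize(res.hp3_outside, rec.dlp))
        strata[rec.extension_tube]["inside"].append(dlp_normalize(res.hp3_inside, rec.dlp))
    if skipped:
        logger.warning("tube_efficiency: excluded %d record(s) with zero DLP", skipped)
    for flag, name in ((False, "without extension tube"), (True, "with extension tube")):
        if not strata[flag]["outside"]:
            raise ValueError(f"empty stratum: no assisted-ventilation records {name}")
    out = []
    for placement in ("outside", "inside"):
        without = float(np.median(strata[False][placement]))
        with_ = float(np.median(strata[True][placement]))
        out.append(reduction_from_pair(without, with_))
    return tuple(out)


def combine_measures(measures) -> int:
    """Combined percent reduction of independent measures.

    Transmissions multiply: {1 - prod(1 - r_i)} x 100, rounded half-up.
    An empty list combines to 0.
    """
    transmission = 1.0
    for m in measures:
        r = m.reduction_fraction if isinstance(m, ProtectionMeasure) else float(m)
        if not 0 <= r < 1:
            raise ValueError(f"reduction fraction must be in [0, 1), got {r}")
        transmission *= 1.0 - r
    return round_half_up((1.0 - transmission) * 100.0)


def max_procedures(annual_limit: float, median_dose: float) -> int:
    """Procedures per year before the annual limit: floor(limit / median dose)."""
    if annual_limit <= 0:
        raise ValueError("annual_limit must be > 0")
    if median_dose <= 0:
        raise ValueError("median_dose must be > 0 (zero dose is unbounded)")
    return int(math.floor(annual_limit / median_dose))


def drl_compare(facility_median: float, drl_value: float) -> bool:
    """True iff the facility median strictly exceeds the reference level."""
    if facility_median <= 0 or drl_value <= 0:
        raise ValueError("both values must be > 0")
    return facility_median > drl_value
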