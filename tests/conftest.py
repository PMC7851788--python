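import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from ctlensdose.dose_analysis import ProcedureRecord
from ctlensdose.hp3_conversion import DosimeterReading

K = 1.650


def make_readings(outside_left, outside_right, ilv, ilh, irv, irh):
    """Six readings (air kerma, mGy) in the canonical slot layout."""
    return [
        DosimeterReading("outside", "left", "none", outside_left),
        DosimeterReading("outside", "right", "none", outside_right),
        DosimeterReading("inside", "left", "vertical", ilv),
        DosimeterReading("inside", "left", "horizontal", ilh),
        DosimeterReading("inside", "right", "vertical", irv),
        DosimeterReading("inside", "right", "horizontal", irh),
    ]


def make_record(
    pid="P1",
    practice="assisted_ventilation",
    profession="intensive_care_physician",
    area="I",
    dlp=1000.0,
    extension_tube=False,
    kermas=(0.20, 0.18, 0.10, 0.08, 0.09, 0.12),
):
    return ProcedureRecord(
        procedure_id=pid,
        profession=profession,
        practice=practice,
        area=area,
        tube_voltage=120.0,
        tube_current=3000.0,
        ctdi_vol=40.0,
        dlp=dlp,
        extension_tube=extension_tube,
        readings=make_readings(*kermas),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default 91-procedure synthetic cohort, seed 0 (session-cached)."""
    from ctlensdose.synthetic_data import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_procedures=91, seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """n=5000 cohort used for convergence checks (session-cached)."""
    from ctlensdose.synthetic_data import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_procedures=5000, seed=1))
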