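"""Air kerma to Hp(3) conversion and the per-procedure aggregation rules.

Each CT-assist procedure carries six dosimeter readings: behind the safety
glasses, an L-shaped pair (one element vertical, one horizontal, to offset
the Sn-filter directional dependence) on each side; outside the glasses,
one dosimeter per side.  The conventions are: per inside side take the
higher of vertical/horizontal; per placement take the higher of left/right;
multiply by the beam-mean conversion coefficient K [Sv/Gy].
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DosimeterReading",
    "Hp3Result",
    "SchemaError",
    "to_hp3",
    "aggregate_orientation",
    "aggregate_side",
    "procedure_hp3",
]

PLACEMENTS = ("inside", "outside")
SIDES = ("left", "right")
ORIENTATIONS = ("vertical", "horizontal", "none")


class SchemaError(ValueError):
    """Raised when a procedure's readings do not form the expected six slots."""


@dataclass(frozen=True)
class DosimeterReading:
    """One dosimeter's air-kerma reading [mGy] and its mounting slot."""

    placement: str
    side: str
    orientation: str
    air_kerma: float

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")
        if self.placement == "inside" and self.orientation not in ("vertical", "horizontal"):
            raise ValueError("inside readings must be oriented vertical or horizontal")
        if self.placement == "outside" and self.orientation != "none":
            raise ValueError("outside readings carry no orientation (use 'none')")
        if not self.air_kerma >= 0:
            raise ValueError(f"air_kerma must be >= 0, got {self.air_kerma}")


@dataclass(frozen=True)
class Hp3Result:
    """Aggregated per-procedure Hp(3) [mSv] outside and inside the glasses.

    ``hp3_outside >= hp3_inside`` is *not* an invariant: observed
    outside/inside ratios in real wear go well below 1.
    """

    hp3_outside: float
    hp3_inside: float
    k_used: float

    def __post_init__(self) -> None:
        if self.hp3_outside < 0 or self.hp3_inside < 0:
            raise ValueError("doses must be >= 0")
        if self.k_used <= 0:
            raise ValueError("k_used must be > 0")


def to_hp3(air_kerma: float, k: float) -> float:
    """Hp(3) [mSv] = air kerma [mGy] x conversion coefficient K [Sv/Gy]."""
    if air_kerma < 0:
        raise ValueError(f"air_kerma must be >= 0, got {air_kerma}")
    if k <= 0:
        raise ValueError(f"conversion coefficient must be > 0, got {k}")
    return air_kerma * k


def aggregate_orientation(vertical: float, horizontal: float) -> float:
    """Higher of the vertical/horizontal pair (the adopted convention)."""
    if vertical < 0 or horizontal < 0:
        raise ValueError("doses must be >= 0")
    return max(vertical, horizontal)


def aggregate_side(left: float, right: float) -> float:
    """Higher of the left/right pair."""
    if left < 0 or right < 0:
        raise ValueError("doses must be >= 0")
    return max(left, right)


def procedure_hp3(readings, k: float) -> Hp3Result:
    """Aggregate exactly six readings into outside/inside Hp(3).

    Expects four inside readings (left/right x vertical/horizontal) and two
    outside readings (left/right); raises :class:`SchemaError` naming the
    missing or duplicated slot otherwise.  The result is invariant to the
    order of ``readings``.
    """
    expected = {("inside", s, o) for s in SIDES for o in ("vertical", "horizontal")}
    expected |= {("outside", s, "none") for s in SIDES}
    slots: dict[tuple, float] = {}
    for r in readings:
        key = (r.placement, r.side, r.orientation)
        if key in slots:
            raise SchemaError(f"duplicate reading for slot {key}")
        slots[key] = r.air_kerma
    missing = expected - slots.keys()
    extra = slots.keys() - expected
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing slots: {sorted(missing)}")
        if extra:
            parts.append(f"unexpected slots: {sorted(extra)}")
        raise SchemaError("; ".join(parts))

    inside_kerma = aggregate_side(
        *(
            aggregate_orientation(
                slots[("inside", side, "vertical")], slots[("inside", side, "horizontal")]
            )
            for side in SIDES
        )
    )
    outside_kerma = aggregate_side(
        slots[("outside", "left", "none")], slots[("outside", "right", "none")]
    )
    return Hp3Result(
        hp3_outside=to_hp3(outside_kerma, k),
        hp3_inside=to_hp3(inside_kerma, k),
        k_used=k,
    )
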