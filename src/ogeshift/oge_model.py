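"""OFFGEL strip geometry: linear pH gradient, wells, and pI -> fraction mapping.

The default layout is the 12-well, 12 cm pH 3-10 strip, so each well spans
(10 - 3)/12 = 0.583 pH units (printed as "0.6" at one decimal in the source
tables).  Wells are half-open intervals [lo, hi) with the last well closed at
the basic end, so a boundary pI belongs to the more basic well.  A pI falling
outside the gradient is clamped to the nearest edge well and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "StripLayout",
    "FractionSet",
    "WellAssignment",
    "DEFAULT_LAYOUT",
    "fraction_interval",
    "locate_pi",
    "map_pi_to_fraction",
    "parse_fraction_set",
]


@dataclass(frozen=True)
class StripLayout:
    ph_min: float = 3.0
    ph_max: float = 10.0
    n_wells: int = 12
    length_cm: float = 12.0  # metadata only

    def __post_init__(self) -> None:
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be below ph_max")
        if self.n_wells < 2:
            raise ValueError("a strip needs at least 2 wells")

    @property
    def well_width(self) -> float:
        return (self.ph_max - self.ph_min) / self.n_wells


DEFAULT_LAYOUT = StripLayout()


def fraction_interval(layout: StripLayout, well: int) -> tuple[float, float]:
    """pH interval [lo, hi) of a well; the last well is closed at ph_max."""
    if not 1 <= well <= layout.n_wells:
        raise ValueError(f"well {well} outside 1..{layout.n_wells}")
    lo = layout.ph_min + (well - 1) * layout.well_width
    return lo, lo + layout.well_width


class WellAssignment(NamedTuple):
    well: int
    clamped: bool


def locate_pi(layout: StripLayout, pi: float) -> WellAssignment:
    """Well whose pH interval contains ``pi``; out-of-range values clamp to
    the edge wells with ``clamped=True``."""
    if pi < layout.ph_min:
        return WellAssignment(1, True)
    if pi > layout.ph_max:
        return WellAssignment(layout.n_wells, True)
    well = int((pi - layout.ph_min) / layout.well_width) + 1
    return WellAssignment(min(well, layout.n_wells), False)


def map_pi_to_fraction(layout: StripLayout, pi: float) -> int:
    return locate_pi(layout, pi).well


@dataclass(frozen=True)
class FractionSet:
    """A sorted, de-duplicated set of well indices (e.g. the "3,4" entries)."""

    wells: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("empty fraction set")
        ordered = tuple(sorted(set(self.wells)))
        object.__setattr__(self, "wells", ordered)

    @classmethod
    def of(cls, *wells: int) -> "FractionSet":
        return cls(tuple(wells))

    def validate(self, layout: StripLayout) -> "FractionSet":
        for w in self.wells:
            if not 1 <= w <= layout.n_wells:
                raise ValueError(f"well {w} outside 1..{layout.n_wells}")
        return self

    @property
    def midpoint(self) -> float:
        return sum(self.wells) / len(self.wells)

    def __str__(self) -> str:
        return ",".join(str(w) for w in self.wells)

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)


def parse_fraction_set(text: str, layout: StripLayout = DEFAULT_LAYOUT) -> FractionSet:
    """Parse a comma-separated well list such as ``"3,4"`` and validate it."""
    tokens = [t.strip() for t in str(text).split(",")]
    if not any(tokens) or "" in tokens:
        raise ValueError(f"malformed fraction list {text!r}")
    try:
        wells = tuple(int(t) for t in tokens)
    except ValueError as err:
        raise ValueError(f"non-integer well in {text!r}") from err
    return FractionSet(wells).validate(layout)
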