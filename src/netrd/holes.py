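"""WHO hole-size banding and the proportionate hole index (PHI).

The WHO physical-integrity protocol for insecticide-treated nets records
every hole of diameter >= 0.5 cm and assigns it to one of four size bands
(roughly: thumb, fist, head, larger than a head).  Each band carries an
integer weight proportional to the area of a circular hole of the band's
assumed diameter, so the hole index

    H_i = alpha*N1 + beta*N2 + gamma*N3 + delta*N4

with (alpha, beta, gamma, delta) = (1, 23, 196, 576) is an area-weighted
hole count.  The weights are the squared ratios of the assumed band radii
to the size-1 radius, rounded to the nearest integer; sizes 3 and 4 are
exact perfect squares (14**2 and 24**2) while size 2 rounds from 23.04.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "HoleSizeBand",
    "BAND_TABLE",
    "HoleCensus",
    "PHIResult",
    "classify_hole",
    "band_area",
    "band_weight",
    "hole_index",
    "census_from_diameters",
    "phi_summary",
    "PRINTED_PI",
    "RECORDING_THRESHOLD_CM",
]

#: Value of pi used in the WHO reference table; reproduces the printed areas.
PRINTED_PI = 3.142

#: Holes below this diameter (cm) are not recorded in field surveys.
RECORDING_THRESHOLD_CM = 0.5


class HoleSizeBand(enum.Enum):
    """The four WHO hole-size bands."""

    size1 = 1
    size2 = 2
    size3 = 3
    size4 = 4


@dataclass(frozen=True)
class BandGeometry:
    """Assumed geometry of one WHO size band.

    ``diameter_range_cm`` is the half-open classification interval
    (lower, upper]; the size-1 lower bound is the closed recording
    threshold 0.5 cm and size 4 is unbounded above.
    """

    band: HoleSizeBand
    description: str
    diameter_range_cm: tuple[float, float]
    assumed_diameter_cm: float

    @property
    def assumed_radius_cm(self) -> float:
        return self.assumed_diameter_cm / 2.0

    def area_cm2(self, pi_value: float = PRINTED_PI) -> float:
        return pi_value * self.assumed_radius_cm**2

    @property
    def weight(self) -> int:
        # Exact radius-ratio convention: only this reproduces all four
        # published weights (1, 23, 196, 576); dividing rounded areas by
        # the rounded size-1 area 1.23 would give 575 for size 4.
        r1 = BAND_TABLE[HoleSizeBand.size1].assumed_radius_cm
        return round((self.assumed_radius_cm / r1) ** 2)


BAND_TABLE: dict[HoleSizeBand, BandGeometry] = {
    HoleSizeBand.size1: BandGeometry(
        HoleSizeBand.size1, "smaller than a thumb", (0.5, 2.0), 1.25
    ),
    HoleSizeBand.size2: BandGeometry(
        HoleSizeBand.size2, "larger than a thumb but smaller than a fist", (2.0, 10.0), 6.0
    ),
    HoleSizeBand.size3: BandGeometry(
        HoleSizeBand.size3, "larger than a fist but smaller than a head", (10.0, 25.0), 17.5
    ),
    HoleSizeBand.size4: BandGeometry(
        HoleSizeBand.size4, "larger than a head", (25.0, math.inf), 30.0
    ),
}


def classify_hole(diameter_cm: float) -> HoleSizeBand:
    """Assign a measured hole diameter (cm) to its WHO size band.

    Bands are half-open intervals (2, 10], (10, 25], (25, inf) above the
    closed size-1 band [0.5, 2], so every recordable diameter classifies
    uniquely.  Diameters below the 0.5 cm recording threshold raise
    ``ValueError``.
    """
    if not math.isfinite(diameter_cm):
        raise ValueError(f"hole diameter must be finite, got {diameter_cm}")
    if diameter_cm < RECORDING_THRESHOLD_CM:
        raise ValueError(
            f"hole diameter {diameter_cm} cm is below the WHO recording "
            f"threshold of {RECORDING_THRESHOLD_CM} cm"
        )
    if diameter_cm <= 2.0:
        return HoleSizeBand.size1
    if diameter_cm <= 10.0:
        return HoleSizeBand.size2
    if diameter_cm <= 25.0:
        return HoleSizeBand.size3
    return HoleSizeBand.size4


def band_area(band: HoleSizeBand, pi_value: float = PRINTED_PI) -> float:
    """Area (cm^2) of the band's assumed circular hole, pi_value * r^2.

    The default ``pi_value`` of 3.142 reproduces the published reference
    areas (1.23, 28.28, 240.56, 706.95 cm^2 after rounding to 2 dp);
    pass ``math.pi`` for exact areas.  The choice never affects weights.
    """
    if pi_value <= 0:
        raise ValueError("pi_value must be positive")
    return BAND_TABLE[band].area_cm2(pi_value)


def band_weight(band: HoleSizeBand) -> int:
    """Integer hole-index weight of a band: round((r_band / r_size1)**2)."""
    return BAND_TABLE[band].weight


@dataclass(frozen=True)
class HoleCensus:
    """Counts of holes per WHO size band for one net."""

    n1: int = 0
    n2: int = 0
    n3: int = 0
    n4: int = 0

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"census count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"census count {name} must be >= 0, got {v}")

    def __add__(self, other: "HoleCensus") -> "HoleCensus":
        return HoleCensus(
            self.n1 + other.n1,
            self.n2 + other.n2,
            self.n3 + other.n3,
            self.n4 + other.n4,
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n4)

    @property
    def total_holes(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4


@dataclass(frozen=True)
class PHIResult:
    """Hole index for one net (or group), with per-band contributions."""

    net_id: str
    hole_index: int
    census: HoleCensus
    contributions: dict[HoleSizeBand, int] = field(default_factory=dict)


def hole_index(census: HoleCensus, net_id: str = "") -> PHIResult:
    """Weighted hole index H_i = 1*N1 + 23*N2 + 196*N3 + 576*N4."""
    counts = dict(zip(HoleSizeBand, census.as_tuple()))
    contributions = {b: band_weight(b) * counts[b] for b in HoleSizeBand}
    return PHIResult(
        net_id=net_id,
        hole_index=sum(contributions.values()),
        census=census,
        contributions=contributions,
    )


def census_from_diameters(diameters_cm: Iterable[float]) -> HoleCensus:
    """Tabulate raw hole diameters (cm) into a band census."""
    counts = {b: 0 for b in HoleSizeBand}
    for d in diameters_cm:
        counts[classify_hole(d)] += 1
    return HoleCensus(*(counts[b] for b in HoleSizeBand))


def phi_summary(records: Sequence, group_by: str = "brand") -> pd.DataFrame:
    """Group-level mean hole index from field survey records.

    Each record must expose ``net_id``, the grouping attribute and either a
    ``HoleCensus`` or a list of raw diameters (cm) via its ``holes`` field
    (see :class:`netrd.records.FieldSurveyRecord`).  Raw diameters are
    classified with :func:`classify_hole` before indexing.  Returns a
    DataFrame indexed by group with columns ``mean_hole_index`` and
    ``n_nets``.
    """
    if len(records) == 0:
        raise ValueError("phi_summary requires at least one record")
    rows = []
    for rec in records:
        holes = rec.holes
        census = holes if isinstance(holes, HoleCensus) else census_from_diameters(holes)
        rows.append(
            {
                "group": getattr(rec, group_by),
                "net_id": rec.net_id,
                "hole_index": hole_index(census, net_id=rec.net_id).hole_index,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group")["hole_index"]
        .agg(mean_hole_index="mean", n_nets="size")
        .sort_index()
    )
    out.index.name = group_by
    return out
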