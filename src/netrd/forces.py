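"""Force/pressure conversions and human-factors reference constants.

The aspirational strength targets for net fabrics come from what a human
user can physically exert on a net: steady isometric limb forces from
EN 1005-3:2002 machinery-safety limits, explosive (dynamic burst) pulling
forces from ergonomics studies, and mean adult body weights in
malaria-endemic countries.  A force applied over a known contact area
converts to the pressure seen by a burst test:

    p [kPa] = F [N] / (A [cm^2] * 1e-4 [m^2/cm^2]) / 1000

e.g. a 308 N maximal overhand pull over the standard 7.3 cm^2 burst
diaphragm is ~422 kPa; the same pull over a 1 cm^2 bed-frame corner
exceeds 3000 kPa, which motivates the 700 kPa aspirational bursting
strength with its built-in safety factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

__all__ = [
    "ForceReference",
    "BodyWeightReference",
    "force_to_pressure",
    "pressure_to_force",
    "reference_forces",
    "body_weights",
    "ISOMETRIC_FORCES",
    "EXPLOSIVE_FORCES",
    "BODY_WEIGHTS_KG",
    "BURST_AREA_CM2",
]

#: Standard burst-test diaphragm area (cm^2).
BURST_AREA_CM2 = 7.3


@dataclass(frozen=True)
class ForceReference:
    """One tabulated human force value (or min-max range), in newtons."""

    activity: str
    population: str  # professional | domestic | male_21_60 | female_21_60
    force_min_n: float
    force_max_n: float

    def __post_init__(self) -> None:
        if self.force_min_n <= 0 or self.force_max_n < self.force_min_n:
            raise ValueError("force range must be positive and ordered")

    @property
    def force_n(self) -> float:
        """Single representative value: the maximum of the range."""
        return self.force_max_n


@dataclass(frozen=True)
class BodyWeightReference:
    """Mean adult body weight for one country (kg)."""

    country: str
    mean_weight_kg: float


def _iso(activity: str, professional: float, domestic: float) -> tuple:
    return (
        ForceReference(activity, "professional", professional, professional),
        ForceReference(activity, "domestic", domestic, domestic),
    )


# EN 1005-3:2002 maximal isometric forces (steady exertion, limbs stationary).
ISOMETRIC_FORCES: tuple[ForceReference, ...] = (
    *_iso("hand work (one hand): power grip", 250, 184),
    *_iso("arm work (sitting, one arm): upwards", 50, 31),
    *_iso("arm work (sitting, one arm): downwards", 75, 44),
    *_iso("arm work (sitting, one arm): outwards", 55, 31),
    *_iso("arm work (sitting, one arm): inwards", 75, 49),
    *_iso("arm work (sitting, one arm): pushing with trunk support", 275, 186),
    *_iso("arm work (sitting, one arm): pushing without trunk support", 62, 30),
    *_iso("arm work (sitting, one arm): pulling with trunk support", 225, 169),
    *_iso("arm work (sitting, one arm): pulling without trunk support", 55, 28),
)

# Explosive (dynamic burst) pulling forces, min-max of mean values.
EXPLOSIVE_FORCES: tuple[ForceReference, ...] = (
    ForceReference("underhand pulling", "male_21_60", 145, 185),
    ForceReference("underhand pulling", "female_21_60", 85, 123),
    ForceReference("overhand pulling", "male_21_60", 99, 308),
    ForceReference("overhand pulling", "female_21_60", 78, 260),
)

#: Mean adult body weight (kg) in malaria-endemic countries, plus the world mean.
BODY_WEIGHTS_KG = MappingProxyType(
    {
        "India": 52.9,
        "Ethiopia": 53.1,
        "Congo": 53.5,
        "Cambodia": 55.7,
        "Mozambique": 56.0,
        "Kenya": 56.3,
        "Uganda": 57.0,
        "Benin": 60.3,
        "Nigeria": 60.7,
        "All of World": 62.0,
    }
)


def force_to_pressure(force_n: float, contact_area_cm2: float) -> float:
    """Pressure (kPa) of a force (N) spread uniformly over an area (cm^2).

    Full precision is returned; round to the nearest integer for reporting.
    """
    if force_n <= 0:
        raise ValueError(f"force must be positive, got {force_n} N")
    if contact_area_cm2 <= 0:
        raise ValueError(f"contact area must be positive, got {contact_area_cm2} cm^2")
    return force_n / (contact_area_cm2 * 1e-4) / 1000.0


def pressure_to_force(pressure_kpa: float, contact_area_cm2: float) -> float:
    """Force (N) equivalent to a pressure (kPa) over an area (cm^2); exact
    inverse of :func:`force_to_pressure`."""
    if pressure_kpa <= 0:
        raise ValueError(f"pressure must be positive, got {pressure_kpa} kPa")
    if contact_area_cm2 <= 0:
        raise ValueError(f"contact area must be positive, got {contact_area_cm2} cm^2")
    return pressure_kpa * 1000.0 * contact_area_cm2 * 1e-4


def reference_forces(
    activity: str | None = None, population: str | None = None
) -> tuple[ForceReference, ...]:
    """Filtered view of the packaged force tables.

    ``activity`` matches case-insensitively as a substring; ``population``
    matches exactly.  With no filters, the full isometric + explosive
    tables are returned.
    """
    rows = ISOMETRIC_FORCES + EXPLOSIVE_FORCES
    if activity is not None:
        needle = activity.lower()
        rows = tuple(r for r in rows if needle in r.activity.lower())
    if population is not None:
        rows = tuple(r for r in rows if r.population == population)
    return rows


def body_weights(country: str | None = None) -> tuple[BodyWeightReference, ...]:
    """Packaged mean adult body weights, optionally filtered by country."""
    items = BODY_WEIGHTS_KG.items()
    if country is not None:
        items = [(c, w) for c, w in items if c.lower() == country.lower()]
    return tuple(BodyWeightReference(c, w) for c, w in items)
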