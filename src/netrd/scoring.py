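"""Resistance-to-damage (RD) scoring for insecticidal nets.

Two algorithms condense four laboratory textile tests — bursting strength
(kPa), snag strength (N), abrasion resistance (rubs endured) and hole
enlargement — into a single 0-100 resistance-to-damage score.

Method 1 (proximity to aspirational values) scores each strength parameter
as its fraction of an aspirational target, each contributing a quarter of
the scale::

    RD = (lambda_B/eta_B)*25 + (lambda_S/eta_S)*25 + (lambda_A/eta_A)*25 + sigma_H/4

where sigma_H is a 0-100 hole-enlargement score from a lookup of final
hole size band x secondary-damage type.  Values above the aspirational
targets score above 100 by design: the scale rewards over-engineering.

Method 2 (KPI score matrix) bins each strength value into tiers worth up
to 25 points, and adds a hole-enlargement score (max 25) net of a
secondary-damage penalty::

    RD = sigma_B + sigma_S + sigma_A + (sigma_H - rho_H),
    rho_H = penalty(damage) * sigma_H / 100

Method 2 is capped at 100 by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .records import (
    HoleEnlargementOutcome,
    SecondaryDamage,
    TextileTestResult,
)

__all__ = [
    "AspirationalValues",
    "HoleEnlargementScoreTable",
    "ScoreMatrix",
    "RDResult",
    "size_band_mm",
    "hole_enlargement_score_m1",
    "rd_method1",
    "bin_score",
    "penalty_score",
    "rd_method2",
    "score_panel",
    "load_config",
]

Method = Literal["method1", "method2"]

#: Hole-size bands (mm) shared by both methods: the 5 mm top band matches
#: the WHO recording threshold, so an enlargement kept under 5 mm is ideal.
_BAND_SMALL = "le_5mm"
_BAND_MEDIUM = "6_20mm"
_BAND_LARGE = "ge_21mm"


def size_band_mm(end_hole_size_mm: float) -> str:
    """Band a final hole size: <=5 mm, (5, 20] mm, >20 mm."""
    if end_hole_size_mm <= 5.0:
        return _BAND_SMALL
    if end_hole_size_mm <= 20.0:
        return _BAND_MEDIUM
    return _BAND_LARGE


@dataclass(frozen=True)
class AspirationalValues:
    """Method-1 aspirational targets (eta) derived from human exertable forces.

    Defaults: 700 kPa bursting (upper bound of explosive-pull pressure over
    plausible contact areas), 200 N snag (above what most users can exert),
    400 abrasion rubs, and a perfect hole-enlargement score of 100.
    """

    bursting_kpa: float = 700.0
    snag_n: float = 200.0
    abrasion_rubs: float = 400.0
    hole_score_max: float = 100.0

    def __post_init__(self) -> None:
        for name in ("bursting_kpa", "snag_n", "abrasion_rubs", "hole_score_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"aspirational {name} must be strictly positive")

    @classmethod
    def from_dict(cls, data: dict) -> "AspirationalValues":
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class HoleEnlargementScoreTable:
    """Method-1 hole-enlargement scores: base score per size band times a
    damage multiplier.  The products reproduce the full published 4x3 grid
    (e.g. laddering with a 6-20 mm final hole: 80 * 0.8 = 64).
    """

    base_scores: dict = field(
        default_factory=lambda: {_BAND_SMALL: 100.0, _BAND_MEDIUM: 80.0, _BAND_LARGE: 40.0}
    )
    damage_multipliers: dict = field(
        default_factory=lambda: {
            SecondaryDamage.NONE: 1.0,
            SecondaryDamage.LADDERING: 0.8,
            SecondaryDamage.UNRAVELLING: 0.5,
            SecondaryDamage.TEARING_COMBINED: 0.4,
        }
    )

    def score(self, outcome: HoleEnlargementOutcome) -> float:
        band = size_band_mm(outcome.end_hole_size_mm)
        return self.base_scores[band] * self.damage_multipliers[outcome.secondary_damage]


def hole_enlargement_score_m1(
    outcome: HoleEnlargementOutcome,
    table: HoleEnlargementScoreTable | None = None,
) -> float:
    """Method-1 hole-enlargement score sigma_H in (0, 100]."""
    return (table or HoleEnlargementScoreTable()).score(outcome)


# Default Method-2 tier edges.  Strength tiers are contiguous half-open
# intervals [edge, next edge); printed integer ranges like 250-299 extend
# naturally to real-valued inputs.  The abrasion row is published with gaps
# (e.g. 50-75); a value in a gap takes the score of the tier below it
# (greatest lower bound), the only gap-free monotone reading.
_DEFAULT_EDGES = {
    "bursting": (
        [250.0, 300.0, 350.0, 400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0],
        [1.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0],
    ),
    "snag": (
        [20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0, 180.0, 200.0],
        [1.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0],
    ),
    "abrasion": (
        [25.0, 75.0, 125.0, 175.0, 250.0, 300.0, 350.0, 400.0],
        [1.0, 3.0, 6.0, 9.0, 13.0, 16.0, 19.0, 22.0, 25.0],
    ),
}


@dataclass(frozen=True)
class ScoreMatrix:
    """Method-2 KPI score matrix.

    For each strength parameter, ``edges[p]`` lists the ascending lower
    edges of the named tiers and ``scores[p]`` the tier scores, with one
    extra leading score for values below the first edge.  Hole-enlargement
    scores and secondary-damage penalties complete the matrix.
    """

    edges: dict = field(
        default_factory=lambda: {p: list(v[0]) for p, v in _DEFAULT_EDGES.items()}
    )
    scores: dict = field(
        default_factory=lambda: {p: list(v[1]) for p, v in _DEFAULT_EDGES.items()}
    )
    hole_scores: dict = field(
        default_factory=lambda: {_BAND_SMALL: 25.0, _BAND_MEDIUM: 20.0, _BAND_LARGE: 10.0}
    )
    damage_penalties: dict = field(
        default_factory=lambda: {
            SecondaryDamage.NONE: 0.0,
            SecondaryDamage.LADDERING: 10.0,
            SecondaryDamage.UNRAVELLING: 20.0,
            SecondaryDamage.TEARING_COMBINED: 30.0,
        }
    )

    def __post_init__(self) -> None:
        for p, e in self.edges.items():
            if sorted(e) != list(e) or len(set(e)) != len(e):
                raise ValueError(f"{p}: tier edges must be strictly increasing")
            s = self.scores[p]
            if len(s) != len(e) + 1:
                raise ValueError(
                    f"{p}: need one more score than edges ({len(e)} edges, {len(s)} scores)"
                )
            if sorted(s) != list(s):
                raise ValueError(f"{p}: tier scores must increase with the edges")

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreMatrix":
        kwargs = {}
        if "edges" in data:
            kwargs["edges"] = {p: [float(x) for x in v] for p, v in data["edges"].items()}
        if "scores" in data:
            kwargs["scores"] = {p: [float(x) for x in v] for p, v in data["scores"].items()}
        if "hole_scores" in data:
            kwargs["hole_scores"] = {k: float(v) for k, v in data["hole_scores"].items()}
        if "damage_penalties" in data:
            kwargs["damage_penalties"] = {
                SecondaryDamage.parse(k): float(v)
                for k, v in data["damage_penalties"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class RDResult:
    """Per-parameter contributions and total RD for one net under one method."""

    net_id: str
    method: Method
    contributions: dict
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.contributions.values())) > 1e-9:
            raise ValueError("total must equal the sum of contributions")


def bin_score(value: float, parameter: str, matrix: ScoreMatrix | None = None) -> float:
    """Score a strength value by its Method-2 tier (greatest lower bound).

    Values below the first named tier take the minimum score.
    """
    matrix = matrix or ScoreMatrix()
    if parameter not in matrix.edges:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of {sorted(matrix.edges)}"
        )
    if value < 0:
        raise ValueError(f"{parameter} value must be >= 0, got {value}")
    edges = matrix.edges[parameter]
    idx = 0
    for e in edges:
        if value >= e:
            idx += 1
        else:
            break
    return matrix.scores[parameter][idx]


def penalty_score(
    outcome: HoleEnlargementOutcome, matrix: ScoreMatrix | None = None
) -> tuple[float, float]:
    """Method-2 hole term: (sigma_H, rho_H) with rho_H = penalty * sigma_H / 100."""
    matrix = matrix or ScoreMatrix()
    sigma_h = matrix.hole_scores[size_band_mm(outcome.end_hole_size_mm)]
    penalty = matrix.damage_penalties[outcome.secondary_damage]
    return sigma_h, penalty * sigma_h / 100.0


def rd_method1(
    record: TextileTestResult,
    aspirational: AspirationalValues | None = None,
    table: HoleEnlargementScoreTable | None = None,
) -> RDResult:
    """Score one net by proximity to aspirational values (can exceed 100)."""
    asp = aspirational or AspirationalValues()
    sigma_h = hole_enlargement_score_m1(record.hole_enlargement, table)
    contributions = {
        "bursting": record.bursting_strength_kpa / asp.bursting_kpa * 25.0,
        "snag": record.snag_strength_n / asp.snag_n * 25.0,
        "abrasion": record.abrasion_rubs / asp.abrasion_rubs * 25.0,
        "hole_enlargement": sigma_h / 4.0,
    }
    return RDResult(
        net_id=record.net_id,
        method="method1",
        contributions=contributions,
        total=sum(contributions.values()),
    )


def rd_method2(
    record: TextileTestResult, matrix: ScoreMatrix | None = None
) -> RDResult:
    """Score one net through the KPI score matrix (maximum total 100)."""
    matrix = matrix or ScoreMatrix()
    sigma_h, rho_h = penalty_score(record.hole_enlargement, matrix)
    contributions = {
        "bursting": bin_score(record.bursting_strength_kpa, "bursting", matrix),
        "snag": bin_score(record.snag_strength_n, "snag", matrix),
        "abrasion": bin_score(float(record.abrasion_rubs), "abrasion", matrix),
        "hole_enlargement": sigma_h - rho_h,
    }
    return RDResult(
        net_id=record.net_id,
        method="method2",
        contributions=contributions,
        total=sum(contributions.values()),
    )


def score_panel(
    panel: Sequence[TextileTestResult],
    method: Method = "method1",
    aspirational: AspirationalValues | None = None,
    matrix: ScoreMatrix | None = None,
    table: HoleEnlargementScoreTable | None = None,
) -> list[RDResult]:
    """Score a panel of nets under one method, preserving input order."""
    if len(panel) == 0:
        raise ValueError("score_panel requires a non-empty panel")
    if method == "method1":
        return [rd_method1(r, aspirational, table) for r in panel]
    if method == "method2":
        return [rd_method2(r, matrix) for r in panel]
    raise ValueError(f"unknown method {method!r}; expected 'method1' or 'method2'")


def load_config(path: str | Path) -> dict:
    """Load a JSON config with optional ``aspirational`` and ``score_matrix``
    sections, returning {'aspirational': AspirationalValues, 'matrix': ScoreMatrix}."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    if "aspirational" in data:
        out["aspirational"] = AspirationalValues.from_dict(data["aspirational"])
    if "score_matrix" in data:
        out["matrix"] = ScoreMatrix.from_dict(data["score_matrix"])
    return out
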