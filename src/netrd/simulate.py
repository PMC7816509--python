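"""Synthetic lab panels and linked field hole data with known ground truth.

No public dataset pairs per-net textile-test values with field hole
censuses, so pipeline testing relies on simulation.  The generator
emulates a procurement-style panel of 10-20 net products whose bursting,
snag and abrasion values span the score-matrix tiers, plus a hole-
enlargement outcome drawn over size-band x damage-type cells.  Matching
field data follow a decreasing linear link: the expected hole index of a
net falls with its lab RD score,

    E[H_i] = max(0, intercept + slope * RD_method1),    slope <= 0,

with additive Gaussian noise.  Each target index is realized as a WHO
band census by greedy decomposition (largest weight first, remainder as
size-1 holes), so the census reproduces the integer target exactly and
small holes dominate the count — as they do in retrieved field nets.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config; runs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .holes import HoleCensus
from .records import (
    FieldSurveyRecord,
    HoleEnlargementOutcome,
    SecondaryDamage,
    TextileTestResult,
)
from .scoring import AspirationalValues, score_panel

__all__ = [
    "SyntheticConfig",
    "generate_lab_panel",
    "generate_field_phi",
    "census_from_target",
    "noise_sd_for_r2",
    "make_fixture_suite",
]

_BAND_RANGES_MM = {"le_5mm": (0.5, 5.0), "6_20mm": (6.0, 20.0), "ge_21mm": (21.0, 40.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Strength distributions default to uniform over ranges spanning the
    full score matrix (bursting 100-900 kPa, snag 10-250 N, abrasion
    10-450 rubs) so that a panel exercises every tier.  ``phi_intercept``
    and ``phi_slope`` define the decreasing expected-PHI link (defaults
    900 and -8: a net at RD 50 expects an index of 500, a hypothetical
    RD-100 net close to 100); ``noise_sd`` is the index noise scale.
    """

    n_nets: int = 16
    seed: int = 0
    distribution: str = "uniform"  # or "normal" (clipped to the range)
    bursting_range_kpa: tuple[float, float] = (100.0, 900.0)
    snag_range_n: tuple[float, float] = (10.0, 250.0)
    abrasion_range_rubs: tuple[int, int] = (10, 450)
    band_probs: dict = field(
        default_factory=lambda: {"le_5mm": 0.35, "6_20mm": 0.40, "ge_21mm": 0.25}
    )
    damage_probs: dict = field(
        default_factory=lambda: {
            SecondaryDamage.NONE: 0.35,
            SecondaryDamage.LADDERING: 0.30,
            SecondaryDamage.UNRAVELLING: 0.20,
            SecondaryDamage.TEARING_COMBINED: 0.15,
        }
    )
    phi_intercept: float = 900.0
    phi_slope: float = -8.0
    noise_sd: float = 60.0
    months_range: tuple[int, int] = (12, 36)

    def __post_init__(self) -> None:
        if self.n_nets < 1:
            raise ValueError("n_nets must be >= 1")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for name, (lo, hi) in (
            ("bursting_range_kpa", self.bursting_range_kpa),
            ("snag_range_n", self.snag_range_n),
            ("abrasion_range_rubs", self.abrasion_range_rubs),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        for probs, keys in (
            (self.band_probs, set(_BAND_RANGES_MM)),
            (self.damage_probs, set(SecondaryDamage)),
        ):
            if set(probs) != keys:
                raise ValueError(f"probability table keys {set(probs)} != expected {keys}")
            p = np.array(list(probs.values()), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("probabilities must be non-negative and sum to 1")
        if self.phi_slope > 0:
            raise ValueError("phi_slope must be <= 0 (higher RD, lower expected PHI)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_in_range(rng: np.random.Generator, lo: float, hi: float, dist: str) -> float:
    if lo == hi:
        return lo
    if dist == "uniform":
        return float(rng.uniform(lo, hi))
    mu, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    return float(np.clip(rng.normal(mu, sd), lo, hi))


def generate_lab_panel(config: SyntheticConfig | None = None) -> list[TextileTestResult]:
    """Draw a reproducible panel of synthetic textile-test records."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    bands = list(config.band_probs)
    band_p = [config.band_probs[b] for b in bands]
    damages = list(config.damage_probs)
    damage_p = [config.damage_probs[d] for d in damages]
    panel = []
    for i in range(config.n_nets):
        band = bands[rng.choice(len(bands), p=band_p)]
        lo_mm, hi_mm = _BAND_RANGES_MM[band]
        lo_a, hi_a = config.abrasion_range_rubs
        panel.append(
            TextileTestResult(
                net_id=f"net{i + 1:03d}",
                brand=f"brand{i % max(1, config.n_nets // 2) + 1}",
                bursting_strength_kpa=_draw_in_range(
                    rng, *config.bursting_range_kpa, config.distribution
                ),
                snag_strength_n=_draw_in_range(rng, *config.snag_range_n, config.distribution),
                abrasion_rubs=int(
                    round(_draw_in_range(rng, lo_a, hi_a, config.distribution))
                ),
                hole_enlargement=HoleEnlargementOutcome(
                    end_hole_size_mm=float(rng.uniform(lo_mm, hi_mm)),
                    secondary_damage=damages[rng.choice(len(damages), p=damage_p)],
                ),
            )
        )
    return panel


def census_from_target(target: float) -> HoleCensus:
    """Realize a target hole index as a band census, greedily largest-first.

    The rounded integer target is decomposed exactly (the size-1 weight is
    1), so ``hole_index(census) == round(target)`` and the census is
    within one weight unit of any real-valued target.
    """
    h = max(0, int(round(target)))
    n4, h = divmod(h, 576)
    n3, h = divmod(h, 196)
    n2, n1 = divmod(h, 23)
    return HoleCensus(n1=n1, n2=n2, n3=n3, n4=n4)


def noise_sd_for_r2(rd_values, slope: float, r_squared: float) -> float:
    """Noise scale giving a target generating r^2 for a linear link.

    With signal sd |slope| * sd(RD), the population r^2 of the noisy link
    is signal_var / (signal_var + noise_var); invert for the noise sd.
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    signal_sd = abs(slope) * float(np.std(np.asarray(rd_values, dtype=float)))
    return signal_sd * np.sqrt((1.0 - r_squared) / r_squared)


def generate_field_phi(
    panel: list[TextileTestResult],
    config: SyntheticConfig | None = None,
    aspirational: AspirationalValues | None = None,
) -> list[FieldSurveyRecord]:
    """Generate field survey records linked to a lab panel's RD scores.

    Each net's expected hole index is ``intercept + slope * RD`` (Method 1),
    plus Gaussian noise, clipped at zero and realized as a band census.
    Seeded from ``config.seed + 1`` so the lab and field draws are
    independent but jointly reproducible.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed + 1)
    rd = [r.total for r in score_panel(panel, "method1", aspirational=aspirational)]
    records = []
    lo_m, hi_m = config.months_range
    for rec, rd_i in zip(panel, rd):
        target = config.phi_intercept + config.phi_slope * rd_i
        if config.noise_sd > 0:
            target += rng.normal(0.0, config.noise_sd)
        records.append(
            FieldSurveyRecord(
                net_id=rec.net_id,
                brand=rec.brand,
                months_in_use=float(rng.integers(lo_m, hi_m + 1)),
                holes=census_from_target(max(0.0, target)),
            )
        )
    return records


_FIXTURE_LAB = """\
net_id,brand,bursting_kpa,snag_n,abrasion_rubs,end_hole_mm,secondary_damage
netA,brandX,350,100,200,10,laddering
netB,brandY,700,200,400,3,none
netC,brandZ,250,59,410,25,tearing_combined
"""

_FIXTURE_FIELD = """\
net_id,brand,months_in_use,n1,n2,n3,n4
netA,brandX,24,2,1,0,0
netB,brandY,36,0,0,0,0
netC,brandZ,12,0,0,1,1
"""

_FIXTURE_CONFIG = """\
{
  "aspirational": {
    "bursting_kpa": 700,
    "snag_n": 200,
    "abrasion_rubs": 400,
    "hole_score_max": 100
  }
}
"""


def make_fixture_suite(output_dir: str | Path) -> list[Path]:
    """Write the small canonical CSV/JSON fixtures used by tests and docs.

    Deterministic and byte-identical across runs.  Returns written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "lab_panel.csv": _FIXTURE_LAB,
        "field_census.csv": _FIXTURE_FIELD,
        "config.json": _FIXTURE_CONFIG,
    }
    paths = []
    for name, content in files.items():
        p = out / name
        p.write_text(content, encoding="utf-8")
        paths.append(p)
    return paths
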