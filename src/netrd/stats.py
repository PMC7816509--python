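"""Association statistics: lab RD vs field PHI, and between-method agreement.

Lab-measured resistance to damage should predict field hole damage: nets
with higher RD accumulate fewer/smaller holes, so the expected association
between RD and the proportionate hole index is negative.  Association is
quantified by the squared Pearson correlation (r^2) on raw (RD, PHI)
pairs with a two-sided t test on n-2 degrees of freedom, plus the
ordinary-least-squares line of PHI on RD.  Agreement between the two RD
scoring methods is additionally summarized by the Spearman rank
correlation, since procurement decisions depend on product ranking.

Non-mechanical field damage (cuts, seam failure, rodents, burns) must be
excluded by the caller before association; this module never filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .records import TextileTestResult
from .scoring import AspirationalValues, ScoreMatrix, score_panel

__all__ = ["AssociationResult", "MethodAgreement", "pearson_association", "method_agreement"]


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association and least-squares line between two paired series."""

    n: int
    r_squared: float
    p_value: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class MethodAgreement:
    """Agreement between Method-1 and Method-2 RD scores on one panel."""

    association: AssociationResult
    spearman_rho: float
    spearman_p: float
    pairs: tuple  # (net_id, rd_method1, rd_method2) per net


def _validate_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError(f"association requires n >= 3 pairs, got n={x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input series")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")


def pearson_association(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Squared Pearson correlation, two-sided p, and OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y)
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return AssociationResult(
        n=int(x.size),
        r_squared=float(r**2),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def method_agreement(
    panel: Sequence[TextileTestResult],
    aspirational: AspirationalValues | None = None,
    matrix: ScoreMatrix | None = None,
) -> MethodAgreement:
    """Score a panel under both RD methods and quantify their agreement."""
    if len(panel) < 3:
        raise ValueError(f"method agreement requires >= 3 nets, got {len(panel)}")
    m1 = score_panel(panel, "method1", aspirational=aspirational)
    m2 = score_panel(panel, "method2", matrix=matrix)
    x = np.array([r.total for r in m1])
    y = np.array([r.total for r in m2])
    assoc = pearson_association(x, y)
    rho, rho_p = sps.spearmanr(x, y)
    pairs = tuple((rec.net_id, float(a), float(b)) for rec, a, b in zip(panel, x, y))
    return MethodAgreement(
        association=assoc,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        pairs=pairs,
    )
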