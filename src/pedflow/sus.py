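"""System Usability Scale scoring, interpretation bands, and correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["SUSResponse", "sus_score", "sus_band", "rank_correlation", "BANDS"]

BANDS = ("very poor", "poor", "average", "good", "excellent")


class SUSError(ValueError):
    pass


@dataclass(frozen=True)
class SUSResponse:
    respondent_id: str
    item_scores: tuple
    age_years: Optional[float] = None
    seniority_months: Optional[float] = None
    occupation: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.item_scores) != 10:
            raise SUSError(f"{self.respondent_id}: expected 10 items, got {len(self.item_scores)}")
        for i, s in enumerate(self.item_scores, start=1):
            if int(s) != s or not 1 <= s <= 5:
                raise SUSError(f"{self.respondent_id}: item {i} must be an integer in 1..5, got {s}")
        if self.age_years is not None and self.age_years <= 0:
            raise SUSError(f"{self.respondent_id}: nonpositive age")
        if self.seniority_months is not None and self.seniority_months < 0:
            raise SUSError(f"{self.respondent_id}: negative seniority")


def sus_score(response: SUSResponse) -> float:
    """Standard scoring: odd items add (s - 1), even items (5 - s), total x 2.5."""
    total = 0
    for i, s in enumerate(response.item_scores, start=1):
        total += (s - 1) if i % 2 == 1 else (5 - s)
    return total * 2.5


def sus_band(score: float) -> str:
    """Interpretation band; the usual published cut-offs, with 68 = average."""
    if not 0 <= score <= 100:
        raise SUSError(f"score must be in [0, 100], got {score}")
    if score < 51:
        return "very poor"
    if score < 68:
        return "poor"
    if score == 68:
        return "average"
    if score <= 80.3:
        return "good"
    return "excellent"


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho (average ranks for ties) and its large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SUSError("x and y must be paired")
    if x.size < 3:
        raise SUSError("need at least 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
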