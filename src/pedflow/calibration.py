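"""Turn printed summary quantities into samplable distributions and tables.

Stage durations are modelled as (optionally zero-inflated) log-normals
quantile-matched to published median/IQR triples.  Length-of-stay reference
percentiles (P50/P75/P95 per admission reason) drive the status-color logic
in :mod:`pedflow.policy`.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "StageIntervalSpec",
    "LognormalParams",
    "CaseMix",
    "LOSReferenceTable",
    "fit_lognormal_from_quantiles",
    "fit_zero_inflated",
    "fit_stage",
    "fit_latency_model",
    "build_los_reference",
    "default_case_mix",
    "default_stage_specs",
    "load_calibration",
    "REASONS",
    "PRIORITIES",
    "DISPOSITIONS",
    "STAGES",
]

#: 75th-percentile deviate of the standard normal; the IQR-ratio fit hinges on it.
_Z75 = float(stats.norm.ppf(0.75))

REASONS = ("fever", "respiratory", "digestive", "trauma", "other")
PRIORITIES = ("high", "moderate", "low")
DISPOSITIONS = ("home", "short_stay", "ward", "lwbs", "picu")

STAGES = (
    "admission_to_triage",
    "triage_to_first_eval",
    "first_eval_to_junior_eval",
    "admission_to_senior_eval",
    "blood_presc_to_draw",
    "blood_draw_to_result",
    "imaging_presc_to_result",
    "specialist_presc_to_eval",
    "treatment_presc_to_admin",
    "final_senior_to_end_of_care",
    "end_of_care_to_discharge",
)


class CalibrationError(ValueError):
    """Raised when printed quantities violate their structural invariants."""


@dataclass(frozen=True)
class StageIntervalSpec:
    """Median/IQR summary of one care-stage interval, in minutes."""

    stage: str
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise CalibrationError(
                f"{self.stage}: quantiles must satisfy q1 <= median <= q3, "
                f"got ({self.q1}, {self.median}, {self.q3})"
            )
        if self.q3 < 0 or self.q1 < 0 or self.median < 0:
            raise CalibrationError(f"{self.stage}: negative quantile")
        if self.median > 0 and self.q1 <= 0:
            # positive median with a zero lower quartile is legal only for the
            # zero-inflated fit; a negative q1 never is
            if self.q1 < 0:
                raise CalibrationError(f"{self.stage}: negative q1")

    @property
    def zero_inflated(self) -> bool:
        return self.median == 0 or self.q1 == 0


@dataclass(frozen=True)
class LognormalParams:
    """A zero-inflated log-normal: P(X = 0) = zero_mass, else exp(mu + sigma·Z)."""

    mu: float
    sigma: float
    zero_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise CalibrationError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.zero_mass <= 1.0:
            raise CalibrationError(f"zero_mass must be in [0, 1], got {self.zero_mass}")

    def quantile(self, p: float | np.ndarray) -> np.ndarray:
        """Monotone quantile function of the mixture."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        if self.zero_mass >= 1.0:
            return np.zeros_like(p)
        inner = np.clip((p - self.zero_mass) / (1.0 - self.zero_mass), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            cont = np.exp(self.mu + self.sigma * stats.norm.ppf(inner))
        return np.where(p <= self.zero_mass, 0.0, cont)

    def cdf(self, x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.zero_mass >= 1.0:
            return np.where(x >= 0, 1.0, 0.0)
        if self.sigma == 0:
            cont = (x >= np.exp(self.mu)).astype(float)
        else:
            with np.errstate(divide="ignore"):
                cont = np.where(
                    x > 0, stats.norm.cdf((np.log(np.maximum(x, 1e-300)) - self.mu) / self.sigma), 0.0
                )
        return self.zero_mass + (1.0 - self.zero_mass) * cont

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Seeded draws; exact zeros occur with probability ``zero_mass``."""
        n = 1 if size is None else int(size)
        draws = np.exp(self.mu + self.sigma * rng.standard_normal(n))
        if self.zero_mass > 0.0:
            draws = np.where(rng.random(n) < self.zero_mass, 0.0, draws)
        if size is None:
            return float(draws[0])
        return draws

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    @property
    def mean(self) -> float:
        if self.zero_mass >= 1.0:
            return 0.0
        return (1.0 - self.zero_mass) * float(np.exp(self.mu + 0.5 * self.sigma**2))


def _as_dist(probs: Mapping, keys: Sequence) -> dict:
    """Validate, order and renormalize a printed percentage distribution."""
    missing = [k for k in keys if k not in probs]
    if missing:
        raise CalibrationError(f"missing categories: {missing}")
    vals = np.array([float(probs[k]) for k in keys])
    if np.any(vals < 0):
        raise CalibrationError("negative probability")
    total = vals.sum()
    if total <= 0:
        raise CalibrationError("distribution sums to zero")
    vals = vals / total
    return dict(zip(keys, vals.tolist()))


@dataclass(frozen=True)
class CaseMix:
    """Marginal patient-attribute distributions (renormalized at construction)."""

    reason_probs: dict
    priority_probs: dict
    blood_test_count_probs: dict
    imaging_count_probs: dict
    specialist_count_probs: dict
    treatment_line_probs: dict
    senior_eval_count_probs: dict
    disposition_probs: dict

    @classmethod
    def from_percentages(cls, raw: Mapping) -> "CaseMix":
        return cls(
            reason_probs=_as_dist(raw["reason"], REASONS),
            priority_probs=_as_dist(raw["priority"], PRIORITIES),
            blood_test_count_probs=_as_dist(raw["blood_tests"], sorted(raw["blood_tests"])),
            imaging_count_probs=_as_dist(raw["imaging"], sorted(raw["imaging"])),
            specialist_count_probs=_as_dist(raw["specialist"], sorted(raw["specialist"])),
            treatment_line_probs=_as_dist(raw["treatment_lines"], sorted(raw["treatment_lines"])),
            senior_eval_count_probs=_as_dist(raw["senior_evals"], sorted(raw["senior_evals"])),
            disposition_probs=_as_dist(raw["disposition"], DISPOSITIONS),
        )

    def distributions(self) -> dict:
        return {
            "reason": self.reason_probs,
            "priority": self.priority_probs,
            "blood_tests": self.blood_test_count_probs,
            "imaging": self.imaging_count_probs,
            "specialist": self.specialist_count_probs,
            "treatment_lines": self.treatment_line_probs,
            "senior_evals": self.senior_eval_count_probs,
            "disposition": self.disposition_probs,
        }


@dataclass(frozen=True)
class LOSReferenceTable:
    """Reason-specific LOS percentiles the status colors are judged against."""

    table: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for key, (p50, p75, p95) in self.table.items():
            if not (0 <= p50 <= p75 <= p95):
                raise CalibrationError(
                    f"reference percentiles for {key!r} must satisfy "
                    f"0 <= p50 <= p75 <= p95, got ({p50}, {p75}, {p95})"
                )

    def percentiles(self, reason: str) -> tuple[float, float, float]:
        try:
            return self.table[reason]
        except KeyError:
            raise KeyError(f"no reference percentiles for reason {reason!r}") from None


def fit_lognormal_from_quantiles(median: float, q1: float, q3: float) -> LognormalParams:
    """Quantile-match a log-normal to a printed ``median [q1-q3]`` triple.

    ``mu = ln(median)`` anchors the analytic median exactly; ``sigma`` comes
    from the IQR ratio, ``ln(q3/q1) / (2 z_0.75)``.  Any asymmetry of the
    printed IQR around the median on the log scale is absorbed by the
    mu-anchoring.
    """
    if not (0 < q1 <= median <= q3):
        raise CalibrationError(
            f"need 0 < q1 <= median <= q3, got ({q1}, {median}, {q3})"
        )
    mu = float(np.log(median))
    sigma = float(np.log(q3 / q1) / (2.0 * _Z75))
    return LognormalParams(mu=mu, sigma=sigma, zero_mass=0.0)


#: Log-scale spread of the continuous part when only one positive quantile is
#: printed (zero-median rows pin nothing but the mixture p75).
_DEFAULT_ZI_SIGMA = 1.0


def fit_zero_inflated(median: float, q1: float, q3: float) -> LognormalParams:
    """Fit a point-mass-at-zero + log-normal mixture to quantiles touching zero.

    * ``median == 0``: at least half the mass sits at zero (durations are
      nonnegative), so ``zero_mass = 0.5`` and the continuous part's median is
      placed at ``q3`` — the mixture's 75th percentile then reproduces ``q3``.
    * ``median > 0, q1 == 0``: ``zero_mass = 0.25`` (the largest weight
      compatible with a zero lower quartile) and the continuous part is solved
      from the two remaining quantile constraints in closed form.
    """
    if median < 0 or q1 < 0 or q3 < 0 or not (q1 <= median <= q3):
        raise CalibrationError(f"invalid quantiles ({q1}, {median}, {q3})")
    if median > 0 and q1 > 0:
        raise CalibrationError("neither median nor q1 is zero; use the plain fit")
    if q3 == 0:
        return LognormalParams(mu=0.0, sigma=0.0, zero_mass=1.0)
    if median == 0:
        return LognormalParams(mu=float(np.log(q3)), sigma=_DEFAULT_ZI_SIGMA, zero_mass=0.5)
    # median > 0, q1 == 0: mixture quantiles 0.5 and 0.75 map to continuous
    # levels 1/3 and 2/3 under zero_mass = 0.25
    w = 0.25
    z_lo = stats.norm.ppf((0.5 - w) / (1 - w))
    z_hi = stats.norm.ppf((0.75 - w) / (1 - w))
    sigma = float((np.log(q3) - np.log(median)) / (z_hi - z_lo))
    mu = float(np.log(median) - z_lo * sigma)
    return LognormalParams(mu=mu, sigma=sigma, zero_mass=w)


def fit_stage(spec: StageIntervalSpec) -> LognormalParams:
    """Dispatch a stage spec to the appropriate fit."""
    if spec.zero_inflated:
        return fit_zero_inflated(spec.median, spec.q1, spec.q3)
    return fit_lognormal_from_quantiles(spec.median, spec.q1, spec.q3)


def fit_latency_model(p_within_5: float, p_within_10: float) -> LognormalParams:
    """Two-quantile log-normal solve for the dashboard transfer latency.

    Satisfies ``F(5) = p_within_5`` and ``F(10) = p_within_10`` analytically.
    """
    if not (0 < p_within_5 < p_within_10 < 1):
        raise CalibrationError(
            f"need 0 < p_within_5 < p_within_10 < 1, got ({p_within_5}, {p_within_10})"
        )
    z5 = stats.norm.ppf(p_within_5)
    z10 = stats.norm.ppf(p_within_10)
    sigma = float((np.log(10.0) - np.log(5.0)) / (z10 - z5))
    mu = float(np.log(5.0) - z5 * sigma)
    return LognormalParams(mu=mu, sigma=sigma, zero_mass=0.0)


def build_los_reference(
    completed_visits: Iterable[tuple[str, float]],
    *,
    min_per_reason: int = 20,
    reasons: Sequence[str] = REASONS,
) -> LOSReferenceTable:
    """Empirical P50/P75/P95 of total LOS per admission reason.

    Uses linear interpolation between order statistics (numpy's default,
    type-7) so results match a sort-and-index oracle exactly.  Reasons with
    fewer than ``min_per_reason`` completed visits fall back to the pooled
    all-reason percentiles.
    """
    by_reason: dict[str, list[float]] = {r: [] for r in reasons}
    pooled: list[float] = []
    n = 0
    for reason, los in completed_visits:
        if reason not in by_reason:
            raise CalibrationError(f"unknown reason category {reason!r}")
        if los < 0:
            raise CalibrationError(f"negative LOS {los}")
        by_reason[reason].append(float(los))
        pooled.append(float(los))
        n += 1
    if n == 0:
        raise CalibrationError("no completed visits")
    pooled_pcts = tuple(np.quantile(pooled, [0.50, 0.75, 0.95]).tolist())
    table = {}
    for reason, vals in by_reason.items():
        if len(vals) >= min_per_reason:
            table[reason] = tuple(np.quantile(vals, [0.50, 0.75, 0.95]).tolist())
        else:
            table[reason] = pooled_pcts
    return LOSReferenceTable(table=table)


@lru_cache(maxsize=1)
def _load_calibration_cached() -> dict:
    text = resources.files("pedflow.data").joinpath("calibration.yaml").read_text()
    return yaml.safe_load(text)


def load_calibration() -> dict:
    """Parse the shipped calibration constants file (callers get a fresh copy)."""
    return deepcopy(_load_calibration_cached())


def default_case_mix() -> CaseMix:
    """Case-mix marginals transcribed from the trial's participant table."""
    return CaseMix.from_percentages(load_calibration()["case_mix"])


def default_stage_specs(arm: str) -> dict[str, StageIntervalSpec]:
    """Per-stage median/IQR specs for one arm (``control`` or ``optimum``)."""
    raw = load_calibration()["stage_specs"]
    if arm not in raw:
        raise CalibrationError(f"unknown arm {arm!r}; expected one of {sorted(raw)}")
    return {
        stage: StageIntervalSpec(stage, float(m), float(lo), float(hi))
        for stage, (m, lo, hi) in raw[arm].items()
    }


@lru_cache(maxsize=1)
def default_age_model() -> LognormalParams:
    """Age in months, quantile-matched to the printed cohort median/IQR."""
    a = load_calibration()["age_months"]
    return fit_lognormal_from_quantiles(a["median"], a["q1"], a["q3"])


def default_latency_model() -> LognormalParams:
    lat = load_calibration()["transfer_latency"]
    return fit_latency_model(lat["p_within_5"], lat["p_within_10"])
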