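"""Trial analysis pipeline: intervals, summaries, census curves, comparisons.

Mirrors trial-style reporting: median [IQR] per interval, ANCOVA on log- or
rank-transformed intervals adjusted for a binary priority covariate,
standardized differences with 95% CIs, a stratified permutation test on
census curves, and the queueing arithmetic used for planning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .simulator import EventLog, MINUTES_PER_DAY

__all__ = [
    "INTERVAL_DEFS",
    "IntervalTable",
    "Summary",
    "ComparisonResult",
    "CensusCurve",
    "extract_intervals",
    "summarize_median_iqr",
    "census_curve",
    "compare_census_curves",
    "ancova_compare",
    "standardized_difference",
    "effect_size_label",
    "littles_law_delta",
]


class AnalysisError(ValueError):
    pass


# interval name -> (from event, to event); first occurrences are used
INTERVAL_DEFS: dict[str, tuple[str, str]] = {
    "admission_to_triage": ("arrival", "triage"),
    "triage_to_first_eval": ("triage", "first_eval"),
    "first_eval_to_junior_eval": ("first_eval", "junior_eval"),
    "admission_to_senior_eval": ("arrival", "senior_eval"),
    "blood_presc_to_draw": ("blood_presc", "blood_draw"),
    "blood_draw_to_result": ("blood_draw", "blood_result_review"),
    "imaging_presc_to_result": ("imaging_presc", "imaging_result_review"),
    "specialist_presc_to_eval": ("specialist_presc", "specialist_eval"),
    "treatment_presc_to_admin": ("treatment_presc", "treatment_admin"),
    "final_senior_to_end_of_care": ("final_decision", "end_of_care"),
    "end_of_care_to_discharge": ("end_of_care", "discharge"),
    "total_los": ("arrival", "discharge"),
}


@dataclass(frozen=True)
class Summary:
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise AnalysisError("summary quantiles out of order")


@dataclass(frozen=True)
class ComparisonResult:
    interval_name: str
    transform: str
    p_value: float
    standardized_difference: float
    ci_low: float
    ci_high: float
    interaction_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.standardized_difference <= self.ci_high:
            raise AnalysisError("effect estimate outside its confidence interval")


@dataclass(frozen=True)
class CensusCurve:
    grid: np.ndarray           # minutes of day, strictly increasing
    mean_count: np.ndarray
    n_days: int


IntervalTable = pd.DataFrame  # columns: patient_id, arm, priority, interval_name, value


def extract_intervals(log: EventLog) -> IntervalTable:
    """Per-patient values for every defined interval (NaN when not applicable)."""
    log.lint()
    ev = log.events
    first_times = ev.groupby(["patient_id", "event"])["t_minutes"].min().unstack()
    prof = log.profiles.set_index("patient_id")
    pieces = []
    for name, (a, b) in INTERVAL_DEFS.items():
        va = first_times[a] if a in first_times else pd.Series(np.nan, index=first_times.index)
        vb = first_times[b] if b in first_times else pd.Series(np.nan, index=first_times.index)
        value = vb - va
        neg = value.dropna() < -1e-9
        if neg.any():
            raise AnalysisError(f"{neg.idxmax()}: negative interval {name}")
        pieces.append(
            pd.DataFrame(
                {
                    "patient_id": first_times.index,
                    "arm": prof["arm"].reindex(first_times.index).to_numpy(),
                    "priority": prof["priority"].reindex(first_times.index).to_numpy(),
                    "interval_name": name,
                    "value": value.to_numpy(),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def summarize_median_iqr(values: Iterable[float]) -> Summary:
    """Median and IQR under linear (type-7) order-statistic interpolation."""
    arr = np.asarray([v for v in values if not (isinstance(v, float) and np.isnan(v))], dtype=float)
    if arr.size == 0:
        raise AnalysisError("no values to summarize")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return Summary(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def _departure_times(log: EventLog) -> pd.DataFrame:
    ev = log.events
    arrivals = ev[ev["event"] == "arrival"].set_index("patient_id")["t_minutes"]
    leave = (
        ev[ev["event"].isin(["discharge", "lwbs"])]
        .groupby("patient_id")["t_minutes"]
        .min()
    )
    out = pd.DataFrame({"arrival": arrivals})
    out["departure"] = leave.reindex(out.index)
    out["day"] = ev[ev["event"] == "arrival"].set_index("patient_id")["day"]
    return out


def census_curve(log: EventLog, grid_step: float = 10.0) -> CensusCurve:
    """Mean number of patients present by time of day, averaged over days.

    Presence spans [arrival, departure); patients spilling past midnight count
    on the following day's early grid points.  Patients still present at the
    end of the log count until the last recorded event.
    """
    spans = _departure_times(log)
    if spans.empty:
        grid = np.arange(0.0, MINUTES_PER_DAY, grid_step)
        return CensusCurve(grid=grid, mean_count=np.zeros_like(grid), n_days=0)
    horizon_end = float(log.events["t_minutes"].max())
    spans["departure"] = spans["departure"].fillna(horizon_end)
    days = sorted(log.profiles["day"].unique())
    n_days = len(days)
    grid = np.arange(0.0, MINUTES_PER_DAY, grid_step)
    counts = np.zeros_like(grid)
    arr = spans["arrival"].to_numpy()
    dep = spans["departure"].to_numpy()
    for day in days:
        t_abs = day * MINUTES_PER_DAY + grid
        counts += ((arr[:, None] <= t_abs) & (t_abs < dep[:, None])).sum(axis=0)
    return CensusCurve(grid=grid, mean_count=counts / max(n_days, 1), n_days=n_days)


def daily_census_curves(log: EventLog, grid_step: float = 10.0) -> pd.DataFrame:
    """One census curve per day: columns day, arm, then one column per grid point."""
    spans = _departure_times(log)
    horizon_end = float(log.events["t_minutes"].max()) if len(log.events) else 0.0
    spans["departure"] = spans["departure"].fillna(horizon_end)
    arm_of_day = log.profiles.drop_duplicates("day").set_index("day")["arm"]
    grid = np.arange(0.0, MINUTES_PER_DAY, grid_step)
    arr = spans["arrival"].to_numpy()
    dep = spans["departure"].to_numpy()
    rows = []
    for day in sorted(log.profiles["day"].unique()):
        t_abs = day * MINUTES_PER_DAY + grid
        counts = ((arr[:, None] <= t_abs) & (t_abs < dep[:, None])).sum(axis=0)
        rows.append([day, arm_of_day.loc[day], *counts])
    return pd.DataFrame(rows, columns=["day", "arm", *[f"t{int(g)}" for g in grid]])


def compare_census_curves(
    daily_curves: pd.DataFrame,
    n_permutations: int,
    rng: np.random.Generator,
    *,
    strata: Optional[dict] = None,
) -> float:
    """Permutation test on the integrated squared difference of arm-mean curves.

    Day-to-arm labels are permuted within weekday/weekend strata when given.
    p = (1 + #{perm >= obs}) / (1 + n_permutations).
    """
    arms = daily_curves["arm"].to_numpy()
    if len(set(arms)) < 2 or min((arms == a).sum() for a in set(arms)) < 2:
        raise AnalysisError("need at least 2 days in each arm")
    values = daily_curves.drop(columns=["day", "arm"]).to_numpy(dtype=float)
    days = daily_curves["day"].to_numpy()
    if strata is None:
        stratum_of = np.zeros(len(days), dtype=int)
    else:
        labels = {s: i for i, s in enumerate(sorted(set(strata.values())))}
        stratum_of = np.array([labels[strata[d]] for d in days])

    def statistic(labels_: np.ndarray) -> float:
        a = values[labels_ == "optimum"].mean(axis=0)
        b = values[labels_ != "optimum"].mean(axis=0)
        return float(np.sum((a - b) ** 2))

    obs = statistic(arms)
    count = 0
    for _ in range(n_permutations):
        perm = arms.copy()
        for s in np.unique(stratum_of):
            idx = np.where(stratum_of == s)[0]
            perm[idx] = perm[rng.permutation(idx)]
        if statistic(perm) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log1p":
        return np.log1p(values)
    if transform == "rank":
        return stats.rankdata(values)
    raise AnalysisError(f"unknown transform {transform!r}")


def ancova_compare(
    intervals: IntervalTable,
    interval_name: str,
    transform: str = "log1p",
    *,
    interaction: bool = False,
) -> ComparisonResult:
    """Arm comparison of one interval, adjusted for binary priority.

    Linear model of the transformed value on arm and priority (low vs.
    moderate/high); the reported p is for the arm effect.  With
    ``interaction=True`` an arm x priority term is added and its p returned
    alongside.
    """
    sub = intervals[(intervals["interval_name"] == interval_name) & intervals["value"].notna()]
    arms = sorted(sub["arm"].unique())
    if len(arms) < 2:
        raise AnalysisError(f"{interval_name}: need both arms, got {arms}")
    y = _transform(sub["value"].to_numpy(dtype=float), transform)
    arm_ind = (sub["arm"] == "optimum").to_numpy(dtype=float)
    low_ind = (sub["priority"] == "low").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(arm_ind), arm_ind, low_ind])
    names = ["const", "arm", "low_priority"]
    if interaction:
        X = np.column_stack([X, arm_ind * low_ind])
        names.append("arm_x_low")
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    p_arm = float(fit.pvalues["arm"])
    inter_p = float(fit.pvalues["arm_x_low"]) if interaction else None
    d, lo, hi = standardized_difference(
        sub["value"].to_numpy(dtype=float), (sub["arm"] == "optimum").to_numpy(), transform
    )
    return ComparisonResult(
        interval_name=interval_name,
        transform=transform,
        p_value=p_arm,
        standardized_difference=d,
        ci_low=lo,
        ci_high=hi,
        interaction_p=inter_p,
    )


def standardized_difference(
    values: np.ndarray, is_treatment: np.ndarray, transform: str = "log1p"
) -> tuple[float, float, float]:
    """Cohen's-d-type effect on the transformed scale, with a 95% normal CI."""
    values = np.asarray(values, dtype=float)
    is_treatment = np.asarray(is_treatment, dtype=bool)
    y = _transform(values, transform)
    a, b = y[is_treatment], y[~is_treatment]
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both arms must be nonempty")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise AnalysisError("zero pooled variance")
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))))
    z = stats.norm.ppf(0.975)
    return d, d - z * se, d + z * se


def effect_size_label(d: float) -> str:
    """Conventional magnitude label for a standardized difference."""
    m = abs(d)
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "moderate"
    return "large"


def littles_law_delta(
    arrivals_per_day: float, delta_los_minutes: float, *, rounded: bool = False
) -> float:
    """Mean-census change implied by a LOS change: (λ per minute) x ΔLOS."""
    if arrivals_per_day < 0:
        raise AnalysisError("arrivals_per_day must be >= 0")
    value = (arrivals_per_day / MINUTES_PER_DAY) * delta_los_minutes
    return float(round(value)) if rounded else float(value)


# transforms the study assigned per interval: rank for the two zero-heavy ones
DEFAULT_TRANSFORMS = {
    name: ("rank" if name in ("specialist_presc_to_eval", "final_senior_to_end_of_care") else "log1p")
    for name in INTERVAL_DEFS
}


def summarize_by_arm(intervals: IntervalTable) -> pd.DataFrame:
    """Median [IQR] of every interval per arm, long format."""
    rows = []
    for (name, arm), grp in intervals.groupby(["interval_name", "arm"]):
        vals = grp["value"].dropna()
        if vals.empty:
            continue
        s = summarize_median_iqr(vals)
        rows.append((name, arm, s.n, s.median, s.q1, s.q3))
    return pd.DataFrame(rows, columns=["interval_name", "arm", "n", "median", "q1", "q3"])


def full_report(intervals: IntervalTable, *, interaction: bool = False) -> pd.DataFrame:
    """One comparison row per interval present in both arms."""
    rows = []
    for name in INTERVAL_DEFS:
        sub = intervals[(intervals["interval_name"] == name) & intervals["value"].notna()]
        if sub.empty or sub["arm"].nunique() < 2:
            continue
        try:
            res = ancova_compare(sub, name, DEFAULT_TRANSFORMS[name], interaction=interaction)
        except AnalysisError:
            continue
        rows.append(
            (
                name,
                res.transform,
                res.p_value,
                res.standardized_difference,
                res.ci_low,
                res.ci_high,
                res.interaction_p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["interval_name", "transform", "p_value", "std_diff", "ci_low", "ci_high", "interaction_p"],
    )
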