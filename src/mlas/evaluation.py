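"""Model evaluation: discrimination, calibration, agreement, bootstrap.

* :func:`td_roc_nne` — cumulative/dynamic time-dependent ROC at an evaluation
  time t*, treating cases as events by t* and controls as survivors past t*.
  Under censoring the joint distribution of (marker, survival) is estimated
  with the nearest-neighbor conditional Kaplan-Meier (symmetric 0/1 kernel on
  marker ranks); with complete data (no observation censored at or before t*)
  the empirical bivariate distribution is used, under which the AUC is
  exactly the Mann-Whitney statistic of the marker against 1(T <= t*).
* :func:`kaplan_meier` — product-limit estimator with Greenwood/log-log
  confidence intervals (via lifelines).
* :func:`calibration_table` — risk tertiles by linear predictor; mean
  predicted survival vs observed Kaplan-Meier on a 30-day grid.
* :func:`bland_altman` — limits-of-agreement analysis of paired scores/ranks.
* :func:`bootstrap_compare` — patient-level bootstrap of two pipelines with
  percentile confidence intervals and a normal-approximation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import EstimationError, ValidationError

__all__ = [
    "kaplan_meier",
    "TdRoc",
    "td_roc_nne",
    "BootstrapComparison",
    "bootstrap_compare",
    "calibration_table",
    "BlandAltman",
    "bland_altman",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def kaplan_meier(times, events, conf_level: float = 0.95) -> pd.DataFrame:
    """Product-limit survival estimate with (log-log) confidence interval.

    Returns a DataFrame ``time, survival, ci_lower, ci_upper`` with one row
    per distinct observed time (step-function values carry forward).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValidationError("times must be nonnegative")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("events must be 0/1")
    if events.sum() == 0:
        warnings.warn("all observations censored: survival curve is identically 1")
    kmf = KaplanMeierFitter(alpha=1.0 - conf_level)
    kmf.fit(times, events)
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    )
    return out


def km_at(km: pd.DataFrame, days) -> pd.DataFrame:
    """Evaluate a :func:`kaplan_meier` table at given days (carry forward)."""
    days = np.asarray(days, dtype=float)
    idx = np.searchsorted(km["time"].to_numpy(), days, side="right") - 1
    idx = np.clip(idx, 0, len(km) - 1)
    first = km["time"].to_numpy()[0]
    out = km.iloc[idx][["survival", "ci_lower", "ci_upper"]].reset_index(drop=True)
    out.loc[days < first, :] = 1.0
    out.insert(0, "time", days)
    return out


# ---------------------------------------------------------------------------
# Time-dependent ROC (cumulative/dynamic, nearest-neighbor estimator)
# ---------------------------------------------------------------------------


@dataclass
class TdRoc:
    """Time-dependent ROC at evaluation time ``t_star``."""

    t_star: float
    span: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    smoothed: bool  # False when the exact complete-data estimator was used


def _nne_conditional_survival(
    marker: np.ndarray, times: np.ndarray, events: np.ndarray, t_star: float, span: float
) -> np.ndarray:
    """Akritas nearest-neighbor conditional Kaplan-Meier S(t*|M_i) for each i,
    using a symmetric 0/1 kernel of half-width floor(span*n) on marker ranks."""
    n = len(marker)
    order = np.argsort(marker, kind="stable")
    t_ord = times[order]
    e_ord = events[order]
    h = max(int(np.floor(span * n)), 1)
    S = np.empty(n)
    for pos in range(n):
        lo, hi = max(0, pos - h), min(n, pos + h + 1)
        t_w = t_ord[lo:hi]
        e_w = e_ord[lo:hi]
        ev_times = np.unique(t_w[(e_w == 1) & (t_w <= t_star)])
        s = 1.0
        for s_time in ev_times:
            at_risk = np.count_nonzero(t_w >= s_time)
            d = np.count_nonzero((t_w == s_time) & (e_w == 1))
            if at_risk > 0:
                s *= 1.0 - d / at_risk
        S[pos] = s
    out = np.empty(n)
    out[order] = S
    return out


def td_roc_nne(
    marker,
    times,
    events,
    t_star: float,
    span: float | None = None,
) -> TdRoc:
    """Cumulative/dynamic time-dependent ROC curve and AUC at ``t_star``.

    ``span`` is the nearest-neighbor fraction (default 0.25 * n**-0.2).
    The bivariate survival is S(c, t) = n^-1 sum_i 1(M_i > c) S(t|M_i);
    sensitivity(c) = [(1 - F(c)) - S(c, t*)] / (1 - S(t*)) and
    specificity(c) = 1 - S(c, t*) / S(t*).  The AUC is the area under the
    resulting curve, computed as the (possibly fractionally weighted)
    Mann-Whitney statistic, which coincides with the trapezoidal area over
    the full threshold grid.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(marker)
    if not (len(times) == len(events) == n):
        raise ValidationError("marker, times, events must have equal length")
    if t_star <= 0:
        raise ValidationError("t_star must be positive")
    if span is None:
        span = 0.25 * n ** (-0.20)
    if not 0.0 < span < 1.0:
        raise ValidationError(f"span {span} outside (0, 1)")
    censored_by_tstar = (events == 0) & (times <= t_star)
    if censored_by_tstar.any():
        D = _nne_conditional_survival(marker, times, events, t_star, span)
        smoothed = True
    else:
        D = (times > t_star).astype(float)
        smoothed = False
    s_tstar = float(D.mean())
    if s_tstar <= 0.0 or s_tstar >= 1.0:
        raise EstimationError(
            f"S(t*) = {s_tstar}: ROC undefined (no cases or no controls at t*)"
        )
    # Case weight a_i = 1 - S(t*|M_i), control weight b_i = S(t*|M_i); the ROC
    # is the weighted empirical ROC of the marker under these weights.
    a = 1.0 - D
    b = D
    order = np.argsort(marker, kind="stable")
    m_ord = marker[order]
    a_ord = a[order]
    b_ord = b[order]
    # threshold grid: descending unique marker values
    uniq, start_idx = np.unique(m_ord, return_index=True)
    cum_a = np.concatenate([[0.0], np.cumsum(a_ord)])
    cum_b = np.concatenate([[0.0], np.cumsum(b_ord)])
    A, B = cum_a[-1], cum_b[-1]
    # tail sums of a/b strictly above each unique threshold value
    end_idx = np.append(start_idx[1:], len(m_ord))
    a_above = A - cum_a[end_idx]
    b_above = B - cum_b[end_idx]
    sens = np.concatenate([[1.0], a_above / A])  # c = -inf first
    fpr = np.concatenate([[1.0], b_above / B])
    thresholds = np.concatenate([[-np.inf], uniq])
    # Weighted Mann-Whitney AUC with tie correction
    a_at = cum_a[end_idx] - cum_a[start_idx]
    b_below = cum_b[start_idx]
    b_at = cum_b[end_idx] - cum_b[start_idx]
    auc = float(np.sum(a_at * (b_below + 0.5 * b_at)) / (A * B))
    return TdRoc(
        t_star=float(t_star),
        span=float(span),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
        smoothed=smoothed,
    )


# ---------------------------------------------------------------------------
# Bootstrap model comparison
# ---------------------------------------------------------------------------


@dataclass
class BootstrapComparison:
    stat_a: float
    stat_b: float
    difference: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    ci_difference: tuple[float, float]
    p_value: float
    reps: int
    seed: int
    level: float
    n_failures: int
    replicates: pd.DataFrame = field(repr=False, default=None)


def bootstrap_compare(
    score_fn_a,
    score_fn_b,
    data: pd.DataFrame,
    *,
    reps: int = 1000,
    seed: int,
    level: float = 0.95,
    id_col: str = "patient_id",
    max_failure_rate: float = 0.1,
) -> BootstrapComparison:
    """Compare two pipelines by a patient-level bootstrap.

    Patients (all their rows together) are resampled with replacement;
    both score functions are re-run on every replicate, so anything they
    estimate internally (weights included) is re-estimated per replicate.
    Percentile confidence intervals at ``level`` are reported for each
    statistic and for the difference; the p-value of the difference uses
    the two-sided normal approximation with the bootstrap SD.
    """
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    stat_a0 = float(score_fn_a(data))
    stat_b0 = float(score_fn_b(data))
    rng = np.random.default_rng(seed)
    ids, inverse = np.unique(data[id_col].to_numpy(), return_inverse=True)
    positions = [np.flatnonzero(inverse == k) for k in range(len(ids))]
    sizes = np.array([len(p) for p in positions])
    reps_a, reps_b = [], []
    failures = 0
    for _ in range(reps):
        chosen = rng.integers(0, len(ids), size=len(ids))
        rows = np.concatenate([positions[k] for k in chosen])
        boot = data.iloc[rows].copy()
        boot[id_col] = np.repeat(np.arange(len(chosen)), sizes[chosen])
        try:
            reps_a.append(float(score_fn_a(boot)))
            reps_b.append(float(score_fn_b(boot)))
        except Exception:
            failures += 1
    if failures > max_failure_rate * reps:
        raise EstimationError(
            f"{failures}/{reps} bootstrap replicates failed (limit "
            f"{max_failure_rate:.0%})"
        )
    ra = np.asarray(reps_a)
    rb = np.asarray(reps_b)
    rd = ra - rb
    alpha = 100.0 * (1.0 - level) / 2.0
    pct = lambda x: (float(np.percentile(x, alpha)), float(np.percentile(x, 100 - alpha)))
    diff0 = stat_a0 - stat_b0
    sd = float(np.std(rd, ddof=1))
    if sd == 0.0:
        p = 1.0 if diff0 == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(diff0) / sd))
    return BootstrapComparison(
        stat_a=stat_a0,
        stat_b=stat_b0,
        difference=diff0,
        ci_a=pct(ra),
        ci_b=pct(rb),
        ci_difference=pct(rd),
        p_value=p,
        reps=reps,
        seed=seed,
        level=level,
        n_failures=failures,
        replicates=pd.DataFrame({"a": ra, "b": rb, "difference": rd}),
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_GROUP_LABELS = {3: ("low", "medium", "high")}


def calibration_table(
    fit,
    data: pd.DataFrame,
    *,
    time_col: str = "time",
    event_col: str = "event",
    n_groups: int = 3,
    grid_step: int = 30,
    horizon: int = 365,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Observed vs predicted survival by risk group.

    Groups are tertiles (or ``n_groups``-tiles) of the fitted linear
    predictor, ties at a boundary going to the lower-risk group.  For every
    group and grid day the table carries the mean of the individual
    predicted survival curves and the Kaplan-Meier estimate of the observed
    outcomes with its confidence interval.
    """
    lp = np.atleast_1d(fit.linear_predictor(data))
    cuts = np.quantile(lp, np.arange(1, n_groups) / n_groups)
    group = np.searchsorted(cuts, lp, side="left")
    days = np.arange(grid_step, horizon + 1, grid_step)
    H = fit.cumulative_hazard_at(days)
    pred = np.exp(-np.outer(np.exp(lp), H))
    labels = _GROUP_LABELS.get(n_groups, tuple(str(g) for g in range(n_groups)))
    parts = []
    for g in range(n_groups):
        mask = group == g
        if not mask.any():
            continue
        if data.loc[mask, event_col].sum() == 0:
            warnings.warn(f"risk group {labels[g]!r} has zero events: CI degenerate")
        km = kaplan_meier(
            data.loc[mask, time_col], data.loc[mask, event_col], conf_level
        )
        obs = km_at(km, days)
        parts.append(
            pd.DataFrame(
                {
                    "group": labels[g],
                    "day": days,
                    "n": int(mask.sum()),
                    "predicted": pred[mask].mean(axis=0),
                    "observed": obs["survival"].to_numpy(),
                    "ci_lower": obs["ci_lower"].to_numpy(),
                    "ci_upper": obs["ci_upper"].to_numpy(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass
class BlandAltman:
    """Limits-of-agreement analysis of paired measurements."""

    means: np.ndarray
    differences: np.ndarray
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float


def bland_altman(values_a, values_b) -> BlandAltman:
    """Pairwise means and differences (A - B) with limits at +/- 2 SD
    (SD with the n-1 denominator) around the mean difference."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValidationError("paired inputs must have equal length")
    if len(a) < 2:
        raise ValidationError("need at least 2 pairs")
    diffs = a - b
    md = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(
        means=(a + b) / 2.0,
        differences=diffs,
        mean_difference=md,
        sd_difference=sd,
        lower_limit=md - 2.0 * sd,
        upper_limit=md + 2.0 * sd,
    )
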