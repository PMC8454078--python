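"""LAS score computation and offer-date ranking.

The allocation score combines the two fitted outcome models: for each
eligible patient at an offer date, predict the daily one-year survival
curves, sum them into expected days alive on the waitlist (WL) and expected
days alive post-transplant (PT), form the raw score PT - 2*WL (in days,
range [-730, 365]) and map it affinely onto [0, 100], higher = greater
transplant priority.  Rankings at an offer date sort eligible patients by
descending score, breaking ties by longer time since listing, then by
patient id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Registry, _merge_tv
from .cox import WeightedCoxResults
from .errors import ValidationError

__all__ = [
    "expected_days",
    "raw_score",
    "normalize",
    "eligible_at",
    "covariates_at",
    "score_cohort",
    "rank_patients",
]

RAW_LOWER = -730.0
RAW_UPPER = 365.0


def expected_days(curve, horizon: int = 365) -> float:
    """Expected days alive within the horizon: sum of S(t), t = 1..horizon."""
    s = np.asarray(curve, dtype=float)
    if len(s) < horizon:
        raise ValidationError(
            f"survival curve defined through day {len(s)} < horizon {horizon}"
        )
    return float(s[:horizon].sum())


def raw_score(pt_days: float, wl_days: float) -> float:
    """Raw allocation score: post-transplant minus twice waitlist days."""
    for name, v in (("PT", pt_days), ("WL", wl_days)):
        if not 0.0 <= v <= 365.0:
            raise ValidationError(f"{name} days {v} outside [0, 365]")
    return pt_days - 2.0 * wl_days


def normalize(raw: float, lower: float = RAW_LOWER, upper: float = RAW_UPPER) -> float:
    """Affine map of the raw score onto [0, 100]."""
    if not lower <= raw <= upper:
        raise ValidationError(f"raw score {raw} outside [{lower}, {upper}]")
    return 100.0 * (raw - lower) / (upper - lower)


def eligible_at(reg: Registry, offer_day: int) -> pd.Index:
    """Patients alive, listed and not yet removed (by transplant, death or
    censoring) on the offer day: list_day <= offer_day < list_day + outcome_day."""
    d = reg.data
    mask = (d["list_day"] <= offer_day) & (
        offer_day < d["list_day"] + d["outcome_day"]
    )
    return pd.Index(d.loc[mask, "patient_id"])


def covariates_at(reg: Registry, patient_ids, offer_day: int) -> pd.DataFrame:
    """Baseline covariates with time-varying values carried forward to the
    offer day (in each patient's own time scale)."""
    d = reg.data.set_index("patient_id").loc[list(patient_ids)].reset_index()
    out = d[["patient_id", "list_day", "outcome_day"]].copy()
    for c in reg.covariate_columns:
        out[c] = d[c].to_numpy()
    if reg.tv is not None and len(reg.tv):
        out["_at"] = offer_day - out["list_day"]
        view = Registry.__new__(Registry)
        view.data = d
        view.tv = reg.tv[reg.tv["patient_id"].isin(out["patient_id"])]
        _merge_tv(out, view, at_col="_at")
        out = out.drop(columns=["_at"])
    return out


def score_cohort(
    reg: Registry,
    pre_fit: WeightedCoxResults,
    post_fit: WeightedCoxResults,
    offer_day: int,
    *,
    variant: str = "modified",
    horizon: int = 365,
    normalization: tuple[float, float] = (RAW_LOWER, RAW_UPPER),
) -> pd.DataFrame:
    """Score every patient eligible at the offer date.

    Returns columns ``patient_id, offer_day, days_listed, WL, PT, raw,
    score, variant``.
    """
    ids = eligible_at(reg, offer_day)
    if len(ids) == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "offer_day", "days_listed",
                "WL", "PT", "raw", "score", "variant",
            ]
        )
    X = covariates_at(reg, ids, offer_day)
    days = np.arange(1, horizon + 1)

    def _expected(fit: WeightedCoxResults) -> np.ndarray:
        lp = np.atleast_1d(fit.linear_predictor(X))
        H = fit.cumulative_hazard_at(days)
        return np.exp(-np.outer(np.exp(lp), H)).sum(axis=1)

    wl = _expected(pre_fit)
    pt = _expected(post_fit)
    raw = pt - 2.0 * wl
    lo, hi = normalization
    score = 100.0 * (np.clip(raw, lo, hi) - lo) / (hi - lo)
    return pd.DataFrame(
        {
            "patient_id": X["patient_id"],
            "offer_day": offer_day,
            "days_listed": offer_day - X["list_day"],
            "WL": wl,
            "PT": pt,
            "raw": raw,
            "score": score,
            "variant": variant,
        }
    )


def rank_patients(results: pd.DataFrame) -> pd.DataFrame:
    """Rank scored patients at one offer date: descending score, ties broken
    by longer time listed, then lexicographic patient id.  Adds ``rank``
    (1 = highest priority)."""
    if results.empty:
        raise ValidationError("cannot rank an empty result set")
    if results["offer_day"].nunique() > 1:
        raise ValidationError("rank_patients expects a single offer date")
    ordered = results.sort_values(
        ["score", "days_listed", "patient_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered
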