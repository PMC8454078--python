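"""Stabilized inverse-probability weights for transplant receipt and censoring.

The daily counting rows produced by :func:`mlas.cohort.expand_daily` are a
discrete-time risk set: on each day a patient still on the waitlist either
dies, receives a transplant, is censored, or continues.  Pooled logistic
regression on these rows therefore estimates the daily discrete-time hazard
of the chosen target event, and the standard marginal-structural-model
construction turns two such models (transplant and censoring), together with
reduced "stabilizer" models, into per-patient per-day stabilized weights

    w_i(t) = prod_{s<=t}  [ (1 - num_T(s)) (1 - num_C(s)) ]
                        / [ (1 - den_T(s)) (1 - den_C(s)) ]

where den_* are the fitted conditional probabilities of transplant/censoring
at day s given the patient's covariate history and num_* come from the
reduced models (by default intercept + flexible time-on-list terms only).

The post-transplant weight of a patient transplanted at day t_tx is the
stabilized inverse probability of their observed selection path up to and
including transplant: the pre-transplant cumulative ratio through t_tx - 1
multiplied by num_T(t_tx) / den_T(t_tx); it is fixed from then on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DegenerateModelError,
    PositivityError,
    SchemaError,
)

__all__ = [
    "restricted_cubic_spline",
    "DiscreteHazard",
    "fit_discrete_hazard",
    "pre_transplant_weights",
    "post_transplant_weights",
    "weight_diagnostics",
]

_PCLIP = (1e-10, 1.0 - 1e-10)


def restricted_cubic_spline(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell-style restricted cubic spline basis (linear tails).

    Returns ``len(knots) - 1`` columns: x itself plus ``len(knots) - 2``
    nonlinear terms, each normalized by the squared knot range.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = len(k)
    if K < 3:
        return x[:, None]
    norm = (k[-1] - k[0]) ** 2
    cols = [x]
    for j in range(K - 2):
        term = (
            np.clip(x - k[j], 0, None) ** 3
            - np.clip(x - k[-2], 0, None) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
            + np.clip(x - k[-1], 0, None) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


class DiscreteHazard:
    """Pooled daily logistic model for the hazard of one target event.

    Parameters
    ----------
    target
        ``"transplant"`` or ``"censor"`` (any ``event_<target>`` column works).
    covariates
        Covariate columns of the counting rows; may be empty for a purely
        time/intercept (stabilizer) model.
    time_knots
        Number of restricted-cubic-spline knots for time on list
        (0 disables time terms).
    """

    def __init__(
        self,
        target: str,
        covariates: list[str] | tuple[str, ...] = (),
        *,
        time_knots: int = 4,
    ) -> None:
        self.target = target
        self.covariates = list(covariates)
        self.time_knots = int(time_knots)
        self.knots_: np.ndarray | None = None
        self.params_: np.ndarray | None = None
        self.converged: bool | None = None

    @property
    def fitted(self) -> bool:
        return self.params_ is not None

    def design(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in rows.columns]
        if missing:
            raise SchemaError(f"counting rows are missing covariates {missing}")
        parts = [np.ones((len(rows), 1))]
        if self.time_knots and self.knots_ is not None:
            parts.append(
                restricted_cubic_spline(rows["stop"].to_numpy(float), self.knots_)
            )
        if self.covariates:
            parts.append(rows[self.covariates].to_numpy(dtype=float))
        return np.hstack(parts)

    def fit(self, rows: pd.DataFrame) -> "DiscreteHazard":
        ycol = f"event_{self.target}"
        if ycol not in rows.columns:
            raise SchemaError(f"counting rows lack column {ycol!r}")
        y = rows[ycol].to_numpy(dtype=float)
        if y.sum() == 0:
            raise DegenerateModelError(
                f"no {self.target} events: daily hazard model is degenerate"
            )
        if self.time_knots:
            qs = np.linspace(0.05, 0.95, self.time_knots)
            knots = np.unique(np.quantile(rows["stop"].to_numpy(float), qs))
            self.knots_ = knots if len(knots) >= 3 else None
        X = self.design(rows)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except Exception as exc:
            raise ConvergenceError(f"daily hazard model failed: {exc}") from exc
        if not res.mle_retvals["converged"]:
            raise ConvergenceError(
                f"daily {self.target} hazard model did not converge "
                "(possible complete separation)"
            )
        if np.any(np.abs(res.params) > 30):
            raise ConvergenceError(
                f"daily {self.target} hazard model has diverging coefficients "
                "(complete separation?)"
            )
        self.params_ = np.asarray(res.params)
        self.converged = bool(res.converged)
        self.n_events_ = int(y.sum())
        self.n_obs_ = len(y)
        return self

    def predict_hazard(self, rows: pd.DataFrame) -> np.ndarray:
        """Fitted daily event probability per row, clipped to (0, 1)."""
        if not self.fitted:
            raise ValueError("model is not fitted")
        eta = self.design(rows) @ self.params_
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, *_PCLIP)


def fit_discrete_hazard(
    rows: pd.DataFrame,
    target: str,
    covariates: list[str] | tuple[str, ...] = (),
    *,
    time_knots: int = 4,
) -> DiscreteHazard:
    """Fit a pooled daily logistic hazard model (see :class:`DiscreteHazard`)."""
    return DiscreteHazard(target, covariates, time_knots=time_knots).fit(rows)


def _survival_ratio(
    rows: pd.DataFrame,
    txp_den: DiscreteHazard,
    cens_den: DiscreteHazard,
    txp_num: DiscreteHazard,
    cens_num: DiscreteHazard,
    check_positivity: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row stabilizing ratio of remaining event-free, plus the transplant
    numerator/denominator hazards (needed for the transplant-day factor)."""
    p_td = txp_den.predict_hazard(rows)
    p_cd = cens_den.predict_hazard(rows)
    p_tn = txp_num.predict_hazard(rows)
    p_cn = cens_num.predict_hazard(rows)
    if check_positivity:
        for name, p in (("transplant", p_td), ("censor", p_cd)):
            bad = (p >= 1.0 - 1e-12) | (p <= 1e-12)
            if bad.any():
                i = int(np.argmax(bad))
                raise PositivityError(
                    f"fitted {name} probability at the positivity boundary for "
                    f"patient {rows['patient_id'].iloc[i]!r} day "
                    f"{int(rows['stop'].iloc[i])}"
                )
    ratio = ((1.0 - p_tn) * (1.0 - p_cn)) / ((1.0 - p_td) * (1.0 - p_cd))
    return ratio, p_tn / p_td, p_td


def _cumprod_by_patient(sorted_rows: pd.DataFrame, ratio: np.ndarray) -> np.ndarray:
    logr = np.log(ratio)
    cum = np.cumsum(logr)
    pid = sorted_rows["patient_id"].to_numpy()
    first = np.concatenate([[True], pid[1:] != pid[:-1]])
    starts = np.flatnonzero(first)
    # subtract the cumulative sum just before each patient's first row
    offset = np.repeat(
        np.concatenate([[0.0], cum[starts[1:] - 1]]), np.diff(np.append(starts, len(cum)))
    )
    return np.exp(cum - offset)


def _truncate(w: np.ndarray, truncation) -> tuple[np.ndarray, tuple | None]:
    if truncation is None:
        return w, None
    lo, hi = np.percentile(w, truncation)
    return np.clip(w, lo, hi), (float(lo), float(hi))


def pre_transplant_weights(
    rows: pd.DataFrame,
    txp_den: DiscreteHazard,
    cens_den: DiscreteHazard,
    txp_num: DiscreteHazard,
    cens_num: DiscreteHazard,
    *,
    truncation: tuple[float, float] | None = (1.0, 99.0),
    check_positivity: bool = False,
) -> pd.DataFrame:
    """Daily stabilized pre-transplant weights (IPTW x IPCW).

    Returns a DataFrame ``patient_id, day, weight, raw_weight`` with one row
    per patient-day; truncation percentiles (applied over all patient-days)
    are recorded in ``.attrs["truncation_bounds"]``.
    """
    sorted_rows = rows.sort_values(["patient_id", "stop"], kind="stable")
    ratio, _, _ = _survival_ratio(
        sorted_rows, txp_den, cens_den, txp_num, cens_num, check_positivity
    )
    raw = _cumprod_by_patient(sorted_rows, ratio)
    w, bounds = _truncate(raw, truncation)
    out = pd.DataFrame(
        {
            "patient_id": sorted_rows["patient_id"].to_numpy(),
            "day": sorted_rows["stop"].to_numpy(),
            "weight": w,
            "raw_weight": raw,
        }
    )
    out.attrs["truncation_bounds"] = bounds
    return out


def post_transplant_weights(
    rows: pd.DataFrame,
    txp_den: DiscreteHazard,
    cens_den: DiscreteHazard,
    txp_num: DiscreteHazard,
    cens_num: DiscreteHazard,
    *,
    truncation: tuple[float, float] | None = (1.0, 99.0),
    include_tx_day: bool = True,
    check_positivity: bool = False,
) -> pd.DataFrame:
    """Fixed post-transplant weights, one row per transplanted patient.

    The weight is the stabilized inverse probability of the observed
    selection path: the pre-transplant cumulative ratio through the day
    before transplant, multiplied (when ``include_tx_day``) by the
    stabilized inverse probability of transplant on the transplant day.
    Returns ``patient_id, weight, raw_weight, tx_day``.
    """
    sorted_rows = rows.sort_values(["patient_id", "stop"], kind="stable")
    ratio, tx_factor, _ = _survival_ratio(
        sorted_rows, txp_den, cens_den, txp_num, cens_num, check_positivity
    )
    is_tx = sorted_rows["event_transplant"].to_numpy() == 1
    # survival ratio applies on event-free days; on the transplant day the
    # relevant factor is the transplant probability ratio instead
    ratio_path = np.where(is_tx, tx_factor if include_tx_day else 1.0, ratio)
    cum = _cumprod_by_patient(sorted_rows, ratio_path)
    raw = cum[is_tx]
    w, bounds = _truncate(raw, truncation) if len(raw) else (raw, None)
    out = pd.DataFrame(
        {
            "patient_id": sorted_rows.loc[is_tx, "patient_id"].to_numpy(),
            "weight": w,
            "raw_weight": raw,
            "tx_day": sorted_rows.loc[is_tx, "stop"].to_numpy(),
        }
    )
    out.attrs["truncation_bounds"] = bounds
    return out


def weight_diagnostics(
    weights: pd.DataFrame,
    *,
    by_day: bool = False,
    flag_threshold: float = 0.1,
) -> pd.DataFrame:
    """Summary statistics of a weight table (column ``weight``; optional
    ``day`` for per-day summaries).  Adds a ``flagged`` column marking rows
    whose mean deviates from 1 by more than ``flag_threshold``."""
    if weights.empty:
        raise ValueError("empty weight table")

    def _stats(w: np.ndarray) -> dict:
        return {
            "n": len(w),
            "mean": float(np.mean(w)),
            "sd": float(np.std(w, ddof=1)) if len(w) > 1 else 0.0,
            "min": float(np.min(w)),
            "p1": float(np.percentile(w, 1)),
            "p50": float(np.percentile(w, 50)),
            "p99": float(np.percentile(w, 99)),
            "max": float(np.max(w)),
        }

    if by_day and "day" in weights.columns:
        recs = []
        for day, grp in weights.groupby("day"):
            recs.append({"day": day, **_stats(grp["weight"].to_numpy())})
        out = pd.DataFrame(recs)
    else:
        out = pd.DataFrame([{"day": None, **_stats(weights["weight"].to_numpy())}])
    out["flagged"] = (out["mean"] - 1.0).abs() > flag_threshold
    return out
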