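"""Weighted Cox proportional-hazards estimation.

Implements the weighted partial likelihood with Breslow handling of ties,

    l(b) = sum_{i: event} w_i [ x_i b - log sum_{j in R(t_i)} w_j exp(x_j b) ],

maximized by Newton-Raphson with step-halving, together with the weighted
Breslow cumulative baseline hazard

    dH0(t) = ( sum_{i: event at t} w_i ) / ( sum_{j in R(t)} w_j exp(x_j b) )

on a daily grid, daily survival prediction S(t|x) = exp(-H0(t) exp(x b)),
and a robust (sandwich) covariance that groups score residuals by patient.

Data may be supplied either in counting-process form (``start``/``stop``
columns, risk set at t = {j : start_j < t <= stop_j}) or as one record per
subject (``duration`` column, implicit start 0).  Observation weights are
arbitrary positive reals; an integer weight k is exactly equivalent to
duplicating the row k times, for both the coefficients and the baseline
hazard.

The model/results split follows the statsmodels convention: construct a
:class:`WeightedCox` from a DataFrame, call :meth:`~WeightedCox.fit`, and
work with the returned :class:`WeightedCoxResults`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, EstimationError, SchemaError, ValidationError

__all__ = ["WeightedCox", "WeightedCoxResults"]


class WeightedCox:
    """Weighted Cox proportional hazards model.

    Parameters
    ----------
    data
        Input table.
    covariates
        Names of the covariate columns to enter the linear predictor.
    event_col
        0/1 event indicator column.
    duration_col
        Follow-up time column for one-record-per-subject data.  Mutually
        exclusive with ``start_col``/``stop_col``.
    start_col, stop_col
        Interval columns for counting-process data.
    weight_col
        Optional positive observation weights (default all 1).
    id_col
        Optional subject identifier used to aggregate score residuals for
        the robust covariance; defaults to one group per row.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: list[str],
        *,
        event_col: str,
        duration_col: str | None = None,
        start_col: str | None = None,
        stop_col: str | None = None,
        weight_col: str | None = None,
        id_col: str | None = None,
    ) -> None:
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise SchemaError(f"covariates not in data: {missing}")
        self.covariates = list(covariates)
        self.X = data[covariates].to_numpy(dtype=float)
        if duration_col is not None:
            self.stop = data[duration_col].to_numpy(dtype=float)
            self.start = np.zeros_like(self.stop)
        elif start_col is not None and stop_col is not None:
            self.start = data[start_col].to_numpy(dtype=float)
            self.stop = data[stop_col].to_numpy(dtype=float)
        else:
            raise SchemaError("provide either duration_col or start_col+stop_col")
        if np.any(self.stop <= self.start):
            raise ValidationError("intervals must satisfy stop > start")
        self.event = data[event_col].to_numpy(dtype=np.int8)
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValidationError("event indicator must be 0/1")
        if weight_col is not None:
            self.w = data[weight_col].to_numpy(dtype=float)
            if np.any(~np.isfinite(self.w)) or np.any(self.w <= 0):
                raise ValidationError("weights must be strictly positive and finite")
        else:
            self.w = np.ones(len(data))
        if self.event.sum() == 0:
            raise ValidationError("no events in the data")
        if id_col is not None:
            self.ids = data[id_col].to_numpy()
        else:
            self.ids = np.arange(len(data))
        self._prepare()

    # -- internals -------------------------------------------------------

    def _prepare(self) -> None:
        # Center covariates for numerical stability; the baseline hazard is
        # re-referenced to x = 0 after fitting.
        self._xbar = self.X.mean(axis=0)
        self._Xc = self.X - self._xbar
        # Daily counting rows (stop = start + 1, integer days): the risk set
        # at day t is exactly {stop == t}, so risk-set sums are bincounts.
        self._daily = bool(
            np.all(self.stop - self.start == 1.0)
            and np.all(self.stop == np.floor(self.stop))
        )
        if self._daily:
            self._day = self.stop.astype(np.int64)
            self._nbins = int(self._day.max()) + 1
        # Suffix-cumsum machinery: risk set {start < t <= stop} at threshold t
        # equals {stop >= t} minus {start >= t} (stop > start guarantees the
        # second set is contained in the first).
        self._ord_stop = np.argsort(self.stop, kind="stable")
        self._ord_start = np.argsort(self.start, kind="stable")
        self._sorted_stop = self.stop[self._ord_stop]
        self._sorted_start = self.start[self._ord_start]
        ev = self.event.astype(bool)
        self.event_times = np.unique(self.stop[ev])
        # per-event-time weighted event count and weighted event covariate sum
        et_index = np.searchsorted(self.event_times, self.stop[ev])
        self._dw = np.zeros(len(self.event_times))
        np.add.at(self._dw, et_index, self.w[ev])
        self._sx = np.zeros((len(self.event_times), self._Xc.shape[1]))
        np.add.at(self._sx, et_index, self.w[ev, None] * self._Xc[ev])
        self._pos_stop = np.searchsorted(self._sorted_stop, self.event_times, "left")
        self._pos_start = np.searchsorted(self._sorted_start, self.event_times, "left")
        p = self._Xc.shape[1]
        iu = np.triu_indices(p)
        self._triu = iu

    def _suffix_at(self, values: np.ndarray) -> np.ndarray:
        """Risk-set sums of per-row ``values`` at every event time."""
        if self._daily:
            et = self.event_times.astype(np.int64)
            cols = [
                np.bincount(self._day, weights=values[:, j], minlength=self._nbins)[et]
                for j in range(values.shape[1])
            ]
            return np.column_stack(cols)
        out = []
        for order, pos in (
            (self._ord_stop, self._pos_stop),
            (self._ord_start, self._pos_start),
        ):
            v = values[order]
            suf = np.concatenate(
                [np.cumsum(v[::-1], axis=0)[::-1], np.zeros((1,) + v.shape[1:])]
            )
            out.append(suf[pos])
        return out[0] - out[1]

    def _risk_sums(self, beta: np.ndarray):
        eta = self._Xc @ beta
        r = np.exp(eta)
        wr = self.w * r
        wrx = wr[:, None] * self._Xc
        i, j = self._triu
        wrxx = wrx[:, i] * self._Xc[:, j]
        S0 = self._suffix_at(wr[:, None])[:, 0]
        S1 = self._suffix_at(wrx)
        S2p = self._suffix_at(wrxx)
        return wr, S0, S1, S2p

    def _loglik_only(self, beta: np.ndarray) -> float:
        eta = self._Xc @ beta
        wr = self.w * np.exp(eta)
        S0 = self._suffix_at(wr[:, None])[:, 0]
        if np.any(S0 <= 0):
            raise EstimationError("empty risk set at an event time")
        ev = self.event.astype(bool)
        return float((self.w[ev] * eta[ev]).sum() - (self._dw * np.log(S0)).sum())

    def fit(
        self,
        *,
        tol: float = 1e-8,
        max_iter: int = 100,
        max_halvings: int = 20,
    ) -> "WeightedCoxResults":
        """Maximize the weighted partial likelihood by Newton-Raphson."""
        p = self._Xc.shape[1]
        beta = np.zeros(p)
        ll = self._loglik_only(beta)
        ev = self.event.astype(bool)
        wx_events = (self.w[ev, None] * self._Xc[ev]).sum(axis=0)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            wr, S0, S1, S2p = self._risk_sums(beta)
            if np.any(S0 <= 0):
                raise EstimationError("empty risk set at an event time")
            m = S1 / S0[:, None]
            grad = wx_events - (self._dw[:, None] * m).sum(axis=0)
            i, j = self._triu
            V = np.zeros((len(self.event_times), p, p))
            V[:, i, j] = S2p / S0[:, None]
            V[:, j, i] = S2p / S0[:, None]
            V -= m[:, :, None] * m[:, None, :]
            hess = -(self._dw[:, None, None] * V).sum(axis=0)
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            new_beta, new_ll = beta + step, -np.inf
            for _ in range(max_halvings + 1):
                new_ll = self._loglik_only(new_beta)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    break
                step = step / 2.0
                new_beta = beta + step
            if not np.isfinite(new_ll):
                raise ConvergenceError("log partial likelihood diverged")
            beta, ll = new_beta, new_ll
            if np.max(np.abs(beta)) > 50:
                raise ConvergenceError(
                    "coefficients diverging (monotone likelihood / separation?)"
                )
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(|grad|_inf = {np.max(np.abs(grad)):.3g})"
            )
        if np.max(np.abs(beta)) > 15:
            # the gradient vanishes on the plateau of a monotone likelihood,
            # so a tiny gradient with an absurd coefficient is separation
            raise ConvergenceError(
                "coefficient magnitude > 15 at convergence: monotone partial "
                "likelihood (separation) suspected"
            )
        # Final quantities at beta-hat.
        wr, S0, S1, S2p = self._risk_sums(beta)
        m = S1 / S0[:, None]
        i, j = self._triu
        V = np.zeros((len(self.event_times), p, p))
        V[:, i, j] = S2p / S0[:, None]
        V[:, j, i] = S2p / S0[:, None]
        V -= m[:, :, None] * m[:, None, :]
        info = (self._dw[:, None, None] * V).sum(axis=0)
        dh_c = self._dw / S0  # centered-scale baseline increments
        shift = float(np.exp(-self._xbar @ beta))
        grid_max = int(np.ceil(self.stop.max()))
        H0 = np.zeros(grid_max + 1)
        day = np.minimum(np.ceil(self.event_times).astype(int), grid_max)
        np.add.at(H0, day, dh_c * shift)
        H0 = np.cumsum(H0)
        robust = self._robust_cov(beta, info, m, dh_c, grid_max)
        try:
            naive = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            naive = np.full((p, p), np.nan)
        return WeightedCoxResults(
            covariates=self.covariates,
            params=pd.Series(beta, index=self.covariates),
            baseline_cumulative_hazard=H0,
            log_likelihood=ll,
            n_iter=n_iter,
            converged=True,
            n_obs=len(self.X),
            n_events=int(self.event.sum()),
            naive_covariance=pd.DataFrame(
                naive, index=self.covariates, columns=self.covariates
            ),
            robust_covariance=pd.DataFrame(
                robust, index=self.covariates, columns=self.covariates
            ),
        )

    def _robust_cov(self, beta, info, m, dh_c, grid_max) -> np.ndarray:
        """Sandwich covariance from per-subject sums of weighted score
        residuals (weights are treated as fixed)."""
        p = self._Xc.shape[1]
        # Day-indexed cumulative centered baseline hazard and its
        # mean-covariate-weighted companion G(t) = sum_{s<=t} m(s) dH(s).
        Hc = np.zeros(grid_max + 1)
        G = np.zeros((grid_max + 1, p))
        day = np.minimum(np.ceil(self.event_times).astype(int), grid_max)
        np.add.at(Hc, day, dh_c)
        np.add.at(G, day, m * dh_c[:, None])
        Hc = np.cumsum(Hc)
        G = np.cumsum(G, axis=0)
        start_i = np.clip(self.start.astype(int), 0, grid_max)
        stop_i = np.clip(self.stop.astype(int), 0, grid_max)
        dH_row = Hc[stop_i] - Hc[start_i]
        dG_row = G[stop_i] - G[start_i]
        r = np.exp(self._Xc @ beta)
        U = -r[:, None] * (self._Xc * dH_row[:, None] - dG_row)
        ev = self.event.astype(bool)
        et_index = np.searchsorted(self.event_times, self.stop[ev])
        U[ev] += self._Xc[ev] - m[et_index]
        U *= self.w[:, None]
        groups = pd.DataFrame(U).groupby(pd.Series(self.ids)).sum().to_numpy()
        M = groups.T @ groups
        try:
            inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.full((p, p), np.nan)
        return inv @ M @ inv


class WeightedCoxResults:
    """Fitted weighted Cox model: coefficients, weighted Breslow baseline
    hazard on the daily grid, and convergence diagnostics."""

    def __init__(
        self,
        *,
        covariates,
        params,
        baseline_cumulative_hazard,
        log_likelihood,
        n_iter,
        converged,
        n_obs,
        n_events,
        naive_covariance=None,
        robust_covariance=None,
    ) -> None:
        self.covariates = list(covariates)
        self.params = params
        self.baseline_cumulative_hazard = np.asarray(
            baseline_cumulative_hazard, dtype=float
        )
        self.log_likelihood = log_likelihood
        self.n_iter = n_iter
        self.converged = converged
        self.n_obs = n_obs
        self.n_events = n_events
        self.naive_covariance = naive_covariance
        self.robust_covariance = robust_covariance

    # -- prediction ------------------------------------------------------

    def _design(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            missing = [c for c in self.covariates if c not in x.columns]
            if missing:
                raise SchemaError(f"missing covariates {missing}")
            return x[self.covariates].to_numpy(dtype=float)
        if isinstance(x, (dict, pd.Series)):
            try:
                return np.array([[float(x[c]) for c in self.covariates]])
            except KeyError as exc:
                raise SchemaError(f"missing covariate {exc}") from exc
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != len(self.covariates):
            raise SchemaError(
                f"expected {len(self.covariates)} covariates, got {arr.shape[1]}"
            )
        return arr

    def linear_predictor(self, x):
        """x beta-hat for a vector, mapping, or DataFrame of covariates."""
        lp = self._design(x) @ self.params.to_numpy()
        return lp if lp.size > 1 else float(lp[0])

    def cumulative_hazard_at(self, days) -> np.ndarray:
        """H0 evaluated at integer days, carried forward beyond the grid."""
        days = np.asarray(days, dtype=int)
        H0 = self.baseline_cumulative_hazard
        return H0[np.clip(days, 0, len(H0) - 1)]

    def predict_survival(self, x, horizon: int = 365):
        """Daily survival S(t|x) = exp(-H0(t) exp(x beta)), t = 1..horizon.

        Returns a Series (single subject) or DataFrame (rows = subjects)
        indexed by day.
        """
        X = self._design(x)
        lp = X @ self.params.to_numpy()
        days = np.arange(1, horizon + 1)
        H = self.cumulative_hazard_at(days)
        S = np.exp(-np.outer(np.exp(lp), H))
        if S.shape[0] == 1 and not isinstance(x, pd.DataFrame):
            return pd.Series(S[0], index=days, name="survival")
        idx = x.index if isinstance(x, pd.DataFrame) else None
        return pd.DataFrame(S, columns=days, index=idx)

    # -- reporting -------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Coefficient table with robust (sandwich) standard errors."""
        se = (
            np.sqrt(np.diag(self.robust_covariance.to_numpy()))
            if self.robust_covariance is not None
            else np.full(len(self.covariates), np.nan)
        )
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "robust se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "params": self.params.to_numpy().tolist(),
            "baseline_cumulative_hazard": self.baseline_cumulative_hazard.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedCoxResults":
        return cls(
            covariates=d["covariates"],
            params=pd.Series(d["params"], index=d["covariates"]),
            baseline_cumulative_hazard=np.asarray(d["baseline_cumulative_hazard"]),
            log_likelihood=d["log_likelihood"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            n_obs=d["n_obs"],
            n_events=d["n_events"],
        )

    @classmethod
    def from_json(cls, path) -> "WeightedCoxResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
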