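"""Waitlist registry data model.

A :class:`Registry` holds one row per wait-listed patient (listing day,
baseline covariates, terminal waitlist outcome, and — for transplanted
patients — post-transplant follow-up) together with an optional long-format
table of time-varying covariate updates.  The module provides CSV I/O,
data-driven eligibility filtering, expansion to the daily counting-process
format used by the pre-transplant analyses, and construction of the
one-row-per-patient post-transplant table.

Conventions
-----------
* Time is measured in integer days since listing; day 0 is the listing day.
* At-risk intervals are half-open ``(start, stop]`` with ``stop = start + 1``;
  events occur at ``stop``.
* Time-varying covariates are step functions: the value carried into
  interval ``(t-1, t]`` is the last update recorded at a day ``<= t - 1``.
* CSV dialect: UTF-8, comma separated, header row, ``NA`` for missing.
"""

from __future__ import annotations

import operator
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, SchemaError, ValidationError

OUTCOMES = ("death", "transplant", "censor")
POST_OUTCOMES = ("death", "censor")

#: Columns every registry table must carry; everything else is a covariate.
REQUIRED_COLUMNS = ("patient_id", "list_day", "outcome", "outcome_day")
OPTIONAL_COLUMNS = ("post_outcome", "post_outcome_day")

_NA = "NA"


@dataclass
class Registry:
    """A validated waitlist registry.

    Parameters
    ----------
    data
        One row per patient with the required columns above plus arbitrary
        covariate columns.
    tv
        Optional long table of time-varying covariate updates with columns
        ``patient_id, day, name, value``; update days must lie in
        ``[0, outcome_day)`` for the patient.
    """

    data: pd.DataFrame
    tv: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- structure -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        skip = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
        return [c for c in self.data.columns if c not in skip]

    @property
    def tv_names(self) -> list[str]:
        if self.tv is None or self.tv.empty:
            return []
        return sorted(self.tv["name"].unique())

    def validate(self) -> None:
        d = self.data
        for col in REQUIRED_COLUMNS:
            if col not in d.columns:
                raise SchemaError(f"registry is missing required column {col!r}")
        dup = d["patient_id"][d["patient_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                f"duplicate patient_id values: {sorted(set(dup.astype(str)))[:5]}"
            )
        problems: list[str] = []
        if (d["outcome_day"] < 1).any():
            bad = d.loc[d["outcome_day"] < 1, "patient_id"].tolist()[:5]
            problems.append(f"outcome_day < 1 for patients {bad}")
        if (d["list_day"] < 0).any():
            bad = d.loc[d["list_day"] < 0, "patient_id"].tolist()[:5]
            problems.append(f"list_day < 0 for patients {bad}")
        unknown = set(d["outcome"].unique()) - set(OUTCOMES)
        if unknown:
            problems.append(f"unknown outcome values {sorted(unknown)}")
        is_tx = d["outcome"].eq("transplant")
        if "post_outcome" in d.columns:
            has_post = d["post_outcome"].notna()
            if (is_tx != has_post).any():
                bad = d.loc[is_tx != has_post, "patient_id"].tolist()[:5]
                problems.append(
                    f"post-transplant fields must be present exactly for "
                    f"transplanted patients; offending ids {bad}"
                )
            if has_post.any() and (d.loc[has_post, "post_outcome_day"] < 1).any():
                problems.append("post_outcome_day < 1 for some transplanted patient")
        elif is_tx.any():
            problems.append("transplanted patients present but no post_outcome column")
        if problems:
            raise ValidationError("; ".join(problems))
        if self.tv is not None and len(self.tv):
            for col in ("patient_id", "day", "name", "value"):
                if col not in self.tv.columns:
                    raise SchemaError(f"tv table is missing column {col!r}")
            end = d.set_index("patient_id")["outcome_day"]
            tv_end = self.tv["patient_id"].map(end)
            if tv_end.isna().any():
                bad = self.tv.loc[tv_end.isna(), "patient_id"].unique()[:5]
                raise ValidationError(f"tv updates for unknown patients {list(bad)}")
            bad = (self.tv["day"] < 0) | (self.tv["day"] >= tv_end)
            if bad.any():
                raise ValidationError(
                    "tv update days must lie in [0, outcome_day); offending rows "
                    f"{self.tv.index[bad].tolist()[:5]}"
                )

    # -- I/O -------------------------------------------------------------

    def write(self, path, tv_path=None) -> None:
        self.data.to_csv(path, index=False, na_rep=_NA)
        if tv_path is not None and self.tv is not None:
            self.tv.to_csv(tv_path, index=False, na_rep=_NA)


def read_registry(path, tv_path=None, *, drop_relistings: bool = False) -> Registry:
    """Read a registry CSV (and optional time-varying covariate CSV).

    Malformed rows are reported with their file line numbers (the header is
    line 1).  A repeated ``patient_id`` is an integrity error unless
    ``drop_relistings`` is set, in which case the first record per id is kept
    as the initial registration and later records are dropped with a warning.
    """
    d = pd.read_csv(path, na_values=[_NA], keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in d.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    lines = pd.Series(np.arange(2, len(d) + 2), index=d.index)
    problems = []
    for col, kind in (("list_day", "listing day"), ("outcome_day", "outcome day")):
        bad = pd.to_numeric(d[col], errors="coerce").isna()
        for i in d.index[bad]:
            problems.append(f"line {lines[i]}: non-numeric {kind} {d.loc[i, col]!r}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    if d["patient_id"].duplicated().any():
        dups = sorted(set(d["patient_id"][d["patient_id"].duplicated()].astype(str)))
        if drop_relistings:
            warnings.warn(
                f"dropping re-listing records for ids {dups[:5]}; "
                "first record per id kept as the initial registration",
                stacklevel=2,
            )
            d = d[~d["patient_id"].duplicated()]
        else:
            raise IntegrityError(f"{path}: duplicate patient_id values {dups[:5]}")
    bad = d.index[d["outcome_day"].astype(float) < 1]
    if len(bad):
        raise ValidationError(
            f"{path}: outcome_day < 1 on lines {[int(lines[i]) for i in bad[:5]]}"
        )
    d["list_day"] = d["list_day"].astype(int)
    d["outcome_day"] = d["outcome_day"].astype(int)
    tv = None
    if tv_path is not None:
        tv = pd.read_csv(tv_path, na_values=[_NA], keep_default_na=False)
    return Registry(d, tv)


def write_registry(reg: Registry, path, tv_path=None) -> None:
    reg.write(path, tv_path)


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

_OPS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
    "!=": operator.ne,
}


@dataclass(frozen=True)
class Condition:
    covariate: str
    op: str
    value: object

    def evaluate(self, d: pd.DataFrame) -> pd.Series:
        if self.covariate not in d.columns:
            raise ConfigurationError(
                f"eligibility condition references unknown covariate {self.covariate!r}"
            )
        if self.op not in _OPS:
            raise ConfigurationError(f"unknown comparison operator {self.op!r}")
        col = d[self.covariate]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = _OPS[self.op](col, self.value)
        return out.fillna(False).astype(bool)


@dataclass(frozen=True)
class EligibilityRule:
    """A named exclusion rule: the conjunction of threshold conditions.

    A patient matching *all* conditions is excluded and logged.
    """

    name: str
    conditions: tuple[Condition, ...]

    def triggered(self, d: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=d.index)
        for c in self.conditions:
            mask &= c.evaluate(d)
        return mask


def standard_exclusions() -> list[EligibilityRule]:
    """The two stock contraindication rules shipped with the package:
    panel reactive antibodies above 90%, and restrictive disease
    (diagnosis group D) combined with height below five feet (60 in)."""
    return [
        EligibilityRule("pra_gt_90", (Condition("pra", ">", 90),)),
        EligibilityRule(
            "group_d_height_lt_5ft",
            (Condition("diag", "==", "D"), Condition("height_in", "<", 60)),
        ),
    ]


def apply_eligibility(
    reg: Registry, rules: list[EligibilityRule]
) -> tuple[Registry, pd.DataFrame]:
    """Drop patients triggering any rule; return the filtered registry and an
    exclusion log with one ``(patient_id, rule)`` row per trigger."""
    d = reg.data
    log_parts = []
    excluded = pd.Series(False, index=d.index)
    for rule in rules:
        hit = rule.triggered(d)
        excluded |= hit
        if hit.any():
            log_parts.append(
                pd.DataFrame(
                    {"patient_id": d.loc[hit, "patient_id"], "rule": rule.name}
                )
            )
    log = (
        pd.concat(log_parts, ignore_index=True)
        if log_parts
        else pd.DataFrame(columns=["patient_id", "rule"])
    )
    kept = d[~excluded].reset_index(drop=True)
    tv = reg.tv
    if tv is not None and len(tv):
        tv = tv[tv["patient_id"].isin(kept["patient_id"])].reset_index(drop=True)
    return Registry(kept, tv), log


# ---------------------------------------------------------------------------
# Counting-process expansion
# ---------------------------------------------------------------------------


def expand_daily(reg: Registry) -> pd.DataFrame:
    """Expand the registry to daily counting rows.

    Each patient contributes ``outcome_day`` rows ``(start, stop]`` with
    ``stop = start + 1``; the terminal event flag is set only on the last
    row.  Baseline covariates are repeated on every row; time-varying
    covariates are carried forward from the last update at a day
    ``<= start``.
    """
    d = reg.data
    counts = d["outcome_day"].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    idx = np.repeat(np.arange(len(d)), counts)
    offsets = np.repeat(np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    stop = np.arange(total, dtype=np.int64) - offsets + 1
    is_last = stop == counts[idx]
    outcome = d["outcome"].to_numpy()[idx]
    rows = pd.DataFrame(
        {
            "patient_id": d["patient_id"].to_numpy()[idx],
            "start": stop - 1,
            "stop": stop,
            "event_death": (is_last & (outcome == "death")).astype(np.int8),
            "event_transplant": (is_last & (outcome == "transplant")).astype(np.int8),
            "event_censor": (is_last & (outcome == "censor")).astype(np.int8),
        }
    )
    for c in reg.covariate_columns:
        rows[c] = d[c].to_numpy()[idx]
    _merge_tv(rows, reg, at_col="start")
    return rows


def _merge_tv(rows: pd.DataFrame, reg: Registry, at_col: str) -> None:
    """Attach time-varying covariate values carried forward to ``rows[at_col]``
    (in patient time), in place."""
    tv = reg.tv
    if tv is None or not len(tv):
        return
    order = rows[[at_col]].copy()
    order["_pos"] = np.arange(len(rows))
    order["patient_id"] = rows["patient_id"]
    left = order.sort_values(at_col, kind="stable")
    for name in reg.tv_names:
        upd = (
            tv.loc[tv["name"] == name, ["patient_id", "day", "value"]]
            .sort_values("day", kind="stable")
            .rename(columns={"value": name})
        )
        merged = pd.merge_asof(
            left,
            upd,
            left_on=at_col,
            right_on="day",
            by="patient_id",
            direction="backward",
        )
        vals = np.empty(len(rows), dtype=float)
        vals[merged["_pos"].to_numpy()] = merged[name].to_numpy(dtype=float)
        if name in rows.columns:  # baseline column provides the pre-update value
            base = rows[name].to_numpy(dtype=float)
            rows[name] = np.where(np.isnan(vals), base, vals)
        else:
            rows[name] = vals


def split_pre_post(reg: Registry) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the daily pre-transplant counting rows (all patients) and the
    one-row-per-patient post-transplant table (transplanted patients only).

    Post-transplant covariates are measured at the transplant day: baseline
    values plus time-varying covariates carried forward to transplant.
    """
    pre = expand_daily(reg)
    d = reg.data
    tx = d[d["outcome"].eq("transplant")].reset_index(drop=True)
    if "post_outcome" not in tx.columns:  # valid only when nobody is transplanted
        tx = tx.assign(post_outcome=pd.Series(dtype=object),
                       post_outcome_day=pd.Series(dtype=float))
    post = pd.DataFrame(
        {
            "patient_id": tx["patient_id"],
            "tx_day": tx["outcome_day"].astype(int),
            "time": tx["post_outcome_day"].astype(int) if len(tx) else
                    pd.Series(dtype=int),
            "event": tx["post_outcome"].eq("death").astype(np.int8),
        }
    )
    for c in reg.covariate_columns:
        post[c] = tx[c].to_numpy()
    if reg.tv is not None and len(reg.tv):
        post["_at"] = post["tx_day"] - 1  # value carried into the transplant interval
        sub = Registry.__new__(Registry)  # light view; skip re-validation
        sub.data = tx
        sub.tv = reg.tv[reg.tv["patient_id"].isin(tx["patient_id"])]
        _merge_tv(post, sub, at_col="_at")
        post = post.drop(columns=["_at"])
    return pre, post
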