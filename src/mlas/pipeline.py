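"""End-to-end modified-LAS pipeline as a model/results pair.

:class:`ModifiedLas` bundles the whole estimation chain over a validated
registry: daily counting-process expansion, the four discrete-time hazard
models behind the stabilized weights, the weighted ("modified") and
unweighted ("existing"-style) pre- and post-transplant Cox models, and LAS
scoring/ranking at offer dates.  ``fit()`` returns a
:class:`ModifiedLasResults` carrying all fitted artifacts.

The "existing"-style comparator is the identical pipeline with every weight
set to 1, which isolates exactly the contribution of the selection-bias
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Registry, split_pre_post
from .cox import WeightedCox, WeightedCoxResults
from .scoring import rank_patients, score_cohort
from .weights import (
    DiscreteHazard,
    post_transplant_weights,
    pre_transplant_weights,
    weight_diagnostics,
)

__all__ = ["LasConfig", "ModifiedLas", "ModifiedLasResults"]


@dataclass
class LasConfig:
    """Covariate lists and tuning knobs of the pipeline.

    ``outcome_covariates_*`` enter the Cox outcome models (follow-up time is
    never included there); ``weight_covariates`` enter the denominator
    selection models and may include time-varying covariates such as the
    severity ``z`` and geography; ``stabilizer_covariates`` (default none —
    intercept plus time only) enter the numerator models.
    """

    outcome_covariates_pre: list[str]
    outcome_covariates_post: list[str]
    weight_covariates: list[str]
    stabilizer_covariates: list[str] = field(default_factory=list)
    time_knots: int = 4
    truncation: tuple[float, float] | None = (1.0, 99.0)
    include_tx_day: bool = True
    horizon: int = 365


class ModifiedLas:
    """Selection-bias-corrected LAS model over a waitlist registry."""

    def __init__(self, registry: Registry, config: LasConfig) -> None:
        self.registry = registry
        self.config = config

    @classmethod
    def from_registry(cls, registry: Registry, config: LasConfig) -> "ModifiedLas":
        return cls(registry, config)

    def fit(self) -> "ModifiedLasResults":
        cfg = self.config
        rows, post = split_pre_post(self.registry)
        txp_den = DiscreteHazard(
            "transplant", cfg.weight_covariates, time_knots=cfg.time_knots
        ).fit(rows)
        cens_den = DiscreteHazard(
            "censor", cfg.weight_covariates, time_knots=cfg.time_knots
        ).fit(rows)
        txp_num = DiscreteHazard(
            "transplant", cfg.stabilizer_covariates, time_knots=cfg.time_knots
        ).fit(rows)
        cens_num = DiscreteHazard(
            "censor", cfg.stabilizer_covariates, time_knots=cfg.time_knots
        ).fit(rows)
        w_pre = pre_transplant_weights(
            rows, txp_den, cens_den, txp_num, cens_num, truncation=cfg.truncation
        )
        w_post = post_transplant_weights(
            rows,
            txp_den,
            cens_den,
            txp_num,
            cens_num,
            truncation=cfg.truncation,
            include_tx_day=cfg.include_tx_day,
        )
        rows = rows.merge(
            w_pre[["patient_id", "day", "weight"]],
            left_on=["patient_id", "stop"],
            right_on=["patient_id", "day"],
            how="left",
        ).drop(columns=["day"])
        post = post.merge(w_post[["patient_id", "weight"]], on="patient_id", how="left")

        def _cox(data, covs, weighted, **kw) -> WeightedCoxResults:
            return WeightedCox(
                data,
                covs,
                weight_col="weight" if weighted else None,
                id_col="patient_id",
                **kw,
            ).fit()

        pre_kw = dict(event_col="event_death", start_col="start", stop_col="stop")
        post_kw = dict(event_col="event", duration_col="time")
        return ModifiedLasResults(
            registry=self.registry,
            config=cfg,
            weight_models={
                "transplant_den": txp_den,
                "censor_den": cens_den,
                "transplant_num": txp_num,
                "censor_num": cens_num,
            },
            pre_weights=w_pre,
            post_weights=w_post,
            pre_weighted=_cox(rows, cfg.outcome_covariates_pre, True, **pre_kw),
            pre_unweighted=_cox(rows, cfg.outcome_covariates_pre, False, **pre_kw),
            post_weighted=_cox(post, cfg.outcome_covariates_post, True, **post_kw),
            post_unweighted=_cox(post, cfg.outcome_covariates_post, False, **post_kw),
        )


class ModifiedLasResults:
    """Everything the fitted pipeline produced."""

    def __init__(
        self,
        *,
        registry,
        config,
        weight_models,
        pre_weights,
        post_weights,
        pre_weighted,
        pre_unweighted,
        post_weighted,
        post_unweighted,
    ) -> None:
        self.registry = registry
        self.config = config
        self.weight_models = weight_models
        self.pre_weights = pre_weights
        self.post_weights = post_weights
        self.pre_weighted = pre_weighted
        self.pre_unweighted = pre_unweighted
        self.post_weighted = post_weighted
        self.post_unweighted = post_unweighted

    def fits(self, variant: str) -> tuple[WeightedCoxResults, WeightedCoxResults]:
        if variant == "modified":
            return self.pre_weighted, self.post_weighted
        if variant == "existing":
            return self.pre_unweighted, self.post_unweighted
        raise ValueError(f"unknown variant {variant!r}")

    def score(self, offer_day: int, variant: str = "modified") -> pd.DataFrame:
        pre, post = self.fits(variant)
        scored = score_cohort(
            self.registry,
            pre,
            post,
            offer_day,
            variant=variant,
            horizon=self.config.horizon,
        )
        return rank_patients(scored) if len(scored) else scored

    def weight_summary(self) -> pd.DataFrame:
        pre = weight_diagnostics(self.pre_weights)
        pre.insert(0, "weights", "pre")
        post = weight_diagnostics(self.post_weights)
        post.insert(0, "weights", "post")
        return pd.concat([pre, post], ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Side-by-side coefficient table of the four outcome models."""
        parts = []
        for model, res in (
            ("pre", self.pre_weighted),
            ("pre", self.pre_unweighted),
            ("post", self.post_weighted),
            ("post", self.post_unweighted),
        ):
            t = res.summary()
            t.insert(0, "model", model)
            t.insert(
                1,
                "variant",
                "modified" if res in (self.pre_weighted, self.post_weighted)
                else "existing",
            )
            parts.append(t)
        return pd.concat(parts)
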