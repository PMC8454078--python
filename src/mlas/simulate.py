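"""Synthetic waitlist simulator with counterfactual ground truth.

The generator emulates the causal structure that makes naive allocation
models biased: each patient carries baseline covariates (age, diagnosis
group A-D, BMI, region, plus PRA and height for the eligibility rules) and
a latent daily severity process Z(t) (Gaussian random walk).  On every day
on the waitlist the patient faces competing discrete hazards of death,
transplant and censoring, each logit-linear in covariates and current
severity.  When the transplant and censoring hazards load on Z, sicker
patients are preferentially removed from the waitlist — exactly the
dependent censoring / survivor-bias mechanism the weighted models are built
to correct.  Transplanted patients then face a post-transplant death hazard
of Cox form with known coefficients ``beta_post`` (including a severity
effect), so the full-population post-transplant law is known ground truth.

Counterfactual consistency: the no-transplant ("untreated") death day of
every patient is generated from the *same* severity path and the same
uniform death draws with the transplant and censoring hazards switched off,
so factual and counterfactual worlds agree up to the moment of removal.
All randomness flows from a single seed through named ``SeedSequence``
spawns, so each stage can be reproduced independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import Registry
from .errors import ConfigurationError, ValidationError

__all__ = [
    "HazardSpec",
    "PostSpec",
    "SimConfig",
    "TruthBundle",
    "preset",
    "simulate",
    "oracle_counterfactual",
]

#: engineered covariate columns written into the registry (besides raw ones)
ENGINEERED = [
    "age_s", "bmi_s", "diag_b", "diag_c", "diag_d",
    "region_e", "region_s", "region_w",
]


@dataclass
class HazardSpec:
    """Daily discrete hazard, logit-linear in engineered covariates and
    severity: p(day) = expit(logit(rate) + sum coef_k x_k + z_coef * Z)."""

    rate: float  # daily probability at covariates = 0, severity = 0
    coef: dict[str, float] = field(default_factory=dict)
    z_coef: float = 0.0

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), logit(self.rate))
        for name, c in self.coef.items():
            if name not in X.columns:
                raise ConfigurationError(f"hazard coefficient on unknown covariate {name!r}")
            lp = lp + c * X[name].to_numpy(dtype=float)
        return lp


@dataclass
class PostSpec:
    """Post-transplant Cox law: constant daily baseline hazard
    ``baseline_hazard`` multiplied by exp(x beta + z_coef * Z(t_tx))."""

    baseline_hazard: float
    coef: dict[str, float] = field(default_factory=dict)
    z_coef: float = 0.0


@dataclass
class SimConfig:
    n: int
    seed: int
    arrival_window: int = 180
    max_followup: int = 365
    post_horizon: int = 365
    death: HazardSpec = field(default_factory=lambda: HazardSpec(6e-4))
    transplant: HazardSpec = field(default_factory=lambda: HazardSpec(3.5e-3))
    censor: HazardSpec = field(default_factory=lambda: HazardSpec(4e-4))
    post: PostSpec = field(default_factory=lambda: PostSpec(4.5e-4))
    severity_init_sd: float = 1.0
    severity_drift: float = 0.002
    severity_step_sd: float = 0.08
    selection_strength: float = 1.0  # scales z_coef in transplant & censor hazards

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name, spec in (("death", self.death), ("transplant", self.transplant),
                           ("censor", self.censor)):
            if not 0.0 <= spec.rate < 1.0:
                raise ConfigurationError(f"{name} daily rate {spec.rate} outside [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, klass in (("death", HazardSpec), ("transplant", HazardSpec),
                           ("censor", HazardSpec), ("post", PostSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthBundle:
    """Ground truth accompanying a simulated registry."""

    cf_time: pd.Series  # counterfactual no-transplant follow-up (days, <= horizon)
    cf_event: pd.Series  # 1 = counterfactual death within the horizon
    beta_post: dict[str, float]
    post_z_coef: float
    config: SimConfig

    def population_survival(self, horizon: int | None = None) -> np.ndarray:
        """Counterfactual no-transplant survival of the whole cohort,
        S(t) for t = 1..horizon (no censoring before the horizon, so this
        is a simple proportion)."""
        horizon = horizon or self.config.max_followup
        death_day = np.where(self.cf_event.to_numpy() == 1,
                             self.cf_time.to_numpy(), np.inf)
        t = np.arange(1, horizon + 1)
        return (death_day[None, :] > t[:, None]).mean(axis=1)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_COMMON = dict(
    death=dict(rate=6e-4, coef={"age_s": 0.3, "diag_d": 0.5, "bmi_s": 0.1}, z_coef=0.8),
    post=dict(
        baseline_hazard=4.5e-4,
        coef={"age_s": 0.35, "diag_d": 0.5, "bmi_s": -0.1},
        z_coef=0.8,
    ),
)

_PRESETS = {
    # transplant and censoring independent of covariates and severity
    "no_selection": dict(
        transplant=dict(rate=3.5e-3),
        censor=dict(rate=4e-4),
        **_COMMON,
    ),
    # transplant strongly increasing in severity, diagnosis and region;
    # censoring dependent on severity (dependent censoring).  Effects are as
    # large as practical positivity allows: pushed much further, sick
    # patients are selected near-deterministically and no finite sample can
    # support the inverse weights (the estimand itself breaks down — which
    # is why positivity-threatened patients are excluded from waitlists
    # analyses in the first place).
    "strong_selection": dict(
        transplant=dict(
            rate=3.5e-3,
            coef={"age_s": -0.4, "diag_d": 0.6,
                  "region_e": 0.6, "region_s": -0.6, "region_w": 0.3},
            z_coef=0.6,
        ),
        censor=dict(rate=4e-4, z_coef=0.4),
        **_COMMON,
    ),
    # moderate severity effects; geography enters selection only
    "paper_like": dict(
        transplant=dict(
            rate=3.5e-3,
            coef={"region_e": 0.3, "region_s": -0.3, "region_w": 0.15},
            z_coef=0.5,
        ),
        censor=dict(rate=4e-4, z_coef=0.3),
        **_COMMON,
    ),
}


def preset(name: str, *, n: int, seed: int, **overrides) -> SimConfig:
    """Named study condition: ``no_selection``, ``strong_selection`` or
    ``paper_like``."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    spec = _PRESETS[name]
    cfg = SimConfig(
        n=n,
        seed=seed,
        death=HazardSpec(**spec["death"]),
        transplant=HazardSpec(**spec["transplant"]),
        censor=HazardSpec(**spec["censor"]),
        post=PostSpec(**spec["post"]),
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_baseline(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(55.0, 10.0, n), 18.0, 80.0)
    bmi = np.clip(rng.normal(25.0, 4.0, n), 15.0, 45.0)
    height = np.round(rng.normal(67.0, 4.0, n), 1)
    pra = np.round(rng.beta(0.8, 3.0, n) * 100.0, 1)
    diag = rng.choice(list("ABCD"), size=n, p=[0.35, 0.15, 0.15, 0.35])
    region = rng.choice(["N", "E", "S", "W"], size=n)
    d = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "diag": diag,
            "bmi": np.round(bmi, 1),
            "height_in": height,
            "pra": pra,
            "region": region,
        }
    )
    d["age_s"] = (d["age"] - 55.0) / 10.0
    d["bmi_s"] = (d["bmi"] - 25.0) / 4.0
    for g in "bcd":
        d[f"diag_{g}"] = d["diag"].eq(g.upper()).astype(float)
    for r in "esw":
        d[f"region_{r}"] = d["region"].eq(r.upper()).astype(float)
    return d


def _severity_paths(
    n: int, T: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    z = np.empty((n, T))
    z[:, 0] = rng.normal(0.0, cfg.severity_init_sd, n)
    steps = rng.normal(cfg.severity_drift, cfg.severity_step_sd, (n, T - 1))
    z[:, 1:] = z[:, [0]] + np.cumsum(steps, axis=1)
    return z


def _first_trigger(trig: np.ndarray, T: int) -> np.ndarray:
    """Index of first True along axis 1, or T when never triggered."""
    any_ = trig.any(axis=1)
    return np.where(any_, trig.argmax(axis=1), T)


def simulate(config: SimConfig) -> tuple[Registry, TruthBundle]:
    """Generate a waitlist cohort and its ground truth.

    Day-by-day competing draws per patient (priority death > transplant >
    censoring within a day); administrative censoring at ``max_followup``.
    The time-varying severity is emitted as tv covariate ``z`` with one
    update per day on the list.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    r_cov, r_z, r_events, r_post = (np.random.default_rng(s) for s in root.spawn(4))
    n, T = cfg.n, cfg.max_followup
    base = _draw_baseline(n, r_cov)
    list_day = r_cov.integers(0, cfg.arrival_window, n)
    z = _severity_paths(n, T, cfg, r_z)

    def _probs(spec: HazardSpec, z_scale: float = 1.0) -> np.ndarray:
        lp = spec.linear_predictor(base)[:, None] + (spec.z_coef * z_scale) * z
        return expit(lp)

    p_death = _probs(cfg.death)
    p_tx = _probs(cfg.transplant, cfg.selection_strength)
    p_cens = _probs(cfg.censor, cfg.selection_strength)
    u_death = r_events.random((n, T))
    u_tx = r_events.random((n, T))
    u_cens = r_events.random((n, T))
    f_death = _first_trigger(u_death < p_death, T)
    f_tx = _first_trigger(u_tx < p_tx, T)
    f_cens = _first_trigger(u_cens < p_cens, T)
    first = np.minimum.reduce([f_death, f_tx, f_cens])
    outcome = np.where(
        first >= T,
        "censor",
        np.where(f_death == first, "death",
                 np.where(f_tx == first, "transplant", "censor")),
    )
    outcome_day = np.minimum(first, T - 1) + 1
    outcome_day = np.where(first >= T, T, outcome_day)

    # counterfactual no-transplant world: same severity paths & death draws
    cf_event = (f_death < T).astype(int)
    cf_time = np.minimum(f_death + 1, T)

    d = base.copy()
    d.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    d.insert(1, "list_day", list_day)
    d["outcome"] = outcome
    d["outcome_day"] = outcome_day

    # post-transplant follow-up for transplanted patients
    is_tx = outcome == "transplant"
    post_outcome = np.full(n, np.nan, dtype=object)
    post_day = np.full(n, np.nan)
    if is_tx.any():
        idx = np.flatnonzero(is_tx)
        z_tx = z[idx, first[idx]]  # severity as of the transplant day
        lp = np.full(len(idx), np.log(cfg.post.baseline_hazard))
        for name, c in cfg.post.coef.items():
            lp += c * base[name].to_numpy(dtype=float)[idx]
        lp += cfg.post.z_coef * z_tx
        h = np.exp(lp)
        p = -np.expm1(-h)  # daily death probability under the Cox law
        days = r_post.geometric(np.clip(p, 1e-12, 1.0))
        died = days <= cfg.post_horizon
        post_outcome[idx] = np.where(died, "death", "censor")
        post_day[idx] = np.where(died, days, cfg.post_horizon)
    d["post_outcome"] = post_outcome
    d["post_outcome_day"] = post_day

    # daily severity as long-format tv updates (days 0 .. outcome_day - 1)
    counts = outcome_day.astype(np.int64)
    ridx = np.repeat(np.arange(n), counts)
    offsets = np.repeat(np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    day_col = np.arange(counts.sum(), dtype=np.int64) - offsets
    tv = pd.DataFrame(
        {
            "patient_id": d["patient_id"].to_numpy()[ridx],
            "day": day_col,
            "name": "z",
            "value": z[ridx, day_col],
        }
    )
    reg = Registry(d, tv)
    pid = d["patient_id"]
    truth = TruthBundle(
        cf_time=pd.Series(cf_time, index=pid, name="cf_time"),
        cf_event=pd.Series(cf_event, index=pid, name="cf_event"),
        beta_post=dict(cfg.post.coef),
        post_z_coef=cfg.post.z_coef,
        config=cfg,
    )
    return reg, truth


def oracle_counterfactual(
    config: SimConfig,
    covariates,
    *,
    n_paths: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """No-transplant survival curve S0(t), t = 1..max_followup, for one
    patient's engineered covariates.

    Transplant is forced to zero and censoring treated as non-informative.
    When severity feeds the death hazard the curve is a Monte-Carlo average
    over ``n_paths`` severity paths; with ``z_coef == 0`` the result equals
    the closed form (1 - p)^t (the Monte-Carlo paths all coincide).
    """
    cfg = config
    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence(cfg.seed).spawn(5)[-1]
    )
    x = pd.DataFrame([dict(covariates)])
    lp0 = float(cfg.death.linear_predictor(x)[0])
    T = cfg.max_followup
    if cfg.death.z_coef == 0.0:
        p = expit(lp0)
        return (1.0 - p) ** np.arange(1, T + 1)
    z = _severity_paths(n_paths, T, cfg, rng)
    p = expit(lp0 + cfg.death.z_coef * z)
    surv = np.cumprod(1.0 - p, axis=1)
    return surv.mean(axis=0)
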