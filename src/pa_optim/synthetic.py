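"""Synthetic cohorts with known data-generating truth.

Every downstream stage of the pipeline (Cox fitting, the S-learner, the
conditional inference tree, the inconsistency association) is exercised on
cohorts drawn here, where the individually optimal physical-activity (PA)
pattern is known exactly.

The data-generating model is a Weibull proportional-hazards model.  For
participant i with covariates x_i and PA pattern p, the survival function is

    S(t | x_i, p) = exp( -(t / scale)^shape * exp(lp_i(p)) ),

with linear predictor

    lp_i(p) = beta_main[p] + sum_j beta_main[j] * c(x_ij)
              + sum_j beta_interaction[p, j] * c(x_ij),

where c() centres continuous covariates at their specification mean (binary
covariates enter raw).  Event times are drawn by inverse transform, and
censoring is the minimum of an administrative horizon and a uniform dropout
time.  The true optimal pattern is the argmax of S(horizon | x, p) over the
four patterns, with ties broken toward the lower-MVPA pattern.

The observed pattern is assigned by a multinomial logit on the covariates,
so that pattern membership is confounded to a controllable degree, as in
any observational activity cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .accelerometry import (
    ActivityWeek,
    Cutpoints,
    MINUTES_PER_DAY,
    PAPattern,
    PATTERN_ORDER,
)

PATTERNS = [p.value for p in PATTERN_ORDER]


# ---------------------------------------------------------------------------
# Truth configuration
# ---------------------------------------------------------------------------

# ("binary", prevalence) or ("normal", mean, sd); the default set is the
# 14-covariate input space of the prediction model (PA pattern + 13 others).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 62.0, 8.0),
    "sex_male": ("binary", 0.48),
    "sedentary_min_day": ("normal", 480.0, 90.0),
    "smoking_current": ("binary", 0.10),
    "antihtn_med": ("binary", 0.25),
    "cancer": ("binary", 0.10),
    "diabetes": ("binary", 0.06),
    "mi": ("binary", 0.03),
    "stroke": ("binary", 0.02),
    "bp_hypertension": ("binary", 0.55),
    "waist_cm": ("normal", 90.0, 12.0),
    "glucose_mmol": ("normal", 5.0, 0.8),
    "hba1c_mmol_mol": ("normal", 36.0, 4.0),
}

# Log-hazard main effects (per unit for continuous covariates, which enter
# centred at their specification mean; reference pattern = baseline PA).
DEFAULT_BETA_MAIN: dict[str, float] = {
    "active_lpa": -0.70,
    "active_regular": -0.55,
    "active_ww": -0.46,
    "age": 0.07,
    "sex_male": 0.45,
    "sedentary_min_day": 0.0015,
    "smoking_current": 0.60,
    "antihtn_med": 0.25,
    "cancer": 0.70,
    "diabetes": 0.50,
    "mi": 0.50,
    "stroke": 0.80,
    "bp_hypertension": 0.20,
    "waist_cm": 0.010,
    "glucose_mmol": 0.08,
    "hba1c_mmol_mol": 0.02,
}

# Pattern x covariate log-hazard interactions.  The default set creates the
# heterogeneity structure the method is meant to detect: stroke makes every
# active pattern harmful (true optimum: baseline PA), diabetes pushes the
# optimum to light activity, sex and age shape the light-vs-MVPA and
# regular-vs-weekend-warrior boundaries.
DEFAULT_BETA_INTERACTION: dict[tuple[str, str], float] = {
    ("active_lpa", "stroke"): 0.90,
    ("active_regular", "stroke"): 1.20,
    ("active_ww", "stroke"): 1.20,
    ("active_regular", "diabetes"): 0.60,
    ("active_ww", "diabetes"): 0.60,
    ("active_lpa", "sex_male"): 0.45,
    ("active_ww", "age"): -0.035,
}

# Multinomial-logit observed-pattern assignment (reference: baseline PA).
# Intercepts approximate the observed pattern shares of a real high-BP
# accelerometer cohort (~18/18/21/44 %); covariate terms (applied to z-scored
# continuous and raw binary covariates, then scaled by confounding_strength)
# make observed membership depend on age, sex and stroke.
DEFAULT_ASSIGNMENT: dict[str, dict[str, float]] = {
    "active_lpa": {"intercept": 0.01, "sex_male": -0.30, "stroke": -0.50},
    "active_regular": {"intercept": 0.18, "age": -0.10, "stroke": -0.50},
    "active_ww": {"intercept": 0.90, "age": 0.10, "sex_male": 0.30, "stroke": -0.50},
}


@dataclass(frozen=True)
class TruthConfig:
    """Full specification of a synthetic cohort's data-generating truth."""

    n: int = 20_000
    covariate_spec: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    pattern_assignment: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ASSIGNMENT.items()}
    )
    confounding_strength: float = 1.0
    beta_main: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_MAIN))
    beta_interaction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_INTERACTION)
    )
    weibull_shape: float = 1.2
    weibull_scale: float = 80.0  # years; sized for a ~15% event fraction
    admin_horizon: float = 15.0  # years of administrative follow-up
    dropout_max: float = 40.0  # uniform dropout on (0, dropout_max) years
    horizon: float = 10.0  # evaluation horizon defining the true optimum
    cause_probs: Mapping[str, float] = field(
        default_factory=lambda: {"cvd": 0.35, "cancer": 0.35, "other": 0.30}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.horizon <= 0:
            raise ValueError("evaluation horizon must be positive")
        for name, spec in self.covariate_spec.items():
            kind = spec[0]
            if kind == "binary":
                if not 0.0 <= spec[1] <= 1.0:
                    raise ValueError(f"{name}: prevalence outside [0, 1]")
            elif kind == "normal":
                if spec[2] < 0:
                    raise ValueError(f"{name}: sd < 0")
            else:
                raise ValueError(f"{name}: unknown covariate kind {kind!r}")

    def with_(self, **kwargs) -> "TruthConfig":
        return replace(self, **kwargs)

    # -- config file round trip (YAML or JSON) -----------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "covariate_spec": {k: list(v) for k, v in self.covariate_spec.items()},
            "pattern_assignment": {k: dict(v) for k, v in self.pattern_assignment.items()},
            "confounding_strength": self.confounding_strength,
            "beta_main": dict(self.beta_main),
            "beta_interaction": {f"{p}:{c}": v for (p, c), v in self.beta_interaction.items()},
            "weibull_shape": self.weibull_shape,
            "weibull_scale": self.weibull_scale,
            "admin_horizon": self.admin_horizon,
            "dropout_max": self.dropout_max,
            "horizon": self.horizon,
            "cause_probs": dict(self.cause_probs),
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "TruthConfig":
        payload = dict(payload)
        payload["covariate_spec"] = {
            k: tuple(v) for k, v in payload["covariate_spec"].items()
        }
        payload["beta_interaction"] = {
            tuple(k.split(":", 1)): v for k, v in payload["beta_interaction"].items()
        }
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "TruthConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def continuous_means(self) -> dict[str, float]:
        return {
            k: v[1] for k, v in self.covariate_spec.items() if v[0] == "normal"
        }


def strong_heterogeneity_config(**kwargs) -> TruthConfig:
    """Truth in the strongly identifiable heterogeneity regime.

    Every interaction has |log-HR| >= 0.5 (except the per-year age slope,
    whose effect across one age SD is comparable) and the pattern contrasts
    at each decision boundary are wide, so a model fitted at n ~ 20,000
    recovers the individually optimal pattern for the vast majority of
    participants.  Structure: stroke makes all active patterns harmful,
    diabetes and female sex favour light activity, age moves the
    regular/weekend-warrior boundary.
    """
    beta_main = dict(DEFAULT_BETA_MAIN)
    beta_main.update({"active_lpa": -0.80, "active_regular": -0.50, "active_ww": -0.20})
    beta_interaction = {
        ("active_lpa", "stroke"): 1.00,
        ("active_regular", "stroke"): 1.20,
        ("active_ww", "stroke"): 1.20,
        ("active_regular", "diabetes"): 0.60,
        ("active_ww", "diabetes"): 0.60,
        ("active_lpa", "sex_male"): 0.60,
        ("active_ww", "age"): -0.050,
    }
    base = TruthConfig(beta_main=beta_main, beta_interaction=beta_interaction)
    return base.with_(**kwargs) if kwargs else base


def stroke_dominant_config(**kwargs) -> TruthConfig:
    """Truth in which stroke is the dominant driver of the optimum.

    Stroke history (prevalence raised to 15%) flips every active pattern to
    harmful, so stroke carries by far the strongest association with the
    optimal pattern; diabetes moves a further 5% to light activity.  Used
    to study whether the heterogeneity tree roots at the clinically
    dominant covariate.
    """
    beta_main = dict(DEFAULT_BETA_MAIN)
    beta_main.update({"active_lpa": -0.45, "active_regular": -0.70, "active_ww": -0.55})
    beta_interaction = {
        ("active_lpa", "stroke"): 0.90,
        ("active_regular", "stroke"): 1.20,
        ("active_ww", "stroke"): 1.20,
        ("active_regular", "diabetes"): 0.60,
        ("active_ww", "diabetes"): 0.60,
    }
    spec = dict(DEFAULT_COVARIATES)
    spec["stroke"] = ("binary", 0.15)
    base = TruthConfig(
        covariate_spec=spec, beta_main=beta_main, beta_interaction=beta_interaction
    )
    return base.with_(**kwargs) if kwargs else base


def no_interaction_config(**kwargs) -> TruthConfig:
    """Default truth with every pattern x covariate interaction removed.

    Under this homogeneous truth the most protective main effect
    (active regular by default) is optimal for everyone.
    """
    beta_main = dict(DEFAULT_BETA_MAIN)
    beta_main["active_ww"] = -0.50  # without the age interaction, a plain benefit
    base = TruthConfig(beta_main=beta_main, beta_interaction={})
    return base.with_(**kwargs) if kwargs else base


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Per-participant truth: linear predictors, true optimum, config."""

    lp: pd.DataFrame  # n x 4, columns = pattern values, centred linear predictors
    optimal: pd.Series  # true optimal pattern label per participant
    config: TruthConfig

    def true_survival(self, t: float) -> pd.DataFrame:
        """S(t) under each pattern from the known Weibull PH truth."""
        h0 = (t / self.config.weibull_scale) ** self.config.weibull_shape
        return np.exp(-h0 * np.exp(self.lp))


def true_optimal_pattern(surv: pd.DataFrame) -> pd.Series:
    """Argmax of survival over the four patterns, ties to lower MVPA.

    Iterating patterns in MVPA order and keeping strictly-greater survival
    means the lowest-MVPA pattern wins any exact tie.
    """
    best = pd.Series(PATTERNS[0], index=surv.index, dtype=object)
    best_val = surv[PATTERNS[0]].to_numpy().copy()
    for p in PATTERNS[1:]:
        v = surv[p].to_numpy()
        better = v > best_val
        best[better] = p
        best_val = np.where(better, v, best_val)
    return best.rename("true_optimal")


def _draw_covariates(config: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, spec in config.covariate_spec.items():
        if spec[0] == "binary":
            cols[name] = (rng.random(config.n) < spec[1]).astype(int)
        else:
            cols[name] = rng.normal(spec[1], spec[2], size=config.n)
    return pd.DataFrame(cols)


def linear_predictors(config: TruthConfig, covariates: pd.DataFrame) -> pd.DataFrame:
    """Centred true linear predictor under each of the four patterns."""
    means = config.continuous_means
    centred = covariates.copy()
    for name, mu in means.items():
        centred[name] = centred[name] - mu

    cov_lp = np.zeros(len(covariates))
    for name in covariates.columns:
        b = config.beta_main.get(name, 0.0)
        if b:
            cov_lp = cov_lp + b * centred[name].to_numpy()

    out = {}
    for p in PATTERNS:
        lp = cov_lp.copy()
        if p != PAPattern.BASELINE.value:
            lp = lp + config.beta_main.get(p, 0.0)
            for (pat, cov), b in config.beta_interaction.items():
                if pat == p and b:
                    lp = lp + b * centred[cov].to_numpy()
        out[p] = lp
    return pd.DataFrame(out, index=covariates.index)


def _assign_patterns(
    config: TruthConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    n = config.n
    util = np.zeros((n, len(PATTERNS)))
    for j, p in enumerate(PATTERNS[1:], start=1):
        coefs = dict(config.pattern_assignment.get(p, {}))
        u = np.full(n, coefs.pop("intercept", 0.0))
        for name, c in coefs.items():
            spec = config.covariate_spec[name]
            x = covariates[name].to_numpy(dtype=float)
            if spec[0] == "normal":
                x = (x - spec[1]) / (spec[2] if spec[2] > 0 else 1.0)
            u = u + config.confounding_strength * c * x
        util[:, j] = u
    util -= util.max(axis=1, keepdims=True)
    prob = np.exp(util)
    prob /= prob.sum(axis=1, keepdims=True)
    cum = prob.cumsum(axis=1)
    draw = rng.random(n)[:, None]
    idx = (draw > cum).sum(axis=1)
    return pd.Series([PATTERNS[i] for i in idx], index=covariates.index, name="pattern")


def generate_cohort(config: TruthConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a full synthetic cohort and its ground truth.

    Returns a participant table (covariates, observed pattern, follow-up
    ``time`` in years, ``event`` indicator, ``cause`` among events) and the
    :class:`SimTruth` oracle.  Bit-for-bit reproducible given config + seed.
    """
    rng = np.random.default_rng(config.seed)
    covariates = _draw_covariates(config, rng)
    pattern = _assign_patterns(config, covariates, rng)
    lp = linear_predictors(config, covariates)
    lp_obs = lp.to_numpy()[np.arange(config.n), [PATTERNS.index(p) for p in pattern]]

    # inverse-transform Weibull PH event times
    e = rng.exponential(size=config.n)
    T = config.weibull_scale * (e / np.exp(lp_obs)) ** (1.0 / config.weibull_shape)
    dropout = rng.uniform(0.0, config.dropout_max, size=config.n)
    C = np.minimum(config.admin_horizon, dropout)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)

    causes = list(config.cause_probs)
    cp = np.asarray([config.cause_probs[c] for c in causes], dtype=float)
    cp = cp / cp.sum()
    cause_idx = (rng.random(config.n)[:, None] > cp.cumsum()[None, :]).sum(axis=1)
    cause = np.where(event == 1, np.asarray(causes, dtype=object)[cause_idx], None)

    table = covariates.copy()
    table.insert(0, "participant_id", [f"P{i:06d}" for i in range(config.n)])
    table["pattern"] = pattern
    table["time"] = time
    table["event"] = event
    table["cause"] = cause

    truth = SimTruth(
        lp=lp,
        optimal=true_optimal_pattern(np.exp(-((config.horizon / config.weibull_scale) ** config.weibull_shape) * np.exp(lp))),
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Deviation world: hazard tied to (in)consistency with the true optimum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviationConfig:
    """A world where deviating from one's optimal pattern raises the hazard.

    A single "frail" indicator determines the true optimum: frail
    participants do best on baseline PA, everyone else on active regular.
    Observed patterns are assigned uniformly at random (a randomized-
    pattern world), and the hazard of anyone not following their optimum
    is multiplied by ``penalty_mvpa`` (optimum demands MVPA, i.e. the
    non-frail) or ``penalty_lpa`` (LPA-primary optimum, i.e. the frail).
    Because the optimum is driven by one binary, the interaction Cox model
    is exactly correctly specified and the true hazard ratios of the
    inconsistency contrasts equal the configured penalties.
    """

    n: int = 20_000
    frail_prevalence: float = 0.25
    beta_cov: Mapping[str, float] = field(
        default_factory=lambda: {"frail": 0.60, "age_z": 0.50, "sex_male": 0.30}
    )
    penalty_mvpa: float = 1.30  # HR of deviating when the optimum is regular
    penalty_lpa: float = 1.30  # HR of deviating when the optimum is baseline
    weibull_shape: float = 1.2
    weibull_scale: float = 70.0  # sized for a ~15% event fraction
    admin_horizon: float = 15.0
    dropout_max: float = 40.0
    horizon: float = 10.0
    cause_probs: Mapping[str, float] = field(
        default_factory=lambda: {"cvd": 0.35, "cancer": 0.35, "other": 0.30}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty_mvpa <= 0 or self.penalty_lpa <= 0:
            raise ValueError("penalties must be positive hazard ratios")
        if not 0.0 < self.frail_prevalence < 1.0:
            raise ValueError("frail prevalence must be in (0, 1)")


def generate_deviation_cohort(config: DeviationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a deviation-world cohort; returns (table, true optimal series)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    frail = (rng.random(n) < config.frail_prevalence).astype(int)
    age_z = rng.normal(size=n)
    sex = (rng.random(n) < 0.5).astype(int)
    optimal = np.where(frail == 1, PAPattern.BASELINE.value, PAPattern.ACTIVE_REGULAR.value)
    pattern = rng.choice(PATTERNS, size=n)
    deviates = pattern != optimal
    lp = (
        config.beta_cov["frail"] * frail
        + config.beta_cov["age_z"] * age_z
        + config.beta_cov["sex_male"] * sex
        + np.where(
            deviates,
            np.where(frail == 1, np.log(config.penalty_lpa), np.log(config.penalty_mvpa)),
            0.0,
        )
    )
    e = rng.exponential(size=n)
    T = config.weibull_scale * (e / np.exp(lp)) ** (1.0 / config.weibull_shape)
    C = np.minimum(config.admin_horizon, rng.uniform(0.0, config.dropout_max, size=n))
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    causes = list(config.cause_probs)
    cp = np.asarray([config.cause_probs[c] for c in causes], dtype=float)
    cp = cp / cp.sum()
    cause_idx = (rng.random(n)[:, None] > cp.cumsum()[None, :]).sum(axis=1)
    cause = np.where(event == 1, np.asarray(causes, dtype=object)[cause_idx], None)
    table = pd.DataFrame(
        {
            "participant_id": [f"D{i:06d}" for i in range(n)],
            "frail": frail,
            "age_z": age_z,
            "sex_male": sex,
            "pattern": pattern,
            "time": time,
            "event": event,
            "cause": cause,
        }
    )
    return table, pd.Series(optimal, name="true_optimal")


# ---------------------------------------------------------------------------
# Activity-week construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityTarget:
    """A weekly-summary target for constructive activity-week generation.

    ``top2_share`` must be exactly achievable in whole minutes, i.e.
    ``top2_share * mvpa_min_week`` integral; valid shares lie in
    [2/7, 1] for a 7-day week (an even spread puts 2/7 in the top 2 days).
    """

    mvpa_min_week: int = 0
    lpa_min_week: int = 0
    top2_share: float = 0.0
    wear_valid: bool = True

    def __post_init__(self) -> None:
        if self.mvpa_min_week < 0 or self.lpa_min_week < 0:
            raise ValueError("target minutes must be >= 0")
        if not 0.0 <= self.top2_share <= 1.0:
            raise ValueError("top2_share outside [0, 1]")


_WEEK_START = pd.Timestamp("2023-01-02 00:00:00")  # a Monday


def generate_activity_week(
    target: ActivityTarget,
    cutpoints: Cutpoints,
    seed: int = 0,
    participant_id: str = "P000000",
    protocol: str | None = None,
) -> ActivityWeek:
    """Emit a 7 x 1440-minute week realizing the target summary exactly.

    MVPA minutes are placed so the two weekend days hold exactly
    ``round(top2_share * mvpa_min_week)`` of them; worn sedentary minutes
    carry a small nonzero value so waist-dialect zero-run recoding does not
    fire.  With ``wear_valid=False`` the emitted week violates the relevant
    protocol rule (71 h of wear for the 72-h rule; <600 worn minutes every
    day for the 10-h-day rule).
    """
    protocol = protocol or {"nhanes": "nhanes", "wrist": "ukb"}[cutpoints.dialect]
    M, L = target.mvpa_min_week, target.lpa_min_week

    if M == 0:
        k = 0
        if target.top2_share not in (0.0,):
            raise ValueError("top2_share must be 0 when MVPA target is 0")
    else:
        k_float = target.top2_share * M
        k = int(round(k_float))
        if abs(k_float - k) > 1e-9:
            raise ValueError(
                f"top2_share {target.top2_share} not achievable in whole minutes "
                f"for {M} MVPA minutes"
            )

    # per-day wear minutes
    if target.wear_valid:
        wear_per_day = [MINUTES_PER_DAY] * 7
    elif protocol == "ukb":
        # 71 h worn in total (< 72 h), spread over all clock hours
        wear_per_day = [11 * 60] * 6 + [5 * 60]
    else:
        wear_per_day = [590] * 7  # no day reaches 600 worn minutes

    # per-day MVPA: weekend days (indices 5, 6) are the top-2 days
    rest = M - k
    if M > 0:
        weekend = [k - k // 2, k // 2]
        weekday = [rest // 5 + (1 if i < rest % 5 else 0) for i in range(5)]
        if rest and max(weekday) > weekend[1]:
            # a weekday would overtake a weekend day: the share is too low
            # to realize with the weekend as the top-2 days
            raise ValueError(
                f"top2_share {target.top2_share} too low to realize "
                f"({max(weekday)} weekday MVPA min vs {weekend[1]} weekend)"
            )
        mvpa_per_day = weekday + weekend
    else:
        mvpa_per_day = [0] * 7

    lpa_per_day = [L // 7 + (1 if i < L % 7 else 0) for i in range(7)]
    for d in range(7):
        if mvpa_per_day[d] + lpa_per_day[d] > wear_per_day[d]:
            raise ValueError("target minutes exceed available wear minutes")

    if cutpoints.dialect == "nhanes":
        v_sed, v_lpa, v_mvpa = 50.0, 500.0, 3000.0
    else:
        v_sed = cutpoints.sedentary_upper / 2.0
        v_lpa = (cutpoints.sedentary_upper + cutpoints.mvpa_lower) / 2.0
        v_mvpa = cutpoints.mvpa_lower * 1.5

    values = np.zeros(7 * MINUTES_PER_DAY)
    wear = np.zeros(7 * MINUTES_PER_DAY, dtype=bool)
    rng = np.random.default_rng(seed)
    for d in range(7):
        base = d * MINUTES_PER_DAY
        w = wear_per_day[d]
        if target.wear_valid or protocol != "ukb":
            wear_idx = np.arange(base, base + w)
        else:
            # spread worn hours across the clock so only the 72-h rule fails
            hours = rng.permutation(24)[: w // 60]
            wear_idx = np.concatenate([
                np.arange(base + h * 60, base + h * 60 + 60) for h in sorted(hours)
            ]) if w >= 60 else np.arange(base, base + w)
        wear[wear_idx] = True
        values[wear_idx] = v_sed
        active = np.concatenate([
            np.full(mvpa_per_day[d], v_mvpa),
            np.full(lpa_per_day[d], v_lpa),
        ])
        values[wear_idx[: len(active)]] = active

    data = pd.DataFrame(
        {
            "timestamp": _WEEK_START + pd.to_timedelta(np.arange(7 * MINUTES_PER_DAY), unit="min"),
            "value": values,
            "wear": wear,
        }
    )
    return ActivityWeek(participant_id=participant_id, data=data, dialect=cutpoints.dialect)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
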