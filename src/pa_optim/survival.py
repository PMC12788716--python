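"""The S-learner's single base learner and its evaluation.

The base learner is a multivariable Cox proportional-hazards model whose
design matrix contains the PA-pattern dummies (baseline PA as reference),
the LASSO-selected covariate main effects, and all second-order
pattern x covariate interaction terms.  Predicted survival is

    S(t | x, p) = exp( -H0(t) * exp(lp(x, p)) ),

with H0 the Breslow baseline cumulative hazard (a right-continuous step
function on the training event times) and lp the linear predictor at the
design origin (baseline pattern, continuous covariates at their training
means, binary covariates at 0).

Covariate selection uses a LASSO-penalized Cox model whose shrinkage
parameter is chosen by 10-fold cross-validated partial-likelihood deviance;
the pattern dummies are forced (penalty factor 0) so that the model can
always predict under all four patterns.  Stepwise backward elimination then
prunes interaction blocks and unsupported main effects by AIC (or a Wald
p-value rule), never removing a main effect while its interaction block
remains and never removing the pattern dummies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accelerometry import PAPattern, PATTERN_ORDER

NONREF_PATTERNS = [p.value for p in PATTERN_ORDER[1:]]


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------


def split_cohort(
    cohort: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, reproducible split into training and internal test sets."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(cohort)
    n_train = int(round(n * fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(f"n={n} too small to populate both sets at fraction {fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = cohort.iloc[perm[:n_train]].copy()
    test = cohort.iloc[perm[n_train:]].copy()
    return train, test


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def pattern_dummies(pattern: pd.Series | np.ndarray, override: str | None = None) -> pd.DataFrame:
    """Indicator columns for the three non-reference patterns."""
    if override is not None:
        n = len(pattern)
        out = {f"pattern[{p}]": np.full(n, 1.0 if p == override else 0.0) for p in NONREF_PATTERNS}
        return pd.DataFrame(out)
    pattern = pd.Series(np.asarray(pattern, dtype=object)).reset_index(drop=True)
    return pd.DataFrame(
        {f"pattern[{p}]": (pattern == p).astype(float) for p in NONREF_PATTERNS}
    )


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    interactions: Sequence[str] | None = None,
    centers: dict[str, float] | None = None,
    pattern_col: str = "pattern",
    pattern_override: str | None = None,
) -> pd.DataFrame:
    """Assemble pattern dummies + main effects + pattern x covariate products.

    ``interactions`` lists the covariates given a full interaction block
    (defaults to all of ``covariates``); ``centers`` maps covariate name to
    the training mean subtracted before entering the design.
    """
    if interactions is None:
        interactions = list(covariates)
    centers = centers or {}
    dummies = pattern_dummies(
        df[pattern_col] if pattern_override is None else np.empty(len(df), dtype=object),
        override=pattern_override,
    )
    dummies.index = df.index
    parts = [dummies]
    main = pd.DataFrame(index=df.index)
    for c in covariates:
        main[c] = df[c].to_numpy(dtype=float) - centers.get(c, 0.0)
    parts.append(main)
    inter = pd.DataFrame(index=df.index)
    for c in interactions:
        for p in NONREF_PATTERNS:
            inter[f"pattern[{p}]:{c}"] = dummies[f"pattern[{p}]"].to_numpy() * main[c].to_numpy()
    parts.append(inter)
    return pd.concat(parts, axis=1)


def continuous_centers(df: pd.DataFrame, covariates: Sequence[str]) -> dict[str, float]:
    """Training means for covariates that are not plain 0/1 indicators."""
    centers = {}
    for c in covariates:
        vals = df[c].dropna().unique()
        if not set(np.unique(vals)).issubset({0, 1, 0.0, 1.0}):
            centers[c] = float(df[c].mean())
    return centers


# ---------------------------------------------------------------------------
# Partial likelihood (Breslow ties) — used for cross-validated deviance
# ---------------------------------------------------------------------------


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-ties Cox log partial likelihood of a fixed linear predictor."""
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order].astype(bool), lp[order]
    r = np.exp(x)
    # risk-set sums: at_risk[i] = sum of r over j with t_j >= t_i
    at_risk = np.cumsum(r[::-1])[::-1]
    # Breslow: each event term uses the risk set at its own time; with ties,
    # all tied events share the denominator at the first index of the tie
    uniq, first = np.unique(t, return_index=True)
    denom_at_first = at_risk[first]
    denom = np.repeat(denom_at_first, np.diff(np.append(first, len(t))))
    return float(np.sum(x[e] - np.log(denom[e])))


# ---------------------------------------------------------------------------
# LASSO-Cox covariate selection
# ---------------------------------------------------------------------------


@dataclass
class LassoFit:
    alphas: np.ndarray
    cv_deviance: np.ndarray
    chosen_alpha: float
    selected: list[str]
    forced: list[str]
    fold_seed: int
    coefficients: pd.Series

    @property
    def all_terms(self) -> list[str]:
        return self.forced + self.selected


def select_covariates_lasso(
    training: pd.DataFrame,
    candidates: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    time_col: str = "time",
    event_col: str = "event",
    pattern_col: str = "pattern",
    n_alphas: int = 50,
) -> LassoFit:
    """LASSO-penalized Cox selection with CV-deviance-minimizing lambda.

    Candidate covariates are standardized internally; the PA-pattern
    dummies carry penalty factor 0 and are therefore always retained.  The
    cross-validated deviance is the glmnet-style quantity
    D(lambda) = -2 * sum_folds [ pl_full(beta^(-f)) - pl_train(beta^(-f)) ].
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    time = training[time_col].to_numpy(dtype=float)
    event = training[event_col].to_numpy(dtype=int)
    if event.sum() < folds:
        raise ValueError(f"need >= {folds} events for {folds}-fold CV")

    keep, dropped = [], []
    for c in candidates:
        if training[c].nunique() < 2:
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        import warnings

        warnings.warn(f"dropping constant candidates: {dropped}")
    candidates = keep

    dummies = pattern_dummies(training[pattern_col].reset_index(drop=True))
    Xc = training[candidates].to_numpy(dtype=float)
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.column_stack([dummies.to_numpy(), (Xc - mu) / sd])
    names = list(dummies.columns) + list(candidates)
    penalty = np.array([0.0] * dummies.shape[1] + [1.0] * len(candidates))
    y = Surv.from_arrays(event.astype(bool), time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, penalty_factor=penalty, alpha_min_ratio=0.01
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(alphas))
    count = np.zeros(len(alphas), dtype=int)
    for tr_idx, _ in kf.split(X):
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, penalty_factor=penalty, alpha_min_ratio=0.01
        )
        m.fit(X[tr_idx], y[tr_idx])
        for j, a in enumerate(np.asarray(m.alphas_)):
            a_i = int(np.argmin(np.abs(alphas - a)))
            beta = m.coef_[:, j]
            pl_full = cox_partial_loglik(X @ beta, time, event)
            pl_tr = cox_partial_loglik(X[tr_idx] @ beta, time[tr_idx], event[tr_idx])
            dev[a_i] += -2.0 * (pl_full - pl_tr)
            count[a_i] += 1

    valid = count == folds  # only alphas every fold actually fitted
    dev_valid = np.where(valid, dev, np.inf)
    best = int(np.argmin(dev_valid))
    chosen = float(alphas[best])
    beta_full = pd.Series(path.coef_[:, best], index=names)
    selected = [c for c in candidates if abs(beta_full[c]) > 1e-10]
    return LassoFit(
        alphas=alphas,
        cv_deviance=dev,
        chosen_alpha=chosen,
        selected=selected,
        forced=list(dummies.columns),
        fold_seed=seed,
        coefficients=beta_full,
    )


# ---------------------------------------------------------------------------
# The interaction Cox model
# ---------------------------------------------------------------------------


def _breslow_baseline(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimator of H0 at the design origin; returns (times, cumhaz)."""
    order = np.argsort(time, kind="stable")
    t, e, r = time[order], event[order].astype(bool), np.exp(lp[order])
    at_risk = np.cumsum(r[::-1])[::-1]
    uniq, first = np.unique(t, return_index=True)
    denom = at_risk[first]
    deaths = np.zeros(len(uniq))
    idx = np.searchsorted(uniq, t[e])
    np.add.at(deaths, idx, 1.0)
    keep = deaths > 0
    h = deaths[keep] / denom[keep]
    return uniq[keep], np.cumsum(h)


@dataclass
class CoxInteractionModel:
    """A fitted Cox model with PA-pattern main effects and interactions."""

    covariates: list[str]
    interactions: list[str]  # covariates carrying a full pattern-interaction block
    terms: list[str]
    beta: pd.Series
    se: pd.Series
    centers: dict[str, float]
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    ties: str = "efron"
    log_likelihood: float = float("nan")
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    def design(self, df: pd.DataFrame, pattern: str | None = None) -> pd.DataFrame:
        d = build_design(
            df,
            self.covariates,
            interactions=self.interactions,
            centers=self.centers,
            pattern_override=pattern,
        )
        return d[self.terms]

    def linear_predictor(self, df: pd.DataFrame, pattern: str | None = None) -> np.ndarray:
        return self.design(df, pattern).to_numpy() @ self.beta.to_numpy()

    def cumulative_hazard(self, t: float | np.ndarray) -> np.ndarray:
        """H0(t): right-continuous step function, H0(0) = 0."""
        idx = np.searchsorted(self.baseline_times, np.atleast_1d(t), side="right")
        H = np.concatenate([[0.0], self.baseline_cumhaz])
        return H[idx]

    def predict_survival(
        self, df: pd.DataFrame, pattern: str | None = None, t: float = 10.0
    ) -> np.ndarray:
        """S(t | x, pattern); warns (via metadata flag) outside training support."""
        if t < 0:
            raise ValueError("t must be >= 0")
        lp = self.linear_predictor(df, pattern)
        H0 = self.cumulative_hazard(float(t))[0]
        return np.exp(-H0 * np.exp(lp))

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "covariates": self.covariates,
            "interactions": self.interactions,
            "terms": self.terms,
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "centers": self.centers,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "ties": self.ties,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CoxInteractionModel":
        import os

        if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, (str, bytes)):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        return cls(
            covariates=payload["covariates"],
            interactions=payload["interactions"],
            terms=payload["terms"],
            beta=pd.Series(payload["beta"]).reindex(payload["terms"]),
            se=pd.Series(payload["se"]).reindex(payload["terms"]),
            centers={k: float(v) for k, v in payload["centers"].items()},
            baseline_times=np.asarray(payload["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(payload["baseline_cumhaz"], dtype=float),
            ties=payload.get("ties", "efron"),
            log_likelihood=payload.get("log_likelihood", float("nan")),
            converged=payload.get("converged", True),
            metadata=payload.get("metadata", {}),
        )


def fit_interaction_cox(
    training: pd.DataFrame,
    covariates: Sequence[str],
    interactions: Sequence[str] | None = None,
    time_col: str = "time",
    event_col: str = "event",
    pattern_col: str = "pattern",
) -> CoxInteractionModel:
    """Fit the interaction Cox model by Efron partial likelihood.

    All second-order pattern x covariate interactions are included unless a
    narrower ``interactions`` list is given.  The Breslow baseline
    cumulative hazard is computed on the training event times at the design
    origin (baseline pattern, centred continuous covariates, binaries 0).
    """
    from lifelines import CoxPHFitter

    covariates = list(covariates)
    if interactions is None:
        interactions = list(covariates)
    centers = continuous_centers(training, covariates)
    design = build_design(
        training, covariates, interactions=interactions, centers=centers,
        pattern_col=pattern_col,
    )
    n_events = int(training[event_col].sum())
    if n_events < design.shape[1]:
        raise ValueError(
            f"{n_events} events < {design.shape[1]} model terms: model not identifiable"
        )
    df = design.copy()
    df["__time"] = training[time_col].to_numpy(dtype=float)
    df["__event"] = training[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, "__time", "__event")  # lifelines uses the Efron tie correction

    beta = cph.params_.reindex(design.columns)
    lp = design.to_numpy() @ beta.to_numpy()
    bt, bh = _breslow_baseline(df["__time"].to_numpy(), df["__event"].to_numpy(), lp)
    return CoxInteractionModel(
        covariates=covariates,
        interactions=list(interactions),
        terms=list(design.columns),
        beta=beta,
        se=cph.standard_errors_.reindex(design.columns),
        centers=centers,
        baseline_times=bt,
        baseline_cumhaz=bh,
        ties="efron",
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        metadata={"n": len(training), "events": n_events},
    )


def backward_eliminate(
    training: pd.DataFrame,
    model: CoxInteractionModel,
    criterion: str = "aic",
    alpha: float = 0.05,
    time_col: str = "time",
    event_col: str = "event",
    pattern_col: str = "pattern",
) -> CoxInteractionModel:
    """Stepwise backward elimination of interaction blocks and main effects.

    Removable units are (a) a covariate's whole pattern-interaction block
    and (b) a covariate main effect once its block is gone; the pattern
    dummies are never removed.  With ``criterion="aic"`` the step removing
    the most AIC is taken until no removal improves AIC; with
    ``criterion="wald"`` the least significant removable unit (block Wald
    test) is dropped while its p-value exceeds ``alpha``.  The elimination
    trace is stored in the returned model's metadata.
    """
    from scipy import stats

    if criterion not in ("aic", "wald"):
        raise ValueError("criterion must be 'aic' or 'wald'")

    current = model
    mains = list(model.covariates)
    inters = list(model.interactions)
    trace: list[dict] = []

    def refit(m: list[str], i: list[str]) -> CoxInteractionModel:
        return fit_interaction_cox(
            training, m, interactions=i,
            time_col=time_col, event_col=event_col, pattern_col=pattern_col,
        )

    while True:
        units: list[tuple[str, str]] = [("interaction", c) for c in inters]
        units += [("main", c) for c in mains if c not in inters]
        if not units:
            break
        if criterion == "aic":
            best_aic, best_unit, best_model = current.aic, None, None
            for kind, c in units:
                m2 = [x for x in mains if not (kind == "main" and x == c)]
                i2 = [x for x in inters if not (kind == "interaction" and x == c)]
                cand = refit(m2, i2)
                if cand.aic < best_aic - 1e-9:
                    best_aic, best_unit, best_model = cand.aic, (kind, c), cand
            if best_unit is None:
                break
        else:
            worst_p, best_unit = alpha, None
            for kind, c in units:
                if kind == "interaction":
                    cols = [f"pattern[{p}]:{c}" for p in NONREF_PATTERNS]
                else:
                    cols = [c]
                b = current.beta[cols].to_numpy()
                s = current.se[cols].to_numpy()
                # block Wald approximation with a diagonal covariance
                stat = float(np.sum((b / s) ** 2))
                p = float(stats.chi2.sf(stat, df=len(cols)))
                if p > worst_p:
                    worst_p, best_unit = p, (kind, c)
            if best_unit is None:
                break
            kind, c = best_unit
            if kind == "interaction":
                inters = [x for x in inters if x != c]
            else:
                mains = [x for x in mains if x != c]
            best_model = refit(mains, inters)
        if criterion == "aic":
            kind, c = best_unit
            if kind == "interaction":
                inters = [x for x in inters if x != c]
            else:
                mains = [x for x in mains if x != c]
        trace.append({"removed": f"{best_unit[0]}:{best_unit[1]}", "aic": best_model.aic})
        current = best_model

    current.metadata = dict(current.metadata, elimination_trace=trace, criterion=criterion)
    return current


def predict_survival(
    model: CoxInteractionModel,
    covariates: pd.DataFrame,
    pattern: str | PAPattern,
    t: float,
) -> np.ndarray:
    """Counterfactual survival probability under the named pattern."""
    p = pattern.value if isinstance(pattern, PAPattern) else pattern
    # the reference level simply zeroes all pattern dummies
    return model.predict_survival(covariates, pattern=p, t=t)


# ---------------------------------------------------------------------------
# Evaluation: IPCW Brier score, time-dependent AUC, calibration
# ---------------------------------------------------------------------------


@dataclass
class MetricResult:
    value: float
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")


@dataclass
class EvaluationResult:
    horizon: float
    brier: MetricResult
    auc: MetricResult
    calibration: pd.DataFrame  # per-decile predicted vs KM-observed risk


def _surv_arrays(time, event):
    from sksurv.util import Surv

    return Surv.from_arrays(np.asarray(event, dtype=bool), np.asarray(time, dtype=float))


def brier_score(
    surv_prob: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t: float,
    n_boot: int = 0,
    seed: int = 0,
) -> MetricResult:
    """IPCW (censoring-adjusted) Brier score at horizon ``t``.

    ``surv_prob`` are predicted survival probabilities at ``t``.  The
    censoring distribution is a Kaplan-Meier estimate on the same sample.
    A seeded bootstrap supplies the optional percentile CI.
    """
    from sksurv.metrics import brier_score as _sksurv_brier

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    surv_prob = np.asarray(surv_prob, dtype=float)
    y = _surv_arrays(time, event)
    _, bs = _sksurv_brier(y, y, surv_prob, [t])
    est = float(bs[0])
    if n_boot <= 0:
        return MetricResult(est)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(time)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = _surv_arrays(time[idx], event[idx])
        try:
            _, b = _sksurv_brier(yb, yb, surv_prob[idx], [t])
            vals.append(float(b[0]))
        except ValueError:
            continue
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return MetricResult(est, float(lo), float(hi))


def time_dependent_auc(
    risk_score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t: float,
    n_boot: int = 0,
    seed: int = 0,
) -> MetricResult:
    """Cumulative/dynamic IPCW AUC at horizon ``t`` (Uno's estimator).

    Cases are subjects with an observed event by ``t``; controls are those
    still at risk after ``t``; case contributions are weighted by the
    inverse censoring survival.  Higher ``risk_score`` must mean higher
    risk (e.g. 1 - predicted survival).
    """
    from sksurv.metrics import cumulative_dynamic_auc

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk_score = np.asarray(risk_score, dtype=float)
    if not ((event == 1) & (time <= t)).any():
        raise ValueError("no cases by the horizon")
    if not (time > t).any():
        raise ValueError("no controls beyond the horizon")
    y = _surv_arrays(time, event)
    auc, _ = cumulative_dynamic_auc(y, y, risk_score, [t])
    est = float(auc[0])
    if n_boot <= 0:
        return MetricResult(est)
    rng = np.random.default_rng(seed)
    vals = []
    n = len(time)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if not ((event[idx] == 1) & (time[idx] <= t)).any() or not (time[idx] > t).any():
            continue
        yb = _surv_arrays(time[idx], event[idx])
        try:
            a, _ = cumulative_dynamic_auc(yb, yb, risk_score[idx], [t])
            vals.append(float(a[0]))
        except ValueError:
            continue
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return MetricResult(est, float(lo), float(hi))


def calibration_bins(
    surv_prob: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    t: float,
    bins: int = 10,
) -> pd.DataFrame:
    """Deciles of predicted risk vs Kaplan-Meier observed risk at ``t``."""
    from lifelines import KaplanMeierFitter

    risk = 1.0 - np.asarray(surv_prob, dtype=float)
    df = pd.DataFrame({"risk": risk, "time": time, "event": event})
    df["bin"] = pd.qcut(df["risk"], q=bins, labels=False, duplicates="drop")
    rows = []
    for b, grp in df.groupby("bin"):
        km = KaplanMeierFitter()
        km.fit(grp["time"], grp["event"])
        observed = 1.0 - float(km.predict(t))
        rows.append(
            {"bin": int(b), "n": len(grp), "predicted_risk": grp["risk"].mean(),
             "observed_risk": observed}
        )
    return pd.DataFrame(rows)


def evaluate_model(
    model: CoxInteractionModel,
    test: pd.DataFrame,
    horizons: Iterable[float] = (5.0, 10.0),
    n_boot: int = 200,
    seed: int = 0,
    time_col: str = "time",
    event_col: str = "event",
) -> list[EvaluationResult]:
    """Brier, AUC and calibration of the model on a held-out set."""
    results = []
    time = test[time_col].to_numpy(dtype=float)
    event = test[event_col].to_numpy(dtype=int)
    for t in horizons:
        sp = model.predict_survival(test, pattern=None, t=t)
        results.append(
            EvaluationResult(
                horizon=float(t),
                brier=brier_score(sp, time, event, t, n_boot=n_boot, seed=seed),
                auc=time_dependent_auc(1.0 - sp, time, event, t, n_boot=n_boot, seed=seed),
                calibration=calibration_bins(sp, time, event, t),
            )
        )
    return results
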