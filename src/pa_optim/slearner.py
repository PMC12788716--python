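"""The S-learner: counterfactual survival under each PA pattern.

A single Cox base learner that includes the PA pattern as a feature is
evaluated four times per participant, varying only the pattern input.
Differences between the four predicted survival probabilities capture the
heterogeneous association of activity pattern with mortality, and the
pattern attaining the highest predicted survival at the decision horizon is
the individually optimal recommendation.  Exact ties are broken toward the
pattern demanding less MVPA (baseline < active LPA < active regular <
active weekend warrior) — the conservative recommendation.

Participants whose observed pattern differs from the predicted optimum are
"inconsistent", subdivided by whether the predicted optimum demands more
MVPA (optimal regular/weekend-warrior) or is LPA-primary (optimal active
LPA, and by this package's convention also optimal baseline).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accelerometry import PAPattern, PATTERN_ORDER
from .survival import CoxInteractionModel

PATTERNS = [p.value for p in PATTERN_ORDER]
SURV_COLS = {p: f"s_{p}" for p in PATTERNS}


class ConsistencyClass(str, enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT_MVPA = "inconsistent_mvpa"
    INCONSISTENT_LPA = "inconsistent_lpa"


@dataclass(frozen=True)
class CounterfactualProfile:
    """One participant's predicted survival under each of the four patterns."""

    participant_id: str
    horizon: float
    survival: dict[str, float]  # pattern value -> S(horizon)
    optimal: PAPattern
    margin: float  # best minus second-best survival, >= 0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if abs(self.survival[self.optimal.value] - max(self.survival.values())) > 1e-12:
            raise ValueError("optimal does not attain the maximum survival")


def _argmax_low_mvpa(surv: np.ndarray) -> np.ndarray:
    """Column argmax over the 4 patterns with ties to the lower-MVPA column.

    ``surv`` is (n, 4) in MVPA order; scanning in order and keeping strictly
    greater values makes the lowest-MVPA pattern win exact ties.
    """
    best = np.zeros(len(surv), dtype=int)
    best_val = surv[:, 0].copy()
    for j in range(1, surv.shape[1]):
        better = surv[:, j] > best_val
        best[better] = j
        best_val = np.where(better, surv[:, j], best_val)
    return best


def counterfactual_table(
    model: CoxInteractionModel,
    covariates: pd.DataFrame,
    t: float = 10.0,
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Counterfactual profiles for a whole cohort (vectorised).

    Returns one row per participant with the four survival probabilities
    at ``t``, the predicted optimal pattern and the decision margin.
    """
    surv = np.column_stack(
        [model.predict_survival(covariates, pattern=p, t=t) for p in PATTERNS]
    )
    best = _argmax_low_mvpa(surv)
    sorted_desc = np.sort(surv, axis=1)[:, ::-1]
    margin = sorted_desc[:, 0] - sorted_desc[:, 1]
    out = pd.DataFrame(
        {SURV_COLS[p]: surv[:, j] for j, p in enumerate(PATTERNS)},
        index=covariates.index,
    )
    if id_col in covariates.columns:
        out.insert(0, id_col, covariates[id_col].to_numpy())
    out["optimal"] = np.asarray(PATTERNS, dtype=object)[best]
    out["margin"] = margin
    out["horizon"] = t
    return out


def counterfactual_profile(
    model: CoxInteractionModel,
    covariates: pd.DataFrame | dict,
    t: float = 10.0,
    participant_id: str = "",
) -> CounterfactualProfile:
    """Single-participant convenience wrapper around the vectorised table."""
    if isinstance(covariates, dict):
        covariates = pd.DataFrame([covariates])
    row = counterfactual_table(model, covariates.head(1), t=t).iloc[0]
    surv = {p: float(row[SURV_COLS[p]]) for p in PATTERNS}
    return CounterfactualProfile(
        participant_id=participant_id or str(row.get("participant_id", "")),
        horizon=t,
        survival=surv,
        optimal=PAPattern(row["optimal"]),
        margin=float(row["margin"]),
    )


def heterogeneous_effect(
    profile: CounterfactualProfile | pd.DataFrame,
    pattern_a: str | PAPattern,
    pattern_b: str | PAPattern,
) -> float | np.ndarray:
    """Survival difference S_A(t) - S_B(t); antisymmetric in (A, B)."""
    a = pattern_a.value if isinstance(pattern_a, PAPattern) else pattern_a
    b = pattern_b.value if isinstance(pattern_b, PAPattern) else pattern_b
    if isinstance(profile, CounterfactualProfile):
        return profile.survival[a] - profile.survival[b]
    return profile[SURV_COLS[a]].to_numpy() - profile[SURV_COLS[b]].to_numpy()


def consistency_labels(
    observed: pd.Series | np.ndarray,
    optimal: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Binary and three-level consistency labels for a cohort.

    Consistent iff observed == predicted optimal; otherwise the three-level
    class depends on the *predicted* optimum: inconsistent-MVPA when it is
    regular/weekend-warrior, inconsistent-LPA when it is active-LPA or
    baseline (the baseline cell is LPA-primary by package convention).
    """
    obs = pd.Series(np.asarray(observed, dtype=object)).reset_index(drop=True)
    opt = pd.Series(np.asarray(optimal, dtype=object)).reset_index(drop=True)
    if len(obs) != len(opt):
        raise ValueError("observed and optimal must align")
    consistent = obs == opt
    needs_mvpa = opt.isin([PAPattern.ACTIVE_REGULAR.value, PAPattern.ACTIVE_WW.value])
    three = np.where(
        consistent,
        ConsistencyClass.CONSISTENT.value,
        np.where(
            needs_mvpa,
            ConsistencyClass.INCONSISTENT_MVPA.value,
            ConsistencyClass.INCONSISTENT_LPA.value,
        ),
    )
    return pd.DataFrame(
        {
            "inconsistent": (~consistent).astype(int).to_numpy(),
            "consistency_class": three,
        }
    )


def label_cohort(
    model: CoxInteractionModel,
    cohort: pd.DataFrame,
    t: float = 10.0,
    pattern_col: str = "pattern",
) -> pd.DataFrame:
    """Attach counterfactual profiles and consistency labels to a cohort."""
    prof = counterfactual_table(model, cohort, t=t)
    labels = consistency_labels(cohort[pattern_col], prof["optimal"])
    labels.index = cohort.index
    out = pd.concat([cohort, prof.drop(columns=["participant_id"], errors="ignore"), labels], axis=1)
    return out.loc[:, ~out.columns.duplicated()]
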