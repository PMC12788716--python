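"""Cohort construction: high blood-pressure classification, inclusion and
exclusion accounting, and covariate-reliability statistics.

High BP follows the elevated-BP-and-hypertension convention of recent
European guidance: any of SBP >= 120 mm Hg, DBP >= 70 mm Hg, a
hospitalization record, or antihypertensive medication qualifies; among the
qualifying, SBP 120-139 or DBP 70-89 without medication (and below the
140/90 hypertension line) is *elevated BP*, everything else *hypertension*.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class BPClass(str, enum.Enum):
    ELEVATED = "elevated"
    HYPERTENSION = "hypertension"


@dataclass(frozen=True)
class BPStatus:
    high_bp: bool
    bp_class: BPClass | None = None

    def __post_init__(self) -> None:
        if self.high_bp != (self.bp_class is not None):
            raise ValueError("bp_class must be set iff high_bp")


def classify_bp(
    sbp: float,
    dbp: float,
    meds: bool = False,
    hospitalization: bool = False,
) -> BPStatus:
    """Classify one participant's blood-pressure status.

    ``high_bp`` iff SBP >= 120 or DBP >= 70 or medication or hospitalization.
    Among high-BP participants, *elevated* requires pressure in the
    120-139 / 70-89 band with neither value at hypertension level and no
    antihypertensive medication; all other high-BP states are hypertension.
    """
    has_sbp = sbp is not None and not (isinstance(sbp, float) and math.isnan(sbp))
    has_dbp = dbp is not None and not (isinstance(dbp, float) and math.isnan(dbp))
    if not (has_sbp and has_dbp):
        if meds or hospitalization:
            return BPStatus(high_bp=True, bp_class=BPClass.HYPERTENSION)
        raise ValueError("missing SBP/DBP with no medication or hospitalization flag")
    if not (sbp > dbp > 0):
        raise ValueError(f"implausible pressures sbp={sbp}, dbp={dbp}")

    high = sbp >= 120 or dbp >= 70 or meds or hospitalization
    if not high:
        return BPStatus(high_bp=False)
    in_band = (120 <= sbp <= 139) or (70 <= dbp <= 89)
    elevated = in_band and not meds and sbp < 140 and dbp < 90
    return BPStatus(True, BPClass.ELEVATED if elevated else BPClass.HYPERTENSION)


def classify_bp_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised convenience wrapper; returns 'normal'/'elevated'/'hypertension'."""
    out = []
    for row in df.itertuples(index=False):
        s = classify_bp(
            getattr(row, "sbp"),
            getattr(row, "dbp"),
            bool(getattr(row, "meds", False)),
            bool(getattr(row, "hospitalization", False)),
        )
        out.append(s.bp_class.value if s.high_bp else "normal")
    return pd.Series(out, index=df.index, name="bp_class")


# ---------------------------------------------------------------------------
# Inclusion / exclusion
# ---------------------------------------------------------------------------

EXCLUSION_STEPS = ("poor_calibration", "inadequate_wear", "not_high_bp", "missing_values")


def apply_inclusion(
    cohort: pd.DataFrame,
    required_columns: list[str] | None = None,
    calibration_col: str = "calibration_ok",
    wear_col: str = "wear_valid",
    high_bp_col: str = "high_bp",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study-flow exclusions in order and account for every row.

    Steps (each participant is counted once, at the first failing step):
    poor device calibration -> inadequate wear time -> not high BP ->
    missing outcome/covariate values.  The returned ledger's step counts
    plus the retained count always sum to the input count.
    """
    required_columns = required_columns or []
    remaining = cohort
    ledger: dict[str, int] = {}

    fail_cal = ~remaining[calibration_col].fillna(False).astype(bool)
    ledger["poor_calibration"] = int(fail_cal.sum())
    remaining = remaining[~fail_cal]

    fail_wear = ~remaining[wear_col].fillna(False).astype(bool)
    ledger["inadequate_wear"] = int(fail_wear.sum())
    remaining = remaining[~fail_wear]

    fail_bp = ~remaining[high_bp_col].fillna(False).astype(bool)
    ledger["not_high_bp"] = int(fail_bp.sum())
    remaining = remaining[~fail_bp]

    if required_columns:
        fail_missing = remaining[required_columns].isna().any(axis=1)
    else:
        fail_missing = pd.Series(False, index=remaining.index)
    ledger["missing_values"] = int(fail_missing.sum())
    remaining = remaining[~fail_missing]

    ledger["retained"] = len(remaining)
    return remaining.copy(), ledger


# ---------------------------------------------------------------------------
# Reliability statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityResult:
    variable: str
    statistic: str  # "ICC" or "kappa"
    estimate: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.estimate > 1 + 1e-12:
            raise ValueError(f"{self.statistic} cannot exceed 1")


def icc(pairs: np.ndarray | pd.DataFrame, variable: str = "") -> ReliabilityResult:
    """ICC(2,1): two-way single-measure absolute-agreement reliability.

    ``pairs`` holds one row per subject and one column per measurement
    occasion (two repeated measurements of the same continuous variable).
    Computed via pingouin's ANOVA-based estimator.
    """
    import pingouin as pg

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("pairs must be an (n, k>=2) array of repeated measurements")
    mask = ~np.isnan(arr).any(axis=1)
    arr = arr[mask]
    n, k = arr.shape
    if n < 2:
        raise ValueError("need >= 2 complete pairs")
    if np.all(arr == arr[:, [0]]):
        # identical repeated measurements: perfect agreement by construction
        return ReliabilityResult(variable, "ICC", 1.0, n)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": arr.ravel(),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # exact fits divide by 0
        res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    est = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    return ReliabilityResult(variable, "ICC", est, n)


def cohens_kappa(table: np.ndarray | pd.DataFrame, variable: str = "") -> ReliabilityResult:
    """Unweighted Cohen kappa from a K x K contingency table of counts.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed diagonal
    proportion and p_e the chance agreement implied by the marginals.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    if (t < 0).any():
        raise ValueError("table counts must be nonnegative")
    total = t.sum()
    if total <= 0:
        raise ValueError("empty table")
    p = t / total
    p_o = np.trace(p)
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if abs(1.0 - p_e) < 1e-15:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return ReliabilityResult(variable, "kappa", float(kappa), int(total))
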