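"""Mortality associations of inconsistent PA patterns.

Multivariable Cox models estimate the hazard ratio of following a pattern
other than the predicted individually optimal one ("inconsistent"), both as
a binary contrast and as the three-level contrast (consistent reference,
inconsistent-MVPA, inconsistent-LPA), with a subgroup harness for the
observed-nonbaseline stratum and a sensitivity harness re-running the
labelling + Cox stage under alternative cohorts, cause-specific outcomes,
truncated follow-up and the internal test split.

The adjustment set is the LASSO-selected covariates, excluding the observed
PA pattern itself: the exposure label is a deterministic function of the
pattern and the covariates, so adjusting for the pattern would absorb the
contrast of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .accelerometry import PAPattern
from .slearner import ConsistencyClass


@dataclass(frozen=True)
class AssociationResult:
    contrast: str  # e.g. "inconsistent vs consistent"
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    events: int
    adjustment: tuple[str, ...] = ()
    subgroup: str = "all"
    outcome: str = "all-cause"

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hr <= self.ci_upper):
            raise ValueError("CI must bracket the HR")
        if self.hr <= 0:
            raise ValueError("HR must be positive")

    @property
    def significant(self) -> bool:
        return not (self.ci_lower <= 1.0 <= self.ci_upper)


def _drop_collinear(
    df: pd.DataFrame, exposure_cols: Sequence[str], adjustment: Sequence[str]
) -> list[str]:
    """Drop adjustment columns linearly dependent on the exposure columns.

    A derived exposure label can coincide exactly with an adjustment
    covariate inside a subgroup; such columns are removed (with a warning)
    rather than letting the partial likelihood become singular.
    """
    import warnings

    kept: list[str] = []
    basis = df[list(exposure_cols)].to_numpy(dtype=float)
    basis = np.column_stack([np.ones(len(df)), basis])
    for c in adjustment:
        x = df[c].to_numpy(dtype=float)
        resid = x - basis @ np.linalg.lstsq(basis, x, rcond=None)[0]
        if np.var(resid) < 1e-12 * max(1.0, np.var(x)):
            warnings.warn(f"adjustment covariate {c!r} collinear with exposure; dropped")
            continue
        kept.append(c)
        basis = np.column_stack([basis, x])
    return kept


def _cox_hr(
    df: pd.DataFrame,
    exposure_cols: Sequence[str],
    adjustment: Sequence[str],
    time_col: str,
    event_col: str,
) -> pd.DataFrame:
    from lifelines import CoxPHFitter

    adjustment = _drop_collinear(df, exposure_cols, adjustment)
    cols = list(exposure_cols) + list(adjustment)
    work = df[cols].astype(float).copy()
    work["__time"] = df[time_col].to_numpy(dtype=float)
    work["__event"] = df[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(work, "__time", "__event")
    s = cph.summary
    return s.loc[list(exposure_cols), ["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]


def fit_inconsistency_cox(
    cohort: pd.DataFrame,
    adjustment: Sequence[str],
    outcome: str = "all-cause",
    levels: Sequence[int] = (2, 3),
    time_col: str = "time",
    event_col: str = "event",
    subgroup: str = "all",
) -> list[AssociationResult]:
    """HRs for the binary and/or three-level inconsistency contrasts.

    Requires ``inconsistent`` (0/1) and ``consistency_class`` columns as
    produced by the S-learner labelling; "consistent" is the reference of
    the three-level contrast.
    """
    results: list[AssociationResult] = []
    n = len(cohort)
    events = int(cohort[event_col].sum())
    if events < 10:
        raise ValueError("need >= 10 events")
    adjustment = [a for a in adjustment if a in cohort.columns]

    if 2 in levels:
        if cohort["inconsistent"].nunique() < 2:
            raise ValueError("empty exposure stratum for the binary contrast")
        tab = _cox_hr(cohort, ["inconsistent"], adjustment, time_col, event_col)
        hr, lo, hi, p = tab.iloc[0]
        results.append(
            AssociationResult(
                "inconsistent vs consistent", hr, lo, hi, p, n, events,
                tuple(adjustment), subgroup, outcome,
            )
        )
    if 3 in levels:
        work = cohort.copy()
        for cls in (ConsistencyClass.INCONSISTENT_MVPA, ConsistencyClass.INCONSISTENT_LPA):
            work[cls.value] = (work["consistency_class"] == cls.value).astype(int)
        expo = [ConsistencyClass.INCONSISTENT_MVPA.value, ConsistencyClass.INCONSISTENT_LPA.value]
        present = [e for e in expo if work[e].sum() > 0]
        if not present:
            raise ValueError("no inconsistent strata present")
        tab = _cox_hr(work, present, adjustment, time_col, event_col)
        for e in present:
            hr, lo, hi, p = tab.loc[e]
            results.append(
                AssociationResult(
                    f"{e} vs consistent", hr, lo, hi, p, n, events,
                    tuple(adjustment), subgroup, outcome,
                )
            )
    return results


def subgroup_analysis(
    cohort: pd.DataFrame,
    adjustment: Sequence[str],
    outcome: str = "all-cause",
    pattern_col: str = "pattern",
    **kwargs,
) -> list[AssociationResult]:
    """Three-level contrast refit within the observed-nonbaseline stratum."""
    sub = cohort[cohort[pattern_col] != PAPattern.BASELINE.value]
    if sub.empty:
        raise ValueError("empty nonbaseline subgroup")
    return fit_inconsistency_cox(
        sub, adjustment, outcome=outcome, levels=(3,), subgroup="nonbaseline", **kwargs
    )


def sort_by_hr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Forest-plot presentation order: rows sorted by hazard ratio."""
    return sorted(results, key=lambda r: r.hr)


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "hr": r.hr,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p_value": r.p_value,
                "n": r.n,
                "events": r.events,
                "subgroup": r.subgroup,
                "outcome": r.outcome,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Sensitivity harness
# ---------------------------------------------------------------------------


@dataclass
class SensitivityReport:
    scenarios: dict[str, list[AssociationResult]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        frames = []
        for name, res in self.scenarios.items():
            f = results_frame(res)
            f.insert(0, "scenario", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _cause_specific(df: pd.DataFrame, cause: str, event_col: str, cause_col: str) -> pd.DataFrame:
    """Treat deaths from other causes as censored at their event time."""
    out = df.copy()
    out[event_col] = ((df[event_col] == 1) & (df[cause_col] == cause)).astype(int)
    return out


def _truncate(df: pd.DataFrame, t_star: float, time_col: str, event_col: str) -> pd.DataFrame:
    out = df.copy()
    over = out[time_col] > t_star
    out.loc[over, time_col] = t_star
    out.loc[over, event_col] = 0
    return out


def sensitivity_suite(
    cohort: pd.DataFrame,
    adjustment: Sequence[str],
    alternate_cohort: pd.DataFrame | None = None,
    causes: Sequence[str] = ("cvd", "cancer"),
    truncate_at: float | None = None,
    test_ids: Sequence[str] | None = None,
    time_col: str = "time",
    event_col: str = "event",
    cause_col: str = "cause",
    id_col: str = "participant_id",
) -> SensitivityReport:
    """Re-run the labelling + Cox association under prespecified variations.

    Scenarios: (a) an alternate labelled cohort, (b) cause-specific
    mortality with competing causes censored, (c) administratively
    truncated follow-up, (d) the internal test split.  A scenario whose
    required columns are absent is skipped with a logged reason.
    """
    report = SensitivityReport()

    def run(name: str, df: pd.DataFrame, outcome: str = "all-cause", **kw) -> None:
        try:
            res = fit_inconsistency_cox(
                df, adjustment, outcome=outcome, time_col=time_col,
                event_col=event_col, **kw,
            )
            res += subgroup_analysis(
                df, adjustment, outcome=outcome, time_col=time_col, event_col=event_col
            )
            report.scenarios[name] = res
        except (ValueError, KeyError) as exc:
            report.skipped[name] = str(exc)

    if alternate_cohort is not None:
        run("alternate_cohort", alternate_cohort)
    else:
        report.skipped["alternate_cohort"] = "no alternate cohort supplied"

    if cause_col in cohort.columns:
        for cause in causes:
            run(
                f"cause_specific:{cause}",
                _cause_specific(cohort, cause, event_col, cause_col),
                outcome=f"{cause}-specific",
            )
    else:
        report.skipped["cause_specific"] = f"missing column {cause_col!r}"

    if truncate_at is not None:
        run(f"truncated:{truncate_at:g}", _truncate(cohort, truncate_at, time_col, event_col))
    else:
        report.skipped["truncated"] = "no truncation horizon supplied"

    if test_ids is not None:
        sub = cohort[cohort[id_col].isin(list(test_ids))]
        run("internal_test_split", sub)
    else:
        report.skipped["internal_test_split"] = "no test ids supplied"

    return report


def forest_plot(results: list[AssociationResult], path=None):
    """Minimal forest plot of HRs with 95% CIs, sorted by HR."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sort_by_hr(results)
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(rows) + 1.5))
    ys = np.arange(len(rows))
    for y, r in zip(ys, rows):
        ax.plot([r.ci_lower, r.ci_upper], [y, y], "-", color="steelblue")
        ax.plot(r.hr, y, "s", color="darkblue")
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.contrast} [{r.subgroup}, {r.outcome}]" for r in rows])
    ax.set_xlabel("hazard ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
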