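"""Accelerometer-derived physical-activity exposure processing.

Turns per-minute device output into validated weekly summaries and one of
four physical-activity (PA) pattern labels:

* ``ACTIVE_WW`` (weekend warrior): >=150 min/week MVPA with >=50% of it
  accumulated in the two highest-MVPA calendar days,
* ``ACTIVE_REGULAR``: >=150 min/week MVPA, spread more evenly,
* ``ACTIVE_LPA``: <150 min/week MVPA but >=1900 min/week light PA,
* ``BASELINE``: below both thresholds (low activity, not necessarily
  sedentary).

Two device dialects are supported: waist-worn counts/min (NHANES-style,
with the conventional <100 / >=2020 cpm cut-points) and wrist-worn
milligravity, for which intensity cut-points must be supplied explicitly —
this package does not ship a wrist activity classifier, so any wrist
analysis must state its cut-point configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

#: weekly MVPA minutes at or above which a participant counts as "active"
MVPA_ACTIVE_MIN = 150.0
#: weekly light-PA minutes at or above which a low-MVPA week is "active LPA"
LPA_ACTIVE_MIN = 1900.0
#: share of weekly MVPA in the top-2 days defining the weekend-warrior pattern
WW_TOP2_SHARE = 0.5


class PAPattern(str, enum.Enum):
    """The four PA patterns, ordered from least to most MVPA-demanding."""

    BASELINE = "baseline"
    ACTIVE_LPA = "active_lpa"
    ACTIVE_REGULAR = "active_regular"
    ACTIVE_WW = "active_ww"

    @property
    def mvpa_rank(self) -> int:
        return _PATTERN_ORDER.index(self)

    @property
    def requires_mvpa(self) -> bool:
        """Whether the pattern demands >=150 weekly MVPA minutes."""
        return self in (PAPattern.ACTIVE_REGULAR, PAPattern.ACTIVE_WW)


#: canonical low-to-high MVPA ordering, also the deterministic tie-break order
_PATTERN_ORDER = [
    PAPattern.BASELINE,
    PAPattern.ACTIVE_LPA,
    PAPattern.ACTIVE_REGULAR,
    PAPattern.ACTIVE_WW,
]

PATTERN_ORDER: tuple[PAPattern, ...] = tuple(_PATTERN_ORDER)


@dataclass(frozen=True)
class Cutpoints:
    """Intensity cut-points for one device dialect.

    A worn minute with value ``v`` is sedentary when ``v < sedentary_upper``,
    light when ``sedentary_upper <= v < mvpa_lower`` and MVPA when
    ``v >= mvpa_lower``.
    """

    dialect: str  # "nhanes" (counts/min, waist) or "wrist" (milligravity)
    sedentary_upper: float
    mvpa_lower: float

    def __post_init__(self) -> None:
        if self.dialect not in ("nhanes", "wrist"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not 0 < self.sedentary_upper < self.mvpa_lower:
            raise ValueError("cut-points must satisfy 0 < sedentary_upper < mvpa_lower")

    @classmethod
    def nhanes(cls) -> "Cutpoints":
        """Waist counts/min: sedentary <100, LPA 100-2019, MVPA >=2020."""
        return cls(dialect="nhanes", sedentary_upper=100.0, mvpa_lower=2020.0)

    @classmethod
    def wrist(cls, sedentary_upper: float, mvpa_lower: float) -> "Cutpoints":
        """Wrist milligravity cut-points; no packaged default is provided."""
        return cls(dialect="wrist", sedentary_upper=sedentary_upper, mvpa_lower=mvpa_lower)

    def metadata(self) -> dict:
        return {
            "dialect": self.dialect,
            "sedentary_upper": self.sedentary_upper,
            "mvpa_lower": self.mvpa_lower,
        }


@dataclass
class ActivityWeek:
    """One participant-week of per-minute device output.

    ``data`` has columns ``timestamp`` (datetime64, strictly increasing),
    ``value`` (counts/min or milligravity, >= 0) and ``wear`` (bool).
    """

    participant_id: str
    data: pd.DataFrame
    dialect: str = "nhanes"

    def __post_init__(self) -> None:
        required = {"timestamp", "value", "wear"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"ActivityWeek data missing columns {sorted(missing)}")
        if len(self.data) > MINUTES_PER_WEEK:
            raise ValueError("more than 10,080 minute records in one week")
        if len(self.data) and (self.data["value"].to_numpy() < 0).any():
            raise ValueError("negative activity values")
        ts = pd.to_datetime(self.data["timestamp"]).to_numpy()
        if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)


INTENSITY_LABELS = ("nonwear", "sedentary", "lpa", "mvpa")


def classify_minutes(week: ActivityWeek, cutpoints: Cutpoints) -> pd.Series:
    """Assign each minute an intensity label under the dialect cut-points.

    Every worn minute receives exactly one of {sedentary, lpa, mvpa};
    non-worn minutes are labelled nonwear.
    """
    if cutpoints.dialect != week.dialect:
        raise ValueError(
            f"cut-point dialect {cutpoints.dialect!r} != week dialect {week.dialect!r}"
        )
    values = week.data["value"].to_numpy(dtype=float)
    worn = week.data["wear"].to_numpy(dtype=bool)
    labels = np.full(len(values), "nonwear", dtype=object)
    labels[worn & (values < cutpoints.sedentary_upper)] = "sedentary"
    labels[worn & (values >= cutpoints.sedentary_upper) & (values < cutpoints.mvpa_lower)] = "lpa"
    labels[worn & (values >= cutpoints.mvpa_lower)] = "mvpa"
    return pd.Series(labels, index=week.data.index, name="intensity")


def _nhanes_calibration_mask(values: np.ndarray, worn: np.ndarray) -> np.ndarray:
    """Recode runs of >60 consecutive zero-count worn minutes as nonwear.

    Mirrors the waist-device convention that long zero runs indicate the
    monitor was not actually worn (poor calibration / nonwear).
    """
    worn = worn.copy()
    zero_worn = worn & (values == 0)
    n = len(values)
    i = 0
    while i < n:
        if zero_worn[i]:
            j = i
            while j < n and zero_worn[j]:
                j += 1
            if j - i > 60:
                worn[i:j] = False
            i = j
        else:
            i += 1
    return worn


def wear_valid(week: ActivityWeek, protocol: str) -> bool:
    """Evaluate wear-time validity under the named study protocol.

    * ``"ukb"``: total worn time >= 72 h AND every one of the 24 clock hours
      has at least one worn minute (pooled over days).
    * ``"nhanes"``: at least one day with >= 600 worn minutes, after runs of
      more than 60 consecutive zero-count worn minutes are recoded nonwear.
    """
    if len(week) == 0:
        raise ValueError("empty activity week")
    ts = pd.to_datetime(week.data["timestamp"])
    worn = week.data["wear"].to_numpy(dtype=bool)
    if protocol == "ukb":
        if worn.sum() < 72 * 60:
            return False
        hours_covered = ts.dt.hour.to_numpy()[worn]
        return len(np.unique(hours_covered)) == 24
    if protocol == "nhanes":
        values = week.data["value"].to_numpy(dtype=float)
        worn = _nhanes_calibration_mask(values, worn)
        per_day = pd.Series(worn).groupby(ts.dt.normalize().to_numpy()).sum()
        return bool((per_day >= 600).any())
    raise ValueError(f"unknown wear protocol {protocol!r}")


@dataclass(frozen=True)
class WeeklySummary:
    """Weekly activity aggregates that feed pattern classification."""

    mvpa_min_week: float
    lpa_min_week: float
    sedentary_min_day: float
    top2_share: float
    wear_valid: bool
    days_observed: int

    def __post_init__(self) -> None:
        if self.mvpa_min_week > 0 and not 0.0 <= self.top2_share <= 1.0:
            raise ValueError("top2_share outside [0, 1]")


_DEFAULT_PROTOCOL = {"nhanes": "nhanes", "wrist": "ukb"}


def summarize_week(
    week: ActivityWeek,
    cutpoints: Cutpoints,
    protocol: str | None = None,
) -> WeeklySummary:
    """Aggregate a classified week into a :class:`WeeklySummary`.

    ``top2_share`` is the fraction of weekly MVPA minutes accumulated in the
    two calendar days with the most MVPA (0 when there is no MVPA).  Days
    are calendar days in device-local time.
    """
    protocol = protocol or _DEFAULT_PROTOCOL[week.dialect]
    labels = classify_minutes(week, cutpoints)
    ts = pd.to_datetime(week.data["timestamp"])
    day = ts.dt.normalize()

    mvpa_by_day = (labels == "mvpa").groupby(day.to_numpy()).sum()
    mvpa_week = float(mvpa_by_day.sum())
    lpa_week = float((labels == "lpa").sum())
    worn_day = week.data["wear"].groupby(day.to_numpy()).sum()
    observed = worn_day[worn_day > 0]
    sed_total = float((labels == "sedentary").sum())
    sed_per_day = sed_total / len(observed) if len(observed) else 0.0
    if mvpa_week > 0:
        top2 = float(mvpa_by_day.sort_values(ascending=False).iloc[:2].sum())
        top2_share = top2 / mvpa_week
    else:
        top2_share = 0.0
    return WeeklySummary(
        mvpa_min_week=mvpa_week,
        lpa_min_week=lpa_week,
        sedentary_min_day=sed_per_day,
        top2_share=top2_share,
        wear_valid=wear_valid(week, protocol),
        days_observed=int(len(observed)),
    )


class InvalidWearError(ValueError):
    """Raised when a pattern is requested for a wear-invalid week."""


def classify_pattern(summary: WeeklySummary) -> PAPattern:
    """Map a valid weekly summary to exactly one of the four PA patterns.

    Thresholds are inclusive: >=150 MVPA min/week, >=50% top-2 share,
    >=1900 LPA min/week.
    """
    if not summary.wear_valid:
        raise InvalidWearError("cannot classify a wear-invalid week (excluded)")
    if summary.mvpa_min_week >= MVPA_ACTIVE_MIN:
        if summary.top2_share >= WW_TOP2_SHARE:
            return PAPattern.ACTIVE_WW
        return PAPattern.ACTIVE_REGULAR
    if summary.lpa_min_week >= LPA_ACTIVE_MIN:
        return PAPattern.ACTIVE_LPA
    return PAPattern.BASELINE


# ---------------------------------------------------------------------------
# LPA dose-response: restricted cubic spline Cox model
# ---------------------------------------------------------------------------


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted (natural) cubic spline basis with k knots -> k-1 columns.

    Column 0 is the identity; the remaining k-2 columns are the truncated
    cubic terms constrained to be linear beyond the boundary knots
    (Harrell's parameterization, normalized by the knot span squared).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(sorted(knots), dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("degenerate knots")

    def cub(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cub(x - t[j])
            - cub(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cub(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / span**2)
    return np.column_stack(cols)


@dataclass
class RCSFit:
    """A fitted restricted-cubic-spline Cox dose-response curve."""

    knots: np.ndarray
    coefficients: np.ndarray  # on the log-hazard scale, one per basis column
    covariance: np.ndarray
    reference: float
    grid: np.ndarray
    hr: np.ndarray
    hr_lower: np.ndarray
    hr_upper: np.ndarray

    def hazard_ratio(self, x: np.ndarray) -> np.ndarray:
        """Pointwise HR at LPA value(s) ``x`` relative to the reference."""
        b = rcs_basis(np.atleast_1d(np.asarray(x, dtype=float)), self.knots)
        b0 = rcs_basis(np.array([self.reference]), self.knots)
        return np.exp((b - b0) @ self.coefficients)


def lpa_dose_response(
    participants: pd.DataFrame,
    knots: int = 4,
    lpa_col: str = "lpa_min_week",
    time_col: str = "time",
    event_col: str = "event",
    grid_size: int = 100,
) -> RCSFit:
    """Fit a Cox model of all-cause mortality on an RCS basis of weekly LPA.

    Knots sit at the (0.05, 0.35, 0.65, 0.95) quantiles for the default 4
    knots (Harrell's recommended placement); the reference is the cohort
    median LPA, where the HR equals 1 exactly.  Used to sanity-check the
    1900 min/week active-LPA threshold against the HR plateau.
    """
    from lifelines import CoxPHFitter

    if knots not in (3, 4, 5):
        raise ValueError("knots must be 3, 4 or 5")
    events = int(participants[event_col].sum())
    if events < 50:
        raise ValueError(f"need >= 50 events, got {events}")
    x = participants[lpa_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant LPA: singular spline basis")
    qs = {3: (0.10, 0.50, 0.90), 4: (0.05, 0.35, 0.65, 0.95), 5: (0.05, 0.275, 0.50, 0.725, 0.95)}
    knot_locs = np.quantile(x, qs[knots])
    if len(np.unique(knot_locs)) < knots:
        raise ValueError("degenerate knot placement (ties in LPA quantiles)")
    basis = rcs_basis(x, knot_locs)
    cols = [f"rcs{i}" for i in range(basis.shape[1])]
    df = pd.DataFrame(basis, columns=cols)
    df["time"] = participants[time_col].to_numpy(dtype=float)
    df["event"] = participants[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, "time", "event")
    beta = cph.params_.to_numpy()
    cov = cph.variance_matrix_.to_numpy()

    reference = float(np.median(x))
    grid = np.linspace(x.min(), x.max(), grid_size)
    b = rcs_basis(grid, knot_locs) - rcs_basis(np.array([reference]), knot_locs)
    log_hr = b @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", b, cov, b))
    return RCSFit(
        knots=knot_locs,
        coefficients=beta,
        covariance=cov,
        reference=reference,
        grid=grid,
        hr=np.exp(log_hr),
        hr_lower=np.exp(log_hr - 1.96 * se),
        hr_upper=np.exp(log_hr + 1.96 * se),
    )


# ---------------------------------------------------------------------------
# IO: long-format minute CSV and summary tables
# ---------------------------------------------------------------------------


def read_activity_csv(path, dialect: str = "nhanes") -> list[ActivityWeek]:
    """Read long-format minute records (participant_id, timestamp, value, wear_flag)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    wear_col = "wear_flag" if "wear_flag" in df.columns else "wear"
    weeks = []
    for pid, grp in df.groupby("participant_id", sort=True):
        weeks.append(
            ActivityWeek(
                participant_id=str(pid),
                data=grp.rename(columns={wear_col: "wear"})[
                    ["timestamp", "value", "wear"]
                ].reset_index(drop=True),
                dialect=dialect,
            )
        )
    return weeks


def write_activity_csv(weeks: Iterable[ActivityWeek], path) -> None:
    frames = []
    for w in weeks:
        d = w.data.copy()
        d.insert(0, "participant_id", w.participant_id)
        frames.append(d.rename(columns={"wear": "wear_flag"}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def summarize_weeks(
    weeks: Iterable[ActivityWeek],
    cutpoints: Cutpoints,
    protocol: str | None = None,
) -> pd.DataFrame:
    """Summary + pattern table for a batch of weeks; invalid weeks get pattern NA."""
    rows = []
    for w in weeks:
        s = summarize_week(w, cutpoints, protocol)
        pattern = classify_pattern(s).value if s.wear_valid else pd.NA
        rows.append(
            {
                "participant_id": w.participant_id,
                "mvpa_min_week": s.mvpa_min_week,
                "lpa_min_week": s.lpa_min_week,
                "sedentary_min_day": s.sedentary_min_day,
                "top2_share": s.top2_share,
                "wear_valid": s.wear_valid,
                "days_observed": s.days_observed,
                "pattern": pattern,
            }
        )
    return pd.DataFrame(rows)
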