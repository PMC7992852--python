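"""Activity-Sleep Index (ASI) construction.

The ASI summarises twelve behaviour dimensions -- six physical-activity
dimensions (frequency of MVPA sessions, frequency of resistance training,
intensity, activity type, MVPA duration, sitting time) and six sleep-health
dimensions (daytime alertness, sleep quality, sleep timing, sleep
regularity, sleep efficiency, sleep duration guideline) -- into a single
composite.  Each dimension is min-max rescaled to 0-10 using the observed
minimum and maximum pooled over every assessment point and both trial arms,
oriented so that *higher always means lower-risk behaviour*, and summed:

    rescaled = ((x - x_min) / (x_max - x_min)) * n        (n = 10)

ASI-12 sums all twelve dimensions (range 0-120); ASI-6 sums the
six-dimension subset {rt_freq, mvpa_dur, sitting, quality, efficiency,
duration} (range 0-60), intended for studies with sparser instruments.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESCALE_UPPER = 10.0

#: Inclusive clock window (minutes after midnight) in which the sleep
#: midpoint is considered well-timed: 02:00-04:00.
MIDPOINT_WINDOW = (120.0, 240.0)

#: Adult (18-64 y) sleep-duration guideline, hours.
DURATION_GUIDELINE = (7.0, 9.0)

#: Weekly MVPA minutes are truncated at this value before scoring
#: (Active Australia convention) so a single extreme recall does not
#: stretch the rescaling bounds.
MVPA_MINUTES_CAP = 840.0


@dataclass(frozen=True)
class Dimension:
    """One ASI behaviour dimension.

    ``reversed_risk`` marks dimensions where a *higher raw value is higher
    risk* (sitting, daytime sleepiness, poor-quality rating, bed/wake-time
    variability); their rescaled score is flipped to ``n - score``.
    """

    name: str
    column: str
    reversed_risk: bool
    description: str


DIMENSIONS: tuple[Dimension, ...] = (
    Dimension("mvpa_freq", "dim_mvpa_freq", False, "MVPA sessions per week"),
    Dimension("rt_freq", "dim_rt_freq", False, "resistance-training days per week"),
    Dimension("intensity", "dim_intensity", False, "proportion of MVPA minutes that were vigorous"),
    Dimension("type", "dim_type", False, "activity type: neither / one of / both MVPA and RT"),
    Dimension("mvpa_dur", "dim_mvpa_dur", False, "MVPA minutes per week (capped)"),
    Dimension("sitting", "dim_sitting", True, "sitting minutes per day"),
    Dimension("alertness", "dim_alertness", True, "trouble staying awake during the day"),
    Dimension("quality", "dim_quality", True, "overall sleep quality rating (higher = worse)"),
    Dimension("timing", "dim_timing", False, "sleep midpoint inside the 02:00-04:00 window"),
    Dimension("regularity", "dim_regularity", True, "variability of bed and wake times"),
    Dimension("efficiency", "dim_efficiency", False, "sleep efficiency percent"),
    Dimension("duration", "dim_duration", False, "meets the age-appropriate duration guideline"),
)

#: ASI-6 subset: dimensions 2, 5, 6, 8, 11 and 12 of the list above.
ASI6_NAMES: tuple[str, ...] = ("rt_freq", "mvpa_dur", "sitting", "quality", "efficiency", "duration")

DIMENSION_COLUMNS: tuple[str, ...] = tuple(d.column for d in DIMENSIONS)
SCORE_COLUMNS: tuple[str, ...] = tuple(f"score_{d.name}" for d in DIMENSIONS)

_BY_NAME: dict[str, Dimension] = {d.name: d for d in DIMENSIONS}


class AsiError(ValueError):
    """Raised for invalid scoring inputs (unknown dimension, bad clock time...)."""


# ---------------------------------------------------------------------------
# rescaling


def rescale_dimension(
    x: float,
    lo: float,
    hi: float,
    *,
    reversed_risk: bool = False,
    n: float = RESCALE_UPPER,
) -> float:
    """Min-max rescale a raw value onto [0, n].

    Values outside the frozen bounds are clipped; degenerate bounds
    (``hi == lo``) return ``n / 2`` with a loud warning, since the dimension
    then carries no information.
    """
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise AsiError("rescaling bounds must be finite")
    if hi < lo:
        raise AsiError(f"invalid bounds: max {hi} < min {lo}")
    if not math.isfinite(x):
        raise AsiError(f"cannot rescale non-finite value {x!r}")
    if hi == lo:
        logger.warning("degenerate bounds (min == max == %s): scoring as %s", lo, n / 2)
        return n / 2
    x = min(max(x, lo), hi)
    score = (x - lo) / (hi - lo) * n
    return n - score if reversed_risk else score


@dataclass
class RescaleBounds:
    """Per-dimension observed min/max, frozen before any scoring call.

    Bounds are pooled over all assessment points and both groups (and, by
    default, both trials).
    """

    lo: dict[str, float] = field(default_factory=dict)
    hi: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.lo:
            if self.hi[name] < self.lo[name]:
                raise AsiError(f"dimension {name!r}: max < min")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"lo": self.lo, "hi": self.hi}, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RescaleBounds":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(lo=payload["lo"], hi=payload["hi"])


def compute_bounds(data: pd.DataFrame, dimensions: Iterable[Dimension] = DIMENSIONS) -> RescaleBounds:
    """Observed min/max per dimension over every wave and group.

    Missing values are ignored; a dimension with no observed value at all is
    an error naming the dimension.
    """
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for dim in dimensions:
        if dim.column not in data.columns:
            raise AsiError(f"dimension column {dim.column!r} absent from dataset")
        col = pd.to_numeric(data[dim.column], errors="coerce")
        if col.notna().sum() == 0:
            raise AsiError(f"dimension {dim.name!r} has no observed values")
        lo[dim.name] = float(col.min())
        hi[dim.name] = float(col.max())
    return RescaleBounds(lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# deriving the 12 dimensions from raw questionnaire fields

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})\s*$")

#: raw questionnaire columns consumed by :func:`derive_dimensions`
RAW_FIELDS: tuple[str, ...] = (
    "walk_min_wk",
    "mod_min_wk",
    "vig_min_wk",
    "mvpa_sessions_wk",
    "rt_days_wk",
    "sitting_min_day",
    "daytime_sleepiness",
    "sleep_quality_rating",
    "bedtime",
    "sleep_duration_hr",
    "time_in_bed_hr",
    "sleep_variability",
)


def parse_clock(value) -> float:
    """Parse an ``HH:MM`` clock time into minutes after midnight."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if not math.isfinite(value) or not 0 <= value < 1440:
            raise AsiError(f"clock time in minutes must be in [0, 1440): {value!r}")
        return float(value)
    m = _CLOCK_RE.match(str(value))
    if not m:
        raise AsiError(f"unparseable clock time: {value!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        raise AsiError(f"unparseable clock time: {value!r}")
    return hh * 60.0 + mm


def sleep_midpoint(bedtime, duration_hr: float) -> float:
    """Clock midpoint of the sleep period, minutes after midnight."""
    return (parse_clock(bedtime) + duration_hr * 60.0 / 2.0) % 1440.0


def derive_dimensions(
    raw: pd.DataFrame,
    *,
    timing_mode: str = "binary",
    mvpa_cap: float = MVPA_MINUTES_CAP,
) -> pd.DataFrame:
    """Populate the twelve ``dim_*`` columns from raw questionnaire fields.

    Expects the columns in :data:`RAW_FIELDS` plus ``age``.  Rows with missing
    raw fields propagate NaN into the derived dimensions.

    ``timing_mode``:
      * ``"binary"`` (default) -- 1 if the sleep midpoint falls inside the
        02:00-04:00 window, else 0.
      * ``"graded"`` -- absolute distance (minutes) from the window, which is
        risk-reversed downstream.
    """
    if timing_mode not in ("binary", "graded"):
        raise AsiError(f"unknown timing_mode {timing_mode!r}")
    missing = [c for c in RAW_FIELDS + ("age",) if c not in raw.columns]
    if missing:
        raise AsiError(f"raw dataset missing required columns: {missing}")

    out = pd.DataFrame(index=raw.index)
    walk = pd.to_numeric(raw["walk_min_wk"], errors="coerce")
    mod = pd.to_numeric(raw["mod_min_wk"], errors="coerce")
    vig = pd.to_numeric(raw["vig_min_wk"], errors="coerce")
    mvpa_min = walk + mod + vig
    rt = pd.to_numeric(raw["rt_days_wk"], errors="coerce")

    out["dim_mvpa_freq"] = pd.to_numeric(raw["mvpa_sessions_wk"], errors="coerce")
    out["dim_rt_freq"] = rt
    # proportion of MVPA that was vigorous; defined as 0 when no MVPA at all
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(mvpa_min > 0, vig / mvpa_min, 0.0)
    out["dim_intensity"] = np.where(mvpa_min.isna() | vig.isna(), np.nan, frac)
    out["dim_type"] = (mvpa_min > 0).astype(float) + (rt > 0).astype(float)
    out.loc[mvpa_min.isna() | rt.isna(), "dim_type"] = np.nan
    out["dim_mvpa_dur"] = mvpa_min.clip(upper=mvpa_cap)
    out["dim_sitting"] = pd.to_numeric(raw["sitting_min_day"], errors="coerce")
    out["dim_alertness"] = pd.to_numeric(raw["daytime_sleepiness"], errors="coerce")
    out["dim_quality"] = pd.to_numeric(raw["sleep_quality_rating"], errors="coerce")

    dur = pd.to_numeric(raw["sleep_duration_hr"], errors="coerce")
    tib = pd.to_numeric(raw["time_in_bed_hr"], errors="coerce")
    midpoints = np.full(len(raw), np.nan)
    for i, (bed, d) in enumerate(zip(raw["bedtime"].to_numpy(), dur.to_numpy())):
        if (bed is None) or (isinstance(bed, float) and math.isnan(bed)) or math.isnan(d):
            continue
        midpoints[i] = sleep_midpoint(bed, d)
    in_window = (midpoints >= MIDPOINT_WINDOW[0]) & (midpoints <= MIDPOINT_WINDOW[1])
    if timing_mode == "binary":
        out["dim_timing"] = np.where(np.isnan(midpoints), np.nan, in_window.astype(float))
    else:
        centre = (MIDPOINT_WINDOW[0] + MIDPOINT_WINDOW[1]) / 2.0
        dist = np.abs(midpoints - centre)
        dist = np.minimum(dist, 1440.0 - dist)  # circular distance
        dist = np.maximum(dist - (MIDPOINT_WINDOW[1] - MIDPOINT_WINDOW[0]) / 2.0, 0.0)
        out["dim_timing"] = -dist  # higher (closer to window) = lower risk

    out["dim_regularity"] = pd.to_numeric(raw["sleep_variability"], errors="coerce")
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(tib > 0, dur / tib * 100.0, np.nan)
    out["dim_efficiency"] = np.clip(eff, 0.0, 100.0)

    age = pd.to_numeric(raw["age"], errors="coerce")
    meets = (dur >= DURATION_GUIDELINE[0]) & (dur <= DURATION_GUIDELINE[1])
    out["dim_duration"] = np.where(dur.isna() | age.isna(), np.nan, meets.astype(float))
    return out


# ---------------------------------------------------------------------------
# composing the index


@dataclass
class AsiScore:
    """Scored profile: twelve 0-10 dimension scores plus the two totals."""

    scores: dict[str, float]
    asi12: float
    asi6: float


def compose_asi(
    data: pd.DataFrame,
    bounds: RescaleBounds,
    *,
    n: float = RESCALE_UPPER,
    max_missing: int = 0,
) -> pd.DataFrame:
    """Rescale every dimension and sum into ASI-12 / ASI-6.

    Returns a copy of ``data`` with ``score_*`` columns and ``asi12`` /
    ``asi6`` totals appended.  A row with more than ``max_missing`` missing
    dimensions is scored as missing (NaN totals) -- no pro-rating, since a
    pro-rated sum would change the index's meaning.
    """
    out = data.copy()
    score_cols = []
    for dim in DIMENSIONS:
        lo, hi = bounds.lo[dim.name], bounds.hi[dim.name]
        col = pd.to_numeric(out[dim.column], errors="coerce").to_numpy(dtype=float)
        if hi == lo:
            logger.warning(
                "dimension %s has degenerate bounds (min == max == %s); scoring as %s",
                dim.name, lo, n / 2,
            )
            scored = np.where(np.isnan(col), np.nan, n / 2)
        else:
            clipped = np.clip(col, lo, hi)
            scored = (clipped - lo) / (hi - lo) * n
            if dim.reversed_risk:
                scored = n - scored
        name = f"score_{dim.name}"
        out[name] = scored
        score_cols.append(name)

    scores = out[score_cols].to_numpy(dtype=float)
    n_missing = np.isnan(scores).sum(axis=1)
    usable = n_missing <= max_missing
    out["asi12"] = np.where(usable, np.nansum(scores, axis=1), np.nan)
    asi6_cols = [f"score_{name}" for name in ASI6_NAMES]
    scores6 = out[asi6_cols].to_numpy(dtype=float)
    usable6 = np.isnan(scores6).sum(axis=1) <= max_missing
    out["asi6"] = np.where(usable6, np.nansum(scores6, axis=1), np.nan)
    # rows with zero observed dimensions are always missing
    out.loc[n_missing == len(DIMENSIONS), "asi12"] = np.nan
    return out


def score_profile(profile: Mapping[str, float], bounds: RescaleBounds, *, n: float = RESCALE_UPPER) -> AsiScore:
    """Score a single complete profile of raw dimension values (keyed by dimension name)."""
    scores: dict[str, float] = {}
    for dim in DIMENSIONS:
        if dim.name not in profile:
            raise AsiError(f"profile missing dimension {dim.name!r}")
        scores[dim.name] = rescale_dimension(
            float(profile[dim.name]), bounds.lo[dim.name], bounds.hi[dim.name],
            reversed_risk=dim.reversed_risk, n=n,
        )
    asi12 = float(sum(scores.values()))
    asi6 = float(sum(scores[k] for k in ASI6_NAMES))
    return AsiScore(scores=scores, asi12=asi12, asi6=asi6)


def dimension_correlations(scored: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix of the 12 rescaled dimensions + ASI-12.

    Pairwise-complete handling; a constant column yields NaN against every
    other column.  Requires at least 3 complete rows overall.
    """
    cols = list(SCORE_COLUMNS) + ["asi12"]
    missing = [c for c in cols if c not in scored.columns]
    if missing:
        raise AsiError(f"scored dataset missing columns: {missing}")
    frame = scored[cols].apply(pd.to_numeric, errors="coerce")
    if (frame.notna().all(axis=1)).sum() < 3:
        raise AsiError("need at least 3 complete rows for a correlation matrix")
    corr = frame.corr(method="spearman", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
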