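"""Descriptive statistics: effect sizes, severity bands, completer analyses.

Covers the study-style descriptive layer around the mediation models:
unadjusted between-group Cohen's d at each assessment point, DASS-21
severity banding and improvement coding, completer vs non-completer
comparisons (t-tests / chi-square), and the exploratory comparison of
ASI-12 change by symptom-responder status.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DASS_SUBSCALES = ("depression", "anxiety", "stress")


class DescriptivesError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cohen's d


@dataclass
class EffectSizeResult:
    """Standardized mean difference, sign convention (group1 - group2) / pooled SD."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    d: float
    ci: tuple[float, float]


def cohens_d(mean1, sd1, n1, mean2, sd2, n2, *, confidence: float = 0.95) -> EffectSizeResult:
    """Cohen's d from group summaries, with a normal-approximation CI.

    ``d = (mean1 - mean2) / s_pooled`` where
    ``s_pooled^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)``.
    The CI uses the standard large-sample variance
    ``(n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))``.
    """
    if n1 < 2 or n2 < 2:
        raise DescriptivesError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise DescriptivesError("group SDs must be positive")
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / s_pooled
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = stats.norm.ppf((1 + confidence) / 2)
    return EffectSizeResult(mean1, sd1, n1, mean2, sd2, n2, float(d), (float(d - z * se), float(d + z * se)))


def cohens_d_from_samples(x1, x2, **kwargs) -> EffectSizeResult:
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise DescriptivesError("each group needs at least 2 observations")
    return cohens_d(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2), **kwargs
    )


# ---------------------------------------------------------------------------
# DASS-21 severity bands


def _load_thresholds() -> dict:
    ref = importlib_resources.files("asimed.resources").joinpath("dass21_severity.json")
    return json.loads(ref.read_text())


_THRESHOLDS = _load_thresholds()
SEVERITY_BANDS: tuple[str, ...] = tuple(_THRESHOLDS["bands"])
_BAND_INDEX = {band: i for i, band in enumerate(SEVERITY_BANDS)}


def classify_severity(score: float, subscale: str, thresholds: dict | None = None) -> str:
    """Band a (doubled) DASS-21 subscale score.

    Lower bounds are inclusive ("closed-left"): a score equal to the first
    mild threshold is mild.
    """
    table = thresholds or _THRESHOLDS
    if subscale not in table["lower_bounds"]:
        raise DescriptivesError(f"unknown DASS subscale {subscale!r}")
    if not math.isfinite(score) or score < 0:
        raise DescriptivesError(f"DASS score must be finite and >= 0, got {score!r}")
    bounds = table["lower_bounds"][subscale]
    i = int(np.searchsorted(bounds, score, side="right")) - 1
    return table["bands"][i]


def severity_order(band: str) -> int:
    return _BAND_INDEX[band]


def classify_change(band_baseline: str, band_followup: str) -> str:
    """"improved" iff the follow-up band is strictly lower than baseline,
    else "no_change_or_worsened"."""
    if severity_order(band_followup) < severity_order(band_baseline):
        return "improved"
    return "no_change_or_worsened"


# ---------------------------------------------------------------------------
# completer vs non-completer comparison


def completion_summary(n_completers: int, n_baseline: int) -> dict[str, float]:
    """Exact completion arithmetic: completers + non-completers = baseline n."""
    if n_completers > n_baseline or n_baseline <= 0:
        raise DescriptivesError("completers cannot exceed baseline sample")
    return {
        "n_baseline": n_baseline,
        "n_completers": n_completers,
        "n_non_completers": n_baseline - n_completers,
        "completion_rate_pct": 100.0 * n_completers / n_baseline,
    }


def compare_completers(
    data: pd.DataFrame,
    wave: int = 3,
    *,
    continuous: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex", "group", "trial"),
    baseline_outcomes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Completers vs non-completers of the behaviour instruments at ``wave``.

    A completer is a participant whose mediator block is observed at the
    wave.  Continuous variables get independent t-tests, categorical ones
    chi-square without continuity correction.
    """
    base = data[data["wave"] == 0].set_index("pid")
    fw = data[data["wave"] == wave].set_index("pid").reindex(base.index)
    completer = fw["observed"].fillna(False).astype(bool)
    if completer.all() or (~completer).all():
        raise DescriptivesError("both completer groups must be non-empty")

    rows = []
    for col in tuple(continuous) + tuple(baseline_outcomes):
        x1 = base.loc[completer, col].astype(float).dropna()
        x2 = base.loc[~completer, col].astype(float).dropna()
        t, p = stats.ttest_ind(x1, x2, equal_var=True)
        rows.append(
            {
                "variable": col, "test": "t",
                "completer_mean": x1.mean(), "non_completer_mean": x2.mean(),
                "statistic": float(t), "df": float(len(x1) + len(x2) - 2), "pvalue": float(p),
            }
        )
    for col in categorical:
        table = pd.crosstab(base[col], completer)
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "variable": col, "test": "chi2",
                "completer_mean": np.nan, "non_completer_mean": np.nan,
                "statistic": float(chi2), "df": float(df), "pvalue": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update(completion_summary(int(completer.sum()), int(len(completer))))
    return out


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction for an r x c table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# descriptive tables and responder analysis


def group_descriptives(data: pd.DataFrame, columns: tuple[str, ...], waves=(0, 3, 6)) -> pd.DataFrame:
    """Mean (SD) by group at each wave plus unadjusted Cohen's d at follow-ups."""
    rows = []
    for col in columns:
        for wave in waves:
            sub = data[data["wave"] == wave]
            x1 = sub.loc[sub["group"] == 1, col].astype(float).dropna()
            x2 = sub.loc[sub["group"] == 0, col].astype(float).dropna()
            row = {
                "variable": col, "wave": wave,
                "intervention_mean": x1.mean(), "intervention_sd": x1.std(ddof=1), "intervention_n": len(x1),
                "control_mean": x2.mean(), "control_sd": x2.std(ddof=1), "control_n": len(x2),
                "d": np.nan, "d_lo": np.nan, "d_hi": np.nan,
            }
            if wave != 0 and len(x1) >= 2 and len(x2) >= 2:
                res = cohens_d_from_samples(x1, x2)
                row.update({"d": res.d, "d_lo": res.ci[0], "d_hi": res.ci[1]})
            rows.append(row)
    return pd.DataFrame(rows)


def asi_change_by_response(
    data: pd.DataFrame,
    subscale: str = "depression",
    *,
    wave: int = 3,
    mediator: str = "asi12",
) -> EffectSizeResult | None:
    """Cohen's d of ASI change (baseline -> wave) for improvers vs non-improvers.

    Improvement is a drop of at least one DASS severity band between baseline
    and the wave.  Returns None (with a warning) when either responder group
    has fewer than two members.
    """
    if subscale not in DASS_SUBSCALES:
        raise DescriptivesError(f"unknown DASS subscale {subscale!r}")
    outcome = f"dass_{subscale}"
    base = data[data["wave"] == 0].set_index("pid")
    fw = data[data["wave"] == wave].set_index("pid").reindex(base.index)
    ok = fw[mediator].notna() & fw[outcome].notna() & base[outcome].notna()
    change = (fw.loc[ok, mediator] - base.loc[ok, mediator]).astype(float)
    # DASS scores are banded after flooring negative simulated values at 0
    banded0 = base.loc[ok, outcome].clip(lower=0).map(lambda s: classify_severity(s, subscale))
    banded1 = fw.loc[ok, outcome].clip(lower=0).map(lambda s: classify_severity(s, subscale))
    improved = [
        classify_change(b0, b1) == "improved" for b0, b1 in zip(banded0, banded1)
    ]
    improved = np.asarray(improved)
    if improved.sum() < 2 or (~improved).sum() < 2:
        warnings.warn("a responder group has fewer than 2 members; effect size not estimable")
        return None
    return cohens_d_from_samples(change[improved], change[~improved])
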