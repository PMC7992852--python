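"""Synthetic pooled two-trial RCT cohorts with known mediation structure.

Emulates the pooled design of two m-health activity/sleep trials: trial A
("synergy", 80 intervention / 80 wait-list control, ages 18-54) and trial B
("refresh", 110 / 55, ages 45-64), assessed at baseline, 3 and 6 months.
Participants are physically inactive adults with poor sleep quality, so the
baseline behaviour distributions sit at the unfavourable end of each raw
scale.

Ground truth is controlled by three path coefficients:

* ``a_true`` -- intervention effect on the 3-month ASI-12, in ASI units.
  It is induced on the *raw* behaviour scales (extra MVPA minutes, fewer
  sitting minutes, better quality ratings, ...) and the raw-shift multiplier
  is calibrated so the covariate-adjusted intervention coefficient on the
  scored ASI-12 equals ``a_true``; the generator therefore exercises the
  full scoring path rather than emitting index values directly.
* ``b_true`` -- mediator->outcome slope (outcome units per ASI-12 point).
* ``cprime_true`` -- direct intervention effect on the outcome.

Follow-up outcomes are linear-Gaussian:
``Y_w = (1-gamma)*mu + gamma*Y_0 + cprime*group + delta*study + b*(M_w - mean(M_w)) + eps``.

A latent participant trait (stable "wellbeing/behaviour propensity") loads
on baseline behaviours, baseline outcomes and the follow-up behaviour
trajectory; it is what makes baseline outcomes informative about follow-up
behaviour and hence makes missing-at-random attrition on age and baseline
outcome consequential for complete-case analyses.

Missingness at follow-up is logistic in age and a baseline outcome
(younger participants and those with worse baseline symptoms drop out
more), monotone across waves by default, with intercepts set so that about
85% complete the 3-month assessment and about 66% the 6-month one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from . import asi

logger = logging.getLogger(__name__)

OUTCOMES: tuple[str, ...] = (
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
    "qol_physical",
    "qol_mental",
    "energy_fatigue",
)

WAVES: tuple[int, ...] = (0, 3, 6)


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class TrialConfig:
    name: str
    n_intervention: int
    n_control: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float

    def validate(self) -> None:
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise ConfigError(f"trial {self.name!r}: group sizes must be positive")
        if self.age_sd <= 0:
            raise ConfigError(f"trial {self.name!r}: age SD must be positive")
        if self.age_max <= self.age_min:
            raise ConfigError(f"trial {self.name!r}: age_max must exceed age_min")


@dataclass(frozen=True)
class OutcomeParams:
    """Baseline distribution and true effects for one outcome scale."""

    mean: float
    sd: float
    b_true: float
    cprime_true: float
    resid_sd: float
    trait_loading: float  # outcome units per trait SD; sign encodes direction

    def validate(self, name: str) -> None:
        if self.sd <= 0 or self.resid_sd <= 0:
            raise ConfigError(f"outcome {name!r}: SDs must be positive")
        if abs(self.trait_loading) >= self.sd:
            raise ConfigError(f"outcome {name!r}: trait loading must be < baseline SD")


@dataclass(frozen=True)
class MissingnessConfig:
    """Logistic MAR model: logit P(missing) = intercept + beta_age*age + beta_y0*Y0."""

    enabled: bool = True
    intercept_3m: float = -0.651
    intercept_6m: float = -0.137
    beta_age: float = -0.03
    beta_baseline_outcome: float = 0.03
    driver_outcome: str = "dass_depression"
    monotone: bool = True
    #: when True, the mediator instruments and the outcome questionnaires are
    #: deleted by independent draws (a participant can return the outcome
    #: survey but skip the activity/sleep instruments, or vice versa)
    item_level: bool = False

    def validate(self) -> None:
        if self.driver_outcome not in OUTCOMES:
            raise ConfigError(f"unknown missingness driver outcome {self.driver_outcome!r}")


def _default_trials() -> tuple[TrialConfig, ...]:
    return (
        TrialConfig("synergy", 80, 80, 41.5, 9.9, 18.0, 54.0),
        TrialConfig("refresh", 110, 55, 52.0, 6.9, 45.0, 64.0),
    )


def _default_outcomes() -> dict[str, OutcomeParams]:
    # baseline means/SDs follow the pooled trials' Table-1-style profile;
    # b_true / cprime_true defaults follow the fitted 3-month paths so the
    # default cohort behaves like the study it emulates
    return {
        "dass_depression": OutcomeParams(10.7, 8.1, -0.10, -0.25, 6.5, -2.8),
        "dass_anxiety": OutcomeParams(6.0, 5.5, -0.04, -0.21, 4.4, -1.9),
        "dass_stress": OutcomeParams(14.2, 6.6, -0.12, -0.26, 5.3, -2.3),
        "qol_physical": OutcomeParams(47.2, 7.2, 0.02, 0.28, 5.8, 2.5),
        "qol_mental": OutcomeParams(42.0, 10.2, 0.17, 0.56, 8.2, 3.6),
        "energy_fatigue": OutcomeParams(44.7, 18.7, 0.28, 1.15, 15.0, 6.5),
    }


#: Raw behaviour field generator settings.  ``drift`` is the secular change
#: from baseline to 3 months common to both arms (the wait-list arms of the
#: emulated trials also improved), ``shift`` is the intervention effect at
#: unit multiplier (rescaled during calibration), ``rho`` the baseline
#: carryover, ``trait`` the loading of the latent propensity on baseline.
_F = dict
FIELD_SPECS: dict[str, dict] = {
    "walk_min_wk": _F(mean=40.0, sd=35.0, lo=0.0, hi=600.0, integer=False, rho=0.5, drift=15.0, shift=35.0, trait=10.0),
    "mod_min_wk": _F(mean=15.0, sd=20.0, lo=0.0, hi=400.0, integer=False, rho=0.5, drift=8.0, shift=20.0, trait=5.0),
    "vig_min_wk": _F(mean=5.0, sd=12.0, lo=0.0, hi=300.0, integer=False, rho=0.5, drift=4.0, shift=15.0, trait=4.0),
    "mvpa_sessions_wk": _F(mean=1.2, sd=1.1, lo=0.0, hi=14.0, integer=True, rho=0.5, drift=0.5, shift=1.2, trait=0.3),
    "rt_days_wk": _F(mean=0.4, sd=0.9, lo=0.0, hi=7.0, integer=True, rho=0.5, drift=0.4, shift=0.8, trait=0.2),
    "sitting_min_day": _F(mean=540.0, sd=110.0, lo=120.0, hi=1080.0, integer=False, rho=0.6, drift=-15.0, shift=-45.0, trait=-20.0),
    "daytime_sleepiness": _F(mean=0.6, sd=0.8, lo=0.0, hi=3.0, integer=True, rho=0.5, drift=-0.05, shift=-0.30, trait=-0.20),
    "sleep_quality_rating": _F(mean=2.1, sd=0.6, lo=0.0, hi=3.0, integer=True, rho=0.4, drift=-0.35, shift=-0.35, trait=-0.15),
    "bedtime_hr": _F(mean=23.25, sd=1.0, lo=None, hi=None, integer=False, rho=0.7, drift=0.0, shift=-0.10, trait=-0.10),
    "sleep_duration_hr": _F(mean=6.4, sd=0.9, lo=3.5, hi=10.0, integer=False, rho=0.55, drift=0.15, shift=0.40, trait=0.20),
    "sleep_efficiency_frac": _F(mean=0.80, sd=0.08, lo=0.45, hi=0.99, integer=False, rho=0.5, drift=0.01, shift=0.04, trait=0.02),
    "sleep_variability": _F(mean=4.6, sd=1.7, lo=0.0, hi=8.0, integer=True, rho=0.5, drift=-0.3, shift=-0.9, trait=-0.40),
}

#: additional noise SD (as a fraction of the field SD) from 3 to 6 months
_WAVE6_NOISE = 0.6


@dataclass(frozen=True)
class CohortConfig:
    trials: tuple[TrialConfig, ...] = field(default_factory=_default_trials)
    prop_female: float = 0.81
    a_true: float = 3.0
    outcomes: Mapping[str, OutcomeParams] = field(default_factory=_default_outcomes)
    gamma: float = 0.5  # baseline-outcome carryover into follow-up outcome
    delta_study: float = 0.0  # study-indicator effect on follow-up outcome
    trait_sd: float = 1.0
    #: loading of the latent trait on the follow-up behaviour trajectory,
    #: as a multiple of each field's intervention-shift template
    trait_followup: float = 0.25
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    calibrate: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.trials:
            raise ConfigError("at least one trial required")
        for t in self.trials:
            t.validate()
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must be in [0, 1]")
        if self.trait_sd < 0:
            raise ConfigError("trait_sd must be >= 0")
        missing = [k for k in OUTCOMES if k not in self.outcomes]
        if missing:
            raise ConfigError(f"outcome parameters missing for: {missing}")
        for name, pars in self.outcomes.items():
            pars.validate(name)
        self.missingness.validate()

    @property
    def n_total(self) -> int:
        return sum(t.n_intervention + t.n_control for t in self.trials)

    @property
    def n_intervention(self) -> int:
        return sum(t.n_intervention for t in self.trials)

    @property
    def n_control(self) -> int:
        return sum(t.n_control for t in self.trials)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def with_paths(config: CohortConfig, *, a_true=None, b_true=None, cprime_true=None) -> CohortConfig:
    """Return a copy of ``config`` with path coefficients overridden.

    ``b_true`` / ``cprime_true`` may be scalars (applied to every outcome) or
    per-outcome mappings.
    """
    outcomes = dict(config.outcomes)
    for name, pars in outcomes.items():
        kw = {}
        if b_true is not None:
            kw["b_true"] = float(b_true[name] if isinstance(b_true, Mapping) else b_true)
        if cprime_true is not None:
            kw["cprime_true"] = float(
                cprime_true[name] if isinstance(cprime_true, Mapping) else cprime_true
            )
        if kw:
            outcomes[name] = replace(pars, **kw)
    kw = {"outcomes": outcomes}
    if a_true is not None:
        kw["a_true"] = float(a_true)
    return replace(config, **kw)


def with_total_n(config: CohortConfig, n_total: int) -> CohortConfig:
    """Scale every group size proportionally so the cohort totals ``n_total``."""
    factor = n_total / config.n_total
    trials = tuple(
        replace(
            t,
            n_intervention=max(1, round(t.n_intervention * factor)),
            n_control=max(1, round(t.n_control * factor)),
        )
        for t in config.trials
    )
    return replace(config, trials=trials)


# ---------------------------------------------------------------------------
# generation internals


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _clip_field(values: np.ndarray, spec: dict) -> np.ndarray:
    if spec["lo"] is not None:
        values = np.clip(values, spec["lo"], spec["hi"])
    if spec["integer"]:
        values = np.round(values)
    return values


def _format_clock(hours: np.ndarray) -> list[str]:
    minutes = np.round((hours % 24.0) * 60.0).astype(int) % 1440
    return [f"{m // 60:02d}:{m % 60:02d}" for m in minutes]


def _raw_frame(fields: dict[str, np.ndarray], age: np.ndarray) -> pd.DataFrame:
    """Assemble the questionnaire-level raw columns for one wave."""
    dur = fields["sleep_duration_hr"]
    eff = fields["sleep_efficiency_frac"]
    tib = np.clip(dur / eff, dur, 18.0)
    return pd.DataFrame(
        {
            "walk_min_wk": fields["walk_min_wk"],
            "mod_min_wk": fields["mod_min_wk"],
            "vig_min_wk": fields["vig_min_wk"],
            "mvpa_sessions_wk": fields["mvpa_sessions_wk"],
            "rt_days_wk": fields["rt_days_wk"],
            "sitting_min_day": fields["sitting_min_day"],
            "daytime_sleepiness": fields["daytime_sleepiness"],
            "sleep_quality_rating": fields["sleep_quality_rating"],
            "bedtime": _format_clock(fields["bedtime_hr"]),
            "sleep_duration_hr": dur,
            "time_in_bed_hr": tib,
            "sleep_variability": fields["sleep_variability"],
            "age": age,
        }
    )


def _fit_a_path(long_df: pd.DataFrame, mediator: str = "asi12") -> float:
    """OLS coefficient of group in M_3 ~ group + M_0 + study (complete rows)."""
    base = long_df[long_df["wave"] == 0].set_index("pid")
    fw = long_df[long_df["wave"] == 3].set_index("pid")
    m0 = base[mediator]
    mw = fw.loc[m0.index, mediator]
    g = base["group"].to_numpy(float)
    s = (base["trial"] != base["trial"].iloc[0]).to_numpy(float)
    mask = m0.notna().to_numpy() & mw.notna().to_numpy()
    X = np.column_stack([np.ones(mask.sum()), g[mask], m0.to_numpy(float)[mask], s[mask]])
    beta, *_ = np.linalg.lstsq(X, mw.to_numpy(float)[mask], rcond=None)
    return float(beta[1])


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a pooled-cohort dataset in long (participant x wave) format.

    Returns one row per participant per wave (0, 3, 6 months) with raw
    questionnaire fields, derived ``dim_*`` columns, rescaled ``score_*``
    columns, ``asi12`` / ``asi6`` totals, the six outcome scales and
    observed/missing flags.  Identical config (including seed) gives a
    byte-identical dataset.  Metadata (seed, config hash, attrition rates)
    is attached in ``DataFrame.attrs``.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    # independent substream for attrition so the complete data are identical
    # whether or not missingness is switched on
    miss_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    n = config.n_total
    trial_names: list[str] = []
    groups = np.empty(n)
    ages = np.empty(n)
    pos = 0
    for t in config.trials:
        for grp, count in ((1, t.n_intervention), (0, t.n_control)):
            ages[pos : pos + count] = _truncated_normal(rng, t.age_mean, t.age_sd, t.age_min, t.age_max, count)
            groups[pos : pos + count] = grp
            trial_names += [t.name] * count
            pos += count
    trial = pd.Series(trial_names)
    study = (trial != config.trials[0].name).to_numpy(float)
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    trait = rng.normal(0.0, config.trait_sd, n)
    pid = np.array([f"p{i:05d}" for i in range(n)])

    # pre-draw every noise array once so the calibration multiplier is the
    # only thing that changes between calibration passes
    z0 = {f: rng.standard_normal(n) for f in FIELD_SPECS}
    z3 = {f: rng.standard_normal(n) for f in FIELD_SPECS}
    z6 = {f: rng.standard_normal(n) for f in FIELD_SPECS}

    def build_behaviours(lam: float) -> pd.DataFrame:
        frames = []
        for wave in WAVES:
            fields = {}
            for name, spec in FIELD_SPECS.items():
                base = spec["mean"] + spec["trait"] * trait + spec["sd"] * z0[name]
                if wave == 0:
                    latent = base
                else:
                    innov = spec["sd"] * np.sqrt(1.0 - spec["rho"] ** 2) * z3[name]
                    latent = (
                        spec["mean"]
                        + spec["drift"]
                        + spec["rho"] * (base - spec["mean"])
                        + config.trait_followup * spec["shift"] * trait
                        + lam * groups * spec["shift"]
                        + innov
                    )
                    if wave == 6:
                        latent = latent + _WAVE6_NOISE * spec["sd"] * z6[name]
                fields[name] = _clip_field(latent, spec)
            frame = _raw_frame(fields, ages)
            frame.insert(0, "wave", wave)
            frames.append(frame)
        raw = pd.concat(frames, ignore_index=True)
        dims = asi.derive_dimensions(raw)
        long_df = pd.concat([raw, dims], axis=1)
        long_df.insert(0, "pid", np.tile(pid, len(WAVES)))
        long_df.insert(1, "trial", np.tile(trial.to_numpy(), len(WAVES)))
        long_df.insert(2, "group", np.tile(groups.astype(int), len(WAVES)))
        bounds = asi.compute_bounds(long_df)
        return asi.compose_asi(long_df, bounds), bounds

    # calibrate the raw-shift multiplier so the fitted intervention effect on
    # the scored ASI-12 has slope a_true (secant on the population slope; the
    # sampling noise of the fitted coefficient is deliberately not cancelled)
    if config.a_true == 0.0 or not config.calibrate:
        lam = 1.0 if (not config.calibrate and config.a_true != 0.0) else 0.0
        if config.a_true == 0.0:
            lam = 0.0
        long_df, bounds = build_behaviours(lam)
    else:
        df0, _ = build_behaviours(0.0)
        df1, _ = build_behaviours(1.0)
        a_at_0 = _fit_a_path(df0)
        slope = _fit_a_path(df1) - a_at_0
        if abs(slope) < 1e-9:
            raise ConfigError("intervention shift template induces no ASI effect")
        lam = config.a_true / slope
        df_l, _ = build_behaviours(lam)
        slope = (_fit_a_path(df_l) - a_at_0) / lam  # re-linearise at the solution
        lam = config.a_true / slope
        long_df, bounds = build_behaviours(lam)

    # outcomes: baseline from the instrument distribution (+ trait), follow-up
    # linear-Gaussian in baseline outcome, group, study and the scored ASI-12
    asi_by_wave = {
        w: long_df.loc[long_df["wave"] == w, "asi12"].to_numpy(float) for w in WAVES
    }
    out_cols: dict[int, dict[str, np.ndarray]] = {w: {} for w in WAVES}
    for name in OUTCOMES:
        pars = config.outcomes[name]
        unique_sd = np.sqrt(pars.sd**2 - pars.trait_loading**2)
        y0 = pars.mean + pars.trait_loading * trait + unique_sd * rng.standard_normal(n)
        out_cols[0][name] = y0
        for wave in (3, 6):
            m = asi_by_wave[wave]
            yw = (
                (1.0 - config.gamma) * pars.mean
                + config.gamma * y0
                + pars.cprime_true * groups
                + config.delta_study * study
                + pars.b_true * (m - m.mean())
                + pars.resid_sd * rng.standard_normal(n)
            )
            out_cols[wave][name] = yw
    for name in OUTCOMES:
        long_df[name] = np.concatenate([out_cols[w][name] for w in WAVES])

    long_df.insert(3, "sex", np.tile(sex, len(WAVES)))
    long_df["observed"] = True
    long_df["observed_outcomes"] = True
    long_df.attrs["seed"] = config.seed
    long_df.attrs["config_hash"] = config.config_hash()
    long_df.attrs["bounds"] = {"lo": bounds.lo, "hi": bounds.hi}
    long_df.attrs["shift_multiplier"] = float(lam)

    if config.missingness.enabled:
        long_df, info = apply_missingness(long_df, config.missingness, rng=miss_rng)
        long_df.attrs.update(info)
    return long_df


# ---------------------------------------------------------------------------
# missingness

_MEDIATOR_BLOCK = tuple(asi.RAW_FIELDS) + asi.DIMENSION_COLUMNS + asi.SCORE_COLUMNS + ("asi12", "asi6")


def apply_missingness(
    data: pd.DataFrame,
    config: MissingnessConfig,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Delete follow-up observations under the logistic MAR model.

    Each participant's wave-3 (and wave-6) measurements are deleted with
    probability ``expit(intercept + beta_age*age + beta_y0*Y0)`` where Y0 is
    the baseline value of the configured driver outcome.  Baseline is never
    deleted.  Returns the masked copy and a dict of marginal rates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    base = data[data["wave"] == 0].set_index("pid")
    if base[config.driver_outcome].isna().any() or base["age"].isna().any():
        raise ConfigError("missingness covariates (age, baseline outcome) contain NaN")
    age = base["age"].to_numpy(float)
    y0 = base[config.driver_outcome].to_numpy(float)
    linpred = config.beta_age * age + config.beta_baseline_outcome * y0
    p3 = expit(config.intercept_3m + linpred)
    p6 = expit(config.intercept_6m + linpred)

    def draw_masks():
        miss3 = rng.random(len(base)) < p3
        miss6 = rng.random(len(base)) < p6
        if config.monotone:
            miss6 |= miss3
        return miss3, miss6

    med3, med6 = draw_masks()
    if config.item_level:
        out3, out6 = draw_masks()
    else:
        out3, out6 = med3, med6

    out = data.copy()
    pid_order = base.index
    masks = {3: (med3, out3), 6: (med6, out6)}
    for wave, (med_mask, out_mask) in masks.items():
        rows = out["wave"] == wave
        med_pids = set(pid_order[med_mask])
        out_pids = set(pid_order[out_mask])
        med_rows = rows & out["pid"].isin(med_pids)
        out_rows = rows & out["pid"].isin(out_pids)
        out.loc[med_rows, list(_MEDIATOR_BLOCK)] = np.nan
        out.loc[med_rows, "observed"] = False
        out.loc[out_rows, list(OUTCOMES)] = np.nan
        out.loc[out_rows, "observed_outcomes"] = False

    info = {
        "missing_rate_3m": float(med3.mean()),
        "missing_rate_6m": float(med6.mean()),
        "completion_rate_3m": float(1.0 - med3.mean()),
        "completion_rate_6m": float(1.0 - med6.mean()),
    }
    logger.info(
        "attrition: %.1f%% missing at 3 months, %.1f%% at 6 months",
        100 * info["missing_rate_3m"], 100 * info["missing_rate_6m"],
    )
    return out, info
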