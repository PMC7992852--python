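"""Pipeline orchestration and IO: simulate/ingest -> score -> describe -> mediate.

The canonical on-disk format is a tidy long CSV, one row per
participant-wave, with the columns listed in ``docs/data_dictionary.md``.
Missing values are empty fields.  Every output file of a run carries the
config hash so result bundles are traceable to their configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asi, descriptives, mediation, synthetic_cohort
from .synthetic_cohort import CohortConfig, OUTCOMES

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pid", "trial", "group", "age", "sex", "wave")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    input_csv: str | None = None  # None => simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcomes: tuple[str, ...] = OUTCOMES
    mediators: tuple[str, ...] = ("asi12",)
    waves: tuple[int, ...] = (3, 6)
    boot: int = 5000
    confidence: float = 0.95
    missing: str = "fiml"
    scheme: str = "table_footnote"
    seed: int = 0
    output_dir: str = "asimed_results"

    def validate(self) -> None:
        bad = [o for o in self.outcomes if o not in OUTCOMES]
        if bad:
            raise PipelineError(f"unknown outcomes {bad}; choose from {OUTCOMES}")
        bad = [m for m in self.mediators if m not in ("asi12", "asi6")]
        if bad:
            raise PipelineError(f"unknown mediators {bad}")
        if any(w not in (3, 6) for w in self.waves):
            raise PipelineError("waves must be drawn from (3, 6)")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land is not part of the analysis
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# IO


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long-format participant-by-wave CSV."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise PipelineError(f"empty input file: {path}")
    data = pd.read_csv(path, float_precision="round_trip")
    if data.empty:
        raise PipelineError(f"input file has no data rows: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise PipelineError(f"input is missing required columns: {missing}")
    dup = data.duplicated(subset=["pid", "wave"])
    if dup.any():
        lines = (data.index[dup] + 2).tolist()[:10]  # +2: header + 1-based
        raise PipelineError(f"duplicated participant-wave keys at lines {lines}")
    bad_wave = ~data["wave"].isin(synthetic_cohort.WAVES)
    if bad_wave.any():
        lines = (data.index[bad_wave] + 2).tolist()[:10]
        raise PipelineError(f"malformed wave values at lines {lines}")
    return data


def write_long_csv(data: pd.DataFrame, path) -> None:
    # shortest round-trip repr so write->read reproduces values exactly
    data.to_csv(path, index=False, na_rep="", float_format=lambda v: repr(float(v)))


def score_dataset(data: pd.DataFrame, *, bounds: asi.RescaleBounds | None = None):
    """Derive dimensions (if absent) and attach ASI scores; returns (df, bounds)."""
    out = data.copy()
    if not set(asi.DIMENSION_COLUMNS).issubset(out.columns):
        dims = asi.derive_dimensions(out)
        out = pd.concat([out.drop(columns=[c for c in dims.columns if c in out.columns]), dims], axis=1)
    if bounds is None:
        bounds = asi.compute_bounds(out)
    out = asi.compose_asi(out, bounds)
    return out, bounds


# ---------------------------------------------------------------------------
# reporting helpers


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def proportion_mediated_pct(ab: float, c_total: float) -> int | None:
    """Proportion mediated as a whole percentage, 100*AB/C rounded half away."""
    prop = mediation.proportion_mediated(ab, c_total)
    if prop is None:
        return None
    return int(round_half_away(prop))


def mediation_table(results: list[dict]) -> pd.DataFrame:
    """Shape mediation results like the published tables:
    A (SE), B (SE), Direct (SE), C (SE), AB [95% CI], proportion mediated."""
    rows = []
    for r in results:
        est: mediation.PathEstimates = r["estimates"]
        rows.append(
            {
                "outcome": r["outcome"],
                "mediator": r["mediator"],
                "wave": r["wave"],
                "A": est.a, "A_se": est.a_se,
                "B": est.b, "B_se": est.b_se,
                "Direct": est.c_prime, "Direct_se": est.c_prime_se,
                "C": est.c_total, "C_se": est.c_total_se,
                "AB": est.ab, "AB_se": est.ab_se,
                "AB_ci_lo": est.ab_ci[0] if est.ab_ci else np.nan,
                "AB_ci_hi": est.ab_ci[1] if est.ab_ci else np.nan,
                "prop_mediated_pct": (
                    proportion_mediated_pct(est.ab, est.c_total)
                    if est.proportion_mediated is not None else np.nan
                ),
                "n": est.n_bc,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write a result bundle to ``config.output_dir``.

    Returns the bundle as a dict: scored dataset, bounds, descriptive tables,
    mediation table and metadata.  Deterministic under a fixed seed.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is None:
        cohort_cfg = config.cohort
        if cohort_cfg.seed != config.seed:
            from dataclasses import replace

            cohort_cfg = replace(cohort_cfg, seed=config.seed)
        data = synthetic_cohort.simulate_cohort(cohort_cfg)
        logger.info("simulated %d participants (%d rows)", cohort_cfg.n_total, len(data))
        scored = data
        bounds = asi.RescaleBounds(**data.attrs["bounds"])
    else:
        data = read_long_csv(config.input_csv)
        logger.info("read %d rows from %s", len(data), config.input_csv)
        scored, bounds = score_dataset(data)
        if "observed" not in scored.columns:
            scored["observed"] = scored["asi12"].notna() | (scored["wave"] == 0)

    n_participants = scored.loc[scored["wave"] == 0, "pid"].nunique()
    table1 = descriptives.group_descriptives(
        scored, tuple(config.outcomes), waves=(0,)
    )
    table2 = descriptives.group_descriptives(
        scored, ("asi12", "asi6") + asi.SCORE_COLUMNS, waves=(0,) + tuple(config.waves)
    )
    completers = descriptives.compare_completers(
        scored, wave=min(config.waves), baseline_outcomes=tuple(config.outcomes)
    )
    logger.info(
        "completion at %d months: %.1f%% of %d participants",
        min(config.waves), completers.attrs["completion_rate_pct"], n_participants,
    )

    results = []
    rng = np.random.default_rng(config.seed + 1)
    for mediator in config.mediators:
        for wave in config.waves:
            for outcome in config.outcomes:
                spec = mediation.MediationSpec(
                    mediator=mediator, outcome=outcome, wave=wave,
                    scheme=config.scheme, boot=config.boot,
                    confidence=config.confidence, missing=config.missing,
                )
                wide = mediation.make_wide(scored, spec)
                if spec.missing == "fiml":
                    est = mediation.fiml_fit(wide, spec)
                    ci = mediation.bc_bootstrap_ci(
                        wide, spec, rng=rng,
                        estimator=lambda w: mediation.fiml_fit(w, spec, compute_se=False).ab,
                    )
                else:
                    est = mediation.estimate_paths(wide, spec)
                    ci = mediation.bc_bootstrap_ci(wide, spec, rng=rng)
                est.ab_ci = ci
                results.append(
                    {"outcome": outcome, "mediator": mediator, "wave": wave, "estimates": est}
                )
                logger.info(
                    "mediation %s/%s wave %d: AB=%.3f CI=(%.3f, %.3f) [n=%d]",
                    mediator, outcome, wave, est.ab, ci[0], ci[1], est.n_bc,
                )

    med_table = mediation_table(results)
    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_participants": int(n_participants),
        "scored": scored,
        "bounds": bounds,
        "table1": table1,
        "table2": table2,
        "completers": completers,
        "mediation": med_table,
    }
    write_results(bundle, outdir)
    return bundle


def write_results(bundle: dict, outdir) -> None:
    """Write the result bundle: CSVs, bounds sidecar and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_long_csv(bundle["scored"], outdir / "scored_dataset.csv")
    bundle["bounds"].to_json(outdir / "rescale_bounds.json")
    for key in ("table1", "table2", "completers", "mediation"):
        bundle[key].to_csv(outdir / f"{key}.csv", index=False, float_format="%.6g")
    summary = {
        "config_hash": bundle["config_hash"],
        "seed": bundle["seed"],
        "n_participants": bundle["n_participants"],
        "completion": {
            k: bundle["completers"].attrs[k]
            for k in ("n_baseline", "n_completers", "completion_rate_pct")
        },
        "mediation": json.loads(
            bundle["mediation"].to_json(orient="records", double_precision=10)
        ),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig (and nested CohortConfig) from YAML."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    cohort_payload = payload.pop("cohort", None)
    cfg = RunConfig(**{k: v for k, v in payload.items() if k in RunConfig.__dataclass_fields__})
    if cohort_payload:
        trials = tuple(
            synthetic_cohort.TrialConfig(**t) for t in cohort_payload.pop("trials", [])
        ) or synthetic_cohort._default_trials()
        outcomes = {
            k: synthetic_cohort.OutcomeParams(**v)
            for k, v in cohort_payload.pop("outcomes", {}).items()
        } or synthetic_cohort._default_outcomes()
        missing_payload = cohort_payload.pop("missingness", None)
        missingness = (
            synthetic_cohort.MissingnessConfig(**missing_payload)
            if missing_payload else synthetic_cohort.MissingnessConfig()
        )
        cfg.cohort = CohortConfig(
            trials=trials, outcomes=outcomes, missingness=missingness, **cohort_payload
        )
    for t in ("outcomes", "mediators", "waves"):
        if isinstance(getattr(cfg, t), list):
            setattr(cfg, t, tuple(getattr(cfg, t)))
    return cfg
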