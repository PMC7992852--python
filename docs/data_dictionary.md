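# Data dictionary — long participant-by-wave table

One row per participant per assessment wave. Missing values are empty
fields. This is the canonical format written by `asimed simulate` /
`run-all` and accepted by `score`, `describe` and `mediate`.

## Keys and design

| column | type | description |
|---|---|---|
| `pid` | str | participant identifier, unique within the dataset |
| `trial` | str | pooled-trial label (`synergy` or `refresh`); the second label in sort order becomes the study indicator = 1 |
| `group` | int | 1 = intervention (combined physical activity + sleep), 0 = wait-list control |
| `sex` | str | `female` / `male` |
| `age` | float | years at baseline (repeated on every wave row) |
| `wave` | int | months since baseline: 0, 3 or 6 |
| `observed` | bool | behaviour instruments (mediator block) observed at this wave |
| `observed_outcomes` | bool | outcome questionnaires observed at this wave |

## Raw behaviour fields (questionnaire level)

| column | units/range | description |
|---|---|---|
| `walk_min_wk`, `mod_min_wk`, `vig_min_wk` | min/wk | walking, moderate and vigorous activity minutes (Active-Australia-style recall) |
| `mvpa_sessions_wk` | sessions/wk | MVPA session count |
| `rt_days_wk` | days/wk, 0–7 | resistance-training frequency |
| `sitting_min_day` | min/day | total sitting time |
| `daytime_sleepiness` | ordinal 0–3 | trouble staying awake (higher = worse) |
| `sleep_quality_rating` | ordinal 0–3 | overall sleep quality (higher = worse) |
| `bedtime` | `HH:MM` | habitual bedtime |
| `sleep_duration_hr` | hours | self-reported sleep duration |
| `time_in_bed_hr` | hours | time in bed (wake − bed) |
| `sleep_variability` | ordinal 0–8 | sum of two bed/wake-time variability items (higher = more variable) |

## Derived dimensions (`dim_*`), rescaled scores (`score_*`), totals

Twelve dimensions in index order: `mvpa_freq`, `rt_freq`, `intensity`,
`type`, `mvpa_dur`, `sitting`, `alertness`, `quality`, `timing`,
`regularity`, `efficiency`, `duration`. Each `dim_<name>` is the raw-scale
dimension value; each `score_<name>` is its 0–10 min–max rescaled,
risk-oriented score. `asi12` (0–120) sums all twelve; `asi6` (0–60) sums
`rt_freq`, `mvpa_dur`, `sitting`, `quality`, `efficiency`, `duration`.
Risk-reversed dimensions (higher raw = higher risk): `sitting`,
`alertness`, `quality`, `regularity`.

## Outcome scales

| column | range convention | direction |
|---|---|---|
| `dass_depression`, `dass_anxiety`, `dass_stress` | doubled DASS-21 subscales (0–42 in real data) | higher = worse |
| `qol_physical`, `qol_mental` | SF-12 component scores | higher = better |
| `energy_fatigue` | 0–100 RAND-36 subscale | higher = better |

Synthetic outcomes are generated on an unbounded Gaussian scale (see
`docs/methods.md`), so simulated values may fall outside the instrument
ranges quoted above.
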