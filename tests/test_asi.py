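"""Index construction: rescaling, bounds, dimension derivation, totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asimed import asi


def dim_row(**overrides):
    """One row of raw dimension values, midrange everywhere by default."""
    base = {
        "dim_mvpa_freq": 2.0, "dim_rt_freq": 1.0, "dim_intensity": 0.2,
        "dim_type": 1.0, "dim_mvpa_dur": 120.0, "dim_sitting": 500.0,
        "dim_alertness": 1.0, "dim_quality": 2.0, "dim_timing": 1.0,
        "dim_regularity": 4.0, "dim_efficiency": 80.0, "dim_duration": 0.0,
    }
    base.update(overrides)
    return base


def synthetic_bounds():
    """Plausible fixed bounds covering every dimension."""
    lo = {"mvpa_freq": 0, "rt_freq": 0, "intensity": 0, "type": 0, "mvpa_dur": 0,
          "sitting": 120, "alertness": 0, "quality": 0, "timing": 0,
          "regularity": 0, "efficiency": 40, "duration": 0}
    hi = {"mvpa_freq": 10, "rt_freq": 7, "intensity": 1, "type": 2, "mvpa_dur": 840,
          "sitting": 1080, "alertness": 3, "quality": 3, "timing": 1,
          "regularity": 8, "efficiency": 100, "duration": 1}
    return asi.RescaleBounds(lo={k: float(v) for k, v in lo.items()},
                             hi={k: float(v) for k, v in hi.items()})


class TestRescale:
    @pytest.mark.parametrize(
        "x, lo, hi, reversed_risk, expected",
        [
            (2.0, 2.0, 8.0, False, 0.0),      # lower bound
            (8.0, 2.0, 8.0, False, 10.0),     # upper bound
            (5.0, 2.0, 8.0, True, 5.0),       # midpoint of a reversed dimension
            (8.0, 2.0, 8.0, True, 0.0),
            (11.0, 2.0, 8.0, False, 10.0),    # clipped to the frozen bounds
        ],
    )
    def test_formula(self, x, lo, hi, reversed_risk, expected):
        assert asi.rescale_dimension(x, lo, hi, reversed_risk=reversed_risk) == pytest.approx(expected)

    def test_degenerate_bounds_score_half(self, caplog):
        with caplog.at_level("WARNING", logger="asimed.asi"):
            assert asi.rescale_dimension(3.0, 3.0, 3.0) == 5.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_non_finite_value_rejected(self):
        with pytest.raises(asi.AsiError):
            asi.rescale_dimension(float("nan"), 0.0, 1.0)

    @given(
        lo=st.floats(-100, 100),
        width=st.floats(0.1, 100),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
        reversed_risk=st.booleans(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_monotonicity(self, lo, width, t1, t2, reversed_risk):
        hi = lo + width
        x1, x2 = lo + min(t1, t2) * width, lo + max(t1, t2) * width
        s1 = asi.rescale_dimension(x1, lo, hi, reversed_risk=reversed_risk)
        s2 = asi.rescale_dimension(x2, lo, hi, reversed_risk=reversed_risk)
        assert 0.0 <= s1 <= 10.0 and 0.0 <= s2 <= 10.0
        if reversed_risk:
            assert s2 <= s1 + 1e-9
        else:
            assert s1 <= s2 + 1e-9

    @given(
        x=st.floats(0, 1), scale=st.floats(0.5, 20), shift=st.floats(-50, 50)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_affine_invariance(self, x, scale, shift):
        """Re-expressing a dimension's units leaves the score unchanged once
        bounds are recomputed on the new scale."""
        direct = asi.rescale_dimension(x, 0.0, 1.0)
        rescaled = asi.rescale_dimension(scale * x + shift, shift, scale + shift)
        assert direct == pytest.approx(rescaled, abs=1e-6)


class TestBounds:
    def test_single_profile_degenerate(self):
        df = pd.DataFrame([dim_row()])
        b = asi.compute_bounds(df)
        for d in asi.DIMENSIONS:
            assert b.lo[d.name] == b.hi[d.name]

    def test_bounds_span_all_waves(self):
        df = pd.DataFrame([dim_row(dim_mvpa_freq=2.0), dim_row(dim_mvpa_freq=8.0)])
        b = asi.compute_bounds(df)
        assert (b.lo["mvpa_freq"], b.hi["mvpa_freq"]) == (2.0, 8.0)

    def test_missing_values_ignored(self):
        df = pd.DataFrame([dim_row(dim_quality=1.0), dim_row(dim_quality=np.nan), dim_row(dim_quality=5.0)])
        b = asi.compute_bounds(df)
        assert (b.lo["quality"], b.hi["quality"]) == (1.0, 5.0)

    def test_entirely_missing_dimension_named_in_error(self):
        df = pd.DataFrame([dim_row(dim_timing=np.nan), dim_row(dim_timing=np.nan)])
        with pytest.raises(asi.AsiError, match="timing"):
            asi.compute_bounds(df)

    def test_json_roundtrip(self, tmp_path):
        b = synthetic_bounds()
        b.to_json(tmp_path / "b.json")
        b2 = asi.RescaleBounds.from_json(tmp_path / "b.json")
        assert b2.lo == b.lo and b2.hi == b.hi


def raw_row(**overrides):
    base = {
        "walk_min_wk": 60.0, "mod_min_wk": 30.0, "vig_min_wk": 30.0,
        "mvpa_sessions_wk": 3.0, "rt_days_wk": 1.0, "sitting_min_day": 480.0,
        "daytime_sleepiness": 1.0, "sleep_quality_rating": 2.0,
        "bedtime": "23:00", "sleep_duration_hr": 8.0, "time_in_bed_hr": 9.0,
        "sleep_variability": 4.0, "age": 45.0,
    }
    base.update(overrides)
    return base


class TestDeriveDimensions:
    def test_activity_type_membership(self):
        df = pd.DataFrame([
            raw_row(walk_min_wk=0, mod_min_wk=0, vig_min_wk=0, rt_days_wk=0),
            raw_row(walk_min_wk=30, mod_min_wk=0, vig_min_wk=0, rt_days_wk=0),
            raw_row(walk_min_wk=30, rt_days_wk=2),
        ])
        dims = asi.derive_dimensions(df)
        assert dims["dim_type"].tolist() == [0.0, 1.0, 2.0]

    def test_vigorous_fraction(self):
        df = pd.DataFrame([
            raw_row(walk_min_wk=60, mod_min_wk=30, vig_min_wk=30),
            raw_row(walk_min_wk=0, mod_min_wk=0, vig_min_wk=0),
        ])
        dims = asi.derive_dimensions(df)
        assert dims["dim_intensity"].tolist() == pytest.approx([0.25, 0.0])

    def test_midpoint_in_window(self):
        # 23:00 bedtime + 8 h sleep -> midpoint 03:00, inside 02:00-04:00
        df = pd.DataFrame([raw_row(bedtime="23:00", sleep_duration_hr=8.0),
                           raw_row(bedtime="21:00", sleep_duration_hr=6.0)])
        dims = asi.derive_dimensions(df)
        assert asi.sleep_midpoint("23:00", 8.0) == 180.0
        assert dims["dim_timing"].tolist() == [1.0, 0.0]

    def test_sleep_efficiency(self):
        df = pd.DataFrame([raw_row(sleep_duration_hr=7.5, time_in_bed_hr=9.0)])
        dims = asi.derive_dimensions(df)
        assert dims["dim_efficiency"].iloc[0] == pytest.approx(7.5 / 9.0 * 100.0)

    def test_duration_guideline(self):
        df = pd.DataFrame([raw_row(sleep_duration_hr=8.0), raw_row(sleep_duration_hr=6.0),
                           raw_row(sleep_duration_hr=7.0), raw_row(sleep_duration_hr=9.0)])
        dims = asi.derive_dimensions(df)
        assert dims["dim_duration"].tolist() == [1.0, 0.0, 1.0, 1.0]

    def test_mvpa_minutes_capped(self):
        df = pd.DataFrame([raw_row(walk_min_wk=700, mod_min_wk=200, vig_min_wk=100)])
        dims = asi.derive_dimensions(df)
        assert dims["dim_mvpa_dur"].iloc[0] == asi.MVPA_MINUTES_CAP

    def test_unparseable_clock_raises(self):
        df = pd.DataFrame([raw_row(bedtime="25:99")])
        with pytest.raises(asi.AsiError, match="clock"):
            asi.derive_dimensions(df)

    def test_missing_raw_field_propagates(self):
        df = pd.DataFrame([raw_row(sleep_duration_hr=np.nan)])
        dims = asi.derive_dimensions(df)
        assert np.isnan(dims["dim_duration"].iloc[0])
        assert np.isnan(dims["dim_timing"].iloc[0])


class TestComposeAsi:
    def best_and_worst(self):
        b = synthetic_bounds()
        best, worst = {}, {}
        for d in asi.DIMENSIONS:
            best[d.name] = b.lo[d.name] if d.reversed_risk else b.hi[d.name]
            worst[d.name] = b.hi[d.name] if d.reversed_risk else b.lo[d.name]
        return b, best, worst

    def test_range_extremes(self):
        b, best, worst = self.best_and_worst()
        assert asi.score_profile(best, b).asi12 == pytest.approx(120.0)
        assert asi.score_profile(worst, b).asi12 == pytest.approx(0.0)
        assert asi.score_profile(best, b).asi6 == pytest.approx(60.0)

    def test_half_best_half_worst(self):
        b, best, worst = self.best_and_worst()
        mixed = dict(best)
        for d in list(asi.DIMENSIONS)[:6]:
            mixed[d.name] = worst[d.name]
        assert asi.score_profile(mixed, b).asi12 == pytest.approx(60.0)

    def test_additivity_and_asi6_subset(self):
        rng = np.random.default_rng(3)
        b = synthetic_bounds()
        rows = []
        for _ in range(20):
            rows.append({d.column: rng.uniform(b.lo[d.name], b.hi[d.name]) for d in asi.DIMENSIONS})
        scored = asi.compose_asi(pd.DataFrame(rows), b)
        totals = scored[[f"score_{d.name}" for d in asi.DIMENSIONS]].sum(axis=1)
        np.testing.assert_allclose(scored["asi12"], totals, atol=1e-12)
        sub = scored[[f"score_{n}" for n in asi.ASI6_NAMES]].sum(axis=1)
        np.testing.assert_allclose(scored["asi6"], sub, atol=1e-12)
        assert scored["asi12"].between(0, 120).all()

    def test_partially_missing_profile_is_missing(self):
        b = synthetic_bounds()
        rows = pd.DataFrame([dim_row(), dim_row(dim_alertness=np.nan)])
        scored = asi.compose_asi(rows, b)
        assert np.isfinite(scored["asi12"].iloc[0])
        assert np.isnan(scored["asi12"].iloc[1])
        # the missing dimension is not in the ASI-6 subset, so asi6 survives
        assert np.isfinite(scored["asi6"].iloc[1])


class TestDimensionCorrelations:
    def scored_frame(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        b = synthetic_bounds()
        rows = [{d.column: rng.uniform(b.lo[d.name], b.hi[d.name]) for d in asi.DIMENSIONS} for _ in range(n)]
        return asi.compose_asi(pd.DataFrame(rows), b)

    def test_unit_diagonal_and_symmetry(self):
        corr = asi.dimension_correlations(self.scored_frame())
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        assert np.nanmax(np.abs(corr.values)) <= 1.0 + 1e-12

    def test_monotone_pair_is_one(self):
        scored = self.scored_frame()
        scored["score_mvpa_freq"] = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        scored["score_rt_freq"] = [10.0, 20.0, 35.0, 40.0, 58.0, 61.0]
        corr = asi.dimension_correlations(scored)
        assert corr.loc["score_mvpa_freq", "score_rt_freq"] == pytest.approx(1.0)

    def test_tied_ranks_match_midrank_oracle(self):
        # x = (1,2,2,3) has midranks (1, 2.5, 2.5, 4); against y = (1,2,3,4)
        # the Pearson correlation of ranks is 4.5/sqrt(4.5*5) = 3/sqrt(10)
        scored = self.scored_frame(n=4)
        scored["score_quality"] = [1.0, 2.0, 2.0, 3.0]
        scored["score_sitting"] = [1.0, 2.0, 3.0, 4.0]
        corr = asi.dimension_correlations(scored)
        assert corr.loc["score_quality", "score_sitting"] == pytest.approx(3.0 / np.sqrt(10.0))

    def test_constant_column_reported_missing(self):
        scored = self.scored_frame()
        scored["score_timing"] = 5.0
        corr = asi.dimension_correlations(scored)
        off_diag = corr.loc["score_timing"].drop("score_timing")
        assert off_diag.isna().all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(asi.AsiError):
            asi.dimension_correlations(self.scored_frame(n=2))
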