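"""Unit and property tests for linear reaction-norm fitting and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from thermnorm.reaction_norms import (
    LinearNorm,
    RegimenObservation,
    StageSeries,
    classify_quality,
    dedup_species,
    derive_elevation,
    fit_all_series,
    fit_linear,
    pool_sexes,
    read_development_csv,
    to_rates,
    truncate_to_linear,
)

from conftest import linear_series, make_series


class TestObservations:
    def test_nonpositive_dev_time_rejected(self):
        with pytest.raises(ValueError):
            RegimenObservation(20.0, 0.0)
        with pytest.raises(ValueError):
            RegimenObservation(20.0, -3.0)

    def test_nonfinite_temperature_rejected(self):
        with pytest.raises(ValueError):
            RegimenObservation(float("nan"), 10.0)

    def test_series_sorts_and_rejects_duplicate_temperatures(self):
        s = make_series([25, 15, 20], [5, 20, 10])
        assert list(s.temperatures) == [15, 20, 25]
        with pytest.raises(ValueError, match="duplicate temperature"):
            make_series([15, 15, 20], [20, 19, 10])

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            make_series([15, 20, 25], [20, 10, 5], stage="imago")


class TestPoolSexes:
    def test_weighted_mean_when_sample_sizes_known(self):
        m = make_series([20.0], [10.0], n=10, sex="male", stage="egg")
        f = make_series([20.0], [12.0], n=30, sex="female", stage="egg")
        pooled = pool_sexes(m, f)
        assert pooled.observations[0].dev_time == pytest.approx(11.5)
        assert pooled.observations[0].n == 40
        assert pooled.observations[0].sex == "pooled"

    def test_simple_mean_without_sample_sizes(self):
        m = make_series([20.0], [10.0], sex="male", stage="egg")
        f = make_series([20.0], [12.0], sex="female", stage="egg")
        assert pool_sexes(m, f).observations[0].dev_time == pytest.approx(11.0)

    def test_identical_series_unchanged(self):
        m = make_series([15, 20, 25], [20, 10, 5], sex="male")
        f = make_series([15, 20, 25], [20, 10, 5], sex="female")
        pooled = pool_sexes(m, f)
        assert np.allclose(pooled.dev_times, m.dev_times)

    def test_mismatched_grid_names_offending_temperature(self):
        m = make_series([15, 20, 25], [20, 10, 5], sex="male")
        f = make_series([15, 22, 25], [20, 10, 5], sex="female")
        with pytest.raises(ValueError, match="20.*22"):
            pool_sexes(m, f)


class TestToRates:
    def test_reciprocal_and_order(self):
        s = make_series([15, 20, 25], [20.0, 10.0, 5.0])
        assert to_rates(s) == [(15, 0.05), (20, 0.1), (25, 0.2)]


class TestFitLinear:
    def test_exact_line(self):
        norm = fit_linear([(15, 0.05), (20, 0.10), (25, 0.15)])
        assert norm.intercept_a == pytest.approx(-0.10)
        assert norm.slope_b == pytest.approx(0.01)
        assert norm.ltt == pytest.approx(10.0)
        assert norm.sdd == pytest.approx(100.0)
        assert norm.r_squared == pytest.approx(1.0)
        assert norm.quality == "good"

    def test_four_point_fit_matches_normal_equations(self):
        T = [15.0, 20.0, 25.0, 30.0]
        R = [0.048, 0.101, 0.149, 0.203]
        norm = fit_linear(list(zip(T, R)))
        # independent oracle: explicit normal equations
        t, r = np.array(T), np.array(R)
        b = np.sum((t - t.mean()) * (r - r.mean())) / np.sum((t - t.mean()) ** 2)
        a = r.mean() - b * t.mean()
        assert norm.slope_b == pytest.approx(b, abs=1e-12)
        assert norm.intercept_a == pytest.approx(a, abs=1e-12)
        assert norm.slope_b == pytest.approx(0.01026, abs=1e-5)
        # second independent route
        lr = stats.linregress(t, r)
        assert norm.slope_b == pytest.approx(lr.slope, abs=1e-10)
        assert norm.r_squared == pytest.approx(lr.rvalue**2, abs=1e-10)

    def test_negative_slope_flags_ltt_undefined(self):
        norm = fit_linear([(15, 0.15), (20, 0.10), (25, 0.05)])
        assert norm.slope_b < 0
        assert not norm.usable
        assert np.isnan(norm.ltt) and np.isnan(norm.sdd)

    def test_too_few_distinct_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([(15, 0.1), (20, 0.2)])

    @given(
        a=st.floats(-0.2, -0.01),
        b=st.floats(0.002, 0.02),
        noise=st.lists(st.floats(-0.003, 0.003), min_size=5, max_size=5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_identities_hold_for_positive_slopes(self, a, b, noise):
        """LTT * b + a = 0 and b * SDD = 1 for every usable fit."""
        T = [14.0, 18.0, 22.0, 26.0, 30.0]
        pts = [(t, a + b * t + e) for t, e in zip(T, noise)]
        if any(r <= 0 for _, r in pts):
            return
        norm = fit_linear(pts)
        if not norm.usable:
            return
        tol = 1e-12 * max(1.0, abs(norm.intercept_a))
        assert abs(norm.ltt * norm.slope_b + norm.intercept_a) <= tol
        assert norm.slope_b * norm.sdd == pytest.approx(1.0, rel=1e-12)

    @given(
        rates=st.lists(st.floats(0.01, 0.5), min_size=4, max_size=8, unique=True)
    )
    @settings(max_examples=60, derandomize=True)
    def test_ols_matches_linregress_oracle(self, rates):
        T = np.linspace(10, 35, len(rates))
        norm = fit_linear(list(zip(T, rates)))
        lr = stats.linregress(T, rates)
        assert norm.intercept_a == pytest.approx(lr.intercept, abs=1e-10)
        assert norm.slope_b == pytest.approx(lr.slope, abs=1e-10)


class TestElevation:
    def test_mean_of_observed_rates(self):
        norm = fit_linear([(15, 0.05), (20, 0.10), (25, 0.15)])
        assert derive_elevation(norm, [(15, 0.05), (20, 0.10), (25, 0.15)]) == pytest.approx(0.10)

    def test_equals_line_at_mean_temperature_for_exact_data(self):
        a, b = -0.08, 0.008
        pts = [(t, a + b * t) for t in (16, 20, 24, 28)]
        norm = fit_linear(pts)
        assert norm.elevation == pytest.approx(a + b * np.mean([16, 20, 24, 28]))

    def test_empty_points_error(self):
        norm = fit_linear([(15, 0.05), (20, 0.10), (25, 0.15)])
        with pytest.raises(ValueError):
            derive_elevation(norm, [])


class TestQualityGate:
    @pytest.mark.parametrize(
        "r2,expected",
        [(0.980, "good"), (0.979, "bad"), (1.0, "good"), (0.0, "bad"),
         (0.9799999, "bad"), (0.9800001, "good")],
    )
    def test_split_at_0_980(self, r2, expected):
        assert classify_quality(r2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_quality(-0.1)


class TestTruncation:
    def test_perfectly_linear_series_unchanged(self):
        s = linear_series(-0.1, 0.01, [15, 18, 21, 24, 27])
        assert truncate_to_linear(s) is not None
        assert len(truncate_to_linear(s)) == 5

    def test_sigmoid_extremes_removed(self):
        """Depressed rates at both ends of a 5-point grid leave the middle 3."""
        a, b = -0.1, 0.01
        temps = [8, 14, 20, 26, 32]
        # sigmoid: flat tail near zero at the cold end, plateau at the hot end,
        # exact line a + bT in the middle
        rates = [0.010, a + b * 14, a + b * 20, a + b * 26, 0.170]
        s = make_series(temps, [1 / r for r in rates])
        out = truncate_to_linear(s)
        assert list(out.temperatures) == [14, 20, 26]
        # exhaustive-window oracle: every other window fits worse than 0.980
        pts = to_rates(s)
        for start in range(0, 3):
            for stop in range(start + 3, 6):
                if (start, stop) == (1, 4):
                    continue
                win = pts[start:stop]
                lr = stats.linregress([p[0] for p in win], [p[1] for p in win])
                assert lr.rvalue**2 < 0.980

    def test_three_point_nonlinear_series_kept_whole(self):
        s = make_series([15, 20, 25], [20.0, 12.0, 5.0])
        assert len(truncate_to_linear(s)) == 3

    @given(
        rates=st.lists(st.floats(0.02, 0.4), min_size=3, max_size=9, unique=True)
    )
    @settings(max_examples=60, derandomize=True)
    def test_only_contiguous_end_windows_removed(self, rates):
        temps = np.linspace(10, 34, len(rates))
        s = make_series(temps, [1 / r for r in rates])
        out = truncate_to_linear(s)
        assert len(out) >= 3
        kept = list(out.temperatures)
        full = list(s.temperatures)
        start = full.index(kept[0])
        assert full[start : start + len(kept)] == kept  # contiguous window


class TestDedup:
    def _rec(self, species, r2, n_temps=4, stage="total", order_tag=""):
        temps = list(np.linspace(15, 30, n_temps))
        s = linear_series(-0.1, 0.01, temps, species_id=species,
                          source_id=order_tag or "s")
        norm = LinearNorm(
            species_id=species, stage=stage, intercept_a=-0.1, slope_b=0.01,
            ltt=10.0, sdd=100.0, elevation=0.1, r_squared=r2,
            quality="good" if r2 >= 0.98 else "bad",
            temps_used=tuple(temps), source_id=order_tag or "s",
        )
        return (s, norm)

    def test_higher_r2_wins(self):
        out = dedup_species([self._rec("A", 0.987), self._rec("A", 0.995)])
        assert len(out) == 1
        assert out[0][1].r_squared == 0.995

    def test_single_record_kept(self):
        assert len(dedup_species([self._rec("A", 0.99)])) == 1

    def test_tie_broken_by_more_temperatures_then_order(self):
        out = dedup_species(
            [self._rec("A", 0.99, n_temps=4), self._rec("A", 0.99, n_temps=6)]
        )
        assert len(out[0][1].temps_used) == 6
        out = dedup_species(
            [self._rec("A", 0.99, order_tag="first"),
             self._rec("A", 0.99, order_tag="second")]
        )
        assert out[0][1].source_id == "first"

    def test_good_and_bad_deduplicated_independently(self):
        out = dedup_species([self._rec("A", 0.99), self._rec("A", 0.90)])
        assert len(out) == 2
        assert {r[1].quality for r in out} == {"good", "bad"}


class TestCsvRoundTrip:
    def test_read_groups_and_pools(self, tmp_path):
        rows = []
        for sex, times in (("male", [20.0, 10.0, 6.0]), ("female", [22.0, 12.0, 8.0])):
            for t, d in zip([15, 20, 25], times):
                rows.append(dict(species_id="A", stage="egg", source_id="s1",
                                 temperature_C=t, dev_time_days=d, n=10, sex=sex))
        for t, d in zip([15, 20, 25], [30.0, 15.0, 9.0]):
            rows.append(dict(species_id="B", stage="egg", source_id="s2",
                             temperature_C=t, dev_time_days=d, n=None, sex=None))
        path = tmp_path / "dev.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        series = read_development_csv(path)
        assert len(series) == 2
        a = next(s for s in series if s.species_id == "A")
        assert a.observations[0].sex == "pooled"
        assert a.observations[0].dev_time == pytest.approx(21.0)

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "dev.csv"
        pd.DataFrame({"species_id": ["A"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_development_csv(path)


def test_fit_all_series_end_to_end():
    series = [
        linear_series(-0.1, 0.01, [15, 20, 25, 30], species_id="A"),
        make_series([15, 20, 25, 30], [25.0, 11.0, 6.2, 4.9], species_id="B"),
    ]
    records = fit_all_series(series)
    assert {nm.species_id for _, nm in records} == {"A", "B"}
    byid = {nm.species_id: nm for _, nm in records}
    assert byid["A"].quality == "good"
    assert byid["A"].r_squared == pytest.approx(1.0)
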