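import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ontopace import (
    daily_max_displacement,
    detect_fledging,
    great_circle_m,
    read_movebank_csv,
    resample_fixes,
    write_movebank_csv,
)
from ontopace.preprocessing import EARTH_RADIUS_M, DisplacementSeries


def fix_table(rows):
    return pd.DataFrame(rows, columns=["individual", "timestamp", "lon", "lat"])


coord = st.tuples(
    st.floats(-179.9, 179.9), st.floats(-89.0, 89.0)
)


class TestGreatCircle:
    def test_identity(self):
        assert great_circle_m((34.5, 31.2), (34.5, 31.2)) == 0.0

    def test_one_degree_arc(self):
        # one degree along the equator = pi * R / 180
        expected = math.pi * EARTH_RADIUS_M / 180.0
        assert great_circle_m((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            expected, rel=1e-9
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_m((0.0, 95.0), (0.0, 0.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(p=coord, q=coord)
    def test_symmetry(self, p, q):
        assert great_circle_m(p, q) == pytest.approx(great_circle_m(q, p), abs=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(p=coord, q=coord, r=coord)
    def test_triangle_inequality(self, p, q, r):
        dpq = great_circle_m(p, q)
        dqr = great_circle_m(q, r)
        dpr = great_circle_m(p, r)
        assert dpr <= dpq + dqr + 1e-6 * max(dpr, 1.0)


class TestResample:
    def test_bin_rule_keeps_earliest(self):
        fixes = fix_table(
            [
                ("a", "2020-01-01 00:00:00Z", 35.0, 32.0),
                ("a", "2020-01-01 00:30:00Z", 35.1, 32.0),
                ("a", "2020-01-01 01:10:00Z", 35.2, 32.0),
            ]
        )
        out = resample_fixes(fixes, 60)
        assert len(out) == 2
        assert list(out["lon"]) == [35.0, 35.2]

    def test_hourly_data_unchanged(self):
        ts = pd.date_range("2020-01-01", periods=5, freq="1h", tz="UTC")
        fixes = fix_table([("a", t, 35.0 + i * 0.01, 32.0) for i, t in enumerate(ts)])
        out = resample_fixes(fixes, 60)
        assert len(out) == 5

    def test_burst_collapses_to_single_fix(self):
        ts = pd.date_range("2020-01-01 06:00", periods=3600, freq="1s", tz="UTC")
        fixes = fix_table([("a", t, 35.0, 32.0) for t in ts])
        assert len(resample_fixes(fixes, 60)) == 1

    def test_empty_table_passes_through(self):
        out = resample_fixes(fix_table([]), 60)
        assert out.empty

    def test_more_fixes_never_survive_smaller_interval(self):
        ts = pd.date_range("2020-01-01", periods=50, freq="7min", tz="UTC")
        fixes = fix_table([("a", t, 35.0, 32.0) for t in ts])
        n60 = len(resample_fixes(fixes, 60))
        n30 = len(resample_fixes(fixes, 30))
        assert n60 <= n30 <= len(fixes)


class TestDetectFledging:
    nest = (35.0, 32.0)

    def _fixes_at_distance(self, meters, day="2020-06-01"):
        # move north: meters / R radians of latitude
        dlat = math.degrees(meters / EARTH_RADIUS_M)
        return ("a", f"{day} 10:00:00Z", self.nest[0], self.nest[1] + dlat)

    def test_within_nest_error_never_fledges(self):
        fixes = fix_table([self._fixes_at_distance(100.0)])
        assert detect_fledging(fixes, self.nest) is None

    def test_first_day_beyond_threshold(self):
        rows = [self._fixes_at_distance(50.0, f"2020-06-{d:02d}") for d in range(1, 12)]
        rows.append(self._fixes_at_distance(500.0, "2020-06-12"))
        fledge = detect_fledging(fix_table(rows), self.nest)
        assert fledge == pd.Timestamp("2020-06-12", tz="UTC")

    def test_threshold_is_inclusive(self):
        # a fix at exactly the threshold distance counts as fledged
        fixes = fix_table([self._fixes_at_distance(200.0)])
        d = great_circle_m(
            self.nest, (fixes["lon"].iloc[0], fixes["lat"].iloc[0])
        )
        assert detect_fledging(fixes, self.nest, threshold_m=d) is not None
        assert detect_fledging(fixes, self.nest, threshold_m=d + 1e-6) is None


class TestDailyMaxDisplacement:
    def _day_fixes(self, n, km_away, day="2020-01-01"):
        ts = pd.date_range(f"{day} 05:00", periods=n, freq="1h", tz="UTC")
        rows = [("a", ts[0], 35.0, 32.0)]
        dlat = math.degrees(km_away * 1000.0 / EARTH_RADIUS_M)
        for t in ts[1:]:
            rows.append(("a", t, 35.0, 32.0 + dlat))
        return rows

    def test_day_with_too_few_fixes_dropped(self):
        fixes = fix_table(self._day_fixes(9, 3.0))
        with pytest.warns(UserWarning):
            out = daily_max_displacement(fixes, min_fixes=10)
        assert len(out[0]) == 0

    def test_displacement_is_max_distance_from_first_fix(self):
        fixes = fix_table(self._day_fixes(12, 3.2))
        out = daily_max_displacement(fixes, min_fixes=10)
        assert out[0].km[0] == pytest.approx(3.2, rel=1e-6)

    def test_stationary_day_floored(self):
        fixes = fix_table(self._day_fixes(12, 0.0))
        out = daily_max_displacement(fixes, min_fixes=10)
        assert out[0].km[0] == 0.001

    def test_order_permutation_invariance(self, rng):
        fixes = fix_table(self._day_fixes(12, 5.0))
        first, rest = fixes.iloc[:1], fixes.iloc[1:]
        shuffled = pd.concat(
            [first, rest.sample(frac=1.0, random_state=1)], ignore_index=True
        )
        a = daily_max_displacement(fixes, min_fixes=10)[0].km
        b = daily_max_displacement(shuffled, min_fixes=10)[0].km
        assert a == pytest.approx(b)

    def test_min_fixes_monotonicity(self):
        rows = self._day_fixes(12, 2.0, "2020-01-01") + self._day_fixes(
            10, 4.0, "2020-01-02"
        )
        fixes = fix_table(rows)
        n10 = sum(len(s) for s in daily_max_displacement(fixes, min_fixes=10))
        n11 = sum(len(s) for s in daily_max_displacement(fixes, min_fixes=11))
        assert n11 <= n10

    def test_day_indexing_from_start_date(self):
        fixes = fix_table(self._day_fixes(12, 2.0, "2020-01-05"))
        out = daily_max_displacement(
            fixes, min_fixes=10, start_dates={"a": pd.Timestamp("2020-01-01")}
        )
        assert out[0].day[0] == 5


def test_movebank_csv_round_trip(tmp_path):
    fixes = fix_table(
        [
            ("bird1", pd.Timestamp("2020-01-01 05:00", tz="UTC"), 35.0, 32.0),
            ("bird1", pd.Timestamp("2020-01-01 06:00", tz="UTC"), 35.1, 32.1),
        ]
    )
    path = tmp_path / "fixes.csv"
    write_movebank_csv(fixes, path)
    back = read_movebank_csv(path)
    assert list(back["individual"]) == ["bird1", "bird1"]
    assert back["lon"].to_numpy() == pytest.approx(fixes["lon"].to_numpy())
    assert back["timestamp"].equals(fixes["timestamp"])


def test_displacement_series_validation():
    with pytest.raises(ValueError):
        DisplacementSeries("a", "g", day=[1, 1], km=[1.0, 2.0])
    with pytest.raises(ValueError):
        DisplacementSeries("a", "g", day=[1, 2], km=[1.0, -2.0])
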