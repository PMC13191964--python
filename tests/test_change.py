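"""Change analytics: rounding/differencing conventions, the seven-band
partition, stratified band tables, regional quartile summaries,
correlations and quadrant classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lbwsae import (
    BAND_LABELS,
    band_percentages_from_counts,
    band_table,
    categorize_change,
    compute_change,
    correlate,
    load_adp_districts,
    load_region_map,
    quadrant_classify,
    round2,
    summarize_region,
)
from lbwsae.published import band_share_table, load_band_counts, region_change_table


def _district_frame(values, state="Karnataka"):
    return pd.DataFrame({
        "district_id": [f"d{i}" for i in range(len(values))],
        "state_id": state, "prevalence_pct": values})


class TestComputeChange:
    @pytest.mark.parametrize("p16,p21,expected", [
        (20.76, 18.71, -2.05),   # northern-region arithmetic
        (16.19, 17.61, 1.42),    # eastern-region arithmetic
        (18.21, 18.24, 0.03),    # national arithmetic
        (12.34, 12.34, 0.00),
    ])
    def test_rounded_difference(self, p16, p21, expected):
        rec = compute_change(_district_frame([p16]), _district_frame([p21]))
        assert rec["change_pp"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_rounding_happens_before_differencing(self):
        # 18.236 -> 18.24 and 18.206 -> 18.21: change must be exactly 0.03
        rec = compute_change(_district_frame([18.206]), _district_frame([18.236]))
        assert rec["change_pp"].iloc[0] == pytest.approx(0.03, abs=1e-12)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(st.floats(0, 60, allow_nan=False), min_size=1, max_size=12))
    def test_antisymmetry(self, values):
        other = [(v * 1.37 + 3.1) % 60 for v in values]
        fwd = compute_change(_district_frame(values), _district_frame(other))
        rev = compute_change(_district_frame(other), _district_frame(values))
        np.testing.assert_allclose(fwd["change_pp"], -rev["change_pp"], atol=1e-12)

    def test_duplicate_district_rejected(self):
        dup = pd.concat([_district_frame([10.0])] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            compute_change(dup, _district_frame([10.0]))

    def test_unmatched_districts_excluded_and_reported(self):
        d1 = _district_frame([10.0, 20.0])
        d2 = _district_frame([11.0, 21.0, 31.0])
        with pytest.warns(RuntimeWarning, match="only one wave"):
            rec = compute_change(d1, d2)
        assert len(rec) == 2
        assert rec.attrs["unmatched"] == ["d2"]

    def test_region_and_adp_joined(self):
        rec = compute_change(_district_frame([10.0]), _district_frame([12.0]),
                             region_map=load_region_map(),
                             adp_districts=["d0"])
        assert rec["region"].iloc[0] == "South"
        assert bool(rec["adp_flag"].iloc[0])
        with pytest.raises(KeyError, match="Atlantis"):
            compute_change(_district_frame([1.0], state="Atlantis"),
                           _district_frame([2.0], state="Atlantis"),
                           region_map=load_region_map())


class TestBands:
    @pytest.mark.parametrize("change,label", [
        (-2.05, "-2.99 to -1.00"),
        (0.03, "-0.99 to 0.99"),
        (5.00, "5.00 and above"),
        (-5.00, "less than -5.00"),
        (-4.99, "-4.99 to -3.00"),
        (-3.00, "-4.99 to -3.00"),
        (-1.00, "-2.99 to -1.00"),
        (0.99, "-0.99 to 0.99"),
        (1.00, "1.00 to 2.99"),
        (4.99, "3.00 to 4.99"),
        (17.3, "5.00 and above"),
        (-0.994, "-0.99 to 0.99"),   # rounds to -0.99
    ])
    def test_band_assignment(self, change, label):
        assert categorize_change(change) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            categorize_change(float("nan"))

    def test_partition_exhaustive_on_hundredths(self):
        """Every rounded change in [-20.00, 20.00] lands in exactly one band."""
        for cents in range(-2000, 2001):
            label = categorize_change(cents / 100)
            assert label in BAND_LABELS

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.floats(-20, 20, allow_nan=False))
    def test_partition_random_changes(self, change):
        assert categorize_change(change) in BAND_LABELS


class TestBandTable:
    def test_published_national_row(self):
        summ = band_percentages_from_counts([92, 78, 140, 145, 135, 68, 62])
        assert summ["pct"] == [12.78, 10.83, 19.44, 20.14, 18.75, 9.44, 8.61]
        assert summ["reduction_gt3_pct"] == pytest.approx(23.61)
        assert summ["increase_gt3_pct"] == pytest.approx(18.05)

    def test_published_rows_sum_to_100(self):
        tab = band_share_table()
        for _, row in tab.iterrows():
            total_pct = sum(row[f"pct_{i}"] for i in range(1, 8))
            assert abs(total_pct - 100.0) <= 0.05

    def test_single_district_is_its_band_at_100(self):
        rec = compute_change(_district_frame([10.0]), _district_frame([11.5]))
        tab = band_table(rec, "all")
        assert tab["total"].iloc[0] == 1
        assert tab["pct_5"].iloc[0] == 100.00

    def test_stratified_by_region_and_adp(self, rng):
        n = 200
        rec = pd.DataFrame({
            "district_id": [f"d{i}" for i in range(n)],
            "band": rng.choice(BAND_LABELS, n),
            "region": rng.choice(["North", "South"], n),
            "adp_flag": rng.random(n) < 0.2})
        by_region = band_table(rec, "region")
        assert set(by_region["group"]) == {"North", "South"}
        assert by_region["total"].sum() == n
        by_adp = band_table(rec, "adp")
        assert list(by_adp["group"]) == ["ADP", "non-ADP"]
        counts = by_region[[f"count_{i}" for i in range(1, 8)]].to_numpy().sum()
        assert counts == n

    def test_group_percentages_sum_to_100(self, rng):
        for trial in range(20):
            counts = rng.integers(0, 50, 7)
            if counts.sum() == 0:
                continue
            summ = band_percentages_from_counts(counts)
            assert abs(sum(summ["pct"]) - 100.0) <= 0.05


class TestPublishedArithmetic:
    def test_region_change_column_reproduced(self):
        tab = region_change_table().set_index("region")
        assert tab.loc["India", "change_pp"] == pytest.approx(0.03)
        assert tab.loc["North", "change_pp"] == pytest.approx(-2.05)
        assert tab.loc["East", "change_pp"] == pytest.approx(1.42)
        assert tab.loc["South", "change_pp"] == pytest.approx(-0.61)

    def test_stratum_aggregates_reproduced(self):
        tab = band_share_table().set_index("group")
        assert tab.loc["East", "increase_gt3_pct"] == pytest.approx(28.57)
        assert tab.loc["South", "increase_gt3_pct"] == pytest.approx(8.51)
        assert tab.loc["ADP", "reduction_gt3_pct"] == pytest.approx(21.37)

    def test_band_counts_fixture_totals(self):
        counts = load_band_counts().set_index("group")
        sums = counts.sum(axis=1)
        assert sums["India"] == 720
        assert sums["ADP"] == 117
        region_total = sums[["North", "North-East", "South", "East", "West", "Central"]].sum()
        assert region_total == 720


class TestRegionSummary:
    def test_trivial_quartiles(self):
        est = pd.DataFrame({
            "district_id": list("abcde"), "state_id": "Kerala", "wave": "W",
            "prevalence_pct": [1, 2, 3, 4, 5]})
        out = summarize_region(est, load_region_map()).set_index("region")
        assert out.loc["South", "median"] == 3
        assert out.loc["South", "iqr"] == pytest.approx(2.0)  # linear interpolation

    def test_constant_values_zero_iqr(self):
        est = pd.DataFrame({
            "district_id": list("abc"), "state_id": "Bihar", "wave": "W",
            "prevalence_pct": [7.0, 7.0, 7.0]})
        out = summarize_region(est, load_region_map()).set_index("region")
        assert out.loc["East", "iqr"] == 0.0

    def test_matches_sort_based_quantile_oracle(self, rng):
        vals = rng.random(37) * 30
        est = pd.DataFrame({
            "district_id": [f"d{i}" for i in range(37)],
            "state_id": "Assam", "wave": "W", "prevalence_pct": vals})
        out = summarize_region(est, load_region_map()).set_index("region")
        # independent oracle: linear interpolation on sorted values
        s = np.sort(vals)

        def quant(q):
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert out.loc["North-East", "median"] == pytest.approx(quant(0.5))
        assert out.loc["North-East", "q1"] == pytest.approx(quant(0.25))
        assert out.loc["North-East", "iqr"] == pytest.approx(quant(0.75) - quant(0.25))


class TestCorrelate:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_small_table(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 1.0, 5.0])
        # textbook formula by hand
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        r, p = correlate(x, y)
        assert r == pytest.approx(float(r_hand))
        assert 0.0 <= p <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestQuadrants:
    def test_tie_rule_and_labels(self):
        labels = quadrant_classify([5.0, 4.0, 9.0], [7.0, 9.0, 2.0], cutoffs=(5.0, 7.0))
        assert labels == ["bottom-left", "top-left", "bottom-right"]

    def test_counts_partition(self, rng):
        x, y = rng.random(500), rng.random(500)
        labels = quadrant_classify(x, y)
        assert len(labels) == 500
        assert set(labels) <= {"bottom-left", "bottom-right", "top-left", "top-right"}


def test_adp_fixture_has_117_slots():
    adp = load_adp_districts()
    assert len(adp) == 117
    assert len(set(adp)) == 117


def test_round2_half_away_from_zero():
    assert round2(2.345) in (2.34, 2.35)  # representation-dependent midpoint
    assert round2(2.005) == pytest.approx(2.01)
    assert round2(-2.005) == pytest.approx(-2.01)
    assert round2(18.236) == pytest.approx(18.24)
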