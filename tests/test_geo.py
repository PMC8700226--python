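"""Per-area aggregation: counts, per-100k rates, quintiles, descriptives."""

import pytest

from takeaway_cuisine.geo import (
    OVERALL,
    aggregate_by_area,
    area_stats_frame,
    assign_quintiles,
    descriptive_summary,
)
from takeaway_cuisine.records import OutletRecord

CLASSES = ["chicken", "pizza"]


def outlet(area, cls):
    return OutletRecord(name=f"shop {area} {cls}", area_code=area), cls


class TestAggregateByArea:
    def test_rate_definition(self):
        classified = [outlet("A", "chicken") for _ in range(50)]
        stats = aggregate_by_area(classified, {"A": 100_000}, CLASSES)
        assert stats[0].rate_per_100k["chicken"] == pytest.approx(50.0)
        assert stats[0].rate_per_100k[OVERALL] == pytest.approx(50.0)

    def test_rate_scales_with_population(self):
        classified = [outlet("A", "pizza") for _ in range(23)]
        stats = aggregate_by_area(classified, {"A": 46_000}, CLASSES)
        assert stats[0].rate_per_100k["pizza"] == pytest.approx(50.0)

    def test_empty_area_has_zero_rates(self):
        classified = [outlet("A", "chicken")]
        stats = aggregate_by_area(classified, {"A": 50_000, "B": 80_000}, CLASSES)
        b = next(s for s in stats if s.area_code == "B")
        assert b.total == 0
        assert all(r == 0.0 for r in b.rate_per_100k.values())

    def test_missing_population_names_area(self):
        classified = [outlet("MISSING", "chicken")]
        with pytest.raises(ValueError, match="MISSING"):
            aggregate_by_area(classified, {"A": 1000}, CLASSES)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            aggregate_by_area([], {"A": 0}, CLASSES)

    def test_totals_consistent(self):
        classified = [outlet("A", "chicken"), outlet("A", "pizza"),
                      outlet("B", "pizza")]
        stats = aggregate_by_area(classified, {"A": 1000, "B": 1000}, CLASSES)
        assert sum(s.total for s in stats) == 3


class TestQuintiles:
    def make_stats(self, rates):
        classified = []
        pops = {}
        for i, r in enumerate(rates):
            area = f"A{i:02d}"
            pops[area] = 100_000
            classified += [outlet(area, "chicken") for _ in range(int(r))]
        return aggregate_by_area(classified, pops, CLASSES)

    def test_five_distinct_rates(self):
        stats = self.make_stats([1, 2, 3, 4, 5])
        assign_quintiles(stats, "chicken")
        assert [s.quintile["chicken"] for s in stats] == [1, 2, 3, 4, 5]

    def test_highest_rate_gets_q5(self):
        stats = self.make_stats([9, 1, 5, 3, 7])
        assign_quintiles(stats, "chicken")
        by_area = {s.area_code: s.quintile["chicken"] for s in stats}
        assert by_area["A00"] == 5 and by_area["A01"] == 1

    def test_ten_areas_two_per_quintile(self):
        stats = self.make_stats(list(range(10)))
        assign_quintiles(stats, "chicken")
        sizes = [sum(1 for s in stats if s.quintile["chicken"] == q)
                 for q in range(1, 6)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_all_equal_rates_still_partition(self):
        stats = self.make_stats([4] * 10)
        assign_quintiles(stats, "chicken")
        sizes = [sum(1 for s in stats if s.quintile["chicken"] == q)
                 for q in range(1, 6)]
        assert sizes == [2, 2, 2, 2, 2]
        # stable tie rule: lowest area codes in Q1
        q1 = sorted(s.area_code for s in stats if s.quintile["chicken"] == 1)
        assert q1 == ["A00", "A01"]

    def test_sizes_differ_by_at_most_one(self):
        stats = self.make_stats(list(range(13)))
        assign_quintiles(stats, "chicken")
        sizes = sorted(sum(1 for s in stats if s.quintile["chicken"] == q)
                       for q in range(1, 6))
        assert max(sizes) - min(sizes) <= 1

    def test_fewer_than_five_areas_rejected(self):
        stats = self.make_stats([1, 2, 3, 4])
        with pytest.raises(ValueError):
            assign_quintiles(stats, "chicken")


class TestDescriptiveSummary:
    def test_single_area_degenerate(self):
        classified = [outlet("A", "chicken") for _ in range(7)]
        stats = aggregate_by_area(classified, {"A": 10_000}, CLASSES)
        summary = descriptive_summary(stats)
        assert summary.median["chicken"] == 7
        assert summary.iqr["chicken"] == (7.0, 7.0)
        assert summary.min_max["chicken"] == (7, 7)

    def test_sorting_oracle(self):
        classified = []
        pops = {}
        for i, n in enumerate([1, 2, 3, 4, 5]):
            area = f"A{i}"
            pops[area] = 10_000
            classified += [outlet(area, "chicken") for _ in range(n)]
        summary = descriptive_summary(aggregate_by_area(classified, pops, CLASSES))
        assert summary.median["chicken"] == 3
        assert summary.min_max["chicken"] == (1, 5)
        assert summary.iqr["chicken"] == (2.0, 4.0)  # linear interpolation

    def test_shares_sum_to_100(self):
        classified = [outlet("A", "chicken"), outlet("A", "pizza"),
                      outlet("B", "pizza")]
        summary = descriptive_summary(
            aggregate_by_area(classified, {"A": 1000, "B": 1000}, CLASSES))
        class_pct = [v for k, v in summary.national_pct.items() if k != OVERALL]
        assert sum(class_pct) == pytest.approx(100.0)

    def test_published_table_style(self):
        classified = [outlet("A", "chicken") for _ in range(5)]
        summary = descriptive_summary(
            aggregate_by_area(classified, {"A": 1000, "B": 1000}, CLASSES))
        row = summary.format_row("chicken")
        assert row["outlets_n_pct"] == "5 (100.0)"
        assert "–" in row["outlets_median_iqr"]


def test_flat_frame_columns():
    classified = [outlet("A", "chicken")]
    stats = aggregate_by_area(classified, {f"A{i}": 1000 for i in range(5)} | {"A": 1000},
                              CLASSES)
    assign_quintiles(stats, "chicken")
    frame = area_stats_frame(stats)
    assert "rate_per_100k_chicken" in frame.columns
    assert "quintile_chicken" in frame.columns
    assert len(frame) == 6
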