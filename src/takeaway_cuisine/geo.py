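"""Per-area aggregation of classified outlets.

The case-study computation: per local-authority counts of outlets by
cuisine, rates per 100,000 residents, rate quintiles (Q5 = highest-rate
fifth), and cross-area descriptive statistics in the "median (IQR)" /
"min-max" style.  Quartiles use linear interpolation between order
statistics; quintile assignment ranks areas by rate with stable
tie-breaking on area code, then cuts the ranking into five groups whose
sizes differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import OutletRecord

__all__ = [
    "AreaStats",
    "DescriptiveSummary",
    "aggregate_by_area",
    "assign_quintiles",
    "descriptive_summary",
    "area_stats_frame",
]

OVERALL = "overall"


@dataclass
class AreaStats:
    """Counts, per-100k rates and quintiles for one area.  The ``overall``
    key aggregates across cuisines."""

    area_code: str
    population: int
    counts: dict[str, int]
    rate_per_100k: dict[str, float] = field(default_factory=dict)
    quintile: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(v for k, v in self.counts.items() if k != OVERALL)


def aggregate_by_area(
    classified: Sequence[tuple[OutletRecord, str]],
    population: Mapping[str, int],
    classes: Sequence[str],
) -> list[AreaStats]:
    """Count outlets per area and cuisine and compute per-100k rates.

    Every area in ``population`` appears in the output (zero counts
    included); an outlet whose area is missing from the population table
    is an error, as is a non-positive population.
    """
    for area, pop in population.items():
        if pop <= 0:
            raise ValueError(f"area {area!r} has non-positive population {pop}")
    counts: dict[str, dict[str, int]] = {
        area: {c: 0 for c in classes} for area in population
    }
    for record, cls in classified:
        area = record.area_code
        if area is None or area not in population:
            raise ValueError(
                f"outlet {record.name!r} has area code {area!r} "
                "not present in the population table"
            )
        if cls not in counts[area]:
            raise ValueError(f"class {cls!r} is not in the class list")
        counts[area][cls] += 1

    stats = []
    for area in sorted(population):
        per_class = counts[area]
        total = sum(per_class.values())
        pop = population[area]
        rates = {c: n / pop * 100_000 for c, n in per_class.items()}
        rates[OVERALL] = total / pop * 100_000
        stats.append(
            AreaStats(
                area_code=area,
                population=int(pop),
                counts=dict(per_class),
                rate_per_100k=rates,
            )
        )
    return stats


def assign_quintiles(stats: Sequence[AreaStats], cls: str = OVERALL) -> list[AreaStats]:
    """Assign rate quintiles (1..5, 5 = highest rates) for one cuisine.

    Areas are ranked by rate ascending, ties broken by area-code order,
    and the ranking is cut into five contiguous groups with sizes
    differing by at most one (larger groups at the low end).  Requires at
    least five areas.  Mutates and returns ``stats``.
    """
    if len(stats) < 5:
        raise ValueError(f"quintiles need >= 5 areas, got {len(stats)}")
    order = sorted(range(len(stats)),
                   key=lambda i: (stats[i].rate_per_100k[cls], stats[i].area_code))
    groups = np.array_split(order, 5)
    for q, group in enumerate(groups, start=1):
        for i in group:
            stats[i].quintile[cls] = q
    return list(stats)


@dataclass(frozen=True)
class DescriptiveSummary:
    """National totals and shares plus across-area distribution of counts,
    per cuisine and overall."""

    national_count: dict[str, int]
    national_pct: dict[str, float]
    median: dict[str, float]
    iqr: dict[str, tuple[float, float]]
    min_max: dict[str, tuple[int, int]]

    def format_row(self, cls: str) -> dict[str, str]:
        """One row in the published table style, e.g. median (IQR) as
        "117 (80-221)"."""
        q1, q3 = self.iqr[cls]
        lo, hi = self.min_max[cls]
        return {
            "cuisine": cls,
            "outlets_n_pct": f"{self.national_count[cls]:,} ({self.national_pct[cls]:.1f})",
            "outlets_median_iqr": f"{self.median[cls]:g} ({q1:g}–{q3:g})",
            "outlets_min_max": f"{lo}–{hi}",
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.format_row(c) for c in self.national_count])


def descriptive_summary(stats: Sequence[AreaStats]) -> DescriptiveSummary:
    """Across-area descriptives of outlet counts, by cuisine and overall."""
    if not stats:
        raise ValueError("no area statistics to summarise")
    classes = [c for c in stats[0].counts]
    national = {c: sum(s.counts[c] for s in stats) for c in classes}
    grand_total = sum(national.values())
    national[OVERALL] = grand_total
    pct = {
        c: (100.0 * n / grand_total if grand_total else 0.0)
        for c, n in national.items()
    }
    median, iqr, min_max = {}, {}, {}
    for c in [*classes, OVERALL]:
        values = np.array(
            [s.counts[c] if c != OVERALL else s.total for s in stats], dtype=float
        )
        median[c] = float(np.median(values))
        q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
        iqr[c] = (float(q1), float(q3))
        min_max[c] = (int(values.min()), int(values.max()))
    return DescriptiveSummary(
        national_count=national, national_pct=pct,
        median=median, iqr=iqr, min_max=min_max,
    )


def area_stats_frame(stats: Sequence[AreaStats]) -> pd.DataFrame:
    """Flat AreaStats table: one row per area with counts, rates and
    quintiles per cuisine — suitable for CSV export or joining onto
    boundary data in external mapping tools."""
    rows = []
    for s in stats:
        row: dict = {"area_code": s.area_code, "population": s.population,
                     "total_outlets": s.total}
        for c, n in s.counts.items():
            row[f"count_{c}"] = n
        for c, r in s.rate_per_100k.items():
            row[f"rate_per_100k_{c}"] = r
        for c, q in s.quintile.items():
            row[f"quintile_{c}"] = q
        rows.append(row)
    return pd.DataFrame(rows)
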