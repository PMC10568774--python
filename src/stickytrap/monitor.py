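"""Pest-population time series from per-day detections.

Counts are per captured frame: a sticky board accumulates insects, so daily
frames naturally yield cumulative-looking curves, and no detrending is
applied.  Days on which no frame was captured are recorded as gaps, never as
zero counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .boxes import DetectionSet

__all__ = ["CountSeries", "aggregate", "report", "read_report"]


@dataclass(frozen=True)
class CountSeries:
    """Per-day, per-class pest counts over a monitoring period.

    ``frame`` is indexed by day (strictly increasing) with one integer column
    per class name; totals and cumulative totals are derived, never stored.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        days = self.frame.index.to_numpy()
        if len(days) > 1 and not (days[1:] > days[:-1]).all():
            raise ValueError("days must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def days(self) -> list[int]:
        return [int(d) for d in self.frame.index]

    @property
    def class_names(self) -> list[str]:
        return list(self.frame.columns)

    def totals(self) -> pd.Series:
        return self.frame.sum(axis=1)

    def cumulative(self) -> pd.Series:
        return self.totals().cumsum()

    def grand_total(self) -> int:
        return int(self.frame.to_numpy().sum())


def aggregate(
    per_day_detections: Mapping[int, DetectionSet],
    class_names: Sequence[str],
) -> CountSeries:
    """Count boxes per day and class.

    Days are sorted; days absent from the mapping are simply absent from the
    series (gaps).  Detections with class ids outside ``class_names`` raise.
    """
    rows = {}
    for day in sorted(per_day_detections):
        counts = per_day_detections[day].counts_by_class()
        bad = [cid for cid in counts if not 0 <= cid < len(class_names)]
        if bad:
            raise ValueError(f"day {day}: class ids {bad} outside the class map")
        rows[int(day)] = [counts.get(cid, 0) for cid in range(len(class_names))]
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(class_names), dtype=int
    )
    frame.index.name = "day"
    return CountSeries(frame)


def report(series: CountSeries, out_dir: str | Path) -> dict[str, Path]:
    """Write the series as plot-ready files; returns the paths written.

    ``counts.csv`` is long-format (day, class, count) with classes in map
    order; ``totals.csv`` holds per-day totals and cumulative totals;
    ``series.json`` bundles everything for programmatic use.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_rows = [
        {"day": day, "class": name, "count": int(series.frame.at[day, name])}
        for day in series.frame.index
        for name in series.class_names
    ]
    counts_path = out_dir / "counts.csv"
    pd.DataFrame(long_rows, columns=["day", "class", "count"]).to_csv(
        counts_path, index=False
    )
    totals = pd.DataFrame(
        {
            "day": series.days,
            "total": series.totals().to_numpy(),
            "cumulative": series.cumulative().to_numpy(),
        }
    )
    totals_path = out_dir / "totals.csv"
    totals.to_csv(totals_path, index=False)
    json_path = out_dir / "series.json"
    json_path.write_text(
        json.dumps(
            {
                "class_names": series.class_names,
                "days": series.days,
                "counts": series.frame.to_numpy().tolist(),
                "totals": [int(v) for v in series.totals()],
                "cumulative": [int(v) for v in series.cumulative()],
            },
            indent=1,
        )
    )
    return {"counts": counts_path, "totals": totals_path, "json": json_path}


def read_report(out_dir: str | Path) -> CountSeries:
    """Rebuild a CountSeries from a written ``counts.csv`` (round trip of report)."""
    long = pd.read_csv(Path(out_dir) / "counts.csv")
    classes = list(dict.fromkeys(long["class"]))  # preserve written order
    frame = long.pivot(index="day", columns="class", values="count")[classes]
    frame.columns.name = None
    frame.index.name = "day"
    return CountSeries(frame.astype(int))
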