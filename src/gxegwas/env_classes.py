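"""Spring-temperature windows, tercile year classification and phenotype
centering.

The temperature covariate of a year is the mean daily temperature over
March 11 – April 20 (inclusive, 41 days).  Years are ranked by this window
mean and split into three classes — cold, intermediate, warm — with any
remainder assigned to the colder classes first, so 17 years split 6/6/5.
Laying dates are centered to the mean of their year x area cell before any
association analysis; this absorbs all year and area main effects
(including the temperature-class main effect, which is why the association
model carries no class main-effect term).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CLASS_LABELS, ValidationError

WINDOW_START = (3, 11)  # March 11
WINDOW_END = (4, 20)  # April 20
WINDOW_DAYS = 41


class DataError(ValueError):
    """Raised when required temperature days are missing."""


@dataclass(frozen=True)
class YearClassification:
    """Per-year window mean and temperature class, plus tercile boundaries."""

    table: pd.DataFrame  # columns year, window_mean, tclass
    boundaries: tuple[float, float]  # 33rd and 67th percentile of window means

    def class_of(self, year: int) -> str:
        t = self.table
        hit = t.loc[t["year"] == year, "tclass"]
        if hit.empty:
            raise KeyError(f"year {year} not classified")
        return hit.iloc[0]

    def sizes(self) -> dict:
        counts = self.table["tclass"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASS_LABELS}


def window_mean(temps: pd.DataFrame, year: int) -> float:
    """Mean daily temperature over March 11 – April 20 of ``year``.

    The window is defined by calendar dates, so leap years change nothing.
    Every one of the 41 days must be present exactly once.
    """
    start = dt.date(year, *WINDOW_START)
    end = dt.date(year, *WINDOW_END)
    dates = pd.to_datetime(temps["date"]).dt.date
    in_window = (dates >= start) & (dates <= end)
    sub = temps.loc[in_window]
    want = {start + dt.timedelta(days=i) for i in range(WINDOW_DAYS)}
    have = set(dates[in_window])
    if have != want:
        missing = sorted(want - have)
        raise DataError(
            f"temperature window {year} missing days: "
            f"{[d.isoformat() for d in missing[:5]]}"
        )
    if len(sub) != WINDOW_DAYS:
        raise DataError(f"duplicate temperature days in window for {year}")
    return float(sub["temp_c"].mean())


def tercile_sizes(n: int) -> tuple[int, int, int]:
    """Balanced partition of n into three class sizes, remainder to the
    colder classes first: 17 -> (6, 6, 5), 18 -> (6, 6, 6)."""
    base, rem = divmod(n, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))


def classify_years(window_means: dict) -> YearClassification:
    """Assign each year to cold/intermediate/warm by ranked window mean.

    Ties in temperature are broken by year ascending; class sizes follow
    :func:`tercile_sizes`.
    """
    if len(window_means) < 3:
        raise ValidationError("at least 3 years required for terciles")
    items = sorted(window_means.items(), key=lambda kv: (kv[1], kv[0]))
    if not all(np.isfinite(v) for _, v in items):
        raise ValidationError("non-finite window mean")
    sizes = tercile_sizes(len(items))
    rows = []
    pos = 0
    for label, size in zip(CLASS_LABELS, sizes):
        for year, mean in items[pos : pos + size]:
            rows.append((int(year), float(mean), label))
        pos += size
    table = pd.DataFrame(rows, columns=["year", "window_mean", "tclass"]).sort_values(
        "year", ignore_index=True
    )
    means = np.array([v for _, v in items])
    boundaries = (
        float(np.quantile(means, 1 / 3)),
        float(np.quantile(means, 2 / 3)),
    )
    return YearClassification(table, boundaries)


def center_phenotypes(
    pheno: pd.DataFrame, classification: YearClassification
) -> pd.DataFrame:
    """Attach ``centered`` (laying date minus its year x area cell mean) and
    ``tclass`` columns.  Singleton cells are allowed (centered value 0)."""
    if pheno[["year", "area"]].isna().any().any():
        raise ValidationError("every record needs year and area")
    out = pheno.copy()
    cell_mean = out.groupby(["year", "area"])["laying_date"].transform("mean")
    out["centered"] = out["laying_date"] - cell_mean
    out["tclass"] = out["year"].map(
        dict(zip(classification.table["year"], classification.table["tclass"]))
    )
    if out["tclass"].isna().any():
        bad = sorted(out.loc[out["tclass"].isna(), "year"].unique())
        raise ValidationError(f"records in unclassified years: {bad}")
    return out
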