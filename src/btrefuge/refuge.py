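"""Effective refuge percentage from crop areas and moth-production weights.

The effective refuge percentage expresses the non-Bt host-plant area —
weighted by each host's production of *H. armigera* adults relative to
non-Bt cotton — as a share of the total selection habitat (weighted non-Bt
hosts plus Bt cotton).  A yearly series can also be reconstructed from the
published linear trend for northern China, 2007-2019
(``y = 2.85 x - 5667`` percent, with x the calendar year).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .popgen import RefugeSeries

__all__ = [
    "CropRecord",
    "effective_refuge_percentage",
    "effective_refuge_by_year",
    "refuge_series_from_regression",
    "read_crop_table",
    "write_crop_table",
    "REGRESSION_SLOPE",
    "REGRESSION_INTERCEPT",
]

#: Fitted linear trend of the effective refuge percentage in northern China
#: (percent per year and percent), 2007-2019.
REGRESSION_SLOPE = 2.85
REGRESSION_INTERCEPT = -5667.0

CROP_TABLE_COLUMNS = ["year", "crop", "area_ha", "bt_fraction", "production_weight"]


@dataclass(frozen=True)
class CropRecord:
    """One crop in one year: area, Bt share, and relative moth production.

    ``production_weight`` is the number of *H. armigera* adults produced per
    hectare relative to non-Bt cotton (which has weight 1 by definition).
    """

    year: int
    crop: str
    area_ha: float
    bt_fraction: float
    production_weight: float

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ValueError(f"area_ha must be >= 0, got {self.area_ha}")
        if not 0.0 <= self.bt_fraction <= 1.0:
            raise ValueError(f"bt_fraction must be in [0, 1], got {self.bt_fraction}")
        if self.production_weight < 0:
            raise ValueError(
                f"production_weight must be >= 0, got {self.production_weight}"
            )


def effective_refuge_percentage(records: Sequence[CropRecord]) -> float:
    """Effective refuge percentage for a single year's crop records.

    ``100 * sum_i(nonbt_area_i * weight_i) /
    (sum_i(nonbt_area_i * weight_i) + bt_area)``, where
    ``nonbt_area_i = area_i * (1 - bt_fraction_i)`` and Bt area enters the
    denominator hectare-for-hectare (selection habitat, not refuge).
    """
    records = list(records)
    if not records:
        raise ValueError("at least one crop record is required")
    years = {r.year for r in records}
    if len(years) > 1:
        raise ValueError(f"records span multiple years: {sorted(years)}")
    weighted_refuge = sum(r.area_ha * (1.0 - r.bt_fraction) * r.production_weight for r in records)
    bt_area = sum(r.area_ha * r.bt_fraction for r in records)
    denominator = weighted_refuge + bt_area
    if denominator <= 0:
        raise ValueError("no host-plant area at all: refuge share undefined")
    return 100.0 * weighted_refuge / denominator


def effective_refuge_by_year(records: Iterable[CropRecord]) -> pd.Series:
    """Effective refuge percentage per year, as a Series indexed by year."""
    by_year: dict[int, list[CropRecord]] = {}
    for r in records:
        by_year.setdefault(r.year, []).append(r)
    return pd.Series(
        {year: effective_refuge_percentage(rows) for year, rows in sorted(by_year.items())},
        name="effective_refuge_pct",
    )


def refuge_series_from_regression(
    slope: float = REGRESSION_SLOPE,
    intercept: float = REGRESSION_INTERCEPT,
    years: Iterable[int] = range(2006, 2021),
    clamp: bool = True,
) -> RefugeSeries:
    """Evaluate a linear refuge trend (percent) into a yearly fraction series.

    ``R(year) = (slope * year + intercept) / 100``, clamped to [0, 1] when
    ``clamp`` is set (extrapolated years can leave the data range).
    """
    values = {}
    for year in years:
        r = (slope * year + intercept) / 100.0
        if clamp:
            r = min(1.0, max(0.0, r))
        values[int(year)] = r
    if not values:
        raise ValueError("years must be non-empty")
    return RefugeSeries(values)


def read_crop_table(path: Union[str, Path]) -> list[CropRecord]:
    """Read a crop-area CSV (year,crop,area_ha,bt_fraction,production_weight)."""
    frame = pd.read_csv(path)
    missing = set(CROP_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"crop table {path} lacks columns: {sorted(missing)}")
    return [
        CropRecord(
            year=int(row.year),
            crop=str(row.crop),
            area_ha=float(row.area_ha),
            bt_fraction=float(row.bt_fraction),
            production_weight=float(row.production_weight),
        )
        for row in frame.itertuples(index=False)
    ]


def write_crop_table(records: Iterable[CropRecord], path: Union[str, Path]) -> None:
    frame = pd.DataFrame([r.__dict__ for r in records], columns=CROP_TABLE_COLUMNS)
    frame.to_csv(path, index=False)
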