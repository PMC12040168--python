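"""Reading, aggregating and summarizing CDP survey and meteorology tables.

The survey file is delimited text (comma by default, tab via ``sep``) with
header columns ``crop,cdp,prefecture,year,month,di``. Where the same
combination was surveyed several times within a month, the monthly DI is the
maximum over those surveys: forecasting the worst within-month damage is what
matters for control decisions, and the aggregation below implements exactly
that rule.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import (
    METEO_VARS,
    SIZE_BIN_LABELS,
    ComboKey,
    ComboSeries,
    ComboSummary,
    MeteoStationRecord,
    PrefectureMeteo,
    SurveyRecord,
)

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["crop", "cdp", "prefecture", "year", "month", "di"]
METEO_COLUMNS = ["station", "prefecture", "year", "month", *METEO_VARS]


class FormatError(ValueError):
    """Malformed input table (missing columns, unparseable header)."""


class RowError(ValueError):
    """A data row violating an invariant, raised only in strict mode."""


def read_survey_table(
    path: str | Path, strict: bool = True, sep: str = ","
) -> list[SurveyRecord]:
    """Read survey records from a delimited text file.

    In strict mode an invalid row (DI outside [0, 100], month outside 1-12,
    empty label) raises :class:`RowError` naming the row; in lenient mode the
    row is skipped with a log message. Row order is preserved.
    """
    df = pd.read_csv(path, sep=sep, dtype={"crop": str, "cdp": str, "prefecture": str})
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[SurveyRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                SurveyRecord(
                    crop=str(row.crop),
                    cdp=str(row.cdp),
                    prefecture=str(row.prefecture),
                    year=int(row.year),
                    month=int(row.month),
                    di=float(row.di),
                )
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowError(f"{path}: row {i + 2}: {exc}") from exc
            logger.warning("skipping row %d of %s: %s", i + 2, path, exc)
    return records


def write_survey_table(
    records: Iterable[SurveyRecord], path: str | Path, sep: str = ","
) -> None:
    df = pd.DataFrame(
        [(r.crop, r.cdp, r.prefecture, r.year, r.month, r.di) for r in records],
        columns=SURVEY_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.crop, r.cdp, r.prefecture, r.year, r.month, r.di) for r in records],
        columns=SURVEY_COLUMNS,
    )


def aggregate_monthly_max(records: Iterable[SurveyRecord]) -> list[ComboSeries]:
    """Collapse repeated within-month surveys to their maximum DI.

    Returns one :class:`ComboSeries` per combination, keys sorted. Empty input
    yields an empty list.
    """
    series: dict[ComboKey, dict[tuple[int, int], float]] = defaultdict(dict)
    for r in records:
        obs = series[r.key]
        ym = (r.year, r.month)
        prev = obs.get(ym)
        obs[ym] = r.di if prev is None else max(prev, r.di)
    return [ComboSeries(k, series[k]) for k in sorted(series)]


def bin_sample_size(n: int) -> str:
    """Sample-size bin with boundaries 10/100/1000 in the lower bin."""
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    if n <= 10:
        return SIZE_BIN_LABELS[0]
    if n <= 100:
        return SIZE_BIN_LABELS[1]
    if n <= 1000:
        return SIZE_BIN_LABELS[2]
    return SIZE_BIN_LABELS[3]


def summarize_combo(series: ComboSeries) -> ComboSummary:
    """Period (inclusive year span), mean months surveyed per active year, size bin.

    Frequency averages the count of distinct surveyed months over *active*
    years only (years with at least one observation), so a combination
    surveyed monthly for 3 years then abandoned still reads as 12 months/year.
    """
    if not series.observations:
        raise ValueError(f"empty series for {series.key}")
    years = series.years()
    months_per_year = defaultdict(set)
    for (y, m) in series.observations:
        months_per_year[y].add(m)
    frequency = sum(len(v) for v in months_per_year.values()) / len(months_per_year)
    n = len(series.observations)
    return ComboSummary(
        key=series.key,
        n_samples=n,
        first_year=years[0],
        last_year=years[-1],
        period_years=years[-1] - years[0] + 1,
        frequency=frequency,
        size_bin=bin_sample_size(n),
    )


def write_combo_summaries(
    summaries: Iterable[ComboSummary], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (
                s.key.crop,
                s.key.cdp,
                s.key.prefecture,
                s.n_samples,
                s.first_year,
                s.last_year,
                s.period_years,
                s.frequency,
                s.size_bin,
            )
            for s in summaries
        ],
        columns=[
            "crop",
            "cdp",
            "prefecture",
            "n_samples",
            "first_year",
            "last_year",
            "period_years",
            "frequency",
            "size_bin",
        ],
    )
    df.to_csv(path, index=False)


def read_meteo_table(
    path: str | Path, strict: bool = True, sep: str = ","
) -> list[MeteoStationRecord]:
    """Read per-station monthly meteorology; blank cells become missing values."""
    df = pd.read_csv(path, sep=sep, dtype={"station": str, "prefecture": str})
    missing = [c for c in METEO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    def _opt(value) -> float | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return float(value)

    out: list[MeteoStationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                MeteoStationRecord(
                    station=str(row.station),
                    prefecture=str(row.prefecture),
                    year=int(row.year),
                    month=int(row.month),
                    temperature=_opt(row.temperature),
                    precipitation=_opt(row.precipitation),
                    humidity=_opt(row.humidity),
                    sunshine=_opt(row.sunshine),
                )
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowError(f"{path}: row {i + 2}: {exc}") from exc
            logger.warning("skipping row %d of %s: %s", i + 2, path, exc)
    return out


def write_meteo_table(
    records: Iterable[MeteoStationRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (
                r.station,
                r.prefecture,
                r.year,
                r.month,
                r.temperature,
                r.precipitation,
                r.humidity,
                r.sunshine,
            )
            for r in records
        ],
        columns=METEO_COLUMNS,
    )
    df.to_csv(path, index=False)


def average_prefecture_meteorology(
    records: Iterable[MeteoStationRecord],
) -> dict[str, PrefectureMeteo]:
    """Average each variable across the stations reporting it that month.

    Missing values are excluded variable-by-variable (complete-case per
    variable), so one station lacking sunshine does not bias the temperature
    mean. Months with no reporting station for a variable simply lack that
    variable in the output.
    """
    sums: dict[str, dict[tuple[int, int], dict[str, list[float]]]] = defaultdict(
        lambda: defaultdict(lambda: {v: [] for v in METEO_VARS})
    )
    for r in records:
        cell = sums[r.prefecture][(r.year, r.month)]
        for var in METEO_VARS:
            value = getattr(r, var)
            if value is not None:
                cell[var].append(value)
    out: dict[str, PrefectureMeteo] = {}
    for pref in sorted(sums):
        values: dict[tuple[int, int], dict[str, float]] = {}
        for ym in sorted(sums[pref]):
            cell = sums[pref][ym]
            entry = {
                var: sum(vals) / len(vals) for var, vals in cell.items() if vals
            }
            if entry:
                values[ym] = entry
            else:
                logger.info("no station data for %s %s; entry absent", pref, ym)
        out[pref] = PrefectureMeteo(prefecture=pref, values=values)
    return out


def meteo_to_frame(meteo: Mapping[str, PrefectureMeteo]) -> pd.DataFrame:
    rows = []
    for pref, pm in meteo.items():
        for (y, m), entry in sorted(pm.values.items()):
            rows.append(
                (pref, y, m, *[entry.get(var) for var in METEO_VARS])
            )
    return pd.DataFrame(
        rows, columns=["prefecture", "year", "month", *METEO_VARS]
    )
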