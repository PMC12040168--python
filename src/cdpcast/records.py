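"""Core record types for crop disease and pest (CDP) survey panels.

A *combination* is a (crop, CDP, prefecture) triple — the unit at which the
national survey reports damage incidence (DI), the percentage of surveyed
plant organs damaged or parasitized, in [0, 100]. Surveys are monthly, so all
timestamps are (year, month) pairs with no day resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

YearMonth = Tuple[int, int]

SIZE_BIN_LABELS = ("<=10", "(10,100]", "(100,1000]", ">1000")


@dataclass(frozen=True, order=True)
class ComboKey:
    """Identity of one crop x CDP x prefecture combination."""

    crop: str
    cdp: str
    prefecture: str

    def __post_init__(self) -> None:
        for name in ("crop", "cdp", "prefecture"):
            if not getattr(self, name):
                raise ValueError(f"ComboKey.{name} must be a non-empty label")


@dataclass(frozen=True)
class SurveyRecord:
    """One survey observation: combination key plus (year, month) and DI%."""

    crop: str
    cdp: str
    prefecture: str
    year: int
    month: int
    di: float

    def __post_init__(self) -> None:
        if not (1 <= self.month <= 12):
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if not (0.0 <= self.di <= 100.0):
            raise ValueError(f"di must be in [0, 100], got {self.di}")
        for name in ("crop", "cdp", "prefecture"):
            if not getattr(self, name):
                raise ValueError(f"SurveyRecord.{name} must be non-empty")

    @property
    def key(self) -> ComboKey:
        return ComboKey(self.crop, self.cdp, self.prefecture)


@dataclass
class ComboSeries:
    """De-duplicated monthly DI series for one combination.

    ``observations`` maps (year, month) -> DI; at most one value per month.
    """

    key: ComboKey
    observations: Dict[YearMonth, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Tuple[YearMonth, float]]:
        return iter(sorted(self.observations.items()))

    def years(self) -> list[int]:
        return sorted({y for (y, _m) in self.observations})

    def subset_years(self, max_year: int) -> "ComboSeries":
        """Observations with year <= ``max_year`` (used for training splits)."""
        return ComboSeries(
            self.key,
            {ym: v for ym, v in self.observations.items() if ym[0] <= max_year},
        )

    def in_year(self, year: int) -> Dict[YearMonth, float]:
        return {ym: v for ym, v in self.observations.items() if ym[0] == year}

    def to_records(self) -> list[SurveyRecord]:
        k = self.key
        return [
            SurveyRecord(k.crop, k.cdp, k.prefecture, y, m, v)
            for (y, m), v in sorted(self.observations.items())
        ]


@dataclass(frozen=True)
class ComboSummary:
    """Survey effort summary for one combination (period, frequency, size)."""

    key: ComboKey
    n_samples: int
    first_year: int
    last_year: int
    period_years: int
    frequency: float
    size_bin: str

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.period_years < 1:
            raise ValueError("period_years must be >= 1")
        if not (1.0 <= self.frequency <= 12.0):
            raise ValueError("frequency must be within [1, 12]")


@dataclass(frozen=True)
class MeteoStationRecord:
    """Monthly meteorology reported by one station.

    Any of the four variables may be missing (None) for a given month.
    """

    station: str
    prefecture: str
    year: int
    month: int
    temperature: float | None  # monthly mean, degC
    precipitation: float | None  # monthly total, mm
    humidity: float | None  # monthly mean, %
    sunshine: float | None  # monthly total, hours

    def __post_init__(self) -> None:
        if not (1 <= self.month <= 12):
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.humidity is not None and not (0.0 <= self.humidity <= 100.0):
            raise ValueError("humidity must be in [0, 100]")
        if self.precipitation is not None and self.precipitation < 0:
            raise ValueError("precipitation must be >= 0")
        if self.sunshine is not None and self.sunshine < 0:
            raise ValueError("sunshine must be >= 0")


METEO_VARS = ("temperature", "precipitation", "humidity", "sunshine")


@dataclass
class PrefectureMeteo:
    """Prefecture-level monthly meteorology: cross-station means per variable.

    ``values`` maps (year, month) -> dict of variable -> mean over the stations
    reporting that variable in that month.
    """

    prefecture: str
    values: Dict[YearMonth, Dict[str, float]] = field(default_factory=dict)

    def get(self, year: int, month: int, var: str) -> float | None:
        entry = self.values.get((year, month))
        if entry is None:
            return None
        return entry.get(var)
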