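"""Expanding-window (rolling-origin) backtesting of DI forecasters.

For each combination, the year *y* runs from the earliest to the latest
observed year. At each increment the data split into: (i) training — all
observations through December of year *y*; (ii) validation — observations in
year *y*+1; (iii) the remainder, never used. The split is *scored* only when
the training part holds at least five observations and the validation part at
least three; a small-sample RMSE is not reliable. The model is refit from
scratch on every scored split, and the per-split validation RMSEs are
averaged (unweighted) into the combination's forecast performance.

"Time points" in both thresholds count observed (year, month) entries after
monthly-max aggregation, not elapsed calendar months.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .forecast import Forecast, ModelSpec
from .records import ComboKey, ComboSeries, PrefectureMeteo, YearMonth

logger = logging.getLogger(__name__)

MIN_TRAIN_OBS = 5
MIN_VALIDATION_OBS = 3


@dataclass(frozen=True)
class Split:
    """One candidate expanding-window split at origin year ``y``."""

    y: int
    n_train: int
    n_validation: int
    scored: bool


@dataclass
class SplitPlan:
    key: ComboKey
    splits: List[Split] = field(default_factory=list)

    @property
    def scored_splits(self) -> List[Split]:
        return [s for s in self.splits if s.scored]


@dataclass
class BacktestResult:
    key: ComboKey
    algorithm: str
    rmse_by_year: Dict[int, float] = field(default_factory=dict)
    average_rmse: Optional[float] = None
    n_scored_splits: int = 0
    pa_window: Optional[int] = None
    flags: List[str] = field(default_factory=list)


def make_splits(series: ComboSeries) -> SplitPlan:
    """Plan every candidate split for a combination.

    One candidate per year ``y`` from the first observed year through the
    last observed year minus one; scored when train >= 5 and validation >= 3
    observations. A plan may contain zero scored splits.
    """
    if not series.observations:
        raise ValueError("cannot plan splits for an empty series")
    years = series.years()
    counts: Dict[int, int] = {}
    for (y, _m) in series.observations:
        counts[y] = counts.get(y, 0) + 1
    plan = SplitPlan(key=series.key)
    cum = 0
    for y in range(years[0], years[-1]):
        cum = sum(c for yy, c in counts.items() if yy <= y)
        n_val = counts.get(y + 1, 0)
        plan.splits.append(
            Split(
                y=y,
                n_train=cum,
                n_validation=n_val,
                scored=cum >= MIN_TRAIN_OBS and n_val >= MIN_VALIDATION_OBS,
            )
        )
    return plan


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error of position-matched prediction/observation pairs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError(
            f"predicted and observed must be equal-length and non-empty "
            f"(got {p.size} vs {o.size})"
        )
    return float(np.sqrt(np.mean((p - o) ** 2)))


def split_seed(master_seed: int, key: ComboKey, y: int, algorithm: str) -> int:
    """Deterministic per-split seed below 2**31, stable across runs."""
    token = f"{master_seed}|{key.crop}|{key.cdp}|{key.prefecture}|{y}|{algorithm}"
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def evaluate_combo(
    series: ComboSeries,
    spec: ModelSpec,
    exog: Optional[PrefectureMeteo] = None,
    master_seed: int = 0,
) -> BacktestResult:
    """Backtest one algorithm on one combination.

    The model is refit on every scored split's training subset only, predicts
    the validation months of year y+1, and the RMSEs are averaged. Stochastic
    algorithms receive a per-split seed derived from (master seed, key, y,
    algorithm). A model failure on one split flags and skips that split; the
    run continues.
    """
    if spec.requires_exog and exog is None:
        raise ValueError(f"{spec.algorithm} requires exogenous meteorology")
    plan = make_splits(series)
    result = BacktestResult(
        key=series.key,
        algorithm=spec.algorithm,
        pa_window=spec.n if spec.algorithm == "PA" else None,
    )
    for s in plan.scored_splits:
        train = series.subset_years(s.y)
        validation = series.in_year(s.y + 1)
        targets = sorted(validation)
        seed = split_seed(master_seed, series.key, s.y, spec.algorithm)
        try:
            model = spec.build(seed=seed)
            forecast: Forecast = model.fit(train, exog=exog).predict(targets)
        except Exception as exc:  # model-level failure: skip split, keep going
            logger.warning(
                "%s failed on %s split y=%d: %s", spec.algorithm, series.key, s.y, exc
            )
            result.flags.append(f"split_failed:{s.y}")
            continue
        result.flags.extend(f"{f}@{s.y}" for f in forecast.flags)
        predicted = forecast.as_array(targets)
        observed = np.array([validation[t] for t in targets], dtype=float)
        result.rmse_by_year[s.y] = rmse(predicted, observed)
    result.n_scored_splits = len(result.rmse_by_year)
    if result.n_scored_splits:
        result.average_rmse = float(
            np.mean(list(result.rmse_by_year.values()))
        )
    return result


def grid_search_pa(
    series: ComboSeries,
    n_range: Optional[Sequence[int]] = None,
    extended: bool = False,
    master_seed: int = 0,
) -> Tuple[int, BacktestResult]:
    """Choose the PA window by minimizing averaged validation RMSE.

    The default grid is n = 1..5; ``extended=True`` widens it to every
    feasible window length (1 up to the series' year span). Ties break toward
    the smallest n. Raises when no split can be scored at all.
    """
    if n_range is None:
        if extended:
            years = series.years()
            n_range = range(1, max(2, years[-1] - years[0] + 1))
        else:
            n_range = range(1, 6)
    best: Optional[Tuple[int, BacktestResult]] = None
    for n in n_range:
        result = evaluate_combo(
            series, ModelSpec(algorithm="PA", n=int(n)), master_seed=master_seed
        )
        if result.average_rmse is None:
            raise ValueError(
                f"{series.key}: no scored splits; PA grid search undefined"
            )
        if best is None or result.average_rmse < best[1].average_rmse - 1e-15:
            best = (int(n), result)
    assert best is not None
    return best
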