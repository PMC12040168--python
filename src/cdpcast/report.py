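"""Aggregation of backtest results into the benchmark's result surfaces.

Combinations are stratified by survey length — STS (<=5 years), MTS (>5 and
<=10), LTS (>10) — and, within a stratum, algorithms are compared pairwise on
the combinations where both produced a result. RMSE distributions are heavy
tailed (approximately log-normal), so the pairwise test is the paired
two-sided Wilcoxon signed-rank test, BH-adjusted across the pairs of a
stratum, and the sample-size trend is fit on log-log axes.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .backtest import BacktestResult, evaluate_combo, grid_search_pa
from .describe import bh_adjust
from .forecast import ALGORITHMS, ModelSpec
from .records import ComboKey, ComboSeries, ComboSummary, PrefectureMeteo

logger = logging.getLogger(__name__)

GROUP_LABELS = ("STS", "MTS", "LTS")

#: offset added to RMSE before taking logs in the trend fit (admits zero RMSE)
TREND_LOG_OFFSET = 0.01


def assign_group(summary: ComboSummary) -> str:
    """Survey-length stratum: STS <=5 years, MTS (5, 10], LTS >10."""
    p = summary.period_years
    if p <= 5:
        return "STS"
    if p <= 10:
        return "MTS"
    return "LTS"


@dataclass(frozen=True)
class PairwiseComparison:
    algorithm_a: str
    algorithm_b: str
    n_combos: int
    mean_difference: float  # mean(a - b) over shared combos
    p_value: float
    p_adjusted: float


@dataclass
class ComparisonTable:
    group: str
    algorithm_stats: Dict[str, Tuple[float, float, int]]  # mean, sd, n
    pairs: List[PairwiseComparison] = field(default_factory=list)
    omitted: List[Tuple[str, str, str]] = field(default_factory=list)


def compare_models(
    results: Iterable[BacktestResult], group: str = "all"
) -> ComparisonTable:
    """Pairwise paired Wilcoxon signed-rank comparisons of per-combination
    average RMSE, restricted to combinations with results for both algorithms,
    BH-adjusted across pairs."""
    by_algo: Dict[str, Dict[ComboKey, float]] = defaultdict(dict)
    for r in results:
        if r.average_rmse is not None:
            by_algo[r.algorithm][r.key] = r.average_rmse
    table = ComparisonTable(group=group, algorithm_stats={})
    for algo, vals in sorted(by_algo.items()):
        arr = np.fromiter(vals.values(), dtype=float)
        table.algorithm_stats[algo] = (
            float(arr.mean()),
            float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            int(arr.size),
        )
    raw: List[Tuple[str, str, int, float, float]] = []
    for a, b in combinations(sorted(by_algo), 2):
        shared = sorted(set(by_algo[a]) & set(by_algo[b]), key=lambda k: (k.crop, k.cdp, k.prefecture))
        if len(shared) < 2:
            table.omitted.append((a, b, f"only {len(shared)} shared combo(s)"))
            continue
        xa = np.array([by_algo[a][k] for k in shared])
        xb = np.array([by_algo[b][k] for k in shared])
        diff = xa - xb
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(xa, xb, zero_method="wilcox", method="auto").pvalue
            )
        raw.append((a, b, len(shared), float(diff.mean()), p))
    if raw:
        adjusted = bh_adjust([r[4] for r in raw])
        table.pairs = [
            PairwiseComparison(a, b, n, d, p, float(adj))
            for (a, b, n, d, p), adj in zip(raw, adjusted)
        ]
    return table


@dataclass(frozen=True)
class TrendFit:
    """OLS of log(average RMSE + offset) on log(n samples) for one algorithm."""

    algorithm: str
    slope: float
    intercept: float
    n_combos: int
    grid_n: Tuple[float, ...]
    grid_rmse: Tuple[float, ...]


def regress_rmse_on_samples(
    results: Iterable[BacktestResult],
    summaries: Dict[ComboKey, ComboSummary],
    offset: float = TREND_LOG_OFFSET,
    grid: Optional[Sequence[float]] = None,
) -> Dict[str, TrendFit]:
    """Per-algorithm log-log trend of averaged RMSE against sample count.

    Algorithms with fewer than three usable combinations are omitted.
    """
    if grid is None:
        grid = np.logspace(0.5, 3.0, 25)
    points: Dict[str, List[Tuple[float, float]]] = defaultdict(list)
    for r in results:
        if r.average_rmse is None or r.key not in summaries:
            continue
        points[r.algorithm].append(
            (summaries[r.key].n_samples, r.average_rmse)
        )
    fits: Dict[str, TrendFit] = {}
    for algo, pts in sorted(points.items()):
        if len(pts) < 3:
            logger.info("trend fit omitted for %s: %d point(s)", algo, len(pts))
            continue
        x = np.log(np.array([p[0] for p in pts], dtype=float))
        y = np.log(np.array([p[1] for p in pts], dtype=float) + offset)
        slope, intercept = np.polyfit(x, y, 1)
        grid_rmse = np.exp(intercept + slope * np.log(np.asarray(grid))) - offset
        fits[algo] = TrendFit(
            algorithm=algo,
            slope=float(slope),
            intercept=float(intercept),
            n_combos=len(pts),
            grid_n=tuple(float(g) for g in grid),
            grid_rmse=tuple(float(v) for v in grid_rmse),
        )
    return fits


def summarize_pa_windows(results: Iterable[BacktestResult]) -> Dict[int, float]:
    """Distribution of the chosen PA window n across combinations."""
    counts = Counter(
        r.pa_window for r in results if r.algorithm == "PA" and r.pa_window
    )
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no PA results with a chosen window")
    return {n: c / total for n, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

def run_benchmark(
    series_list: Sequence[ComboSeries],
    meteo: Optional[Dict[str, PrefectureMeteo]] = None,
    algorithms: Sequence[str] = ALGORITHMS,
    master_seed: int = 0,
    pa_grid: Optional[Sequence[int]] = None,
) -> List[BacktestResult]:
    """Backtest every algorithm on every combination admitting scored splits.

    PA's window is grid-searched per combination (default n = 1..5); the
    other algorithms run with their defaults. Combinations with zero scored
    splits are skipped, mirroring the survey-data exclusions.
    """
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    results: List[BacktestResult] = []
    for series in series_list:
        from .backtest import make_splits

        if not make_splits(series).scored_splits:
            continue
        exog = (
            meteo.get(series.key.prefecture) if meteo is not None else None
        )
        for algo in algorithms:
            spec = ModelSpec(algorithm=algo)
            if spec.requires_exog and exog is None:
                raise ValueError(
                    f"{algo} requested but no meteorology for prefecture "
                    f"{series.key.prefecture!r}"
                )
            try:
                if algo == "PA":
                    _best_n, result = grid_search_pa(
                        series, n_range=pa_grid, master_seed=master_seed
                    )
                else:
                    result = evaluate_combo(
                        series, spec, exog=exog, master_seed=master_seed
                    )
            except ValueError as exc:
                logger.warning("%s on %s skipped: %s", algo, series.key, exc)
                continue
            if result.average_rmse is not None:
                results.append(result)
    return results


def results_frame(results: Iterable[BacktestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.key.crop,
                r.key.cdp,
                r.key.prefecture,
                r.algorithm,
                r.pa_window,
                r.n_scored_splits,
                r.average_rmse,
                ";".join(r.flags),
            )
            for r in results
        ],
        columns=[
            "crop", "cdp", "prefecture", "algorithm", "pa_window",
            "n_scored_splits", "average_rmse", "flags",
        ],
    )


def comparison_frame(table: ComparisonTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                table.group, p.algorithm_a, p.algorithm_b, p.n_combos,
                p.mean_difference, p.p_value, p.p_adjusted,
            )
            for p in table.pairs
        ],
        columns=[
            "group", "algorithm_a", "algorithm_b", "n_combos",
            "mean_difference", "p_value", "p_adjusted",
        ],
    )
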