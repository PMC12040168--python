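"""Descriptive characterization of CDP survey panels.

Covers the survey's quantitative screening: sample-size composition at four
aggregation levels, the marginal DI distribution (cumulative fractions and
heaped round-value spikes), complete-case Pearson correlations between
different crops sharing the same disease/pest and prefecture, and a one-way
monthly ANOVA per combination with Benjamini-Hochberg FDR control across
combinations.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import SIZE_BIN_LABELS, ComboKey, ComboSeries, SurveyRecord
from .survey import bin_sample_size

logger = logging.getLogger(__name__)

LEVELS = ("crop", "cdp", "crop_cdp", "crop_cdp_prefecture")

PCC_STRONG = 0.7
PCC_MODERATE = 0.4
LOW_N_PAIRS = 10


@dataclass(frozen=True)
class SizeBinReport:
    level: str
    counts: Dict[str, int]
    proportions: Dict[str, float]
    total: int


@dataclass(frozen=True)
class DIDistributionSummary:
    thresholds: Tuple[float, ...]
    cumulative_fractions: Tuple[float, ...]
    heap_points: Tuple[float, ...]
    heap_fractions: Tuple[float, ...]
    n: int


@dataclass(frozen=True)
class CorrelationRecord:
    cdp: str
    prefecture: str
    crop_a: str
    crop_b: str
    n_pairs: int
    pcc: float
    category: str
    low_n: bool


@dataclass(frozen=True)
class AnovaResult:
    key: ComboKey
    n: int
    n_months: int
    f_stat: float
    p_value: float
    p_adjusted: float | None = None


@dataclass(frozen=True)
class AnovaIneligible:
    key: ComboKey
    reason: str


def _level_key(record: SurveyRecord, level: str) -> tuple:
    if level == "crop":
        return (record.crop,)
    if level == "cdp":
        return (record.cdp,)
    if level == "crop_cdp":
        return (record.crop, record.cdp)
    if level == "crop_cdp_prefecture":
        return (record.crop, record.cdp, record.prefecture)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def size_bin_report(records: Iterable[SurveyRecord], level: str) -> SizeBinReport:
    """Sample-size composition at an aggregation level.

    Samples are pooled by the level's key (e.g. all prefectures of one crop x
    CDP pair at level ``crop_cdp``) and the pooled counts are binned.
    """
    counts_by_key: Dict[tuple, int] = defaultdict(int)
    for r in records:
        counts_by_key[_level_key(r, level)] += 1
    if not counts_by_key:
        raise ValueError("size_bin_report requires at least one record")
    bin_counts = {label: 0 for label in SIZE_BIN_LABELS}
    for n in counts_by_key.values():
        bin_counts[bin_sample_size(n)] += 1
    total = len(counts_by_key)
    return SizeBinReport(
        level=level,
        counts=bin_counts,
        proportions={k: v / total for k, v in bin_counts.items()},
        total=total,
    )


def di_distribution_summary(
    records: Iterable[SurveyRecord],
    thresholds: Sequence[float] = (1.0, 3.0, 5.0, 10.0),
    heap_points: Sequence[float] = (0.1, 1.0, 2.0, 3.0),
) -> DIDistributionSummary:
    """Cumulative fractions of DI at or below each threshold, plus the
    fraction exactly equal to each round heap point."""
    values = np.array([r.di for r in records], dtype=float)
    if values.size == 0:
        raise ValueError("di_distribution_summary requires at least one record")
    cumulative = tuple(float((values <= t).mean()) for t in thresholds)
    heaps = tuple(float((values == h).mean()) for h in heap_points)
    return DIDistributionSummary(
        thresholds=tuple(float(t) for t in thresholds),
        cumulative_fractions=cumulative,
        heap_points=tuple(float(h) for h in heap_points),
        heap_fractions=heaps,
        n=int(values.size),
    )


def categorize_pcc(pcc: float) -> str:
    """Strong iff PCC >= 0.7, moderate iff 0.4 <= PCC < 0.7, else weak.

    The categories bound positive correlation only; negative values are weak.
    """
    if not (-1.0 - 1e-12 <= pcc <= 1.0 + 1e-12):
        raise ValueError(f"PCC out of [-1, 1]: {pcc}")
    if pcc >= PCC_STRONG:
        return "strong"
    if pcc >= PCC_MODERATE:
        return "moderate"
    return "weak"


def cross_crop_pcc(
    series_collection: Iterable[ComboSeries], min_pairs: int = 2
) -> List[CorrelationRecord]:
    """Pearson correlation between crops sharing a CDP and prefecture.

    Observations are matched on exact (year, month); months where either crop
    lacks a DI are dropped (complete case). A pair is emitted only when at
    least ``min_pairs`` matched points exist and both matched series vary;
    pairs resting on fewer than 10 points carry a ``low_n`` flag rather than
    being suppressed, so small-sample correlations remain countable.
    """
    grouped: Dict[Tuple[str, str], Dict[str, ComboSeries]] = defaultdict(dict)
    for s in series_collection:
        grouped[(s.key.cdp, s.key.prefecture)][s.key.crop] = s
    out: List[CorrelationRecord] = []
    for (cdp, pref) in sorted(grouped):
        by_crop = grouped[(cdp, pref)]
        for crop_a, crop_b in combinations(sorted(by_crop), 2):
            sa, sb = by_crop[crop_a], by_crop[crop_b]
            common = sorted(set(sa.observations) & set(sb.observations))
            if len(common) < min_pairs:
                logger.debug(
                    "skipping %s/%s %s-%s: %d matched points",
                    cdp, pref, crop_a, crop_b, len(common),
                )
                continue
            xa = np.array([sa.observations[ym] for ym in common])
            xb = np.array([sb.observations[ym] for ym in common])
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.debug(
                    "skipping %s/%s %s-%s: zero variance", cdp, pref, crop_a, crop_b
                )
                continue
            pcc = float(stats.pearsonr(xa, xb).statistic)
            out.append(
                CorrelationRecord(
                    cdp=cdp,
                    prefecture=pref,
                    crop_a=crop_a,
                    crop_b=crop_b,
                    n_pairs=len(common),
                    pcc=pcc,
                    category=categorize_pcc(pcc),
                    low_n=len(common) < LOW_N_PAIRS,
                )
            )
    return out


def monthly_anova(series: ComboSeries) -> AnovaResult | AnovaIneligible:
    """One-way fixed-effects ANOVA of DI grouped by calendar month.

    Eligibility requires at least two distinct months, each with at least two
    observations — the weakest rule leaving the F statistic a positive-df
    denominator. Ineligible series return an explicit marker with the reason.
    """
    groups: Dict[int, List[float]] = defaultdict(list)
    for (_y, m), di in series.observations.items():
        groups[m].append(di)
    usable = {m: v for m, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        return AnovaIneligible(series.key, "data collected in a single month")
    if len(usable) < 2:
        return AnovaIneligible(
            series.key, "fewer than two months with at least two observations"
        )
    arrays = [np.asarray(v, dtype=float) for _m, v in sorted(usable.items())]
    n = int(sum(a.size for a in arrays))
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical values everywhere: no variation to explain
        return AnovaResult(series.key, n, len(arrays), f_stat=0.0, p_value=1.0)
    f_stat, p_value = stats.f_oneway(*arrays)
    if np.isnan(f_stat):
        # zero within-group variance with equal means
        f_stat, p_value = 0.0, 1.0
    return AnovaResult(series.key, n, len(arrays), float(f_stat), float(p_value))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def batch_monthly_anova(
    series_collection: Iterable[ComboSeries],
) -> Tuple[List[AnovaResult], List[AnovaIneligible]]:
    """Run the monthly ANOVA per combination and BH-adjust jointly.

    The correction is applied once across every eligible combination of the
    run — the screening is a single family of tests.
    """
    results: List[AnovaResult] = []
    ineligible: List[AnovaIneligible] = []
    for s in series_collection:
        r = monthly_anova(s)
        if isinstance(r, AnovaIneligible):
            ineligible.append(r)
        else:
            results.append(r)
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        results = [
            AnovaResult(r.key, r.n, r.n_months, r.f_stat, r.p_value, float(adj))
            for r, adj in zip(results, adjusted)
        ]
    return results, ineligible


def size_bin_report_frame(reports: Iterable[SizeBinReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for label in SIZE_BIN_LABELS:
            rows.append(
                (rep.level, label, rep.counts[label], rep.proportions[label], rep.total)
            )
    return pd.DataFrame(
        rows, columns=["level", "size_bin", "count", "proportion", "total"]
    )


def pcc_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cdp, r.prefecture, r.crop_a, r.crop_b, r.n_pairs, r.pcc, r.category, r.low_n)
            for r in records
        ],
        columns=[
            "cdp", "prefecture", "crop_a", "crop_b", "n_pairs", "pcc", "category", "low_n",
        ],
    )


def anova_frame(
    results: Iterable[AnovaResult], ineligible: Iterable[AnovaIneligible] = ()
) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            (r.key.crop, r.key.cdp, r.key.prefecture, "ok", r.n, r.n_months,
             r.f_stat, r.p_value, r.p_adjusted)
        )
    for r in ineligible:
        rows.append(
            (r.key.crop, r.key.cdp, r.key.prefecture, r.reason, None, None,
             None, None, None)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "crop", "cdp", "prefecture", "status", "n", "n_months",
            "f_stat", "p_value", "p_adjusted",
        ],
    )
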