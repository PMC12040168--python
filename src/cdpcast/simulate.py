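"""Synthetic CDP survey panels with known ground truth.

The national survey data this package analyzes are governmental and not
publicly deposited, so every downstream stage is exercised on synthetic
panels that emulate the survey's documented structure:

* damage incidence (DI) is log-normal on the margin, with "heaping" — excess
  probability mass at the round reported values 0.1, 1, 2 and 3% — layered on
  top as independent replacement;
* each combination (crop x CDP x prefecture) is surveyed over a period of
  1-27 years and during a contiguous block of 1-12 months per year (a growing
  season), so panels are sparse and irregular;
* log DI decomposes into a combination baseline, a fixed month effect
  (seasonality), a year-level AR(1) effect (short-memory dependence that makes
  a past-averages forecaster informative), and observation noise.

Ground truth (baselines, month effects, realized year effects, heap
assignments) is retained for recovery tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import ComboKey, MeteoStationRecord, SurveyRecord

logger = logging.getLogger(__name__)

# Marginal cumulative-DI calibration targets: fraction of DI values at or
# below 1, 3, 5 and 10 percent. These define the default log-normal scale.
DEFAULT_CDF_TARGETS: Dict[float, float] = {1.0: 0.405, 3.0: 0.605, 5.0: 0.701, 10.0: 0.818}

# Default heaping: probability that a reported DI is replaced by a round value.
DEFAULT_HEAP_PROBS: Dict[float, float] = {0.1: 0.065, 1.0: 0.053, 2.0: 0.029, 3.0: 0.015}

FIRST_SURVEY_YEAR = 1996
MAX_PERIOD_YEARS = 27

Sampler = Mapping[int, float]


def calibrate_lognormal(targets: Mapping[float, float]) -> Tuple[float, float]:
    """Least-squares (mu, sigma) of log DI matching cumulative fractions.

    Solves log(x_i) ~ mu + sigma * Phi^-1(p_i) over the (threshold, fraction)
    pairs; exact when the targets are consistent with a single log-normal.
    """
    x = np.log(np.fromiter(targets.keys(), dtype=float))
    z = stats.norm.ppf(np.fromiter(targets.values(), dtype=float))
    sigma, mu = np.polyfit(z, x, 1)
    if sigma <= 0:
        raise ValueError("calibration targets imply non-increasing CDF")
    return float(mu), float(sigma)


def _default_period_probs() -> Dict[int, float]:
    # 19.1% single-year combos and 4.0% full-length (27 y) combos, with a
    # gentle geometric decay over the lengths in between.
    probs = {1: 0.191, MAX_PERIOD_YEARS: 0.040}
    rest = 1.0 - sum(probs.values())
    decay = 0.92
    weights = {k: decay ** (k - 2) for k in range(2, MAX_PERIOD_YEARS)}
    total = sum(weights.values())
    for k, w in weights.items():
        probs[k] = rest * w / total
    return probs


def _default_frequency_probs() -> Dict[int, float]:
    # Just over half of combos are surveyed <=3 months/year and ~80.6%
    # <=6 months/year; the rest taper off toward year-round surveys.
    return {
        1: 0.20, 2: 0.17, 3: 0.15,
        4: 0.11, 5: 0.10, 6: 0.076,
        7: 0.05, 8: 0.04, 9: 0.03,
        10: 0.025, 11: 0.02, 12: 0.029,
    }


def _validate_sampler(sampler: Sampler, lo: int, hi: int, name: str) -> None:
    if not sampler:
        raise ValueError(f"{name} must be non-empty")
    total = 0.0
    for k, p in sampler.items():
        if not (lo <= int(k) <= hi):
            raise ValueError(f"{name}: value {k} outside [{lo}, {hi}]")
        if p < 0:
            raise ValueError(f"{name}: negative probability for {k}")
        total += p
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"{name}: probabilities sum to {total}, expected 1")


def _draw(sampler: Sampler, rng: np.random.Generator) -> int:
    keys = sorted(sampler)
    probs = np.array([sampler[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the documented survey structure.

    All effect sizes are on the log-DI scale. ``year_effect_logsd`` is the
    stationary standard deviation of the AR(1) year effect; the innovation sd
    is derived from it and ``year_ar_coefficient``.
    """

    n_combos: int = 100
    period_sampler: Dict[int, float] = field(default_factory=_default_period_probs)
    frequency_sampler: Dict[int, float] = field(default_factory=_default_frequency_probs)
    baseline_logmean: float = 0.0
    baseline_logsd: float = 1.0
    month_effect_amplitude: float = 0.5
    year_ar_coefficient: float = 0.5
    year_effect_logsd: float = 0.5
    obs_noise_logsd: float = 0.5
    heap_points: Tuple[float, ...] = (0.1, 1.0, 2.0, 3.0)
    heap_probs: Tuple[float, ...] = (0.065, 0.053, 0.029, 0.015)
    meteo_coupling: float = 0.0
    n_stations_per_prefecture: int = 2
    prefecture_pool: int = 8
    temp_mean: float = 14.0
    temp_amplitude: float = 10.0
    temp_noise_sd: float = 1.0
    precip_logmean: float = math.log(120.0)
    precip_log_amplitude: float = 0.4
    precip_logsd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_combos < 1:
            raise ValueError("n_combos must be >= 1")
        # JSON configs carry string keys; normalize samplers to int -> float
        self.period_sampler = {int(k): float(v) for k, v in self.period_sampler.items()}
        self.frequency_sampler = {
            int(k): float(v) for k, v in self.frequency_sampler.items()
        }
        _validate_sampler(self.period_sampler, 1, MAX_PERIOD_YEARS, "period_sampler")
        _validate_sampler(self.frequency_sampler, 1, 12, "frequency_sampler")
        if not (0.0 <= self.year_ar_coefficient < 1.0):
            raise ValueError("year_ar_coefficient must be in [0, 1)")
        for name in ("baseline_logsd", "month_effect_amplitude",
                     "year_effect_logsd", "obs_noise_logsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.heap_points) != len(self.heap_probs):
            raise ValueError("heap_points and heap_probs must align")
        if any(p < 0 for p in self.heap_probs):
            raise ValueError("heap_probs must be >= 0")
        if sum(self.heap_probs) > 1.0 + 1e-12:
            raise ValueError("heap_probs must sum to <= 1")

    @classmethod
    def calibrated(cls, **overrides) -> "SyntheticConfig":
        """Config whose marginal log-DI scale matches the default CDF targets.

        The cumulative targets describe the *reported* DI distribution, heaps
        included, so the log-normal component is fitted to the targets net of
        the heap mass below each threshold. The calibrated total log-scale
        variance is split 40% between-combo baseline, 30% month effects, 20%
        year effects, 10% observation noise: between-combination heterogeneity
        dominates the marginal distribution, while within a combination the
        structured (month + year) signal outweighs survey noise — the regime
        in which monthly historical averages are an informative forecaster.
        """
        heap_points = overrides.get("heap_points", (0.1, 1.0, 2.0, 3.0))
        heap_probs = overrides.get("heap_probs", (0.065, 0.053, 0.029, 0.015))
        total_heap = sum(heap_probs)
        continuous_targets = {}
        for threshold, target in DEFAULT_CDF_TARGETS.items():
            below = sum(
                p for pt, p in zip(heap_points, heap_probs) if pt <= threshold
            )
            continuous_targets[threshold] = (target - below) / (1.0 - total_heap)
        mu, sigma = calibrate_lognormal(continuous_targets)
        var = sigma ** 2
        params = dict(
            baseline_logmean=mu,
            baseline_logsd=math.sqrt(0.40 * var),
            # month-effect variance is 0.75 * A^2 (sinusoid + jitter)
            month_effect_amplitude=math.sqrt(0.30 * var / 0.75),
            year_effect_logsd=math.sqrt(0.20 * var),
            obs_noise_logsd=math.sqrt(0.10 * var),
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class ComboTruth:
    """Realized generator state for one combination."""

    key: ComboKey
    baseline: float
    month_effects: Tuple[float, ...]  # 12 values, sum to 0
    year_effects: Dict[int, float]
    active_months: Tuple[int, ...]
    first_year: int
    last_year: int
    heap_assignments: Dict[Tuple[int, int], float]  # (year, month) -> heap point


@dataclass
class SyntheticTruth:
    """Ground truth for a generated panel, keyed by combination."""

    config: SyntheticConfig
    combos: Dict[ComboKey, ComboTruth] = field(default_factory=dict)


def apply_heaping(
    values: Sequence[float],
    heap_points: Sequence[float],
    heap_probs: Sequence[float],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Independently replace each value by a round heap point with its probability.

    Returns (heaped values, assignment array with the heap point or NaN).
    Replacement — rather than rounding of nearby values — is deliberate: only
    the marginal spike at the round numbers matters for the analyses built on
    top of this generator.
    """
    if len(heap_points) != len(heap_probs):
        raise ValueError("heap_points and heap_probs must align")
    probs = np.asarray(heap_probs, dtype=float)
    if (probs < 0).any():
        raise ValueError("heap_probs must be >= 0")
    if probs.sum() > 1.0 + 1e-12:
        raise ValueError("heap_probs must sum to <= 1")
    out = np.asarray(values, dtype=float).copy()
    assignment = np.full(out.shape, np.nan)
    u = rng.random(out.shape)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    for j, point in enumerate(heap_points):
        mask = (u >= edges[j]) & (u < edges[j + 1])
        out[mask] = point
        assignment[mask] = point
    return out, assignment


def _month_effects(amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-sum seasonal profile: random-phase sinusoid plus month jitter.

    The jitter (sd = amplitude / 2) roughens the profile so that seasonal
    peaks are sharper than a first harmonic — outbreak seasonality follows
    crop phenology, not a smooth sinusoid. Total month-effect variance is
    therefore 0.75 * amplitude**2 (sinusoid A^2/2 plus jitter A^2/4).
    """
    phase = rng.uniform(0, 12)
    months = np.arange(1, 13)
    s = amplitude * np.sin(2 * np.pi * (months - phase) / 12.0)
    if amplitude > 0:
        s = s + rng.normal(0.0, 0.5 * amplitude, 12)
    return s - s.mean()


def _active_month_block(n_active: int, rng: np.random.Generator) -> Tuple[int, ...]:
    """Contiguous growing-season block of months, wrapping over December."""
    start = int(rng.integers(1, 13))
    return tuple(sorted(((start - 1 + i) % 12) + 1 for i in range(n_active)))


def _seasonal_temperature(month: np.ndarray | int, mean: float, amplitude: float):
    """Noise-free northern-hemisphere temperature curve (peak in July)."""
    return mean + amplitude * np.cos(2 * np.pi * (np.asarray(month) - 7) / 12.0)


def generate_panel(
    config: SyntheticConfig, seed: int | None = None
) -> Tuple[list[SurveyRecord], SyntheticTruth]:
    """Generate a survey panel plus its ground truth.

    For each combination: draw a survey period and a contiguous active-month
    block; for each observed (year, month), log DI = baseline + month effect +
    AR(1) year effect + noise; exponentiate; apply heaping; clip to [0, 100].
    Deterministic given (config, seed). Per-combination RNG substreams are
    spawned from the master seed, so increasing ``n_combos`` never perturbs
    previously generated combinations.
    """
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    streams = root.spawn(config.n_combos)
    truth = SyntheticTruth(config=config)
    records: list[SurveyRecord] = []
    n_clipped = 0
    rho = config.year_ar_coefficient
    innov_sd = config.year_effect_logsd * math.sqrt(max(0.0, 1.0 - rho ** 2))
    for i in range(config.n_combos):
        rng = np.random.default_rng(streams[i])
        key = ComboKey(
            crop=f"crop{i % 23:02d}",
            cdp=f"cdp{i % 41:02d}",
            prefecture=f"pref{i % config.prefecture_pool:02d}",
        )
        period = _draw(config.period_sampler, rng)
        n_active = _draw(config.frequency_sampler, rng)
        start_year = FIRST_SURVEY_YEAR + int(
            rng.integers(0, MAX_PERIOD_YEARS - period + 1)
        )
        years = list(range(start_year, start_year + period))
        active = _active_month_block(n_active, rng)
        baseline = rng.normal(config.baseline_logmean, config.baseline_logsd)
        s = _month_effects(config.month_effect_amplitude, rng)
        # stationary AR(1) year effects
        innovations = rng.normal(0.0, 1.0, period)
        u_arr = np.empty(period)
        u_arr[0] = config.year_effect_logsd * innovations[0]
        for t in range(1, period):
            u_arr[t] = rho * u_arr[t - 1] + innov_sd * innovations[t]
        u: Dict[int, float] = {y: float(u_arr[t]) for t, y in enumerate(years)}
        yms: list[Tuple[int, int]] = [(y, m) for y in years for m in active]
        month_idx = np.array([m - 1 for (_y, m) in yms])
        year_idx = np.array([t for t in range(period) for _ in active])
        log_di = (
            baseline
            + s[month_idx]
            + u_arr[year_idx]
            + rng.normal(0.0, config.obs_noise_logsd, len(yms))
        )
        if config.meteo_coupling != 0.0:
            months = np.array([m for (_y, m) in yms])
            anomaly = (
                _seasonal_temperature(months, config.temp_mean, config.temp_amplitude)
                - config.temp_mean
            ) / config.temp_amplitude
            log_di = log_di + config.meteo_coupling * anomaly
        raw = np.exp(log_di)
        heaped, assignment = apply_heaping(
            raw, config.heap_points, config.heap_probs, rng
        )
        clipped = np.clip(heaped, 0.0, 100.0)
        n_clipped += int((clipped != heaped).sum())
        heap_map = {
            ym: float(a) for ym, a in zip(yms, assignment) if not math.isnan(a)
        }
        truth.combos[key] = ComboTruth(
            key=key,
            baseline=float(baseline),
            month_effects=tuple(float(v) for v in s),
            year_effects=u,
            active_months=active,
            first_year=years[0],
            last_year=years[-1],
            heap_assignments=heap_map,
        )
        for (y, m), di in zip(yms, clipped):
            records.append(
                SurveyRecord(key.crop, key.cdp, key.prefecture, y, m, float(di))
            )
    if n_clipped:
        logger.info("clipped %d synthetic DI values to [0, 100]", n_clipped)
    return records, truth


def generate_meteorology(
    config: SyntheticConfig,
    prefectures: Sequence[str],
    years: Sequence[int],
    seed: int | None = None,
) -> list[MeteoStationRecord]:
    """Monthly station meteorology: sinusoidal temperature, seasonal log-normal
    precipitation, plus humidity and sunshine filler variables.

    Deterministic given (config, prefectures, years, seed).
    """
    if not prefectures or not len(years):
        raise ValueError("need at least one prefecture and one year")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7_001]))
    records: list[MeteoStationRecord] = []
    months = np.arange(1, 13)
    for pref in prefectures:
        pref_offset = rng.normal(0.0, 2.0)
        for s_idx in range(config.n_stations_per_prefecture):
            station = f"{pref}-st{s_idx}"
            for y in years:
                base_t = _seasonal_temperature(
                    months, config.temp_mean + pref_offset, config.temp_amplitude
                )
                t_noise = (
                    rng.normal(0.0, config.temp_noise_sd, 12)
                    if config.temp_noise_sd > 0
                    else np.zeros(12)
                )
                log_p = (
                    config.precip_logmean
                    + config.precip_log_amplitude
                    * np.sin(2 * np.pi * (months - 6) / 12.0)
                    + (
                        rng.normal(0.0, config.precip_logsd, 12)
                        if config.precip_logsd > 0
                        else np.zeros(12)
                    )
                )
                hum = np.clip(rng.normal(70.0, 5.0, 12), 0.0, 100.0)
                sun = np.maximum(
                    rng.normal(150.0, 25.0, 12)
                    + 30.0 * np.cos(2 * np.pi * (months - 7) / 12.0),
                    0.0,
                )
                for j, m in enumerate(months):
                    records.append(
                        MeteoStationRecord(
                            station=station,
                            prefecture=pref,
                            year=int(y),
                            month=int(m),
                            temperature=float(base_t[j] + t_noise[j]),
                            precipitation=float(np.exp(log_p[j])),
                            humidity=float(hum[j]),
                            sunshine=float(sun[j]),
                        )
                    )
    return records
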