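"""Trajectory ensembles, condition comparisons and the heat-shock protocol.

Transcription levels are estimated by averaging completed-transcript counts
over many independently seeded trajectories; between-condition changes are
reported as ratios of ensemble means. The ratio of means (not the mean of
per-trajectory ratios) is used deliberately: per-trajectory count ratios are
heavy-tailed, Cauchy-like quantities without a finite mean, while the ratio
of ensemble means is stable and matches how molecular assays pool molecules.
Spread on a ratio comes from a seeded nonparametric bootstrap over trajectory
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import kernel
from .engine import (
    TemperatureSchedule,
    TrajectoryResult,
    constant_schedule,
    counts_in_window,
    run_trajectory,
)
from .locus import Locus

__all__ = [
    "EnsembleResult",
    "RatioEstimate",
    "run_ensemble",
    "compare_conditions",
    "heat_shock_protocol",
    "DEFAULT_WARMUP_S",
]

#: Time the system is given to forget its empty initial state before counting
#: (the traffic pattern is stationary after about three hours of modeled time).
DEFAULT_WARMUP_S = 3 * 3600.0


def _trajectory_seed(master_seed, index: int):
    """Seed entropy for trajectory ``index``; stable across conditions so the
    same index can share random numbers between two compared conditions."""
    if isinstance(master_seed, (int, np.integer)):
        return (int(master_seed), index)
    return tuple(int(s) for s in master_seed) + (index,)


@dataclass
class EnsembleResult:
    """Per-unit transcription rates averaged over an ensemble of trajectories."""

    table: pd.DataFrame  # index: gene/group unit; columns: mean_per_hour, sd_per_hour, n
    per_trajectory: pd.DataFrame  # rows: trajectories; columns: units; counts in window
    window: tuple[float, float]
    condition: str
    seeds: list

    @property
    def means_per_hour(self) -> pd.Series:
        return self.table["mean_per_hour"]


def run_ensemble(
    locus: Locus,
    condition: str,
    duration: float,
    n: int,
    seed,
    temperature: Optional[float] = None,
    schedule: Optional[TemperatureSchedule] = None,
    warmup: float = 0.0,
    count_window: Optional[tuple[float, float]] = None,
) -> EnsembleResult:
    """Run ``n`` independent trajectories and average per-hour transcript rates.

    Counting starts after ``warmup`` seconds (or inside ``count_window`` if
    given). Results are reproducible from ``seed``: trajectory ``i`` uses the
    derived seed ``(seed, i)``.
    """
    if n < 2:
        raise ValueError("an ensemble needs n >= 2 trajectories to estimate spread")
    if count_window is None:
        count_window = (warmup, duration)
    t0, t1 = count_window
    if not 0.0 <= t0 < t1 <= duration:
        raise ValueError(f"count window {count_window} outside [0, {duration}]")

    units = locus.count_units()
    rows = []
    seeds = []
    for i in range(n):
        s = _trajectory_seed(seed, i)
        seeds.append(s)
        res = run_trajectory(
            locus, condition, duration, s, schedule=schedule, temperature=temperature
        )
        rows.append(counts_in_window(res, locus, t0, t1))
    per_traj = pd.DataFrame(rows, columns=units, index=range(n)).fillna(0).astype(int)
    hours = (t1 - t0) / 3600.0
    rates = per_traj / hours
    table = pd.DataFrame(
        {
            "mean_per_hour": rates.mean(axis=0),
            "sd_per_hour": rates.std(axis=0, ddof=1),
            "n": n,
        }
    )
    return EnsembleResult(
        table=table,
        per_trajectory=per_traj,
        window=(t0, t1),
        condition=condition,
        seeds=seeds,
    )


@dataclass
class RatioEstimate:
    """Per-unit transcription-level ratio between two conditions with spread."""

    table: pd.DataFrame  # index: unit; columns: ratio, spread, n, defined
    condition_a: str
    condition_b: str

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]


def _bootstrap_ratio_spread(
    counts_a: np.ndarray, counts_b: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """SD of the ratio of means under paired resampling of trajectory indices."""
    n = counts_a.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    means_a = counts_a[idx].mean(axis=1)
    means_b = counts_b[idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(means_b > 0, means_a / np.maximum(means_b, 1e-300), np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanstd(ratios, axis=0)


def compare_conditions(
    locus: Locus,
    condition_a: str,
    condition_b: str,
    duration: float,
    n: int,
    seed,
    temperature: Optional[float] = None,
    schedule_a: Optional[TemperatureSchedule] = None,
    schedule_b: Optional[TemperatureSchedule] = None,
    warmup: float = 0.0,
    count_window: Optional[tuple[float, float]] = None,
    n_boot: int = 1000,
    share_seeds: bool = True,
) -> RatioEstimate:
    """Ratio of ensemble-mean transcription levels, condition A over B.

    With ``share_seeds`` (default) the i-th trajectories of both conditions
    use common random numbers, so comparing a condition against itself gives
    ratios of exactly 1 and between-condition variance is reduced. A unit
    whose denominator mean is zero is flagged undefined (NaN), not raised.
    """
    seed_b = seed if share_seeds else _trajectory_seed(seed, 0x5EED)
    ens_a = run_ensemble(
        locus, condition_a, duration, n, seed,
        temperature=temperature, schedule=schedule_a,
        warmup=warmup, count_window=count_window,
    )
    ens_b = run_ensemble(
        locus, condition_b, duration, n, seed_b,
        temperature=temperature, schedule=schedule_b,
        warmup=warmup, count_window=count_window,
    )
    boot_rng = kernel.stream_rng(
        seed if isinstance(seed, (int, tuple)) else tuple(seed), "bootstrap"
    )
    units = list(ens_a.per_trajectory.columns)
    ratios, spreads, defined = [], [], []
    a = ens_a.per_trajectory.to_numpy(dtype=float)
    b = ens_b.per_trajectory.to_numpy(dtype=float)
    spread_all = _bootstrap_ratio_spread(a, b, n_boot, boot_rng)
    for j, u in enumerate(units):
        mean_a, mean_b = a[:, j].mean(), b[:, j].mean()
        if mean_b > 0:
            ratios.append(mean_a / mean_b)
            spreads.append(spread_all[j])
            defined.append(True)
        else:
            ratios.append(np.nan)
            spreads.append(np.nan)
            defined.append(False)
    table = pd.DataFrame(
        {"ratio": ratios, "spread": spreads, "n": n, "defined": defined}, index=units
    )
    return RatioEstimate(table=table, condition_a=condition_a, condition_b=condition_b)


def heat_shock_protocol(
    locus: Locus,
    condition: str,
    n: int,
    seed,
    t1: float = DEFAULT_WARMUP_S,
    t2: float = 1.5 * 3600.0,
    t3: float = 0.25 * 3600.0,
    temp_normal: float = 21.0,
    temp_shock: float = 40.0,
    temp_after: float = 25.0,
    count_window: str = "shock+aftershock",
    n_boot: int = 1000,
) -> RatioEstimate:
    """Shocked-over-control transcription ratio per gene (HT/WT).

    The shocked population grows at ``temp_normal`` for ``t1`` (warm-up, at
    least the time to stationarity), is exposed to ``temp_shock`` for ``t2``
    and returns to ``temp_after`` for ``t3``; the control sees ``temp_normal``
    instead of the shock. Binding intensities are unchanged — only elongation
    rates respond to temperature. Transcripts are counted during
    ``shock+aftershock`` (``t2 + t3``, default) or ``aftershock`` only.
    """
    if t1 <= 0:
        raise ValueError("warm-up t1 must be positive (schedule shorter than warm-up)")
    duration = t1 + t2 + t3
    shocked = TemperatureSchedule(((t1, temp_normal), (t2, temp_shock), (t3, temp_after)))
    control = TemperatureSchedule(((t1, temp_normal), (t2, temp_normal), (t3, temp_after)))
    if count_window == "shock+aftershock":
        window = (t1, duration)
    elif count_window == "aftershock":
        window = (t1 + t2, duration)
    else:
        raise ValueError("count_window must be 'shock+aftershock' or 'aftershock'")
    return compare_conditions(
        locus, condition, condition, duration, n, seed,
        schedule_a=shocked, schedule_b=control,
        count_window=window, n_boot=n_boot, share_seeds=True,
    )
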