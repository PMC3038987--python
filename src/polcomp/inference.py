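"""Inverse mode: estimate binding intensities from measured transcription ratios.

Unknown promoter intensities (and optionally terminator probabilities) are
found by exhaustive search on a grid, scoring each candidate by the worst-case
symmetric relative discrepancy between simulated and experimental vectors of
transcription levels (or level ratios), after pruning the grid with a
strand-balance condition: where transcription on the two strands competes,
the total binding intensity entering the contested region from each side must
be similar, otherwise one strand simply silences the other and the measured
genes could not all be transcribed. Several experiments are combined by
ranking candidates under each experiment separately and minimizing the
weighted total rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .calibration import intensity_upper_bound
from .engine import TemperatureSchedule
from .experiments import compare_conditions, run_ensemble
from .locus import Locus, Strand, Terminator

__all__ = [
    "discrepancy_ratio",
    "discrepancy_level",
    "competing_regions",
    "balance_filter",
    "Unknown",
    "ExperimentTarget",
    "InferenceProblem",
    "CandidateScore",
    "rank_candidates",
    "grid_search",
    "hypothesis_scan",
    "LAMBDA_MAX",
]

#: Default upper bound for a binding intensity (1/s), from the rrn calibration.
LAMBDA_MAX = round(intensity_upper_bound(), 3)  # 1.113


def _max_symmetric_relative(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("discrepancy requires strictly positive entries")
    return float(np.max(np.abs(a - b) / ((a + b) / 2.0)))


def discrepancy_ratio(z, z0) -> float:
    """Worst-case symmetric relative error between ratio vectors.

    ``max_i |z_i - z0_i| / ((z_i + z0_i)/2)``. The averaged denominator makes
    the measure symmetric in the two arguments and equal for a ratio pair and
    its reciprocals (a 3-fold vs 2-fold mismatch scores the same as 1/3 vs
    1/2).
    """
    return _max_symmetric_relative(np.asarray(z, dtype=float), np.asarray(z0, dtype=float))


def discrepancy_level(y, y0) -> float:
    """Worst-case symmetric relative error between absolute level vectors."""
    return _max_symmetric_relative(np.asarray(y, dtype=float), np.asarray(y0, dtype=float))


# ---------------------------------------------------------------------------
# Strand-balance pruning
# ---------------------------------------------------------------------------


def competing_regions(locus: Locus) -> list[dict]:
    """Regions where transcription from the two strands competes head-on.

    A region is the maximal interval bounded by a convergent promoter pair —
    a plus-strand promoter with the nearest minus-strand promoter downstream
    of it — with no other promoter in between. For each region, ``plus`` is
    the set of plus-strand promoters at or upstream of its left edge (their
    transcription enters from the left) and ``minus`` the minus-strand
    promoters at or downstream of its right edge.
    """
    proms = sorted(locus.promoters, key=lambda p: p.tss)
    regions = []
    for i, p in enumerate(proms):
        if p.strand is not Strand.PLUS:
            continue
        nxt = proms[i + 1] if i + 1 < len(proms) else None
        if nxt is not None and nxt.strand is Strand.MINUS:
            regions.append(
                {
                    "interval": (p.tss, nxt.tss),
                    "plus": [q.id for q in proms if q.strand is Strand.PLUS and q.tss <= p.tss],
                    "minus": [q.id for q in proms if q.strand is Strand.MINUS and q.tss >= nxt.tss],
                }
            )
    return regions


def balance_filter(lambdas: Mapping[str, float], locus: Locus, D: float) -> bool:
    """True iff every competing region is dynamically balanced within ``D``.

    ``lambdas`` maps promoter id to binding intensity for one condition; for
    each competing region the absolute difference between the summed
    intensities entering on the two strands must not exceed ``D`` (1/s).
    A locus without convergent promoter pairs always passes.
    """
    for region in competing_regions(locus):
        plus = sum(lambdas[i] for i in region["plus"])
        minus = sum(lambdas[i] for i in region["minus"])
        if abs(plus - minus) > D:
            return False
    return True


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Unknown:
    """One free parameter: a promoter intensity or a terminator probability.

    ``element`` names the promoter or terminator; ``condition`` selects which
    condition's intensity is free (ignored for terminators). The grid runs
    from ``bounds[0]`` to ``bounds[1]`` in steps of ``step``.
    """

    element: str
    condition: Optional[str] = None
    bounds: tuple[float, float] = (0.0, LAMBDA_MAX)
    step: float = 0.01
    kind: str = "promoter"  # or "terminator"

    def grid(self) -> np.ndarray:
        lo, hi = self.bounds
        n = int(round((hi - lo) / self.step))
        return lo + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class ExperimentTarget:
    """One optimization criterion: an experimental vector to approximate.

    ``kind='ratio'`` compares per-unit ratios of condition_a over condition_b
    against ``values``; ``kind='level'`` compares absolute per-hour levels of
    ``condition_a``. ``schedule_a/b`` override the constant temperature, e.g.
    for a heat-shock criterion.
    """

    kind: str
    values: Mapping[str, float]
    condition_a: str
    condition_b: Optional[str] = None
    weight: float = 1.0
    schedule_a: Optional[TemperatureSchedule] = None
    schedule_b: Optional[TemperatureSchedule] = None

    def __post_init__(self):
        if self.kind not in ("ratio", "level"):
            raise ValueError("experiment kind must be 'ratio' or 'level'")
        if self.kind == "ratio" and self.condition_b is None:
            raise ValueError("ratio experiments need condition_b")
        if self.weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class InferenceProblem:
    """A grid-search problem: locus, unknowns, experiments and budget."""

    locus: Locus
    unknowns: Sequence[Unknown]
    experiments: Sequence[ExperimentTarget]
    balance_threshold: float = 0.8  # D, chosen in [0.1, 0.8]
    n_trajectories: int = 50
    duration: float = 24 * 3600.0
    warmup: float = 0.0
    temperature: float = 23.0
    seed: int = 0
    constraints: Sequence[tuple[int, int]] = ()  # (i_low, i_high): value_i <= value_j

    def __post_init__(self):
        if not self.unknowns:
            raise ValueError("no unknowns to search")
        if not self.experiments:
            raise ValueError("no experiments to fit")
        if not 0.0 < self.balance_threshold:
            raise ValueError("balance threshold D must be positive")


@dataclass
class CandidateScore:
    """One evaluated grid point."""

    params: tuple[float, ...]
    discrepancies: tuple[float, ...]
    ranks: tuple[float, ...] = ()
    total_rank: float = 0.0
    weighted_sum: float = 0.0


def _apply_params(locus: Locus, unknowns: Sequence[Unknown], values) -> Locus:
    """Locus with unknown elements substituted by candidate values."""
    promoters = list(locus.promoters)
    terminators = list(locus.terminators)
    for unk, val in zip(unknowns, values):
        if unk.kind == "promoter":
            for i, p in enumerate(promoters):
                if p.id == unk.element:
                    intens = dict(p.intensity_by_condition)
                    if unk.condition is None:
                        for c in intens:
                            intens[c] = float(val)
                    else:
                        intens[unk.condition] = float(val)
                    promoters[i] = replace(p, intensity_by_condition=intens)
                    break
            else:
                raise KeyError(f"unknown promoter {unk.element!r}")
        elif unk.kind == "terminator":
            for i, t in enumerate(terminators):
                if t.id == unk.element:
                    terminators[i] = replace(t, p_terminate=float(val))
                    break
            else:
                raise KeyError(f"unknown terminator {unk.element!r}")
        else:
            raise ValueError(f"unknown kind {unk.kind!r}")
    return replace(locus, promoters=tuple(promoters), terminators=tuple(terminators))


def _passes_balance(problem: InferenceProblem, candidate_locus: Locus) -> bool:
    conditions = set()
    for exp in problem.experiments:
        conditions.add(exp.condition_a)
        if exp.condition_b:
            conditions.add(exp.condition_b)
    for cond in conditions:
        lambdas = {p.id: p.intensity(cond) for p in candidate_locus.promoters}
        if not balance_filter(lambdas, candidate_locus, problem.balance_threshold):
            return False
    return True


def _evaluate(problem: InferenceProblem, candidate_locus: Locus) -> tuple[float, ...]:
    """Per-experiment discrepancies for one candidate, with common random
    numbers (the same master seed) across candidates."""
    out = []
    for exp in problem.experiments:
        units = list(exp.values)
        target = np.array([exp.values[u] for u in units], dtype=float)
        if exp.kind == "ratio":
            est = compare_conditions(
                candidate_locus, exp.condition_a, exp.condition_b,
                problem.duration, problem.n_trajectories, problem.seed,
                temperature=None if exp.schedule_a else problem.temperature,
                schedule_a=exp.schedule_a, schedule_b=exp.schedule_b,
                warmup=problem.warmup, n_boot=10,  # spread unused in scoring
                share_seeds=True,
            )
            model = est.table.loc[units, "ratio"].to_numpy()
        else:
            ens = run_ensemble(
                candidate_locus, exp.condition_a, problem.duration,
                problem.n_trajectories, problem.seed,
                temperature=None if exp.schedule_a else problem.temperature,
                schedule=exp.schedule_a, warmup=problem.warmup,
            )
            model = ens.table.loc[units, "mean_per_hour"].to_numpy()
        if np.any(~np.isfinite(model)) or np.any(model <= 0):
            out.append(np.inf)
        else:
            out.append(_max_symmetric_relative(model, target))
    return tuple(out)


def rank_candidates(
    discrepancies: np.ndarray, weights: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank candidates per experiment and combine into weighted total ranks.

    Returns ``(ranks, total_rank, weighted_sum)`` where ``ranks[i, j]`` is
    candidate i's rank under experiment j (1 = best, ties share the minimum
    rank), ``total_rank`` is the weighted sum of ranks and ``weighted_sum``
    the weighted sum of raw discrepancies (used to break total-rank ties).
    """
    discrepancies = np.asarray(discrepancies, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ranks = np.column_stack(
        [rankdata(discrepancies[:, j], method="min") for j in range(discrepancies.shape[1])]
    )
    total = ranks @ weights
    wsum = discrepancies @ weights
    return ranks, total, wsum


def grid_search(problem: InferenceProblem) -> list[CandidateScore]:
    """Exhaustively score the balance-pruned grid; best candidate first.

    Candidates are ordered by weighted total rank, ties broken by the
    weighted discrepancy sum, then lexicographically by parameter values.
    Every candidate is simulated with the same trajectory seeds (common
    random numbers), so the search is deterministic given the problem.
    """
    axes = [u.grid() for u in problem.unknowns]
    weights = [e.weight for e in problem.experiments]
    survivors: list[tuple[tuple[float, ...], Locus]] = []
    for values in itertools.product(*axes):
        if any(values[i] > values[j] + 1e-12 for i, j in problem.constraints):
            continue
        cand = _apply_params(problem.locus, problem.unknowns, values)
        if _passes_balance(problem, cand):
            survivors.append((values, cand))
    if not survivors:
        raise ValueError(
            "no grid point satisfies the strand-balance condition; "
            "increase the balance threshold D or widen the bounds"
        )
    disc = np.array([_evaluate(problem, cand) for _, cand in survivors])
    ranks, total, wsum = rank_candidates(disc, weights)
    scored = [
        CandidateScore(
            params=tuple(values),
            discrepancies=tuple(disc[i]),
            ranks=tuple(ranks[i]),
            total_rank=float(total[i]),
            weighted_sum=float(wsum[i]),
        )
        for i, (values, _) in enumerate(survivors)
    ]
    scored.sort(key=lambda c: (c.total_rank, c.weighted_sum, c.params))
    return scored


def hypothesis_scan(
    problem: InferenceProblem,
    hypotheses: Mapping[str, Sequence[Terminator]],
    extra_unknowns: Optional[Mapping[str, Sequence[Unknown]]] = None,
) -> pd.DataFrame:
    """Compare structural hypotheses: re-fit with alternative element sets.

    Each hypothesis names a set of candidate terminators added to the locus
    (an empty set is the null structure); optional per-hypothesis unknowns
    let their probabilities be fitted too. Returns a table of the best
    weighted discrepancy sum and best parameters per hypothesis.
    """
    rows = []
    for name, elements in hypotheses.items():
        locus_h = replace(
            problem.locus, terminators=tuple(problem.locus.terminators) + tuple(elements)
        )
        unknowns_h = list(problem.unknowns) + list((extra_unknowns or {}).get(name, ()))
        problem_h = replace(problem, locus=locus_h, unknowns=unknowns_h)
        best = grid_search(problem_h)[0]
        rows.append(
            {
                "hypothesis": name,
                "best_discrepancy": max(best.discrepancies),
                "weighted_sum": best.weighted_sum,
                "params": best.params,
            }
        )
    return pd.DataFrame(rows).set_index("hypothesis")
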