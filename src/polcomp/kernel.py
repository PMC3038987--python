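"""Random-variate sampling with a seedable, stream-splittable contract.

Every stochastic element of a simulation (each promoter's attempt clock, each
promoter's abortive-initiation draws, each terminator's Bernoulli trials, each
factor site) owns a named substream split from one master seed, so a single
element can be replayed in isolation and common-random-number comparisons are
possible across parameter settings.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NEVER",
    "RngStream",
    "stream_rng",
    "sample_interarrival",
    "sample_abort_process",
    "bernoulli",
    "AbortOutcome",
]

#: Sentinel returned for an intensity of zero: the event never happens.
NEVER = math.inf


def _label_entropy(label: str) -> int:
    """Stable 128-bit integer derived from a stream label."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:16], "little")


def stream_rng(seed, label: str) -> np.random.Generator:
    """Independent generator for ``(seed, label)``.

    Identical pairs give bit-identical draw sequences; distinct labels give
    statistically independent streams. ``seed`` may be an int or a tuple of
    ints (entropy words).
    """
    if isinstance(seed, (int, np.integer)):
        entropy = (int(seed),)
    else:
        entropy = tuple(int(s) for s in seed)
    ss = np.random.SeedSequence(entropy=list(entropy) + [_label_entropy(label)])
    return np.random.Generator(np.random.PCG64(ss))


@dataclass
class RngStream:
    """A named substream: ``RngStream(seed, label).rng`` is the generator."""

    seed: object
    label: str

    def __post_init__(self):
        self.rng = stream_rng(self.seed, self.label)


def _uniform_open(rng) -> float:
    """U in (0, 1): redraw the (measure-zero) exact 0 so -log never overflows."""
    xi = rng.random()
    while xi == 0.0:
        xi = rng.random()
    return xi


def sample_interarrival(lam: float, rng, size=None):
    """Exponential waiting time with rate ``lam`` (1/s), as ``-ln(xi)/lam``.

    ``lam == 0`` returns :data:`NEVER`. With ``size`` given, returns an ndarray
    (vectorized draws from the same generator).
    """
    if lam < 0:
        raise ValueError(f"intensity must be >= 0, got {lam}")
    if size is not None:
        if lam == 0.0:
            return np.full(size, NEVER)
        xi = rng.random(size)
        xi = np.where(xi == 0.0, np.nextafter(0.0, 1.0), xi)
        return -np.log(xi) / lam
    if lam == 0.0:
        return NEVER
    return -math.log(_uniform_open(rng)) / lam


@dataclass(frozen=True)
class AbortOutcome:
    """One abortive-initiation phase: total duration and the short RNAs made."""

    total_duration: float
    abortive_lengths: tuple[int, ...]

    @property
    def n_aborts(self) -> int:
        return len(self.abortive_lengths)


def sample_abort_process(abort_params: tuple[float, float], nu_p: float, rng) -> AbortOutcome:
    """Draw one abortive-initiation phase for a promoter-bound enzyme.

    The phase duration is ``t = -ln(xi) * t0``. The number of aborted attempts
    ``k`` is the largest integer for which the running sum
    ``-(ln xi_1 + ... + ln xi_k)`` stays within the budget ``t * nu_p / r0``
    (zero if the first summand already exceeds it); each attempt ``i`` releases
    an RNA of the integer length nearest to ``-r0 * ln(xi_i)``, never shorter
    than 1 nt. Given ``t`` the count is the occupancy of a unit-rate Poisson
    process on ``[0, t * nu_p / r0]``, so marginally ``k`` follows a geometric
    law with mean ``t0 * nu_p / r0``.
    """
    t0, r0 = abort_params
    if t0 <= 0 or r0 <= 0 or nu_p <= 0:
        raise ValueError(
            f"abort parameters and elongation rate must be positive, "
            f"got t0={t0}, r0={r0}, nu_p={nu_p}"
        )
    t = -math.log(_uniform_open(rng)) * t0
    budget = t * nu_p / r0
    lengths: list[int] = []
    acc = 0.0
    while True:
        neg_log = -math.log(_uniform_open(rng))
        acc += neg_log
        if acc > budget:
            break
        size = math.floor(r0 * neg_log + 0.5)  # half rounds away from zero
        lengths.append(max(1, size))
    return AbortOutcome(total_duration=t, abortive_lengths=tuple(lengths))


def bernoulli(p: float, rng) -> bool:
    """True with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p == 0.0:
        return False
    if p == 1.0:
        return True
    return rng.random() < p
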