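"""Event-driven simulation of polymerase traffic on one locus trajectory.

The simulator processes a single chronological queue of events: promoter
binding attempts (Poisson clocks), ends of abortive-initiation phases, factor
binding/release, temperature phase changes, and per-polymerase "milestone"
events. Elongation is deterministic at the temperature-dependent rate, so a
polymerase moves linearly between events and the time of its next interaction
(checkpoint crossing, contact with a same-strand leader, head-on collision)
is computed exactly rather than nucleotide by nucleotide; the observable
rules are those of a per-nucleotide walk in the continuum limit.

Rules enforced:

* a binding attempt succeeds only if no polymerase footprint and no bound
  factor overlaps the promoter's holoenzyme window;
* a bacterial-type polymerase first runs an abortive-initiation phase during
  which the holoenzyme footprint blocks the promoter, then elongates with the
  core footprint;
* same-strand polymerases never overlap or overtake: a faster trailing
  polymerase comes footprint-to-footprint (one nucleotide of headway) with
  its leader and is dragged at the leader's speed until the leader moves away
  or disappears;
* if the 3' ends of two antiparallel polymerases meet, both detach and are
  removed instantly (head-on collision);
* the first entry of a polymerase into the proximal shoulder of a terminator
  triggers a single Bernoulli trial with the terminator's probability;
* a moving polymerase displaces a bound factor on contact without delay;
* a gene's transcript count increments when a same-strand polymerase that
  initiated at or upstream of the gene's 5' end moves its 3' end past the
  gene's 3' end.

All randomness flows through named substreams of one master seed, so a
trajectory is reproducible bit for bit; all static geometry enters the event
arithmetic as exact integer differences, so a mirrored locus replays the
exactly mirrored trajectory.
"""

from __future__ import annotations

import bisect
import heapq
import math
from dataclasses import dataclass
from typing import Optional

from . import kernel
from .locus import Gene, Locus, Promoter

__all__ = [
    "TemperatureSchedule",
    "constant_schedule",
    "Fate",
    "TrajectoryResult",
    "run_trajectory",
    "Simulation",
    "counts_in_window",
]


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureSchedule:
    """Ordered phases of ``(duration_s, temperature_C)``."""

    phases: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        phases = tuple((float(d), float(T)) for d, T in self.phases)
        for dur, _ in phases:
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        object.__setattr__(self, "phases", phases)

    @property
    def total(self) -> float:
        return sum(d for d, _ in self.phases)

    def boundaries(self) -> list[tuple[float, float]]:
        """Internal ``(time, new_temperature)`` change points."""
        out = []
        t = 0.0
        for i, (dur, _) in enumerate(self.phases[:-1]):
            t += dur
            out.append((t, self.phases[i + 1][1]))
        return out

    def temperature_at(self, t: float) -> float:
        acc = 0.0
        for dur, temp in self.phases:
            acc += dur
            if t < acc:
                return temp
        return self.phases[-1][1]


def constant_schedule(temperature: float, duration: float) -> TemperatureSchedule:
    return TemperatureSchedule(phases=((duration, temperature),))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


class Fate:
    """Terminal outcomes of a successfully initiated polymerase."""

    COMPLETED_RUNOFF = "completed_runoff"
    COLLIDED = "collided"
    TERMINATED_AT_HAIRPIN = "terminated_at_hairpin"
    UNFINISHED = "unfinished"  # still on the DNA when the modeled time ended


@dataclass
class TrajectoryResult:
    """Per-gene completed-transcript tallies for one trajectory."""

    counts: dict[str, int]
    completions: list[tuple[float, str]]
    promoter_tallies: dict[str, dict[str, int]]
    fates: dict[str, int]
    duration: float
    seed: object
    condition: str

    def grouped_counts(self, locus: Locus) -> dict[str, int]:
        """Counts with grouped genes pooled under their group id."""
        out: dict[str, int] = {u: 0 for u in locus.count_units()}
        for g in locus.genes:
            unit = g.group if g.group is not None else g.id
            out[unit] += self.counts[g.id]
        return out


def counts_in_window(
    result: TrajectoryResult, locus: Locus, t_from: float, t_to: float
) -> dict[str, int]:
    """Per-unit completed transcripts inside ``[t_from, t_to]``."""
    unit_of = {g.id: (g.group if g.group is not None else g.id) for g in locus.genes}
    out = {u: 0 for u in locus.count_units()}
    for t, gid in result.completions:
        if t_from <= t <= t_to:
            out[unit_of[gid]] += 1
    return out


# ---------------------------------------------------------------------------
# Internal polymerase state
# ---------------------------------------------------------------------------

_INIT = 0
_ELONG = 1

# event kinds (heap payload discriminators)
_BIND = 0
_CLEAR = 1
_MILE = 2
_PHASE = 3
_FBIND = 4
_FREL = 5

# milestone tags
_TAG_CP = 0
_TAG_CONTACT = 1
_TAG_COLLIDE = 2

# checkpoint kinds
_CP_GENE = 0
_CP_FACTOR = 1
_CP_TERM = 2
_CP_RUNOFF = 3


class _Pol:
    __slots__ = (
        "pid", "cls", "sdir", "tss", "origin", "state", "s", "t_ref", "v",
        "own_rate", "trail", "lead", "version", "cp_idx", "cp_entries",
        "coupled", "alive", "init_time",
    )

    def __init__(self, pid, cls, sdir, tss, origin, init_time):
        self.pid = pid
        self.cls = cls
        self.sdir = sdir
        self.tss = tss
        self.origin = origin
        self.state = _INIT
        self.s = 0.0  # distance traveled from the tss, nt
        self.t_ref = init_time
        self.v = 0.0
        self.own_rate = 0.0
        self.trail = 0  # footprint extent behind the 3' end, nt
        self.lead = 0  # footprint extent ahead of the 3' end, nt
        self.version = 0
        self.cp_idx = 0
        self.cp_entries = ()
        self.coupled = False  # dragged at a slower leader's speed, zero headway
        self.alive = True
        self.init_time = init_time

    def progress(self, t: float) -> float:
        return self.s + self.v * (t - self.t_ref)

    def key(self, t: float) -> float:
        """Ordering key along the strand's direction of travel (= sdir * pos)."""
        return self.sdir * self.tss + self.progress(t)

    def update_to(self, t: float) -> None:
        self.s = self.progress(t)
        self.t_ref = t


def _dist3p(p: _Pol, q: _Pol, t: float) -> float:
    """Distance from p's 3' end to q's 3' end along p's direction of travel.

    Exact-integer static geometry plus travel distances, so a mirrored locus
    yields bit-identical values.
    """
    a = p.sdir * (q.tss - p.tss)
    b = (p.sdir * q.sdir) * q.progress(t)
    return (a + b) - p.progress(t)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


class Simulation:
    """One trajectory of the event-driven automaton.

    Most callers should use :func:`run_trajectory`; the class is public so
    single mechanisms (binding, exclusion, collision) can be exercised and
    inspected directly in tests and examples.
    """

    def __init__(
        self,
        locus: Locus,
        condition: str,
        duration: float,
        seed,
        schedule: Optional[TemperatureSchedule] = None,
        temperature: Optional[float] = None,
    ):
        if not locus.promoters:
            raise ValueError("locus has no promoters: nothing to simulate")
        if schedule is None:
            if temperature is None:
                raise ValueError("provide a schedule or a constant temperature")
            schedule = constant_schedule(temperature, duration)
        if schedule.total + 1e-9 < duration:
            raise ValueError(
                f"schedule covers {schedule.total} s but duration is {duration} s"
            )
        self.locus = locus
        self.condition = condition
        self.duration = float(duration)
        self.seed = seed
        self.schedule = schedule
        self.now = 0.0
        self.temp = schedule.phases[0][1]

        self._heap: list = []
        self._seq = 0
        self._streams: dict[str, object] = {}
        self._next_pid = 0
        self.chains: dict[int, list[_Pol]] = {1: [], -1: []}
        self.counts: dict[str, int] = {g.id: 0 for g in locus.genes}
        self.completions: list[tuple[float, str]] = []
        self.fates: dict[str, int] = {
            Fate.COMPLETED_RUNOFF: 0,
            Fate.COLLIDED: 0,
            Fate.TERMINATED_AT_HAIRPIN: 0,
            Fate.UNFINISHED: 0,
        }
        self.promoter_tallies = {
            p.id: {"attempts": 0, "successes": 0, "aborts": 0} for p in locus.promoters
        }
        self.factor_bound: dict[str, bool] = {f.id: False for f in locus.factor_sites}
        self._factor_version: dict[str, int] = {f.id: 0 for f in locus.factor_sites}

        exts = [0]
        for p in locus.promoters:
            for fp in (p.pclass.holo_footprint, p.pclass.core_footprint):
                exts += [abs(fp[0]), abs(fp[1])]
        self._maxext = max(exts) + 2

        self._lam = {p.id: p.intensity(condition) for p in locus.promoters}
        self._windows = {p.id: p.occupancy_window() for p in locus.promoters}
        self._cps = self._build_checkpoints()

        for p in locus.promoters:
            lam = self._lam[p.id]
            if lam > 0.0:
                dt = kernel.sample_interarrival(lam, self._rng("promoter:" + p.id))
                self._push(dt, _BIND, p)
        for f in locus.factor_sites:
            if f.lambda_f > 0.0:
                dt = kernel.sample_interarrival(f.lambda_f, self._rng("factor:" + f.id))
                self._push(dt, _FBIND, f)
        for t_change, new_temp in schedule.boundaries():
            if t_change < duration:
                self._push(t_change, _PHASE, new_temp)

    # -- infrastructure ----------------------------------------------------

    def _rng(self, label: str):
        rng = self._streams.get(label)
        if rng is None:
            rng = kernel.stream_rng(self.seed, label)
            self._streams[label] = rng
        return rng

    def _push(self, t: float, kind: int, *data) -> None:
        if t == math.inf:
            return
        self._seq += 1
        heapq.heappush(self._heap, (t, self._seq, kind, data))

    def _build_checkpoints(self):
        """Static checkpoint lists per (strand direction, polymerase class).

        Keys are 3'-end positions in direction coordinates (``sdir * pos``)
        at which the checkpoint triggers, sorted in travel order.
        """
        locus = self.locus
        classes = {p.pclass.name: p.pclass for p in locus.promoters}
        out: dict[tuple[int, str], tuple[list, list]] = {}
        for sdir in (1, -1):
            for cname, cls in classes.items():
                entries = []
                for g in locus.genes:
                    if g.strand.direction != sdir:
                        continue
                    pos = g.end - 1 if sdir == 1 else g.start
                    entries.append((sdir * pos, 0, _CP_GENE, g))
                for f in locus.factor_sites:
                    # trigger when the leading footprint edge touches the site
                    if sdir == 1:
                        pos = f.interval[0] - cls.core_footprint[1]
                    else:
                        pos = (f.interval[1] - 1) - cls.core_footprint[0]
                    entries.append((sdir * pos, 1, _CP_FACTOR, f))
                for term in locus.terminators:
                    arms = term.shoulder_intervals
                    pos = arms[0][0] if sdir == 1 else arms[1][1] - 1
                    entries.append((sdir * pos, 2, _CP_TERM, term))
                end_pos = locus.length - 1 if sdir == 1 else 0
                entries.append((sdir * end_pos, 3, _CP_RUNOFF, None))
                entries.sort(key=lambda e: (e[0], e[1]))
                keys = [e[0] for e in entries]
                out[(sdir, cname)] = (entries, keys)
        return out

    # -- chain bookkeeping -------------------------------------------------

    def _chain_index(self, p: _Pol) -> int:
        chain = self.chains[p.sdir]
        t = self.now
        k = p.key(t)
        lo, hi = 0, len(chain)
        while lo < hi:
            mid = (lo + hi) // 2
            if chain[mid].key(t) < k:
                lo = mid + 1
            else:
                hi = mid
        i = lo
        while i < len(chain) and chain[i] is not p:
            i += 1
        if i < len(chain):
            return i
        i = lo - 1
        while i >= 0 and chain[i] is not p:
            i -= 1
        if i >= 0:
            return i
        raise RuntimeError("polymerase not found in its chain")

    def _leader(self, p: _Pol) -> Optional[_Pol]:
        chain = self.chains[p.sdir]
        i = self._chain_index(p)
        return chain[i + 1] if i + 1 < len(chain) else None

    def _follower(self, p: _Pol) -> Optional[_Pol]:
        chain = self.chains[p.sdir]
        i = self._chain_index(p)
        return chain[i - 1] if i > 0 else None

    def _nearest_opposite(self, sdir: int, key: float) -> Optional[_Pol]:
        """Nearest antiparallel polymerase strictly ahead of direction-key
        ``key`` on strand ``sdir`` — the head-on collision target."""
        opp = self.chains[-sdir]
        if not opp:
            return None
        t = self.now
        target = -key + 1e-7  # include a partner at exactly zero distance
        lo, hi = 0, len(opp)
        while lo < hi:
            mid = (lo + hi) // 2
            if opp[mid].key(t) < target:
                lo = mid + 1
            else:
                hi = mid
        return opp[lo - 1] if lo > 0 else None

    def _facing_partner(self, p: _Pol) -> Optional[_Pol]:
        return self._nearest_opposite(p.sdir, p.key(self.now))

    # -- occupancy ---------------------------------------------------------

    def _window_occupied(self, lo: int, hi: int) -> bool:
        """Any polymerase footprint or bound factor overlapping ``[lo, hi]``?"""
        t = self.now
        for sdir in (1, -1):
            chain = self.chains[sdir]
            if not chain:
                continue
            wmin, wmax = (lo, hi) if sdir == 1 else (-hi, -lo)
            a = wmin - self._maxext
            lo_i, hi_i = 0, len(chain)
            while lo_i < hi_i:
                mid = (lo_i + hi_i) // 2
                if chain[mid].key(t) < a:
                    lo_i = mid + 1
                else:
                    hi_i = mid
            span = (wmax - wmin) + 2 * self._maxext
            for i in range(lo_i, len(chain)):
                p = chain[i]
                # relative coordinates keep the test mirror-exact
                c1 = (p.sdir * p.tss - wmin) + p.progress(t)
                if c1 > span - self._maxext:
                    break
                c2 = (p.sdir * p.tss - wmax) + p.progress(t)
                if c1 + p.lead >= 0.0 and c2 - p.trail <= 0.0:
                    return True
        for f in self.locus.factor_sites:
            if self.factor_bound[f.id] and f.interval[0] <= hi and f.interval[1] - 1 >= lo:
                return True
        return False

    # -- scheduling / propagation -------------------------------------------

    def _reschedule(self, p: _Pol) -> None:
        """Invalidate p's pending milestone and schedule a fresh one."""
        if not p.alive or p.state != _ELONG:
            return
        p.version += 1
        self._schedule_milestone(p)

    def _schedule_milestone(self, p: _Pol) -> None:
        t = self.now
        best_t = math.inf
        best = None
        entries, _keys = p.cp_entries
        if p.v > 0.0 and p.cp_idx < len(entries):
            key = entries[p.cp_idx][0]
            # anchored at (s, t_ref) so the time is identical no matter which
            # passive checkpoints fired in between
            tc = p.t_ref + ((key - p.sdir * p.tss) - p.s) / p.v
            if tc < best_t:
                best_t, best = tc, (_TAG_CP, None, 0)
        leader = self._leader(p)
        leader_d = math.inf
        if leader is not None:
            leader_d = _dist3p(p, leader, t)
            if p.v > leader.v:
                sep = p.lead + leader.trail  # footprints in contact, never overlapping
                tc = t + (leader_d - sep) / (p.v - leader.v)
                if tc < best_t:
                    best_t, best = tc, (_TAG_CONTACT, leader, leader.version)
        q = self._facing_partner(p)
        if q is not None:
            d = _dist3p(p, q, t)
            if d < leader_d and p.v + q.v > 0.0:
                tc = t + d / (p.v + q.v)
                if tc < best_t:
                    best_t, best = tc, (_TAG_COLLIDE, q, q.version)
        if best is not None:
            tag, partner, pver = best
            self._push(max(best_t, t), _MILE, p, p.version, tag, partner, pver)

    def _speed_changed(self, p: _Pol) -> None:
        """After p's speed changed: refresh p and its collision target, and
        drag any contact-coupled follower (recursively down the chain)."""
        self._reschedule(p)
        if p.alive:
            q = self._facing_partner(p)
            if q is not None:
                self._reschedule(q)
            f = self._follower(p)
        else:
            f = None
        if f is None:
            return
        if f.coupled:
            f.update_to(self.now)
            if p.alive and p.v < f.own_rate:
                f.v = p.v
                f.coupled = True
            else:
                f.v = f.own_rate
                f.coupled = False
            self._speed_changed(f)
        else:
            # an approaching follower's contact time depends on p's speed
            self._reschedule(f)

    def _insert(self, p: _Pol) -> None:
        chain = self.chains[p.sdir]
        t = self.now
        k = p.key(t)
        lo, hi = 0, len(chain)
        while lo < hi:
            mid = (lo + hi) // 2
            if chain[mid].key(t) < k:
                lo = mid + 1
            else:
                hi = mid
        chain.insert(lo, p)
        if lo > 0:
            self._reschedule(chain[lo - 1])
        q = self._facing_partner(p)
        if q is not None:
            self._reschedule(q)

    def _remove(self, p: _Pol, fate: str) -> None:
        p.alive = False
        p.version += 1
        self.fates[fate] += 1
        key = p.key(self.now)
        chain = self.chains[p.sdir]
        i = self._chain_index(p)
        follower = chain[i - 1] if i > 0 else None
        chain.pop(i)
        if follower is not None:
            if follower.coupled:
                follower.update_to(self.now)
                follower.v = follower.own_rate
                follower.coupled = False
                self._speed_changed(follower)
            else:
                self._reschedule(follower)
        q = self._nearest_opposite(p.sdir, key)
        if q is not None:
            self._reschedule(q)

    # -- operations ---------------------------------------------------------

    def attempt_binding(self, promoter: Promoter) -> bool:
        """Process one binding attempt at the current time; True on success."""
        tally = self.promoter_tallies[promoter.id]
        tally["attempts"] += 1
        lo, hi = self._windows[promoter.id]
        if self._window_occupied(lo, hi):
            return False
        tally["successes"] += 1
        self._next_pid += 1
        cls = promoter.pclass
        p = _Pol(
            self._next_pid,
            cls,
            promoter.strand.direction,
            promoter.tss,
            promoter.id,
            self.now,
        )
        p.cp_entries = self._cps[(p.sdir, cls.name)]
        p.cp_idx = bisect.bisect_right(p.cp_entries[1], p.sdir * p.tss)
        if cls.abort_params is not None:
            u, d = cls.holo_footprint
            p.trail, p.lead = -u, d
            outcome = kernel.sample_abort_process(
                cls.abort_params, cls.rate_at(self.temp), self._rng("abort:" + promoter.id)
            )
            tally["aborts"] += outcome.n_aborts
            self._insert(p)
            self._push(self.now + outcome.total_duration, _CLEAR, p, p.version)
        else:
            u, d = cls.core_footprint
            p.trail, p.lead = -u, d
            p.state = _ELONG
            self._insert(p)
            self._start_elongation(p)
            self._speed_changed(p)
        return True

    def _start_elongation(self, p: _Pol) -> None:
        """Switch an inserted polymerase to elongation at the current rate,
        capped by a leader already at contact distance."""
        p.state = _ELONG
        u, d = p.cls.core_footprint
        p.trail, p.lead = -u, d
        p.own_rate = p.cls.rate_at(self.temp)
        p.v = p.own_rate
        p.coupled = False
        leader = self._leader(p)
        if leader is not None and leader.v < p.own_rate:
            sep = p.lead + leader.trail  # footprints in contact, never overlapping
            if _dist3p(p, leader, self.now) <= sep + 1e-9:
                p.v = leader.v
                p.coupled = True

    # -- event handlers ------------------------------------------------------

    def _handle_bind(self, promoter: Promoter) -> None:
        self.attempt_binding(promoter)
        dt = kernel.sample_interarrival(
            self._lam[promoter.id], self._rng("promoter:" + promoter.id)
        )
        self._push(self.now + dt, _BIND, promoter)

    def _handle_clear(self, p: _Pol, version: int) -> None:
        if not p.alive or p.version != version:
            return
        p.update_to(self.now)
        p.version += 1
        self._start_elongation(p)
        self._speed_changed(p)

    def _handle_mile(self, p: _Pol, version: int, tag: int, partner, pver) -> None:
        if not p.alive or p.version != version:
            return
        if tag == _TAG_CONTACT:
            # validate against the *current* leader geometrically: stored
            # partner versions would livelock two mutually rescheduling
            # polymerases
            leader = self._leader(p)
            if (
                leader is not None
                and p.v > leader.v
                and _dist3p(p, leader, self.now) - (p.lead + leader.trail) <= 1e-7
            ):
                p.update_to(self.now)
                p.v = leader.v
                p.coupled = True
                self._speed_changed(p)
            else:
                self._reschedule(p)
            return
        if tag == _TAG_COLLIDE:
            q = self._facing_partner(p)
            if q is not None and _dist3p(p, q, self.now) <= 1e-7:
                p.update_to(self.now)
                q.update_to(self.now)
                self._remove(p, Fate.COLLIDED)
                self._remove(q, Fate.COLLIDED)
            else:
                self._reschedule(p)
            return
        # note: (s, t_ref) are deliberately NOT re-anchored at checkpoints, so
        # adding a passive checkpoint (e.g. a never-firing terminator) leaves
        # all subsequent event times bit-identical
        entries, _keys = p.cp_entries
        key, _prio, kind, obj = entries[p.cp_idx]
        if kind == _CP_RUNOFF:
            self._remove(p, Fate.COMPLETED_RUNOFF)
            return
        if kind == _CP_GENE:
            g: Gene = obj
            if p.sdir * (g.five_prime - p.tss) >= 0:
                self.counts[g.id] += 1
                self.completions.append((self.now, g.id))
            p.cp_idx += 1
            self._reschedule(p)
            return
        if kind == _CP_TERM:
            stop = kernel.bernoulli(obj.p_terminate, self._rng("terminator:" + obj.id))
            if stop:
                self._remove(p, Fate.TERMINATED_AT_HAIRPIN)
            else:
                p.cp_idx += 1
                self._reschedule(p)
            return
        if kind == _CP_FACTOR:
            if self.factor_bound[obj.id]:
                self.factor_bound[obj.id] = False
                self._factor_version[obj.id] += 1
            p.cp_idx += 1
            self._reschedule(p)
            return
        raise AssertionError(f"unknown checkpoint kind {kind}")

    def _handle_phase(self, new_temp: float) -> None:
        self.temp = new_temp
        for sdir in (1, -1):
            chain = self.chains[sdir]
            for p in chain:
                if p.state == _ELONG:
                    p.update_to(self.now)
                    p.own_rate = p.cls.rate_at(new_temp)
            for i in range(len(chain) - 1, -1, -1):  # front first
                p = chain[i]
                if p.state != _ELONG:
                    continue
                leader = chain[i + 1] if i + 1 < len(chain) else None
                if p.coupled and leader is not None and leader.v < p.own_rate:
                    p.v = leader.v
                else:
                    p.v = p.own_rate
                    p.coupled = False
        for chain in self.chains.values():
            for p in list(chain):
                self._reschedule(p)

    def _handle_fbind(self, site) -> None:
        if not self.factor_bound[site.id]:
            lo, hi = site.interval[0], site.interval[1] - 1
            if not self._window_occupied(lo, hi):
                self.factor_bound[site.id] = True
                self._factor_version[site.id] += 1
                if site.residence is not None:
                    dt = kernel.sample_interarrival(
                        1.0 / site.residence, self._rng("factor-release:" + site.id)
                    )
                    self._push(self.now + dt, _FREL, site, self._factor_version[site.id])
        dt = kernel.sample_interarrival(site.lambda_f, self._rng("factor:" + site.id))
        self._push(self.now + dt, _FBIND, site)

    def _handle_frel(self, site, version: int) -> None:
        if self._factor_version[site.id] == version and self.factor_bound[site.id]:
            self.factor_bound[site.id] = False
            self._factor_version[site.id] += 1

    # -- main loop -----------------------------------------------------------

    def step(self) -> bool:
        """Process the next queued event; False once modeled time is spent."""
        heap = self._heap
        while heap:
            t, _seq, kind, data = heapq.heappop(heap)
            if t > self.duration:
                return False
            self.now = t
            if kind == _MILE:
                self._handle_mile(*data)
            elif kind == _BIND:
                self._handle_bind(*data)
            elif kind == _CLEAR:
                self._handle_clear(*data)
            elif kind == _PHASE:
                self._handle_phase(*data)
            elif kind == _FBIND:
                self._handle_fbind(*data)
            elif kind == _FREL:
                self._handle_frel(*data)
            return True
        return False

    def run(self) -> TrajectoryResult:
        while self.step():
            pass
        self.now = self.duration
        for chain in self.chains.values():
            for p in list(chain):
                if p.alive:
                    p.alive = False
                    self.fates[Fate.UNFINISHED] += 1
            chain.clear()
        return TrajectoryResult(
            counts=self.counts,
            completions=self.completions,
            promoter_tallies=self.promoter_tallies,
            fates=self.fates,
            duration=self.duration,
            seed=self.seed,
            condition=self.condition,
        )


def run_trajectory(
    locus: Locus,
    condition: str,
    duration: float,
    seed,
    schedule: Optional[TemperatureSchedule] = None,
    temperature: Optional[float] = None,
) -> TrajectoryResult:
    """Simulate one trajectory; reproducible bit for bit from its arguments."""
    sim = Simulation(
        locus, condition, duration, seed, schedule=schedule, temperature=temperature
    )
    return sim.run()
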