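"""Event-driven engine: deterministic motion, exclusion, collision, schedules."""

import math

import numpy as np
import pytest
from scipy import stats

from polcomp import (
    PolymeraseClass,
    Simulation,
    TemperatureSchedule,
    load_locus,
    mirror_locus,
    run_trajectory,
    toy_locus,
)
from polcomp.engine import counts_in_window
from polcomp.fixtures import make_toy_locus


def _silent(doc):
    """Set every promoter intensity to zero (manual-binding experiments)."""
    for p in doc["promoters"]:
        p["intensity"] = {c: 0.0 for c in p["intensity"]}
    return doc


def _assert_exclusion(sim):
    """No two same-strand footprints overlap; order is strict."""
    for sdir, chain in sim.chains.items():
        for back, front in zip(chain, chain[1:]):
            gap = (front.key(sim.now)) - (back.key(sim.now))
            sep = back.lead + front.trail  # footprint contact allowed
            assert gap >= sep - 1e-6, (sdir, gap, sep)


def test_lone_polymerase_traverses_at_the_elongation_rate():
    doc = _silent(make_toy_locus("single_gene", pclass="NEP"))
    locus = load_locus(doc)
    gene = locus.genes[0]
    prom = locus.promoters[0]
    sim = Simulation(locus, "wt", 600.0, 1, temperature=23.0)
    assert sim.attempt_binding(prom)
    res = sim.run()
    assert res.counts[gene.id] == 1
    assert res.fates["completed_runoff"] == 1
    t_done, gid = res.completions[0]
    assert gid == gene.id
    assert t_done == pytest.approx(((gene.end - 1) - prom.tss) / 45.0)


def test_symmetric_convergent_polymerases_collide_at_the_midpoint():
    doc = {
        "format": 1,
        "length": 1200,
        "genes": [
            {"id": "gA", "strand": "+", "start": 150, "end": 900},
            {"id": "gB", "strand": "-", "start": 200, "end": 950},
        ],
        "promoters": [
            {"id": "pA", "strand": "+", "tss": 100, "class": "NEP", "intensity": {"wt": 0.0}},
            {"id": "pB", "strand": "-", "tss": 999, "class": "NEP", "intensity": {"wt": 0.0}},
        ],
    }
    locus = load_locus(doc)
    sim = Simulation(locus, "wt", 600.0, 1, temperature=23.0)
    assert sim.attempt_binding(locus.promoter("pA"))
    assert sim.attempt_binding(locus.promoter("pB"))
    while sim.step():
        if sim.fates["collided"] == 2:
            break
    assert sim.fates["collided"] == 2
    # 3' ends meet halfway between tss 100 and 999 at equal rates
    assert sim.now == pytest.approx((999 - 100) / 2 / 45.0)
    res = sim.run()
    assert all(c == 0 for c in res.counts.values())


def test_zero_probability_terminator_is_a_bit_exact_no_op():
    doc = make_toy_locus("tandem_with_terminator", p_terminate=0.0)
    with_term = load_locus(doc)
    doc_no = dict(doc)
    doc_no["terminators"] = []
    without = load_locus(doc_no)
    r1 = run_trajectory(with_term, "wt", 3000.0, 42, temperature=23.0)
    r2 = run_trajectory(without, "wt", 3000.0, 42, temperature=23.0)
    assert r1.completions == r2.completions
    assert r1.counts == r2.counts
    assert r1.promoter_tallies == r2.promoter_tallies


def test_overlapping_promoter_windows_are_mutually_exclusive():
    doc = {
        "format": 1,
        "length": 2000,
        "genes": [{"id": "g", "strand": "+", "start": 300, "end": 1300}],
        "promoters": [
            {"id": "p1", "strand": "+", "tss": 200, "class": "PEP", "intensity": {"wt": 0.0}},
            {"id": "p2", "strand": "+", "tss": 230, "class": "PEP", "intensity": {"wt": 0.0}},
        ],
    }
    locus = load_locus(doc)
    sim = Simulation(locus, "wt", 100.0, 1, temperature=23.0)
    assert sim.attempt_binding(locus.promoter("p1"))
    # p2's holoenzyme window overlaps the polymerase sitting on p1
    assert not sim.attempt_binding(locus.promoter("p2"))
    tallies = sim.promoter_tallies
    assert tallies["p2"] == {"attempts": 1, "successes": 0, "aborts": 0}


def test_bound_factor_blocks_promoter_until_displaced():
    doc = {
        "format": 1,
        "length": 3000,
        "genes": [{"id": "g", "strand": "+", "start": 300, "end": 1300}],
        "promoters": [
            {"id": "p1", "strand": "+", "tss": 200, "class": "NEP", "intensity": {"wt": 0.0}},
            {"id": "p2", "strand": "+", "tss": 1500, "class": "NEP", "intensity": {"wt": 0.0}},
        ],
        "factor_sites": [{"id": "f", "interval": [1490, 1510], "lambda_f": 0.0}],
    }
    locus = load_locus(doc)
    sim = Simulation(locus, "wt", 300.0, 1, temperature=23.0)
    sim.factor_bound["f"] = True
    assert not sim.attempt_binding(locus.promoter("p2"))
    # an elongating polymerase pushes the factor off without being delayed
    assert sim.attempt_binding(locus.promoter("p1"))
    res = sim.run()
    assert not sim.factor_bound["f"]
    t_done, _ = res.completions[0]
    assert t_done == pytest.approx((1299 - 200) / 45.0)  # timing unchanged


def test_lone_promoter_throughput_matches_renewal_prediction():
    """Initiation rate at a saturated promoter is 1/(1/lambda + t_occupied):
    exponential wait plus the mean abort duration plus the time for the core
    footprint to clear the holoenzyme window."""
    lam = 0.1
    locus = toy_locus("single_gene", lam=lam)
    duration = 2000.0
    nu = 12.1
    clear_nt = 20 + 15  # window downstream edge + core trailing extent
    t_occupied = 0.4 + clear_nt / nu
    predicted = duration / (1.0 / lam + t_occupied)
    succ = []
    for i in range(200):
        r = run_trajectory(locus, "wt", duration, (900, i), temperature=23.0)
        succ.append(r.promoter_tallies["pA"]["successes"])
    succ = np.asarray(succ, dtype=float)
    se = succ.std(ddof=1) / math.sqrt(len(succ))
    assert abs(succ.mean() - predicted) < 3 * se


def test_initiations_are_poisson_when_clearance_vanishes():
    """With a point footprint and a very fast polymerase the promoter is
    effectively always free, so initiations form a Poisson process."""
    doc = {
        "format": 1,
        "length": 2000,
        "polymerases": {
            "GHOST": {
                "holo_footprint": [0, 0],
                "core_footprint": [0, 0],
                "rate_table": {23.0: 1500.0},
                "abort_params": None,
            }
        },
        "genes": [{"id": "g", "strand": "+", "start": 150, "end": 250}],
        "promoters": [
            {"id": "p", "strand": "+", "tss": 100, "class": "GHOST", "intensity": {"wt": 1.0}}
        ],
    }
    locus = load_locus(doc)
    width = 100.0
    counts = []
    for i in range(20):
        r = run_trajectory(locus, "wt", 5000.0, (77, i), temperature=23.0)
        times = np.array([t for t, _ in r.completions])
        edges = np.arange(100.0, 4900.0 + width, width)
        counts.append(np.histogram(times, bins=edges)[0])
    counts = np.concatenate(counts).astype(float)
    # index-of-dispersion chi-square: variance equals the mean for Poisson
    mean = counts.mean()
    assert mean == pytest.approx(width * 1.0, rel=0.02)
    d = ((counts - mean) ** 2).sum() / mean
    p = stats.chi2.sf(d, df=counts.size - 1)
    assert 1e-3 < p


def test_fast_polymerase_cannot_overtake_a_slow_leader():
    """A phage-type enzyme (45 nt/s) behind a bacterial-type one (12.1 nt/s)
    is dragged at the leader's speed; footprints never overlap."""
    doc = {
        "format": 1,
        "length": 4000,
        "genes": [{"id": "g", "strand": "+", "start": 300, "end": 3500}],
        "promoters": [
            {"id": "nep", "strand": "+", "tss": 100, "class": "NEP", "intensity": {"wt": 0.3}},
            {"id": "pep", "strand": "+", "tss": 200, "class": "PEP", "intensity": {"wt": 0.3}},
        ],
    }
    locus = load_locus(doc)
    sim = Simulation(locus, "wt", 600.0, 5, temperature=23.0)
    k = 0
    while sim.step():
        k += 1
        if k % 25 == 0:
            _assert_exclusion(sim)
    res = sim.run()
    assert sum(v["successes"] for v in res.promoter_tallies.values()) == sum(
        res.fates.values()
    )


def test_event_times_are_chronological(locus1):
    sim = Simulation(locus1, "wt", 600.0, 9, temperature=23.0)
    last = 0.0
    while sim.step():
        assert sim.now >= last
        last = sim.now


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mirrored_locus_replays_the_mirrored_trajectory_exactly(seed):
    locus = toy_locus("convergent_pair", seed=seed, lam=0.12)
    mirrored = mirror_locus(locus)
    r = run_trajectory(locus, "wt", 1500.0, seed, temperature=23.0)
    rm = run_trajectory(mirrored, "wt", 1500.0, seed, temperature=23.0)
    assert r.completions == rm.completions  # same times, same genes, bit-exact
    assert r.counts == rm.counts
    assert r.fates == rm.fates
    assert r.promoter_tallies == rm.promoter_tallies


@pytest.mark.parametrize("kind,seed", [
    ("convergent_pair", 3), ("divergent_pair", 4), ("tandem_with_terminator", 5),
])
def test_every_initiation_ends_in_exactly_one_fate(kind, seed):
    locus = toy_locus(kind, seed=seed, lam=0.15)
    r = run_trajectory(locus, "wt", 1800.0, seed, temperature=23.0)
    successes = sum(v["successes"] for v in r.promoter_tallies.values())
    assert successes == sum(r.fates.values())
    assert all(c >= 0 for c in r.counts.values())


def test_phase_change_rescales_remaining_traversal_time():
    """A polymerase mid-gene when the temperature jumps finishes the rest of
    the gene at the new rate."""
    doc = _silent(make_toy_locus("single_gene"))  # bacterial-type enzyme
    locus = load_locus(doc)
    gene = locus.genes[0]
    prom = locus.promoters[0]
    dist = (gene.end - 1) - prom.tss

    sim = Simulation(locus, "wt", 600.0, 8, temperature=21.0)
    assert sim.attempt_binding(prom)
    t_cold = sim.run().completions[0][0]
    t_abort_end = t_cold - dist / 9.2
    boundary = 60.0
    assert t_abort_end < boundary < t_cold

    sched = TemperatureSchedule(((boundary, 21.0), (600.0 - boundary, 40.0)))
    sim2 = Simulation(locus, "wt", 600.0, 8, schedule=sched)
    assert sim2.attempt_binding(prom)
    t_shock = sim2.run().completions[0][0]
    covered_cold = (boundary - t_abort_end) * 9.2
    predicted = boundary + (dist - covered_cold) / 36.8
    assert t_shock == pytest.approx(predicted, rel=1e-9)


def test_missing_temperature_in_rate_table_is_an_error():
    locus = toy_locus("single_gene")
    with pytest.raises(ValueError, match="extrapolation"):
        run_trajectory(locus, "wt", 100.0, 1, temperature=80.0)


def test_empty_promoter_set_is_an_error():
    doc = make_toy_locus("single_gene")
    doc["promoters"] = []
    with pytest.raises(ValueError, match="no promoters"):
        run_trajectory(load_locus(doc), "wt", 100.0, 1, temperature=23.0)


def test_locus2_traffic_is_stationary_after_warmup(locus2):
    """Per-hour transcript rates in hours 3-6 match hours 6-12 within
    Monte-Carlo error once the polymerase traffic pattern has filled in."""
    diffs = []
    for i in range(6):
        r = run_trajectory(locus2, "wt", 12 * 3600.0, (55, i), temperature=21.0)
        early = counts_in_window(r, locus2, 3 * 3600.0, 6 * 3600.0)
        late = counts_in_window(r, locus2, 6 * 3600.0, 12 * 3600.0)
        diffs.append(early["rpl23-rpl2"] / 3.0 - late["rpl23-rpl2"] / 6.0)
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / math.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se + 1e-9
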