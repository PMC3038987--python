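"""Inverse mode: discrepancies, balance pruning, grid search, hypotheses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polcomp import (
    ExperimentTarget,
    InferenceProblem,
    Terminator,
    Unknown,
    balance_filter,
    discrepancy_level,
    discrepancy_ratio,
    grid_search,
    hypothesis_scan,
    run_ensemble,
    toy_locus,
)
from polcomp.inference import rank_candidates

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def test_discrepancy_examples_match_hand_arithmetic():
    assert discrepancy_ratio([3.0], [2.0]) == pytest.approx(0.4)
    assert discrepancy_ratio([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert discrepancy_level([10.0, 10.0], [10.0, 30.0]) == pytest.approx(1.0)


def test_discrepancy_is_the_same_for_a_ratio_pair_and_its_reciprocals():
    """The averaged denominator scores a 3-vs-2 mismatch exactly like
    1/3-vs-1/2: both give 0.4."""
    assert discrepancy_ratio([1 / 3], [1 / 2]) == pytest.approx(0.4)
    assert discrepancy_ratio([3.0], [2.0]) == pytest.approx(
        discrepancy_ratio([1 / 3], [1 / 2])
    )


def test_discrepancy_rejects_non_positive_entries():
    with pytest.raises(ValueError):
        discrepancy_ratio([1.0, 0.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        discrepancy_level([1.0], [-2.0])


@given(st.lists(st.tuples(positive, positive), min_size=1, max_size=6))
@settings(max_examples=200, deadline=None)
def test_discrepancy_is_symmetric_and_matches_elementwise_maximum(pairs):
    z = np.array([a for a, _ in pairs])
    z0 = np.array([b for _, b in pairs])
    brute = max(abs(a - b) / ((a + b) / 2) for a, b in pairs)
    assert discrepancy_ratio(z, z0) == pytest.approx(brute)
    assert discrepancy_ratio(z, z0) == pytest.approx(discrepancy_ratio(z0, z))


@given(
    st.lists(st.tuples(positive, positive), min_size=1, max_size=4),
    st.floats(min_value=0.01, max_value=100.0),
    st.integers(min_value=0, max_value=3),
)
@settings(max_examples=100, deadline=None)
def test_discrepancy_invariant_under_joint_rescaling_of_a_coordinate(pairs, factor, idx):
    z = np.array([a for a, _ in pairs])
    z0 = np.array([b for _, b in pairs])
    z2, z02 = z.copy(), z0.copy()
    i = idx % len(pairs)
    z2[i] *= factor
    z02[i] *= factor
    assert discrepancy_ratio(z2, z02) == pytest.approx(discrepancy_ratio(z, z0))


# ---------------------------------------------------------------------------
# Balance filter
# ---------------------------------------------------------------------------


def test_single_strand_locus_always_passes(single_gene):
    assert balance_filter({"pA": 5.0}, single_gene, 0.01)


def test_unbalanced_convergent_pair_fails(convergent_pair):
    assert not balance_filter({"pA": 0.5, "pB": 0.1}, convergent_pair, 0.3)
    assert balance_filter({"pA": 0.5, "pB": 0.1}, convergent_pair, 0.45)


def test_reference_locus1_wild_type_vector_is_balanced(locus1):
    # plus strand feeds 0.003 + 0.054 + 0.037 = 0.094 against 0.093
    lambdas = {"N1": 0.003, "N2": 0.054, "P1": 0.037, "P2": 0.093}
    assert balance_filter(lambdas, locus1, 0.8)
    assert not balance_filter(lambdas, locus1, 0.0005)


@given(st.lists(st.floats(min_value=0, max_value=1.0), min_size=4, max_size=4),
       st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
@settings(max_examples=100, deadline=None)
def test_balance_filter_is_monotone_in_threshold(lams, d1, d2):
    locus = toy_locus("locus1_fixture")
    lambdas = dict(zip(["N1", "N2", "P1", "P2"], lams))
    lo, hi = sorted([d1, d2])
    if balance_filter(lambdas, locus, lo):
        assert balance_filter(lambdas, locus, hi)


# ---------------------------------------------------------------------------
# Ranking and grid search
# ---------------------------------------------------------------------------


def test_single_experiment_rank_order_equals_discrepancy_order():
    disc = np.array([[0.5], [0.1], [0.3]])
    ranks, total, _ = rank_candidates(disc, [1.0])
    assert list(ranks[:, 0]) == [3, 1, 2]
    assert list(total) == [3, 1, 2]


def test_total_rank_ties_break_on_weighted_discrepancy_sum():
    # A ranks (1, 3), B ranks (2, 2), C ranks (3, 1): all total 4; D is worse.
    # The tie among A, B, C breaks on the weighted discrepancy sum.
    disc = np.array([[0.1, 0.9], [0.2, 0.3], [0.3, 0.25], [0.4, 0.95]])
    ranks, total, wsum = rank_candidates(disc, [1.0, 1.0])
    assert list(ranks[0]) == [1, 3] and list(ranks[1]) == [2, 2]
    assert list(total) == [4.0, 4.0, 4.0, 8.0]
    order = sorted(range(4), key=lambda i: (total[i], wsum[i]))
    assert order[0] == 1  # B wins the tie: 0.5 < 0.55 < 1.0


def _recovery_problem(data_seed: int, truth: float = 0.10):
    locus = toy_locus("single_gene", lam=truth)
    data = run_ensemble(
        locus, "wt", 2500.0, 20, (7777, data_seed), temperature=23.0, warmup=300.0
    )
    y0 = {"gA": float(data.table.loc["gA", "mean_per_hour"])}
    return InferenceProblem(
        locus=locus,
        unknowns=[Unknown(element="pA", condition="wt", bounds=(0.04, 0.16), step=0.02)],
        experiments=[ExperimentTarget(kind="level", values=y0, condition_a="wt")],
        n_trajectories=20,
        duration=2500.0,
        warmup=300.0,
        temperature=23.0,
        seed=1234,
    )


def test_parameter_recovery_lands_within_one_grid_step_in_most_replicates():
    truth, step = 0.10, 0.02
    hits = 0
    for rep in range(20):
        best = grid_search(_recovery_problem(rep))[0]
        if abs(best.params[0] - truth) <= step + 1e-9:
            hits += 1
    assert hits >= 18  # >= 90% of 20 replicates


def test_grid_search_is_deterministic():
    a = grid_search(_recovery_problem(0))
    b = grid_search(_recovery_problem(0))
    assert [c.params for c in a] == [c.params for c in b]
    assert [c.discrepancies for c in a] == [c.discrepancies for c in b]


def test_empty_surviving_grid_suggests_larger_threshold(locus1):
    problem = InferenceProblem(
        locus=locus1,
        unknowns=[Unknown(element="P1", condition="wt", bounds=(0.9, 1.0), step=0.05)],
        experiments=[
            ExperimentTarget(kind="ratio", values={"ycf1": 0.76},
                             condition_a="sig4ko", condition_b="wt")
        ],
        balance_threshold=0.1,
        n_trajectories=2,
        duration=100.0,
        temperature=23.0,
        seed=1,
    )
    with pytest.raises(ValueError, match="balance"):
        grid_search(problem)


def test_knockout_constraint_prunes_grid_points():
    locus = toy_locus("single_gene", lam=0.1)
    # two unknowns on the same promoter: knockout (index 0) <= wild type (1)
    doc_unknowns = [
        Unknown(element="pA", condition="wt", bounds=(0.05, 0.10), step=0.05),
        Unknown(element="pA", condition="wt", bounds=(0.05, 0.10), step=0.05),
    ]
    problem = InferenceProblem(
        locus=locus,
        unknowns=doc_unknowns,
        experiments=[ExperimentTarget(kind="level", values={"gA": 20.0}, condition_a="wt")],
        n_trajectories=2,
        duration=300.0,
        temperature=23.0,
        seed=5,
        constraints=[(0, 1)],
    )
    scored = grid_search(problem)
    assert all(c.params[0] <= c.params[1] + 1e-12 for c in scored)
    assert len(scored) == 3  # (.05,.05), (.05,.10), (.10,.10)


# ---------------------------------------------------------------------------
# Hypothesis scanning
# ---------------------------------------------------------------------------


def _tandem_problem(y0, seed=99):
    locus = toy_locus("tandem_with_terminator", p_terminate=0.0)
    locus = locus.__class__(
        name=locus.name, length=locus.length, genes=locus.genes,
        promoters=locus.promoters, terminators=(),  # base structure: no terminator
    )
    return InferenceProblem(
        locus=locus,
        unknowns=[Unknown(element="p1", condition="wt", bounds=(0.08, 0.12), step=0.02)],
        experiments=[ExperimentTarget(kind="level", values=y0, condition_a="wt")],
        n_trajectories=10,
        duration=2000.0,
        warmup=300.0,
        temperature=23.0,
        seed=seed,
    )


def _candidate_terminator(p=0.0):
    return Terminator(id="tX", shoulder_intervals=((1200, 1220), (1224, 1244)), p_terminate=p)


def test_a_terminator_fixed_at_zero_probability_changes_nothing():
    locus = toy_locus("tandem_with_terminator", p_terminate=0.6)
    data = run_ensemble(locus, "wt", 2000.0, 10, (1, 2), temperature=23.0, warmup=300.0)
    y0 = {u: float(v) for u, v in data.table["mean_per_hour"].items()}
    problem = _tandem_problem(y0)
    table = hypothesis_scan(
        problem, {"none": [], "null_terminator": [_candidate_terminator(p=0.0)]}
    )
    assert table.loc["none", "best_discrepancy"] == pytest.approx(
        table.loc["null_terminator", "best_discrepancy"]
    )


def test_data_generated_with_a_terminator_prefer_the_terminator_hypothesis():
    truth = toy_locus("tandem_with_terminator", p_terminate=0.6)
    data = run_ensemble(truth, "wt", 2000.0, 10, (3, 4), temperature=23.0, warmup=300.0)
    y0 = {u: float(v) for u, v in data.table["mean_per_hour"].items()}
    problem = _tandem_problem(y0)
    table = hypothesis_scan(
        problem,
        {"without": [], "with_terminator": [_candidate_terminator()]},
        extra_unknowns={
            "with_terminator": [
                Unknown(element="tX", kind="terminator", bounds=(0.0, 0.8), step=0.2)
            ]
        },
    )
    assert (
        table.loc["with_terminator", "best_discrepancy"]
        < table.loc["without", "best_discrepancy"]
    )
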