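"""Case fragments, greedy layer and the two unsigned approximation solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _strategies import rand_instance
from sbirt.breakpoints import (
    OVERCHARGED,
    SOFT,
    UNDERCHARGED,
    classify_pairs,
    classify_state,
    find_softly_connected_pair,
    lower_bound,
)
from sbirt.genome import (
    Genome,
    Instance,
    Move,
    Reversal,
    Transposition,
    apply_operation,
    apply_solution,
    apply_transposition,
    identity_genome,
)
from sbirt.unsigned import (
    create_hard_undercharged,
    fix_over_under,
    fix_single_overcharged_no_under,
    fix_two_overcharged,
    greedy_step,
    redistribute_three,
    remove_overcharged_by_move,
    resolve_softly_connected,
    sort_generic_transpositions,
    sort_reversals_transpositions,
)

COMMON = settings(derandomize=True, max_examples=80, deadline=None)


def _apply_all(genome, ops):
    for op in ops:
        genome = apply_operation(genome, op)
    return genome


# ---------------------------------------------------------------------------
# redistribute_three
# ---------------------------------------------------------------------------

def _brute_force_redistribution_exists(genome, i, j, k, targets):
    """Independent oracle: search all cut choices of the two-transposition
    pattern for one that realizes the redistribution."""
    for x in range(genome.gap(i) + 1):
        for y in range(genome.gap(j) + 1):
            for z in range(genome.gap(k) + 1):
                mid = apply_transposition(genome, Transposition(i, j, k, x, y, z))
                m = i + k - j
                for x2 in range(mid.gap(i) + 1):
                    for y2 in range(mid.gap(m) + 1):
                        for z2 in range(mid.gap(k) + 1):
                            out = apply_transposition(
                                mid, Transposition(i, m, k, x2, y2, z2)
                            )
                            if out.genes == genome.genes and (
                                out.gap(i), out.gap(j), out.gap(k)
                            ) == targets:
                                return True
    return False


def test_redistribution_identity_targets():
    g = identity_genome(4, (2, 3, 1, 0, 0))
    plan = redistribute_three(Instance(g, (2, 3, 1, 0, 0)), 1, 2, 3, 2, 3, 1)
    out = _apply_all(g, plan.operations)
    assert out.genes == g.genes
    assert out.gaps == g.gaps  # net no-op on sizes


def test_redistribution_moves_everything_across():
    g = identity_genome(4, (5, 0, 0, 1, 1))
    plan = redistribute_three(Instance(g, (5, 0, 0, 1, 1)), 1, 2, 3, 0, 0, 5)
    out = _apply_all(g, plan.operations)
    assert out.genes == g.genes
    assert (out.gap(1), out.gap(2), out.gap(3)) == (0, 0, 5)
    assert out.gaps[3:] == g.gaps[3:]


def test_redistribution_matches_brute_force_oracle():
    g = identity_genome(4, (2, 1, 3, 0, 0))
    total = 6
    inst = Instance(g, g.gaps)
    for a in range(total + 1):
        for b in range(total + 1 - a):
            c = total - a - b
            assert _brute_force_redistribution_exists(g, 1, 2, 3, (a, b, c))
            plan = redistribute_three(inst, 1, 2, 3, a, b, c)
            out = _apply_all(g, plan.operations)
            assert out.genes == g.genes
            assert (out.gap(1), out.gap(2), out.gap(3)) == (a, b, c)


@given(st.data())
@COMMON
def test_redistribution_property(data):
    n = data.draw(st.integers(3, 6))
    gaps = data.draw(st.lists(st.integers(0, 6), min_size=n + 1, max_size=n + 1))
    g = identity_genome(n, gaps)
    i, j, k = sorted(
        data.draw(
            st.lists(
                st.integers(1, n + 1), min_size=3, max_size=3, unique=True
            )
        )
    )
    total = g.gap(i) + g.gap(j) + g.gap(k)
    a = data.draw(st.integers(0, total))
    b = data.draw(st.integers(0, total - a))
    c = total - a - b
    plan = redistribute_three(Instance(g, gaps), i, j, k, a, b, c)
    out = _apply_all(g, plan.operations)
    assert out.genes == g.genes
    assert (out.gap(i), out.gap(j), out.gap(k)) == (a, b, c)
    for r in range(1, n + 2):
        if r not in (i, j, k):
            assert out.gap(r) == g.gap(r)


def test_redistribution_rejects_sum_mismatch():
    g = identity_genome(4, (2, 3, 1, 0, 0))
    with pytest.raises(ValueError):
        redistribute_three(Instance(g, g.gaps), 1, 2, 3, 9, 0, 0)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def test_fix_two_overcharged_example():
    inst = Instance(identity_genome(2, (3, 3, 0)), (1, 1, 4))
    frag = fix_two_overcharged(inst)
    assert len(frag) == 2
    out = apply_solution(inst.source, frag)
    assert out == inst.target_genome()  # b1: 3 -> 0 here


def test_fix_two_overcharged_prefers_soft_absorber():
    # soft breakpoint (0,2) available: the surplus must land in its region
    src = Genome((0, 2, 1, 3, 4), (1, 5, 0, 6))
    inst = Instance(src, (3, 2, 4, 3))
    report = classify_pairs(inst)
    assert report.pairs[1].label == OVERCHARGED
    assert report.pairs[3].label == OVERCHARGED
    assert report.pairs[0].label == SOFT
    frag = fix_two_overcharged(inst)
    out = apply_solution(src, frag)
    assert out.genes == src.genes
    assert out.gap(2) == 2 and out.gap(4) == 3  # exact targets
    assert out.gap(1) == 1 + 3 + 3  # leftmost soft region absorbed the surplus
    after = classify_state(out, inst.target_gaps)
    assert after.b == report.b - 2


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_fix_two_overcharged_removes_two(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(3, 9)))
    report = classify_pairs(inst)
    if len(report.with_label(OVERCHARGED)) < 2:
        return
    frag = fix_two_overcharged(inst)
    assert len(frag) == 2
    after = classify_state(apply_solution(inst.source, frag), inst.target_gaps)
    assert after.b <= report.b - 2


def test_resolve_softly_connected_example(unsigned_example):
    frag = resolve_softly_connected(unsigned_example, 0, 3)
    assert frag == [Reversal(1, 3, 1, 0)]
    after = classify_state(
        apply_solution(unsigned_example.source, frag), unsigned_example.target_gaps
    )
    assert after.b == 2  # 4 -> 2
    # the new adjacency got exactly its target size
    assert apply_solution(unsigned_example.source, frag).gap(1) == 1


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=80, deadline=None)
def test_resolve_softly_connected_properties(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(3, 9)))
    pair = find_softly_connected_pair(inst)
    if pair is None:
        return
    report = classify_pairs(inst)
    super_hard = {
        p.index: (p.left, p.right) for p in report.pairs if p.super_hard
    }
    frag = resolve_softly_connected(inst, *pair)
    assert len(frag) == 1
    out = apply_solution(inst.source, frag)
    after = classify_state(out, inst.target_gaps)
    assert after.b <= report.b - 1
    # no super hard breakpoint is removed: its element pair still breaks
    still = {
        (p.left, p.right) for p in after.pairs if p.is_breakpoint
    } | {(p.right, p.left) for p in after.pairs if p.is_breakpoint}
    for elems in super_hard.values():
        assert elems in still


def test_fix_over_under_equal_sums_double_reversal():
    inst = Instance(identity_genome(6, (1, 3, 0, 3, 5, 2, 0)), (1, 3, 0, 3, 1, 2, 4))
    frag = fix_over_under(inst)
    assert frag == [Reversal(5, 6, 1, 0), Reversal(5, 6, 1, 0)]
    assert apply_solution(inst.source, frag) == inst.target_genome()


def test_fix_over_under_strict_surplus():
    inst = Instance(identity_genome(2, (4, 0, 1)), (1, 2, 2))
    report = classify_pairs(inst)
    assert report.with_label(OVERCHARGED) == (0,)
    assert report.with_label(UNDERCHARGED) == (1, 2)
    frag = fix_over_under(inst)
    assert len(frag) == 2 and all(isinstance(op, Transposition) for op in frag)
    after = classify_state(apply_solution(inst.source, frag), inst.target_gaps)
    assert after.b <= report.b - 2


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=80, deadline=None)
def test_fix_over_under_removes_two(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(2, 9)))
    report = classify_pairs(inst)
    if (
        len(report.with_label(OVERCHARGED)) != 1
        or not report.with_label(UNDERCHARGED)
        or find_softly_connected_pair(inst) is not None
    ):
        return
    frag = fix_over_under(inst)
    assert len(frag) == 2
    after = classify_state(apply_solution(inst.source, frag), inst.target_gaps)
    assert after.b <= report.b - 2


def test_create_hard_undercharged_merging_reversal():
    # decreasing strip, (pi_i, pi_j) consecutive: the reversal dumps every
    # nucleotide of both soft regions onto the new pair, which stays below
    # its target because the pair was not softly connected
    src = Genome((0, 1, 3, 2, 4), (3, 0, 0, 1))
    inst = Instance(src, (0, 2, 0, 2))
    assert find_softly_connected_pair(inst) is None
    frag = create_hard_undercharged(inst)
    assert frag == [Reversal(2, 3, 0, 1)]
    out = apply_solution(src, frag)
    after = classify_state(out, inst.target_gaps)
    assert out.gap(2) == 1  # both regions merged, 1 < 2
    assert after.pairs[1].label == UNDERCHARGED
    before = classify_pairs(inst)
    assert after.b <= before.b
    assert find_softly_connected_pair(Instance(out, inst.target_gaps)) is None


def _search_create_cases(kind, seeds=range(4000), limit=12):
    """Collect qualifying random instances whose creation step is of ``kind``."""
    found = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        inst = rand_instance(rng, n=int(rng.integers(3, 8)))
        report = classify_pairs(inst)
        if report.b_soft == 0 or find_softly_connected_pair(inst) is not None:
            continue
        frag = create_hard_undercharged(inst)
        assert len(frag) == 1
        op = frag[0]
        if kind == "reversal" and not isinstance(op, Reversal):
            continue
        if kind == "zero-cut-reversal" and not (
            isinstance(op, Reversal) and op.x == 0 and op.y == 0
        ):
            continue
        found.append((inst, report, frag))
        if len(found) >= limit:
            break
    return found


def test_create_hard_undercharged_transposition_case():
    # only increasing strips and no soft pair with merge-able ends: the
    # cut-free transposition over three soft breakpoints joins two of them
    # into a super hard undercharged breakpoint without removing a hard one
    src = Genome((0, 3, 4, 1, 2, 5), (1, 20, 1, 0, 1))
    inst = Instance(src, (4, 0, 4, 3, 12))
    assert find_softly_connected_pair(inst) is None
    frag = create_hard_undercharged(inst)
    assert frag == [Transposition(1, 3, 5, 0, 0, 0)]
    out = apply_solution(src, frag)
    before = classify_pairs(inst)
    after = classify_state(out, inst.target_gaps)
    assert after.b <= before.b
    assert after.b_hard > before.b_hard  # hard breakpoints created, none removed
    created = [p for p in after.pairs if p.label == UNDERCHARGED]
    assert created and any(p.super_hard for p in created)


@pytest.mark.parametrize("kind", ["reversal", "zero-cut-reversal"])
def test_create_hard_undercharged_branches(kind):
    cases = _search_create_cases(kind)
    assert cases, f"no qualifying random instance exercised the {kind} branch"
    for inst, before, frag in cases:
        out = apply_solution(inst.source, frag)
        after = classify_state(out, inst.target_gaps)
        assert UNDERCHARGED in {p.label for p in after.pairs}
        assert after.b <= before.b
        # no adjacency destroyed: every adjacency element pair survives
        adj_before = {
            frozenset((p.left, p.right)) for p in before.pairs if not p.is_breakpoint
        }
        adj_after = {
            frozenset((p.left, p.right)) for p in after.pairs if not p.is_breakpoint
        }
        assert adj_before <= adj_after


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_fix_single_overcharged_guarantee(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(3, 9)))
    report = classify_pairs(inst)
    if (
        len(report.with_label(OVERCHARGED)) != 1
        or report.with_label(UNDERCHARGED)
        or find_softly_connected_pair(inst) is not None
        or report.b == 0
    ):
        return
    frag = fix_single_overcharged_no_under(inst)
    after = classify_state(apply_solution(inst.source, frag), inst.target_gaps)
    removed = report.b - after.b
    assert (len(frag) <= 3 and removed >= 2) or (len(frag) <= 4 and removed >= 3)
    assert removed / len(frag) >= 2 / 3
    if removed == 2 and len(frag) == 3:
        # the remaining state cannot already be sorted
        assert after.b > 0


def test_remove_overcharged_by_move_example():
    inst = Instance(identity_genome(6, (1, 3, 0, 3, 5, 2, 0)), (1, 3, 0, 3, 1, 2, 4))
    mv = remove_overcharged_by_move(inst)
    assert mv == Move(5, 5, 7, 0, 4, 0)
    out = apply_operation(inst.source, mv)
    assert out == inst.target_genome()  # deficit matched exactly: both removed


def test_remove_overcharged_by_move_directions():
    # receiver left of the overcharged region: backward move form
    inst = Instance(identity_genome(2, (0, 5, 1)), (4, 1, 1))
    mv = remove_overcharged_by_move(inst)
    assert mv.i == 1 and mv.j == mv.k == 2  # tau^(i,k,k): pull from region 2
    out = apply_operation(inst.source, mv)
    assert out.gaps == (4, 1, 1)


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=80, deadline=None)
def test_remove_overcharged_by_move_removes_one(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(2, 9)))
    report = classify_pairs(inst)
    if not report.with_label(OVERCHARGED):
        return
    mv = remove_overcharged_by_move(inst)
    after = classify_state(apply_operation(inst.source, mv), inst.target_gaps)
    assert after.b <= report.b - 1


# ---------------------------------------------------------------------------
# greedy layer
# ---------------------------------------------------------------------------

def test_greedy_finds_two_removing_reversal(unsigned_example):
    op = greedy_step(unsigned_example)
    assert isinstance(op, Reversal)
    before = classify_pairs(unsigned_example).b
    after = classify_state(
        apply_operation(unsigned_example.source, op), unsigned_example.target_gaps
    ).b
    assert after == before - 2


def test_greedy_none_when_sorted():
    inst = Instance(identity_genome(3, (1, 2, 3, 4)), (1, 2, 3, 4))
    assert greedy_step(inst) is None


def test_greedy_finds_three_removing_transposition():
    # a transposed identity is undone by one transposition removing 3 breakpoints
    target = identity_genome(6, (1, 2, 3, 4, 5, 6, 7))
    source = apply_transposition(target, Transposition(2, 4, 6, 1, 1, 1))
    inst = Instance(source, target.gaps)
    before = classify_pairs(inst)
    assert before.b == 3
    op = greedy_step(inst)
    assert isinstance(op, Transposition)
    after = classify_state(apply_operation(source, op), inst.target_gaps)
    assert after.b == 0


def test_greedy_move_pairing_requires_flag():
    # one overcharged and one undercharged with matching excess: only the
    # generic-transposition greedy may fix both with a single move
    inst = Instance(identity_genome(2, (3, 1, 0)), (1, 1, 2))
    assert greedy_step(inst, allow_moves=False) is None
    op = greedy_step(inst, allow_moves=True)
    assert isinstance(op, Move)
    after = classify_state(apply_operation(inst.source, op), inst.target_gaps)
    assert after.b == 0


# ---------------------------------------------------------------------------
# full solvers
# ---------------------------------------------------------------------------

def test_sorted_instance_yields_empty_solution():
    inst = Instance(identity_genome(3, (1, 2, 3, 4)), (1, 2, 3, 4))
    assert sort_reversals_transpositions(inst) == ()
    assert sort_generic_transpositions(inst) == ()


def test_solver_lengths_on_worked_example(unsigned_example):
    b1 = classify_pairs(unsigned_example).b
    sol1 = sort_reversals_transpositions(unsigned_example)
    assert 3 * len(sol1) <= 4 * b1
    assert apply_solution(unsigned_example.source, sol1) == unsigned_example.target_genome()
    sol2 = sort_generic_transpositions(unsigned_example)
    assert len(sol2) <= b1
    # greedy reaches the breakpoint lower bound on this instance
    sol2g = sort_generic_transpositions(unsigned_example, greedy=True)
    assert len(sol2g) == lower_bound(unsigned_example) == 2


@pytest.mark.parametrize("greedy", [False, True])
@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_solver_soundness_and_bounds(greedy, seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(2, 10)))
    b1 = classify_pairs(inst).b
    sol1 = sort_reversals_transpositions(inst, greedy=greedy)
    assert apply_solution(inst.source, sol1) == inst.target_genome()
    assert 3 * len(sol1) <= 4 * b1
    sol2 = sort_generic_transpositions(inst, greedy=greedy)
    assert apply_solution(inst.source, sol2) == inst.target_genome()
    assert len(sol2) <= b1


@given(st.integers(0, 2 ** 31 - 1))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_no_emitted_operation_increases_breakpoints(seed):
    rng = np.random.default_rng(seed)
    inst = rand_instance(rng, n=int(rng.integers(2, 8)))
    for solver in (sort_reversals_transpositions, sort_generic_transpositions):
        g = inst.source
        b = classify_state(g, inst.target_gaps).b
        for op in solver(inst, greedy=True):
            g = apply_operation(g, op)
            b_new = classify_state(g, inst.target_gaps).b
            assert b_new <= b
            b = b_new
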