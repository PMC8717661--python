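"""Approximation algorithms for sorting unsigned genomes with intergenic regions.

Two solvers are provided, both driven by the breakpoint census:

* :func:`sort_reversals_transpositions` -- a 4-approximation using reversals
  and (three-region) transpositions.  Each loop iteration dispatches on the
  number of overcharged breakpoints and the existence of a softly connected
  pair, applying a short fragment of operations that removes breakpoints at
  an amortized rate of at least 3 per 4 operations, for a solution of length
  at most ``4 * b1 / 3``.
* :func:`sort_generic_transpositions` -- a 3-approximation that additionally
  uses intergenic moves (degenerate transpositions).  Every iteration removes
  at least one breakpoint with exactly one operation, for a solution of
  length at most ``b1``.

Both accept an optional greedy layer that, at the start of each iteration,
searches for a single transposition removing three breakpoints, or a single
reversal/transposition (or move, for the generic solver) removing two.

Every emitted operation cuts only inside breakpoint regions and never
destroys an adjacency; this is what makes the solutions liftable to signed
instances (see :mod:`sbirt.signed`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from .breakpoints import (
    ADJACENCY,
    OVERCHARGED,
    SOFT,
    UNDERCHARGED,
    BreakpointReport,
    classify_state,
)
from .genome import (
    Genome,
    Instance,
    InvalidInstanceError,
    Move,
    Reversal,
    Transposition,
    apply_operation,
    validate_instance,
)

__all__ = [
    "AlgorithmError",
    "RedistributionPlan",
    "redistribute_three",
    "fix_two_overcharged",
    "resolve_softly_connected",
    "fix_over_under",
    "create_hard_undercharged",
    "fix_single_overcharged_no_under",
    "remove_overcharged_by_move",
    "greedy_step",
    "sort_reversals_transpositions",
    "sort_generic_transpositions",
]

logger = logging.getLogger(__name__)


class AlgorithmError(RuntimeError):
    """An internal guarantee of the sorting procedure was violated."""


def _tgt(target_gaps, a: int, b: int) -> int:
    """Target size of the region between consecutive elements a and b."""
    return target_gaps[max(abs(a), abs(b)) - 1]


def _require_valid(inst: Instance) -> None:
    reasons = validate_instance(inst)
    if reasons:
        raise InvalidInstanceError("; ".join(reasons))


# ---------------------------------------------------------------------------
# Nucleotide redistribution over three regions (two transpositions)
# ---------------------------------------------------------------------------

def _solve_transposition_cuts(sizes, targets):
    """Cuts (x, y, z) of one transposition mapping region sizes to targets.

    A transposition over regions of sizes ``(s1, s2, s3)`` produces sizes
    ``(x + s2 - y, z + s1 - x, y + s3 - z)``; the map to ``(a, b, c)`` is
    feasible iff ``a <= s1 + s2``, ``b <= s1 + s3`` and ``c <= s2 + s3``.
    Returns ``None`` when infeasible.
    """
    s1, s2, s3 = sizes
    a, b, c = targets
    if a + b + c != s1 + s2 + s3:
        return None
    x = max(0, a - s2, s1 - b)
    if x > min(s1, a, s1 - b + s3):
        return None
    y = x + s2 - a
    z = b - s1 + x
    return (x, y, z)


@dataclass(frozen=True)
class RedistributionPlan:
    """Two consecutive transpositions realizing an arbitrary redistribution.

    The first transposition swaps the two gene segments delimited by regions
    ``(i, j, k)``; the second swaps them back, so the gene order is unchanged
    while the three regions end up with the requested sizes.
    """

    regions: tuple  # (i, j, k), 1-based region indices, i < j < k
    targets: tuple  # (a, b, c) requested sizes
    first: Transposition
    second: Transposition

    @property
    def operations(self) -> tuple:
        return (self.first, self.second)


def _plan_redistribution(genome: Genome, i: int, j: int, k: int, a: int, b: int, c: int) -> RedistributionPlan:
    s1, s2, s3 = genome.gap(i), genome.gap(j), genome.gap(k)
    total = s1 + s2 + s3
    if a < 0 or b < 0 or c < 0 or a + b + c != total:
        raise ValueError(
            f"targets ({a},{b},{c}) must be non-negative and sum to {total}"
        )
    # Intermediate sizes (p, q, r) after the first swap, chosen by greedy
    # water-filling against the feasibility bounds of both transpositions;
    # such an intermediate always exists (see docs/methods.md).
    p = min(s1 + s2, a + b, total)
    q = min(s1 + s3, a + c, total - p)
    r = total - p - q
    if r > min(s2 + s3, b + c):
        raise AlgorithmError("no feasible redistribution intermediate (bug)")
    cuts1 = _solve_transposition_cuts((s1, s2, s3), (p, q, r))
    cuts2 = _solve_transposition_cuts((p, q, r), (a, b, c))
    if cuts1 is None or cuts2 is None:
        raise AlgorithmError("redistribution cut solve failed (bug)")
    first = Transposition(i, j, k, *cuts1)
    second = Transposition(i, i + k - j, k, *cuts2)
    return RedistributionPlan((i, j, k), (a, b, c), first, second)


def redistribute_three(inst: Instance, i: int, j: int, k: int, a: int, b: int, c: int) -> RedistributionPlan:
    """Plan two transpositions setting regions ``(i, j, k)`` to sizes ``(a, b, c)``.

    Requires ``1 <= i < j < k <= n + 1`` and ``a + b + c`` equal to the
    current total of the three regions.  Applying both operations leaves the
    gene order (and every other region) unchanged.
    """
    g = inst.source
    if not 1 <= i < j < k <= g.n + 1:
        raise ValueError(f"regions ({i},{j},{k}) must satisfy 1 <= i < j < k <= n+1")
    return _plan_redistribution(g, i, j, k, a, b, c)


# ---------------------------------------------------------------------------
# Case fragments
# ---------------------------------------------------------------------------

def _choose_extra_region(report: BreakpointReport, exclude) -> int:
    """Pick a third breakpoint region: leftmost soft, else leftmost
    undercharged, else leftmost remaining breakpoint."""
    for wanted in (SOFT, UNDERCHARGED, None):
        for pair in report.pairs:
            if not pair.is_breakpoint or pair.index in exclude:
                continue
            if wanted is None or pair.label == wanted:
                return pair.index
    raise AlgorithmError("no spare breakpoint region available (invalid instance?)")


def _fix_two_overcharged(genome: Genome, target_gaps, report=None) -> list:
    if report is None:
        report = classify_state(genome, target_gaps)
    over = report.with_label(OVERCHARGED)
    if len(over) < 2:
        raise ValueError("need at least two overcharged breakpoints")
    p1, p2 = over[0], over[1]
    t1 = _tgt(target_gaps, genome.genes[p1], genome.genes[p1 + 1])
    t2 = _tgt(target_gaps, genome.genes[p2], genome.genes[p2 + 1])
    surplus = (genome.gaps[p1] - t1) + (genome.gaps[p2] - t2)
    p3 = _choose_extra_region(report, {p1, p2})
    t3 = genome.gaps[p3] + surplus
    triple = sorted(((p1 + 1, t1), (p2 + 1, t2), (p3 + 1, t3)))
    (i, a), (j, b), (k, c) = triple
    plan = _plan_redistribution(genome, i, j, k, a, b, c)
    return list(plan.operations)


def _softly_connected_case(genome: Genome, target_gaps, pi: int, pj: int,
                           report: BreakpointReport):
    """Which connection pattern applies to a softly connected pair (pi < pj).

    Returns ``(case, values, target_size)`` where case is one of
    "ends-left", "ends-right", "inner", "outer"; only patterns whose
    consecutive elements do not already form an adjacency and whose
    combined-region budget covers the target size qualify.
    """
    g = genome.genes
    budget = genome.gaps[pi] + genome.gaps[pj]
    candidates = (
        ("ends-left", pi, pj),          # (pi_i, pi_j) consecutive
        ("ends-right", pi + 1, pj + 1),  # (pi_{i+1}, pi_{j+1})
        ("inner", pi + 1, pj),          # (pi_{i+1}, pi_j)
        ("outer", pi, pj + 1),          # (pi_i, pi_{j+1})
    )
    for case, pa, pb in candidates:
        va, vb = g[pa], g[pb]
        if abs(va - vb) != 1:
            continue
        if abs(pa - pb) == 1 and report.pairs[min(pa, pb)].label == ADJACENCY:
            continue
        if budget >= _tgt(target_gaps, va, vb):
            return case, (va, vb), _tgt(target_gaps, va, vb)
    return None


def _resolve_softly_connected(genome: Genome, target_gaps, pi: int, pj: int,
                              report=None) -> list:
    if report is None:
        report = classify_state(genome, target_gaps)
    if report.pairs[pi].label != SOFT or report.pairs[pj].label != SOFT:
        raise ValueError("both breakpoints must be soft")
    found = _softly_connected_case(genome, target_gaps, pi, pj, report)
    if found is None:
        raise ValueError(f"breakpoints {pi} and {pj} are not softly connected")
    case, _, tm = found
    si, sj = genome.gaps[pi], genome.gaps[pj]  # regions pi+1, pj+1

    if case == "ends-left":
        # reversal brings pi_j next to pi_i; its new region gets exactly tm
        x = min(si, tm)
        return [Reversal(pi + 1, pj, x, tm - x)]
    if case == "ends-right":
        # same reversal, but the exact size goes on the right boundary
        keep = si + sj - tm
        x = min(si, keep)
        return [Reversal(pi + 1, pj, x, keep - x)]
    if case == "inner":
        # transposition over a third region between the pair: a soft one when
        # the pair is not adjacent (one always exists then), else the single
        # hard breakpoint separating them -- which is never super hard, being
        # flanked by two soft breakpoints
        t = next(
            (c for c in range(pi + 2, pj + 1) if report.pairs[c - 1].label == SOFT),
            None,
        )
        if t is None:
            t = next(
                (c for c in range(pi + 2, pj + 1) if report.pairs[c - 1].is_breakpoint),
                None,
            )
        if t is None:
            raise AlgorithmError("no breakpoint region between an inner-connected pair")
        z = min(sj, tm)
        x = si + z - tm
        return [Transposition(pi + 1, t, pj + 1, x, 0, z)]
    # case == "outer": transposition over a third *soft* breakpoint before or
    # after the pair (cutting a hard one would remove it, which the signed
    # lifting and the super-hard bookkeeping both forbid); one always exists
    right = next(
        (p.index for p in report.pairs if p.label == SOFT and p.index > pj), None
    )
    if right is not None:
        yprime = min(sj, tm)
        return [
            Transposition(pi + 1, pj + 1, right + 1, tm - yprime, sj - yprime, 0)
        ]
    left = next(
        (p.index for p in report.pairs if p.label == SOFT and p.index < pi), None
    )
    if left is not None:
        if tm >= sj:
            y, z = tm - sj, 0
        else:
            y, z = 0, sj - tm
        return [Transposition(left + 1, pi + 1, pj + 1, 0, y, z)]
    raise AlgorithmError("no third soft breakpoint for an outer-connected pair")


def _fix_over_under(genome: Genome, target_gaps, report=None) -> list:
    if report is None:
        report = classify_state(genome, target_gaps)
    over = report.with_label(OVERCHARGED)
    under = report.with_label(UNDERCHARGED)
    if len(over) != 1 or not under:
        raise ValueError("need exactly one overcharged and some undercharged breakpoint")
    oi, uj = over[0], under[0]
    tx = _tgt(target_gaps, genome.genes[oi], genome.genes[oi + 1])
    ty = _tgt(target_gaps, genome.genes[uj], genome.genes[uj + 1])
    combined = genome.gaps[oi] + genome.gaps[uj]
    if combined < tx + ty:
        raise AlgorithmError("combined regions below combined targets (invalid state)")
    if combined == tx + ty:
        # a double reversal shuttles the excess between the two regions
        a, b = min(oi, uj) + 1, max(oi, uj)
        left_tgt = tx if oi < uj else ty
        x1 = min(genome.gaps[a - 1], left_tgt)
        first = Reversal(a, b, x1, left_tgt - x1)
        second = Reversal(a, b, left_tgt, 0)
        return [first, second]
    # strict surplus: redistribute against a third breakpoint region
    surplus = combined - (tx + ty)
    p3 = _choose_extra_region(report, {oi, uj})
    t3 = genome.gaps[p3] + surplus
    triple = sorted(((oi + 1, tx), (uj + 1, ty), (p3 + 1, t3)))
    (i, a), (j, b), (k, c) = triple
    plan = _plan_redistribution(genome, i, j, k, a, b, c)
    return list(plan.operations)


def _create_hard_undercharged(genome: Genome, target_gaps, report=None) -> list:
    if report is None:
        report = classify_state(genome, target_gaps)
    softs = report.with_label(SOFT)
    if not softs:
        raise ValueError("need at least one soft breakpoint")
    g = genome.genes
    # A soft pair whose outer (or inner) elements are consecutive in the
    # target: one reversal merges them, dumping every nucleotide of both
    # regions onto the new pair, which is undercharged because the pair was
    # not softly connected.
    for ai in range(len(softs)):
        for bj in range(ai + 1, len(softs)):
            i, j = softs[ai], softs[bj]
            if abs(g[i] - g[j]) == 1:
                if genome.gaps[i] + genome.gaps[j] >= _tgt(target_gaps, g[i], g[j]):
                    raise AlgorithmError("softly connected pair present; wrong case")
                return [Reversal(i + 1, j, genome.gaps[i], genome.gaps[j])]
            if abs(g[i + 1] - g[j + 1]) == 1:
                if genome.gaps[i] + genome.gaps[j] >= _tgt(
                    target_gaps, g[i + 1], g[j + 1]
                ):
                    raise AlgorithmError("softly connected pair present; wrong case")
                return [Reversal(i + 1, j, 0, 0)]
    # Only increasing strips: a cut-free transposition over three soft
    # breakpoints joins two of them into a (super hard) undercharged pair.
    soft_set = set(softs)
    pos = genome.positions()

    def soft_between(lo, hi):
        return next((s for s in softs if lo < s < hi), None)

    for i in softs:
        for v in (g[i + 1] - 1, g[i + 1] + 1):
            if not 0 <= v <= genome.n + 1:
                continue
            k = pos[v]  # middle new pair (pi_k, pi_{i+1})
            if k in soft_set and k > i:
                j = soft_between(i, k)
                if j is not None:
                    return [Transposition(i + 1, j + 1, k + 1, 0, 0, 0)]
        for v in (g[i] - 1, g[i] + 1):
            if not 0 <= v <= genome.n + 1:
                continue
            jpos = pos[v] - 1  # first new pair (pi_i, pi_{j+1})
            if jpos in soft_set and jpos > i:
                k = soft_between(jpos, genome.n + 1)
                if k is not None:
                    return [Transposition(i + 1, jpos + 1, k + 1, 0, 0, 0)]
        for v in (g[i] - 1, g[i] + 1):
            # last new pair (pi_j, pi_{k+1}), with the loop index in role j
            if not 0 <= v <= genome.n + 1:
                continue
            kpos = pos[v] - 1
            if kpos in soft_set and kpos > i:
                h = next((s for s in softs if s < i), None)
                if h is not None:
                    return [Transposition(h + 1, i + 1, kpos + 1, 0, 0, 0)]
    raise AlgorithmError("could not create a hard undercharged breakpoint")


def _remove_overcharged_by_move(genome: Genome, target_gaps, report=None) -> Move:
    if report is None:
        report = classify_state(genome, target_gaps)
    over = report.with_label(OVERCHARGED)
    if not over:
        raise ValueError("need an overcharged breakpoint")
    oi = over[0]
    w = genome.gaps[oi] - _tgt(target_gaps, genome.genes[oi], genome.genes[oi + 1])
    receiver = None
    for p in report.pairs:  # an undercharged breakpoint missing exactly w
        if p.label == UNDERCHARGED and p.index != oi:
            deficit = _tgt(target_gaps, p.left, p.right) - genome.gaps[p.index]
            if deficit == w:
                receiver = p.index
                break
    if receiver is None:
        receiver = _choose_extra_region(report, {oi})
    src, dst = oi + 1, receiver + 1
    if src < dst:
        return Move(src, src, dst, 0, w, 0)
    return Move(dst, src, src, 0, 0, w)


def _find_softly_connected(genome: Genome, target_gaps, report: BreakpointReport):
    """Fast scan for the lexicographically smallest softly connected pair.

    Uses the inverse permutation: a softly connected pair must expose two
    elements consecutive in the target, so it suffices to look at the value
    neighbours of each soft breakpoint's two boundary elements.
    """
    softs = report.with_label(SOFT)
    if len(softs) < 2:
        return None
    soft_set = set(softs)
    g = genome.genes
    gaps = genome.gaps
    pos = genome.positions()
    n = genome.n
    best = None
    for i in softs:
        for p_val in (i, i + 1):
            val = g[p_val]
            for v in (val - 1, val + 1):
                if not 0 <= v <= n + 1:
                    continue
                q = pos[v]
                # the consecutive elements must not already be an adjacency
                if abs(p_val - q) == 1 and report.pairs[min(p_val, q)].label == ADJACENCY:
                    continue
                # v may be the left element of soft pair q, or the right
                # element of soft pair q - 1
                for j in (q, q - 1):
                    if j == i or j not in soft_set:
                        continue
                    if gaps[i] + gaps[j] < _tgt(target_gaps, val, v):
                        continue
                    pair = (i, j) if i < j else (j, i)
                    if best is None or pair < best:
                        best = pair
    return best


# ---------------------------------------------------------------------------
# Greedy layer
# ---------------------------------------------------------------------------

def _greedy_candidates(genome: Genome, target_gaps, allow_moves: bool, report=None):
    """Yield ``(removed, sort_key, op)`` for breakpoint-removing single ops.

    Candidate cut positions are restricted to breakpoint regions, so no
    adjacency is ever destroyed; cut values are forced by the target sizes.
    """
    if report is None:
        report = classify_state(genome, target_gaps)
    bps = report.breakpoints
    bpset = set(bps)
    g = genome.genes
    gaps = genome.gaps
    pos = genome.positions()
    n = genome.n

    def neighbours(v):
        for w in (v - 1, v + 1):
            if 0 <= w <= n + 1:
                yield w

    # --- transpositions removing three breakpoints -------------------------
    for p1 in bps:
        i = p1 + 1
        for vj in neighbours(g[p1]):
            j = pos[vj]
            if j <= i or (j - 1) not in bpset:
                continue
            for vk in neighbours(g[j - 1]):
                k = pos[vk]
                if k <= j or k > n + 1 or (k - 1) not in bpset:
                    continue
                if abs(g[k - 1] - g[i]) != 1:
                    continue
                a = _tgt(target_gaps, g[i - 1], g[j])
                b = _tgt(target_gaps, g[k - 1], g[i])
                c = _tgt(target_gaps, g[j - 1], g[k])
                cuts = _solve_transposition_cuts(
                    (gaps[i - 1], gaps[j - 1], gaps[k - 1]), (a, b, c)
                )
                if cuts is not None:
                    yield 3, (0, i, j, k), Transposition(i, j, k, *cuts)

    # --- reversals removing two breakpoints --------------------------------
    for p1 in bps:
        i = p1 + 1
        for vj in neighbours(g[p1]):
            j = pos[vj]
            if j < i or j > n or j not in bpset:
                continue
            if abs(g[i] - g[j + 1]) != 1:
                continue
            t_left = _tgt(target_gaps, g[p1], g[j])
            t_right = _tgt(target_gaps, g[i], g[j + 1])
            if gaps[i - 1] + gaps[j] != t_left + t_right:
                continue
            x = min(gaps[i - 1], t_left)
            yield 2, (0, i, j), Reversal(i, j, x, t_left - x)

    # --- transpositions removing two breakpoints ---------------------------
    def transposition_pair(i, j, k, exact):
        sizes = (gaps[i - 1], gaps[j - 1], gaps[k - 1])
        total = sum(sizes)
        a = _tgt(target_gaps, g[i - 1], g[j]) if "a" in exact else None
        b = _tgt(target_gaps, g[k - 1], g[i]) if "b" in exact else None
        c = _tgt(target_gaps, g[j - 1], g[k]) if "c" in exact else None
        free = total - sum(v for v in (a, b, c) if v is not None)
        if free < 0:
            return None
        a = free if a is None else a
        b = free if b is None else b
        c = free if c is None else c
        cuts = _solve_transposition_cuts(sizes, (a, b, c))
        if cuts is None:
            return None
        return Transposition(i, j, k, *cuts)

    for p1 in bps:
        i = p1 + 1
        for vj in neighbours(g[p1]):
            j = pos[vj]
            if j <= i or (j - 1) not in bpset:
                continue
            # new pairs at regions i and i+k-j ("a" and "b" exact)
            for vk in neighbours(g[i]):
                k = pos[vk] + 1
                if k <= j or k > n + 1 or (k - 1) not in bpset:
                    continue
                op = transposition_pair(i, j, k, "ab")
                if op is not None:
                    yield 2, (1, i, j, k), op
            # new pairs at regions i and k ("a" and "c" exact)
            for vk in neighbours(g[j - 1]):
                k = pos[vk]
                if k <= j or k > n + 1 or (k - 1) not in bpset:
                    continue
                op = transposition_pair(i, j, k, "ac")
                if op is not None:
                    yield 2, (1, i, j, k), op
    for p3 in bps:
        k = p3 + 1
        # new pairs at regions i+k-j and k ("b" and "c" exact)
        for vi in neighbours(g[k - 1]):
            i = pos[vi]
            if i < 1 or i >= k or (i - 1) not in bpset:
                continue
            for vj in neighbours(g[k]):
                j = pos[vj] + 1
                if j <= i or j >= k or (j - 1) not in bpset:
                    continue
                op = transposition_pair(i, j, k, "bc")
                if op is not None:
                    yield 2, (1, i, j, k), op

    # --- moves removing two breakpoints ------------------------------------
    if allow_moves:
        overs = [
            (p.index, gaps[p.index] - _tgt(target_gaps, p.left, p.right))
            for p in report.pairs
            if p.label == OVERCHARGED
        ]
        unders = [
            (p.index, _tgt(target_gaps, p.left, p.right) - gaps[p.index])
            for p in report.pairs
            if p.label == UNDERCHARGED
        ]
        for oi, w in overs:
            for uj, deficit in unders:
                if deficit != w:
                    continue
                src, dst = oi + 1, uj + 1
                if src < dst:
                    op = Move(src, src, dst, 0, w, 0)
                else:
                    op = Move(dst, src, src, 0, 0, w)
                yield 2, (2, min(src, dst), max(src, dst)), op


def _greedy_step(genome: Genome, target_gaps, allow_moves: bool, report=None):
    best3 = None
    best2 = None
    for removed, key, op in _greedy_candidates(genome, target_gaps, allow_moves, report):
        if removed >= 3:
            if best3 is None or key < best3[0]:
                best3 = (key, op)
        else:
            if best2 is None or key < best2[0]:
                best2 = (key, op)
    if best3 is not None:
        return best3[1]
    if best2 is not None:
        return best2[1]
    return None


# ---------------------------------------------------------------------------
# Main loops
# ---------------------------------------------------------------------------

def _dispatch(genome: Genome, target_gaps, report: BreakpointReport):
    """One non-greedy fragment of the reversal+transposition solver."""
    over = report.with_label(OVERCHARGED)
    under = report.with_label(UNDERCHARGED)
    if len(over) >= 2:
        return "two-overcharged", _fix_two_overcharged(genome, target_gaps, report)
    pair = _find_softly_connected(genome, target_gaps, report)
    if pair is not None:
        return (
            "softly-connected",
            _resolve_softly_connected(genome, target_gaps, *pair, report=report),
        )
    if len(over) == 1 and under:
        return "over+under", _fix_over_under(genome, target_gaps, report)
    if len(over) == 1:
        return "single-overcharged", _fix_single_overcharged(genome, target_gaps)
    raise AlgorithmError(
        "no overcharged breakpoint and no softly connected pair with b1 > 0 "
        "(instance is invalid or a classification bug)"
    )


def _fix_single_overcharged(genome: Genome, target_gaps) -> list:
    """Fragment for one overcharged, no undercharged, no softly connected pair.

    Creates a hard undercharged breakpoint with one operation and then
    re-dispatches until at least two breakpoints are gone within three
    operations, or three within four.
    """
    report = classify_state(genome, target_gaps)
    b_start = report.b
    ops = list(_create_hard_undercharged(genome, target_gaps))
    state = genome
    for op in ops:
        state = apply_operation(state, op)
    while True:
        report = classify_state(state, target_gaps)
        removed = b_start - report.b
        if (len(ops) <= 3 and removed >= 2) or (len(ops) <= 4 and removed >= 3):
            return ops
        if report.b == 0 or len(ops) >= 4:
            raise AlgorithmError("single-overcharged fragment guarantee violated")
        case, frag = _dispatch(state, target_gaps, report)
        if case == "single-overcharged":
            raise AlgorithmError("breakpoint-creation step re-entered (bug)")
        for op in frag:
            state = apply_operation(state, op)
            ops.append(op)


def _run(inst: Instance, greedy: bool, moves: bool):
    _require_valid(inst)
    genome = inst.source
    target_gaps = inst.target_gaps
    solution = []
    max_iter = 8 * (genome.n + 2) + 16
    report = classify_state(genome, target_gaps)
    for _ in range(max_iter):
        if report.b == 0:
            break
        b_before = report.b
        if greedy:
            op = _greedy_step(genome, target_gaps, allow_moves=moves, report=report)
            if op is not None:
                genome = apply_operation(genome, op)
                solution.append(op)
                report = classify_state(genome, target_gaps)
                if logger.isEnabledFor(logging.DEBUG):
                    logger.debug("greedy: %r (b1 %d -> %d)", op, b_before, report.b)
                continue
        if moves:
            over = report.with_label(OVERCHARGED)
            if over:
                case, frag = "overcharged-move", [
                    _remove_overcharged_by_move(genome, target_gaps, report)
                ]
            else:
                pair = _find_softly_connected(genome, target_gaps, report)
                if pair is None:
                    raise AlgorithmError(
                        "no overcharged breakpoint and no softly connected pair"
                    )
                case, frag = "softly-connected", _resolve_softly_connected(
                    genome, target_gaps, *pair, report=report
                )
        else:
            case, frag = _dispatch(genome, target_gaps, report)
        for op in frag:
            genome = apply_operation(genome, op)
            solution.append(op)
        report = classify_state(genome, target_gaps)
        logger.debug("%s: %d op(s), b1 %d -> %d", case, len(frag), b_before, report.b)
        if report.b >= b_before:
            raise AlgorithmError(f"fragment '{case}' did not remove a breakpoint")
    else:
        raise AlgorithmError("iteration limit exceeded (non-terminating loop?)")
    if genome.genes != inst.target_genome().genes or genome.gaps != inst.target_gaps:
        raise AlgorithmError("solver finished without reaching the target genome")
    return tuple(solution)


def sort_reversals_transpositions(inst: Instance, greedy: bool = False) -> tuple:
    """4-approximation using reversals and transpositions.

    Returns an operation sequence of length at most ``4 * b1 / 3`` whose
    application transforms the source into the target genome.
    """
    return _run(inst, greedy=greedy, moves=False)


def sort_generic_transpositions(inst: Instance, greedy: bool = False) -> tuple:
    """3-approximation using reversals and generic transpositions (incl. moves).

    Returns an operation sequence of length at most ``b1``; every non-greedy
    iteration removes at least one breakpoint with exactly one operation.
    """
    return _run(inst, greedy=greedy, moves=True)


# ---------------------------------------------------------------------------
# Public wrappers over the case fragments (operate on an Instance)
# ---------------------------------------------------------------------------

def fix_two_overcharged(inst: Instance) -> list:
    """Two transpositions removing (at least) two overcharged breakpoints."""
    _require_valid(inst)
    return _fix_two_overcharged(inst.source, inst.target_gaps)


def resolve_softly_connected(inst: Instance, bp_i: int, bp_j: int) -> list:
    """One reversal or transposition removing a breakpoint of a softly
    connected pair; the new adjacency receives exactly its target size."""
    _require_valid(inst)
    return _resolve_softly_connected(inst.source, inst.target_gaps, bp_i, bp_j)


def fix_over_under(inst: Instance) -> list:
    """Two operations removing one overcharged plus one undercharged breakpoint."""
    _require_valid(inst)
    return _fix_over_under(inst.source, inst.target_gaps)


def create_hard_undercharged(inst: Instance) -> list:
    """One operation creating a hard (possibly super hard) undercharged breakpoint."""
    _require_valid(inst)
    return _create_hard_undercharged(inst.source, inst.target_gaps)


def fix_single_overcharged_no_under(inst: Instance) -> list:
    """At most three operations removing two breakpoints, or four removing three."""
    _require_valid(inst)
    report = classify_state(inst.source, inst.target_gaps)
    if len(report.with_label(OVERCHARGED)) != 1 or report.with_label(UNDERCHARGED):
        raise ValueError("need exactly one overcharged and no undercharged breakpoint")
    return _fix_single_overcharged(inst.source, inst.target_gaps)


def remove_overcharged_by_move(inst: Instance) -> Move:
    """A single intergenic move removing an overcharged breakpoint."""
    _require_valid(inst)
    return _remove_overcharged_by_move(inst.source, inst.target_gaps)


def greedy_step(inst: Instance, allow_moves: bool = False):
    """A single operation removing >= 3 (transposition) or >= 2 breakpoints, or None."""
    _require_valid(inst)
    return _greedy_step(inst.source, inst.target_gaps, allow_moves)
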