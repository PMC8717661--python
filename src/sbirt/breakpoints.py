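"""Breakpoint detection, classification, strips and distance lower bounds.

For an unsigned instance, a consecutive pair ``(pi_i, pi_{i+1})`` is a
*type-one breakpoint* when the two elements are not consecutive in value
(a *soft* breakpoint: the gene order itself is wrong) or when they are
consecutive but the intergenic region between them has the wrong number of
nucleotides relative to the target (a *hard* breakpoint, *overcharged* if it
has too many nucleotides and *undercharged* if too few).  For a signed
instance the analogous *type-two breakpoint* requires ``pi_{i+1} - pi_i = 1``
with orientation taken into account for an adjacency.

Since a reversal can remove at most two breakpoints and a (generic)
transposition at most three, ``ceil(b / 3)`` is a lower bound on the
rearrangement distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome import Genome, Instance, InvalidInstanceError, validate_instance

__all__ = [
    "ADJACENCY",
    "SOFT",
    "OVERCHARGED",
    "UNDERCHARGED",
    "PairInfo",
    "BreakpointReport",
    "Strip",
    "classify_pairs",
    "classify_state",
    "is_connected",
    "find_softly_connected_pair",
    "compute_strips",
    "lower_bound",
]

ADJACENCY = "adjacency"
SOFT = "soft"
OVERCHARGED = "overcharged"
UNDERCHARGED = "undercharged"

HARD_LABELS = (OVERCHARGED, UNDERCHARGED)


@dataclass(frozen=True)
class PairInfo:
    """Classification of the consecutive pair ``(genes[index], genes[index+1])``."""

    index: int
    left: int
    right: int
    label: str
    super_hard: bool = False

    @property
    def is_breakpoint(self) -> bool:
        return self.label != ADJACENCY

    @property
    def is_hard(self) -> bool:
        return self.label in HARD_LABELS


@dataclass(frozen=True)
class BreakpointReport:
    """Per-pair labels and breakpoint counts for one genome state."""

    pairs: tuple
    signed: bool

    @property
    def breakpoints(self) -> tuple:
        return tuple(p.index for p in self.pairs if p.is_breakpoint)

    @property
    def b(self) -> int:
        """Total breakpoints: b1 for unsigned states, b2 for signed ones."""
        return sum(1 for p in self.pairs if p.is_breakpoint)

    @property
    def b_hard(self) -> int:
        return sum(1 for p in self.pairs if p.is_hard)

    @property
    def b_soft(self) -> int:
        return sum(1 for p in self.pairs if p.label == SOFT)

    def with_label(self, label: str) -> tuple:
        return tuple(p.index for p in self.pairs if p.label == label)

    def to_tsv(self) -> str:
        lines = ["position\tleft\tright\tlabel\tsuper_hard"]
        for p in self.pairs:
            lines.append(f"{p.index}\t{p.left}\t{p.right}\t{p.label}\t{int(p.super_hard)}")
        return "\n".join(lines) + "\n"


def _pair_label(genome: Genome, target_gaps, index: int) -> str:
    a, b = genome.genes[index], genome.genes[index + 1]
    if genome.signed:
        order_ok = (b - a) == 1
    else:
        order_ok = abs(b - a) == 1
    if not order_ok:
        return SOFT
    m = max(abs(a), abs(b))
    size = genome.gaps[index]  # region index + 1, 0-based storage
    want = target_gaps[m - 1]
    if size == want:
        return ADJACENCY
    return OVERCHARGED if size > want else UNDERCHARGED


def classify_state(genome: Genome, target_gaps) -> BreakpointReport:
    """Classify every consecutive pair of a genome against target gap sizes."""
    n = genome.n
    labels = [_pair_label(genome, target_gaps, i) for i in range(n + 1)]
    pairs = []
    for i in range(n + 1):
        super_hard = False
        if labels[i] in HARD_LABELS:
            if i == 0 or i == n:
                super_hard = True
            else:
                # flanked by a hard breakpoint or an adjacency
                if labels[i - 1] != SOFT or labels[i + 1] != SOFT:
                    super_hard = True
        pairs.append(
            PairInfo(i, genome.genes[i], genome.genes[i + 1], labels[i], super_hard)
        )
    return BreakpointReport(tuple(pairs), genome.signed)


def classify_pairs(inst: Instance) -> BreakpointReport:
    """Breakpoint census of an instance (type one if unsigned, type two if signed)."""
    reasons = validate_instance(inst)
    if reasons:
        raise InvalidInstanceError("; ".join(reasons))
    return classify_state(inst.source, inst.target_gaps)


def _connection_candidates(genome: Genome, bp1: int, bp2: int):
    """The element pairs of two breakpoints that may be consecutive in the target.

    Yields ``(value_a, value_b, pos_a, pos_b)`` for each candidate, including
    the breakpoints' own element pairs.
    """
    i, j = bp1, bp2
    g = genome.genes
    combos = (
        (i, i + 1),
        (j, j + 1),
        (i, j),
        (i, j + 1),
        (i + 1, j),
        (i + 1, j + 1),
    )
    seen = set()
    for pa, pb in combos:
        if pa == pb or (pa, pb) in seen:
            continue
        seen.add((pa, pb))
        yield g[pa], g[pb], pa, pb


def is_connected(inst: Instance, bp1: int, bp2: int) -> bool:
    """Whether two type-one breakpoints can form an adjacency from their own regions.

    True iff some element pair drawn from the two breakpoints is consecutive
    in the target order, does not already form an adjacency, and the two
    breakpoint regions together hold at least the target size of the region
    between the consecutive elements.
    """
    if inst.signed:
        raise InvalidInstanceError("connectivity is defined for unsigned instances")
    report = classify_state(inst.source, inst.target_gaps)
    for bp in (bp1, bp2):
        if not report.pairs[bp].is_breakpoint:
            raise ValueError(f"pair {bp} is not a breakpoint")
    if bp1 == bp2:
        raise ValueError("connectivity needs two distinct breakpoints")
    i, j = min(bp1, bp2), max(bp1, bp2)
    g = inst.source
    budget = g.gaps[i] + g.gaps[j]  # regions i+1 and j+1 (0-based storage)
    for va, vb, pa, pb in _connection_candidates(g, i, j):
        if abs(va - vb) != 1:
            continue
        if abs(pa - pb) == 1 and report.pairs[min(pa, pb)].label == ADJACENCY:
            continue
        if budget >= inst.target_gaps[max(va, vb) - 1]:
            return True
    return False


def find_softly_connected_pair(inst: Instance) -> Optional[tuple]:
    """Leftmost pair of connected breakpoints that are both soft, or ``None``."""
    report = classify_state(inst.source, inst.target_gaps)
    softs = report.with_label(SOFT)
    for a in range(len(softs)):
        for b in range(a + 1, len(softs)):
            if is_connected(inst, softs[a], softs[b]):
                return (softs[a], softs[b])
    return None


@dataclass(frozen=True)
class Strip:
    """Maximal run of positions free of soft breakpoints."""

    start: int
    end: int
    direction: str  # "increasing" | "decreasing"

    @property
    def singleton(self) -> bool:
        return self.start == self.end


def compute_strips(inst: Instance) -> list:
    """Partition positions ``0..n+1`` into strips separated by soft breakpoints.

    A singleton strip is increasing iff it sits at an extremity of the
    extended permutation; longer strips take the direction of their elements.
    """
    if inst.signed:
        raise InvalidInstanceError("strips are defined for unsigned instances")
    report = classify_state(inst.source, inst.target_gaps)
    n = inst.n
    strips = []
    start = 0
    for i in range(n + 1):
        if report.pairs[i].label == SOFT:
            strips.append(_make_strip(inst.source, start, i, n))
            start = i + 1
    strips.append(_make_strip(inst.source, start, n + 1, n))
    return strips


def _make_strip(genome: Genome, start: int, end: int, n: int) -> Strip:
    if start == end:
        direction = "increasing" if start in (0, n + 1) else "decreasing"
    else:
        direction = (
            "increasing" if genome.genes[start + 1] > genome.genes[start] else "decreasing"
        )
    return Strip(start, end, direction)


def lower_bound(inst: Instance) -> int:
    """Breakpoint lower bound ``ceil(b / 3)`` on the rearrangement distance."""
    report = classify_pairs(inst)
    return -(-report.b // 3)
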