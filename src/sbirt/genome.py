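"""Core data model for genomes with intergenic regions and the edit alphabet.

A linear genome with ``n`` genes is represented by an *extended* permutation
(sentinels ``0`` and ``n + 1`` at the ends) together with the ``n + 1``
non-negative integer sizes of the intergenic regions that separate the genes
and flank the genome.  Three conservative rearrangement operations rewrite
this state:

* a reversal inverts a gene segment, splitting and re-merging the two
  flanking intergenic regions (and flips gene orientations when signed);
* a transposition swaps two consecutive gene segments, cutting three
  intergenic regions;
* an intergenic move relocates nucleotides between two intergenic regions
  without touching the gene order (a degenerate transposition with ``i = j``
  or ``j = k``).

Positions and intergenic regions are 1-based: region ``r`` sits immediately
left of the element at position ``r``, and region ``n + 1`` is right of the
last gene.  Operation validation is strict -- out-of-range positions or cut
values raise :class:`OperationError`, they are never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

__all__ = [
    "Genome",
    "Instance",
    "Reversal",
    "Transposition",
    "Move",
    "Operation",
    "Solution",
    "OperationError",
    "InvalidInstanceError",
    "apply_reversal",
    "apply_transposition",
    "apply_move",
    "apply_operation",
    "apply_solution",
    "identity_genome",
    "is_valid_instance",
    "validate_instance",
]


class OperationError(ValueError):
    """An operation's parameters violate its bounds against a genome."""


class InvalidInstanceError(ValueError):
    """An instance fails its structural or conservation invariants."""


@dataclass(frozen=True)
class Genome:
    """Extended gene order plus intergenic sizes.

    Parameters
    ----------
    genes
        Extended element sequence of length ``n + 2``; ``genes[0] == 0`` and
        ``genes[n + 1] == n + 1``.  Interior entries are a permutation of
        ``1..n`` in absolute value; negative entries encode reversed gene
        orientation and are only allowed when ``signed`` is true.
    gaps
        The ``n + 1`` intergenic sizes; ``gaps[r - 1]`` is the size of
        region ``r``.
    signed
        Whether gene orientations are tracked.
    """

    genes: tuple
    gaps: tuple
    signed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(int(v) for v in self.genes))
        object.__setattr__(self, "gaps", tuple(int(v) for v in self.gaps))
        n = len(self.genes) - 2
        if n < 1:
            raise InvalidInstanceError("genome needs at least one gene")
        if self.genes[0] != 0 or self.genes[-1] != n + 1:
            raise InvalidInstanceError(
                f"sentinels must be 0 and {n + 1}, got "
                f"{self.genes[0]} and {self.genes[-1]}"
            )
        interior = [abs(v) for v in self.genes[1:-1]]
        if sorted(interior) != list(range(1, n + 1)):
            raise InvalidInstanceError(
                "interior elements must be a permutation of 1..n in absolute value"
            )
        if not self.signed and any(v < 0 for v in self.genes):
            raise InvalidInstanceError("negative elements in an unsigned genome")
        if len(self.gaps) != n + 1:
            raise InvalidInstanceError(
                f"expected {n + 1} intergenic sizes, got {len(self.gaps)}"
            )
        if any(g < 0 for g in self.gaps):
            raise InvalidInstanceError("intergenic sizes must be non-negative")

    @property
    def n(self) -> int:
        return len(self.genes) - 2

    def gap(self, region: int) -> int:
        """Size of intergenic region ``region`` (1-based, 1..n+1)."""
        if not 1 <= region <= self.n + 1:
            raise IndexError(f"region {region} out of range 1..{self.n + 1}")
        return self.gaps[region - 1]

    @property
    def total_intergenic(self) -> int:
        return sum(self.gaps)

    def positions(self) -> dict:
        """Map element value (absolute) -> position, including sentinels."""
        return {abs(v): p for p, v in enumerate(self.genes)}

    def is_identity(self) -> bool:
        return all(self.genes[p] == p for p in range(self.n + 2))


def identity_genome(n: int, gaps: Sequence, signed: bool = False) -> Genome:
    """The identity genome ``(0, 1, ..., n + 1)`` with the given gap sizes."""
    return Genome(tuple(range(n + 2)), tuple(gaps), signed=signed)


def _trusted(genes: tuple, gaps: tuple, signed: bool) -> Genome:
    # internal constructor for operation results, whose invariants are
    # preserved by construction; skips the O(n log n) validation
    g = object.__new__(Genome)
    object.__setattr__(g, "genes", genes)
    object.__setattr__(g, "gaps", gaps)
    object.__setattr__(g, "signed", signed)
    return g


@dataclass(frozen=True)
class Reversal:
    """Intergenic reversal of positions ``i..j`` with cuts ``x`` / ``y``.

    Region ``i`` is split into ``x | gap(i) - x`` and region ``j + 1`` into
    ``y | gap(j+1) - y``; the inner parts travel with the reversed segment.
    """

    i: int
    j: int
    x: int
    y: int

    def check(self, g: Genome) -> None:
        if not 1 <= self.i <= self.j <= g.n:
            raise OperationError(f"reversal positions ({self.i},{self.j}) out of range")
        if not 0 <= self.x <= g.gap(self.i):
            raise OperationError(
                f"reversal cut x={self.x} outside [0, {g.gap(self.i)}]"
            )
        if not 0 <= self.y <= g.gap(self.j + 1):
            raise OperationError(
                f"reversal cut y={self.y} outside [0, {g.gap(self.j + 1)}]"
            )

    @property
    def regions(self) -> tuple:
        return (self.i, self.j + 1)


@dataclass(frozen=True)
class Transposition:
    """Intergenic transposition swapping segments ``[i..j-1]`` and ``[j..k-1]``."""

    i: int
    j: int
    k: int
    x: int
    y: int
    z: int

    def check(self, g: Genome) -> None:
        if not 1 <= self.i < self.j < self.k <= g.n + 1:
            raise OperationError(
                f"transposition positions ({self.i},{self.j},{self.k}) out of range"
            )
        for cut, region, name in (
            (self.x, self.i, "x"),
            (self.y, self.j, "y"),
            (self.z, self.k, "z"),
        ):
            if not 0 <= cut <= g.gap(region):
                raise OperationError(
                    f"transposition cut {name}={cut} outside [0, {g.gap(region)}]"
                )

    @property
    def regions(self) -> tuple:
        return (self.i, self.j, self.k)


@dataclass(frozen=True)
class Move:
    """Intergenic move: a degenerate transposition with ``i == j`` or ``j == k``.

    The forward form ``(i, i, k)`` moves ``y - x`` nucleotides from region
    ``i`` into region ``k`` after its ``z``-th nucleotide; the backward form
    ``(i, k, k)`` moves ``z - y`` nucleotides from region ``k`` into region
    ``i``.  Gene order is never changed and the moved amount must be positive.
    """

    i: int
    j: int
    k: int
    x: int
    y: int
    z: int

    def check(self, g: Genome) -> None:
        if self.i == self.j:
            i, k = self.i, self.k
            if not 1 <= i < k <= g.n + 1:
                raise OperationError(f"move regions ({i},{k}) out of range")
            if g.gap(i) < 1 or not 0 <= self.x <= g.gap(i) - 1:
                raise OperationError(f"move cut x={self.x} outside [0, {g.gap(i) - 1}]")
            if not self.x < self.y <= g.gap(i):
                raise OperationError(
                    f"move cut y={self.y} outside ({self.x}, {g.gap(i)}]"
                )
            if not 0 <= self.z <= g.gap(k):
                raise OperationError(f"move cut z={self.z} outside [0, {g.gap(k)}]")
        elif self.j == self.k:
            i, k = self.i, self.k
            if not 1 <= i < k <= g.n + 1:
                raise OperationError(f"move regions ({i},{k}) out of range")
            if not 0 <= self.x <= g.gap(i):
                raise OperationError(f"move cut x={self.x} outside [0, {g.gap(i)}]")
            if g.gap(k) < 1 or not 0 <= self.y <= g.gap(k) - 1:
                raise OperationError(f"move cut y={self.y} outside [0, {g.gap(k) - 1}]")
            if not self.y < self.z <= g.gap(k):
                raise OperationError(
                    f"move cut z={self.z} outside ({self.y}, {g.gap(k)}]"
                )
        else:
            raise OperationError("a move requires i == j or j == k")

    @property
    def amount(self) -> int:
        return self.y - self.x if self.i == self.j else self.z - self.y

    @property
    def source_region(self) -> int:
        return self.i if self.i == self.j else self.k

    @property
    def dest_region(self) -> int:
        return self.k if self.i == self.j else self.i

    @property
    def regions(self) -> tuple:
        return (self.i, self.k)


Operation = Union[Reversal, Transposition, Move]
Solution = tuple


def apply_reversal(g: Genome, r: Reversal) -> Genome:
    """Apply a reversal, returning the rewritten genome."""
    r.check(g)
    i, j, x, y = r.i, r.j, r.x, r.y
    xp = g.gap(i) - x
    yp = g.gap(j + 1) - y
    segment = g.genes[i : j + 1][::-1]
    if g.signed:
        segment = tuple(-v for v in segment)
    genes = g.genes[:i] + segment + g.genes[j + 1 :]
    gaps = (
        g.gaps[: i - 1]
        + (x + y,)
        + g.gaps[i:j][::-1]
        + (xp + yp,)
        + g.gaps[j + 1 :]
    )
    return _trusted(genes, gaps, g.signed)


def apply_transposition(g: Genome, t: Transposition) -> Genome:
    """Apply a transposition, returning the rewritten genome."""
    t.check(g)
    i, j, k, x, y, z = t.i, t.j, t.k, t.x, t.y, t.z
    xp = g.gap(i) - x
    yp = g.gap(j) - y
    zp = g.gap(k) - z
    genes = g.genes[:i] + g.genes[j:k] + g.genes[i:j] + g.genes[k:]
    gaps = (
        g.gaps[: i - 1]
        + (x + yp,)
        + g.gaps[j : k - 1]
        + (z + xp,)
        + g.gaps[i : j - 1]
        + (y + zp,)
        + g.gaps[k:]
    )
    return _trusted(genes, gaps, g.signed)


def apply_move(g: Genome, m: Move) -> Genome:
    """Apply an intergenic move; gene order is untouched."""
    m.check(g)
    w = m.amount
    if w <= 0:
        raise OperationError("move must transfer a positive number of nucleotides")
    gaps = list(g.gaps)
    gaps[m.source_region - 1] -= w
    gaps[m.dest_region - 1] += w
    return _trusted(g.genes, tuple(gaps), g.signed)


def apply_operation(g: Genome, op: Operation) -> Genome:
    if isinstance(op, Reversal):
        return apply_reversal(g, op)
    if isinstance(op, Move):
        return apply_move(g, op)
    if isinstance(op, Transposition):
        if op.i == op.j or op.j == op.k:
            raise OperationError("degenerate transposition: use Move")
        return apply_transposition(g, op)
    raise TypeError(f"unknown operation {op!r}")


def apply_solution(g: Genome, solution: Iterable) -> Genome:
    """Apply a sequence of operations left to right.

    Raises :class:`OperationError` annotated with the index of the first
    operation that is invalid against the genome state at its turn.
    """
    current = g
    for idx, op in enumerate(solution):
        try:
            current = apply_operation(current, op)
        except OperationError as exc:
            raise OperationError(f"operation {idx} ({op!r}): {exc}") from exc
    return current


@dataclass(frozen=True)
class Instance:
    """A sorting instance: source genome plus target intergenic sizes.

    The target gene order is always the identity (signed: all orientations
    positive), so the target genome is fully determined by ``target_gaps``.
    """

    source: Genome
    target_gaps: tuple
    signed: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "target_gaps", tuple(int(v) for v in self.target_gaps))
        if self.signed is None:
            object.__setattr__(self, "signed", self.source.signed)
        if self.signed != self.source.signed:
            raise InvalidInstanceError("instance/source signedness mismatch")
        if len(self.target_gaps) != self.source.n + 1:
            raise InvalidInstanceError(
                f"expected {self.source.n + 1} target sizes, got {len(self.target_gaps)}"
            )

    @property
    def n(self) -> int:
        return self.source.n

    def target_genome(self) -> Genome:
        return identity_genome(self.n, self.target_gaps, signed=self.signed)

    def is_sorted(self) -> bool:
        return (
            self.source.is_identity()
            and self.source.gaps == self.target_gaps
        )


def validate_instance(inst: Instance) -> list:
    """Machine-readable reasons why an instance is invalid (empty = valid)."""
    reasons = []
    if any(v < 0 for v in inst.target_gaps):
        reasons.append("negative target intergenic size")
    src_total = inst.source.total_intergenic
    tgt_total = sum(inst.target_gaps)
    if src_total != tgt_total:
        reasons.append(
            f"intergenic nucleotides not conserved: source {src_total} != target {tgt_total}"
        )
    return reasons


def is_valid_instance(inst: Instance) -> bool:
    """True iff the intergenic sums match and structural invariants hold."""
    return not validate_instance(inst)
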