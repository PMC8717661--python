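"""Signed instances via reduction to the unsigned problem.

A signed gene ``+g`` is mapped to the unsigned pair ``(2g - 1, 2g)`` and
``-g`` to ``(2g, 2g - 1)``, with a zero-size intergenic region inserted
inside each pair.  The image instance has size ``2n`` and exactly the same
number of breakpoints (every type-two breakpoint maps to one type-one
breakpoint, and the intra-pair boundaries are adjacencies by construction).

Because the unsigned solvers cut only inside breakpoint regions -- which in
an image all have odd index -- their solutions never split a gene pair and
can be mapped back index-by-index: a reversal ``(i, j)`` becomes
``((i + 1) / 2, j / 2)`` and a (generic) transposition ``(i, j, k)`` becomes
``((i + 1) / 2, (j + 1) / 2, (k + 1) / 2)``, keeping all cut values and the
solution length.  This turns the unsigned 4- and 3-approximations into
signed ones with the same factors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import (
    Genome,
    Instance,
    InvalidInstanceError,
    Move,
    Reversal,
    Transposition,
    validate_instance,
)
from .unsigned import sort_generic_transpositions, sort_reversals_transpositions

__all__ = [
    "SignedMapping",
    "ParityError",
    "to_unsigned",
    "lift_solution",
    "sort_signed_reversals_transpositions",
    "sort_signed_generic_transpositions",
]


class ParityError(RuntimeError):
    """An unsigned operation cuts an intra-pair region and cannot be lifted."""


@dataclass(frozen=True)
class SignedMapping:
    """A signed instance together with its unsigned image.

    Signed position ``p`` corresponds to unsigned positions ``2p - 1`` and
    ``2p``; signed region ``r`` corresponds to unsigned region ``2r - 1``.
    """

    signed_instance: Instance
    image: Instance

    def lift(self, solution) -> tuple:
        return lift_solution(self, solution)


def _map_gaps(gaps) -> tuple:
    out = []
    for idx, g in enumerate(gaps):
        out.append(g)
        if idx < len(gaps) - 1:
            out.append(0)
    return tuple(out)


def to_unsigned(inst: Instance) -> SignedMapping:
    """Map a signed instance to its unsigned image of size ``2n``."""
    if not inst.signed:
        raise InvalidInstanceError("to_unsigned expects a signed instance")
    reasons = validate_instance(inst)
    if reasons:
        raise InvalidInstanceError("; ".join(reasons))
    n = inst.n
    genes = [0]
    for v in inst.source.genes[1:-1]:
        g = abs(v)
        if v > 0:
            genes.extend((2 * g - 1, 2 * g))
        else:
            genes.extend((2 * g, 2 * g - 1))
    genes.append(2 * n + 1)
    image_source = Genome(tuple(genes), _map_gaps(inst.source.gaps), signed=False)
    image = Instance(image_source, _map_gaps(inst.target_gaps))
    return SignedMapping(inst, image)


def _lift_op(op):
    if isinstance(op, Reversal):
        if op.i % 2 == 0 or op.j % 2 == 1:
            raise ParityError(f"reversal {op!r} cuts inside a gene pair")
        return Reversal((op.i + 1) // 2, op.j // 2, op.x, op.y)
    if isinstance(op, (Transposition, Move)):
        if any(v % 2 == 0 for v in (op.i, op.j, op.k)):
            raise ParityError(f"{op!r} cuts inside a gene pair")
        cls = Move if isinstance(op, Move) else Transposition
        return cls(
            (op.i + 1) // 2, (op.j + 1) // 2, (op.k + 1) // 2, op.x, op.y, op.z
        )
    raise TypeError(f"unknown operation {op!r}")


def lift_solution(mapping: SignedMapping, solution) -> tuple:
    """Map an unsigned-image solution back to the signed instance.

    The lifted solution has the same length; a parity violation (an unsigned
    operation cutting an adjacency inside a gene pair) is a hard error.
    """
    return tuple(_lift_op(op) for op in solution)


def sort_signed_reversals_transpositions(inst: Instance, greedy: bool = False) -> tuple:
    """4-approximation for signed instances (reversals and transpositions).

    Solves the unsigned image and lifts the solution; length <= ``4 * b2 / 3``.
    """
    mapping = to_unsigned(inst)
    return mapping.lift(sort_reversals_transpositions(mapping.image, greedy=greedy))


def sort_signed_generic_transpositions(inst: Instance, greedy: bool = False) -> tuple:
    """3-approximation for signed instances (reversals and generic transpositions).

    Solves the unsigned image and lifts the solution; length <= ``b2``.
    """
    mapping = to_unsigned(inst)
    return mapping.lift(sort_generic_transpositions(mapping.image, greedy=greedy))
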