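"""Plain-text formats for instances and solutions.

Instance records (one or more per file) are five lines each::

    signed | unsigned
    n
    pi_1 ... pi_n          (interior elements; signed integers when signed)
    gap_1 ... gap_{n+1}    (source intergenic sizes)
    tgt_1 ... tgt_{n+1}    (target intergenic sizes)

Solutions are one operation per line: ``R i j x y`` for reversals,
``T i j k x y z`` for transpositions and ``M i j k x y z`` for moves; in a
multi-record stream, solutions are separated by a single blank line.
"""

from __future__ import annotations

from typing import Iterable, List, TextIO

from .genome import Genome, Instance, Move, Reversal, Transposition

__all__ = [
    "read_instances",
    "write_instances",
    "read_solutions",
    "write_solutions",
    "format_operation",
    "parse_operation",
]


def _record_lines(handle: TextIO):
    for line in handle:
        line = line.strip()
        if line and not line.startswith("#"):
            yield line


def read_instances(handle: TextIO) -> List[Instance]:
    lines = _record_lines(handle)
    instances = []
    while True:
        try:
            mode = next(lines)
        except StopIteration:
            break
        if mode not in ("signed", "unsigned"):
            raise ValueError(f"expected 'signed' or 'unsigned', got {mode!r}")
        signed = mode == "signed"
        n = int(next(lines))
        interior = [int(v) for v in next(lines).split()]
        gaps = [int(v) for v in next(lines).split()]
        target = [int(v) for v in next(lines).split()]
        if len(interior) != n:
            raise ValueError(f"expected {n} elements, got {len(interior)}")
        genes = (0, *interior, n + 1)
        source = Genome(genes, tuple(gaps), signed=signed)
        instances.append(Instance(source, tuple(target)))
    return instances


def write_instances(handle: TextIO, instances: Iterable[Instance]) -> None:
    for inst in instances:
        handle.write("signed\n" if inst.signed else "unsigned\n")
        handle.write(f"{inst.n}\n")
        handle.write(" ".join(str(v) for v in inst.source.genes[1:-1]) + "\n")
        handle.write(" ".join(str(v) for v in inst.source.gaps) + "\n")
        handle.write(" ".join(str(v) for v in inst.target_gaps) + "\n")


def format_operation(op) -> str:
    if isinstance(op, Reversal):
        return f"R {op.i} {op.j} {op.x} {op.y}"
    if isinstance(op, Move):
        return f"M {op.i} {op.j} {op.k} {op.x} {op.y} {op.z}"
    if isinstance(op, Transposition):
        return f"T {op.i} {op.j} {op.k} {op.x} {op.y} {op.z}"
    raise TypeError(f"unknown operation {op!r}")


def parse_operation(line: str):
    fields = line.split()
    kind, args = fields[0].upper(), [int(v) for v in fields[1:]]
    if kind == "R" and len(args) == 4:
        return Reversal(*args)
    if kind == "T" and len(args) == 6:
        return Transposition(*args)
    if kind == "M" and len(args) == 6:
        return Move(*args)
    raise ValueError(f"malformed operation line: {line!r}")


def read_solutions(handle: TextIO) -> List[tuple]:
    """Read blank-line-separated solutions (a single solution reads as one)."""
    solutions = [[]]
    for raw in handle:
        line = raw.strip()
        if not line:
            if solutions[-1]:
                solutions.append([])
            continue
        if line.startswith("#"):
            continue
        solutions[-1].append(parse_operation(line))
    if not solutions[-1] and len(solutions) > 1:
        solutions.pop()
    return [tuple(s) for s in solutions]


def write_solutions(handle: TextIO, solutions: Iterable) -> None:
    first = True
    for sol in solutions:
        if not first:
            handle.write("\n")
        first = False
        for op in sol:
            handle.write(format_operation(op) + "\n")
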