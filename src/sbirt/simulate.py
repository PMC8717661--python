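"""Seeded instance simulators.

Four protocols are supported, all with the identity as target genome and
intergenic target sizes drawn uniformly from ``[0..100]``:

* ``ds1`` -- unsigned; the source is the target perturbed by ``d`` random
  operations, reversals and transpositions equally likely.
* ``ds2`` -- unsigned; the source gene order and intergenic size list are
  independent random shuffles of the target's, producing instances with many
  breakpoints.
* ``sirit`` -- signed; two-level design (several random targets, several
  instances per target), ``d`` random reversals/transpositions (50/50).
* ``sirgt`` -- signed; like ``sirit`` but with 50% reversals, 40%
  transpositions and 10% intergenic moves.

Operation parameters are drawn uniformly over their valid ranges: positions
uniformly over valid index tuples, then cuts uniformly over the integer
ranges the current region sizes allow.  Since every perturbing operation is
conservative (and shuffling preserves the size multiset), generated
instances are always valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .genome import (
    Genome,
    Instance,
    Move,
    Reversal,
    Transposition,
    apply_operation,
    identity_genome,
)

__all__ = [
    "PROTOCOLS",
    "INTERGENIC_RANGE",
    "DatasetSpec",
    "random_target",
    "random_operation",
    "gen_instance",
    "generate_dataset",
]

PROTOCOLS = ("ds1", "ds2", "sirit", "sirgt")

#: Inclusive range from which target intergenic sizes are drawn.
INTERGENIC_RANGE = (0, 100)

#: Operation-type mixes (reversal, transposition, move) per protocol.
MIXES = {
    "ds1": (0.5, 0.5, 0.0),
    "sirit": (0.5, 0.5, 0.0),
    "sirgt": (0.5, 0.4, 0.1),
}


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of one simulated dataset group."""

    protocol: str
    n: int = 100
    ops: int = 0  # number of perturbing operations d (unused by ds2)
    count: int = 1
    seed: int = 0
    targets: Optional[int] = None  # two-level protocols: number of target genomes

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n < 1 or self.count < 1 or self.ops < 0:
            raise ValueError("n and count must be >= 1, ops >= 0")

    @property
    def signed(self) -> bool:
        return self.protocol in ("sirit", "sirgt")

    @property
    def mix(self) -> tuple:
        return MIXES.get(self.protocol, (0.5, 0.5, 0.0))


def random_target(n: int, rng: np.random.Generator, signed: bool = False) -> Genome:
    """Identity genome with intergenic sizes uniform in ``INTERGENIC_RANGE``."""
    lo, hi = INTERGENIC_RANGE
    gaps = rng.integers(lo, hi + 1, size=n + 1)
    return identity_genome(n, tuple(int(v) for v in gaps), signed=signed)


def _random_reversal(g: Genome, rng: np.random.Generator) -> Reversal:
    n = g.n
    while True:  # uniform over {(i, j): 1 <= i <= j <= n}
        i = int(rng.integers(1, n + 1))
        j = int(rng.integers(1, n + 1))
        if i <= j:
            break
    x = int(rng.integers(0, g.gap(i) + 1))
    y = int(rng.integers(0, g.gap(j + 1) + 1))
    return Reversal(i, j, x, y)


def _random_transposition(g: Genome, rng: np.random.Generator) -> Transposition:
    n = g.n
    i, j, k = sorted(
        int(v) for v in rng.choice(np.arange(1, n + 2), size=3, replace=False)
    )
    x = int(rng.integers(0, g.gap(i) + 1))
    y = int(rng.integers(0, g.gap(j) + 1))
    z = int(rng.integers(0, g.gap(k) + 1))
    return Transposition(i, j, k, x, y, z)


def _random_move(g: Genome, rng: np.random.Generator):
    """A random move, or ``None`` when no region has a nucleotide to spare."""
    n = g.n
    for _ in range(64):
        i, k = sorted(
            int(v) for v in rng.choice(np.arange(1, n + 2), size=2, replace=False)
        )
        forward = bool(rng.integers(0, 2))
        src = i if forward else k
        if g.gap(src) < 1:
            continue
        if forward:
            x = int(rng.integers(0, g.gap(i)))
            y = int(rng.integers(x + 1, g.gap(i) + 1))
            z = int(rng.integers(0, g.gap(k) + 1))
            return Move(i, i, k, x, y, z)
        x = int(rng.integers(0, g.gap(i) + 1))
        y = int(rng.integers(0, g.gap(k)))
        z = int(rng.integers(y + 1, g.gap(k) + 1))
        return Move(i, k, k, x, y, z)
    if g.total_intergenic == 0:
        return None
    sources = [r for r in range(1, n + 2) if g.gap(r) >= 1]
    src = sources[int(rng.integers(0, len(sources)))]
    others = [r for r in range(1, n + 2) if r != src]
    dst = others[int(rng.integers(0, len(others)))]
    y = int(rng.integers(1, g.gap(src) + 1))
    if src < dst:
        return Move(src, src, dst, 0, y, 0)
    return Move(dst, src, src, 0, 0, y)


def random_operation(g: Genome, rng: np.random.Generator, mix=(0.5, 0.5, 0.0)):
    """Draw an operation type from ``mix`` and uniform valid parameters."""
    p_rev, p_trans, p_move = mix
    u = rng.random()
    if u < p_rev:
        return _random_reversal(g, rng)
    if u < p_rev + p_trans or p_move == 0.0:
        return _random_transposition(g, rng)
    op = _random_move(g, rng)
    if op is None:  # genome without nucleotides: fall back to a transposition
        return _random_transposition(g, rng)
    return op


def _perturb(target: Genome, d: int, mix, rng: np.random.Generator) -> Genome:
    g = target
    for _ in range(d):
        g = apply_operation(g, random_operation(g, rng, mix))
    return g


def gen_instance(spec: DatasetSpec, rng: np.random.Generator, target: Optional[Genome] = None) -> Instance:
    """Generate one instance under the given protocol.

    ``target`` lets two-level protocols reuse a target genome across
    instances; when omitted a fresh random target is drawn.
    """
    if target is None:
        target = random_target(spec.n, rng, signed=spec.signed)
    if spec.protocol == "ds2":
        genes = [0] + [int(v) for v in rng.permutation(np.arange(1, spec.n + 1))] + [
            spec.n + 1
        ]
        gaps = tuple(int(v) for v in rng.permutation(np.asarray(target.gaps)))
        source = Genome(tuple(genes), gaps, signed=False)
    else:
        source = _perturb(target, spec.ops, spec.mix, rng)
    return Instance(source, target.gaps)


def generate_dataset(spec: DatasetSpec) -> Iterator[Instance]:
    """Yield ``spec.count`` instances, reproducibly from ``spec.seed``.

    For the two-level signed protocols, ``spec.targets`` target genomes are
    drawn and ``spec.count`` instances are generated from each (total
    ``targets * count``); otherwise each instance gets a fresh target.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.signed and spec.targets:
        for _ in range(spec.targets):
            target = random_target(spec.n, rng, signed=True)
            for _ in range(spec.count):
                yield gen_instance(spec, rng, target=target)
    else:
        for _ in range(spec.count):
            yield gen_instance(spec, rng)
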