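"""Shared hypothesis strategies and plain random builders for tests."""

import numpy as np
from hypothesis import strategies as st

from sbirt.genome import Genome, Instance, Move, Reversal, Transposition


def rand_instance(rng: np.random.Generator, n: int, max_gap: int = 6,
                  signed: bool = False) -> Instance:
    """A valid random instance with small intergenic sizes (plain numpy rng)."""
    interior = [int(v) for v in rng.permutation(np.arange(1, n + 1))]
    if signed:
        signs = rng.choice((-1, 1), size=n)
        interior = [v * int(s) for v, s in zip(interior, signs)]
    gaps = tuple(int(v) for v in rng.integers(0, max_gap + 1, size=n + 1))
    total = sum(gaps)
    cuts = sorted(int(v) for v in rng.integers(0, total + 1, size=n))
    points = [0, *cuts, total]
    target = tuple(points[i + 1] - points[i] for i in range(n + 1))
    return Instance(Genome((0, *interior, n + 1), gaps, signed=signed), target)


@st.composite
def genomes(draw, max_n=7, max_gap=8, signed=None):
    n = draw(st.integers(1, max_n))
    if signed is None:
        signed = draw(st.booleans())
    perm = draw(st.permutations(list(range(1, n + 1))))
    if signed:
        signs = draw(st.lists(st.sampled_from((1, -1)), min_size=n, max_size=n))
        interior = [p * s for p, s in zip(perm, signs)]
    else:
        interior = list(perm)
    gaps = draw(st.lists(st.integers(0, max_gap), min_size=n + 1, max_size=n + 1))
    return Genome((0, *interior, n + 1), tuple(gaps), signed=signed)


@st.composite
def reversals_for(draw, g: Genome) -> Reversal:
    i = draw(st.integers(1, g.n))
    j = draw(st.integers(i, g.n))
    x = draw(st.integers(0, g.gap(i)))
    y = draw(st.integers(0, g.gap(j + 1)))
    return Reversal(i, j, x, y)


@st.composite
def transpositions_for(draw, g: Genome) -> Transposition:
    if g.n < 2:
        raise ValueError("transpositions need n >= 2")
    i = draw(st.integers(1, g.n - 1))
    j = draw(st.integers(i + 1, g.n))
    k = draw(st.integers(j + 1, g.n + 1))
    x = draw(st.integers(0, g.gap(i)))
    y = draw(st.integers(0, g.gap(j)))
    z = draw(st.integers(0, g.gap(k)))
    return Transposition(i, j, k, x, y, z)


@st.composite
def moves_for(draw, g: Genome):
    """A valid move, or None when the genome has no nucleotides."""
    regions = [r for r in range(1, g.n + 2) if g.gap(r) >= 1]
    if not regions:
        return None
    src = draw(st.sampled_from(regions))
    others = [r for r in range(1, g.n + 2) if r != src]
    dst = draw(st.sampled_from(others))
    lo = draw(st.integers(0, g.gap(src) - 1))
    hi = draw(st.integers(lo + 1, g.gap(src)))
    cut = draw(st.integers(0, g.gap(dst)))
    if src < dst:
        return Move(src, src, dst, lo, hi, cut)
    return Move(dst, src, src, cut, lo, hi)


@st.composite
def genome_and_operation(draw, max_n=7, max_gap=8, signed=None, kinds="rtm"):
    g = draw(genomes(max_n=max_n, max_gap=max_gap, signed=signed))
    avail = [k for k in kinds if k != "t" or g.n >= 2]
    kind = draw(st.sampled_from(avail))
    if kind == "r":
        op = draw(reversals_for(g))
    elif kind == "t":
        op = draw(transpositions_for(g))
    else:
        op = draw(moves_for(g))
    return g, op


@st.composite
def instances(draw, max_n=7, max_gap=6, signed=None):
    """A valid instance: random source and a random re-split of its nucleotides."""
    g = draw(genomes(max_n=max_n, max_gap=max_gap, signed=signed))
    total = g.total_intergenic
    cuts = sorted(draw(st.lists(st.integers(0, total), min_size=g.n, max_size=g.n)))
    points = [0, *cuts, total]
    target = tuple(points[i + 1] - points[i] for i in range(g.n + 1))
    return Instance(g, target)
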