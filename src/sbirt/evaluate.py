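"""Solution verification, approximation ratios, an exact BFS oracle and the
experiment harness.

Approximation ratios are reported against the breakpoint lower bound
``ceil(b / 3)`` (``b1`` for unsigned instances, ``b2`` for signed ones), so a
ratio of 1.00 certifies an optimal solution.  The exact oracle does a
breadth-first search over genome states and is only feasible for tiny
instances; a size guard rejects anything larger.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable

import numpy as np
import pandas as pd

from . import signed as signed_mod
from . import unsigned as unsigned_mod
from .breakpoints import lower_bound
from .genome import (
    Genome,
    Instance,
    InvalidInstanceError,
    Move,
    Reversal,
    Transposition,
    apply_operation,
    apply_solution,
    identity_genome,
)
from .simulate import DatasetSpec, generate_dataset

__all__ = [
    "ALGORITHMS",
    "SizeLimitError",
    "solve",
    "verify_solution",
    "approximation_ratio",
    "exact_distance_bfs",
    "distance_table",
    "run_experiment",
]


#: Solver registry: name -> (callable, signed?)
ALGORITHMS = {
    "alg1": (unsigned_mod.sort_reversals_transpositions, False),
    "alg2": (unsigned_mod.sort_generic_transpositions, False),
    "alg3": (signed_mod.sort_signed_reversals_transpositions, True),
    "alg4": (signed_mod.sort_signed_generic_transpositions, True),
}


class SizeLimitError(ValueError):
    """Instance exceeds the exact oracle's search guard."""


def solve(inst: Instance, algorithm: str, greedy: bool = False) -> tuple:
    """Run a registered solver on an instance of matching signedness."""
    fn, needs_signed = ALGORITHMS[algorithm]
    if inst.signed != needs_signed:
        kind = "signed" if needs_signed else "unsigned"
        raise InvalidInstanceError(f"{algorithm} expects a {kind} instance")
    return fn(inst, greedy=greedy)


def verify_solution(inst: Instance, solution) -> bool:
    """True iff applying the solution to the source yields the target genome."""
    final = apply_solution(inst.source, solution)
    return final == inst.target_genome()


def approximation_ratio(inst: Instance, solution) -> float:
    """Solution length over the ``ceil(b / 3)`` lower bound (1.0 if sorted)."""
    if not verify_solution(inst, solution):
        raise ValueError("solution does not sort the instance")
    lb = lower_bound(inst)
    if lb == 0:
        return 1.0  # already sorted, empty solution is optimal
    return len(solution) / lb


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def _enumerate_operations(g: Genome, moves: bool):
    n = g.n
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            for x in range(g.gap(i) + 1):
                for y in range(g.gap(j + 1) + 1):
                    yield Reversal(i, j, x, y)
    for i, j, k in itertools.combinations(range(1, n + 2), 3):
        for x in range(g.gap(i) + 1):
            for y in range(g.gap(j) + 1):
                for z in range(g.gap(k) + 1):
                    yield Transposition(i, j, k, x, y, z)
    if moves:
        for i, k in itertools.combinations(range(1, n + 2), 2):
            for x in range(g.gap(i)):
                for y in range(x + 1, g.gap(i) + 1):
                    for z in range(g.gap(k) + 1):
                        yield Move(i, i, k, x, y, z)
            for y in range(g.gap(k)):
                for z in range(y + 1, g.gap(k) + 1):
                    for x in range(g.gap(i) + 1):
                        yield Move(i, k, k, x, y, z)


def _state(g: Genome):
    return (g.genes, g.gaps)


def _bfs(start: Genome, moves: bool, stop_state=None) -> Dict[tuple, int]:
    dist = {_state(start): 0}
    frontier = [start]
    while frontier:
        nxt = []
        for g in frontier:
            d = dist[_state(g)]
            for op in _enumerate_operations(g, moves):
                h = apply_operation(g, op)
                s = _state(h)
                if s not in dist:
                    dist[s] = d + 1
                    if stop_state is not None and s == stop_state:
                        return dist
                    nxt.append(h)
        frontier = nxt
    return dist


def _guard(n: int, total: int, max_n: int, max_total: int) -> None:
    if n > max_n or total > max_total:
        raise SizeLimitError(
            f"exact search limited to n <= {max_n} and total intergenic "
            f"<= {max_total} (got n={n}, total={total})"
        )


def exact_distance_bfs(inst: Instance, moves: bool = False, max_n: int = 4, max_total: int = 6) -> int:
    """Exact rearrangement distance by breadth-first search (tiny instances).

    ``moves`` selects the generic-transposition alphabet.  The state space is
    every (permutation, gap composition) with the instance's nucleotide
    total, so the guard on ``n`` and the intergenic total is enforced.
    """
    _guard(inst.n, inst.source.total_intergenic, max_n, max_total)
    if inst.is_sorted():
        return 0
    target = _state(inst.target_genome())
    dist = _bfs(inst.source, moves, stop_state=target)
    if target not in dist:
        raise InvalidInstanceError("target unreachable (sums differ?)")
    return dist[target]


def distance_table(n: int, target_gaps, signed: bool = False, moves: bool = False,
                   max_n: int = 4, max_total: int = 8) -> Dict[tuple, int]:
    """Exact distances from *every* genome state to the given target.

    Every operation is invertible by an operation of the same type, so the
    state graph is undirected and one search from the target genome yields
    the distance of all sources sharing its nucleotide total.
    """
    _guard(n, sum(target_gaps), max_n, max_total)
    target = identity_genome(n, target_gaps, signed=signed)
    return _bfs(target, moves)


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------

def _summary(values) -> tuple:
    arr = np.asarray(values, dtype=float)
    return float(arr.min()), float(arr.mean()), float(arr.max())


def run_experiment(
    specs: Iterable[DatasetSpec],
    algorithms: Iterable[str],
    greedy_variants: Iterable[bool] = (False, True),
    verify: bool = True,
) -> pd.DataFrame:
    """Generate each dataset group, solve it with each variant and aggregate.

    Every solution is re-applied and checked against the target before being
    counted; an unverifiable solution aborts the run.  Ratios use the
    ``ceil(b / 3)`` breakpoint lower bound.
    """
    algorithms = list(algorithms)
    greedy_variants = list(greedy_variants)
    rows = []
    for spec in specs:
        instances = list(generate_dataset(spec))
        bounds = [lower_bound(inst) for inst in instances]
        for algorithm in algorithms:
            for greedy in greedy_variants:
                dists, ratios = [], []
                for inst, lb in zip(instances, bounds):
                    sol = solve(inst, algorithm, greedy=greedy)
                    if verify and not verify_solution(inst, sol):
                        raise RuntimeError(
                            f"{algorithm} produced an unverifiable solution"
                        )
                    dists.append(len(sol))
                    ratios.append(len(sol) / max(1, lb))
                dmin, davg, dmax = _summary(dists)
                rmin, ravg, rmax = _summary(ratios)
                rows.append(
                    {
                        "protocol": spec.protocol,
                        "n": spec.n,
                        "ops": spec.ops,
                        "algorithm": algorithm,
                        "greedy": greedy,
                        "count": len(instances),
                        "seed": spec.seed,
                        "dist_min": dmin,
                        "dist_avg": round(davg, 2),
                        "dist_max": dmax,
                        "ratio_min": round(rmin, 2),
                        "ratio_avg": round(ravg, 2),
                        "ratio_max": round(rmax, 2),
                    }
                )
    return pd.DataFrame(rows)
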