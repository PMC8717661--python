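# sbirt — sorting genomes by intergenic reversals and transpositions

`sbirt` estimates the rearrangement distance between two genomes that share
the same set of genes, taking into account both the **gene order** and the
**sizes of the intergenic regions** (the nucleotide stretches between
consecutive genes and at the genome extremities). It is aimed at comparative
genomics work where gene-order-only models are too coarse — for example,
building rearrangement-based distance matrices between bacterial genomes.

## The model

A genome with `n` genes is written as an extended permutation
`π = (π₀ = 0, π₁, …, πₙ, πₙ₊₁ = n+1)` (signed when gene orientation is
known) plus a list `π̆` of `n+1` non-negative integers, where `π̆ᵢ` is the
number of nucleotides immediately left of `πᵢ`. The target genome is the
identity `(ι, ῐ)`, so an instance is the triple `(π, π̆, ῐ)`; it is valid iff
`Σπ̆ = Σῐ` (all operations are conservative). Three operations are allowed:

* **reversal** `ρ⁽ⁱ’ʲ⁾₍ₓ,ᵧ₎` — inverts the segment `πᵢ…πⱼ`, splitting the
  flanking regions at `x` and `y` (flips signs in the signed model);
* **transposition** `τ⁽ⁱ’ʲ’ᵏ⁾₍ₓ,ᵧ,ᵤ₎` — swaps the consecutive segments
  `πᵢ…πⱼ₋₁` and `πⱼ…πₖ₋₁`, cutting three regions;
* **intergenic move** — a degenerate transposition (`i = j` or `j = k`) that
  relocates nucleotides between two regions without moving genes.

A consecutive pair `(πᵢ, πᵢ₊₁)` is a **breakpoint** when the elements are not
consecutive in the target (*soft*) or when they are consecutive but the
region between them has the wrong size (*hard*: *overcharged* with too many
nucleotides, *undercharged* with too few). Since a reversal removes at most
two breakpoints and a (generic) transposition at most three, the distance is
bounded below by `⌈b/3⌉`. The solvers remove breakpoints case by case:

* `sort_reversals_transpositions` (unsigned) emits at most `4·b₁/3`
  operations — a **4-approximation**;
* `sort_generic_transpositions` (unsigned, moves allowed) removes one
  breakpoint per operation — at most `b₁` operations, a **3-approximation**;
* `sort_signed_reversals_transpositions` / `sort_signed_generic_transpositions`
  reduce a signed instance to an unsigned one of size `2n` (each signed gene
  becomes an ordered pair of unsigned elements) and lift the solution back,
  preserving length and the approximation factors.

An optional **greedy layer** first looks for a single operation removing
three (transposition) or two breakpoints, which markedly shortens solutions
in practice without affecting the guarantees. An exact BFS oracle is included
for tiny instances, along with seeded simulators for four dataset protocols
(`ds1`, `ds2`, `sirit`, `sirgt`) and an experiment harness.

## Worked example

The unsigned instance `π = (0 3 2 1 4 5 6 7)`, `π̆ = (4,0,3,0,5,2,0)`,
`ῐ = (1,3,0,3,1,2,4)`:

```python
from sbirt import Genome, Instance, classify_pairs, lower_bound, solve, approximation_ratio
from sbirt.io import format_operation

source = Genome((0, 3, 2, 1, 4, 5, 6, 7), (4, 0, 3, 0, 5, 2, 0))
inst = Instance(source, (1, 3, 0, 3, 1, 2, 4))

report = classify_pairs(inst)
print(f"b1 = {report.b} (hard: {report.b_hard}, soft: {report.b_soft})")
print(f"lower bound = {lower_bound(inst)}")
solution = solve(inst, "alg2", greedy=True)
for op in solution:
    print(format_operation(op))
print(f"distance estimate = {len(solution)}, ratio = {approximation_ratio(inst, solution):.2f}")
```

prints

```
b1 = 4 (hard: 2, soft: 2)
lower bound = 2
R 1 3 1 0
M 5 5 7 0 4 0
distance estimate = 2, ratio = 1.00
```

The instance has four breakpoints, so at least two operations are needed.
The greedy generic-transposition solver finds exactly two: the reversal
`ρ⁽¹’³⁾₍₁,₀₎` straightens the decreasing strip `(3 2 1)` and fixes both soft
breakpoints, and one move shifts the 4-nucleotide excess of the overcharged
region onto the undercharged one. The ratio of 1.00 against the `⌈b₁/3⌉`
lower bound certifies the solution is optimal.

The same is available from the shell:

```sh
sbirt generate --protocol ds1 --n 100 --ops 5 --count 10 --seed 1 --out ds.txt
sbirt solve --algorithm alg2 --greedy --in ds.txt --out sols.txt
sbirt verify --in ds.txt --solution sols.txt
sbirt evaluate --protocol ds1 --n 100 --ops 5 --count 100 --algorithm alg1 --algorithm alg2 --seed 1 --out table.tsv
```

(`alg1`/`alg2` are the unsigned 4- and 3-approximations, `alg3`/`alg4`
their signed counterparts.)

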