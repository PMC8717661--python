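# Methods

## Model and assumptions

`sbirt` models a linear genome as an extended permutation of `{0, …, n+1}`
(sentinels fixed at the ends; signs carried per gene when orientation is
known) together with `n+1` non-negative integer intergenic sizes. Both
genomes must share the same gene set with no duplicated genes, and no
nucleotides are inserted or deleted: every operation — reversal,
transposition, intergenic move — conserves the total intergenic content, so
an instance is valid only when source and target intergenic totals agree.
Circular genomes and gene insertions/deletions are out of scope.

All indices are 1-based, matching the usual notation in the genome
rearrangement literature: region `r` lies immediately left of the element at
position `r`. Operation parameters are validated strictly and rejected when
out of range — never clamped — because the case constructions below depend on
exact cut arithmetic.

## Breakpoints and the lower bound

A consecutive pair is an adjacency when its elements are consecutive in the
target (absolute values for unsigned genomes, signed difference `+1` for
signed ones) *and* the region between them already has its target size;
otherwise it is a breakpoint: *soft* if the order is wrong, *hard*
(overcharged/undercharged) if only the size is wrong. A hard breakpoint is
*super hard* when it sits at an extremity or is flanked by a hard breakpoint
or an adjacency. Two breakpoints are *connected* when some element pair drawn
from them is consecutive in the target, does not already form an adjacency,
and the two breakpoint regions jointly hold at least that pair's target size;
*softly connected* if in addition both are soft.

A reversal touches two region boundaries and a generic transposition three,
so they remove at most 2 and 3 breakpoints respectively; hence
`⌈b/3⌉ ≤ distance`, the denominator used for all reported approximation
ratios. (Ratios for signed instances use `⌈b₂/3⌉`; tighter signed bounds
based on cycle graphs exist in the literature but are not implemented here,
so signed ratios are comparable only against this breakpoint bound.)

## Nucleotide redistribution in two transpositions

Several cases need an arbitrary redistribution of nucleotides across three
regions `i < j < k` without disturbing gene order. One transposition maps
region sizes `(s₁, s₂, s₃)` to `(x + s₂ − y, z + s₁ − x, y + s₃ − z)`; a
target `(a, b, c)` with the same sum is reachable iff `a ≤ s₁+s₂`,
`b ≤ s₁+s₃` and `c ≤ s₂+s₃`, in which case the cuts are the linear solution
`x = max(0, a−s₂, s₁−b)`, `y = x+s₂−a`, `z = b−s₁+x`. The redistribution
plan applies one transposition to an intermediate `(p, q, r)` and a second
(over regions `i, i+k−j, k`) back to the original order with the final sizes.
The intermediate is chosen by greedy water-filling under the combined upper
bounds `p ≤ min(s₁+s₂, a+b)`, `q ≤ min(s₁+s₃, a+c)`, `r ≤ min(s₂+s₃, b+c)`;
a short case analysis shows the three bounds always sum to at least the
total, so the greedy fill never fails. The construction is validated in the
test suite against a brute-force search over all cut choices on small sizes.

## The unsigned solvers

Both solvers loop until no breakpoint remains, recomputing the census each
iteration (`O(n)`); each iteration emits a short fragment:

**Reversal+transposition solver (factor 4).** Dispatch order:
1. *≥ 2 overcharged*: redistribute the combined surplus of the two
   overcharged regions into a third breakpoint region (leftmost soft, else
   leftmost undercharged, else leftmost breakpoint) — 2 transpositions, ≥ 2
   breakpoints removed.
2. *Softly connected pair* `(i, j)` (leftmost): one operation forming an
   adjacency with exactly its target size, feasible by connectivity. The
   pattern decides the operation: ends consecutive (`πᵢ,πⱼ` or
   `πᵢ₊₁,πⱼ₊₁`) → the reversal of `i+1..j`; inner pair (`πᵢ₊₁,πⱼ`)
   → a transposition whose third cut lands on a soft breakpoint between the
   pair, falling back to the single hard breakpoint separating them when
   `j = i+2` (that breakpoint is flanked by two soft ones, hence never super
   hard); outer pair (`πᵢ,πⱼ₊₁`) → a transposition whose third cut is a
   *soft* breakpoint right (preferred) or left of the pair. Restricting the
   third cut to soft breakpoints is what preserves every super hard
   breakpoint: cutting a hard breakpoint's region would separate its
   elements and remove it. A soft third always exists — if every pair outside
   (respectively strictly inside) the pair's span were order-correct, those
   spans would be monotone runs of consecutive values, which contradicts the
   connection pattern.
3. *One overcharged + some undercharged, no softly connected pair*: when the
   two regions hold exactly their combined targets, a double reversal of the
   span between them shuttles the excess across (cut arithmetic clamps to
   whichever side holds the surplus); otherwise the strict surplus goes to a
   third breakpoint region by redistribution — 2 operations, ≥ 2 removed.
4. *One overcharged, nothing undercharged, no softly connected pair*: create
   a hard undercharged breakpoint with one operation — a reversal merging a
   soft pair whose outer (or inner) elements are consecutive, dumping all
   nucleotides of both regions onto the new pair (undercharged precisely
   because the pair was not connected), or, when no such pair exists, a
   cut-free transposition over three soft breakpoints (only-increasing-strips
   situation) that creates a super hard undercharged breakpoint — then
   re-dispatch cases 1–3 until ≥ 2 breakpoints are gone within 3 operations
   or ≥ 3 within 4. The fragment's guarantee is asserted at run time.

Amortized, at most 4 operations per 3 breakpoints → length ≤ `4b₁/3` and,
against the `b₁/3` bound, a 4-approximation.

**Generic-transposition solver (factor 3).** If an overcharged breakpoint
exists, one intergenic move transfers its excess to another breakpoint's
region (an undercharged one missing exactly that amount when available — then
two breakpoints fall — else the leftmost soft, else any breakpoint);
otherwise a softly connected pair must exist and case 2 applies. One
operation per breakpoint → length ≤ `b₁`.

Every emitted operation cuts only inside breakpoint regions, which is the
invariant the signed lifting needs.

## Greedy layer

At the top of each iteration the solver optionally searches, via the inverse
permutation, for a single transposition removing three breakpoints, then for
a reversal or transposition removing two (the generic solver also pairs an
overcharged with an exactly matching undercharged breakpoint by one move).
Candidates cut only breakpoint regions; cut values are forced by the target
sizes and checked with the one-transposition feasibility test above. Ties
break lexicographically on (operation type, positions), reversals before
transpositions before moves. The enumeration is `O(b)` per iteration with
constant-factor value-neighbour lookups, keeping the solvers `O(n²)`
overall. Greedy operations remove ≥ 2 breakpoints each, so the approximation
factors are unaffected.

## Signed instances

Each signed gene `+g` maps to the unsigned pair `(2g−1, 2g)` and `−g` to
`(2g, 2g−1)`, with a zero-size region inside each pair (both in source and
target). Breakpoint counts are preserved exactly, and intra-pair boundaries
are adjacencies whose regions have odd..even parity such that every
breakpoint region of the image has odd index. Because the unsigned solvers
cut only breakpoint regions, their operations map back by halving indices
(`i' = (i+1)/2`, reversal ends `j' = j/2`), keeping all cut values and the
solution length; a parity violation aborts loudly since it would mean a gene
pair was split. Moves lift by the same rule. The factors 4 and 3 carry over
with `b₂` in place of `b₁`.

## Simulators

Four seeded protocols generate study data, all with identity targets and
intergenic sizes uniform on `[0..100]` (integer):

* `ds1` (unsigned): the source is the target perturbed by `d` random
  operations, reversal/transposition equally likely per draw (independent
  coin flips, not an exact split);
* `ds2` (unsigned): gene order and size list are independent uniform
  shuffles of the target's — many breakpoints, near-worst-case inputs;
* `sirit` / `sirgt` (signed): a two-level design — several random targets,
  several instances per target — with `d` operations mixed 50/50
  (reversal/transposition) or 50/40/10 (reversal/transposition/move).

Operation positions are uniform over valid index tuples (rejection sampling
for reversal pairs, sorted distinct draws for transpositions and moves) and
cuts uniform over their valid integer ranges; a move with an empty source
region is re-drawn, falling back to a transposition on an all-zero genome.
Generated instances are valid by construction.

The simulators emulate genomes evolving by conservative rearrangements only.
They do not model gene insertions/deletions, duplicated genes, unequal gene
content, circular chromosomes, or realistic (heavy-tailed) intergenic size
distributions, so passing tests say nothing about those aspects of real
genomes; on real data the pipeline additionally requires orthology pairing
and deletion preprocessing, which are out of scope here.

## Exact oracle

`exact_distance_bfs` does breadth-first search over genome states
(permutation + gap composition) with either operation alphabet. Each
operation is invertible by an operation of the same type, so the state graph
is undirected and `distance_table` computes exact distances from the target
to *every* state of the same nucleotide total with one search — this is what
makes the exhaustive tiny-instance comparisons feasible (all ~98,000
instances with `n ≤ 3` and at most 4 nucleotides, both signednesses). The
state space is exponential, so a guard (default `n ≤ 4`, total ≤ 6–8)
rejects larger inputs.

## Reported statistics and problem sizes

Experiment summaries report min/mean/max solution length and length over
`⌈b/3⌉`, to two decimals, each solution re-applied and verified first. The
acceptance script uses: 1000 `ds1` instances (n = 100, d = 5) for the mean
greedy ratio of the generic solver; 10,000 mixed unsigned instances
(`ds1` n = 50 with d ∈ {5,…,50}, `ds2` n ∈ {25, 50}) for the worst
`3·length/b₁` of both unsigned solvers; and 500 `ds1` instances per
d ∈ {5, 10, …, 100} at n = 100 for the worst greedy ratio — sizes chosen so
a full run stays within a few minutes on one CPU while the sweep still spans
light to saturating perturbation levels. All randomness derives from the
single `--seed` argument through spawned seed sequences.

## Known limitations

* The `⌈b/3⌉` denominator makes signed ratios conservative compared to
  cycle-graph-based bounds; signed distance columns are still comparable.
* The greedy search enumerates all candidate breakpoint pairs/triples, which
  can find slightly shorter solutions than more restrictive greedy variants;
  reported averages may differ within a few percent from implementations
  with different tie-breaking.
* The BFS oracle is exact but only for toy sizes; approximation-factor
  checks at larger sizes rely on the breakpoint lower bound instead.
* Solvers assume valid instances; unequal nucleotide totals are rejected up
  front rather than repaired.
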