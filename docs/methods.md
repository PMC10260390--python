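# Methods

## Problem and objective

Input: a multiset of unrooted 4-leaf topologies (quartets) over a taxon
set, each with a positive weight (frequency for unweighted input).
Output: an unrooted binary tree on all taxa. The implicit objective is
maximum quartet consistency — maximize the total weight of input
quartets whose topology is induced by the output tree. The problem is
NP-hard, so the method is a heuristic; the `oracle` module provides the
exact optimum by exhaustive enumeration for ≤ 8 taxa ((2n−5)!!
topologies, at most 10,395) and is used to bound the heuristic from
above in tests.

## Pipeline

### Frequency counting (`quartet_store`)

Each input record is mapped to a canonical key (pairs sorted
lexicographically, pairs ordered by smaller element), so the 8
encodings of one split collide and the 3 topologies of one 4-subset do
not. Counting is a single hash-map pass; per-taxon *relevant quartet*
lists are built in the same pass. Weights are kept as exact integers
whenever every input weight is integral — this preserves the argument
that each committed refinement pass raises the integer partition score
by ≥ 1 and therefore terminates within m passes. Taxon labels are
restricted to `[A-Za-z0-9_.-]` and the prefix `__D` is reserved for
internally generated dummy taxa, so user labels can never collide with
them.

### Initial bipartition (`bipartition.initial_bipartition`)

Quartets are processed in descending weight, ties broken by canonical
key. The first quartet seeds its left pair LEFT and right pair RIGHT.
For later quartets, already-placed taxa never move; unassigned taxa are
placed so the quartet becomes satisfied if either orientation of the
quartet against the sides permits it (the orientation putting the
left pair LEFT is tried first); when neither does, its unassigned taxa
go to the currently smaller side (ties LEFT). Taxa not covered by any
quartet are finally distributed alternately starting with the smaller
side. These placement rules are this package's own deterministic
choice; published descriptions of frequency-ordered seeding leave the
unsatisfiable case open.

### FM refinement (`bipartition.mfm_bipartition`)

Classic Fiduccia–Mattheyses pass structure adapted to the quartet
score. Each outer pass: reset every taxon to FREE, compute quartet
statuses, the satisfied/violated/deferred weights (s, v, d) and each
taxon's gain (score change if it alone switched sides); then repeatedly
move the maximum-gain *eligible* free taxon, lock it, log
`(taxon, gain)`, and update s/v/d and the gains of free taxa — only
over the moved taxon's relevant quartets. After the pass, the shortest
move prefix with maximum cumulative gain (MCGain) is found; if
MCGain > 0 the pass is rolled back to that prefix and committed,
otherwise every move is undone and the pre-pass state is returned.

Numerical and tie-break choices:

* Max-gain ties and best-prefix ties go to the lexicographically
  smallest taxon label / smallest prefix index. Taxon "indices" are
  assigned in sorted-label order, so label order and index order agree.
* A free taxon whose side has exactly one member is ineligible to
  move — this keeps both sides non-empty (classical FM uses a balance
  constraint instead; the quartet formulation never defines one).
* Deferred quartets contribute 0 to score and enter gains only through
  status transitions (a flip can turn DEFERRED into SATISFIED/VIOLATED
  and vice versa).
* With non-integer weights, committing requires MCGain > 1e−9 and a
  hard cap of max(1000, ⌈total weight⌉) outer passes applies (the ≤ m
  termination argument needs integer scores); exceeding the cap raises
  a diagnostic error carrying the best state found.
* Locked statuses do not persist across passes: every pass starts with
  all taxa FREE, per the pass-reset reading of the algorithm.

### Routing and recursion (`puzzle`)

Quartets with a 4-0 side assignment pass unchanged into that child;
3-1 quartets have the deserted taxon replaced by the level's dummy
taxon and follow the other three; 2-2 quartets (satisfied or violated)
are consumed — after substitution they would retain at most two real
taxa, so no 4-leaf topology survives. Violated 2-2 quartets are thus
consumed rather than dummy-modified; the alternative reading (modifying
them) leaves no well-defined 4-leaf topology to route, so consumption
is the design choice here. Weight is conserved exactly:
weight(Q_l) + weight(Q_r) + consumed = weight(Q) at every level.

Dummy labels are `__D<depth>_<serial>` with a run-global serial, so a
parent's dummy can be an ordinary taxon in any child without collision.
Recursion bottoms out at ≤ 3 taxa (star/edge/leaf). Children receive
P_side ∪ {dummy}; subtrees are merged by deleting the dummy leaf from
both and joining the attachment points with one edge, suppressing
degree-2 relics, so binary children merge into a binary tree.

**Termination guard.** An (n−1, 1) bipartition would make the big child
(big side + dummy) as large as its parent, so the recursion would not
shrink. When a side ends with exactly one taxon, the maximum-gain taxon
(ties: smallest label) of the big side is moved over, giving (n−2, 2)
and two strictly smaller children. This guard is an addition beyond the
published description, which only guards against empty sides.

### Variants

`fi` (default): at every divide step, dummy-modified quartets that
become topologically identical are merged with summed frequencies, and
each child's quartet list is re-sorted by weight. `f`: duplicates stay
unmerged and children inherit their parent's processing order (sorting
happens only at the top level). The two differ only in the processing
order seen by the initial bipartition — scores are sums either way —
but that order changes the greedy seeding and hence the search
trajectory. The directional expectation (fi at least as good as f on
average) is asserted over 50 noisy 20-taxon instances; on that stated
world the means are nearly equal (the margin at 25-taxon scale in the
original study is likewise small).

## Synthetic data (`simulate`)

`random_binary_tree(n, seed)` grows an unrooted binary tree by uniform
random edge attachment (Yule-like), labels `T1..Tn`. It stands in for
clock-based model-tree simulators; it reproduces the only property the
pipeline consumes — a random binary topology — and does not model
branch lengths, clock structure, or taxon sampling biases.

`sample_quartet_set(tree, SimConfig(n, k, c, seed))` draws
m = round(n^k) records: a uniform random 4-subset per record (with
replacement across records, so duplicates exercise frequency counting);
with probability `c` the record carries the tree-induced topology,
otherwise one of the two alternative splits uniformly. `c` is therefore
exactly the expected agreement fraction, and the calibration test
checks the empirical fraction against a 99% binomial band. Defaults in
the CLI are n = 25, k = 2, c = 1.0 — the smallest taxon count and the
middle quartet-count exponent of the standard simulation grid
(n from 25 up, k ∈ {1.5, 2, 2.8}, c ∈ {0.7 .. 1.0}). Where a test
needs an unstated m at n = 20, k = 2 (m = 400) is used. This noise
model is an independent-error model: it does not emulate the correlated
discordance of real gene trees (ILS produces topologically clustered
errors), so a green recovery test establishes robustness to independent
quartet noise only.

`decompose_gene_trees` enumerates every 4-subset of every gene tree
(incomplete leaf sets allowed; star restrictions from polytomies are
skipped) and optionally merges records into frequency weights — the
convention used when feeding gene-tree data to weighted amalgamation.
Induced topologies are computed with the four-point condition on
unit-edge path lengths.

## Evaluation (`treekit`)

nRF = |splits(T1) Δ splits(T2)| / (2(n−3)), the symmetric split
difference normalized by the binary-tree maximum. Non-binary inputs are
allowed and simply contribute fewer splits; 0 means topologically
identical split sets. Newick parsing is delegated to DendroPy; rooted
inputs are silently unrooted and branch lengths/support values dropped.
Serialization is deterministic (children ordered by smallest contained
leaf), so identical topologies print identically.

## Degenerate inputs and edge cases

* Empty record list → empty store (n = 0); the pipeline requires ≥ 4
  distinct taxa.
* Mixed weighted/unweighted lines in one quartet file are rejected as
  ambiguous.
* A store whose quartets do not cover all requested taxa still assigns
  every taxon (alternating fill), and base cases fire for ≤ 3 taxa even
  with an empty child store.
* Unweighted file output requires integer weights (each key is written
  weight-many times), keeping write→read→count an exact round trip.

## Known limitations

* The FM inner loop selects the max-gain taxon by linear scan rather
  than the classical gain-bucket structure; per-level cost is
  O(n² + m), fine for desk-scale n (thousands) but not for the
  billion-quartet regime.
* Quartet files with branch lengths or support values, and streaming
  out-of-core quartet storage, are out of scope.
* The heuristic has no optimality guarantee; tests bound it by the
  exhaustive oracle only for n ≤ 8.
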