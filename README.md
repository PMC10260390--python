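# quartetfm

Species-tree estimation by **quartet amalgamation**: given a set of
unrooted 4-leaf topologies (*quartets*, written `a,b|c,d`), optionally
weighted by frequency, reconstruct a species tree on the full taxon set
that agrees with as much quartet weight as possible.

Quartet-based summary methods are a standard route to species trees
under gene-tree discordance (e.g. incomplete lineage sorting): gene
trees are decomposed into quartets, whose frequencies carry the
phylogenetic signal, and the quartets are amalgamated into a single
tree. `quartetfm` implements the amalgamation step for workflows where
the quartets come from gene trees, from SVD-style site-pattern methods,
or from any other upstream source.

## Method

The core is a recursive divide-and-conquer over the taxon set *P* with
quartet set *Q* (|P| = n, |Q| = m):

1. **Bipartition** *P* into (*P_l*, *P_r*). Relative to a bipartition a
   quartet `a,b|c,d` is *satisfied* (the pairs {a,b} and {c,d} occupy
   opposite sides), *violated* (a 2-2 split crossing the pairs), or
   *deferred* (≥ 3 taxa on one side). The partition score is
   `s − v` (satisfied minus violated weight). An initial greedy
   bipartition seeds the sides from the quartets in descending weight
   order; a Fiduccia–Mattheyses refinement then repeatedly moves the
   maximum-gain free taxon, locks it, logs `(taxon, gain)`, and at the
   end of each pass rolls back to the move prefix with maximum
   cumulative gain (MCGain), iterating while MCGain > 0. Hash-indexed
   *relevant quartet* lists make each gain update O(1) per affected
   quartet, and with integer weights the pass count is bounded by m.
2. **Route** every quartet into the child problems: 4-0 quartets pass
   unchanged, 3-1 quartets have their lone (*deserted*) taxon replaced
   by a fresh *dummy taxon* and follow their three taxa, 2-2 quartets
   are consumed. The dummy joins both children's taxon sets.
3. **Recurse** until ≤ 3 taxa remain (a star), then **merge** sibling
   subtrees by deleting the dummy leaf from each and joining the
   attachment points with an edge.

Two variants are exposed: the default `fi` merges dummy-modified
quartets that become topologically identical (summing frequencies) and
re-sorts each child's quartets by weight at every divide step; `f`
keeps duplicates unmerged and sorts only once at the top, reproducing
the older behavior. See `docs/methods.md` for the full model,
parameter, and design discussion.

## Worked example

Simulate a 10-taxon model tree with m = 10² = 100 quartets at 90%
consistency, amalgamate them, and evaluate:

```sh
$ quartetfm simulate --n 10 --k 2 --c 0.9 --seed 1 \
      --tree-out model.nwk --quartets-out quartets.txt
$ quartetfm amalgamate quartets.txt estimate.nwk
$ quartetfm rf model.nwk estimate.nwk
0.0
$ quartetfm score estimate.nwk quartets.txt
satisfied=87 violated=13 deferred=0 total=100
```

The estimated tree is topologically identical to the model tree
(normalized Robinson–Foulds distance 0.0) even though 13 of the 100
input quartets disagreed with the model tree — exactly the noise level
the consistency parameter `c = 0.9` injected (the sampler drew 87
agreeing quartets here).

The same operations are available as library functions:

```python
from quartetfm import run_pipeline, read_quartet_file, nrf
tree = run_pipeline(read_quartet_file("quartets.txt"))
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline desk-scale claim from
scratch: it draws a random binary 25-taxon model tree, enumerates all
C(25,4) = 12,650 induced quartets (a fully consistent, noiseless set),
runs the full amalgamation pipeline, and reports the normalized
Robinson–Foulds distance between the estimate and the model tree:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
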