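# Methods

## The morphing model

`molmorph` searches chemical space for a connected path between a start
molecule M_S and a target molecule M_T.  Chemical space is discretised by a
set of elementary graph edits ("morphing operators"); two molecules are
neighbours when one operator application maps one onto the other.  The search
is an iterative, fingerprint-guided stochastic beam:

1. every candidate molecule of the current generation spawns a batch of
   one-edit products (morphs);
2. morphs violating the molecular-weight cap or the synthetic-accessibility
   threshold are discarded;
3. survivors are scored by distance to M_T — one minus the fingerprint
   similarity, by default Morgan (circular, radius 2, 2048 bits) with the
   Tanimoto coefficient;
4. scored morphs are sorted (ascending distance, ties broken by canonical
   SMILES) and accepted into the next generation by rank: the best K
   unconditionally, rank r > K with probability exp(−λ·(r−K)/K), stopping at
   a hard cap;
5. the run ends when an accepted morph's canonical SMILES equals the
   target's (complete path), when no candidate admits any edit (dead), or at
   the iteration cap (partial path to the closest molecule reached).

Molecule identity is canonical-SMILES equality throughout: deduplication,
target detection and the tabu set all use it, so fingerprint collisions can
never cause a false "target found".

### Operators

Operators act on the kekulized heavy-atom graph; hydrogens are implicit and
re-derived after each edit, and products must satisfy standard valences and
stay connected.  The inventory and its site semantics are this package's
reconstruction of the classical morphing edit set:

| code | edit | sites |
|------|------|-------|
| AA | add atom | any atom with free valence × palette element; new single bond |
| RA | remove atom | degree-1 atoms (connectivity guaranteed) |
| AB | add bond | unbonded pair with free valence → single bond; bonded pair → order + 1 (max triple) |
| RB | remove bond | order ≥ 2 → decrement; order-1 ring bond → delete (a cycle edge never disconnects) |
| MA | mutate atom | element swap where the new element's max valence covers the atom's bond-order sum |
| BR | bond reroute | detach one end of a bond, reattach to another free-valence atom on the connected side, keeping bond order |
| BC | bond contraction | delete a degree-2 atom whose neighbours are not bonded; neighbours gain a single bond |
| IA | interlay atom | insert a palette atom into a single bond (disabled by default) |

Free valence is the implicit hydrogen count, which handles hypervalent
sulfur and charged centres uniformly (charged atoms simply expose no free
valence and are not mutated).  IA is restricted to single bonds so BC↔IA is
an exact inverse pair; AA↔RA and AB↔RB are inverse pairs by construction.
BR is the single edit that preserves both the molecular formula and the bond
multiset, so on symmetric molecules a reroute can reproduce the parent; BR
sites are therefore verified by application during enumeration and
symmetry no-ops dropped.

The element palette defaults to the elements of the target molecule plus
carbon, steering mutation chemistry toward the target composition without a
hand-tuned pool.

### Batch generation semantics

`generate_morphs(parent, n_gen, …)` enumerates all applicable
(operator, site) pairs.  When the batch size `n_gen` is at least that count
the batch is exhaustive — every distinct one-edit product is produced;
otherwise `n_gen` draws are sampled, operator uniform over the enabled kinds
with sites, then site uniform within the operator.  The exhaustive regime
gives a useful determinism guarantee: a target one edit away from a parent is
found in the next iteration with certainty whenever `n_gen` covers the
parent's site count.

### Generations, idleness and pruning

The next generation is the set of newly accepted morphs **plus** the current
candidates that produced no accepted child; those carried candidates age by
one idle iteration each time.  A candidate that did produce an accepted
child retires in favour of its children.  Once a non-root molecule has been
idle for `idle_threshold` iterations it is discarded with its whole subtree —
unless it lies on the lineage of the current best (minimum-distance)
molecule, which is always protected, as is the root.  Discarded molecules
enter a tabu set and are never re-accepted, which prevents cycling.  When an
accepted child improves on its parent's distance, the idle counters of the
entire improving lineage are reset (a full reset, this package's choice among
the plausible damping schemes).

### Decoys

With user-supplied decoy molecules the score of a morph becomes the average
of its distance to the target and its distance to the *closest* decoy,
pulling the search through regions near the decoys rather than along the
most direct route.  Since only half the score is the decoy term, adding a
decoy can never shift a distance by more than 0.5.

## Filters

* Molecular weight: morphs above `mw_limit` (default 500 Da) are rejected,
  keeping products lead-like and bounding molecule growth.
* Synthetic accessibility: the fragment-contribution + complexity-penalty
  SAScore on the 1 (easy) … 10 (hard) scale, computed with RDKit's published
  implementation and fragment-frequency table.  Morphs scoring above
  `sa_threshold` (default 6.0, the conventional hard-to-make boundary; the
  cut-off is configurable) are rejected.  The filter can be switched off.

Weight is checked before SAScore because it is far cheaper; the survivor set
does not depend on the order.

## Selection parameters

Defaults: `n_gen_per_parent` 80, `accept_best` (K) 50, `accept_cap` 150,
decay λ 1.0, `idle_threshold` 5, `max_iterations` 1000.  The rank-based
acceptance probability exp(−λ·(r−K)/K) is scale-free in the distance values
(only the ordering matters) and reduces to deterministic top-K selection as
λ → ∞; λ = 0 accepts every rank up to the cap.  All randomness flows through
a single seeded NumPy generator, so a fixed seed reproduces a run bit for
bit in single-worker mode.

## Layouts

PCA treats fingerprint bits as 0/1 reals, mean-centres and projects on the
top-2 principal directions; each axis's sign is fixed by making its
largest-magnitude loading positive so the output is deterministic.  The
stress layout minimises E = Σ_{i<j} (1/d_ij²)(‖x_i−x_j‖ − d_ij)² by
node-wise damped-Newton relaxation (the classical Kamada–Kawai scheme) from
a seeded random start, accepting only energy-decreasing moves; d_ij is the
fingerprint distance between molecules, not a graph shortest path.
Duplicate molecules (d_ij = 0) are coalesced before layout.  Termination:
`max_iters` node updates or a full pass improving the energy by less than
`tol` (default 1e-9).

## Synthetic data

The pair generators define the test conditions:

* `make_synthetic_pair(seed_mol, k)` applies k random valid edits and
  returns start, target and the operator trace, so the true minimum path
  length is bounded by k and convergence can be asserted.
* `make_band_pairs(band, n)` random-walks away from a drug-like seed
  molecule until the Morgan/Tanimoto similarity between walk endpoint and
  start falls inside the requested band — 70–80%, 50–60% or 30–40%,
  emulating similarity-tiered benchmark sets.  Steps that drop the running
  similarity by more than 0.3 are rejected, so band membership reflects
  cumulative divergence over several edits rather than one drastic edit
  (e.g. a ring opening); the far band genuinely lies more operator
  applications away.  On the 8–21 heavy-atom seed pool a single edit moves
  Morgan/Tanimoto similarity by ~0.4–0.7 on average (small molecules share
  few unchanged environments), which is why the cap is 0.3 and not smaller.

What the generators do not emulate: real benchmark pairs are independently
chosen bioactive compounds, typically larger (drug-sized), whose similarity
is measured with structural-key fingerprints, and whose true edit distance is
unknown and much larger than here.  Passing the synthetic tests shows the
engine recovers paths whose existence is guaranteed and that difficulty
scales with start/target separation; it does not certify absolute iteration
counts on real pairs.

## Problem sizes used in tests and the acceptance script

The full benchmark protocol (tiered 20-pair sets × 5 repetitions × two
filter settings at defaults) is hours of single-core compute and is exposed
as the `molmorph benchmark` command rather than run in the test suite.  The
shipped tests and `scripts/acceptance.py` use a scaled-down surrogate chosen
as this package's standard smoke protocol: 10 pairs per similarity band, one
run per pair, a lean configuration (`n_gen_per_parent` 12, K 6, cap 18,
SA filter off — the "synthesizability off" arm), iteration cap 1000; and for
known-edit-distance pairs (k ≤ 3) 10–20 seeded runs with `n_gen_per_parent`
60, K 20, cap 40.  Under these conditions the band medians are single-digit
to low-double-digit and strictly ordered near < mid < far, and k ≤ 3 pairs
are recovered in ≥ 90% of runs within 50 iterations.

## Numerical choices and degenerate inputs

* Ties in distance are always broken lexicographically by canonical SMILES;
  the only random stream is the seeded generator.
* Tanimoto/Dice/Cosine on two all-zero fingerprints are defined as 1
  (identical empty environments); Cosine with exactly one empty vector is 0.
* start = target returns a trivially complete one-molecule path, not an
  error.
* A molecule admitting no edit (e.g. methane under {RA}) yields a failure
  value from `random_morph` and a dead search, never an exception.
* All-identical fingerprints give a PCA layout collapsed at the origin.

## Known limitations

* Stereochemistry and tautomers are outside the identity model; operators
  act on constitution only.
* RA removes only degree-1 atoms; interior deletions happen via BC.  Ring
  addition/removal as single coarse operators is not provided.
* The candidate-generation flow is generational (accepted morphs plus
  childless carried parents), not a global all-leaves frontier; with very
  small caps the search can die even though unexplored leaves remain in the
  tree.
* Morph generation is single-threaded; seeded determinism is guaranteed in
  this mode.
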