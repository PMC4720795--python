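# Methods

## Problem setting

Given *n* curated gene sets from several species and a homology table, the
package asks which genes recur across the most independent lines of
evidence, and how the sets themselves cluster by shared content. Both
questions are answered on a single structure: the bipartite incidence graph
between homology clusters and gene sets.

## Harmonization

Members are replaced by homology-cluster ids keyed on `(species, gene_id)`.
Two deliberate choices:

* **Unmapped genes become singleton clusters** (`solo:<species>:<gene_id>`)
  instead of being discarded. Dropping them would silently delete
  within-species intersections wherever homology coverage is incomplete;
  keeping them inflates nothing, since a singleton cluster can never gain
  cross-species degree. `unmapped_count` reports how often this happened.
* **No alias resolution.** Identifiers are case-sensitive and only
  whitespace-trimmed; translating between symbol conventions is the
  homology table's job, not the parser's.

Tier (provenance grade I–V) and the optional platform `universe` are
carried as metadata only; the library never filters on them.

## Maximal bicliques via closure

The set-groups of maximal bicliques (with non-empty gene side) are exactly
the closed set-groups — collections *T* equal to the set of all sets
containing ∩*T*. Every such *T* is an intersection of per-gene
memberships ("intents"), and every non-empty intersection of intents is
closed, so the enumerator simply closes the distinct gene intents under
pairwise intersection. Set-groups are packed into integer bitmasks, making
intersection and subset tests single-word operations; on the default
32-set synthetic corpus (~550 concepts) enumeration takes well under
0.1 s. Correctness is defined by an exhaustive oracle (`brute_force_bicliques`,
capped at 20 sets) that iterates the full power set and applies the closure
test; the two paths are compared on hundreds of random instances.

## Hierarchy construction

Nodes are the closed set-groups with non-empty intersection **plus a forced
terminal for every individual set**, even when its singleton group is not
closed (a set wholly contained in another). Without the forcing, such sets
would vanish from the display; with closure required for non-singleton
nodes, no two nodes can carry identical (closure, payload) content. Edges
are the cover relation of strict signature containment, computed by a
largest-first scan that keeps only maximal proper subsets; the result is
checked in the tests against a networkx transitive-reduction oracle. Node
and edge order is deterministic: level descending, then lexicographic
signature.

Cohesiveness is summarized against `2**n - n - 1` possible multi-set
combinations (all subsets of size ≥ 2). The reported counts are the
populated level-≥2 nodes and those whose payload exceeds `min_genes`
(default 2) genes.

## Bootstrap consensus

Defaults: fraction 0.75, 1000 iterations, retention threshold 0.50,
sampling **with replacement** followed by deduplication, i.e. drawing
⌈0.75·|s|⌉ times from each set *s*. A without-replacement mode is provided
because either reading of "sampling 75% of members" is defensible; with
fraction 1 and no replacement the procedure reduces to the identity and
must reproduce the full hierarchy exactly, which is asserted in the tests.

Node and edge identity across iterations is the set-group signature: gene
payloads fluctuate under resampling, but which combination of sets a node
represents is stable. Edge presence is counted raw (not conditioned on
both endpoints existing in that iteration). Retention keeps nodes with
frequency strictly above the threshold and edges whose frequency passes
*and* whose endpoints are retained; no Hasse re-reduction is applied after
pruning, because re-reduction could re-admit an edge when an intermediate
node drops out and would break the monotonicity guarantee (raising the
retention threshold never adds anything). Each retained edge is still a
cover edge of every bootstrap hierarchy it was counted in.

Randomness: one root `SeedSequence`, one spawned substream per iteration.
Growing the iteration count therefore extends, rather than reshuffles, the
sequence of resamples.

## Set algebra and emphasis genes

`threshold k` keeps genes in **at least** k inputs, so k=1 is the union
and k=|inputs| the intersection — the boundary identities are property-
tested. The "known genes" emphasis list is the harmonized union of the
curated input sets; emphasis marking flags every hierarchy node whose
payload meets the list, and the depth profile reports how far up the
hierarchy flagged nodes reach. Because "known" is evaluated on cluster
ids, a human annotation marks the mouse ortholog as known too.

## Prioritization

Ranking is by degree descending, ties by species coverage descending
(cross-species recurrence is stronger evidence than within-species
repetition), then lexicographic id; the tie-break is a package convention,
chosen so output is total and reproducible. `fraction_of_sets` is
degree / number of set vertices. The novel-gene report lists the top-k
records with `known=False`; an all-known corpus yields an explicitly
flagged empty report rather than an error.

## Synthetic corpus generator

The generator emulates the statistical shape of a curated multi-species
corpus at desk scale; its defaults are the package's reference study
conditions:

| parameter | default | rationale |
|---|---|---|
| species | 5 | fly, zebrafish, human, mouse, rat panel |
| sets | 32 | a realistic curated-query yield |
| homology clusters | 800 | desk-scale pool (≈1/8 of a full corpus) |
| set sizes | lognormal(μ=3.3, σ=0.9), clipped ≥ 2 | heavy tail typical of expression/QTL candidate lists; mean ≈ 40 gives ≈ 1300 membership edges |
| species coverage | anchor species always; others p = 0.26 | ≈ 2 genes per cluster across 5 species, matching partial-homology corpora |
| planted genes | 6 at degree 9/32 ≈ 28% | recurrent cross-species signal, inserted into sets spanning ≥ 4 species |
| known list | all planted but one, + 50 background clusters | the withheld gene is the designated novel candidate |
| strict_separation | on | background cluster reuse capped at degree 8, so planted degree 9 is strictly separated |

Planted clusters are made fully covered across species (conserved genes)
and are excluded from the background pools, so their realized degree is
exact. Insertion is post-hoc into chosen sets rather than via a shared
pathway model — sufficient for exercising degree-based discovery, which is
what the pipeline measures.

What the generator does **not** emulate: co-expression structure,
ontology-driven correlation between sets, identifier noise, or any
depth-profile separation between known and novel genes (the background
sample of known genes is uniform). Passing tests therefore demonstrate
algorithmic correctness and closed-loop recovery of a planted degree
signal, not performance on the idiosyncrasies of real curated corpora.

## Problem sizes

The test suite and the acceptance script run everything at the generator's
default scale: 32 sets / 800-cluster pool, 200–1000 bootstrap iterations,
oracle comparisons on 200 random instances of ≤ 12 sets × ≤ 30 genes, and
planted-recovery sweeps over 25–100 seeds. These sizes keep a full run in
minutes on one core while leaving every code path exercised at the same
ratios (planted degree 9/32, 75%/50% bootstrap) the method is designed
around.

## Numerical and degenerate-input conventions

* Resample size is ⌈fraction·|s|⌉; a resampled-empty set keeps a flagged
  terminal node with an empty payload and can never join a combination.
* A single-set corpus yields a one-terminal hierarchy and zero possible
  combinations; cohesiveness ratios are defined as 0 in that case.
* All exports (GraphML via networkx, a hand-emitted DOT dialect, a JSON
  dialect with a loader) sort elements, so equal inputs give byte-equal
  files; emphasis status is carried as a node attribute (`color`:
  blue/white), not styling.
* The default gene-degree threshold of the exported gene-set graph view is
  2 (drop the degree-1 tail, which dominates vertex count but carries no
  intersection signal); it is a parameter everywhere.

## Known limitations

* Enumeration is exact and single-threaded; corpora with hundreds of
  strongly overlapping sets would need the concept count, not the set
  count, to stay manageable.
* The bootstrap treats sets independently; correlated curation (the same
  lab submitting near-duplicate sets) is visible in the hierarchy but not
  modeled in the resampling.
* No statistical significance is attached to degree ranks; the output is a
  prioritization, not a hypothesis test.
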