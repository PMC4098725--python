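# Methods

## Model

The package detects protein complexes conserved between two species
S₁ and S₂ from three inputs: a PPI network per species (undirected
simple graphs G₁, G₂ with reliability weights in (0, 1]) and an
ortholog-group mapping. A group is a set of proteins across the two
species deemed homologous by sequence and/or shared functional
domains; several members per species (paralogs) make the induced
protein-level correspondence θ many-to-many, and groups with members
in one species only are retained as paralog groups.

**Interolog network.** Nodes are θ-pairs (p, q); an edge joins
(p, q) and (r, s) when (p, r) ∈ E₁ *and* (q, s) ∈ E₂, i.e. the
interaction is conserved in both species. When one protein maps to
several counterparts, all pairs become nodes and *shared-protein*
edges (weight 1.0) join nodes that reuse a protein of either species,
wiring paralog duplicates into one neighborhood. Conserved edges are
weighted by the product of the two source-edge weights: the product
stays in (0, 1] and penalizes pairs that are unreliable in both
species. Node set restriction (θ-pairs must occur in the respective
networks) and pruning of degree-0 nodes are both on by default and
individually switchable.

Rationale for the symmetric shared-protein rule: paralog expansions
occur in both species (1-to-many groups exist in each direction), so
the rule is applied for a shared protein of either species rather
than one fixed side; a flag removes these edges entirely. During
clustering, shared-protein and conserved edges are treated
identically — provenance tags are kept on every edge so callers can
drop one class (`InterologNetwork.without_shared_protein_edges`).

**Conserved subnetwork.** The subgraph of one species' network
restricted to edges (p, r) for which some counterpart pair
(q, s) ∈ θ(p) × θ(r) interacts in the other species. Its edge set
equals the side-projection of the interolog network's conserved
edges (a cross-operation invariant the tests enforce).

## Clustering engines

**CMC-style clique merging.** Maximal cliques (exact enumeration via
networkx) of size ≥ `min_size` are ranked by weighted density (sum of
internal edge weights over node pairs), ties broken lexicographically.
Scanning in rank order, a lower-ranked clique B overlapping the
current cluster A by |A ∩ B| / |B| ≥ `overlap_threshold` is merged
into A when the inter-connectivity — mean edge weight between B \ A
and A over all cross pairs — reaches `merge_threshold`, and is
discarded otherwise. Defaults: min_size 4, overlap 0.5, merge 0.25.
The size floor of 4 matches the convention of evaluating complexes
with more than three subunits.

**MCL.** The adjacency matrix plus self-loops (weight 1.0) is column
normalized, then expansion (matrix power, 2) and inflation (entrywise
power 2.0 with renormalization) alternate, pruning entries below
1e-5, until the maximum entrywise change falls below 1e-6 (cap 200
iterations, warning on non-convergence). Clusters are read as
connected components of the limit matrix's support — the attractor
basins — giving a partition of the nodes; clusters under `min_size`
are dropped from the reported set. A fully pruned column is restarted
at its own node, which keeps every column stochastic (the tests check
column sums to ±1e-9 after every round). Dense numpy arrays are used:
the intended regime is networks of at most a few thousand nodes.

**Edge re-weighting (optional preprocessing).** Iterated
Czekanowski–Dice neighborhood similarity: round k scores edge (u, v)
as Σ_{x ∈ N[u] ∩ N[v]} (w_{k−1}(x,u) + w_{k−1}(x,v)) divided by
(λ_u + S_u + λ_v + S_v), with closed neighborhoods N[·],
S_u = Σ_{x ∈ N[u]} w_{k−1}(x, u), w(u, u) ≡ 1, and
λ_u = max(0, mean(S) − S_u) penalizing sparsely connected nodes.
Default 2 iterations; weights stay in (0, 1], and two nodes with
identical closed neighborhoods and at-least-average connectivity
score 1.0. Off by default (`score_edges_iterations = 0`).

## Conservation scores and evaluation

For complex pair (C₁, C₂), let I_Ci(g) be the number of members of Ci
in group g (a member of k groups counts once per group). The multiset
Jaccard is MSJ = Σ_g min(I_C1, I_C2) / Σ_g max(I_C1, I_C2) over the
union of groups; the plain group Jaccard ignores multiplicity.
Members belonging to no group enter as species-private groups —
multiplicity in the max sum only (MSJ), or extra union elements
(plain) — so unmapped proteins dilute rather than inflate
conservation. This treatment of unmapped members is an
interpretation; `ignore_ungrouped=True` switches it off.

The gold standard keeps all cross-catalog pairs with both sizes
≥ 4 and MSJ ≥ 0.5. Predictions (back-projected cluster pairs, or
single-sided sets from baselines) are matched to curated complexes at
protein-set Jaccard ≥ t = 0.50. Precision is the fraction of
predictions whose every non-empty side matches; a gold pair is
detected when a single prediction matches both sides (interolog
pipeline) or when each side is matched by some prediction
(`paired=False`, used for the independently clustered baseline arms —
a single-sided prediction can never match both sides at once).
A benchmark complex may be matched by several predictions and vice
versa; no one-to-one assignment is made. Empty prediction sets give
precision 0 by convention; an empty gold standard gives recall NaN
(printed as NA) with a warning.

## Synthetic scenarios

The generator emulates the target regime: complexes conserved across
two species through a many-to-many ortholog map, embedded in noisy
interactomes. Per complex of size s (uniform in 4–8): s ortholog
groups with one base member per species; with probability 0.2
(`paralog_expansion_rate`) a group gains an extra member on a random
side. For each group pair, an interaction pattern is planted with
probability 0.9 (`p_intra`); a planted pattern is realized in both
species with probability 0.9 (`p_conserve`) and in one random species
otherwise; realized patterns connect all cross-members, and every
realized edge is then lost independently with probability 0.1
(`edge_loss_rate`). 100 background proteins per species join 1-to-1
groups at rate 0.3 so θ extends beyond the planted complexes, and per
species 2× the planted edge count (`noise_edge_multiplier`) of noise
edges is sampled uniformly over pairs outside every planted complex.
These defaults define the standard noisy conditions used by the test
suite and the acceptance script; the numbers reflect commonly assumed
interactome error regimes (intra-complex densities near 0.9, false
positive rates of the same order as true edges).

Noise edges are drawn independently per species, hence non-conserved
by construction — which is precisely the property the interolog
construction exploits, and why it filters them. The returned
benchmark lists exactly the planted pairs with their true MSJ
computed from the group structure (the tests verify the evaluation
module reproduces these scores at zero noise).

`degrade_conservation` breaks a chosen fraction of conserved edge
pairs in exactly one species (coin flip: drop the species-1 edge, or
all its species-2 counterparts), degrading interolog density while
approximately preserving single-species density. Its signature takes
the ortholog map (needed to identify conserved edge pairs) rather
than the complex-pair benchmark.

**What the generator does not emulate:** realistic degree
distributions (hubs), correlated noise (sticky proteins, bait
effects), inter-complex protein sharing, complexes absent from one
species, and ID-mapping ambiguity. Passing tests therefore show that
the method's machinery behaves as specified under its own model
assumptions, not that the headline recall transfers to any particular
real interactome release.

## Design choices and defaults

* **Default engine MCL.** With conserved-edge probability around
  p_intra · p_conserve · (1 − loss)² ≈ 0.66 inside a planted complex,
  maximal cliques of size ≥ 4 are unreliable seeds for the smallest
  complexes, while MCL only needs the complex's interolog subgraph to
  be connected; both engines remain available everywhere and agree in
  the zero-noise limit.
* **Scenario sizes.** Tests and the acceptance script run 5–10
  scenarios of 20 complexes over ~230 proteins per species; at these
  sizes the full three-arm comparison completes in seconds while the
  planted-recovery statistics are stable across seeds.
* **Determinism.** All iteration is over sorted structures; every
  random draw flows from one integer seed; file writers emit floats
  with `repr` so round trips are exact.
* **Ortholog-map merging.** When two orthology resources are used,
  `OrthologMap.merged_with` takes the naive union of groups (colliding
  ids suffixed). Reconciling disagreeing group boundaries is out of
  scope and the merge is flagged as an interpretation.
* **File dialects.** The OrthoMCL group-file dialect and the two
  catalog TSV dialects are pragmatic stand-ins for whatever export
  format a user's orthology/complex resources produce; no header
  auto-detection is attempted (determinism over magic).

## Known limitations

* Exact clique enumeration and dense-matrix MCL limit practical graph
  sizes to roughly 50k edges / a few thousand nodes.
* Hierarchical-overlap clustering engines are not implemented; two
  engines suffice to exercise the interolog construction.
* Absolute precision/recall on real yeast–human data depends on the
  specific database releases and clustering parameters and is not
  reproduced here; the evaluation machinery (MSJ gold standard,
  J ≥ 0.5 matching, per-arm comparison) is what the package
  guarantees.
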