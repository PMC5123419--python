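# Methods

## Problem and model

A protein–protein interaction network is a simple undirected graph G =
(V, E); a protein complex is modelled as a node set Q that is (i) dense —
induced density D(Q) = |E_Q| / C(|Q|,2) close to 1 — and (ii) egocentric —
contained in the closed 1-neighborhood of one of its members. Both
assumptions are empirical regularities of curated complexes embedded in
large PPINs, and both get stronger as networks accumulate interactions
(missed true interactions are far more common than spurious ones, so
embedded complexes densify over time). A γ-quasi-clique — every member
adjacent to at least γ(|Q|−1) of the others — implies density ≥ γ and is
the structural target.

The formal object is the partial dense cover PDC(G, r, δ, q): for each
vertex v the largest set containing v, inside N^r(v) ∪ {v}, of size ≥ q
and density ≥ δ, or the empty set. Radius is fixed at r = 1. Exact
computation is NP-complete (it relaxes minimum clique cover / maximum
clique), so the algorithm is a deterministic polynomial heuristic, and
maximality of each returned set is approximated, never guaranteed; no
post-hoc expansion is attempted.

## Algorithm

Phase I computes core numbers by the bucket-queue minimum-degree-removal
algorithm (O(n + m)) and core counts CC(v) = |{u ∈ N(v) : C(u) ≥ C(v)}|,
then orders vertices by (C(v), CC(v)) descending. C(v) upper-bounds the
size of the densest quasi-clique through v, so large complexes are seeded
first; among equal cores, CC favours the member adjacent to most of its
complex (its "leader"). Phase II builds the candidate set {v} ∪ {u ∈ N(v)
: C(u) ≥ C(v)} and filters it by size and by one of two count conditions
(see Parameters). Phase III peels minimum-degree nodes until the density
target is met or the set is too small. Phase IV removes duplicates,
subsets and near-duplicates.

### Design choices where the procedure was open

* **Seed membership.** The candidate subgraph passed to peeling includes
  the seed v itself; Phase-II density is computed on that same set. The
  seed is not protected during peeling — it has maximal degree in its own
  ego-candidate, so it is removed only in degenerate cases — but a peel
  result that lost its seed is discarded, because the cover definition
  requires v ∈ f(v).
* **Stopping order.** The density rule is checked before any removal, so a
  candidate already at density ≥ δ is emitted whole (the cover asks for
  the largest qualifying set).
* **Tie-breaks.** Peeling ties among minimum-degree nodes go to the
  smallest neighbour-degree sum S(v) = Σ_{w∈N(v)} |N(w)| on the residual
  subgraph; every remaining tie anywhere (vertex ordering, peeling,
  pruning victims) falls back to ascending node index, fixed by label
  order of the input. This makes the whole pipeline bit-reproducible.
* **Near-duplicate pruning.** Of a pair with Jaccard similarity above the
  threshold, the smaller set is dropped; at equal sizes, the one whose
  seed came later in the Phase-I order. Intersections are obtained by
  counting 2-paths in the bipartite set–element graph, visiting set-nodes
  in increasing size order, which also yields the subset test
  |Γ_i ∩ Γ_j| = |Γ_j|.
* **Strictness.** Filter policy 0 rejects at density ≤ δ_low (strict pass
  above); policy 1 uses ≥ on the degree bound (q−1)δ; the catalogue
  diagnostics count densities with strict > at 0.9 and 0.5.

## Parameters

| name | meaning | default | why |
|------|---------|---------|-----|
| q | minimum cluster size | 4 | complexes below ~3–4 proteins are not dense-subgraph signals |
| δ | target induced density, (0,1] | 0.9 | embedded complexes in large PPINs sit mostly above 0.9 |
| δ_low | Phase-II rejection density | 0.5 | Turán-style bound: density > 1/2 guarantees a large near-clique |
| policy | Phase-II filter, {0,1,2} | 2 | the union of the two filters discards least signal |
| jaccard_max | Phase-IV similarity threshold, (0,1] | 0.8 | merges near-duplicates while keeping genuinely overlapping complexes distinct |
| ω | PR-product match threshold in the F-measure | 0.2 | standard in the comparison literature; rankings are robust to it |

## Evaluation measures

Predicted collection P versus gold standard B. The F-measure thresholds
the precision-recall product PR(p,b) = |p∩b|²/(|p||b|) at ω and takes the
harmonic mean of hit fractions N_p/|P| and N_b/|B|. The Jaccard and PR
measures weight each set by its size, score it by its best match on the
other side, and harmonically combine the two directions. Semantic
similarity scores a set by the fraction of its member pairs co-occurring
in some set of the other collection, size-weighted and harmonically
combined; it is the only measure that explicitly rewards placing a
multi-complex protein in several clusters. Their sum is the Aggregated
Score in [0, 4]. Sets of size 1 have no member pairs; they are scored
Den = 0 with weight 1 in semantic similarity — degenerate predictions are
penalised rather than skipped or crashed on. Gold complexes of size ≤ 2
are excluded from B by default (the catalogue statistics follow the same
size ≥ 3 convention); predictions are compared as given, without
restricting gold sets to network-present proteins (the diagnostics
operation, which measures embedded structure, does restrict).

## GO enrichment

Each cluster is assigned the annotation class minimising the upper-tail
hypergeometric probability H(M, p, g) = Σ_{i≥|p∩g|} C(g,i) C(|M|−g, |p|−i)
/ C(|M|, |p|), evaluated in log space (log-binomials via the log-gamma
function, combined with logsumexp), which keeps p-values exact down to the
1e-300 regime where a linear-space sum would underflow. The background M
defaults to all annotated proteins of the loaded GAF namespace — the
natural null for "is this cluster more coherent than a random annotated
set" — and is overridable with, e.g., the network node set. Multiple
testing is corrected across the vector of per-cluster best p-values with
Benjamini–Hochberg step-up q-values at π₀ = 1: deterministic and
conservative relative to Storey's spline-estimated π₀, so threshold-sweep
counts (clusters with q below 10⁻² … 10⁻⁷) are lower bounds. Annotations
are used as flat sets; no propagation along the GO DAG is performed, and
rows with evidence codes IEA, ND or NAS are dropped at load.

## Synthetic benchmarks

The generator emulates the embedded-complex structure measured on real
catalogues: an Erdős–Rényi background G(n, p_bg) plus planted complexes,
each densified by adding uniformly random missing member-pair edges until
every member reaches within-complex degree γ_plant(size−1) — i.e. until
the set is a γ_plant-quasi-clique, the same object the algorithm targets —
with optional pairwise member overlaps. The reference conditions used in
tests and in the acceptance script are n = 200, p_bg = 0.05, five planted
10-cliques (γ_plant = 1): background average degree ≈ 10 against planted
core numbers ≈ 9, so recovery is non-trivial but achievable, mirroring
the high-density regime of complexes in large PPINs. What the generator
does **not** emulate: heavy-tailed PPIN degree distributions (hubs such as
ubiquitin), correlated false-positive edges from high-throughput
experiments, and catalogue incompleteness. Passing the synthetic recovery
and robustness checks therefore demonstrates algorithmic correctness in
the regime the method assumes, not performance on any particular real
network.

Baselines: Rand1 redraws the gold size distribution from all vertices,
Rand2 only from catalogue-covered vertices (a strictly stronger hint),
Rand3 applies one global vertex permutation to the gold standard,
preserving every intersection size. Noise injection adds
round(fraction·m) uniformly random new edges among non-adjacent pairs.

## Numerical and degenerate-input conventions

Density is undefined for sets of fewer than two nodes (zero denominator);
callers treat such sets as automatic failures. The quasi-clique inequality
is compared exactly (integer degree ≥ γ(|Q|−1), no tolerance). Empty
cluster collections raise rather than returning 0, since every measure's
denominator would vanish. Harmonic means return 0 when both sides are 0.
The hypergeometric tail is clamped to ≤ 1 after exponentiation to absorb
rounding at k = small intersections.

## Problem sizes

The test suite and acceptance script run on graphs of 40–200 nodes
(oracle comparisons on up to 40 nodes against definitional iterative
removal and brute-force enumeration; recovery, overlap, robustness and
baseline-discrimination experiments on the 200-node reference benchmark
over 50 seeds). These sizes were chosen so that every claim is checked
against an exhaustive or definitional oracle where one exists; the
algorithm itself is near-linear in m and runs unchanged on
hundred-thousand-edge networks.

## Known limitations

* Maximality of each cover set is heuristic; a denser superset may exist.
* r > 1 neighborhoods, edge weights and directed interactions are out of
  scope; confidence scores act only as a load-time filter (e.g. the
  String ≥ 700 convention).
* No cross-database identifier mapping: node IDs are opaque strings, and
  the caller must bring graph, catalogue and annotations into a common
  namespace.
* Whether the Phase-II density filter should include the seed, and which
  of a too-similar pair Phase IV should drop, are underdetermined by the
  design requirements; the conventions above (include the seed; drop the
  smaller / later-seeded) are fixed choices, not tuned values.
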