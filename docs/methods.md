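# Methods

## Model

The multiscale network has two node kinds (proteins, biological functions)
and three edge classes: undirected protein–protein interactions,
undirected protein–function annotations, and a function hierarchy stored
child→parent and required to be acyclic. Each edge expands into directed
*moves*; five move classes (protein→protein, protein→function,
function→protein, hierarchy up, hierarchy down) carry scalar bias weights,
and the transition probability from node *i* to *j* is the weight of the
move divided by the total weight of *i*'s moves. Nodes without moves form
the dangling set *J*; their rows are zero and the walk mass they collect is
re-injected through the restart vector.

A diffusion profile is the fixed point of the restart walk

r_{k+1} = (1 − α) s + α r_k M + α (Σ_{j∈J} r_k[j]) s,  r_0 = s.

The α factor on the dangling term is forced by mass conservation: with it,
Σ r_{k+1} = (1 − α) + α (Σ r_k over live rows + dangling mass) = 1 at every
iteration; without it the iterate is not a probability vector. The solver
asserts this invariant per-iteration in debug mode. Because the update map
is an L1-contraction with factor α, residuals shrink geometrically and the
fixed point is unique for α < 1; the starting vector only affects the
iteration count. Iteration stops when the L1 change is ≤ ε.

A closed-form oracle (`diffuse_exact`) solves r = (1 − α) s + α r M̃, where
M̃ replaces dangling rows by s, with a dense linear solve. It is guarded to
≤ 2000 nodes and exists to cross-check the power iteration, not to replace
it at scale.

Compounds and the disease are represented purely as restart vectors —
uniform over the compound's in-network targets, or over the
disease-associated proteins — never as inserted network nodes. The ranking
statistic is the Pearson correlation of the two profiles (equivalently the
cosine of the mean-centered vectors); it is symmetric, invariant to adding
a constant to both profiles, and undefined (an explicit error) for a
constant profile, which can only arise on degenerate networks.

## Parameters

| parameter | default | role |
|---|---|---|
| α (continuation probability) | 0.85 | how far influence propagates; no canonical published value exists, so it is configuration, flagged as a choice |
| ε (L1 tolerance) | 1e−6 | stopping rule of the power iteration |
| max_iter | 10000 | safety cap; non-convergence is flagged on the profile, never silent |
| edge-class weights | all 1.0 | walk bias; uniform weights reduce exactly to the unweighted walk on the untyped union graph. Biasing toward functions is supported but no specific bias values are baked in |
| k (mechanism size) | 20 | nodes taken from each profile when extracting a mechanism subnetwork |
| min_targets | 3 | compounds with fewer in-network targets are excluded from ranking (configurable down to 1) |
| universe | network proteins | population for the hypergeometric overlap test; configurable because the appropriate universe depends on how targets were curated |

## Statistics

The overlap p-value is the upper tail P(X ≥ k) of the hypergeometric
distribution, computed exactly in log space via log-gamma binomials (tested
against exhaustive enumeration over the full N ≤ 12 grid). Upper-tail is
the right direction for overrepresentation. Enrichment over a GMT
collection applies the same test per set with Benjamini–Hochberg adjustment
across the collection; per-compound overlap tests are reported unadjusted.

AUROC is computed by mid-ranks (the Mann–Whitney relation), so tied scores
receive half credit; AUPR is average precision with tied blocks processed
jointly (no interpolation), which is conservative for small positive
counts. Both are implemented from scratch and cross-checked in the test
suite against scikit-learn to 1e−9.

## Mechanism extraction

The selection is the union of the top-k nodes of the compound profile, the
top-k of the disease profile, the compound targets and the disease
proteins, each node tagged with every origin that selected it. Ties in the
top-k are broken lexicographically by node id so output is deterministic.
"Linked" in the omission rule is read as adjacency within the induced
subgraph (1 hop by default; `max_hops` is configurable): a node whose only
origins are compound-side is dropped if it cannot reach a disease-origin
node or any selected biological function within that horizon. Disease
proteins and disease-top-k nodes are never dropped. The highest-visited
node of the compound profile is annotated as the primary mechanism
candidate. Top-k is taken jointly over both node kinds; a per-kind split is
not implemented.

## Synthetic benchmark

The generator emulates the *structure* of real inputs, not their content:

- **PPI layer**: Barabási–Albert preferential attachment (default 500
  proteins, 2 edges per new node) — connected and heavy-tailed, like
  curated interactomes, but without their clustering or functional modules.
- **Function hierarchy**: 150 functions in a rooted DAG; each non-root
  node draws 1–3 parents among earlier nodes, acyclic by construction.
- **Annotations**: each function annotates proteins inside the closed PPI
  neighborhood of a random anchor (Poisson quota, ≈2 annotations per
  protein on average), so network-close proteins share functions, as GO
  annotations do.
- **Disease**: a 20-protein module grown by snowball sampling from a random
  anchor — connected and network-localized.
- **Compounds**: 40 compounds, 8 planted positives. Target counts for
  positives and negatives come from one geometric distribution clipped to
  3–25 (most compounds have few targets, a long tail has many), so recovery
  cannot be a target-set-size artifact. Positives draw targets from within
  1 PPI hop of the disease module, with a 10% noise fraction drawn
  uniformly; negatives draw uniformly. Setting `noise=1` removes the
  planted signal entirely and is the negative control.

All draws flow through a single numpy PCG64 generator seeded once per
benchmark, in documented order (network, disease, compounds), so identical
config + seed give byte-identical files; the truth labels are written only
to `truth_labels.tsv`, never into the standard inputs.

What passing the planted-recovery check shows: the diffusion/correlation
machinery detects network proximity between compound targets and a disease
module, at an effect size chosen to be realistic rather than trivial
(positives are near the module, not inside it). What it does not show:
performance on real interactomes, whose degree structure, annotation depth
and curation biases the generator does not model, nor anything about the
biology of any specific compound class.

## Numerical and design choices

- Node order is lexicographic by id, fixed at network build time, making
  matrices, profiles and every output file bit-reproducible.
- Duplicate input edges are deduplicated with a logged warning (the
  interactome is a binary relation); self-loops and kind/endpoint
  mismatches are hard errors; hierarchy cyclicity is checked at build time.
- Scores are written to 6 decimal places; profiles to 10 significant
  digits in scientific notation; all table rows are sorted on stable keys.
- Rank ties are broken by compound id (ascending) after descending score.
- The pipeline writes a manifest (config snapshot, SHA-256 input checksums,
  stage counts, timestamps); reruns are byte-identical except the manifest
  timestamps. On a stage failure, partial outputs move to a `_failed`
  subdirectory and the error names the stage.
- Problem sizes in the test suite and acceptance script (networks ≤ 650
  nodes, 10 benchmark seeds) were chosen as the smallest scales at which
  the heavy-tail, locality and recovery properties are stably measurable.

## Known limitations

- Per-edge weights, spectral/Krylov solvers and compound/disease node
  insertion are out of scope; bias is per move class only.
- Published overlap tables rarely state their hypergeometric universe, yet
  the p-values depend on it strongly; here it is explicit configuration.
- AUPR on small positive counts is high-variance; the benchmark reports it
  but acceptance gates on AUROC.
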