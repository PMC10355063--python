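# Methods

## Model and procedure

`wastrid` estimates an unrooted binary species tree from a collection of
unrooted gene trees, under the assumption that gene-tree/species-tree
discordance is driven by incomplete lineage sorting (ILS) and that each
gene is single-copy. The pipeline is:

1. **Read** one newick tree per line. Branch supports are read either
   from internal node labels (the FastTree/IQ-TREE convention, default)
   or from `[&...]`/`[...]` comments. Absent annotations are recorded as
   absent, never as zero. Taxa are indexed in first-appearance order, and
   every matrix the pipeline produces uses that order.
2. **Normalize supports** (support mode only) onto [0, 1]. Bootstrap-style
   percentages are divided by 100; approximate-Bayes supports, whose
   analytic minimum is 1/3, are mapped affinely by (s − 1/3)/(2/3) — the
   natural affine map sending the attainable range onto the unit interval.
   Internal edges lacking a support receive a configurable default of 1.0
   (with a warning): an unannotated edge is treated as trusted, so the
   method degrades to the unweighted distance rather than silently
   deleting paths.
3. **Per-gene distances.** For each gene tree G and leaf pair u, v,
   d_G(u, v) is the sum of edge weights along the u–v path: 1 per edge
   (unweighted), the support s(e) with leaf edges fixed at 1 (support
   mode), or the branch length l(e) optionally divided by the gene's
   branch-length diameter (path-length mode). All pairs of one gene are
   computed by a single post-order traversal that carries, per node, the
   vector of accumulated weights to the leaves below and combines child
   vectors over all unordered child pairs — polytomies are handled
   naturally and the cost is exactly one write per leaf pair, O(m²) for a
   gene with m leaves, O(k n²) overall.
4. **Averaging.** D[u, v] is the mean of d_G(u, v) over the genes
   containing both u and v; the per-pair gene counts are kept, and pairs
   with count zero are marked missing (never imputed as 0).
5. **Imputation** (only when the matrix is incomplete): UPGMA* on the
   masked matrix gives a tree U1; missing entries are filled with U1's
   edge-count path lengths (D1); an NNI-only BME search on D1 gives U2,
   whose path lengths produce the final completion D2. Defined entries
   are copied verbatim at both stages and are never altered.
6. **Tree search.** Balanced minimum evolution on the complete matrix:
   greedy taxon insertion minimizing the Pauplin length
   L(T) = Σ_{u<v} 2^(1−p_uv) D[u,v], then steepest-descent NNI to a local
   optimum, then (by default) single steepest SPR passes interleaved with
   NNI re-convergence until no move improves. On an additive matrix L(T)
   equals the generating tree's total branch length and is minimized by
   its topology; the local search recovers that topology exactly whenever
   the matrix is within the safety radius (L∞ perturbation below half the
   minimum branch length), which is the property that makes the whole
   pipeline consistent.

## Semantics and conventions

* **Unrooted semantics, rooted storage.** Trees are stored with
  parent/child links, but every quantity is a function of the unrooted
  topology. A degree-2 root is suppressed before any edge is counted:
  its two incident edges merge with lengths summed; their supports
  annotate the *same* unrooted split, so the merged edge keeps the
  defined annotation (the mean when both halves are annotated). Distance
  tables are invariant under rerooting (tested across five rerootings per
  tree).
* **UPGMA\*** joins the cluster pair with the smallest mean of *defined*
  cross-pair distances; only pairs with at least one defined distance are
  joinable. On a complete matrix this is exactly classic average-linkage
  UPGMA (cross-checked against scipy on 200 random matrices). Ties break
  lexicographically on the clusters' smallest taxon indices, making the
  join sequence platform-independent. If the defined-pair graph is
  disconnected the run stops with an error naming the components: no
  principled distance exists between components, and inventing one would
  silently fabricate signal.
* **Determinism.** Candidate moves are enumerated in sorted node order,
  ties go to the earliest candidate, greedy insertion follows matrix
  order (a seeded random order is available), and averaging sums in gene
  order. Identical input and configuration yield byte-identical newick
  output.
* **Numerics.** Move acceptance requires a relative score decrease of
  1e−10; all scoring is by full O(n²) rescoring of the Pauplin length, so
  scores are always consistent with a fresh recomputation (no incremental
  drift). Sums are plain double-precision accumulation; test tolerances
  are 1e−9.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `mode` | `support` | edge weighting: `internode`, `support`, `length`, `length-raw` |
| `support_scale` | `raw01` | raw scale of supports: `raw01`, `percent100`, `abayes` |
| `missing_support` | 1.0 | value assigned to unannotated internal edges |
| `imputation` | `auto` | two-stage completion when the matrix is incomplete; `off` = hard error |
| `moves` | `nni_and_spr` | local-search move set (`nni_only` disables SPR) |
| `insertion_order` | `matrix_order` | greedy start order; `random` uses the seed |
| `seed` | 0 | drives any randomized choice; echoed in the run report |

Path-length mode defaults to per-gene max-path normalization: dividing by
the branch-length diameter puts genes with different rates on a common
scale, and the normalized diameter pair sums to exactly 1.

## The synthetic-data generator

The `fixtures` module emulates the conditions the pipeline is meant for:

* **Species trees**: uniform random unrooted binary topologies (sequential
  uniform edge insertion), rooted on a random edge; branch lengths in
  coalescent units from a configurable law. The standard test condition
  fixes every internal branch at 0.5 coalescent units (quartet
  concordance ≈ 0.60, i.e. AD ≈ 55%, a high-ILS regime) with 16 taxa.
* **Gene trees**: Kingman coalescence within each species-tree branch —
  j lineages merge at rate j(j−1)/2 for the branch's duration, the root
  branch is infinite. The simulator is calibrated against the closed-form
  quartet concordance 1 − (2/3)e^(−t) (pectinate 4-taxon tree, internal
  branch t) at k = 10⁴.
* **Gene-tree error**: a configurable number of uniform random NNI moves
  per tree; every internal edge of the perturbed tree then draws a
  support — edges whose split exists in the true gene tree from
  0.6 + 0.4·Beta(5,1), spurious edges from 0.7·Beta(2,5) — and branch
  lengths get multiplicative lognormal jitter. This reproduces the key
  statistical feature of real annotated gene trees (support correlates
  with correctness) without simulating sequences.
* **Missing data**: i.i.d. deletion of a uniform random m-subset of taxa
  per gene, and clade-based deletion in which each gene keeps only the
  taxa of one uniformly chosen rooted species-tree clade with at least
  ⌈x·n⌉ leaves (the root clade always qualifies).

What passing these tests does *not* show: the generator injects topological
error directly at the tree level, so alignment-length effects, model
misspecification in gene-tree inference, and real support estimators
(bootstrap, SH-like, aBayes) are outside its reach; support laws are
plausible but not calibrated to any inference tool. Conclusions about
real datasets should rest on the method's contracts (oracle equality,
safety radius, consistency trends), not on the generator's absolute error
levels.

A structural note on clade-based deletion: because each gene's leaf set
is a single clade, the defined-pair graph is a union of cliques over a
laminar family — the average matrix is complete whenever any covering
clade is drawn at least once (essentially always at x = 0.5 with
k ≥ 100), and otherwise disconnected. The imputation path is therefore
exercised with i.i.d. deletion, which does produce missing-but-connected
matrices.

## Problem sizes used in tests

The default suite and the acceptance script run at desk scale, chosen to
make every Monte-Carlo check statistically meaningful while staying
single-core friendly: 16 taxa and up to 300 genes for end-to-end
consistency (100 seeds), n ≤ 40 for distance-oracle equality (200 trees),
n ≤ 20 for additive-recovery (150 matrices), n ≤ 7 for exhaustive-search
oracles (300 instances), and k = 10⁴ for simulator calibration. The
engine itself has no hard-coded size limits; cost grows as O(k n²) for
the matrix and O(p n²) for the search moves.

## Design choices where the design was open

* NNI/SPR interleaving: NNI to convergence, then one steepest SPR pass,
  repeated — a deterministic schedule; other schedules reach the same
  local optima on all tested instances but would change tie-breaking.
* Steepest descent (best improving move) rather than first-improvement,
  for determinism.
* The greedy start is included in the NNI-only pass used during
  imputation, mirroring the full search.
* Clade enumeration for clade-based deletion uses the species tree's
  stored root.
* Output trees carry topology only; branch-length estimation is omitted
  because every evaluation here is topological (nRF).

## Known limitations

* One individual per species (no multi-allele mapping).
* No branch supports on the output species tree.
* Full rescoring makes the search roughly O(p n² · n) per SPR sweep in
  practice at large n; thousands of taxa would want the incremental
  subtree-average bookkeeping of the classical BME implementations.
* The imputation refuses disconnected defined-pair graphs by design.
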