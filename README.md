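# wastrid

Species-tree estimation from weighted internode distances.

## The problem

Different regions of a genome can have different evolutionary histories:
under incomplete lineage sorting (ILS), modeled by the multispecies
coalescent (MSC), individual gene trees disagree with the species tree
that contains them. Summary methods resolve this by estimating a tree per
gene and then combining the gene trees. One classical family of summary
methods is distance-based: for each gene tree *G* and each pair of taxa
*u*, *v* present in *G*, compute the **internode distance**

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>G</sub>(u, v) = Σ<sub>e ∈ P<sub>G</sub>(u,v)</sub> w(e)

over the edges of the u–v path, average it across the genes containing
both taxa,

&nbsp;&nbsp;&nbsp;&nbsp;D[u, v] = (Σ<sub>G ∈ 𝒢<sub>u,v</sub></sub> d<sub>G</sub>(u, v)) / |𝒢<sub>u,v</sub>|,

and hand the matrix to a distance method with a positive safety radius.
Under the MSC the averaged matrix converges to an additive matrix for the
species tree, so the procedure is statistically consistent.

Estimated gene trees carry error, and not all branches are equally
trustworthy. This package therefore supports three edge weightings:

* `internode` — w(e) = 1 (the classical edge count);
* `support` — w(e) = s(e), the branch support in [0, 1]
  (leaf-incident edges count 1), so unreliable branches contribute less;
* `length` — w(e) = l(e), the branch length, normalized per gene by the
  maximum leaf-to-leaf path length (`length-raw` skips normalization).

The tree is then found by heuristic **balanced minimum evolution** (BME):
minimize the Pauplin length L(T) = Σ<sub>u&lt;v</sub> 2<sup>1−p<sub>uv</sub></sup> D[u, v],
where p<sub>uv</sub> is the edge-count distance in T, via greedy taxon
insertion followed by NNI and SPR steepest descent. When some taxon pair
co-occurs in no gene, the undefined entries are imputed by a two-stage
completion: UPGMA\* (UPGMA restricted to cluster pairs with at least one
defined distance) supplies a tree whose path lengths fill the gaps, an
NNI-only BME pass refines it, and the refilled matrix feeds the final
search.

## Worked example

Simulate a 16-taxon condition and infer the species tree back:

```sh
wastrid simulate -n 16 -k 100 --internal-length 0.5 --seed 7 --prefix demo
wastrid infer -i demo.genes.nwk -o demo.inferred.nwk --mode internode --seed 7
wastrid compare demo.inferred.nwk demo.species.nwk
```

which prints (tree to `demo.inferred.nwk`, log lines to stderr):

```
n=16 k=100 missing_pairs=0 balanced_length=35.391953
rf	nrf
0	0.000000
```

`missing_pairs=0` says every taxon pair co-occurred in some gene, so no
imputation was needed; `rf 0 / nrf 0.0` says the inferred topology is
exactly the model species tree. With support-annotated gene trees
(`--mode support`, the default) supply `--support-scale`
(`raw01`, `percent100`, or `abayes`; aBayes values are mapped affinely
from [1/3, 1] onto [0, 1]).

The same pipeline is available as a library:

```python
from wastrid import RunConfig, infer_species_tree
tree, report = infer_species_tree("demo.genes.nwk", RunConfig(mode="support"))
```

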