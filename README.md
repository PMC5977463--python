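# rxntrees

Rule-based decomposition of enzymatic reactions into binary trees of
compound pairs and loner compounds, with topology clustering,
reactant-pair validation and enzyme-class enrichment.

## The problem

Metabolic databases describe reactions as stoichiometric equations, but
many downstream tools (path finders, reaction classifiers) need to know
*which substrate turns into which product*. Curated reactant-pair
annotations (KEGG RPAIR/RCLASS style) provide that mapping but require
slow atom mapping and manual curation. `rxntrees` predicts these pairs
from nothing but molecular weights and network statistics, using two
simple rules:

- **Balance rule.** Enumerate the elements of the Cartesian product
  (ECPs) — every pairing of a non-empty substrate subset *a* with a
  non-empty product subset *b*, excluding the pairing of both full
  sides — and select the one minimising the normalised weight difference

      d_ab = |W_a − W_b| / max(W_a, W_b)

  Cofactors and pool metabolites change very little during a reaction,
  so the minimum-d ECP is usually a chemically meaningful pair.

- **Count rule.** When several ECPs tie at the minimum d (e.g. ADP and
  dGDP share the formula C10H15N5O10P2, so ATP_ADP and ATP_dGDP tie
  exactly), pick the ECP that occurs most frequently across the whole
  reaction network — currency couples such as ATP/ADP recur in hundreds
  of reactions.

Selection recurses on the remainder (and into multi-compound
selections) until every compound sits in exactly one *pair tip* or
*loner tip*, yielding a tree structure (TS) per reaction. Trees
serialize to a compact string format (RSF), e.g. `>(!(C)(C_C))` — `>`
root, `!` balance split, `!!` count split, `(C_C)` pair, `(C)` loner.
Reactions sharing a pattern form a cluster of tree structures (CTS).

Predicted pairs are validated against curated annotations: with *y*
matching pairs out of *n*, the hit rate θ gets a beta posterior whose
2.5%/97.5% quantiles give a per-cluster credible interval; the interval
average ranks clusters into high (≥ 0.8), medium (≥ 0.6) and low
confidence bands. Per-cluster enzyme-class preferences are tested with
two-sided Fisher exact tests on EC-number prefixes, Benjamini–Hochberg
FDR control, and (Haldane–Anscombe-corrected) odds ratios.

## Worked example

```python
from rxntrees import (bundled_examples, build_count_index, build_trees,
                      cluster_trees, to_rsf, topology_pattern)

catalog, reactions, rpairs = bundled_examples()
index = build_count_index(reactions, catalog)
trees = build_trees(reactions, catalog, index)
for t in trees[:3]:
    print(t.reaction_id, topology_pattern(t), to_rsf(t))
```

prints

```
R00658 >(!(C)(C_C)) >(!(_C00001)(C00631_C00074))
R02090 >(!!(C_C)(C_C)) >(!!(C00362_C00361)(C00002_C00008))
R00760 >(!(C_C)(C_C)) >(!(C00095_C00085)(C00002_C00008))
```

R00658 (enolase): 2-phospho-D-glycerate pairs with phosphoenolpyruvate
(smallest relative weight difference) and water is left as a
product-side loner. R02090 (dGMP kinase): ADP and dGDP weigh exactly
the same, so the balance rule ties; the count rule resolves the tie in
favour of the network-frequent ATP_ADP pair (`!!` marker). R00760
(fructokinase) splits into the sugar pair and the ATP_ADP pair.

The same pipeline is scriptable from the shell:

```sh
rxntrees simulate --out-dir data --seed 42 --n-reactions 500
rxntrees build-trees --compounds data/compounds.tsv \
    --reactions data/reactions.tsv --out data/trees.tsv
rxntrees cluster  --trees data/trees.tsv --out data/clusters.tsv
rxntrees validate --trees data/trees.tsv --rpairs data/rpairs.tsv \
    --out-table data/precision.tsv --out-crosstab data/crosstab.tsv
rxntrees enrich   --trees data/trees.tsv --reactions data/reactions.tsv \
    --out data/enrichment.tsv
```

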