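# gsatk — gene-set association toolkit

Tools for analyzing collections of gene sets: disease gene lists, pathways,
expression signatures, microRNA target lists, network modules. The toolkit
covers the analytical core of an integrated gene-set database — scoring how
similar two gene sets are, searching collections for sets enriched in a
query gene list, ranking sets by differential expression, building and
exporting gene-set association networks, and characterizing the
distribution of gene-set sizes — and runs entirely on user-supplied (GMT or
tabular) or synthetic collections. It is aimed at computational biologists
who want these analyses scriptable and reproducible, without a hosted
database behind them.

## The statistics at the core

**Similarity.** For gene sets P_i and P_j, a weighted blend of the Jaccard
and cover coefficients:

    S_ij = α · |P_i ∩ P_j| / |P_i ∪ P_j|  +  (1−α) · |P_i ∩ P_j| / min(|P_i|, |P_j|)

with α = 0.8 by default. The cover term keeps the score high when a large
set contains a small one; since min ≤ union, the score is non-increasing
in α.

**Enrichment.** A query of q genes against a set of scale K under a
universe of N genes is tested with the one-sided Fisher's exact
(hypergeometric) test, P(X ≥ hits); results are filtered (hits ≥ 2,
p < 0.05 by default), BH-FDR adjusted, and ranked by decreasing hits.

**Differential gene-set expression.** With x_i = |FC| of the set's genes
measured in an expression table,

    NORM_ABS_FC = ( (1/n) Σ x_i^p )^(1/p),   p = 6 by default

a power mean that accentuates the most differential genes in a set.

**GSAN.** An undirected network whose nodes are gene sets (size = scale,
color = NORM_ABS_FC, line color = source) and whose edges are overlapping
pairs passing a similarity floor (≥ 0.1) and an edge-level Fisher/FDR
filter (< 0.05); exported as node/edge tables, SIF and GraphML for
Cytoscape.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Generate a synthetic collection (150 sets, 1,000-gene universe, block
community structure) with a differential signal planted on `SET0003`, then
run the full search-and-prioritize workflow:

```bash
gsatk synth --seed 17 --universe 1000 --sets 150 --min-scale 10 --max-scale 100 \
      --model block-community --target SET0003 --out-dir fx
```

```python
from gsatk import (read_gmt, read_expression, top_differential_genes,
                   search_by_genes, prioritize_sets, NormParams)

coll = read_gmt("fx/collection.gmt")
expr = read_expression("fx/expression.tsv")
top = top_differential_genes(expr, n=100)          # top |FC|, p < 0.05
res = search_by_genes(top, [coll])
for r in res[:3]:
    print(f"{r.set_id}  hits={r.hits}  scale={r.set_scale}  "
          f"p={r.p_value:.3g}  fdr={r.fdr:.3g}")
print(prioritize_sets(list(coll), expr, NormParams(6)).head(3).to_string(index=False))
```

Output:

```
SET0003  hits=14  scale=14  p=1.43e-18  fdr=9.72e-17
SET0013  hits=12  scale=98  p=0.00972  fdr=0.0441
SET0103  hits=8  scale=17  p=1.61e-06  fdr=5.46e-05
 set_id                       name  scale source  norm_abs_fc  rank
SET0003  Synthetic set 3 (block 3)     14   user     4.118766     1
SET0033 Synthetic set 33 (block 3)     12   user     3.727350     2
SET0053 Synthetic set 53 (block 3)     14   user     3.629493     3
```

The planted set `SET0003` tops both analyses: all 14 of its genes appear
among the top-100 differential genes (hits=14 at p ≈ 1e−18), and its
power-mean fold change (4.12) leads the prioritization, followed by its
block-3 neighbours, which share its planted core genes — exactly the
leakage pattern the statistic is designed to surface.

The association network for the same collection:

```bash
gsatk gsan --gmt fx/collection.gmt --expr fx/expression.tsv --out-prefix crc
# 150 nodes, 1039 edges -> crc.nodes.tsv, crc.edges.tsv, crc.sif, crc.graphml
```

Other subcommands: `search`, `disease-search`, `similarity`, `alpha-scan`,
`prioritize`, `scaledist`, `ingest`. Every run writes a JSON manifest
recording the configuration, input checksums and filter-stage counts.

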