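# voronet

Voronoi-tessellation network analysis of gene–variant disease-association
maps, with cluster detection and relative disease-risk scoring.

## The problem

Complex-disease risk depends on association signals at two scales: how
strongly a **gene** is linked to the disease (e.g. a literature/text-mining
Z-score), and how much of the **variant-level** deleteriousness mass within
that gene (1−SIFT or PolyPhen scores, both in [0, 1]) sits on variants
flagged for the disease. `voronet` places each gene on a 2D map

* x = S_G = Z-score / max Z-score over the gene table,
* y = S_V = Σ(disease-variant scores) / Σ(all variant scores) per gene,

and asks where genes crowd together on that map. Dense groups are found
with a Voronoi tessellation: each gene's cell area A_i gives a local
density f_i = 1/A_i, normalized as

    f̃_i = (mean bounded-cell area) / A_i ,

so Σ 1/f̃_i = n over the n bounded cells. Cells on the diagram boundary
have infinite area and are excluded. A chi-square family

    F(t) = χ²CDF(c·t^b ; df = a)

is fitted by least squares to the empirical CDF of the lowest 80% of the
f̃ values (the background of non-clustered cells), and the clustering
threshold t\* is the 90% quantile of the fitted law. Clusters are
connected components of cells with f̃ > t\*, linked by *qualified*
Delaunay edges — pairs whose edge midpoint is at least as close to the
pair as to any other site (the Gabriel-graph condition). Each cluster's
score is the sum of its members' f̃; a clustered gene's **risk score** is
f̃(gene) × cluster score, and the **relative risk** between two carriers
is the ratio of their risk scores. Independently, the **relative disease
association** between gene sets is the ratio of their summed S_G·S_V
products.

## Worked example

Synthetic benchmark: two tight Gaussian blobs (15 points each, sd 0.01)
planted on 40 uniform background points.

```python
from voronet import VoronoiRiskModel, synthetic

gvmap, labels = synthetic.make_mock_map(synthetic.two_blob_spec(seed=11))
res = VoronoiRiskModel(gvmap).fit()
print(res.summary())
```

```
Voronoi gene-variant risk analysis
==================================
disease label:        synthetic-mock
genes on map:         70
bounded cells:        60
qualified edges:      109 (of 197 Delaunay)
background:           lowest 80%, cutoff 420 (n=48)
chi-square fit:       a=2.24, b=1, c=0.373 (objective 0.219)
threshold (90%):      13.43
clusters (>= 2 cells): 2
  cluster 1: score 7218.23, 13 genes [G0029, G0041, G0043, G0044, G0045, G0048, G0049, G0050, G0051, G0052, G0053, G0054, G0055]
  cluster 2: score 5438.07, 9 genes [G0058, G0061, G0062, G0063, G0064, G0065, G0068, G0069, G0070]
```

Both planted blobs are recovered as the two clusters. 60 of the 70 cells
are bounded; the lowest 80% of their normalized densities (48 values, all
≤ 420) form the background sample, whose fitted chi-square law puts the
90% clustering threshold at 13.43. Per-gene risk compares carriers:

```python
ri, rj = res.risk_score("G0049"), res.risk_score("G0062")
print(f"risk(G0049) = {ri.f_norm:.2f} * {ri.cluster_score:.2f} = {ri.risk:.2f}")
print(f"relative risk = {res.relative_risk('G0049', 'G0062'):.2f}")
```

```
risk(G0049) = 905.57 * 7218.23 = 6536585.29
relative risk = 53.45
```

G0049 sits deep inside the denser cluster (f̃ = 905.6), G0062 at the rim
of the other (f̃ = 22.5), so the first carrier's network-supported risk
is ~53× the second's. `res.frame` exposes the full per-gene table and
`res.plot()` draws the tessellation with clusters highlighted.

The same pipeline runs stage-by-stage from the shell over TSV files:

```sh
voronet build-map --genes genes.tsv --variants variants.tsv --out map.tsv
voronet tessellate --map map.tsv --out-cells cells.tsv --out-edges edges.tsv
voronet fit-threshold --cells cells.tsv --out fit.json
voronet cluster --cells cells.tsv --edges edges.tsv --threshold 13.43 --out clusters.tsv
voronet risk --clusters clusters.tsv --cells cells.tsv --map map.tsv \
             --compare G0049 G0062 --out risk.json
```

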