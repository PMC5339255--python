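# Methods

## The gene–variant map

Two score tables define the map. The gene table assigns each gene a
disease-association Z-score (dimensionless; larger = stronger
association); the variant table assigns each variant locus one or more
per-allele deleteriousness scores in [0, 1] (1−SIFT or PolyPhen, higher
= more damaging) and a boolean disease flag. Trait curation — deciding
which variants count as disease-associated — is input, not computed.

Per-locus scores are collapsed by the arithmetic **mean** (default) or
the **range** (max − min); the mean is the configuration carried into
the downstream analysis. The gene coordinate is x = Z/Z_max over the
supplied gene table, so the strongest gene sits at exactly x = 1. The
variant coordinate is the disease-associated fraction of the gene's
aggregated score mass, y ∈ [0, 1]. Genes whose total variant score is
zero have an undefined (0/0) fraction and are excluded with a warning
rather than set to 0 — a zero denominator is missing evidence, not
evidence of absence. Genes with a positive denominator but no
disease-flagged variant are kept at y = 0 by default
(`drop_zero_disease_genes=True` drops them instead). At least three
mapped genes are required before tessellation.

## Tessellation and normalized density

The Voronoi diagram is computed with Qhull (scipy.spatial.Voronoi);
Delaunay edges are its ridge pairs. A cell with a finite polygon gets
its area from the shoelace formula over its vertices (angle-ordered
about their centroid — exact for convex cells); cells touching the
diagram boundary are unbounded and carry no density. No bounding box is
imposed by default, mirroring the convention of simply excluding
boundary cells; an explicit `bounding_box=True` extension clips the
diagram to the unit square (implemented by tessellating the sites
together with their mirror images across the four sides), making every
cell bounded.

Densities are f_i = 1/A_i, normalized by the inverse mean bounded-cell
area: f̃_i = Ā/A_i with Ā the mean over the n bounded cells. The
algebraic identity Σ 1/f̃_i = n is asserted on every run (1e-9
relative). f̃ is invariant under translation, rotation and uniform
scaling of the map.

Coordinates are treated as exact; coinciding points are an error that
names the colliding genes. A deterministic uniform jitter
(`jitter=eps, seed=s`) is available as an explicit opt-in, because a
silent perturbation would make results irreproducible.

Neighbor qualification: a Delaunay pair (p, q) is kept when the midpoint
of pq is at least as close to p as to any other site — equivalently the
open disk on diameter pq contains no third site. The tie is non-strict
(a site exactly on the circle does not disqualify): the case has measure
zero and inclusion preserves symmetry. This is the Gabriel graph, and
the implementation (Delaunay edges + midpoint test) is checked in the
tests against an all-pairs brute-force construction.

## Background model and threshold

The clustering threshold comes from the *background* — cells not part of
any dense structure. The background sample is the lowest 80% of the
bounded-cell f̃ values by the nearest-rank quantile (the ⌈0.8·n⌉-th
order statistic; every value ≤ that cutoff is included). The sample is
fitted with the three-parameter chi-square family

    F(t) = χ²CDF(c·t^b ; df = a),   a ∈ (0.01, 50), b ∈ (0.2, 10), c ∈ (1e-6, 10),

by least squares between F and the empirical CDF at the sorted sample
values (the CDF, not a histogram, is the fitting target — binning noise
on samples of tens of points would dominate a histogram fit). The
optimiser is `scipy.optimize.least_squares` in (a, log c) from a small
deterministic grid of starts, with c initialised so the model median
matches the sample median.

**Integer-profiled exponent.** By default the density exponent b is
profiled over the integers 1..6, fitting (a, c) for each b and keeping
the best. The continuous-b fit (`integer_b=False`) is available but the
least-squares surface has a long ridge along which (a, b, c) trade off
at nearly equal objective: on simulated samples of n = 5000 a global
optimiser routinely finds parameter triples 10–30% from the truth with a
*lower* objective than the truth itself, so individual continuous-b
estimates are not reliably identified even though the fitted CDF — and
hence the threshold — is essentially the same. Integer profiling breaks
the ridge (median recovery errors of a few percent in the same study)
and matches the exactly-integer exponent reported for this family in
practice. Fits require ≥ 10 distinct background values; a constant
background is rejected.

The clustering threshold t\* solves F(t\*) = significance (default
0.90). With the chi-square quantile function this inverts in closed
form, t\* = (χ²ppf(s, a)/c)^(1/b), satisfying |F(t\*) − s| ≤ 1e-8; the
tests confirm it against an independent quadrature-plus-bisection
inversion. Because t\* comes from the fitted law rather than an
empirical quantile, it can lie below the 80% background cutoff — the
regime the published autoimmune analysis shows (threshold 3.96 below
cutoff 5.3). The significance quantile is read on the fitted background
law itself; with the published rounded parameters (0.78, 3, 0.04) this
reproduces the published threshold to within the rounding of the
parameters (3.81 vs 3.96 printed).

## Cluster detection and scores

Candidate cells are bounded with f̃ strictly above t\* ("above the
threshold"; boundary cells can never join clusters). Clusters are the
connected components of the candidate subgraph under qualified edges,
computed with networkx. The randomized flood-fill formulation gives
provably the same partition and is retained only as a test oracle, which
also demonstrates visiting-order independence. Components need
`min_size` ≥ 2 members by default — a single-cell "cluster" has no
network support; dense singletons are reported unclustered with an
`above_threshold` flag. A cluster's score is the sum of its members' f̃.
Labels 1, 2, … are assigned in descending score, ties broken by the
lexicographically smallest member gene, making the numbering
deterministic (any published numbering is arbitrary, so validation
against external cluster lists should match by membership, not label).

## Risk and association statistics

For a clustered gene g, risk(g) = f̃(g) × score(cluster(g)). The
relative risk between carriers i and j is risk(i)/risk(j), unrounded
internally and conventionally displayed at two decimals; the Σf in the
ratio is the gene's *own cluster* score (the published worked example —
112.71 vs 506.11 giving 0.22 — fixes this reading). Unclustered or
boundary genes raise a "no risk defined" error distinct from "gene not
found": absence of network support is not zero risk. A patient carrying
several candidate genes is summarised by summing risk over their
clustered genes; the published examples only exercise single-gene
patients, so the multi-gene path is a flagged extension.

The relative disease association between gene sets is
Σ S_G·S_V (set i) / Σ S_G·S_V (set j). Alongside the exact ratio the
package reports `ratio_as_reported`, the ratio of the two-decimal-
rounded sums, because association products are often quoted rounded:
for the published pair the rounded products 0.24 and 0.02 give 12 while
the exact ratio is ≈ 14.6. Both are returned; nothing internal is
rounded.

## Synthetic data

`make_mock_map` emulates normally-distributed mock data for exercising
tessellation and clustering: background points uniform on the unit
square plus isotropic Gaussian blobs truncated to the square by
resampling (clipping would pile density onto the border). The benchmark
spec plants two 15-point blobs (sd 0.01, centers (0.3, 0.3) and
(0.7, 0.7)) on 40 background points: blob-core cells are 10²–10³ ×
denser than background, far above any fitted threshold. The zero-blob
variant keeps the 40 uniform points only. `make_toy_tables` emits small
gene/variant score tables (20 genes, 1–5 loci each, 1–4 alleles per
locus, Bernoulli(0.6) disease flags) whose normalized map is frozen as a
golden file computed independently. All generators are driven by one
integer seed and are byte-reproducible.

What the generator does *not* emulate: real score tables have correlated
gene and variant scores, discrete score clumps (many loci share SIFT
values), duplicate coordinates from ties, and cluster fractions far
below the synthetic benchmark's 30/70. Passing the synthetic benchmarks
therefore shows the machinery is correct, not that the thresholding is
well calibrated for any particular real dataset.

## Numerical choices and degenerate inputs

* Empirical CDF convention (i − 0.5)/n; fit objective reported as the
  summed squared CDF residual.
* Harmonic-identity runtime check at 1e-9 relative; threshold inversion
  tolerance 1e-8 on F(t\*).
* Duplicate coordinates, all-collinear sites, empty density lists,
  zero-variance backgrounds, non-positive maximum Z and zero association
  denominators are all rejected with typed exceptions rather than
  propagated as NaN.
* Map TSVs are written with 6 decimals; re-loading a written map is
  exact at that precision.

## Known limitations

* **Boundary cells.** Only infinite cells are excluded; *bounded* cells
  near the hull can still be enormous slivers (circumcenters far outside
  the map), which inflate the mean bounded-cell area and hence every f̃.
  Clustering of points on the map boundary is not assessed at all.
* **Background contamination.** The lowest-80% rule presumes that at
  most ~20% of cells belong to clusters. When far more of the map is
  clustered — as in the planted two-blob benchmark, where 30 of 70
  points are planted — the background sample absorbs cluster cells, the
  fitted tail stretches, and the 90% threshold rises enough to shed the
  low-density rim of each cluster (measured mean membership F1 ≈ 0.85
  against planted labels, versus ≈ 0.95 for an oracle threshold).
* **Uniform maps are not cluster-free.** In uniform data the densest
  cells are chance close pairs, which are always mutually
  Gabriel-adjacent; a ~90th-percentile threshold with min_size = 2
  therefore admits occasional two-to-three-cell false clusters. Users
  needing a conservative null should raise the significance level or
  min_size.
* The chi-square-family background is an empirical convenience, not a
  derived law; alternative background distributions are not implemented.
* Scores are taken as given; no calibration to absolute disease
  probability is attempted.
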