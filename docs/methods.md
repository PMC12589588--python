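# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic-tissue generator does and
does not emulate, and the known limitations.

## Decoding

Spots carry an R × C intensity matrix (rounds × channels). The per-round
call is the argmax channel; ties break to the lowest channel index so the
call is deterministic. The channel sequence is looked up in the codebook;
sequences without a barcode are counted as unmatched and dropped, and a
round with all-zero intensities makes the spot undecodable (counted, not
raised).

The per-cycle quality is q = max(x)/Σx over the C channels of that cycle.
This reading of the metric — denominator over *all* channels — is the one
consistent with its documented range [1/C, 1] (0.25–1 for four channels);
a denominator over the non-called channels would range over [1/(C-1), ∞).
Per-spot quality aggregates cycles by the minimum, the conservative
choice; a mean aggregate is available (`quality_aggregate`). The quality
floor `min_quality` defaults to 0.5 — no published cutoff exists for this
protocol family, and 0.5 (the called channel carries at least half the
cycle's signal in every cycle) is a natural midpoint of the metric's
range. It is configurable and can be set to 0 to disable filtering.

## Assignment

Nuclear masks are expanded by `expansion_um` (default 2 µm, the value used
by both imaging protocols this pipeline targets). Raster masks use
nearest-original-label dilation (no overlaps, contested pixels to the
closest seed); centroid nuclei grow their radius. Assignment is purely
geometric: a transcript inside one expanded region takes its cell id;
inside several overlapping centroid disks it takes the nearest centre,
with exact ties to the lower cell id. This deterministic rule replaces the
probabilistic re-segmentation some upstream pipelines use; externally
produced assignments can be fed directly to `build_matrix`.

QC protocols (all strict inequalities):

| protocol         | rule                                             |
|------------------|--------------------------------------------------|
| `hybiss`         | drop if distinct genes < 3 **or** total counts < 5 |
| `scrinshot`      | drop if total counts < 25                         |
| `scrinshot_copd` | drop if total counts < 8                          |

The high-plex exclusion sentence is grammatically ambiguous in its source
protocol ("less than 3 genes and less than 5 transcripts"); the OR reading
is used because an AND reading would keep single-gene cells with one
count, defeating the filter's purpose. The active rule is recorded in the
QC report.

## Typing

Normalization scales each cell's total to the median pre-normalization
total; the high-plex route follows with log1p, the high-sensitivity route
applies total-count scaling only. Clustering is PCA (when `n_pcs` > 0;
subclustering uses the matrix directly) → Euclidean kNN graph → Leiden at
the given resolution with an explicit seed. Default parameters
(20 neighbors, resolution 1.5, 7 PCs) are the protocol's published
clustering settings. Duplicate expression rows are collapsed before graph
construction so identical cells always co-cluster.

Cluster annotation replaces manual marker reading with a reproducible
rule: per gene min-max scaling across cells, cluster score per type = mean
scaled expression of the type's markers, winner takes the cluster. A
cluster whose top two scores differ by less than 10% of the top score is
labeled "nan" — the automated analogue of manual doublet/ambiguity
exclusion. The per-cluster score table is returned for review; the margin
is configurable.

Rare-cell calling: for each rare marker, threshold = 20% of the gene's
maximum count over cells; a cell is positive when its count strictly
exceeds the threshold, and a candidate when positive for ≥1 marker. A
marker with zero counts everywhere yields threshold 0 (warning logged);
any positive count then calls the cell.

## Niches and enrichment

Microenvironments are each cell's k = 20 nearest neighbors, Euclidean,
strictly within the same sample; ties at the k-th distance break by cell
id. Composition rows always sum to k, so the library-size normalization
before clustering is a near no-op retained for variable-k extensions,
followed by log1p.

Because compositions are integer vectors over few types, duplicate rows
are common and would fragment a cell-level kNN graph into disconnected
cliques. The niche graph is therefore built over *distinct* composition
profiles, with edge weights multiplicity₍ᵢ₎ × multiplicity₍ⱼ₎ ×
exp(−(d/σ)²) (σ = mean neighbor distance), and Leiden communities are
mapped back to cells. With many types and mostly-unique rows this reduces
to the standard construction. Clusters below the 50-cell floor are unique
microenvironments, not general neighborhoods: their cells are labeled
unassigned (−1) rather than deleted, so cell counts are conserved.

Enrichment for a type pair is the symmetrized count of neighbor
incidences in the kNN graph; the null permutes type labels over fixed
positions within each sample (default 1000 permutations);
z = (obs − μ_null)/σ_null, undefined (NaN) when σ_null = 0. "Positive
enrichment" means z > 2 strictly; the co-localization graph keeps isolated
type nodes. Rows are canonicalized (sample, cell id) internally, so
results are exactly invariant to input order. Neighbor search is not
masked across tissue gaps — cells across a lumen can be neighbors.

Condition contrasts on per-sample proportions: zeros are replaced by half
the minimum positive value of that category, values are logit-transformed,
each category gets a two-sided unpaired equal-variance t-test, and
Holm–Šídák adjusts across categories. Categories constant across both
conditions report p = 1 without raising.

## Baso-luminal axes

Raw depth is the minimum distance from a point to the basal polyline
(true segment distance, not vertex distance). Per-airway normalization
divides by the maximum observed point distance, since the epithelial
thickness is not observable from the point set itself; the farthest point
defines 1. Consequently the recovered depths are rank-faithful but not
numerically identical to the generator's thickness-based truth, and the
recovery tests assert rank order (Spearman ρ = 1), not exact values.

Depth bins are 10 equal-width half-open intervals, last bin closed so
depth 1.0 is included. Gene selection keeps genes with (i) > 1500
transcripts in every donor, (ii) presence in all donors, (iii) variance of
per-donor mean depth < 0.15 (mean depth is a [0, 1] quantity, making 0.15
a meaningful scale), and (iv) bin-profile standard deviation > 0.05. The
variability statistic is the sd of the 10 bin fractions; the alternative
reading (sd of per-bin mean distances) is selectable via `layer_stat` and
flagged in the output table. Layer comparisons run one-way ANOVA on
donor-level mean depths (the balanced-nesting collapse of a nested
design) followed by Tukey HSD.

Rare-cell density divides counts by basal-membrane polyline length in mm;
regions with < 2 mm of membrane are flagged ineligible because shorter
stretches give unstable rates. A reference tally of 180 manually surveyed
rare epithelial cells across six subtypes ships with the module as a
bookkeeping cross-check.

## Compartment statistics

Compartment membership is point-in-polygon, first matching polygon in
file order on overlap (warning logged); unclaimed cells form an "outside"
category. Proportions are computed against all cells of the compartment —
unannotated "nan" cells stay in the denominator — so the per-row
proportions sum to 1 with "nan" included.

PERMANOVA: pseudo-F on Bray–Curtis (default; Euclidean available)
distances, SS_total = Σ_{i<j} d²/n and SS_within = Σ_g Σ_{i<j∈g} d²/n_g.
The p-value uses the (b+1)/(m+1) estimator so it can never be zero;
`method="exact"` enumerates all distinct label arrangements for ≤8
samples. The distance choice and permutation count are configurable
because no canonical values exist for this application. Type-I error is
calibrated at α = 0.05 (test suite, 1000 null simulations).

Friedman's test (complete blocks, ≥3) is followed by Dunn's pairwise
z-tests on mean ranks, se = √(k(k+1)/6b), with Šidák family adjustment —
implemented in-package since no installed library provides the post-hoc.
Paired Wilcoxon and Kruskal–Wallis cover the matched-pairs and unmatched
designs. Multiple-testing correction is per family (Dunn within Friedman,
Holm–Šídák within the t-test family); no global correction across
families.

Spot-deconvolution conversion: per spot, keep the 10 largest weights
(ties at the cutoff by type name, no padding when fewer are nonzero) and
multiply by 10 cells/spot; region totals are n_spots × 10. Cross-method
correlations (Pearson and Spearman) are computed after regrouping to a
shared coarse vocabulary, with absent types filled with 0.

## Synthetic tissue

The generator emulates, at desk scale, the structures the analyses
operate on: a circular airway (lumen radius 150 µm, epithelium 50 µm
thick) whose four epithelial types sit at planted relative depths
(basal 0.12, suprabasal 0.38, secretory 0.65, ciliated 0.88 — basal
membrane at the outer boundary); an 800 × 800 µm alveolar field with a
six-type stromal/epithelial/endothelial/immune mixture; optional polygon
niches with their own mixtures; and a per-type multiplicative abundance
shift for "COPD" samples (default AT0 × 4, the direction and rough
magnitude of the disease contrast the pipeline is meant to detect).

Cells are a hard-core point process (minimum separation 8 µm = one
nucleus diameter) so segmentation-free assignment is meaningful.
Expression is a two-marker-per-type profile (12 mean counts per marker
over a 0.2 off-target floor, within the 1–20 counts/cell range of
targeted in-situ panels; the AT0 profile co-expresses the AT2 markers at
reduced level). Counts are negative binomial via a Gamma–Poisson mixture
(dispersion 10; Poisson as dispersion → ∞) — the conventional
overdispersed count model, since no count model is documented for these
protocols. Transcripts scatter uniformly within the 4 µm nuclear disk:
kept at ≤ half the hard-core distance so a transcript is always nearer
its own nucleus than any neighbor's, which makes the ≥99%
correct-assignment property hold by construction. Background transcripts
(off by default) form a spatial Poisson process with uniform gene labels.

What passing tests on this tissue do **not** show about real data:
segmentation errors, optical crowding, probe efficiency differences
between genes, spatial expression gradients within a type, doublets, 3-D
effects and RNA degradation are all absent. The generator validates the
statistical machinery and its contracts, not protocol-specific error
modes.

## Numerical conventions

* Coordinates are µm, y increasing downward; label rasters convert via
  `pixel_size`. MatrixMarket files are 1-based on disk, 0-based in memory.
* All stochastic operations take an explicit seed; derived per-sample
  seeds come from a seed sequence of the master seed.
* Boundary rules: QC cutoffs and rare-cell positivity are strict
  inequalities; the enrichment graph uses strict z > 2; depth bin edges
  are half-open with the last bin closed; argmax and assignment ties break
  deterministically (lowest index / lower cell id).
* Exact-tie tolerance in geometric assignment is 1e-12 µm; permutation
  p-value comparisons use a 1e-12 slack on F to make ties robust to
  floating-point noise.

## Known limitations

* The detection-power guarantee of the condition contrast is bounded by
  the per-category t-test with n = 3 samples per condition: with a
  0.10 → 0.30 shift and proportion-scale sd 0.02, the noncentral-t power
  at the Holm–Šídák step-1 threshold is 0.884, so roughly one simulated
  cohort in nine misses the shifted category at adjusted p < 0.05.
  Pooling variance across categories would raise power but assumes
  homoscedastic logit proportions, which the zero-replacement rule
  violates; the per-category test is kept.
* Niche discovery inherits Leiden's resolution dependence; the default
  (1.0) recovers two planted coarse niches but finer mixtures may split.
* Per-airway depth normalization is relative to the observed point cloud,
  so sparsely sampled airways compress the axis.
* The geometric assigner does not model overlapping cells or doublets;
  cells closer than the expansion radius compete by distance only.
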