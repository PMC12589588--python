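# lungscape

Reusable analysis pipeline for spatially resolved transcriptomics of human
lung tissue. It covers the computational steps between decoded imaging data
and biological statements about tissue organization:

* **decoding** — calling gene barcodes from per-round, per-channel spot
  intensities of combinatorial in-situ sequencing, with a per-spot quality
  metric;
* **assignment** — expanding segmented nuclei by a fixed radius (2 µm) and
  assigning transcripts to the nearest cell region, producing a sparse
  cell-by-gene matrix with per-protocol QC filters;
* **typing** — total-count normalization, PCA/kNN/Leiden clustering,
  reproducible marker-based cluster annotation, rare-cell positivity
  calling, and fine-to-coarse label regrouping;
* **niches** — pairwise cell-type neighborhood enrichment against a
  permutation null, the z > 2 co-localization graph, kNN-composition niche
  discovery, and healthy-vs-disease composition statistics
  (logit-transformed Holm–Šídák multiple t-tests);
* **axes** — baso-luminal gradient quantification (distance to the basal
  membrane polyline, normalized per airway, binned into 10 layers with
  gene-selection filters and nested ANOVA + Tukey comparisons) and
  rare-cell densities per millimetre of basal membrane;
* **compartment statistics** — cell-type proportions inside histological
  compartment polygons, PERMANOVA on composition distance matrices,
  Friedman/Dunn, paired Wilcoxon and Kruskal–Wallis batteries, and the
  cross-method proportion correlation protocol (including the top-10 × 10
  cells-per-spot conversion for spot deconvolution data);
* **synthetic tissue** — a generator of airway + alveolar test tissue with
  known cell types, planted niches, layer structure and condition shifts,
  so every stage is testable without any external download.

## The statistics at the core

For a cell *i* with k = 20 nearest neighbors within its sample, the
neighborhood composition is the vector **n**ᵢ ∈ ℕᵀ of neighbor counts per
type (Σ **n**ᵢ = k). Niches are Leiden communities of cells with similar
**n**ᵢ; clusters of < 50 cells are treated as unique microenvironments and
set aside. Pairwise enrichment for types (a, b) compares the observed
symmetrized neighbor-incidence count against label permutations:
z = (obs − mean_perm) / sd_perm, and type pairs with z > 2 form the
co-localization graph.

The per-cycle decoding quality of a spot with channel intensities
x₁…x_C is q = max(x) / Σx, ranging from 1/C (uninformative) to 1
(one-hot); per-spot quality aggregates cycles by the minimum.

Relative baso-luminal depth of a point is d/d_max per airway, where d is
its minimum distance to the traced basal-membrane polyline, giving each
airway a [0, 1] axis independent of epithelial thickness.

PERMANOVA computes the pseudo-F of among- vs within-group sums of squares
on a Bray–Curtis distance matrix of per-sample type-proportion vectors,
with p = (b + 1)/(m + 1) over label permutations.

## Worked example

```python
from lungscape.synthetic import SynthConfig, generate_tissue, default_profiles
from lungscape.assignment import expand_nuclei, assign_transcripts, build_matrix, qc_filter
from lungscape.celltyping import normalize, cluster, annotate, MarkerDictionary

cfg = SynthConfig()                               # one airway + alveolar field
cm, tx, nuclei, geom = generate_tissue(cfg, seed=1)
assigned = assign_transcripts(tx, expand_nuclei(nuclei, 2.0))
filtered, report = qc_filter(build_matrix(assigned), "hybiss")
norm = normalize(filtered, "hybiss")
labels = cluster(norm, n_neighbors=20, resolution=1.5, n_pcs=7, seed=1)
prof = default_profiles()
markers = MarkerDictionary({t: [g for g in prof.columns if prof.loc[t, g] >= 5]
                            for t in prof.index})
types, scores = annotate(labels, norm, markers)
```

This prints (via the surrounding report calls):

```
simulated 1500 cells, 41737 transcripts
assigned fraction: 1.000
QC: kept 1461/1500 cells (0.974)
clusters: 10, annotation accuracy vs truth: 0.994
```

1500 synthetic cells of 10 types yield ~42k transcripts; every transcript
falls inside an expanded nucleus (the generator scatters them within the
nuclear disk), the high-plex QC rule removes 39 low-information cells, and
Leiden clustering plus marker scoring recovers the generating type of
99.4% of cells. Running `pairwise_enrichment` on the same map ranks the
epithelial layer neighbors first (`basal–suprabasal z ≈ 46`,
`ciliated–secretory z ≈ 45`), i.e. the planted airway-layer adjacency.

The same stages are available from a shell:

```sh
lungscape simulate --seed 1 --out sim/
lungscape assign sim/transcripts.csv sim/nuclei.csv --protocol hybiss --out out/
lungscape niches out/cellmap.csv --k 20 --permutations 1000 --seed 1 --out out/
```

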