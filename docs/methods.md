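# Methods

`stromascope` re-implements a single-cell spatial analysis workflow for
Imaging Mass Cytometry (IMC) of solid tumor tissue — developed around
pancreatic ductal adenocarcinoma (PDAC) and its cancer-associated
fibroblasts (CAFs) — as a tested, seed-reproducible library. This note
documents the models, the defaults and the design choices that were
genuinely open.

## Data model

An ROI is a (C, H, W) stack of ion counts ("dual counts"), one channel per
metal-tagged antibody, at a known µm/pixel scale (~1 µm for IMC). The panel
(31 markers by default: 29 phenotyping markers + 2 iridium DNA channels)
fixes channel order everywhere. All per-cell results live in one flat cell
table (pandas DataFrame) with `raw_*`, `asinh_*` and `norm_*` intensity
columns, µm-scale centroids and areas, QC flags, and population/subtype
assignments. Coordinates are pixel-centered, origin top-left, x = column,
y = row.

## Preprocessing

*Hot pixels* are isolated detector spikes. A pixel is replaced by the
maximum `m` of its square neighborhood (radius 2, center excluded, clipped
to the image at borders) when `value − m > 50` dual counts. The rule never increases a
pixel and is idempotent whenever spikes are isolated — which is what the
physical artifact looks like and what the generator plants.

*Intensity clipping.* Per marker, values below a configurable low threshold
(default 0; in practice set by inspection) are zeroed, and the upper tail is
clipped at the 99.99th percentile pooled across **all** ROIs of the batch,
but never below 10 dual counts. Percentiles are linear-interpolation order
statistics; the pooling choice follows the batch-level reading of "overall
signal" and makes the cutoff independent of ROI count ordering. The fixed
stage order is hot-pixel → low threshold → upper clip.

*Positive-area fractions* (e.g. Pan-Ck+, CD45+, CD31+, FAP+ area) are
computed on a Gaussian-smoothed channel (σ = 2 px by default, configurable)
as the fraction of pixels above a threshold; they are segmentation-free.

## Segmentation

The original workflow used an interactively trained pixel classifier
(Ilastik) plus CellProfiler; those models are not reproducible from a paper,
so the package ships a deterministic seeded-watershed segmenter: sum the DNA
channels, Gaussian-smooth (σ = 1 px), threshold (half-Otsu by default),
take local maxima (min distance 3 µm) as seeds, watershed, then expand each
nucleus by a 3 µm cytoplasm rim without crossing neighbors
(`skimage.segmentation.expand_labels`). Externally produced label masks are
accepted everywhere a mask is consumed, so a better segmenter can be swapped
in without touching downstream code.

Per-cell features are arithmetic means of channel values over the label's
pixels, area = pixel count × (µm/px)², centroid = center of mass.

## Object QC

Four independent rules (evaluated jointly, hence order-independent and
idempotent): area < 10 µm²; area > 1000 µm²; asinh-transformed intensity
> 2 in more than 15 markers; asinh intensity < 0.01 in all clustering
markers. The intensity rules run on the asinh scale, not the [0,1]
normalized scale: raw dual counts routinely exceed 2, and min-max normalized
values never can, so the conventional cutoffs are only meaningful after the
variance-stabilizing transform. The blank-cell rule defaults to *all*
clustering markers (a cell blank in every informative channel carries no
phenotype); an any-marker switch exists.

## Transformation and normalization

`v → asinh(v / cofactor)` with cofactor 1 (a literal reading of the usual
IMC recipe; 5 is common practice and config-exposed), then per marker
clipped to the pooled 1st–99th percentiles of QC-passing cells and rescaled
linearly to [0,1]. The pipeline order is asinh → QC → percentile
normalization, so the normalization pool is exactly the QC-passing cells.
Transformed values are weakly monotone in the raw values (clipping creates
ties at the ends; about 2% of values are clipped by construction).

## Clustering and hierarchical annotation

Clustering is the PhenoGraph construction: exact Euclidean kNN graph
(k = 60 first pass, k = 20 within populations), edge weights = Jaccard
overlap of the endpoints' neighborhoods, partition by seeded Leiden
modularity (RB configuration, resolution 1.0). Seed-fixed runs are
deterministic and row-order invariant up to label renaming. Functional —
not bit-level — equivalence with any particular PhenoGraph release is the
goal; modularity on kNN graphs over-splits large homogeneous groups
(granularity ~k), which is why cluster-level *annotation* rules, not raw
cluster identity, define populations.

Annotation: each cluster's mean normalized profile is gated against marker
rules (required-positive / required-negative sets). A marker's positivity
threshold interpolates the cluster-mean range, `min + q·(max − min)` with
q = 0.5: with a handful of clusters the empirical order-statistic quantile
can coincide with an expressing cluster's own mean, making strict positivity
unsatisfiable, so the midrange interpolation is used instead. Markers whose
cluster means span < 0.1 on the normalized scale are uninformative and can
never be called positive. A cluster satisfying several gates goes to the
best margin (logged); none → `other`.

The refine loop mirrors the two-pass manual workflow: each major population
(tumor, immune, EC, CAF, islet) is re-clustered at k = 20; sub-clusters
whose profile gates into a *different* population are reassigned wholesale;
then each repaired population is re-clustered and its sub-clusters labeled
by subtype gates (myCAF, iCAF, apCAF; T/B/macrophage), unmatched ones
getting numbered names ("CAF 2"). Rule tables are plain data (YAML-round-
trippable `MarkerRule` lists) because marker gating logic is inherently
editable domain knowledge.

UMAP embeddings are reporting-only, never used for assignment.

## Spatial statistics

*Neighbor graph.* Two cells are neighbors when the minimum Euclidean
distance between their mask pixels (border-to-border) is ≤ 30 µm. The
implementation prefilters candidate pairs by centroid distance + label
extents, then resolves each candidate by exact pixel-pair distances, so it
equals the brute-force definition by construction (and is tested
edge-for-edge against it). For ground-truth tables without masks a
centroid-distance graph is provided; distances-to-tumor use centroids
("center of mass") deliberately, matching the source convention that border
distances define neighborhood and centroid distances define separation.

*Patch-method interaction score.* Per ROI and ordered (reference, target)
pair: the fraction of reference cells with ≥ 1 target neighbor. The null
permutes the subtype labels over the ROI's fixed cell positions (graph
geometry held fixed — the standard exchangeable null); p-values are
one-sided add-one estimators `p = (1 + #{perm ≥ obs})/(n_perm + 1)` with
n_perm = 5000, α = 0.01 per side. Because class sizes are
permutation-invariant, the statistic is compared as an integer count —
no floating-point ties. Scores: +1 (p_high < α), −1 (p_low < α), else 0,
averaged over ROIs into an asymmetric reference × target matrix. Pairs with
< 10 cells of either subtype in an ROI are excluded and recorded; pairs
eligible nowhere are missing, not zero. Cells labeled `other` are outside
the tested universe. The permutation statistic is the patch fraction (the
reported quantity); an edge-count statistic is a config switch away.

*Cellular neighborhoods.* Per cell, neighbors are counted over a fixed
class list (detailed CAF and immune subtypes + aggregated tumor and EC — 29
classes at full panel scale), normalized to sum to 1; isolated cells keep
zero vectors and form a "sparse" neighborhood unless dropped. k-means
(k = 10, 1500 iterations, 10 restarts, best inertia, fixed seed) clusters
the vectors; a per-neighborhood class-enrichment table (upper-tail
hypergeometric on aggregated neighbor counts, BH across classes) supports
manual annotation of the resulting regions. Fewer distinct vectors than k
produce duplicated centroids, reported via `n_effective` rather than an
error.

## Clinical enrichment

Patients split into good/bad prognosis by CA19-9 (> 100 IU/L is bad; the
boundary goes to the low group), disease-free survival (≤ 13.5 months bad)
and overall survival (≤ 18 months bad) — boundary conventions follow the
figure-caption definitions of the source analysis. For each CAF subtype and
group, an upper-tail hypergeometric test on cells (universe = all CAF
cells; a patient-level mode would be a trivial extension but the cell-level
universe matches the frequency-normalized presentation this analysis uses),
BH-corrected across subtypes within the group. Score: fdr floored at 1e-10,
set to 1 above 1e-3; −log10(fdr_good) when the good side is significant
(positive), +log10(fdr_bad) when the bad side is (negative); both
significant → smaller fdr wins (logged), an exact tie → 0, the only value
consistent with antisymmetry under group swap. |score| ≤ 10 always.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
tissue biology. Cells are non-overlapping discs (nucleus + cytoplasm
annulus; default nuclear radius 2.5 µm, cell radius 4.5 µm, ≥ 1 µm
clearance) placed by rejection sampling; per-pixel counts are Poisson around
per-cell log-normal-scaled profile means (dispersion 0.15), nuclear markers
only inside nuclei, on a Poisson background (rate 0.1). Hot pixels are
single-pixel spikes exceeding the local neighborhood maximum by 150 counts,
placed ≥ 3 px apart (Chebyshev) so each is unambiguously isolated, and
recorded in ground truth. Spatial rules: *attraction* places each subtype-B
cell (with probability = strength) in an annulus around a random subtype-A
anchor — the annulus starts at the disc-contact distance, so a range below
contact degenerates to closest-allowed placement; *avoidance* rejects
placements within range (enforcement drawn per cell at the rule's
strength, checked symmetrically); *domain* rules partition each ROI into
one Voronoi region per rule with its own composition. Placement that cannot
succeed (packing fraction > 45% or attempts exhausted) raises an explicit
error rather than silently truncating.

The default cohort is 8 patients × 3 ROIs × 500 cells on 350 × 350 px ROIs
at 1 µm/px — deliberately smaller than a 1 mm² acquisition so the full
pipeline (including 5000-permutation interaction tests on every ROI) runs
in minutes on one core while keeping realistic per-cell densities (~11
neighbors within 30 µm). The default composition is ~35% tumor, ~21%
immune (T/B/macrophage), 7% endothelial, 3% islet and ~34% CAF across
three variants (myCAF-, iCAF- and apCAF-like), echoing the published PDAC
compartment sizes. Prognosis groups multiply bad-group subtype frequencies
by a configurable shift; clinical values are drawn so the conventional
thresholds reproduce the planted grouping exactly. All randomness flows
from the single config seed through named per-ROI generators.

What the generator does **not** emulate: tissue morphology (glands,
vessels, ECM texture), antibody spillover between channels, 3-D sections,
segmentation errors correlated with cell type, and patient-level batch
effects. Passing tests therefore demonstrate correctness of the statistical
machinery on data satisfying its assumptions, not robustness to every
artifact of real acquisitions.

## Numerical and degenerate-input conventions

Percentiles: linear interpolation between order statistics, everywhere. A
marker whose normalization percentiles coincide is set to 0 with a warning.
Blank images segment to empty masks with a warning, not an error. KS test:
D is the explicit ECDF supremum; the p-value uses the exact small-sample
distribution where available (verified against exhaustive permutation
enumeration) and the asymptotic one otherwise. Hypergeometric tails come
from `scipy.stats.hypergeom` (tested to 1e-10 against exact integer
enumeration for N ≤ 60). k-means ties and restarts are governed by the
fixed seed; Leiden uses a fixed seed with run-to-convergence iterations.

## Known limitations

- The watershed segmenter under-splits heavily overlapping nuclei and is
  not a substitute for a trained pixel classifier on real tissue; use
  external masks for production data.
- Modularity clustering granularity scales with k; raw cluster counts are
  not comparable across datasets — only the annotated populations are.
- The cell-level hypergeometric universe treats cells as exchangeable
  across patients within a group; strong per-patient clustering of a
  subtype can inflate significance (the patient-level mode trades power for
  robustness).
- Interaction scores quantize evidence at ±1 per ROI; with few ROIs the
  mean score is coarse.
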