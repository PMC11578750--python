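# stromascope

Single-cell spatial analysis of Imaging Mass Cytometry (IMC) data, built
around the tumor-microenvironment questions typical of pancreatic ductal
adenocarcinoma (PDAC): which cell subtypes are present, which of them sit
next to which, what spatial neighborhoods the tissue is organized into, and
which cancer-associated-fibroblast (CAF) subtypes are enriched in patients
with poor prognosis.

The package takes multichannel ion-count images (one channel per
metal-tagged antibody, ~1 µm/pixel) through a complete, seed-reproducible
pipeline:

1. **Preprocessing** — isolated hot-pixel spikes removed by a
   neighborhood-maximum rule (radius 2, threshold 50 dual counts); per-marker
   low thresholds; upper clipping at the 99.99th percentile pooled over all
   ROIs (floor 10); Gaussian-smoothed positive-area fractions.
2. **Segmentation** — DNA-seeded watershed with cytoplasm expansion (or
   externally supplied label masks), per-cell intensity/shape quantification,
   and object QC (area 10–1000 µm², asinh intensity > 2 in > 15 markers,
   blank in all clustering markers).
3. **Phenotyping** — asinh transform, pooled 1–99% normalization to [0,1],
   PhenoGraph-style clustering (kNN graph + Jaccard weights + seeded Leiden,
   k = 60 then k = 20), rule-based annotation into five populations (tumor,
   immune, endothelial, CAF, islet), a misannotation-repair loop, and
   subtype gating (myCAF / iCAF / apCAF, T / B / macrophage).
4. **Spatial statistics** — exact 30 µm border-to-border neighbor graphs;
   the *patch method* interaction score: per ROI, the fraction of reference
   cells with ≥ 1 target neighbor, tested against a 5000-fold label
   permutation null at p < 0.01, scored ±1/0 and averaged over ROIs;
   centroid distances to tumor; two-sample KS comparisons; cellular
   neighborhoods by k-means (k = 10, 1500 iterations, 10 restarts) on
   29-class neighbor-composition vectors.
5. **Clinical enrichment** — patients split by CA19-9 (100 IU/L), DFS
   (13.5 months) or OS (18 months); per CAF subtype, an upper-tail
   hypergeometric test per group with BH correction, summarized as a signed
   score: −log10(fdr) for good-group enrichment, +log10(fdr) for bad-group
   (negative values), fdr capped at 1e-10 and zeroed above 1e-3.

Because raw IMC acquisitions of this kind are rarely public, the package
includes a first-class synthetic-data generator (`stromascope.synthetic`)
that plants known ground truth — subtype marker profiles, hot pixels,
pairwise spatial attraction/avoidance, compositional domains, and cohort
frequency shifts between prognosis groups — so every stage is testable end
to end. See `docs/methods.md` for the models and design choices.

## Worked example

Plant an iCAF-like subtype at 5× frequency in the poor-prognosis group of a
synthetic cohort and ask whether the enrichment stage finds it:

```python
import stromascope as st

# a small synthetic cohort: 8 patients, 2 ROIs each, iCAF-like cells
# planted at 5x frequency in the poor-prognosis group
config = st.SyntheticCohortConfig(seed=7, rois_per_patient=2, cells_per_roi=300,
                                  group_frequency_shift={"CAF_i": 5.0})
cohort = st.simulate_cohort(config, render_images=False)

scores = st.enrichment_table(cohort.cells, cohort.clinical, "ca19_9")
print(scores[["subtype", "n_subtype", "fdr_bad", "fdr_good", "score"]].to_string(index=False))
```

which prints:

```
subtype  n_subtype      fdr_bad     fdr_good  score
 CAF_ap        351 1.000000e+00 2.570872e-16   10.0
  CAF_i       1217 6.906012e-66 1.000000e+00  -10.0
 CAF_my        609 1.000000e+00 1.094928e-32   10.0
```

The planted subtype scores −10 (the capped maximum for bad-group
enrichment: its cells are massively over-represented among the CAF cells of
high-CA19-9 patients), while the other two subtypes — compositionally
displaced by the shift — score +10 in the good group. On a cohort with no
planted shift every subtype scores 0.

The full image-level pipeline runs from a single config:

```bash
stromascope run --out-dir my_run --seed 1          # simulate + analyze
stromascope simulate --out-dir data --seed 1       # or write TIFFs/CSVs first
stromascope enrich --cells my_run/cells.csv --clinical my_run/clinical.csv \
    --parameter ca19_9 --out scores.csv
```

`run` writes the cell table (`cells.csv`), per-ROI interaction tests and
the reference × target score matrix, neighborhood assignments and their
class-enrichment table, per-parameter CAF enrichment scores, and a
`manifest.json` with config hash and output checksums. Identical config +
seed gives byte-identical tables.

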