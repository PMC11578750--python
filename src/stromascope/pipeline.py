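"""End-to-end orchestration: simulate/load → preprocess → segment → phenotype
→ spatial statistics → clinical enrichment, with a reproducibility manifest.

Identical config + seed yields byte-identical cell tables, interaction score
matrices and enrichment tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Panel, default_panel
from .enrichment import PARAMETERS, enrichment_table
from .io import read_clinical, read_mask, read_roi_stack
from .phenotyping import (annotate_populations, asinh_transform, cluster_cells,
                          default_population_rules, default_subtype_rules,
                          normalize_intensities, refine_populations)
from .preprocess import clip_intensities, remove_hot_pixels
from .segmentation import qc_filter, quantify_cells, segment_cells
from .spatial import (build_neighbor_graph, cluster_neighborhoods,
                      interaction_test_all, min_distance_to,
                      neighborhood_compositions, score_matrix)
from .synthetic import SyntheticCohortConfig, simulate_cohort


@dataclass
class PipelineConfig:
    """All stage parameters with their conventional defaults, range-checked."""

    out_dir: str = "stromascope_run"
    seed: int = 0
    # input: either simulate a cohort or read files
    simulate: bool = True
    synthetic: SyntheticCohortConfig | None = None
    images_dir: str | None = None
    masks_dir: str | None = None
    panel_path: str | None = None
    clinical_path: str | None = None
    # preprocessing
    hp_radius: int = 2
    hp_threshold: float = 50.0
    top_percentile: float = 99.99
    clip_floor: float = 10.0
    # segmentation + QC
    cytoplasm_expand_um: float = 3.0
    area_min: float = 10.0
    area_max: float = 1000.0
    high_value: float = 2.0
    high_count: int = 15
    floor_value: float = 0.01
    # phenotyping
    cofactor: float = 1.0
    low_pct: float = 1.0
    high_pct: float = 99.0
    k: int = 60
    k_sub: int = 20
    resolution: float = 1.0
    # spatial
    radius_um: float = 30.0
    n_perm: int = 5000
    alpha: float = 0.01
    min_cells: int = 10
    kmeans_k: int = 10
    kmeans_iters: int = 1500
    kmeans_inits: int = 10
    # enrichment
    ca19_9_threshold: float = 100.0
    dfs_threshold: float = 13.5
    os_threshold: float = 18.0

    def __post_init__(self) -> None:
        checks = [
            (self.hp_radius >= 1, "hp_radius >= 1"),
            (self.hp_threshold > 0, "hp_threshold > 0"),
            (0 < self.top_percentile < 100, "top_percentile in (0, 100)"),
            (self.clip_floor >= 0, "clip_floor >= 0"),
            (self.cytoplasm_expand_um >= 0, "cytoplasm_expand_um >= 0"),
            (0 <= self.area_min < self.area_max, "0 <= area_min < area_max"),
            (self.cofactor > 0, "cofactor > 0"),
            (0 <= self.low_pct < self.high_pct <= 100, "0 <= low_pct < high_pct <= 100"),
            (self.k >= 2 and self.k_sub >= 2, "k and k_sub >= 2"),
            (self.radius_um > 0, "radius_um > 0"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0 < self.alpha < 1, "alpha in (0, 1)"),
            (self.min_cells >= 1, "min_cells >= 1"),
            (self.kmeans_k >= 2, "kmeans_k >= 2"),
            (self.kmeans_iters >= 1 and self.kmeans_inits >= 1, "kmeans budget >= 1"),
            (self.ca19_9_threshold >= 0 and self.dfs_threshold >= 0
             and self.os_threshold >= 0, "clinical thresholds >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: requires {msg}")
        if self.simulate and self.synthetic is None:
            self.synthetic = SyntheticCohortConfig(seed=self.seed)
        if not self.simulate and (self.images_dir is None or self.clinical_path is None):
            raise ValueError("non-simulated runs need images_dir and clinical_path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            syn.pop("panel", None)
            syn["profiles"] = [p["name"] for p in syn["profiles"]]
            d["synthetic"] = syn
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=str)),
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted for every run."""

    config_hash: str
    version: str
    seed: int
    started: float
    finished: float = 0.0
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def spatial_class_labels(cells: pd.DataFrame) -> pd.Series:
    """Map each cell to its neighborhood-analysis class.

    CAF and immune cells keep their detailed subtype; tumor and endothelial
    cells are aggregated into their macro population; islet and unassigned
    cells map to ``other`` (excluded from composition classes but kept as
    graph nodes).
    """
    cls = pd.Series("other", index=cells.index, dtype=object)
    detailed = cells["population"].isin(["CAF", "immune"])
    cls[detailed] = cells.loc[detailed, "subtype"]
    agg = cells["population"].isin(["tumor", "EC"])
    cls[agg] = cells.loc[agg, "population"]
    return cls


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, writing all intermediates to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), __version__, config.seed, time.time())
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, index=False) -> None:
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)

    # ------------------------------------------------------------------ input
    if config.simulate:
        cohort = simulate_cohort(config.synthetic, render_images=True)
        panel = config.synthetic.panel
        images = [b.image for b in cohort.rois]
        ext_masks = None
        clinical = cohort.clinical.drop(columns=["group"])
        save_csv(cohort.clinical, "clinical_truth.csv")
        save_csv(cohort.cells, "cells_truth.csv")
    else:
        panel = Panel.from_csv(config.panel_path) if config.panel_path else default_panel()
        paths = sorted(Path(config.images_dir).glob("*.tif*"))
        if not paths:
            raise ValueError(f"no TIFF stacks under {config.images_dir}")
        images = [read_roi_stack(p, panel) for p in paths]
        ext_masks = None
        if config.masks_dir:
            ext_masks = {p.stem: read_mask(p) for p in sorted(Path(config.masks_dir).glob("*.tif*"))}
        clinical = read_clinical(config.clinical_path)
    save_csv(clinical, "clinical.csv")

    # ------------------------------------------------------------- preprocess
    images = [remove_hot_pixels(im, config.hp_radius, config.hp_threshold)
              for im in images]
    images = clip_intensities(images, config.top_percentile, config.clip_floor,
                              panel.low_thresholds)

    # ------------------------------------------------------------ segment + QC
    tables = []
    masks = {}
    for im in images:
        if ext_masks is not None and im.roi_id in ext_masks:
            mask = ext_masks[im.roi_id]
        else:
            mask = segment_cells(im, panel.nuclear_markers, config.cytoplasm_expand_um)
        masks[im.roi_id] = mask
        tables.append(quantify_cells(im, mask))
    cells = pd.concat(tables, ignore_index=True)

    markers = panel.clustering_markers
    all_markers = panel.names
    cells = asinh_transform(cells, all_markers, config.cofactor)
    cells, qc_report = qc_filter(cells, markers, config.area_min, config.area_max,
                                 config.high_value, config.high_count, config.floor_value)
    save_csv(qc_report, "qc_report.csv")
    cells = normalize_intensities(cells, all_markers, config.low_pct, config.high_pct)

    # -------------------------------------------------------------- phenotype
    good = cells[cells["qc_pass"]].reset_index(drop=True)
    result = cluster_cells(good, markers, k=config.k, seed=config.seed,
                           resolution=config.resolution)
    good = annotate_populations(good, result)
    good = refine_populations(good, markers,
                              default_population_rules(), default_subtype_rules(),
                              k_sub=config.k_sub, seed=config.seed)
    save_csv(result.profiles, "cluster_profiles.csv", index=True)

    # ---------------------------------------------------------------- spatial
    interactions = []
    comps, counts_list = [], []
    good["spatial_class"] = spatial_class_labels(good)
    class_list = sorted(set(good["spatial_class"]) - {"other"})
    subtype_classes = sorted(set(good.loc[good["subtype"] != "other", "subtype"]))
    for i, (roi_id, roi_cells) in enumerate(good.groupby("roi_id", sort=True)):
        graph = build_neighbor_graph(masks[roi_id], config.radius_um)
        keep = np.isin(graph.cell_ids, roi_cells["cell_id"].to_numpy())
        graph.cell_ids = graph.cell_ids[keep]
        graph.adjacency = graph.adjacency[keep][:, keep].tocsr()
        ordered = roi_cells.set_index("cell_id").loc[graph.cell_ids]
        res = interaction_test_all(graph, ordered["subtype"].to_numpy(),
                                   n_perm=config.n_perm, alpha=config.alpha,
                                   min_cells=config.min_cells,
                                   seed=[config.seed, 500 + i],
                                   classes=subtype_classes)
        interactions.append(res)
        comp, cnt = neighborhood_compositions(graph, ordered["spatial_class"].to_numpy(),
                                              class_list, return_counts=True)
        comp_df = comp.copy()
        comp_df.insert(0, "roi_id", roi_id)
        comp_df.insert(1, "cell_id", graph.cell_ids)
        comps.append(comp_df)
        counts_list.append(cnt)
    interactions = pd.concat(interactions, ignore_index=True)
    save_csv(interactions, "interactions.csv")
    save_csv(score_matrix(interactions), "score_matrix.csv", index=True)

    comp_all = pd.concat(comps, ignore_index=True)
    counts_all = pd.concat(counts_list, ignore_index=True)
    model = cluster_neighborhoods(comp_all[class_list], k=config.kmeans_k,
                                  iters=config.kmeans_iters, inits=config.kmeans_inits,
                                  seed=config.seed, counts=counts_all)
    comp_all["neighborhood"] = model.assignments
    save_csv(comp_all, "neighborhoods.csv")
    save_csv(model.enrichment, "neighborhood_enrichment.csv")

    nb_map = comp_all.set_index(["roi_id", "cell_id"])["neighborhood"]
    good["neighborhood"] = nb_map.reindex(
        pd.MultiIndex.from_frame(good[["roi_id", "cell_id"]])).to_numpy()

    caf_subtypes = sorted(set(good.loc[good["population"] == "CAF", "subtype"]))
    if caf_subtypes and (good["population"] == "tumor").any():
        good["dist_to_tumor_um"] = min_distance_to(good, caf_subtypes, "tumor")
    save_csv(good, "cells.csv")

    # ------------------------------------------------------------- enrichment
    thr = {"ca19_9": config.ca19_9_threshold, "dfs": config.dfs_threshold,
           "os": config.os_threshold}
    for param in PARAMETERS:
        tab = enrichment_table(good, clinical, param, population="CAF",
                               threshold=thr[param])
        save_csv(tab, f"enrichment_{param}.csv")

    manifest.finished = time.time()
    manifest.outputs = {p.name: _sha256(p) for p in written}
    manifest.to_json(out / "manifest.json")
    return manifest
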