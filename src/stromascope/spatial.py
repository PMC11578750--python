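"""Spatial statistics: neighbor graphs, interaction scores, neighborhoods.

Neighbors are cells whose mask *borders* lie within a radius (default 30 µm)
of each other. Pairwise association between subtypes is scored per ROI by the
patch method (fraction of reference cells with at least one target neighbor)
against a label-permutation null: significantly positive pairs score +1,
significantly negative −1, otherwise 0, and scores are averaged over ROIs.
Cellular neighborhoods are k-means clusters of per-cell neighbor-composition
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import SegmentationMask


@dataclass
class NeighborGraph:
    """Undirected cell-adjacency within ``radius_um`` for one ROI.

    ``adjacency`` is a boolean CSR matrix aligned with ``cell_ids``;
    symmetric, no self-edges.
    """

    roi_id: str
    cell_ids: np.ndarray
    adjacency: sparse.csr_matrix
    radius_um: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edge_list(self) -> pd.DataFrame:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame({
            "roi_id": self.roi_id,
            "cell_a": self.cell_ids[coo.row],
            "cell_b": self.cell_ids[coo.col],
        })


def build_neighbor_graph(mask: SegmentationMask, radius_um: float = 30.0) -> NeighborGraph:
    """Exact border-to-border neighbor graph from a labeled mask.

    Edge (a, b) iff the minimum Euclidean distance between any pixel of a and
    any pixel of b is <= ``radius_um``. Candidate pairs are pre-filtered by
    centroid distance plus per-label extents, then resolved by exact
    pixel-pair distances, so the result equals the brute-force definition.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    um = mask.um_per_px
    flat = mask.labels.ravel()
    nz = np.flatnonzero(flat)
    if len(nz) == 0:
        return NeighborGraph(mask.roi_id, np.empty(0, dtype=int),
                             sparse.csr_matrix((0, 0), dtype=bool), radius_um)
    labs = flat[nz]
    order = np.argsort(labs, kind="stable")
    labs_sorted = labs[order]
    ids, starts = np.unique(labs_sorted, return_index=True)
    bounds = np.append(starts, len(labs_sorted))
    w = mask.labels.shape[1]
    rows = (nz[order] // w).astype(np.float64)
    cols = (nz[order] % w).astype(np.float64)

    n = len(ids)
    coords = [np.column_stack([rows[bounds[i]:bounds[i + 1]],
                               cols[bounds[i]:bounds[i + 1]]]) for i in range(n)]
    centroids = np.array([c.mean(axis=0) for c in coords])
    extents = np.array([np.sqrt(((c - centroids[i]) ** 2).sum(axis=1).max())
                        for i, c in enumerate(coords)])

    radius_px = radius_um / um
    tree = cKDTree(centroids)
    emax = extents.max() if n else 0.0
    cand = tree.query_pairs(radius_px + 2 * emax + 1e-9, output_type="ndarray")

    edges_i, edges_j = [], []
    for i, j in cand:
        if np.linalg.norm(centroids[i] - centroids[j]) > radius_px + extents[i] + extents[j] + 1e-9:
            continue
        dmin = cdist(coords[i], coords[j]).min()
        if dmin * um <= radius_um + 1e-9:
            edges_i.append(i)
            edges_j.append(j)

    data = np.ones(2 * len(edges_i), dtype=bool)
    ii = np.concatenate([edges_i, edges_j]) if edges_i else np.empty(0, dtype=int)
    jj = np.concatenate([edges_j, edges_i]) if edges_i else np.empty(0, dtype=int)
    adj = sparse.csr_matrix((data, (ii, jj)), shape=(n, n), dtype=bool)
    return NeighborGraph(mask.roi_id, ids.astype(int), adj, radius_um)


def graph_from_centroids(x_um, y_um, radius_um: float = 30.0,
                         roi_id: str = "", cell_ids=None) -> NeighborGraph:
    """Neighbor graph treating cells as points (centroid distance <= radius).

    Used for ground-truth tables without rendered masks; with masks,
    :func:`build_neighbor_graph` gives the border-distance graph instead.
    """
    pts = np.column_stack([np.asarray(x_um, float), np.asarray(y_um, float)])
    n = len(pts)
    if cell_ids is None:
        cell_ids = np.arange(1, n + 1)
    pairs = cKDTree(pts).query_pairs(radius_um + 1e-9, output_type="ndarray")
    if len(pairs):
        ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
        jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = sparse.csr_matrix((np.ones(len(ii), dtype=bool), (ii, jj)),
                                shape=(n, n), dtype=bool)
    else:
        adj = sparse.csr_matrix((n, n), dtype=bool)
    return NeighborGraph(roi_id, np.asarray(cell_ids), adj, radius_um)


# ---------------------------------------------------------------------------
# patch-method interaction scoring

def patch_fraction(graph: NeighborGraph, labels, ref: str, target: str) -> float:
    """Fraction of ``ref`` cells with >= 1 neighbor labeled ``target``.

    ``labels`` is aligned with ``graph.cell_ids``. Self-pairs never count
    (the graph has no self-edges); ``ref == target`` is allowed. Returns NaN
    when the ROI has no ``ref`` cells (undefined, to be excluded upstream).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels must align with graph.cell_ids")
    ref_mask = labels == ref
    if not ref_mask.any():
        return float("nan")
    has_target = graph.adjacency.dot((labels == target).astype(np.int64)) > 0
    return float(has_target[ref_mask].mean())


def _permutation_counts(adj, codes, n_classes, n_perm, rng, chunk=256,
                        statistic="patch"):
    """Permutation-null tail counts for every ordered class pair.

    Statistic per (ref, target): with ``statistic="patch"``, the number of
    ref cells with >= 1 target neighbor (an integer; the class sizes, hence
    the patch-fraction denominators, are permutation-invariant); with
    ``"edges"``, the total ref→target neighbor-pair count. Returns
    (obs, ge, le): observed counts and the number of permutations with
    statistic >= / <= observed.
    """
    n = len(codes)
    c = n_classes

    def per_cell(m):
        return (m > 0).astype(np.float32) if statistic == "patch" else m.astype(np.float32)

    onehot_codes = np.zeros((n, c), dtype=np.float32)
    onehot_codes[np.arange(n), codes] = 1.0
    has = per_cell(adj.dot(onehot_codes))
    obs = (onehot_codes.T @ has).astype(np.int64)  # c×c: ref rows, target cols

    ge = np.zeros((c, c), dtype=np.int64)
    le = np.zeros((c, c), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(codes, (b, n)), axis=1)
        big = np.zeros((b, n, c), dtype=np.float32)  # one-hot permuted labels
        big[np.arange(b)[:, None], np.arange(n)[None, :], perms] = 1.0
        flat = np.ascontiguousarray(big.transpose(1, 0, 2)).reshape(n, b * c)
        has_p = per_cell(adj.dot(flat)).reshape(n, b, c)
        # group rows by the *permuted* reference label of each cell
        stats_p = np.matmul(big.transpose(0, 2, 1),
                            np.ascontiguousarray(has_p.transpose(1, 0, 2),
                                                 dtype=np.float32))
        ge += (stats_p >= obs[None, :, :] - 0.5).sum(axis=0)
        le += (stats_p <= obs[None, :, :] + 0.5).sum(axis=0)
        done += b
    return obs, ge, le


def interaction_test_all(graph: NeighborGraph, labels, n_perm: int = 5000,
                         alpha: float = 0.01, min_cells: int = 10,
                         seed=0, classes=None,
                         statistic: str = "patch") -> pd.DataFrame:
    """Permutation interaction test for every ordered subtype pair of one ROI.

    The null permutes subtype labels over the ROI's fixed cell positions
    (graph held fixed). One-sided p-values use the add-one estimator
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)``; a pair scores +1 when
    ``p_high < alpha``, −1 when ``p_low < alpha``, else 0. Pairs where either
    subtype has fewer than ``min_cells`` cells are recorded with
    ``included=False``. Passing ``classes`` restricts the tested universe
    (cells with other labels drop out of the permutation); ``statistic``
    selects the patch fraction (default, the reported quantity) or the raw
    ref→target edge count.
    """
    if statistic not in ("patch", "edges"):
        raise ValueError("statistic must be 'patch' or 'edges'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels must align with graph.cell_ids")
    if classes is None:
        classes = sorted(set(labels))
    classes = list(classes)
    lut = {s: i for i, s in enumerate(classes)}
    keep = np.array([l in lut for l in labels])
    codes_all = np.array([lut[l] for l in labels[keep]], dtype=np.intp)
    adj = graph.adjacency[keep][:, keep].tocsr()

    rng = np.random.default_rng(seed)
    obs, ge, le = _permutation_counts(adj, codes_all, len(classes), n_perm, rng,
                                      statistic=statistic)
    counts = np.bincount(codes_all, minlength=len(classes))

    rows = []
    for r, ref in enumerate(classes):
        for t, target in enumerate(classes):
            included = counts[r] >= min_cells and counts[t] >= min_cells
            frac = obs[r, t] / counts[r] if counts[r] else np.nan
            p_high = (1 + ge[r, t]) / (n_perm + 1)
            p_low = (1 + le[r, t]) / (n_perm + 1)
            score = 1 if p_high < alpha else (-1 if p_low < alpha else 0)
            rows.append((graph.roi_id, ref, target, int(counts[r]), int(counts[t]),
                         frac, p_high, p_low, score, included))
    return pd.DataFrame(rows, columns=[
        "roi_id", "ref", "target", "n_ref", "n_target",
        "patch_fraction", "p_high", "p_low", "score", "included"])


def interaction_test(graph: NeighborGraph, labels, ref: str, target: str,
                     n_perm: int = 5000, alpha: float = 0.01,
                     min_cells: int = 10, seed: int = 0) -> pd.Series:
    """Single-pair convenience wrapper around :func:`interaction_test_all`.

    All labels participate in the permutation (the null must shuffle the full
    label vector); only the requested pair's row is returned.
    """
    df = interaction_test_all(graph, labels, n_perm=n_perm, alpha=alpha,
                              min_cells=min_cells, seed=seed)
    row = df[(df["ref"] == ref) & (df["target"] == target)].iloc[0]
    return row


def score_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Mean per-ROI ±1 score per (reference, target) pair.

    Only rows with ``included=True`` contribute; pairs eligible in no ROI are
    missing (NaN), never 0. Reference/target asymmetry is intentional.
    """
    inc = results[results["included"]]
    mat = inc.pivot_table(index="ref", columns="target", values="score", aggfunc="mean")
    refs = sorted(results["ref"].unique())
    targets = sorted(results["target"].unique())
    return mat.reindex(index=refs, columns=targets)


# ---------------------------------------------------------------------------
# distances

def min_distance_to(table: pd.DataFrame, from_subtypes: list[str],
                    to_population: str) -> pd.Series:
    """Per-cell minimum centroid distance (µm) to a target population.

    Computed within each ROI independently; cells in ROIs without any target
    cell get NaN (undefined, flagged by absence). Only cells whose subtype is
    in ``from_subtypes`` receive a value.
    """
    out = pd.Series(np.nan, index=table.index, name="min_dist_um")
    for _, roi in table.groupby("roi_id"):
        targets = roi[roi["population"] == to_population]
        sources = roi[roi["subtype"].isin(from_subtypes)]
        if len(sources) == 0 or len(targets) == 0:
            continue
        tree = cKDTree(targets[["centroid_x_um", "centroid_y_um"]].to_numpy())
        d, _ = tree.query(sources[["centroid_x_um", "centroid_y_um"]].to_numpy())
        out.loc[sources.index] = d
    return out


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    D is the supremum ECDF difference, computed here directly; the p-value
    comes from :func:`scipy.stats.ks_2samp` (exact for small samples,
    asymptotic otherwise).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / len(a)
    cdf_b = np.searchsorted(b, allv, side="right") / len(b)
    d = float(np.abs(cdf_a - cdf_b).max())
    p = float(stats.ks_2samp(a, b, alternative="two-sided").pvalue)
    return d, p


# ---------------------------------------------------------------------------
# cellular neighborhoods

def neighborhood_compositions(graph: NeighborGraph, labels, class_list,
                              exclude=("other",), return_counts: bool = False):
    """Per-cell neighbor-composition vectors over a fixed class list.

    For each cell, neighbors (self excluded) are counted per class and the
    counts normalized to sum to 1; isolated cells get all-zero vectors.
    Labels in ``exclude`` stay in the graph but contribute to no class;
    any other label missing from ``class_list`` is an error.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels must align with graph.cell_ids")
    class_list = list(class_list)
    lut = {s: i for i, s in enumerate(class_list)}
    unknown = set(labels) - set(class_list) - set(exclude)
    if unknown:
        raise ValueError(f"labels not mappable to a class: {sorted(map(str, unknown))}")

    onehot = np.zeros((graph.n_cells, len(class_list)), dtype=np.float64)
    for i, l in enumerate(labels):
        if l in lut:
            onehot[i, lut[l]] = 1.0
    counts = graph.adjacency.dot(onehot)
    totals = counts.sum(axis=1, keepdims=True)
    comp = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    comp_df = pd.DataFrame(comp, index=graph.cell_ids, columns=class_list)
    if return_counts:
        return comp_df, pd.DataFrame(counts, index=graph.cell_ids, columns=class_list)
    return comp_df


@dataclass
class NeighborhoodModel:
    """k-means partition of composition vectors into spatial neighborhoods."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_effective: int
    enrichment: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def cluster_neighborhoods(vectors, k: int = 10, iters: int = 1500, inits: int = 10,
                          seed: int = 0, counts: pd.DataFrame | None = None,
                          drop_isolated: bool = False) -> NeighborhoodModel:
    """k-means over composition vectors (best inertia of ``inits`` restarts).

    Isolated cells (all-zero vectors) form their own "sparse" neighborhood
    unless ``drop_isolated`` removes them (their assignment is then -1).
    When ``counts`` (raw neighbor counts per class) are supplied, a
    per-neighborhood class-enrichment table (upper-tail hypergeometric with
    BH correction across classes) is emitted to support manual annotation.
    Degenerate inputs with fewer distinct vectors than k yield duplicated
    centroids and fewer effective clusters, reported in ``n_effective``.
    """
    import warnings as _warnings

    from sklearn.cluster import KMeans
    from sklearn.exceptions import ConvergenceWarning

    x = np.asarray(vectors, dtype=np.float64)
    index = vectors.index if isinstance(vectors, pd.DataFrame) else pd.RangeIndex(len(x))
    if len(x) < k:
        raise ValueError(f"need at least k={k} vectors, got {len(x)}")
    assign = np.full(len(x), -1, dtype=int)
    use = np.ones(len(x), dtype=bool)
    if drop_isolated:
        use = x.sum(axis=1) > 0
        if use.sum() < k:
            raise ValueError("fewer non-isolated vectors than k")
    km = KMeans(n_clusters=k, max_iter=iters, n_init=inits, random_state=seed,
                algorithm="lloyd")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        assign[use] = km.fit_predict(x[use])
    n_eff = len(np.unique(np.unique(km.cluster_centers_, axis=0), axis=0))

    enrich = None
    if counts is not None:
        enrich = _neighborhood_enrichment(np.asarray(counts, float)[use], assign[use],
                                          list(counts.columns), k)
    return NeighborhoodModel(k, km.cluster_centers_, assign, float(km.inertia_),
                             n_eff, enrich,
                             {"iters": iters, "inits": inits, "seed": seed})


def _neighborhood_enrichment(counts, assign, class_names, k) -> pd.DataFrame:
    """Hypergeometric over-representation of each class in each neighborhood."""
    from statsmodels.stats.multitest import multipletests

    total = counts.sum()
    class_tot = counts.sum(axis=0)
    rows = []
    for nb in range(k):
        sel = assign == nb
        nb_counts = counts[sel].sum(axis=0)
        nb_tot = nb_counts.sum()
        pvals = np.ones(len(class_names))
        for ci in range(len(class_names)):
            if nb_tot == 0 or class_tot[ci] == 0:
                continue
            pvals[ci] = stats.hypergeom.sf(int(round(nb_counts[ci])) - 1, int(round(total)),
                                           int(round(class_tot[ci])), int(round(nb_tot)))
        fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
        for ci, name in enumerate(class_names):
            global_frac = class_tot[ci] / total if total else 0.0
            nb_frac = nb_counts[ci] / nb_tot if nb_tot else 0.0
            rows.append((nb, name, nb_frac, global_frac, pvals[ci], fdr[ci]))
    return pd.DataFrame(rows, columns=[
        "neighborhood", "class", "mean_fraction", "global_fraction", "p_value", "fdr"])
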