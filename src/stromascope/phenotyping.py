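"""Intensity transformation, clustering and hierarchical cell annotation.

The phenotyping path follows the standard mass-cytometry recipe: asinh
transform, percentile normalization pooled over all cells, graph-based
clustering (kNN graph, Jaccard-refined edge weights, modularity community
detection — the PhenoGraph construction), rule-based assignment of clusters
to five major populations (tumor, immune, endothelial, CAF, pancreatic
islet), a misannotation-repair loop on each population subset, and a final
per-population re-clustering labeled into subtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import NearestNeighbors

from .core import ASINH_PREFIX, NORM_PREFIX, RAW_PREFIX, intensity_columns

logger = logging.getLogger(__name__)

MAJOR_POPULATIONS = ("tumor", "immune", "EC", "CAF", "islet")
OTHER = "other"

#: cluster-mean spread (normalized scale) below which a marker carries no
#: information and positivity cannot be claimed
_MIN_SPREAD = 0.1


# ---------------------------------------------------------------------------
# transforms

def asinh_transform(table: pd.DataFrame, markers: list[str], cofactor: float = 1.0) -> pd.DataFrame:
    """Add ``asinh_<marker>`` = asinh(raw / cofactor) columns."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    out = table.copy()
    for m in markers:
        out[ASINH_PREFIX + m] = np.arcsinh(out[RAW_PREFIX + m] / cofactor)
    return out


def normalize_intensities(table: pd.DataFrame, markers: list[str],
                          low_pct: float = 1.0, high_pct: float = 99.0) -> pd.DataFrame:
    """Clip asinh values to pooled percentiles and rescale to [0, 1].

    Percentiles are computed per marker over QC-passing cells pooled across
    ROIs (the "overall signal"); clipping uses linear-interpolation
    percentiles. A marker whose two percentiles coincide is set to 0 with a
    warning. Weakly monotone: within-marker order is preserved up to the
    ties created by clipping.
    """
    out = table.copy()
    pool = out[out["qc_pass"]] if "qc_pass" in out.columns else out
    if len(pool) == 0:
        raise ValueError("no cells available to compute normalization percentiles")
    for m in markers:
        col = ASINH_PREFIX + m
        lo, hi = np.percentile(pool[col], [low_pct, high_pct])
        if hi <= lo:
            warnings.warn(f"marker {m}: degenerate percentile range, set to 0")
            out[NORM_PREFIX + m] = 0.0
        else:
            out[NORM_PREFIX + m] = (out[col].clip(lo, hi) - lo) / (hi - lo)
    return out


def transform_normalize(table: pd.DataFrame, markers: list[str], cofactor: float = 1.0,
                        low_pct: float = 1.0, high_pct: float = 99.0) -> pd.DataFrame:
    """asinh transform followed by pooled 1–99% min-max normalization."""
    return normalize_intensities(asinh_transform(table, markers, cofactor),
                                 markers, low_pct, high_pct)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusteringResult:
    """Community partition of cells in normalized marker space."""

    labels: np.ndarray                  # per-cell cluster id, aligned to the input rows
    profiles: pd.DataFrame              # cluster × marker mean normalized intensity
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.profiles)


def cluster_cells(table: pd.DataFrame, markers: list[str], k: int = 60,
                  seed: int = 0, resolution: float = 1.0) -> ClusteringResult:
    """PhenoGraph-style clustering on the ``norm_*`` columns.

    Builds an exact Euclidean k-nearest-neighbor graph, reweights each edge
    by the Jaccard overlap of the two endpoints' graph neighborhoods, and
    partitions by seeded modularity (Leiden, RB configuration at the given
    resolution). Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not markers:
        raise ValueError("markers must be nonempty")
    cols = intensity_columns(markers, NORM_PREFIX)
    x = table[cols].to_numpy()
    n = len(x)
    if n == 0:
        raise ValueError("empty table")
    if n <= k:
        raise ValueError(f"only {n} cells for k={k}; use a smaller k")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((i, j) if i < j else (j, i))
    edges = sorted(edges)
    g = ig.Graph(n=n, edges=edges)
    weights = g.similarity_jaccard(pairs=edges, loops=False)

    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution,
        seed=seed, n_iterations=-1,
    )
    labels = np.asarray(part.membership)

    prof = (pd.DataFrame(x, columns=markers)
            .groupby(labels).mean()
            .rename_axis("cluster"))
    return ClusteringResult(labels, prof,
                            {"k": k, "seed": seed, "resolution": resolution})


# ---------------------------------------------------------------------------
# rule-based annotation

@dataclass(frozen=True)
class MarkerRule:
    """Gating rule: a population/subtype is positive/negative for given markers."""

    name: str
    required_positive: tuple[str, ...] = ()
    required_negative: tuple[str, ...] = ()
    positivity_quantile: float = 0.5

    def __post_init__(self) -> None:
        overlap = set(self.required_positive) & set(self.required_negative)
        if overlap:
            raise ValueError(f"rule {self.name}: markers both + and -: {sorted(overlap)}")
        if not 0 < self.positivity_quantile < 1:
            raise ValueError("positivity_quantile must be in (0, 1)")


def default_population_rules() -> list[MarkerRule]:
    """Gates for the five major populations on cluster-mean profiles."""
    return [
        MarkerRule("tumor", ("Pan-Ck",), ("CD45", "CD31")),
        MarkerRule("immune", ("CD45",), ("Pan-Ck",)),
        MarkerRule("EC", ("CD31",), ("CD45", "Pan-Ck")),
        MarkerRule("islet", ("peptide-C",), ()),
        MarkerRule("CAF", ("vimentin",), ("CD45", "Pan-Ck", "CD31")),
    ]


def default_subtype_rules() -> dict[str, list[MarkerRule]]:
    """Named subtype gates per population; unmatched sub-clusters get numbered."""
    return {
        "CAF": [
            MarkerRule("myCAF", ("aSMA", "vimentin"), ("FAP", "CD74")),
            MarkerRule("iCAF", ("FAP",), ("CD74",)),
            MarkerRule("apCAF", ("CD74", "HLA-DR"), ()),
        ],
        "immune": [
            MarkerRule("T_cell", ("CD3",), ("CD20", "CD68")),
            MarkerRule("B_cell", ("CD20",), ("CD3",)),
            MarkerRule("macrophage", ("CD68",), ("CD3", "CD20")),
        ],
    }


def rules_to_yaml(rules, path) -> None:
    data = [{"name": r.name, "required_positive": list(r.required_positive),
             "required_negative": list(r.required_negative),
             "positivity_quantile": r.positivity_quantile} for r in rules]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def rules_from_yaml(path) -> list[MarkerRule]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [MarkerRule(d["name"], tuple(d.get("required_positive", ())),
                       tuple(d.get("required_negative", ())),
                       d.get("positivity_quantile", 0.5)) for d in data]


def marker_thresholds(profiles: pd.DataFrame, quantile: float = 0.5) -> pd.Series:
    """Per-marker positivity threshold from cluster-mean profiles.

    The threshold interpolates the cluster-mean range: ``min + q*(max-min)``.
    Markers whose cluster means span less than ``_MIN_SPREAD`` (on the [0,1]
    normalized scale) are uninformative; their threshold is +inf so no
    cluster is called positive for them.
    """
    lo = profiles.min(axis=0)
    hi = profiles.max(axis=0)
    thr = lo + quantile * (hi - lo)
    thr[hi - lo < _MIN_SPREAD] = np.inf
    return thr


def _rule_score(profile: pd.Series, rule: MarkerRule, thr: pd.Series) -> tuple[bool, float]:
    """(satisfied, margin) of a cluster-mean profile against a gate."""
    margins = []
    ok = True
    for m in rule.required_positive:
        if not np.isfinite(thr[m]):
            ok = False
            margins.append(-1.0)
            continue
        margins.append(profile[m] - thr[m])
        ok &= profile[m] > thr[m]
    for m in rule.required_negative:
        if not np.isfinite(thr[m]):
            margins.append(1.0)  # uninformative marker counts as negative
            continue
        margins.append(thr[m] - profile[m])
        ok &= profile[m] <= thr[m]
    return ok, (float(np.mean(margins)) if margins else 0.0)


def assign_clusters(profiles: pd.DataFrame, rules: list[MarkerRule],
                    thresholds: pd.Series | None = None) -> pd.Series:
    """Map each cluster to the best-satisfied rule name, else ``other``.

    A cluster satisfying several gates goes to the best-scoring one and is
    logged as ambiguous.
    """
    if thresholds is None:
        q = rules[0].positivity_quantile if rules else 0.5
        thresholds = marker_thresholds(profiles, q)
    out = {}
    for cid, profile in profiles.iterrows():
        hits = []
        for rule in rules:
            ok, margin = _rule_score(profile, rule, thresholds)
            if ok:
                hits.append((margin, rule.name))
        if not hits:
            out[cid] = OTHER
        else:
            if len(hits) > 1:
                logger.info("cluster %s ambiguous between %s; keeping best",
                            cid, [h[1] for h in hits])
            out[cid] = max(hits)[1]
    return pd.Series(out, name="population")


def annotate_populations(table: pd.DataFrame, result: ClusteringResult,
                         rules: list[MarkerRule] | None = None,
                         positivity_quantile: float = 0.5) -> pd.DataFrame:
    """Assign every clustered cell to a major population via cluster gates."""
    rules = rules or default_population_rules()
    thr = marker_thresholds(result.profiles, positivity_quantile)
    mapping = assign_clusters(result.profiles, rules, thr)
    out = table.copy()
    out["cluster"] = result.labels
    out["population"] = mapping.reindex(result.labels).to_numpy()
    return out


def refine_populations(table: pd.DataFrame, markers: list[str],
                       population_rules: list[MarkerRule] | None = None,
                       subtype_rules: dict[str, list[MarkerRule]] | None = None,
                       k_sub: int = 20, seed: int = 0,
                       positivity_quantile: float = 0.5) -> pd.DataFrame:
    """Repair misannotated sub-clusters, then split populations into subtypes.

    Phase 1: each major population is re-clustered; a sub-cluster whose mean
    profile satisfies a *different* population's gate better than its own is
    reassigned wholesale. Phase 2: each (repaired) population is re-clustered
    again and its sub-clusters are labeled by the population's subtype gates;
    sub-clusters matching no gate get numbered names like ``CAF 2``.
    Populations with fewer than ``k_sub + 1`` cells are left unrefined with a
    warning.
    """
    population_rules = population_rules or default_population_rules()
    subtype_rules = subtype_rules or default_subtype_rules()
    out = table.copy()
    if "population" not in out.columns:
        raise ValueError("run annotate_populations first")

    # phase 1 — cluster every population once, pool the sub-cluster profiles,
    # and re-gate them against the major-population rules
    sub_results: dict[str, ClusteringResult] = {}
    pooled = []
    for pop in MAJOR_POPULATIONS:
        sel = out.index[out["population"] == pop]
        if len(sel) == 0:
            continue
        if len(sel) <= k_sub:
            warnings.warn(f"population {pop}: {len(sel)} cells < k_sub={k_sub}, left unrefined")
            continue
        res = cluster_cells(out.loc[sel], markers, k=k_sub, seed=seed)
        sub_results[pop] = res
        prof = res.profiles.copy()
        prof.index = [f"{pop}:{c}" for c in prof.index]
        pooled.append(prof)
    if pooled:
        pooled_prof = pd.concat(pooled)
        thr = marker_thresholds(pooled_prof, positivity_quantile)
        mapping = assign_clusters(pooled_prof, population_rules, thr)
        for pop, res in sub_results.items():
            sel = out.index[out["population"] == pop]
            for cid in res.profiles.index:
                new_pop = mapping[f"{pop}:{cid}"]
                if new_pop not in (pop, OTHER):
                    cells = sel[res.labels == cid]
                    logger.info("reassigning %d cells %s -> %s", len(cells), pop, new_pop)
                    out.loc[cells, "population"] = new_pop

    # phase 2 — final subtype split within each repaired population
    out["subtype"] = OTHER
    for pop in MAJOR_POPULATIONS:
        sel = out.index[out["population"] == pop]
        if len(sel) == 0:
            continue
        if len(sel) <= k_sub:
            out.loc[sel, "subtype"] = f"{pop} 1"
            continue
        res = cluster_cells(out.loc[sel], markers, k=k_sub, seed=seed)
        rules = subtype_rules.get(pop, [])
        if rules:
            thr = marker_thresholds(res.profiles, positivity_quantile)
            mapping = assign_clusters(res.profiles, rules, thr)
        else:
            mapping = pd.Series(OTHER, index=res.profiles.index)
        sizes = pd.Series(res.labels).value_counts()
        counter = 0
        names = {}
        for cid in sizes.index:  # biggest first for stable numbering
            if mapping[cid] != OTHER:
                names[cid] = mapping[cid]
            else:
                counter += 1
                names[cid] = f"{pop} {counter}"
        out.loc[sel, "subtype"] = pd.Series(res.labels, index=sel).map(names)
    return out


# ---------------------------------------------------------------------------
# embedding

def embed_2d(table: pd.DataFrame, markers: list[str], seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP of the normalized marker space, for reporting only.

    Deterministic for a fixed seed; never used for any assignment.
    """
    if len(table) == 0:
        return np.empty((0, 2))
    import umap  # deferred: heavy import

    x = table[intensity_columns(markers, NORM_PREFIX)].to_numpy()
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return reducer.fit_transform(x)
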