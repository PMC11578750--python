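"""Clinical splits and signed, capped hypergeometric enrichment scores.

Patients are dichotomized by conventional thresholds (CA19-9 100 IU/L,
DFS 13.5 months, OS 18 months) into good/bad prognosis groups. For each CAF
subtype the over-representation of its cells in each group is tested with an
upper-tail hypergeometric test, BH-corrected across subtypes within the
group, and summarized as a signed score: −log10(fdr) for the good group,
+log10(fdr) for the bad group (so negative scores mean bad-group
enrichment), with fdr floored at 1e-10 and set to 1 (score 0) above 0.001.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: clinical parameter -> (column, threshold, bad-side predicate)
PARAMETERS = {
    "ca19_9": ("ca19_9_iu_l", 100.0),
    "dfs": ("dfs_months", 13.5),
    "os": ("os_months", 18.0),
}

FDR_CAP = 1e-10
FDR_SIGNIFICANT = 1e-3


def split_patients(clinical: pd.DataFrame, parameter: str,
                   threshold: float | None = None) -> dict[str, list[str]]:
    """Dichotomize patients into ``bad`` and ``good`` prognosis groups.

    Bad is CA19-9 > threshold (high tumor burden), DFS <= threshold (early
    relapse) or OS <= threshold (short survival); the boundary value goes to
    the good group for CA19-9 and to the bad group for DFS/OS. Patients with
    a missing value are excluded with a warning.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {sorted(PARAMETERS)}")
    col, default_thr = PARAMETERS[parameter]
    thr = default_thr if threshold is None else threshold
    vals = clinical[col]
    missing = clinical[vals.isna()]
    if len(missing):
        warnings.warn(f"{parameter}: excluding patients with missing values: "
                      f"{list(missing['patient_id'])}")
    present = clinical[vals.notna()]
    if parameter == "ca19_9":
        bad = present[present[col] > thr]
    else:
        bad = present[present[col] <= thr]
    good = present.drop(bad.index)
    return {"bad": list(bad["patient_id"]), "good": list(good["patient_id"])}


def hypergeom_upper_tail(x: int, total: int, group: int, subtype: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N=total, K=group, n=subtype)."""
    if not (0 <= group <= total and 0 <= subtype <= total):
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(x - 1, total, group, subtype))


def hypergeometric_enrichment(cells: pd.DataFrame,
                              groups: dict[str, list[str]]) -> pd.DataFrame:
    """Per-subtype upper-tail hypergeometric enrichment in each group.

    The universe is cells: N = all cells in ``cells`` (typically the CAF
    compartment), K = cells from the group's patients, n = cells of the
    subtype, x = subtype cells from the group; p = P(X >= x). BH correction
    runs across subtypes within each group.
    """
    for g in ("bad", "good"):
        if not groups.get(g):
            raise ValueError(f"group {g!r} is empty; cannot test enrichment")
    if "subtype" not in cells.columns or cells["subtype"].isna().all():
        raise ValueError("cells must carry subtype labels")
    n_total = len(cells)
    if n_total == 0:
        raise ValueError("no cells supplied")
    subtypes = sorted(cells["subtype"].unique())
    out = pd.DataFrame(index=pd.Index(subtypes, name="subtype"))
    for g in ("bad", "good"):
        in_group = cells["patient_id"].isin(groups[g])
        big_k = int(in_group.sum())
        pvals = []
        for s in subtypes:
            of_subtype = cells["subtype"] == s
            n = int(of_subtype.sum())
            x = int((of_subtype & in_group).sum())
            pvals.append(hypergeom_upper_tail(x, n_total, big_k, n))
        out[f"n_{g}"] = [int(((cells["subtype"] == s) & in_group).sum()) for s in subtypes]
        out[f"p_{g}"] = pvals
        out[f"fdr_{g}"] = multipletests(pvals, method="fdr_bh")[1]
    out["n_subtype"] = [int((cells["subtype"] == s).sum()) for s in subtypes]
    return out


def enrichment_score(fdr_good: float, fdr_bad: float,
                     cap: float = FDR_CAP, significant: float = FDR_SIGNIFICANT) -> float:
    """Signed, capped log10-fdr score in [−10, 10].

    Each fdr is floored at ``cap`` and set to 1 when above ``significant``.
    Good-group significance gives −log10(fdr_good) (positive), bad-group
    +log10(fdr_bad) (negative). Both non-significant -> 0; both significant
    -> the smaller fdr wins (logged).
    """
    for f in (fdr_good, fdr_bad):
        if not 0 < f <= 1:
            raise ValueError(f"fdr must be in (0, 1], got {f}")
    g = 1.0 if fdr_good > significant else max(fdr_good, cap)
    b = 1.0 if fdr_bad > significant else max(fdr_bad, cap)
    g_sig, b_sig = g < 1.0, b < 1.0
    if not g_sig and not b_sig:
        return 0.0
    if g_sig and b_sig:
        logger.info("both groups significant (good=%.3g, bad=%.3g); smaller fdr wins",
                    fdr_good, fdr_bad)
        if g == b:  # perfect tie: no direction, and the only antisymmetric value
            return 0.0
        return -np.log10(g) if g < b else np.log10(b)
    return float(-np.log10(g)) if g_sig else float(np.log10(b))


def enrichment_table(cells: pd.DataFrame, clinical: pd.DataFrame,
                     parameter: str, population: str = "CAF",
                     threshold: float | None = None) -> pd.DataFrame:
    """Per-subtype enrichment scores for one clinical parameter.

    Restricts ``cells`` to the requested population (CAF by default,
    matching the subtype-level prognosis analysis), splits patients, runs the
    hypergeometric tests and attaches the signed capped score.
    """
    sub = cells[cells["population"] == population]
    if len(sub) == 0:
        raise ValueError(f"no cells of population {population!r}")
    groups = split_patients(clinical, parameter, threshold)
    res = hypergeometric_enrichment(sub, groups)
    res["parameter"] = parameter
    res["score"] = [enrichment_score(row["fdr_good"], row["fdr_bad"])
                    for _, row in res.iterrows()]
    return res.reset_index()
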