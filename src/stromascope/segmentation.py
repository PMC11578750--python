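"""Cell segmentation, per-cell quantification and object QC.

Nuclei are detected on the summed, Gaussian-smoothed DNA channels
(threshold + local-maximum seeds), split by seeded watershed and expanded by
a fixed cytoplasm rim without crossing neighboring cells. Externally produced
label masks can be used instead; everything downstream only consumes the
labeled mask.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops_table
from skimage.segmentation import expand_labels, watershed

from .core import ASINH_PREFIX, RAW_PREFIX, ROIImage, SegmentationMask, intensity_columns


def segment_cells(
    image: ROIImage,
    nuclear_markers: list[str],
    cytoplasm_expand_um: float = 3.0,
    smooth_sigma_px: float = 1.0,
    seed_min_distance_um: float = 3.0,
    nuclear_threshold: float | None = None,
) -> SegmentationMask:
    """Watershed segmentation seeded on nuclear signal.

    ``nuclear_threshold`` (dual counts, on the smoothed summed nuclear image)
    defaults to half the Otsu threshold, which is robust for sparse nuclei on
    a faint Poisson background. Deterministic for fixed input. An image with
    no nuclear signal yields an empty mask with a warning, not an error.
    """
    if not nuclear_markers:
        raise ValueError("at least one nuclear marker is required")
    nuc = sum(image.channel(m) for m in nuclear_markers)
    smoothed = ndimage.gaussian_filter(nuc, sigma=smooth_sigma_px)

    if nuclear_threshold is None:
        if smoothed.max() <= 0 or np.ptp(smoothed) == 0:
            warnings.warn(f"ROI {image.roi_id}: no nuclear signal, empty mask")
            return SegmentationMask(image.roi_id,
                                    np.zeros(image.shape, dtype=np.int32),
                                    image.um_per_px)
        from skimage.filters import threshold_otsu
        nuclear_threshold = 0.5 * threshold_otsu(smoothed)

    foreground = smoothed > nuclear_threshold
    if not foreground.any():
        warnings.warn(f"ROI {image.roi_id}: no nuclear signal, empty mask")
        return SegmentationMask(image.roi_id,
                                np.zeros(image.shape, dtype=np.int32),
                                image.um_per_px)

    min_dist_px = max(1, int(round(seed_min_distance_um / image.um_per_px)))
    peaks = peak_local_max(smoothed, min_distance=min_dist_px, labels=foreground,
                           exclude_border=False)
    seeds = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    nuclei = watershed(-smoothed, seeds, mask=foreground)

    expand_px = cytoplasm_expand_um / image.um_per_px
    cells = expand_labels(nuclei, distance=expand_px)

    # relabel to a contiguous 1..N range, ordered by first pixel occurrence
    ids = np.unique(cells[cells > 0])
    lut = np.zeros(cells.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return SegmentationMask(image.roi_id, lut[cells], image.um_per_px)


def quantify_cells(image: ROIImage, mask: SegmentationMask) -> pd.DataFrame:
    """One row per label: mean raw intensity per marker, area (µm²), centroid (µm).

    Mean intensity is the arithmetic mean of channel values over the label's
    pixels; area is the pixel count times ``um_per_px²``; centroids follow
    the pixel-centered x=column / y=row convention.
    """
    if mask.labels.shape != image.shape:
        raise ValueError("mask and image dimensions differ")
    if mask.labels.min() < 0:
        raise ValueError("mask labels must be non-negative")
    cols = ["cell_id", "roi_id", "patient_id", "centroid_x_um", "centroid_y_um",
            "area_um2"] + intensity_columns(image.marker_names)
    if mask.n_cells == 0:
        return pd.DataFrame(columns=cols)

    stack = np.moveaxis(image.channels, 0, -1)  # H, W, C for regionprops
    props = regionprops_table(
        mask.labels, intensity_image=stack,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    um = image.um_per_px
    table = pd.DataFrame({
        "cell_id": props["label"].astype(int),
        "roi_id": image.roi_id,
        "patient_id": image.patient_id,
        "centroid_x_um": props["centroid-1"] * um,
        "centroid_y_um": props["centroid-0"] * um,
        "area_um2": props["area"] * um ** 2,
    })
    for i, name in enumerate(image.marker_names):
        table[RAW_PREFIX + name] = props[f"intensity_mean-{i}"]
    return table


QC_RULES = ("area_small", "area_large", "high_many_markers", "low_all_clustering")


def qc_filter(
    table: pd.DataFrame,
    clustering_markers: list[str],
    area_min: float = 10.0,
    area_max: float = 1000.0,
    high_value: float = 2.0,
    high_count: int = 15,
    floor_value: float = 0.01,
    low_rule_mode: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag implausible objects; returns (table with ``qc_pass``, discard report).

    Rules (a cell failing any is marked ``qc_pass=False``):

    - area < ``area_min`` µm² (debris);
    - area > ``area_max`` µm² (clumps);
    - asinh-transformed mean intensity > ``high_value`` in more than
      ``high_count`` markers (smears/antibody aggregates);
    - asinh intensity below ``floor_value`` in *all* clustering markers
      (blank, uninformative objects). ``low_rule_mode="any"`` switches to the
      stricter any-marker reading.

    Intensity rules run on the asinh scale (``asinh_*`` columns), where the
    conventional cutoffs 2 and 0.01 are meaningful; raw dual counts routinely
    exceed 2. The report counts discards per rule per ROI; rules are evaluated
    independently, so the filter is order-independent and idempotent.
    """
    if len(table) == 0:
        raise ValueError("qc_filter requires a nonempty table")
    if not clustering_markers:
        raise ValueError("clustering_markers must be nonempty")
    if low_rule_mode not in ("all", "any"):
        raise ValueError("low_rule_mode must be 'all' or 'any'")
    acols = intensity_columns(clustering_markers, ASINH_PREFIX)
    missing = [c for c in acols if c not in table.columns]
    if missing:
        raise ValueError(
            f"asinh-transformed columns missing (run asinh_transform first): {missing[:3]}...")

    out = table.copy()
    # the high-intensity rule spans every transformed marker; the blank-cell
    # rule only the markers that feed clustering
    all_acols = [c for c in out.columns if c.startswith(ASINH_PREFIX)]
    a_all = out[all_acols].to_numpy()
    a = out[acols].to_numpy()
    fails = {
        "area_small": out["area_um2"].to_numpy() < area_min,
        "area_large": out["area_um2"].to_numpy() > area_max,
        "high_many_markers": (a_all > high_value).sum(axis=1) > high_count,
    }
    low = a < floor_value
    fails["low_all_clustering"] = low.all(axis=1) if low_rule_mode == "all" else low.any(axis=1)

    any_fail = np.zeros(len(out), dtype=bool)
    for f in fails.values():
        any_fail |= f
    out["qc_pass"] = ~any_fail

    rows = []
    for roi, grp_idx in out.groupby("roi_id").indices.items():
        for rule in QC_RULES:
            rows.append((roi, rule, int(fails[rule][grp_idx].sum())))
    report = pd.DataFrame(rows, columns=["roi_id", "rule", "n_discarded"])
    return out, report
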