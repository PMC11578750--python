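"""File formats: multi-page TIFF stacks, label masks, CSV tables, YAML config.

Conventions: TIFF page order equals panel order; masks are 16-bit label
TIFFs; CSVs are UTF-8, comma-separated, header row, '.' decimal, missing
values as empty fields. ROI metadata (roi_id, patient_id, µm/px) travels in
the TIFF description tag as JSON, with filename fallbacks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Panel, ROIImage, SegmentationMask


def write_roi_stack(image: ROIImage, path) -> None:
    """Write a ROI as a multi-page TIFF, one page per channel in panel order."""
    meta = {"roi_id": image.roi_id, "patient_id": image.patient_id,
            "um_per_px": image.um_per_px, "markers": list(image.marker_names)}
    tifffile.imwrite(path, image.channels.astype(np.float32),
                     description=json.dumps(meta))


def read_roi_stack(path, panel: Panel) -> ROIImage:
    """Read a multi-page TIFF stack and validate it against the panel."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(panel):
        raise ValueError(
            f"{path.name}: stack has {arr.shape[0]} channels but panel has {len(panel)}")
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        pass
    markers = meta.get("markers", panel.names)
    if list(markers) != panel.names:
        raise ValueError(f"{path.name}: channel order differs from panel order")
    return ROIImage(meta.get("roi_id", path.stem),
                    meta.get("patient_id", path.stem.split("_")[0]),
                    arr.astype(np.float64), tuple(panel.names),
                    float(meta.get("um_per_px", 1.0)))


def write_mask(mask: SegmentationMask, path) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    meta = {"roi_id": mask.roi_id, "um_per_px": mask.um_per_px}
    tifffile.imwrite(path, mask.labels.astype(np.uint16), description=json.dumps(meta))


def read_mask(path) -> SegmentationMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc)
    except (TypeError, ValueError):
        pass
    return SegmentationMask(meta.get("roi_id", path.stem), arr.astype(np.int32),
                            float(meta.get("um_per_px", 1.0)))


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "qc_pass" in df.columns:
        df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "ca19_9_iu_l", "dfs_months", "os_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
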