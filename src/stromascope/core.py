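"""Core containers shared across the pipeline.

Imaging Mass Cytometry (IMC) data come as multichannel ion-count images
(one channel per metal-tagged antibody, ~1 µm/pixel, "dual counts" units).
The pipeline reduces them to a per-cell feature table (the *cell table*)
that every downstream stage consumes.

Coordinate convention: pixel-centered, origin at the top-left, ``x`` is the
column index and ``y`` the row index, both converted to µm via ``um_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column prefixes of the cell table
RAW_PREFIX = "raw_"        # mean dual counts over the cell's pixels
ASINH_PREFIX = "asinh_"    # asinh(raw / cofactor)
NORM_PREFIX = "norm_"      # asinh values clipped to pooled 1-99% and rescaled to [0,1]

#: non-intensity columns of the cell table
CELL_COLUMNS = (
    "cell_id", "roi_id", "patient_id",
    "centroid_x_um", "centroid_y_um", "area_um2",
    "qc_pass", "population", "subtype",
)

ROLES = ("lineage", "functional", "nuclear", "ECM")


@dataclass(frozen=True)
class Panel:
    """Ordered antibody panel shared by all images and tables.

    ``markers`` has columns ``name, metal, role, use_for_clustering,
    low_threshold``; row order defines channel order in every ROI stack.
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "metal", "role", "use_for_clustering", "low_threshold"}
        missing = required - set(self.markers.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        names = self.markers["name"]
        if names.duplicated().any():
            raise ValueError("panel marker names must be unique")
        if not (self.markers["role"] == "nuclear").any():
            raise ValueError("panel must contain at least one nuclear marker")
        bad_roles = set(self.markers["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown panel roles: {sorted(bad_roles)}")
        if (self.markers["low_threshold"] < 0).any():
            raise ValueError("low_threshold must be non-negative")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return list(self.markers["name"])

    @property
    def nuclear_markers(self) -> list[str]:
        sel = self.markers["role"] == "nuclear"
        return list(self.markers.loc[sel, "name"])

    @property
    def clustering_markers(self) -> list[str]:
        sel = self.markers["use_for_clustering"].astype(bool)
        return list(self.markers.loc[sel, "name"])

    @property
    def low_thresholds(self) -> dict[str, float]:
        return dict(zip(self.markers["name"], self.markers["low_threshold"].astype(float)))

    def index_of(self, name: str) -> int:
        idx = self.markers.index[self.markers["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not in panel")
        return int(self.markers.index.get_loc(idx[0]))

    @classmethod
    def from_csv(cls, path) -> "Panel":
        df = pd.read_csv(path)
        df["use_for_clustering"] = df["use_for_clustering"].astype(bool)
        return cls(df.reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.markers.to_csv(path, index=False)


# The 31-plex PDAC panel used as default: epithelial/tumor, immune,
# endothelial, fibroblast/ECM and islet markers plus two iridium DNA
# intercalator channels.
_DEFAULT_PANEL_ROWS = [
    # name, metal, role, use_for_clustering, low_threshold
    ("DNA1", "Ir191", "nuclear", False, 0.0),
    ("DNA2", "Ir193", "nuclear", False, 0.0),
    ("Pan-Ck", "Nd148", "lineage", True, 0.0),
    ("Ck-7", "Yb174", "lineage", True, 0.0),
    ("CD45", "Sm152", "lineage", True, 0.0),
    ("CD3", "Er170", "lineage", True, 0.0),
    ("CD8", "Dy162", "lineage", True, 0.0),
    ("CD20", "Dy161", "lineage", True, 0.0),
    ("CD68", "Tb159", "lineage", True, 0.0),
    ("CD66b", "Gd152", "lineage", True, 0.0),
    ("CD31", "Nd145", "lineage", True, 0.0),
    ("CD34", "Nd142", "lineage", True, 0.0),
    ("peptide-C", "Tm169", "lineage", True, 0.0),
    ("aSMA", "Pr141", "lineage", True, 0.0),
    ("vimentin", "Nd143", "lineage", True, 0.0),
    ("FAP", "Sm147", "lineage", True, 0.0),
    ("S100A4", "Eu151", "lineage", True, 0.0),
    ("CD74", "Gd155", "lineage", True, 0.0),
    ("HLA-DR", "Gd156", "lineage", True, 0.0),
    ("CD44", "Gd158", "lineage", True, 0.0),
    ("podoplanin", "Dy163", "lineage", True, 0.0),
    ("cadherin-11", "Dy164", "lineage", True, 0.0),
    ("desmin", "Ho165", "lineage", True, 0.0),
    ("CD146", "Er166", "lineage", True, 0.0),
    ("collagen-I", "Tm167", "ECM", True, 0.0),
    ("collagen-3A", "Er168", "ECM", True, 0.0),
    ("PTX3", "Yb171", "functional", True, 0.0),
    ("CA-IX", "Yb172", "functional", True, 0.0),
    ("CD163", "Yb173", "functional", True, 0.0),
    ("CD206", "Lu175", "functional", True, 0.0),
    ("MMP-9", "Yb176", "functional", True, 0.0),
]


def default_panel() -> Panel:
    """The default 31-marker panel (29 clustering markers + 2 DNA channels)."""
    df = pd.DataFrame(
        _DEFAULT_PANEL_ROWS,
        columns=["name", "metal", "role", "use_for_clustering", "low_threshold"],
    )
    return Panel(df)


@dataclass
class ROIImage:
    """One region of interest: a (C, H, W) stack of ion-count channels.

    Channel order equals panel order. Counts are non-negative reals (dual
    counts); ``um_per_px`` converts pixel to physical coordinates.
    """

    roi_id: str
    patient_id: str
    channels: np.ndarray
    marker_names: tuple[str, ...]
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (C, H, W) array")
        if self.channels.shape[0] != len(self.marker_names):
            raise ValueError(
                f"channel count {self.channels.shape[0]} != "
                f"marker count {len(self.marker_names)}"
            )
        if np.any(self.channels < 0):
            raise ValueError("counts must be non-negative")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        self.marker_names = tuple(self.marker_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in image") from None
        return self.channels[i]

    def copy(self) -> "ROIImage":
        return ROIImage(self.roi_id, self.patient_id, self.channels.copy(),
                        self.marker_names, self.um_per_px)


@dataclass
class SegmentationMask:
    """Labeled cell mask: 0 = background, 1..N = cell ids."""

    roi_id: str
    labels: np.ndarray
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def cell_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


def intensity_columns(markers, prefix: str = RAW_PREFIX) -> list[str]:
    """Column names holding per-cell intensities for ``markers``."""
    return [prefix + m for m in markers]
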