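"""Synthetic IMC cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: 31-channel
ion-count ROIs with Poisson background and isolated hot-pixel spikes, cells
rendered as non-overlapping discs (nucleus + cytoplasm annulus) drawn from
configurable subtype marker profiles, planted pairwise spatial attraction /
avoidance, planted spatial domains of distinct composition, and a multi-patient
cohort whose subtype frequencies differ between two prognosis groups with
clinical values (CA19-9, DFS, OS) consistent with the planted grouping.

All randomness flows from the single config seed through per-ROI named
generators, so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Panel, ROIImage, SegmentationMask, RAW_PREFIX, default_panel
from .preprocess import neighborhood_max

_MAX_PACKING = 0.45          # disc-area fraction above which placement is refused
_PLACE_ATTEMPTS = 500        # rejection-sampling attempts per cell
_HOT_MARGIN = 150.0          # spike excess over the local neighborhood maximum
_EFFECTIVE_PX = 60.0         # pseudo pixel count for table-only intensity noise


@dataclass(frozen=True)
class SubtypeProfile:
    """Marker signature of one simulated cell subtype.

    ``means`` maps marker name -> mean dual counts per pixel (markers not
    listed default to 0). ``dispersion`` is the SD of a log-normal per-cell
    scale factor applied to every marker mean.
    """

    name: str
    means: dict[str, float]
    population: str = ""
    dispersion: float = 0.15
    nuclear_radius_um: float = 2.5
    cell_radius_um: float = 4.5

    def __post_init__(self) -> None:
        if self.nuclear_radius_um <= 0 or self.cell_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.cell_radius_um < self.nuclear_radius_um:
            raise ValueError("cell radius must be >= nuclear radius")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if any(v < 0 for v in self.means.values()):
            raise ValueError("marker means must be non-negative")

    def mean_vector(self, marker_names) -> np.ndarray:
        unknown = set(self.means) - set(marker_names)
        if unknown:
            raise ValueError(f"profile {self.name!r} names unknown markers: {sorted(unknown)}")
        return np.array([self.means.get(m, 0.0) for m in marker_names])


@dataclass(frozen=True)
class SpatialRule:
    """Planted spatial structure between two subtypes.

    kind="attraction": subtype_b cells are placed within ``range_um`` of a
    subtype_a anchor with probability ``strength``.
    kind="avoidance": placements of subtype_b within ``range_um`` of subtype_a
    (and vice versa) are suppressed with probability ``strength``.
    kind="domain": declares one spatial region type in which a fraction
    ``strength`` of cells is drawn uniformly from {subtype_a, subtype_b}
    instead of the global mix; the ROI is partitioned into one Voronoi region
    per domain rule.
    """

    kind: str
    subtype_a: str
    subtype_b: str
    range_um: float = 30.0
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("attraction", "avoidance", "domain"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.range_um <= 0:
            raise ValueError("range_um must be positive")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


@dataclass
class SyntheticCohortConfig:
    """Study-design knobs of a simulated cohort.

    Defaults emulate the acquisition this pipeline targets at desk scale:
    8 patients, 3 ROIs each, ~500 cells per ROI at 1 µm/px, a tumor-dominated
    mix with ~34% cancer-associated fibroblasts, faint Poisson background and
    a sparse sprinkling of hot pixels.
    """

    n_patients: int = 8
    rois_per_patient: int = 3
    roi_size_px: tuple[int, int] = (350, 350)
    um_per_px: float = 1.0
    cells_per_roi: int = 500
    profiles: tuple[SubtypeProfile, ...] = ()
    frequencies: dict[str, float] | None = None
    rules: tuple[SpatialRule, ...] = ()
    group_frequency_shift: dict[str, float] = field(default_factory=dict)
    n_bad_patients: int | None = None
    hot_pixel_rate: float = 1e-5
    background_rate: float = 0.1
    seed: int = 0
    panel: Panel | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.rois_per_patient < 1 or self.cells_per_roi < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.hot_pixel_rate <= 1.0:
            raise ValueError("hot_pixel_rate must be in [0, 1]")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not self.profiles:
            self.profiles = tuple(default_profiles())
        self.profiles = tuple(self.profiles)
        self.rules = tuple(self.rules)
        if self.panel is None:
            self.panel = default_panel()
        names = {p.name for p in self.profiles}
        if len(names) != len(self.profiles):
            raise ValueError("profile names must be unique")
        for r in self.rules:
            for s in (r.subtype_a, r.subtype_b):
                if s not in names:
                    raise ValueError(f"rule references unknown subtype {s!r}")
        if self.frequencies is None:
            self.frequencies = default_frequencies() if names == {
                p.name for p in default_profiles()} else {n: 1.0 / len(names) for n in names}
        if set(self.frequencies) != names:
            raise ValueError("frequencies must cover exactly the profile set")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("frequencies must be non-negative")
        for s, mult in self.group_frequency_shift.items():
            if s not in names:
                raise ValueError(f"group_frequency_shift names unknown subtype {s!r}")
            if mult <= 0:
                raise ValueError("frequency multipliers must be > 0")
        if self.n_bad_patients is None:
            self.n_bad_patients = self.n_patients // 2
        if not 0 < self.n_bad_patients < self.n_patients:
            raise ValueError("n_bad_patients must split the cohort into two nonempty groups")

    @property
    def n_rois(self) -> int:
        return self.n_patients * self.rois_per_patient

    def profile_map(self) -> dict[str, SubtypeProfile]:
        return {p.name: p for p in self.profiles}


def default_profiles() -> list[SubtypeProfile]:
    """Nine subtypes spanning the five major tissue populations.

    Tumor (Pan-Ck/Ck-7), three immune subtypes (T, B, macrophage), endothelium
    (CD31/CD34), pancreatic islet (peptide-C) and three CAF variants:
    myofibroblastic (aSMA+vimentin), inflammatory/FAP+ and antigen-presenting
    (CD74/HLA-DR). DNA channels are shared by all.
    """
    dna = {"DNA1": 10.0, "DNA2": 8.0}
    mk = lambda name, pop, means: SubtypeProfile(name=name, population=pop, means={**dna, **means})
    return [
        mk("tumor", "tumor", {"Pan-Ck": 20.0, "Ck-7": 14.0, "CA-IX": 3.0}),
        mk("T_cell", "immune", {"CD45": 16.0, "CD3": 12.0, "CD8": 6.0}),
        mk("B_cell", "immune", {"CD45": 16.0, "CD20": 12.0}),
        mk("macrophage", "immune", {"CD45": 12.0, "CD68": 12.0, "CD163": 6.0, "HLA-DR": 4.0}),
        mk("EC", "EC", {"CD31": 16.0, "CD34": 8.0}),
        mk("islet", "islet", {"peptide-C": 18.0}),
        mk("CAF_my", "CAF", {"aSMA": 16.0, "vimentin": 12.0, "S100A4": 4.0}),
        mk("CAF_i", "CAF", {"FAP": 14.0, "vimentin": 10.0, "aSMA": 5.0, "PTX3": 5.0}),
        mk("CAF_ap", "CAF", {"CD74": 14.0, "HLA-DR": 10.0, "vimentin": 8.0}),
    ]


def default_frequencies() -> dict[str, float]:
    """Cohort-level subtype mix (~35% tumor, ~21% immune, ~34% CAF)."""
    return {
        "tumor": 0.35, "T_cell": 0.09, "B_cell": 0.04, "macrophage": 0.08,
        "EC": 0.07, "islet": 0.03, "CAF_my": 0.15, "CAF_i": 0.11, "CAF_ap": 0.08,
    }


@dataclass
class ROIBundle:
    """One simulated ROI: image + mask + ground-truth cell table."""

    roi_id: str
    patient_id: str
    cells: pd.DataFrame
    image: ROIImage | None = None
    mask: SegmentationMask | None = None
    hot_pixels: pd.DataFrame | None = None


@dataclass
class Cohort:
    """A simulated multi-patient study."""

    config: SyntheticCohortConfig
    rois: list[ROIBundle]
    clinical: pd.DataFrame

    @property
    def cells(self) -> pd.DataFrame:
        return pd.concat([r.cells for r in self.rois], ignore_index=True)


# ---------------------------------------------------------------------------
# cell placement

def _group_frequencies(config: SyntheticCohortConfig, group: str) -> dict[str, float]:
    freq = dict(config.frequencies)
    if group == "bad":
        for s, mult in config.group_frequency_shift.items():
            freq[s] *= mult
    total = sum(freq.values())
    return {k: v / total for k, v in freq.items()}


def _sample_in_annulus(rng, cx, cy, rmin, rmax):
    """Uniform position with distance to (cx, cy) in [rmin, rmax]."""
    r = np.sqrt(rng.random() * (rmax ** 2 - rmin ** 2) + rmin ** 2)
    theta = rng.random() * 2.0 * np.pi
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def _place_cells(rng, config: SyntheticCohortConfig, freqs: dict[str, float]):
    """Rejection-sample non-overlapping disc centers honoring spatial rules.

    Returns (x, y, subtype names, domain ids) with coordinates in µm.
    Raises ValueError when the requested cells cannot be placed.
    """
    h_px, w_px = config.roi_size_px
    um = config.um_per_px
    height, width = h_px * um, w_px * um
    n = config.cells_per_roi
    prof = config.profile_map()
    names = list(freqs)
    pvec = np.array([freqs[s] for s in names])

    area = sum(
        np.pi * (prof[s].cell_radius_um + 0.5) ** 2 * freqs[s] for s in names
    ) * n
    if area > _MAX_PACKING * height * width:
        raise ValueError(
            f"cells_per_roi={n} infeasible: expected disc area {area:.0f} µm² exceeds "
            f"{_MAX_PACKING:.0%} of the {height * width:.0f} µm² ROI"
        )

    domain_rules = [r for r in config.rules if r.kind == "domain"]
    avoid_rules = [r for r in config.rules if r.kind == "avoidance"]
    attract_rules = [r for r in config.rules if r.kind == "attraction"]
    gap = 1.0  # µm clearance so labels never share a pixel

    dom_seeds = None
    if domain_rules:
        dom_seeds = np.column_stack([
            rng.uniform(0, width, len(domain_rules)),
            rng.uniform(0, height, len(domain_rules)),
        ])

    xs = np.empty(n)
    ys = np.empty(n)
    subtypes: list[str] = []
    domains = np.full(n, -1, dtype=int)
    radii = np.empty(n)
    placed_by_subtype: dict[str, list[int]] = {s: [] for s in names}

    def overlaps(x, y, r, k) -> bool:
        if k == 0:
            return False
        d2 = (xs[:k] - x) ** 2 + (ys[:k] - y) ** 2
        return bool(np.any(d2 < (radii[:k] + r + gap) ** 2))

    def violates_avoidance(x, y, s, k, enforce) -> bool:
        for ri, rule in enumerate(avoid_rules):
            if not enforce[ri]:
                continue
            other = None
            if s == rule.subtype_b:
                other = rule.subtype_a
            elif s == rule.subtype_a:
                other = rule.subtype_b
            if other is None:
                continue
            idx = placed_by_subtype[other]
            if idx:
                d2 = (xs[idx] - x) ** 2 + (ys[idx] - y) ** 2
                if np.any(d2 < rule.range_um ** 2):
                    return True
        return False

    if domain_rules:
        order = list(range(n))
        chosen: list[str | None] = [None] * n
    else:
        counts = rng.multinomial(n, pvec)
        expanded: list[str] = []
        for s, c in zip(names, counts):
            expanded.extend([s] * c)
        targets = {r.subtype_b for r in attract_rules}
        first = [s for s in expanded if s not in targets]
        last = [s for s in expanded if s in targets]
        rng.shuffle(first)
        rng.shuffle(last)
        chosen = first + last
        order = list(range(n))

    for k in order:
        placed = False
        for _ in range(_PLACE_ATTEMPTS):
            if domain_rules:
                # position first, then subtype from the local domain mix
                x = rng.uniform(0, width)
                y = rng.uniform(0, height)
                d = int(np.argmin((dom_seeds[:, 0] - x) ** 2 + (dom_seeds[:, 1] - y) ** 2))
                rule = domain_rules[d]
                if rng.random() < rule.strength:
                    s = rule.subtype_a if rng.random() < 0.5 else rule.subtype_b
                else:
                    s = names[rng.choice(len(names), p=pvec)]
            else:
                s = chosen[k]
                d = -1
                x = y = None
            r = prof[s].cell_radius_um
            enforce = [rng.random() < rule.strength for rule in avoid_rules]
            my_attract = [ru for ru in attract_rules
                          if ru.subtype_b == s and placed_by_subtype[ru.subtype_a]]
            if x is None:
                use_anchor = bool(my_attract) and rng.random() < max(
                    ru.strength for ru in my_attract)
                if use_anchor:
                    ru = my_attract[int(rng.choice(len(my_attract)))]
                    anchors = placed_by_subtype[ru.subtype_a]
                    a = anchors[int(rng.choice(len(anchors)))]
                    # discs cannot overlap, so the feasible region around an
                    # anchor is an annulus; a contact-range rule degenerates
                    # to placement at the closest allowed distance
                    rmin = radii[a] + r + gap
                    rmax = max(ru.range_um, rmin + 1.0)
                    x, y = _sample_in_annulus(rng, xs[a], ys[a], rmin, rmax)
                else:
                    x = rng.uniform(r + 0.5, width - r - 0.5)
                    y = rng.uniform(r + 0.5, height - r - 0.5)
            if not (r + 0.5 <= x <= width - r - 0.5 and r + 0.5 <= y <= height - r - 0.5):
                continue
            if overlaps(x, y, r, k) or violates_avoidance(x, y, s, k, enforce):
                continue
            xs[k], ys[k], radii[k] = x, y, r
            subtypes.append(s)
            domains[k] = d
            placed_by_subtype[s].append(k)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cells_per_roi={n} infeasible at the requested radii/rules: "
                f"could not place cell {k} after {_PLACE_ATTEMPTS} attempts"
            )
    return xs, ys, np.array(subtypes, dtype=object), domains, radii


# ---------------------------------------------------------------------------
# rendering

def _render_roi(rng, config, xs, ys, subtypes, roi_id, patient_id):
    """Rasterize placed cells into a label mask and Poisson count stack."""
    panel = config.panel
    marker_names = panel.names
    nuclear = set(panel.nuclear_markers)
    h, w = config.roi_size_px
    um = config.um_per_px
    prof = config.profile_map()

    labels = np.zeros((h, w), dtype=np.uint16)
    stack = rng.poisson(config.background_rate, size=(len(marker_names), h, w)).astype(np.float64)

    cell_means = np.zeros((len(xs), len(marker_names)))
    areas_px = np.zeros(len(xs), dtype=int)
    cols_um = np.arange(w) * um
    rows_um = np.arange(h) * um

    for i, (x, y, s) in enumerate(zip(xs, ys, subtypes)):
        p = prof[s]
        base = p.mean_vector(marker_names)
        scale = np.exp(rng.normal(0.0, p.dispersion, size=len(marker_names)))
        lam = base * scale
        cell_means[i] = lam

        r = p.cell_radius_um
        c0, c1 = np.searchsorted(cols_um, [x - r, x + r + 1e-9])
        r0, r1 = np.searchsorted(rows_um, [y - r, y + r + 1e-9])
        cc, rr = np.meshgrid(cols_um[c0:c1], rows_um[r0:r1])
        d2 = (cc - x) ** 2 + (rr - y) ** 2
        disc = d2 <= r ** 2
        nuc = d2 <= p.nuclear_radius_um ** 2
        labels[r0:r1, c0:c1][disc] = i + 1
        areas_px[i] = int(disc.sum())
        for m, name in enumerate(marker_names):
            if lam[m] <= 0:
                continue
            target = nuc if name in nuclear else disc
            cnt = int(target.sum())
            if cnt == 0:
                continue
            block = stack[m, r0:r1, c0:c1]
            block[target] += rng.poisson(lam[m], size=cnt)

    return labels, stack, cell_means, areas_px


def _inject_hot_pixels(rng, config, stack):
    """Plant isolated single-pixel spikes; returns the ground-truth record.

    Spikes exceed the local neighborhood maximum by a fixed margin so the
    radius=2 / threshold=50 removal rule detects exactly the planted set.
    Planted pixels keep Chebyshev distance >= 3 within a channel so no spike
    hides inside another's neighborhood.
    """
    c, h, w = stack.shape
    n_hot = int(round(config.hot_pixel_rate * c * h * w))
    records = []
    if n_hot == 0:
        return pd.DataFrame(
            columns=["channel", "channel_index", "row", "col", "clean_value", "hot_value"])
    nbmax_cache: dict[int, np.ndarray] = {}
    taken: dict[int, list[tuple[int, int]]] = {}
    marker_names = config.panel.names
    attempts = 0
    while len(records) < n_hot and attempts < 100 * n_hot:
        attempts += 1
        ci = int(rng.integers(c))
        r = int(rng.integers(h))
        col = int(rng.integers(w))
        if any(max(abs(r - rr), abs(col - cc)) < 3 for rr, cc in taken.get(ci, [])):
            continue
        if ci not in nbmax_cache:
            nbmax_cache[ci] = neighborhood_max(stack[ci], radius=2)
        clean = stack[ci, r, col]
        hot = max(nbmax_cache[ci][r, col] + _HOT_MARGIN, config.background_rate + 100.0)
        stack[ci, r, col] = hot
        taken.setdefault(ci, []).append((r, col))
        records.append((marker_names[ci], ci, r, col, clean, hot))
    return pd.DataFrame(
        records, columns=["channel", "channel_index", "row", "col", "clean_value", "hot_value"])


# ---------------------------------------------------------------------------
# public API

def roi_ids(config: SyntheticCohortConfig) -> list[tuple[str, str, str]]:
    """(roi_id, patient_id, group) for every ROI in acquisition order."""
    out = []
    for idx in range(config.n_rois):
        p = idx // config.rois_per_patient
        group = "bad" if p < config.n_bad_patients else "good"
        patient_id = f"P{p + 1:02d}"
        out.append((f"{patient_id}_R{idx % config.rois_per_patient + 1}", patient_id, group))
    return out


def simulate_roi(config: SyntheticCohortConfig, roi_index: int,
                 render_images: bool = True) -> ROIBundle:
    """Simulate one ROI: image stack, label mask and ground-truth cell table.

    The mask labels are exactly the ground-truth cells; pixel counts are
    Poisson around the cell's subtype profile plus background; nuclear
    channels are positive only inside nuclei; hot pixels are isolated spikes
    recorded in the returned bundle. Reruns with the same config and index
    are bit-identical.
    """
    if not 0 <= roi_index < config.n_rois:
        raise ValueError(f"roi_index {roi_index} out of range [0, {config.n_rois})")
    roi_id, patient_id, group = roi_ids(config)[roi_index]
    rng = np.random.default_rng([config.seed, 1000 + roi_index])
    freqs = _group_frequencies(config, group)
    xs, ys, subtypes, domains, radii = _place_cells(rng, config, freqs)

    prof = config.profile_map()
    marker_names = config.panel.names
    n = len(xs)
    table = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "roi_id": roi_id,
        "patient_id": patient_id,
        "group": group,
        "centroid_x_um": xs,
        "centroid_y_um": ys,
        "subtype": subtypes,
        "population": [prof[s].population for s in subtypes],
        "domain_id": domains,
        "radius_um": radii,
    })

    image = mask = None
    hot = None
    if render_images:
        labels, stack, cell_means, areas_px = _render_roi(
            rng, config, xs, ys, subtypes, roi_id, patient_id)
        hot = _inject_hot_pixels(rng, config, stack)
        image = ROIImage(roi_id, patient_id, stack, tuple(marker_names), config.um_per_px)
        mask = SegmentationMask(roi_id, labels, config.um_per_px)
        table["area_um2"] = areas_px * config.um_per_px ** 2
        for m, name in enumerate(marker_names):
            table[RAW_PREFIX + name] = cell_means[:, m]
    else:
        # table-only mode: draw noisy per-cell mean intensities directly
        table["area_um2"] = np.pi * radii ** 2
        base = np.stack([prof[s].mean_vector(marker_names) for s in subtypes])
        disp = np.array([prof[s].dispersion for s in subtypes])[:, None]
        lam = base * np.exp(rng.normal(0.0, disp, size=base.shape))
        lam = lam + config.background_rate
        vals = rng.poisson(lam * _EFFECTIVE_PX) / _EFFECTIVE_PX
        for m, name in enumerate(marker_names):
            table[RAW_PREFIX + name] = vals[:, m]

    return ROIBundle(roi_id, patient_id, table, image, mask, hot)


def simulate_cohort(config: SyntheticCohortConfig,
                    render_images: bool = True) -> Cohort:
    """Simulate the full cohort plus a clinical table matching the grouping.

    Patients are split into ``bad`` (first ``n_bad_patients``) and ``good``
    groups; bad-group subtype frequencies are multiplied by
    ``group_frequency_shift``. Clinical values are drawn so that the
    conventional thresholds (CA19-9 > 100 IU/L, DFS <= 13.5 months,
    OS <= 18 months) reproduce the planted grouping exactly.
    """
    if config.n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    rois = [simulate_roi(config, i, render_images=render_images)
            for i in range(config.n_rois)]

    rng = np.random.default_rng([config.seed, 77])
    rows = []
    for p in range(config.n_patients):
        group = "bad" if p < config.n_bad_patients else "good"
        if group == "bad":
            ca, dfs, os_m = rng.uniform(150, 900), rng.uniform(2, 12.5), rng.uniform(5, 17)
        else:
            ca, dfs, os_m = rng.uniform(5, 80), rng.uniform(15, 40), rng.uniform(24, 60)
        rows.append((f"P{p + 1:02d}", round(ca, 1), round(dfs, 1), round(os_m, 1), group))
    clinical = pd.DataFrame(
        rows, columns=["patient_id", "ca19_9_iu_l", "dfs_months", "os_months", "group"])
    return Cohort(config, rois, clinical)


def simulate_cell_table(n_cells: int,
                        profiles: list[SubtypeProfile] | None = None,
                        frequencies: dict[str, float] | None = None,
                        panel: Panel | None = None,
                        background_rate: float = 0.1,
                        seed: int = 0,
                        roi_id: str = "R1",
                        patient_id: str = "P01") -> pd.DataFrame:
    """Draw a standalone ground-truth cell table (no image, no geometry rules).

    Convenience generator for phenotyping tests: per-cell raw mean intensities
    are Poisson-noised log-normal draws around the subtype profile means.
    """
    profiles = list(profiles) if profiles else default_profiles()
    panel = panel or default_panel()
    names = [p.name for p in profiles]
    if frequencies is None:
        frequencies = {n: 1.0 / len(names) for n in names}
    pvec = np.array([frequencies[n] for n in names])
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)
    prof = {p.name: p for p in profiles}
    idx = rng.choice(len(names), size=n_cells, p=pvec)
    subtypes = np.array(names, dtype=object)[idx]

    base = np.stack([prof[s].mean_vector(panel.names) for s in subtypes])
    disp = np.array([prof[s].dispersion for s in subtypes])[:, None]
    lam = base * np.exp(rng.normal(0.0, disp, size=base.shape)) + background_rate
    vals = rng.poisson(lam * _EFFECTIVE_PX) / _EFFECTIVE_PX

    table = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "roi_id": roi_id,
        "patient_id": patient_id,
        "centroid_x_um": rng.uniform(0, 1000, n_cells),
        "centroid_y_um": rng.uniform(0, 1000, n_cells),
        "area_um2": np.array([np.pi * prof[s].cell_radius_um ** 2 for s in subtypes]),
        "subtype": subtypes,
        "population": [prof[s].population for s in subtypes],
    })
    for m, name in enumerate(panel.names):
        table[RAW_PREFIX + name] = vals[:, m]
    return table
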