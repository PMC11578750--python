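"""Raw channel cleanup: hot-pixel removal, intensity clipping, positive area.

IMC detectors produce isolated single-pixel count spikes ("hot pixels").
They are removed by comparing each pixel to the maximum of its square
neighborhood; low-intensity background is zeroed per marker, and extreme
values are clipped at a high percentile pooled across all ROIs of a batch.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import ROIImage


def _neighborhood_footprint(radius: int) -> np.ndarray:
    """Square (2r+1)² footprint with the center excluded."""
    fp = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    fp[radius, radius] = False
    return fp


def neighborhood_max(channel: np.ndarray, radius: int = 2) -> np.ndarray:
    """Per-pixel maximum over the square neighborhood, center excluded.

    At the borders the neighborhood is clipped to the image, so the maximum
    runs over in-bounds neighbors only and the pixel never sees itself.
    """
    return ndimage.maximum_filter(
        np.asarray(channel, dtype=float),
        footprint=_neighborhood_footprint(radius),
        mode="constant", cval=-np.inf,
    )


def remove_hot_pixels(image: ROIImage, radius: int = 2, threshold: float = 50.0) -> ROIImage:
    """Replace isolated count spikes by their neighborhood maximum.

    For each pixel, let ``m`` be the maximum over the square neighborhood of
    the given ``radius`` excluding the pixel itself. If ``value - m >
    threshold`` the value is replaced by ``m``; otherwise it is unchanged.
    Applied independently per channel. Never increases any pixel value, and
    is idempotent on images whose spikes are isolated.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    h, w = image.shape
    if 2 * radius + 1 > min(h, w):
        raise ValueError(f"radius {radius} too large for image of shape {(h, w)}")
    out = image.channels.copy()
    for c in range(out.shape[0]):
        m = neighborhood_max(out[c], radius)
        hot = out[c] - m > threshold
        out[c][hot] = m[hot]
    return ROIImage(image.roi_id, image.patient_id, out, image.marker_names, image.um_per_px)


def clip_intensities(
    images: list[ROIImage],
    top_percentile: float = 99.99,
    floor: float = 10.0,
    low_thresholds: dict[str, float] | None = None,
) -> list[ROIImage]:
    """Zero sub-threshold background and clip the extreme upper tail.

    Per marker: pixels below that marker's low threshold are set to 0; the
    upper cutoff is ``max(P, floor)`` where ``P`` is the ``top_percentile``
    value of the marker pooled over *all* supplied ROIs (linear-interpolation
    percentile); pixels above the cutoff are set to the cutoff.
    """
    if not images:
        raise ValueError("clip_intensities requires at least one ROI")
    if not 0 < top_percentile < 100:
        raise ValueError("top_percentile must be in (0, 100)")
    low_thresholds = low_thresholds or {}
    names = images[0].marker_names
    for im in images:
        if im.marker_names != names:
            raise ValueError("all ROIs must share the same panel order")

    cutoffs = np.empty(len(names))
    for i in range(len(names)):
        pooled = np.concatenate([im.channels[i].ravel() for im in images])
        cutoffs[i] = max(np.percentile(pooled, top_percentile), floor)

    out = []
    for im in images:
        ch = im.channels.copy()
        for i, name in enumerate(names):
            low = low_thresholds.get(name, 0.0)
            if low > 0:
                ch[i][ch[i] < low] = 0.0
            np.minimum(ch[i], cutoffs[i], out=ch[i])
        out.append(ROIImage(im.roi_id, im.patient_id, ch, names, im.um_per_px))
    return out


def positive_area_fraction(
    image: ROIImage, marker: str, threshold: float, gauss_radius: float = 2.0
) -> float:
    """Fraction of pixels positive for ``marker`` after Gaussian smoothing.

    The channel is smoothed with a Gaussian of sigma ``gauss_radius`` (px)
    and the fraction of pixels strictly above ``threshold`` is returned.
    Used for stain-level area estimates (e.g. Pan-Ck+, CD45+, CD31+, FAP+
    area) that do not depend on segmentation.
    """
    ch = image.channel(marker)  # raises KeyError for unknown marker
    smoothed = ndimage.gaussian_filter(ch, sigma=gauss_radius)
    return float(np.mean(smoothed > threshold))
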