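"""Automatic counting and sizing of labelled somata in flatmount fields.

A labelled soma appears as a bright blob on a dark background. Counting is
binary: threshold (Otsu by default, or a fixed 8-bit level), take maximal
8-connected foreground components, convert pixel areas to um^2 via the image
scale. The projected-area diameter D_a of a soma is the diameter of the
circle with the same area, A = pi D^2 / 4. Touching somata are counted as
one component — no watershed splitting is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .events import FlatmountImage

logger = logging.getLogger(__name__)

SizeClass = Literal["small", "medium", "large"]

#: Imaging size-class bounds (um): small < 9.4 <= medium <= 12.6 < large.
DEFAULT_DIAMETER_BOUNDS = (9.4, 12.6)


@dataclass(frozen=True)
class SomaDetection:
    """One detected soma: centroid (um), area (um^2) and area diameter (um)."""

    centroid_um: tuple[float, float]
    area_um2: float
    area_diameter_um: float


@dataclass(frozen=True)
class SizeHistogram:
    """Soma-size histogram with uniform bins starting at 0 um."""

    bin_edges_um: np.ndarray
    counts: np.ndarray
    densities_per_mm2: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def area_to_diameter(area_um2):
    """Diameter of the circle with projected area ``area_um2``: 2*sqrt(A/pi)."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area < 0):
        raise ValueError("projected area cannot be negative")
    out = 2.0 * np.sqrt(area / np.pi)
    return out if out.ndim else float(out)


def diameter_to_area(d_um):
    """Inverse of :func:`area_to_diameter`: A = pi*D^2/4."""
    d = np.asarray(d_um, dtype=float)
    out = np.pi * d ** 2 / 4.0
    return out if out.ndim else float(out)


def classify_by_diameter(d_um, bounds: Sequence[float] = DEFAULT_DIAMETER_BOUNDS):
    """Assign small/medium/large by area diameter.

    The medium interval is closed ([lower, upper]), so boundary values are
    medium; small is strictly below, large strictly above.
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("diameter class bounds must be strictly increasing")
    d = np.asarray(d_um, dtype=float)
    out = np.where(d < lo, "small", np.where(d <= hi, "medium", "large"))
    return out if out.ndim else str(out)


def detect_somata(image: FlatmountImage, min_area_um2: float = 5.0,
                  threshold: int | str = "otsu") -> list[SomaDetection]:
    """Detect labelled somata as bright 8-connected components.

    Parameters
    ----------
    image:
        Grayscale field with a positive um/pixel scale.
    min_area_um2:
        Components below this area are discarded as noise (default 5 um^2,
        well below any plausible soma).
    threshold:
        ``"otsu"`` for a global Otsu threshold, or a fixed intensity level;
        pixels strictly above the threshold are foreground.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be non-negative")
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    if not np.any(px > 0):
        return []
    if threshold == "otsu":
        level = threshold_otsu(px) if np.ptp(px) > 0 else 0.0
    else:
        level = float(threshold)
    mask = px > level
    labelled = measure.label(mask, connectivity=2)
    px_area = image.scale ** 2
    detections = []
    for region in measure.regionprops(labelled):
        area = region.area * px_area
        if area < min_area_um2:
            continue
        cy, cx = region.centroid
        detections.append(SomaDetection(
            centroid_um=(cx * image.scale, cy * image.scale),
            area_um2=area,
            area_diameter_um=area_to_diameter(area),
        ))
    logger.info("detected %d somata (threshold=%s, min_area=%.1f um^2)",
                len(detections), threshold, min_area_um2)
    return detections


def density(detections: Sequence[SomaDetection] | int, field_area_mm2: float) -> float:
    """Cell density in cells/mm^2 for a counted field."""
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    n = detections if isinstance(detections, (int, np.integer)) else len(detections)
    return n / field_area_mm2


def size_histogram(detections: Sequence[SomaDetection], bin_width_um: float = 2.0,
                   field_area_mm2: float | None = None) -> SizeHistogram:
    """Histogram of area diameters in uniform left-closed bins from 0 um."""
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    d = np.array([s.area_diameter_um for s in detections], dtype=float)
    top = d.max() if d.size else bin_width_um
    n_bins = max(1, int(np.ceil((top + 1e-12) / bin_width_um)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    # Left-closed right-open bins; np.histogram closes the last bin on the
    # right, which the +1e-12 ceiling above makes irrelevant here.
    counts, _ = np.histogram(d, bins=edges)
    if field_area_mm2:
        dens = counts / field_area_mm2
    else:
        dens = np.full_like(counts, np.nan, dtype=float)
    return SizeHistogram(bin_edges_um=edges, counts=counts, densities_per_mm2=dens)


def empirical_percentile(values, q):
    """Percentile by linear interpolation between closest ranks.

    This is the size-distribution percentile used for quantile matching: the
    cumulative cell-number percentile Q of the soma sizes ordered small to
    large. Continuous in the data and shared by every stage of the package.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0) | (q_arr >= 100)):
        raise ValueError("percentile Q must lie strictly inside (0, 100)")
    out = np.percentile(arr, q_arr, method="linear")
    return out if out.ndim else float(out)
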