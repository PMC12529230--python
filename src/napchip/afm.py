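"""AFM topograph quantification: background leveling, complex segmentation,
per-complex maximum height, foci counting and height-bin statistics.

A "complex" is an 8-connected component of pixels above a height threshold
(measured after subtracting a least-squares background plane) with at least
``min_area_px`` pixels. Foci are regional maxima within one complex with a
height prominence of at least ``foci_prominence`` nm and pairwise separation
of at least ``min_separation_px`` pixels; every detected complex has at
least one focus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima
from sklearn.base import BaseEstimator

__all__ = [
    "HeightMap",
    "AfmComplexStats",
    "read_height_map",
    "level_plane",
    "AfmComplexSegmenter",
    "segment_complexes",
    "count_foci",
    "afm_report",
    "DEFAULT_HEIGHT_BINS",
]

DEFAULT_HEIGHT_BINS = (0.0, 2.0, 4.0, 6.0)  # nm bin edges; last bin is > 6 nm
DEFAULT_TALL_CUTOFF = 12.0  # nm


@dataclass
class HeightMap:
    """Topograph heights (nm) on a square-pixel grid."""

    values: np.ndarray
    pixel_size: float = 1.0  # nm per pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("height map contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def read_height_map(path: str | Path, pixel_size: float = 1.0,
                    nm_per_unit: float = 1.0) -> HeightMap:
    """Read a plain whitespace-separated matrix, or a single-channel
    grayscale image scaled by ``nm_per_unit``."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".tsv", ".dat", ".mat", ""):
        values = np.loadtxt(path)
    else:
        import imageio.v3 as iio

        values = np.asarray(iio.imread(path), dtype=float)
        if values.ndim == 3:
            raise ValueError("expected a single-channel grayscale image")
    return HeightMap(values * nm_per_unit, pixel_size=pixel_size)


def level_plane(values: np.ndarray) -> np.ndarray:
    """Subtract the least-squares background plane z = a*x + b*y + c."""
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    design = np.column_stack([xx.ravel(), yy.ravel(), np.ones(values.size)])
    coef, *_ = np.linalg.lstsq(design, values.ravel(), rcond=None)
    return values - (design @ coef).reshape(values.shape)


def count_foci(
    heights: np.ndarray,
    mask: np.ndarray,
    prominence_nm: float = 0.5,
    min_separation_px: float = 5.0,
) -> int:
    """Count regional maxima within ``mask`` with prominence >=
    ``prominence_nm``; maxima closer than ``min_separation_px`` to a taller
    retained focus are suppressed. Never returns less than 1 for a
    non-empty mask."""
    if not mask.any():
        raise ValueError("empty complex mask")
    patch = np.where(mask, heights, heights[mask].min() - 10 * prominence_nm)
    maxima = h_maxima(patch, prominence_nm) & mask
    if not maxima.any():
        return 1
    labeled = label(maxima, connectivity=2)
    coords, peaks = [], []
    for region in regionprops(labeled, intensity_image=patch):
        coords.append(region.centroid)
        peaks.append(region.intensity_max)
    order = np.argsort(peaks)[::-1]
    kept: list[tuple[float, float]] = []
    for i in order:
        y, x = coords[i]
        if all(np.hypot(y - ky, x - kx) >= min_separation_px for ky, kx in kept):
            kept.append((y, x))
    return max(1, len(kept))


class AfmComplexSegmenter(BaseEstimator):
    """Segmenter for DNA(-protein) complexes in an AFM topograph.

    Parameters
    ----------
    height_threshold : float
        Height (nm) above the leveled background defining complex pixels.
    min_area_px : int
        Minimum component area to count as a complex.
    foci_prominence : float
        Minimum regional-maximum prominence (nm) for a focus.
    min_separation_px : float
        Minimum pairwise focus separation (pixels).
    level : bool
        Subtract the least-squares background plane before thresholding.

    ``fit(height_map)`` sets ``labels_`` (component image, 0 = background)
    and ``complexes_`` (one row per complex: label, max_height_nm, area_px,
    foci_count).
    """

    def __init__(self, height_threshold: float = 1.0, min_area_px: int = 4,
                 foci_prominence: float = 0.5, min_separation_px: float = 5.0,
                 level: bool = True):
        self.height_threshold = height_threshold
        self.min_area_px = min_area_px
        self.foci_prominence = foci_prominence
        self.min_separation_px = min_separation_px
        self.level = level

    def fit(self, height_map: HeightMap, y=None):
        values = height_map.values
        if self.level:
            values = level_plane(values)
        self.leveled_ = values
        mask = values > self.height_threshold
        labeled = label(mask, connectivity=2)  # 8-connected
        rows = []
        keep = np.zeros_like(labeled)
        for region in regionprops(labeled, intensity_image=values):
            if region.area < self.min_area_px:
                continue
            comp_mask = labeled == region.label
            foci = count_foci(values, comp_mask,
                              prominence_nm=self.foci_prominence,
                              min_separation_px=self.min_separation_px)
            keep[comp_mask] = region.label
            rows.append({
                "label": int(region.label),
                "max_height_nm": float(region.intensity_max),
                "area_px": int(region.area),
                "foci_count": int(foci),
            })
        self.labels_ = keep
        self.complexes_ = pd.DataFrame(
            rows, columns=["label", "max_height_nm", "area_px", "foci_count"])
        return self


def segment_complexes(
    height_map: HeightMap,
    height_threshold: float = 1.0,
    min_area_px: int = 4,
    **kwargs,
) -> pd.DataFrame:
    """Thin functional wrapper over :class:`AfmComplexSegmenter`."""
    seg = AfmComplexSegmenter(height_threshold=height_threshold,
                              min_area_px=min_area_px, **kwargs)
    return seg.fit(height_map).complexes_


@dataclass
class AfmComplexStats:
    n_complexes: int
    bin_labels: list[str]
    bin_percent: dict[str, float]
    percent_above_tall_cutoff: float
    tall_cutoff_nm: float
    mean_foci: float
    foci_counts: dict[int, int] = field(default_factory=dict)


def afm_report(
    complexes: pd.DataFrame,
    bins: tuple[float, ...] = DEFAULT_HEIGHT_BINS,
    tall_cutoff: float = DEFAULT_TALL_CUTOFF,
) -> AfmComplexStats:
    """Histogram of per-complex maximum heights over half-open bins
    ``[b0,b1), [b1,b2), ..., > b_last`` (percentages summing to 100 for a
    non-empty population), the percentage above ``tall_cutoff`` and the foci
    distribution. An empty population yields an empty report."""
    edges = list(bins)
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]:g}")
    if len(complexes) == 0:
        return AfmComplexStats(0, labels, {l: float("nan") for l in labels},
                               float("nan"), tall_cutoff, float("nan"), {})
    heights = complexes.max_height_nm.to_numpy()
    counts = []
    for lo, hi in zip(edges, edges[1:]):
        counts.append(int(((heights >= lo) & (heights < hi)).sum()))
    counts.append(int((heights >= edges[-1]).sum()))
    # heights below the first edge are out of histogram range by definition;
    # percentages are relative to all analyzed complexes
    n = len(heights)
    pct = {l: 100.0 * c / n for l, c in zip(labels, counts)}
    foci = complexes.foci_count.value_counts().sort_index()
    return AfmComplexStats(
        n_complexes=n,
        bin_labels=labels,
        bin_percent=pct,
        percent_above_tall_cutoff=100.0 * float((heights > tall_cutoff).mean()),
        tall_cutoff_nm=tall_cutoff,
        mean_foci=float(complexes.foci_count.mean()),
        foci_counts={int(k): int(v) for k, v in foci.items()},
    )
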