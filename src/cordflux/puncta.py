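"""Thresholding, punctum detection and density/intensity readouts.

Workflow: auto-threshold an image (Otsu or a brightest-fraction
percentile rule), extract connected components as puncta, then report
puncta per 100 µm of cord and integrated ("detectable") intensity over a
region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .core import Image

__all__ = [
    "RoiCircle",
    "Punctum",
    "PunctaSet",
    "auto_threshold",
    "detect_puncta",
    "puncta_density",
    "integrated_density",
]


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is attempted on a constant image."""


@dataclass(frozen=True)
class RoiCircle:
    """Circular region of interest (default radius 50 px, the standard
    cell-body/intestinal ROI size)."""

    x_px: float
    y_px: float
    radius_px: float = 50.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (xx - self.x_px) ** 2 + (yy - self.y_px) ** 2 <= self.radius_px**2


@dataclass(frozen=True)
class Punctum:
    punctum_id: int
    x_um: float
    y_um: float
    area_px: int
    area_um2: float
    integrated_intensity: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass
class PunctaSet:
    """Detected fluorescent objects plus the detection context."""

    puncta: list[Punctum]
    threshold: float
    pixel_size_um: float
    cord_length_um: Optional[float] = None

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    @property
    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of (x_um, y_um) centroids."""
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([[p.x_um, p.y_um] for p in self.puncta])

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["punctum_id", "x_um", "y_um", "area_px", "area_um2",
                "integrated_intensity"]
        return pd.DataFrame(
            [[getattr(p, c) for c in cols] for p in self.puncta], columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def auto_threshold(
    img: Image,
    method: str = "otsu",
    percentile: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Automatically threshold an image.

    ``method="otsu"`` maximizes the between-class variance of the
    intensity histogram; ``method="percentile"`` retains exactly the
    brightest ``percentile`` fraction of pixels (ties broken by intensity,
    then by flat index).  Returns (boolean mask, threshold value); the
    mask is True where a pixel counts as above threshold.
    """
    data = img.data
    if data.size == 0:
        raise ValueError("cannot threshold an empty image")
    if method == "otsu":
        if np.ptp(data) == 0:
            raise DegenerateHistogramError(
                "Otsu thresholding is undefined on a constant image "
                f"(all pixels = {data.flat[0]:g}); use the percentile method"
            )
        t = float(threshold_otsu(data))
        return data > t, t
    if method == "percentile":
        if not 0.0 < percentile <= 1.0:
            raise ValueError("percentile must be in (0, 1]")
        k = int(round(percentile * data.size))
        k = max(k, 1)
        flat = data.ravel()
        # stable sort on index, then stable sort descending on value:
        # top-k are the brightest pixels, ties resolved by smaller index
        order = np.argsort(-flat, kind="stable")
        top = order[:k]
        mask = np.zeros(data.size, dtype=bool)
        mask[top] = True
        t = float(flat[top[-1]])
        return mask.reshape(data.shape), t
    raise ValueError(f"unknown threshold method {method!r}")


def detect_puncta(
    mask: np.ndarray,
    img: Image,
    min_area: int = 4,
    connectivity: int = 8,
    threshold: float = 0.0,
    cord_length_um: Optional[float] = None,
) -> PunctaSet:
    """Extract puncta as connected components of a thresholded mask.

    Centroids are intensity-weighted (better sub-pixel accuracy than
    geometric centroids) and reported in µm.  Components smaller than
    ``min_area`` pixels are rejected.  Two spots merged into one
    component are counted once — a documented limitation of
    connected-component detection.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    skconn = 1 if connectivity == 4 else 2
    labels = measure.label(mask, connectivity=skconn)
    px = img.pixel_size_um
    puncta = []
    for region in measure.regionprops(labels, intensity_image=img.data):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        puncta.append(Punctum(
            punctum_id=len(puncta),
            x_um=cx * px,
            y_um=cy * px,
            area_px=int(region.area),
            area_um2=float(region.area) * px * px,
            integrated_intensity=float(region.image_intensity[region.image].sum()),
            bbox=tuple(region.bbox),
        ))
    return PunctaSet(puncta=puncta, threshold=threshold, pixel_size_um=px,
                     cord_length_um=cord_length_um)


def puncta_density(ps: PunctaSet, cord_length_um: Optional[float] = None) -> float:
    """Puncta per 100 µm of analyzed cord length."""
    length = cord_length_um if cord_length_um is not None else ps.cord_length_um
    if length is None or length <= 0:
        raise ZeroDivisionError("cord_length_um must be positive")
    return len(ps) * 100.0 / length


def integrated_density(
    img: Image,
    region: Union[np.ndarray, RoiCircle],
    threshold: float = 0.0,
) -> float:
    """Sum of detectable (above-threshold) pixel intensities in a region.

    Below-threshold pixels contribute zero; ``region`` is a boolean mask
    or an :class:`RoiCircle`.
    """
    if isinstance(region, RoiCircle):
        in_bounds = (0 <= region.x_px < img.shape[1]
                     and 0 <= region.y_px < img.shape[0])
        region_mask = region.mask(img.shape)
        if not region_mask.any() and not in_bounds:
            raise ValueError("ROI lies fully outside the image")
    else:
        region_mask = np.asarray(region, dtype=bool)
        if region_mask.shape != img.shape:
            raise ValueError("region mask shape must match the image")
    sel = region_mask & (img.data > threshold)
    return float(img.data[sel].sum())
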