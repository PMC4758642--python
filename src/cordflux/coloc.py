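"""Colocalization estimators.

Two estimators are provided, matching the two acquisition contexts they
serve:

* :func:`tolerance_coloc` — the scatter-plot/tolerance-factor method used
  for neuronal cell bodies: after per-channel min-max rescaling over the
  above-threshold pixels, a pixel is colocalized when it is above
  threshold in both channels and the rescaled intensities agree within a
  tolerance.  The fraction is normalized to above-threshold channel-1
  pixels and a binary mask of colocalized pixels is returned.
* :func:`pearson_coloc` — the Pearson correlation of the two channels
  over the jointly thresholded pixels (intestinal images).

:func:`adjacency_fraction` measures "adjacent but not overlapping"
organelle relationships: the fraction of A-puncta whose nearest B-punctum
centroid lies within a distance cutoff (1 µm in the canonical use).

Autofluorescent pixels (e.g. flagged by spectral unmixing or a
DAPI-channel mask) can be excluded from both channels before any
statistic via the ``exclude`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .core import Image
from .puncta import PunctaSet

__all__ = [
    "ColocResult",
    "PearsonResult",
    "tolerance_coloc",
    "pearson_coloc",
    "adjacency_fraction",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.1
"""Default intensity-match tolerance on min-max rescaled values.

One tolerance applies across exposures because both channels are rescaled
to [0, 1] over their above-threshold pixels before comparison.
"""


@dataclass
class ColocResult:
    """Tolerance-method colocalization result with its binary mask."""

    fraction_ch1_colocalized: float  # NaN when undefined (no ch1 pixels)
    n_colocalized_px: int
    n_ch1_px: int
    tolerance: float
    mask: np.ndarray

    @property
    def defined(self) -> bool:
        return self.n_ch1_px > 0


@dataclass
class PearsonResult:
    r: float  # NaN when undefined (constant channel)
    n_px: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def _rescale_over_mask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1] over the masked pixels (0 if constant)."""
    out = np.zeros_like(data, dtype=float)
    if not mask.any():
        return out
    vals = data[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        out[mask] = (data[mask] - lo) / (hi - lo)
    return out


def _apply_exclusion(mask: np.ndarray, exclude: Optional[np.ndarray]) -> np.ndarray:
    if exclude is None:
        return mask
    exclude = np.asarray(exclude, dtype=bool)
    if exclude.shape != mask.shape:
        raise ValueError("exclusion mask shape must match the channel masks")
    return mask & ~exclude


def tolerance_coloc(
    ch1: Image,
    ch2: Image,
    mask1: np.ndarray,
    mask2: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
    exclude: Optional[np.ndarray] = None,
) -> ColocResult:
    """Tolerance-factor pixel colocalization.

    A pixel is colocalized iff it is above threshold in both channels and
    the per-channel min-max rescaled intensities differ by at most
    ``tolerance``.  The fraction is n_colocalized / n_ch1 (channel-1
    normalization); when channel 1 has no above-threshold pixels the
    fraction is returned as NaN with ``defined == False``.
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    mask1 = _apply_exclusion(np.asarray(mask1, dtype=bool), exclude)
    mask2 = _apply_exclusion(np.asarray(mask2, dtype=bool), exclude)
    if mask1.shape != ch1.shape or mask2.shape != ch2.shape:
        raise ValueError("masks must match the image shape")

    r1 = _rescale_over_mask(ch1.data, mask1)
    r2 = _rescale_over_mask(ch2.data, mask2)
    joint = mask1 & mask2
    coloc = joint & (np.abs(r1 - r2) <= tolerance)

    n1 = int(mask1.sum())
    nc = int(coloc.sum())
    frac = nc / n1 if n1 > 0 else float("nan")
    return ColocResult(fraction_ch1_colocalized=frac, n_colocalized_px=nc,
                       n_ch1_px=n1, tolerance=tolerance, mask=coloc)


def pearson_coloc(
    ch1: Image,
    ch2: Image,
    joint_mask: np.ndarray,
    exclude: Optional[np.ndarray] = None,
) -> PearsonResult:
    """Pearson correlation of the two channels over the masked pixels.

    Requires at least 3 masked pixels; a constant channel yields an
    undefined (NaN) coefficient rather than an error.
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    joint_mask = _apply_exclusion(np.asarray(joint_mask, dtype=bool), exclude)
    n = int(joint_mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 pixels for a correlation, got {n}")
    a = ch1.data[joint_mask]
    b = ch2.data[joint_mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return PearsonResult(r=float("nan"), n_px=n)
    r = float(pearsonr(a, b).statistic)
    return PearsonResult(r=r, n_px=n)


def adjacency_fraction(
    psA: PunctaSet,
    psB: PunctaSet,
    max_dist_um: float = 1.0,
) -> float:
    """Fraction of A-puncta with a B-centroid within ``max_dist_um``.

    Captures the "adjacent (within 1 µm) but not overlapping"
    relationship between organelle populations.  Returns NaN when B is
    empty (undefined); raises when A is empty.
    """
    if max_dist_um < 0:
        raise ValueError("max_dist_um must be non-negative")
    a = psA.centroids_um
    b = psB.centroids_um
    if len(a) == 0:
        raise ValueError("psA must contain at least one punctum")
    if len(b) == 0:
        return float("nan")
    dists, _ = cKDTree(b).query(a, k=1)
    return float(np.mean(dists <= max_dist_um))
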