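"""Core in-memory containers shared by all analysis stages.

Images are plain 2D float arrays with a physical pixel size; stacks are
ordered collections of co-registered images.  All physical coordinates are
in micrometres (µm), pixel coordinates are 0-based with x rightward and
y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "Image",
    "LambdaStack",
    "TimeLapse",
    "read_tiff_image",
    "write_tiff_image",
    "read_tiff_stack",
    "write_tiff_stack",
]

DEFAULT_PIXEL_SIZE_UM = 0.16
"""Default µm/pixel.

A 100X objective with an EMCCD camera gives roughly 0.16 µm/px, so a
512-px field of view spans ~82 µm of ventral cord; always overridable
because it is acquisition-dependent.
"""


@dataclass
class Image:
    """A single-channel 2D fluorescence image.

    Parameters
    ----------
    data
        Intensity grid (rows x cols), finite and non-negative.
    pixel_size_um
        Physical pixel size in µm/pixel (> 0).
    channel
        Free-text channel label (e.g. ``"GFP"``).
    """

    data: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Image data must be 2D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Image intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("Image intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def width_um(self) -> float:
        return self.data.shape[1] * self.pixel_size_um

    def copy(self) -> "Image":
        return replace(self, data=self.data.copy())


@dataclass
class LambdaStack:
    """A wavelength (lambda) scan: co-registered per-band images.

    Each pixel carries an emission spectrum sampled at ``wavelengths_nm``
    (strictly increasing band centres).  ``data`` has shape
    (n_bands, rows, cols).
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("LambdaStack data must be 3D (band, row, col)")
        if len(self.wavelengths_nm) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} bands but {len(self.wavelengths_nm)} wavelengths"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def band(self, i: int) -> Image:
        return Image(self.data[i], pixel_size_um=self.pixel_size_um,
                     channel=f"{self.wavelengths_nm[i]:g} nm")


@dataclass
class TimeLapse:
    """An ordered time-lapse stack acquired at a constant frame rate.

    ``data`` has shape (n_frames, rows, cols); the frame interval is
    1/``frame_rate_hz`` seconds.
    """

    data: np.ndarray
    frame_rate_hz: float = 3.1
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("TimeLapse data must be 3D (frame, row, col)")
        if self.data.shape[0] < 2:
            raise ValueError("TimeLapse needs at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame(self, i: int) -> Image:
        return Image(self.data[i], pixel_size_um=self.pixel_size_um)


# ---------------------------------------------------------------------------
# TIFF I/O (thin wrappers over tifffile; ImageJ-compatible axis order)

def write_tiff_image(path, img: Image) -> None:
    tifffile.imwrite(str(path), img.data.astype(np.float32),
                     metadata={"axes": "YX", "pixel_size_um": img.pixel_size_um})


def read_tiff_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> Image:
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Image(data, pixel_size_um=pixel_size_um)


def write_tiff_stack(path, data: np.ndarray) -> None:
    """Write a multi-page TIFF; page order = leading axis (time or band)."""
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32),
                     metadata={"axes": "TYX"})


def read_tiff_stack(path) -> np.ndarray:
    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return data
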