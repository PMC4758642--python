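"""Synthetic fluorescence-microscopy data with recorded ground truth.

Generates the kinds of acquisitions used to study retrograde transport in
C. elegans: sparse diffraction-limited puncta along a linear neurite,
two-channel images with a controllable colocalized fraction, lambda-scan
stacks mixing GFP with intestinal autofluorescence, and time-lapse movies
of vesicles moving anterograde/retrograde over a photobleached region.
Every generator returns a :class:`GroundTruth` alongside its data and is
bit-reproducible for a fixed seed.

Conventions: the neurite ("cord") runs horizontally; anterior is to the
left, so negative velocities are retrograde.  Puncta are isotropic 2D
Gaussians evaluated at pixel centres; the default spot width corresponds
to a FWHM of ~0.6 µm, within the 0.5-0.7 µm range typical of synaptic
receptor clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_PIXEL_SIZE_UM, Image, LambdaStack, TimeLapse

__all__ = [
    "SimImageSpec",
    "SimMovieSpec",
    "VesicleSpec",
    "GroundTruth",
    "make_puncta_image",
    "make_two_channel_image",
    "make_lambda_stack",
    "make_movie",
    "make_rab6_family",
    "BLEACH_BACKGROUND_FACTOR",
]

# Photobleached background retained after bleaching; bleaching is applied
# to improve contrast for moving-vesicle detection, the exact depth is an
# acquisition choice.
BLEACH_BACKGROUND_FACTOR = 0.2

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355


@dataclass(frozen=True)
class SimImageSpec:
    """Parameters for a single synthetic puncta image.

    Defaults give a 512x64 px field at 0.16 µm/px (~82 µm of cord) with
    spots of FWHM ≈ 0.59 µm.
    """

    width_px: int = 512
    height_px: int = 64
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_puncta: int = 12
    punctum_sigma_um: float = 0.25
    punctum_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be non-negative")
        if self.punctum_sigma_um <= 0 or self.punctum_amplitude <= 0:
            raise ValueError("punctum sigma and amplitude must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background and noise must be non-negative")

    @property
    def cord_length_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def punctum_fwhm_um(self) -> float:
        return FWHM_PER_SIGMA * self.punctum_sigma_um


@dataclass(frozen=True)
class VesicleSpec:
    """One simulated vesicle: start position, signed velocity and kinetics.

    Negative velocity moves toward the anterior (leftward) — retrograde.
    """

    start_x_um: float
    velocity_um_per_s: float
    pause_prob_per_frame: float = 0.0
    pause_len_frames: int = 0
    reversal_prob_per_frame: float = 0.0


@dataclass(frozen=True)
class SimMovieSpec:
    """Parameters for a synthetic vesicle-transport movie."""

    frames: int = 150
    frame_rate_hz: float = 3.1
    cord_length_um: float = 80.0
    vesicles: tuple = ()
    bleached_interval_um: tuple = (20.0, 60.0)
    stationary_n: int = 0
    height_px: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    punctum_sigma_um: float = 0.25
    punctum_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2 or self.frames > 500:
            raise ValueError("frames must be in [2, 500]")
        if self.frame_rate_hz <= 0 or self.cord_length_um <= 0:
            raise ValueError("frame rate and cord length must be positive")
        if self.stationary_n < 0:
            raise ValueError("stationary_n must be non-negative")
        for v in self.vesicles:
            if not 0.0 <= v.start_x_um <= self.cord_length_um:
                raise ValueError(
                    f"vesicle start {v.start_x_um} µm outside cord "
                    f"[0, {self.cord_length_um}]"
                )

    @property
    def width_px(self) -> int:
        return int(round(self.cord_length_um / self.pixel_size_um))


@dataclass
class GroundTruth:
    """Ground truth emitted alongside every simulated dataset.

    Only the fields relevant to the generator that produced it are set.
    """

    puncta: Optional[pd.DataFrame] = None          # per-punctum truth
    tracks: Optional[pd.DataFrame] = None          # per-frame vesicle truth
    track_classes: Optional[pd.DataFrame] = None   # per-vesicle class/direction
    coloc_labels: Optional[np.ndarray] = None      # per-pixel colocalization
    gfp_abundance: Optional[np.ndarray] = None
    auto_abundance: Optional[np.ndarray] = None

    def to_csv(self, path) -> None:
        """Write the object-level truth tables (puncta and/or tracks)."""
        frames = [df for df in (self.puncta, self.tracks, self.track_classes)
                  if df is not None]
        if not frames:
            raise ValueError("no tabular ground truth to write")
        pd.concat(frames, keys=range(len(frames))).to_csv(path, index=False)


def _render_spots(shape, centers_px, sigma_px, amplitudes) -> np.ndarray:
    """Render isotropic Gaussians at sub-pixel centres onto a zero canvas.

    Each spot is evaluated at pixel centres within a ±5 sigma window.
    """
    h, w = shape
    canvas = np.zeros((h, w), dtype=float)
    r = int(np.ceil(5 * sigma_px))
    for (cx, cy), amp in zip(centers_px, amplitudes):
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma_px**2))
        canvas[y0:y1, x0:x1] += amp * np.outer(gy, gx)
    return canvas


def _place_along_cord(rng, n, width_px, sigma_px, min_sep_px=None):
    """Draw n x-positions on the cord with a minimum pairwise separation.

    Separation defaults to 6 sigma so that spots remain individually
    resolvable; falls back to even spacing if rejection sampling cannot
    satisfy the constraint (very dense requests).
    """
    if n == 0:
        return np.empty(0)
    margin = 4 * sigma_px
    lo, hi = margin, width_px - margin
    if min_sep_px is None:
        min_sep_px = 6 * sigma_px
    if (hi - lo) < min_sep_px * (n - 1):
        return np.linspace(lo, hi, n)
    for _ in range(200):
        xs = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(xs)) >= min_sep_px:
            return xs
    # deterministic fallback: evenly spaced with a random phase
    xs = np.linspace(lo, hi, n)
    return xs


def make_puncta_image(spec: SimImageSpec) -> tuple[Image, GroundTruth]:
    """Simulate sparse diffraction-limited puncta along a horizontal cord.

    Returns the image plus per-punctum ground-truth centroids (µm) and
    amplitudes.  With ``noise_sd=0`` and ``n_puncta=0`` the image is
    identically ``background_level``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_px = spec.punctum_sigma_um / spec.pixel_size_um
    xs = _place_along_cord(rng, spec.n_puncta, spec.width_px, sigma_px)
    cy = (spec.height_px - 1) / 2.0
    centers = [(x, cy) for x in xs]
    amps = np.full(spec.n_puncta, spec.punctum_amplitude)
    canvas = _render_spots((spec.height_px, spec.width_px), centers, sigma_px, amps)
    canvas += spec.background_level
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, None)
    img = Image(canvas, pixel_size_um=spec.pixel_size_um, channel="ch1")
    truth = GroundTruth(puncta=pd.DataFrame({
        "punctum_id": np.arange(spec.n_puncta),
        "x_um": xs * spec.pixel_size_um,
        "y_um": np.full(spec.n_puncta, cy * spec.pixel_size_um),
        "amplitude": amps,
    }))
    return img, truth


def make_two_channel_image(
    spec: SimImageSpec,
    coloc_fraction: float,
    offset_um: float = 0.0,
) -> tuple[tuple[Image, Image], GroundTruth]:
    """Simulate a two-colour image with a controlled colocalized fraction.

    Channel 1 always contains ``n_puncta`` puncta.  A fraction
    ``coloc_fraction`` of them also appear at identical positions in
    channel 2 (so the tolerance-colocalized fraction of channel-1 pixels
    tracks ``coloc_fraction`` directly).  With ``offset_um == 0`` the
    non-shared channel-1 puncta have no channel-2 counterpart, and an
    equal number of channel-2-only puncta are placed at disjoint
    positions; with ``offset_um > 0`` each non-shared channel-1 punctum
    instead gets a channel-2 partner displaced along the cord by
    ``offset_um`` (for adjacency statistics).

    Ground truth: the puncta table labels each punctum ``shared`` /
    ``ch1`` / ``ch2`` / ``offset_pair`` with its per-channel centroid,
    and ``coloc_labels`` marks pixels within 2 sigma of a shared punctum
    centre.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    if offset_um < 0:
        raise ValueError("offset_um must be non-negative")
    rng = np.random.default_rng(spec.seed)
    sigma_px = spec.punctum_sigma_um / spec.pixel_size_um
    offset_px = offset_um / spec.pixel_size_um

    n = spec.n_puncta
    n_shared = int(round(coloc_fraction * n))
    n_nonshared = n - n_shared
    # extra ch2-only distractors only in the disjoint (offset == 0) layout
    n_total = n + (n_nonshared if offset_px == 0 else 0)
    min_sep = max(6 * sigma_px, 2 * offset_px + 6 * sigma_px)
    xs = _place_along_cord(rng, n_total,
                           spec.width_px - int(np.ceil(offset_px)) - 1,
                           sigma_px, min_sep_px=min_sep)
    xs = rng.permutation(xs)
    shared = np.zeros(n_total, dtype=bool)
    shared[:n_shared] = True  # positions already randomized by permutation

    cy = (spec.height_px - 1) / 2.0
    rows = []
    ch1_centers, ch2_centers = [], []
    for i, x in enumerate(xs):
        if shared[i]:
            ch1_centers.append((x, cy))
            ch2_centers.append((x, cy))
            rows.append((i, "shared", x, x))
        elif i < n and offset_px > 0:
            ch1_centers.append((x, cy))
            ch2_centers.append((x + offset_px, cy))
            rows.append((i, "offset_pair", x, x + offset_px))
        elif i < n:
            ch1_centers.append((x, cy))
            rows.append((i, "ch1", x, np.nan))
        else:
            ch2_centers.append((x, cy))
            rows.append((i, "ch2", np.nan, x))

    shape = (spec.height_px, spec.width_px)
    amp = spec.punctum_amplitude
    im1 = _render_spots(shape, ch1_centers, sigma_px, [amp] * len(ch1_centers))
    im2 = _render_spots(shape, ch2_centers, sigma_px, [amp] * len(ch2_centers))
    for im in (im1, im2):
        im += spec.background_level
    if spec.noise_sd > 0:
        im1 += rng.normal(0.0, spec.noise_sd, size=shape)
        im2 += rng.normal(0.0, spec.noise_sd, size=shape)
    im1 = np.clip(im1, 0.0, None)
    im2 = np.clip(im2, 0.0, None)

    yy, xx = np.mgrid[0:spec.height_px, 0:spec.width_px]
    labels = np.zeros(shape, dtype=bool)
    for i, x in enumerate(xs):
        if shared[i]:
            labels |= (xx - x) ** 2 + (yy - cy) ** 2 <= (2 * sigma_px) ** 2

    df = pd.DataFrame(rows, columns=["punctum_id", "kind", "x1_px", "x2_px"])
    df["x1_um"] = df["x1_px"] * spec.pixel_size_um
    df["x2_um"] = df["x2_px"] * spec.pixel_size_um
    df["offset_um"] = (df["x2_um"] - df["x1_um"]).abs()
    truth = GroundTruth(puncta=df, coloc_labels=labels)
    px = spec.pixel_size_um
    pair = (Image(im1, pixel_size_um=px, channel="ch1"),
            Image(im2, pixel_size_um=px, channel="ch2"))
    return pair, truth


def make_lambda_stack(
    gfp_abundance: Image,
    auto_abundance: Image,
    gfp_profile,
    auto_profile,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[LambdaStack, GroundTruth]:
    """Simulate a 9-band lambda scan (500-580 nm at 10 nm intervals).

    Per-pixel spectrum = gfp_abundance * gfp_profile
    + auto_abundance * auto_profile + Gaussian noise.
    """
    g = np.asarray(gfp_profile.weights, dtype=float)
    a = np.asarray(auto_profile.weights, dtype=float)
    if g.shape != (9,) or a.shape != (9,):
        raise ValueError("spectral profiles must have exactly 9 bands")
    if gfp_abundance.shape != auto_abundance.shape:
        raise ValueError("abundance images must share a shape")
    G = gfp_abundance.data
    A = auto_abundance.data
    stack = G[None] * g[:, None, None] + A[None] * a[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)
    ls = LambdaStack(stack, wavelengths_nm=np.arange(500, 581, 10),
                     pixel_size_um=gfp_abundance.pixel_size_um)
    truth = GroundTruth(gfp_abundance=G.copy(), auto_abundance=A.copy())
    return ls, truth


def _simulate_trajectory(rng, ves: VesicleSpec, spec: SimMovieSpec):
    """Per-frame x positions (µm); NaN once the vesicle leaves the cord.

    Pauses hold position for ``pause_len_frames``; reversals flip the
    velocity sign for the remainder of the trajectory (or until the next
    reversal).
    """
    dt = 1.0 / spec.frame_rate_hz
    x = ves.start_x_um
    v = ves.velocity_um_per_s
    pause_left = 0
    xs = np.full(spec.frames, np.nan)
    reversed_flags = np.zeros(spec.frames, dtype=bool)
    for t in range(spec.frames):
        xs[t] = x
        if v != 0.0:
            if pause_left > 0:
                pause_left -= 1
            else:
                if ves.reversal_prob_per_frame > 0 and rng.random() < ves.reversal_prob_per_frame:
                    v = -v
                    reversed_flags[t] = True
                if ves.pause_prob_per_frame > 0 and rng.random() < ves.pause_prob_per_frame:
                    pause_left = ves.pause_len_frames
                else:
                    x = x + v * dt
        if not 0.0 <= x <= spec.cord_length_um:
            xs[t + 1:] = np.nan
            break
    return xs, reversed_flags


def make_movie(spec: SimMovieSpec) -> tuple[TimeLapse, GroundTruth]:
    """Simulate a time-lapse of vesicles moving along a bleached cord.

    Vesicles are Gaussian spots following their ground-truth trajectories;
    the background inside ``bleached_interval_um`` is scaled by
    :data:`BLEACH_BACKGROUND_FACTOR`.  Vesicles that leave the cord simply
    disappear from subsequent frames (they exit the field of view).
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px
    sigma_px = spec.punctum_sigma_um / spec.pixel_size_um
    cy = (h - 1) / 2.0

    vesicles = list(spec.vesicles)
    for _ in range(spec.stationary_n):
        vesicles.append(VesicleSpec(
            start_x_um=float(rng.uniform(0.1, 0.9) * spec.cord_length_um),
            velocity_um_per_s=0.0))

    traj = []
    for ves in vesicles:
        xs, rev = _simulate_trajectory(rng, ves, spec)
        traj.append((ves, xs, rev))

    background = np.full((h, w), spec.background_level)
    b0, b1 = spec.bleached_interval_um
    x_um_axis = (np.arange(w) + 0.5) * spec.pixel_size_um
    bleached_cols = (x_um_axis >= b0) & (x_um_axis <= b1)
    background[:, bleached_cols] *= BLEACH_BACKGROUND_FACTOR

    frames = np.empty((spec.frames, h, w))
    for t in range(spec.frames):
        centers, amps = [], []
        for ves, xs, _rev in traj:
            if np.isfinite(xs[t]):
                centers.append((xs[t] / spec.pixel_size_um, cy))
                amps.append(spec.punctum_amplitude)
        frame = background + _render_spots((h, w), centers, sigma_px, amps)
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=(h, w))
        frames[t] = np.clip(frame, 0.0, None)

    rows, cls_rows = [], []
    for vid, (ves, xs, rev) in enumerate(traj):
        mobile = ves.velocity_um_per_s != 0.0
        finite = np.isfinite(xs)
        net = (xs[finite][-1] - xs[finite][0]) if finite.any() else 0.0
        if not mobile:
            direction = "none"
        elif net < 0 or (net == 0 and ves.velocity_um_per_s < 0):
            direction = "retrograde"
        else:
            direction = "anterograde"
        cls_rows.append((vid, "mobile" if mobile else "stationary", direction,
                         abs(ves.velocity_um_per_s), ves.start_x_um))
        for t in range(spec.frames):
            if np.isfinite(xs[t]):
                rows.append((vid, t, xs[t], bool(rev[t])))

    truth = GroundTruth(
        tracks=pd.DataFrame(rows, columns=["vesicle_id", "frame", "x_um", "reversed"]),
        track_classes=pd.DataFrame(
            cls_rows,
            columns=["vesicle_id", "true_class", "true_direction",
                     "true_speed_um_per_s", "start_x_um"]),
    )
    movie = TimeLapse(frames, frame_rate_hz=spec.frame_rate_hz,
                      pixel_size_um=spec.pixel_size_um)
    return movie, truth


# ---------------------------------------------------------------------------
# Synthetic Rab6-family protein sequences

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
# one dissimilar replacement per residue (always lands outside the
# recipient's similarity group)
_DISSIMILAR = {aa: _AMINO[(i + 7) % 20] for i, aa in enumerate(_AMINO)}
_DISSIMILAR["M"] = "W"  # +7 would give V, which shares the ILVM group

DIAGNOSTIC_POSITIONS = (63, 106, 139)


def make_rab6_family(seed: int = 0, length: int = 210, divergence: float = 0.10):
    """Generate a synthetic Rab6-like protein family for desk-scale tests.

    These are synthetic stand-ins, not the real GenBank sequences: random
    proteins constructed to carry the documented subfamily structure — a
    Rab6A-like reference with V63/T106/S139, a Rab6A'-like variant
    differing at exactly three residues (one of them I63), a Rab6B-like
    sequence with V63/S106/T139, and a RAB-6.1-like / RAB-6.2-like pair
    whose pairwise conservation is 1 - ``divergence`` (substitutions are
    drawn outside the similarity groups, so identity equals conservation).

    Returns a dict mapping name -> residue string, all of ``length``
    residues (gapless family, so alignment positions equal sequence
    positions).
    """
    if length < max(DIAGNOSTIC_POSITIONS):
        raise ValueError(f"length must be >= {max(DIAGNOSTIC_POSITIONS)}")
    rng = np.random.default_rng(seed)
    base = list(rng.choice(list(_AMINO), size=length))

    def with_diag(seq, p63, p106, p139):
        s = list(seq)
        s[62], s[105], s[138] = p63, p106, p139
        return s

    rab6a = with_diag(base, "V", "T", "S")

    # Rab6A' = Rab6A with exactly 3 substitutions, one of them position 63
    rab6a_prime = list(rab6a)
    rab6a_prime[62] = "I"
    candidates = [i for i in range(length) if i not in (62, 105, 138)]
    for i in rng.choice(candidates, size=2, replace=False):
        rab6a_prime[i] = _DISSIMILAR[rab6a_prime[i]]

    rab6b = with_diag(base, "V", "S", "T")

    # RAB-6.1-like: diverged from the Rab6A-like reference but keeps the
    # Rab6A-type diagnostic residues (V63, T106, S139)
    rab61 = list(rab6a)
    n_sub = int(round(divergence * length))
    sub_sites = rng.choice(candidates, size=n_sub, replace=False)
    for i in sub_sites:
        rab61[i] = _DISSIMILAR[rab61[i]]

    # RAB-6.2-like: same backbone divergence pattern relative to RAB-6.1
    # (so the RAB-6.1/RAB-6.2 conservation is 1 - divergence), with
    # Rab6B-type diagnostics (I63, S106, T139)
    rab62 = list(rab61)
    sub_sites2 = rng.choice(candidates, size=n_sub, replace=False)
    for i in sub_sites2:
        rab62[i] = _DISSIMILAR[rab61[i]]
    rab62 = with_diag(rab62, "I", "S", "T")
    # position 63 differs between rab61 (V) and rab62 (I): part of divergence
    ypt6 = with_diag(rab61, "I", "D", "T")

    return {
        "Rab6A_synthetic": "".join(rab6a),
        "Rab6Aprime_synthetic": "".join(rab6a_prime),
        "Rab6B_synthetic": "".join(rab6b),
        "RAB-6.1_synthetic": "".join(rab61),
        "RAB-6.2_synthetic": "".join(rab62),
        "Ypt6_synthetic": "".join(ypt6),
    }
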