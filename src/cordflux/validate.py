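"""Ground-truth evaluation utilities for synthetic data.

Matches detected kymograph tracks against the per-vesicle ground truth
emitted by the movie generator, so recovery of class, direction and
velocity can be scored.  Matching is by overlap: each true vesicle is
assigned the detected track sharing the most (frame, position) points
within a pixel tolerance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .kymo import Track
from .simdata import GroundTruth

__all__ = ["evaluate_tracking"]


def evaluate_tracking(
    truth: GroundTruth,
    tracks: Sequence[Track],
    pixel_size_um: float,
    match_tol_px: float = 2.0,
) -> pd.DataFrame:
    """Score detected tracks against movie ground truth.

    Returns one row per true vesicle with the matched track's class,
    direction and mean velocity next to the true values.  Vesicles with
    no overlapping track get ``matched = False``.
    """
    if truth.tracks is None or truth.track_classes is None:
        raise ValueError("ground truth does not contain vesicle tracks")
    rows = []
    tt = truth.tracks
    for _, v in truth.track_classes.iterrows():
        sub = tt[tt["vesicle_id"] == v["vesicle_id"]]
        fx = dict(zip(sub["frame"], sub["x_um"] / pixel_size_um))
        best, best_n = None, 0
        for t in tracks:
            n = sum(1 for f, x in zip(t.frames, t.x_px)
                    if f in fx and abs(fx[f] - x) <= match_tol_px)
            if n > best_n:
                best, best_n = t, n
        rows.append({
            "vesicle_id": v["vesicle_id"],
            "true_class": v["true_class"],
            "true_direction": v["true_direction"],
            "true_speed_um_per_s": v["true_speed_um_per_s"],
            "matched": best is not None,
            "matched_points": best_n,
            "detected_class": best.track_class if best else None,
            "detected_direction": best.direction if best else None,
            "detected_velocity_um_per_s":
                best.mean_velocity_um_per_s if best else np.nan,
        })
    return pd.DataFrame(rows)
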