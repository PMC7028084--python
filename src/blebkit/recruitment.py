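"""Actin-recruitment delay inside blebs from two-channel intensity traces.

The membrane (cytoplasmic mCherry) signal rises as soon as the bleb inflates;
cortical actin (Lifeact-GFP) follows after a short lag. Within a bleb ROI the
mean intensity of each channel is extracted per plane, normalized to [0, 1]
over the observation window, and the delay is the difference between the two
channels' first threshold crossings (linearly interpolated between samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from .io import LabeledMovie

__all__ = ["IntensityTrace", "DelayEstimate", "plane_timestamps",
           "extract_trace", "estimate_delay"]


@dataclass(frozen=True)
class IntensityTrace:
    """Per-channel mean ROI intensity over time plus [0, 1] normalization."""

    timestamps_s: np.ndarray
    raw_membrane: np.ndarray
    raw_actin: np.ndarray
    norm_membrane: np.ndarray
    norm_actin: np.ndarray
    degenerate_channels: tuple[str, ...] = ()


@dataclass(frozen=True)
class DelayEstimate:
    """delay_s = actin crossing time - membrane crossing time (positive:
    actin later)."""

    delay_s: float
    threshold: float
    t_membrane_s: float
    t_actin_s: float


def plane_timestamps(frame_interval_s: float, n_planes: int) -> np.ndarray:
    """Time offset of each z-plane within a stack.

    Every plane of a z-stack is treated as one frame; plane k (0-based) sits
    at k * (frame_interval / n_planes).
    """
    if frame_interval_s <= 0 or n_planes < 1:
        raise ValueError("frame interval must be positive and n_planes >= 1")
    return np.arange(n_planes) * (frame_interval_s / n_planes)


def _normalize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v), True
    return (v - lo) / (hi - lo), False


def extract_trace(
    movie: LabeledMovie,
    roi_polygon_um: np.ndarray,
    frames: slice | np.ndarray | None = None,
) -> IntensityTrace:
    """Mean intensity of both channels inside a polygon ROI, per plane.

    ``roi_polygon_um`` is an (N, 2) array of (x, y) vertices in micrometres.
    ``frames`` restricts the window (normalization happens over that window
    only). A channel that is constant over the window is flagged degenerate
    and its normalized trace is all zeros.
    """
    poly = np.asarray(roi_polygon_um, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("ROI polygon must be (N >= 3, 2) vertices")
    px = movie.pixel_size_um
    H, W = movie.pixels.shape[2:]
    if poly.min() < 0 or poly[:, 0].max() > W * px or poly[:, 1].max() > H * px:
        raise ValueError("ROI polygon extends outside the image bounds")
    rowcol = np.column_stack([poly[:, 1] / px - 0.5, poly[:, 0] / px - 0.5])
    mask = polygon2mask((H, W), rowcol)
    if not mask.any():
        raise ValueError("empty ROI: polygon covers no pixel centers")

    if frames is None:
        frames = slice(None)
    mem = movie.channel("membrane")[frames].astype(float)
    act = movie.channel("actin")[frames].astype(float)
    ts = movie.timestamps_s[frames]
    raw_m = mem[:, mask].mean(axis=1)
    raw_a = act[:, mask].mean(axis=1)
    norm_m, deg_m = _normalize(raw_m)
    norm_a, deg_a = _normalize(raw_a)
    degenerate = tuple(
        name for name, deg in (("membrane", deg_m), ("actin", deg_a)) if deg
    )
    return IntensityTrace(ts, raw_m, raw_a, norm_m, norm_a, degenerate)


def _first_crossing(t: np.ndarray, v: np.ndarray, threshold: float,
                    name: str) -> float:
    above = v >= threshold
    if not above.any():
        raise ValueError(f"channel {name!r} never reaches threshold {threshold}")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing samples
    f = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def estimate_delay(trace: IntensityTrace, threshold: float = 0.5) -> DelayEstimate:
    """Actin-minus-membrane delay from interpolated threshold crossings."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for name in trace.degenerate_channels:
        raise ValueError(f"channel {name!r} is degenerate (constant over window)")
    t_mem = _first_crossing(trace.timestamps_s, trace.norm_membrane, threshold,
                            "membrane")
    t_act = _first_crossing(trace.timestamps_s, trace.norm_actin, threshold,
                            "actin")
    return DelayEstimate(
        delay_s=t_act - t_mem, threshold=threshold,
        t_membrane_s=t_mem, t_actin_s=t_act,
    )
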