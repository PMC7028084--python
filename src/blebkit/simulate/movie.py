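"""Synthetic two-channel blebbing-cell movies with pixel-level ground truth.

Renders a rounded cell body (cytoplasmic mCherry fills the membrane channel;
Lifeact-GFP marks the cortical actin rim) with balloon-like membrane blebs
nucleating at the leading edge. Default geometry and kinetics follow the
reported morphology of blebbing Arp3-knockdown T cells: about five blebs per
leading edge, each ~3 um across and ~2% of whole-cell area, expanding over
19 s and retracting over 32 s, with cortical actin reappearing in the bleb
about 1 s after the membrane protrudes.

The bleb's projected area ramps linearly in time during expansion and
retraction (radius ~ sqrt(area)); the actin signal inside a bleb is a uniform
fill at a fraction of the cortical-rim intensity whose footprint is the
membrane footprint delayed by ``actin_lag_s``, so the mean actin intensity in
a bleb ROI is an exact time-shift of the membrane intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ..io import LabeledMovie

__all__ = ["MovieSimConfig", "BlebPlacementError", "BlebGroundTruth", "GroundTruth",
           "render_bleb_movie"]

FOREGROUND = 10000  # uint16 counts for membrane fill / actin rim


class BlebPlacementError(ValueError):
    """Requested blebs cannot be placed on the leading-edge arc without overlap."""


class MovieSimConfig(BaseModel):
    """Geometry, kinetics and imaging parameters of the synthetic movie.

    ``cell_radius_um`` defaults to 9.8 um so that a fully expanded 3-um bleb
    occupies ~2% of whole-cell (body + blebs) area, matching the reported
    bleb-size distribution.
    """

    model_config = {"extra": "forbid", "frozen": True}

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = Field(0.3, gt=0)
    n_frames: int = Field(14, ge=1)
    frame_interval_s: float = Field(5.0, gt=0)
    z_steps_per_frame: int = Field(1, ge=1)
    cell_radius_um: float = Field(9.8, gt=0)
    n_blebs: int = Field(5, ge=0)
    bleb_diameter_um: float = Field(3.0, gt=0)
    expansion_duration_s: float = Field(19.0, gt=0)
    plateau_duration_s: float = Field(10.0, ge=0)
    retraction_duration_s: float = Field(32.0, gt=0)
    actin_lag_s: float = Field(1.0, ge=0)
    leading_edge_halfangle_deg: float = Field(60.0, gt=0, le=180)
    bleb_actin_fill_fraction: float = Field(0.4, ge=0, le=1)
    rim_width_px: int = Field(2, ge=1)
    noise_sd: float = Field(0.0, ge=0, lt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _geometry(self) -> "MovieSimConfig":
        if self.bleb_diameter_um >= 2 * self.cell_radius_um:
            raise ValueError("bleb diameter must be smaller than the cell diameter")
        return self

    @property
    def plane_interval_s(self) -> float:
        return self.frame_interval_s / self.z_steps_per_frame

    @property
    def n_planes(self) -> int:
        return self.n_frames * self.z_steps_per_frame

    @property
    def bleb_lifetime_s(self) -> float:
        return (self.expansion_duration_s + self.plateau_duration_s
                + self.retraction_duration_s)


@dataclass
class BlebGroundTruth:
    """Programmed kinetics and per-plane footprint of one bleb."""

    bleb_id: int
    angle_deg: float
    birth_s: float
    death_s: float
    radius_um: np.ndarray          # per plane, 0 when absent
    centroid_um: np.ndarray        # per plane (x, y), NaN when absent
    masks: np.ndarray              # per plane, bool HxW, bleb footprint beyond body

    @property
    def present(self) -> np.ndarray:
        return self.masks.any(axis=(1, 2))


@dataclass
class GroundTruth:
    """Everything the renderer knows: masks, kinetics and echoed parameters."""

    config: MovieSimConfig
    cell_masks: np.ndarray          # (T, H, W) bool, body plus blebs
    body_mask: np.ndarray           # (H, W) bool, cell body only
    cell_center_um: tuple[float, float]
    heading_deg: float
    blebs: list[BlebGroundTruth]
    steady_frames: list[int]        # planes with every bleb at plateau area
    actin_lag_s: float

    def summary_dict(self) -> dict:
        """JSON-serializable scalar summary (masks omitted)."""
        return {
            "actin_lag_s": self.actin_lag_s,
            "heading_deg": self.heading_deg,
            "cell_center_um": list(self.cell_center_um),
            "steady_frames": self.steady_frames,
            "blebs": [
                {
                    "bleb_id": b.bleb_id,
                    "angle_deg": b.angle_deg,
                    "birth_s": b.birth_s,
                    "death_s": b.death_s,
                    "max_radius_um": float(np.nanmax(b.radius_um)),
                }
                for b in self.blebs
            ],
            "config": self.config.model_dump(),
        }


def _area_fraction(t: float, cfg: MovieSimConfig) -> float:
    """Bleb area as a fraction of its maximum, piecewise linear in time."""
    E, P, R = (cfg.expansion_duration_s, cfg.plateau_duration_s,
               cfg.retraction_duration_s)
    if t <= 0:
        return 0.0
    if t < E:
        return t / E
    if t <= E + P:
        return 1.0
    if t < E + P + R:
        return 1.0 - (t - E - P) / R
    return 0.0


def _bleb_angles(cfg: MovieSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Evenly spaced bleb angles (deg) within the leading-edge cone, jittered.

    Raises :class:`BlebPlacementError` when the requested blebs cannot fit on
    the arc without overlapping.
    """
    if cfg.n_blebs == 0:
        return np.empty(0)
    r = cfg.bleb_diameter_um / 2.0
    center_dist = cfg.cell_radius_um + 0.8 * r
    halfwidth = math.degrees(math.asin(min(r / center_dist, 1.0)))
    gap = math.degrees(3.0 * cfg.pixel_size_um / cfg.cell_radius_um)
    span = 2.0 * cfg.leading_edge_halfangle_deg
    needed = cfg.n_blebs * (2 * halfwidth + gap)
    if needed > span:
        raise BlebPlacementError(
            f"{cfg.n_blebs} blebs of diameter {cfg.bleb_diameter_um} um need "
            f"{needed:.1f} deg of arc but the leading edge spans {span:.1f} deg"
        )
    if cfg.n_blebs == 1:
        base = np.array([0.0])
        slack = span / 2 - halfwidth
    else:
        pitch = span / cfg.n_blebs
        base = -span / 2 + pitch * (np.arange(cfg.n_blebs) + 0.5)
        slack = (pitch - 2 * halfwidth - gap) / 2
    jitter = rng.uniform(-0.5, 0.5, size=cfg.n_blebs) * max(slack, 0.0)
    return base + jitter


def render_bleb_movie(cfg: MovieSimConfig) -> tuple[LabeledMovie, GroundTruth]:
    """Render the movie and its ground truth; deterministic for a fixed seed.

    Each z-plane is treated as one frame at its own timestamp (offset
    ``frame_interval_s / z_steps_per_frame`` between planes), matching how
    fast intra-stack kinetics are analyzed.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_shape
    px = cfg.pixel_size_um
    # pixel-center coordinates in um
    ys = (np.arange(H) + 0.5) * px
    xs = (np.arange(W) + 0.5) * px
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    cx, cy = W / 2 * px, H / 2 * px
    dist_body = np.hypot(X - cx, Y - cy)
    body = dist_body <= cfg.cell_radius_um
    rim = body & (dist_body >= cfg.cell_radius_um - cfg.rim_width_px * px)

    angles = _bleb_angles(cfg, rng)
    r_max = cfg.bleb_diameter_um / 2.0
    heading_deg = 0.0  # stationary cell: leading edge along +x

    T = cfg.n_planes
    times = np.arange(T) * cfg.plane_interval_s
    mem = np.zeros((T, H, W), dtype=float)
    act = np.zeros((T, H, W), dtype=float)
    cell_masks = np.zeros((T, H, W), dtype=bool)
    bleb_masks = np.zeros((len(angles), T, H, W), dtype=bool)
    radius_tab = np.zeros((len(angles), T))
    centroid_tab = np.full((len(angles), T, 2), np.nan)

    def bleb_footprint(angle_deg: float, t_rel: float) -> tuple[np.ndarray, float]:
        s = _area_fraction(t_rel, cfg)
        if s <= 0:
            return np.zeros((H, W), dtype=bool), 0.0
        r = r_max * math.sqrt(s)
        d = cfg.cell_radius_um + 0.8 * r
        a = math.radians(angle_deg)
        bx, by = cx + d * math.cos(a), cy + d * math.sin(a)
        disk = np.hypot(X - bx, Y - by) <= r
        return disk & ~body, r

    for k, t in enumerate(times):
        frame_mask = body.copy()
        actin = np.where(rim, float(FOREGROUND), 0.0)
        for i, ang in enumerate(angles):
            fp, r = bleb_footprint(ang, t)
            frame_mask |= fp
            bleb_masks[i, k] = fp
            radius_tab[i, k] = r
            if fp.any():
                centroid_tab[i, k, 0] = X[fp].mean()
                centroid_tab[i, k, 1] = Y[fp].mean()
            # delayed actin fill inside the bleb
            fp_lag, _ = bleb_footprint(ang, t - cfg.actin_lag_s)
            fill = cfg.bleb_actin_fill_fraction * FOREGROUND
            actin = np.where(fp_lag & ~rim, np.maximum(actin, fill), actin)
        mem[k] = np.where(frame_mask, float(FOREGROUND), 0.0)
        act[k] = actin
        cell_masks[k] = frame_mask

    if cfg.noise_sd > 0:
        mem += rng.normal(0.0, cfg.noise_sd * FOREGROUND, size=mem.shape)
        act += rng.normal(0.0, cfg.noise_sd * FOREGROUND, size=act.shape)
    pixels = np.stack([mem, act], axis=1)
    pixels = np.clip(pixels, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    movie = LabeledMovie(
        pixels=pixels,
        pixel_size_um=px,
        timestamps_s=times,
        channel_names=("membrane", "actin"),
        frame_interval_s=cfg.frame_interval_s,
        z_steps_per_frame=cfg.z_steps_per_frame,
    )

    blebs = []
    for i, ang in enumerate(angles):
        present = bleb_masks[i].any(axis=(1, 2))
        blebs.append(
            BlebGroundTruth(
                bleb_id=i,
                angle_deg=float(ang),
                birth_s=0.0,
                death_s=float(cfg.bleb_lifetime_s),
                radius_um=radius_tab[i],
                centroid_um=centroid_tab[i],
                masks=bleb_masks[i],
            )
        )
    E, P = cfg.expansion_duration_s, cfg.plateau_duration_s
    steady = [int(k) for k, t in enumerate(times) if E <= t <= E + P] if len(angles) else []
    gt = GroundTruth(
        config=cfg,
        cell_masks=cell_masks,
        body_mask=body,
        cell_center_um=(cx, cy),
        heading_deg=heading_deg,
        blebs=blebs,
        steady_frames=steady,
        actin_lag_s=cfg.actin_lag_s,
    )
    return movie, gt
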