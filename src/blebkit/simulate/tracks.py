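"""Synthetic 3D cell tracks: isotropic Brownian motion and persistent random walks.

Stands in for tracking-software exports so the motility statistics can be
validated against known generating parameters. Two presets mirror the study
conditions for control and Arp3-knockdown T cells migrating in 3D collagen:
diffusion coefficients of 26.7 and 10.4 um^2/min and mean speeds of 5 +/- 2.3
and 2.3 +/- 1.4 um/min, sampled every ~20 s for ~15 min.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from ..motility import Track

__all__ = ["TrackSimConfig", "CONTROL3D", "KD3D", "simulate_tracks"]


class TrackSimConfig(BaseModel):
    """Parameters for a simulated track ensemble.

    Brownian mode draws per-axis Gaussian displacements with variance
    2*D*dt; PRW mode moves each cell at a per-track constant speed whose
    direction decorrelates with time constant ``persistence_time``.
    """

    model_config = {"extra": "forbid", "frozen": True}

    n_tracks: int = Field(220, ge=1)
    n_frames: int = Field(45, ge=2)
    dt_s: float = Field(20.0, gt=0)
    mode: Literal["brownian", "prw"] = "brownian"
    diffusion_coeff_um2_min: float = Field(26.7, ge=0)
    speed_mean_um_min: float = Field(5.0, ge=0)
    speed_sd_um_min: float = Field(2.3, ge=0)
    persistence_time_s: float = Field(60.0, gt=0)
    ndim: Literal[2, 3] = 3
    seed: int = 0

    @model_validator(mode="after")
    def _finite(self) -> "TrackSimConfig":
        vals = [
            self.dt_s,
            self.diffusion_coeff_um2_min,
            self.speed_mean_um_min,
            self.speed_sd_um_min,
            self.persistence_time_s,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite simulation parameter")
        return self


#: Control T cells in 3D collagen: D = 26.7 um^2/min, speed 5 +/- 2.3 um/min.
CONTROL3D = TrackSimConfig(
    n_tracks=220,
    diffusion_coeff_um2_min=26.7,
    speed_mean_um_min=5.0,
    speed_sd_um_min=2.3,
)

#: Arp3-knockdown T cells: D = 10.4 um^2/min, speed 2.3 +/- 1.4 um/min.
KD3D = TrackSimConfig(
    n_tracks=55,
    diffusion_coeff_um2_min=10.4,
    speed_mean_um_min=2.3,
    speed_sd_um_min=1.4,
)


def _brownian(cfg: TrackSimConfig, rng: np.random.Generator) -> np.ndarray:
    D_um2_s = cfg.diffusion_coeff_um2_min / 60.0
    sigma = np.sqrt(2.0 * D_um2_s * cfg.dt_s)
    steps = rng.standard_normal((cfg.n_tracks, cfg.n_frames - 1, cfg.ndim)) * sigma
    pos = np.concatenate(
        [np.zeros((cfg.n_tracks, 1, cfg.ndim)), np.cumsum(steps, axis=1)], axis=1
    )
    return pos


def _prw(cfg: TrackSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Constant-speed steps; direction relaxes on the unit sphere.

    Per step the direction vector is blended with isotropic noise,
    d <- normalize(a*d + sqrt(1-a^2)*eta), a = exp(-dt/persistence_time),
    which gives an exponentially decorrelating heading. Speeds are per-track,
    drawn from a Gaussian truncated at zero.
    """
    if cfg.speed_sd_um_min > 0:
        a = -cfg.speed_mean_um_min / cfg.speed_sd_um_min
        speeds = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=cfg.speed_mean_um_min,
            scale=cfg.speed_sd_um_min,
            size=cfg.n_tracks,
            random_state=rng,
        )
    else:
        speeds = np.full(cfg.n_tracks, cfg.speed_mean_um_min)
    speeds_um_s = speeds / 60.0

    alpha = np.exp(-cfg.dt_s / cfg.persistence_time_s)
    d = rng.standard_normal((cfg.n_tracks, cfg.ndim))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pos = np.zeros((cfg.n_tracks, cfg.n_frames, cfg.ndim))
    for k in range(1, cfg.n_frames):
        eta = rng.standard_normal((cfg.n_tracks, cfg.ndim))
        eta /= np.linalg.norm(eta, axis=1, keepdims=True)
        d = alpha * d + np.sqrt(1.0 - alpha**2) * eta
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pos[:, k] = pos[:, k - 1] + d * (speeds_um_s[:, None] * cfg.dt_s)
    return pos


def simulate_tracks(cfg: TrackSimConfig) -> list[Track]:
    """Simulate an ensemble of tracks; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "brownian":
        pos = _brownian(cfg, rng)
    elif cfg.mode == "prw":
        pos = _prw(cfg, rng)
    else:  # pragma: no cover - pydantic rejects earlier
        raise ValueError(f"unknown mode {cfg.mode!r}")
    t = np.arange(cfg.n_frames) * cfg.dt_s
    return [Track(track_id=i, t_s=t, pos_um=pos[i]) for i in range(cfg.n_tracks)]
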