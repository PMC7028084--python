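"""End-to-end pipeline: segmentation -> bleb detection -> linking -> kinetics
-> actin-delay, plus independent track-motility statistics.

Configuration is a single validated :class:`RunConfig`; every output carries a
provenance block (config hash, seed, package version) so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .io import LabeledMovie, read_movie, read_tracks
from .morphometry import (
    BlebDetectionParams,
    BlebTrack,
    bleb_kinetics,
    bleb_summary,
    detect_blebs,
    segment_cell,
    track_blebs,
)
from .motility import compute_msd, compute_track_stats, filter_tracks, fit_diffusion_coefficient
from .recruitment import estimate_delay, extract_trace

log = logging.getLogger("blebkit")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class RunConfig(BaseModel):
    """Parameters for every pipeline stage; unknown keys are rejected."""

    model_config = {"extra": "forbid"}

    movie_tiff: str | None = None
    movie_json: str | None = None
    tracks_csv: str | None = None
    out_dir: str = "."

    detection: BlebDetectionParams = BlebDetectionParams()
    heading_deg: float = 0.0
    max_link_dist_um: float = 2.0
    delay_threshold: float = 0.5
    min_track_length_um: float = 5.0
    msd_dimensionality: int = Field(3, ge=2, le=3)
    msd_lag_fraction: float = Field(0.25, gt=0, le=1)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded)."""
        params = self.model_dump(
            exclude={"movie_tiff", "movie_json", "tracks_csv", "out_dir",
                     "log_level"}
        )
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class PipelineResult(BaseModel):
    model_config = {"arbitrary_types_allowed": True}

    blebs: pd.DataFrame | None = None
    kinetics: pd.DataFrame | None = None
    delays: pd.DataFrame | None = None
    track_stats: pd.DataFrame | None = None
    msd: pd.DataFrame | None = None
    summary: dict = {}


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _bleb_roi_polygon(track: BlebTrack, pixel_size_um: float,
                      pad_um: float) -> np.ndarray:
    """Rectangle ROI (um) around the union of a track's region footprints."""
    union = np.zeros_like(track.regions[0].mask)
    for reg in track.regions:
        union |= reg.mask
    rr, cc = np.nonzero(union)
    px = pixel_size_um
    x0, x1 = (cc.min() + 0.5) * px - pad_um, (cc.max() + 0.5) * px + pad_um
    y0, y1 = (rr.min() + 0.5) * px - pad_um, (rr.max() + 0.5) * px + pad_um
    H, W = union.shape
    x0, y0 = max(x0, 0.0), max(y0, 0.0)
    x1, y1 = min(x1, W * px), min(y1, H * px)
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all configured stages in dependency order and write outputs.

    Bleb stages need a movie; track statistics need a track table. Any stage
    failure aborts with the stage name in the exception message.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    summary: dict = {"provenance": _provenance(config)}

    if config.movie_tiff:
        if not config.movie_json:
            raise ValueError("stage read_movie: metadata sidecar path required")
        movie = read_movie(config.movie_tiff, config.movie_json)
        _run_bleb_stages(config, movie, result, summary)

    if config.tracks_csv:
        _run_track_stages(config, result, summary)

    for name in ("blebs", "kinetics", "delays", "track_stats", "msd"):
        df = getattr(result, name)
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    result.summary = summary
    return result


def _run_bleb_stages(config: RunConfig, movie: LabeledMovie,
                     result: PipelineResult, summary: dict) -> None:
    membrane = movie.channel("membrane")
    actin = movie.channel("actin")
    masks = []
    regions_by_frame = []
    for k in range(movie.n_frames):
        try:
            cm = segment_cell(membrane[k], movie.pixel_size_um, frame_index=k)
        except Exception as exc:
            raise RuntimeError(f"stage segment (frame {k}): {exc}") from exc
        masks.append(cm)
        regions_by_frame.append(
            detect_blebs(membrane[k], actin[k], cm, params=config.detection,
                         heading_deg=config.heading_deg)
        )
    n_regions = sum(len(r) for r in regions_by_frame)
    log.info("detected %d bleb regions over %d frames", n_regions, movie.n_frames)

    tracks = track_blebs(regions_by_frame, max_link_dist_um=config.max_link_dist_um)
    result.blebs = bleb_summary(tracks, movie.timestamps_s)

    kin_rows = []
    for trk in tracks:
        e, r = bleb_kinetics(trk, movie.timestamps_s)
        kin_rows.append({"track_id": trk.track_id, "expansion_s": e,
                         "retraction_s": r})
    result.kinetics = pd.DataFrame(
        kin_rows, columns=["track_id", "expansion_s", "retraction_s"]
    )

    delay_rows = []
    for trk in tracks:
        frames = trk.frames
        roi = _bleb_roi_polygon(trk, movie.pixel_size_um,
                                pad_um=2 * movie.pixel_size_um)
        window = np.arange(frames[0], frames[-1] + 1)
        try:
            trace = extract_trace(movie, roi, frames=window)
            est = estimate_delay(trace, threshold=config.delay_threshold)
            delay = est.delay_s
        except ValueError as exc:
            log.warning("delay skipped for bleb track %d: %s", trk.track_id, exc)
            delay = np.nan
        delay_rows.append({"bleb_id": trk.track_id, "delay_s": delay})
    result.delays = pd.DataFrame(delay_rows, columns=["bleb_id", "delay_s"])
    summary["bleb_stages"] = {
        "n_frames": movie.n_frames,
        "n_regions": n_regions,
        "n_bleb_tracks": len(tracks),
        "mean_delay_s": (float(np.nanmean(result.delays["delay_s"]))
                         if len(delay_rows) else None),
    }


def _run_track_stages(config: RunConfig, result: PipelineResult,
                      summary: dict) -> None:
    tracks = read_tracks(config.tracks_csv)
    n_in = len(tracks)
    kept = filter_tracks(tracks, config.min_track_length_um)
    log.info("track filter: %d in, %d kept (min path %.1f um)",
             n_in, len(kept), config.min_track_length_um)
    stats = [compute_track_stats(tr) for tr in kept]
    result.track_stats = pd.DataFrame(
        [
            {
                "track_id": s.track_id,
                "mean_speed_um_min": s.mean_speed_um_min,
                "path_length_um": s.path_length_um,
                "net_displacement_um": s.net_displacement_um,
                "confinement_ratio": s.confinement_ratio,
                "duration_s": s.duration_s,
            }
            for s in stats
        ],
        columns=["track_id", "mean_speed_um_min", "path_length_um",
                 "net_displacement_um", "confinement_ratio", "duration_s"],
    )
    summary["track_stages"] = {"n_tracks_in": n_in, "n_tracks_kept": len(kept)}
    if kept:
        msd = compute_msd(kept)
        result.msd = pd.DataFrame(
            {"lag_s": msd.lags_s, "msd_um2": msd.msd_um2, "n_pairs": msd.n_pairs}
        )
        est = fit_diffusion_coefficient(
            msd, d=config.msd_dimensionality,
            lag_fraction=config.msd_lag_fraction,
        )
        summary["diffusion"] = {
            "D_um2_min": est.D_um2_min,
            "slope_um2_s": est.slope_um2_s,
            "dimensionality": est.dimensionality,
            "lag_range_s": list(est.lag_range_s),
            "r_squared": est.r_squared,
            "clamped": est.clamped,
        }
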