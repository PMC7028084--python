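"""Per-track and population motility statistics for migrating T cells.

The unit of analysis is a :class:`Track`: a time-ordered sequence of 2D or 3D
positions (in micrometres) for one cell, typically exported from a tracking
package. From tracks we compute mean speed, confinement ratio, mean squared
displacement (MSD), a diffusion (motility) coefficient by linear regression of
the population MSD, a straightness z-score against an isotropic null, and
distances from an injection site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Track",
    "TrackStats",
    "MSDCurve",
    "DiffusionEstimate",
    "StraightnessZ",
    "filter_tracks",
    "compute_track_stats",
    "compute_msd",
    "fit_diffusion_coefficient",
    "straightness_zscore",
    "distance_from_injection_site",
]


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing timestamps (s) and
    positions (um), shape (n, d) with d in {2, 3}."""

    track_id: int | str
    t_s: np.ndarray
    pos_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        p = np.asarray(self.pos_um, dtype=float)
        if p.ndim != 2 or p.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        if t.shape != (p.shape[0],):
            raise ValueError("timestamps and positions disagree in length")
        if len(t) < 2:
            raise ValueError("a track needs at least two points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("non-finite coordinates in track")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "pos_um", p)

    @property
    def n_points(self) -> int:
        return self.pos_um.shape[0]

    @property
    def ndim(self) -> int:
        return self.pos_um.shape[1]

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.pos_um, axis=0), axis=1)

    def path_length(self) -> float:
        return float(self.step_lengths().sum())

    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.pos_um[-1] - self.pos_um[0]))

    def is_uniformly_sampled(self, rtol: float = 0.05) -> bool:
        dt = np.diff(self.t_s)
        return bool(np.all(np.abs(dt - dt.mean()) <= rtol * dt.mean()))


@dataclass(frozen=True)
class TrackStats:
    track_id: int | str
    mean_speed_um_min: float
    path_length_um: float
    net_displacement_um: float
    confinement_ratio: float
    duration_s: float


@dataclass(frozen=True)
class MSDCurve:
    """MSD versus time lag. ``scope`` is 'per-track' or 'population'."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    scope: str


@dataclass(frozen=True)
class DiffusionEstimate:
    D_um2_min: float
    slope_um2_s: float
    dimensionality: int
    lag_range_s: tuple[float, float]
    r_squared: float
    clamped: bool = False


@dataclass(frozen=True)
class StraightnessZ:
    straightness: float
    z_score: float
    null_mean: float
    null_sd: float
    n_null: int
    seed: int | None


def filter_tracks(
    tracks: Iterable[Track], min_track_length_um: float = 5.0
) -> list[Track]:
    """Drop tracks whose total path length is below ``min_track_length_um``.

    The 5 um default excludes essentially stationary (e.g. blebbing-in-place)
    cells from motility statistics.
    """
    kept = [tr for tr in tracks if tr.path_length() >= min_track_length_um]
    return kept


def compute_track_stats(track: Track) -> TrackStats:
    """Path length, net displacement, confinement ratio and mean speed.

    Confinement ratio = net displacement / path length (0 for a zero-length
    path). Mean speed = path length / duration, reported in um/min.
    """
    duration = track.duration_s
    if duration <= 0:
        raise ValueError("track duration must be positive")
    path = track.path_length()
    net = track.net_displacement()
    ratio = net / path if path > 0 else 0.0
    # guard against tiny float excess above 1 for perfectly straight tracks
    ratio = min(ratio, 1.0)
    return TrackStats(
        track_id=track.track_id,
        mean_speed_um_min=path / duration * 60.0,
        path_length_um=path,
        net_displacement_um=net,
        confinement_ratio=ratio,
        duration_s=duration,
    )


def _per_track_msd(track: Track, max_lag_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """MSD at integer frame lags 1..max_lag using all overlapping start points."""
    n = track.n_points
    msd = np.full(max_lag_frames, np.nan)
    npairs = np.zeros(max_lag_frames, dtype=int)
    for lag in range(1, max_lag_frames + 1):
        if lag >= n:
            break
        disp = track.pos_um[lag:] - track.pos_um[:-lag]
        sq = np.einsum("ij,ij->i", disp, disp)
        msd[lag - 1] = sq.mean()
        npairs[lag - 1] = sq.size
    return msd, npairs


def compute_msd(
    tracks: Sequence[Track] | Track, max_lag_frames: int | None = None
) -> MSDCurve:
    """Population (or single-track) MSD curve at uniform frame lags.

    Per-track MSD averages the squared displacement over every overlapping
    pair of frames for each lag; the population MSD is the unweighted mean of
    the per-track MSDs at each lag, excluding tracks too short to reach it.
    Requires (near-)uniform sampling; the lag axis is in seconds using the
    median frame interval across tracks.
    """
    if isinstance(tracks, Track):
        tracks = [tracks]
    if not tracks:
        raise ValueError("no tracks given")
    dts = []
    for tr in tracks:
        if not tr.is_uniformly_sampled():
            raise ValueError(f"track {tr.track_id} is not uniformly sampled")
        dts.append(np.median(np.diff(tr.t_s)))
    dt = float(np.median(dts))
    longest = max(tr.n_points for tr in tracks)
    if max_lag_frames is None:
        max_lag_frames = longest - 1
    max_lag_frames = min(max_lag_frames, longest - 1)

    per = np.vstack([_per_track_msd(tr, max_lag_frames)[0] for tr in tracks])
    pairs = np.vstack([_per_track_msd(tr, max_lag_frames)[1] for tr in tracks])
    with np.errstate(invalid="ignore"):
        pop = np.nanmean(per, axis=0)
    scope = "population" if len(tracks) > 1 else "per-track"
    valid = ~np.isnan(pop)
    lags = (np.arange(1, max_lag_frames + 1) * dt)[valid]
    return MSDCurve(
        lags_s=lags,
        msd_um2=pop[valid],
        n_pairs=pairs.sum(axis=0)[valid],
        scope=scope,
    )


def fit_diffusion_coefficient(
    msd: MSDCurve, d: int = 3, lag_fraction: float = 0.25
) -> DiffusionEstimate:
    """Diffusion coefficient from a short-lag linear fit of the MSD.

    Fits a least-squares line through the origin, MSD = slope * lag, over lags
    up to ``lag_fraction`` of the maximum observed lag (short lags carry the
    least statistical noise). For simple diffusion in ``d`` dimensions the
    slope is 2*d*D, so D = slope / (2 d), converted to um^2/min.
    """
    if d not in (2, 3):
        raise ValueError("dimensionality must be 2 or 3")
    cutoff = lag_fraction * msd.lags_s.max()
    sel = msd.lags_s <= cutoff
    if sel.sum() < 3:
        sel = np.zeros_like(sel)
        sel[: min(3, len(sel))] = True
    x = msd.lags_s[sel]
    y = msd.msd_um2[sel]
    if np.allclose(y, 0.0):
        return DiffusionEstimate(0.0, 0.0, d, (float(x[0]), float(x[-1])), 1.0, True)
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    ss_tot = float(np.dot(y, y))  # through-origin R^2: share of sum-of-squares
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    clamped = slope < 0
    slope_rep = max(slope, 0.0)
    D = slope_rep / (2.0 * d) * 60.0
    return DiffusionEstimate(D, slope_rep, d, (float(x[0]), float(x[-1])), r2, clamped)


def straightness_zscore(
    track: Track, n_null: int = 1000, seed: int | None = None
) -> StraightnessZ:
    """Z-score of the track's straightness against an isotropic null.

    Straightness S = net displacement / path length. The null model preserves
    the observed step lengths and redraws each step's direction uniformly at
    random (on the circle in 2D, the sphere in 3D); z = (S - mean_null)/sd_null.
    """
    if track.n_points < 3:
        raise ValueError("need at least 3 points for a straightness z-score")
    steps = track.step_lengths()
    path = steps.sum()
    if path <= 0:
        raise ValueError("zero path length: straightness undefined")
    S = min(track.net_displacement() / path, 1.0)

    rng = np.random.default_rng(seed)
    d = track.ndim
    n_steps = steps.size
    dirs = rng.standard_normal((n_null, n_steps, d))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    net = np.linalg.norm((dirs * steps[None, :, None]).sum(axis=1), axis=1)
    null_S = net / path
    mu, sd = float(null_S.mean()), float(null_S.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null distribution (sd 0)")
    return StraightnessZ(S, (S - mu) / sd, mu, sd, n_null, seed)


def distance_from_injection_site(
    points_px: np.ndarray, origin_px: Sequence[float], pixel_size_um: float
) -> np.ndarray:
    """Planar Euclidean distance (um) of each point from an injection site.

    Both points and origin are in pixel coordinates; the distance in pixels is
    scaled by the pixel size. Only x and y are used even if z is present.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size must be positive")
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))[:, :2]
    org = np.asarray(origin_px, dtype=float)[:2]
    return np.linalg.norm(pts - org, axis=1) * pixel_size_um
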