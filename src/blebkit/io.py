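"""Readers and writers for the package's on-disk formats.

Movies travel as multi-page TIFF (channel-interleaved, membrane then actin,
uint16) with a JSON metadata sidecar carrying the physical calibration; track
tables are plain CSV with the canonical header
``track_id,frame,t_s,x_um,y_um,z_um``. Alternative column layouts (e.g.
tracking-software exports) are accepted through a column map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .motility import Track

__all__ = [
    "LabeledMovie",
    "read_movie",
    "write_movie",
    "read_tracks",
    "write_tracks",
]

REQUIRED_META = ("pixel_size_um", "frame_interval_s", "z_steps_per_frame",
                 "channel_names")
TRACK_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um", "z_um")


@dataclass
class LabeledMovie:
    """Two-channel calibrated pixel grid over time.

    ``pixels`` has shape (T, C=2, H, W); ``timestamps_s`` gives each plane's
    acquisition time (strictly increasing). Channel roles come from
    ``channel_names`` and are never guessed from pixel content.
    """

    pixels: np.ndarray
    pixel_size_um: float
    timestamps_s: np.ndarray
    channel_names: tuple[str, str] = ("membrane", "actin")
    frame_interval_s: float | None = None
    z_steps_per_frame: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must have shape (T, 2, H, W)")
        if self.timestamps_s.shape != (self.pixels.shape[0],):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps_s) > 1 and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.pixels[:, idx]


def write_movie(movie: LabeledMovie, path_tiff: str | Path,
                path_json: str | Path) -> None:
    """Write the movie as channel-interleaved multipage TIFF plus JSON sidecar."""
    T, C, H, W = movie.pixels.shape
    pages = movie.pixels.reshape(T * C, H, W)
    tifffile.imwrite(path_tiff, pages, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "z_steps_per_frame": movie.z_steps_per_frame,
        "channel_names": list(movie.channel_names),
        "timestamps_s": movie.timestamps_s.tolist(),
        "n_frames": T,
    }
    Path(path_json).write_text(json.dumps(meta, indent=1))


def read_movie(path_tiff: str | Path, path_json: str | Path) -> LabeledMovie:
    """Read a movie written by :func:`write_movie`; validates calibration."""
    meta = json.loads(Path(path_json).read_text())
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"metadata sidecar missing keys: {missing}")
    pages = tifffile.imread(path_tiff)
    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(meta["channel_names"])
    if n_channels != 2:
        raise ValueError("exactly two channels (membrane, actin) expected")
    if pages.shape[0] % n_channels:
        raise ValueError(
            f"{pages.shape[0]} TIFF pages not divisible by {n_channels} channels"
        )
    T = pages.shape[0] // n_channels
    pixels = pages.reshape(T, n_channels, *pages.shape[1:])
    if "timestamps_s" in meta:
        ts = np.asarray(meta["timestamps_s"], dtype=float)
        if ts.shape != (T,):
            raise ValueError("timestamps in sidecar do not match frame count")
    else:
        ts = np.arange(T) * (meta["frame_interval_s"] / meta["z_steps_per_frame"])
    return LabeledMovie(
        pixels=pixels,
        pixel_size_um=float(meta["pixel_size_um"]),
        timestamps_s=ts,
        channel_names=tuple(meta["channel_names"]),
        frame_interval_s=meta["frame_interval_s"],
        z_steps_per_frame=int(meta["z_steps_per_frame"]),
    )


def write_tracks(tracks: list[Track], path_csv: str | Path) -> None:
    rows = []
    for tr in tracks:
        pos = tr.pos_um
        z = pos[:, 2] if pos.shape[1] == 3 else np.zeros(len(pos))
        for k in range(len(pos)):
            rows.append(
                (tr.track_id, k, tr.t_s[k], pos[k, 0], pos[k, 1], z[k])
            )
    pd.DataFrame(rows, columns=list(TRACK_COLUMNS)).to_csv(path_csv, index=False)


def read_tracks(
    path_csv: str | Path, column_map: dict[str, str] | None = None
) -> list[Track]:
    """Parse a track CSV into :class:`Track` objects.

    ``column_map`` renames source columns to the canonical names, e.g.
    ``{"TrackID": "track_id", "Time": "t_s", "Position X": "x_um", ...}`` for
    tracking-software exports. Rows are grouped by id and sorted by time;
    duplicate (id, t) rows are rejected. A ``z_um`` column is optional (tracks
    are 2D without it).
    """
    df = pd.read_csv(path_csv)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"track_id", "t_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    has_z = "z_um" in df.columns
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicate timestamps in track {tid}")
        cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
        tracks.append(Track(track_id=tid, t_s=t, pos_um=grp[cols].to_numpy(float)))
    return tracks
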