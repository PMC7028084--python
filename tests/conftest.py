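import numpy as np
import pytest

from blebkit.morphometry import detect_blebs, segment_cell, track_blebs
from blebkit.simulate import MovieSimConfig, render_bleb_movie


@pytest.fixture(scope="session")
def default_fixture():
    """Noise-free default blebbing-cell movie plus its ground truth."""
    cfg = MovieSimConfig()
    movie, gt = render_bleb_movie(cfg)
    return cfg, movie, gt


@pytest.fixture(scope="session")
def default_detections(default_fixture):
    """Per-frame bleb detections on the default fixture (default params)."""
    cfg, movie, gt = default_fixture
    membrane = movie.channel("membrane")
    actin = movie.channel("actin")
    regions_by_frame = []
    for k in range(movie.n_frames):
        cm = segment_cell(membrane[k], cfg.pixel_size_um, frame_index=k)
        regions_by_frame.append(detect_blebs(membrane[k], actin[k], cm))
    return regions_by_frame


@pytest.fixture(scope="session")
def default_bleb_tracks(default_detections):
    return track_blebs(default_detections)


@pytest.fixture(scope="session")
def single_bleb_fixture():
    """Single-bleb movie at 5 s frame interval for kinetics recovery."""
    cfg = MovieSimConfig(n_blebs=1, frame_interval_s=5.0, n_frames=14,
                         noise_sd=0.0, seed=0)
    return cfg, *render_bleb_movie(cfg)


@pytest.fixture(scope="session")
def delay_fixture():
    """Single-bleb movie sampled every 0.65 s for delay recovery.

    Finer 0.15 um pixels keep the rasterization staircase of the small bleb's
    pixel count well below the half-sample timing tolerance.
    """
    cfg = MovieSimConfig(n_blebs=1, frame_interval_s=0.65,
                         z_steps_per_frame=1, n_frames=40, noise_sd=0.0,
                         seed=0, pixel_size_um=0.15, image_shape=(192, 192))
    return cfg, *render_bleb_movie(cfg)


def bleb_roi_polygon(gt_bleb, pixel_size_um, pad_px=1):
    """Rectangle ROI (um) around the union of a ground-truth bleb's masks."""
    union = gt_bleb.masks.any(axis=0)
    rr, cc = np.nonzero(union)
    x0 = (cc.min() - pad_px + 0.5) * pixel_size_um
    x1 = (cc.max() + pad_px + 0.5) * pixel_size_um
    y0 = (rr.min() - pad_px + 0.5) * pixel_size_um
    y1 = (rr.max() + pad_px + 0.5) * pixel_size_um
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
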