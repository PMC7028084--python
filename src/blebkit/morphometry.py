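"""Cell and bleb segmentation, shape features, bleb tracking and kinetics.

A cell is segmented from the membrane channel as the largest Otsu-foreground
component. Blebs are found with an actin-void peripheral-protrusion operator:
geometric protrusions (the cell mask minus its morphological opening) that
touch the cell boundary and whose mean actin intensity falls below a quantile
of the cortical-rim actin distribution. Detected regions are linked through
time by greedy nearest-centroid matching and each linked bleb's expansion and
retraction durations are read off its area-versus-time profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CellMask",
    "AspectRatio",
    "BlebRegion",
    "BlebTrack",
    "BlebDetectionParams",
    "EmptySegmentationError",
    "max_intensity_projection",
    "segment_cell",
    "aspect_ratio",
    "detect_blebs",
    "track_blebs",
    "bleb_kinetics",
    "bleb_summary",
    "bleb_overlay",
]


class EmptySegmentationError(ValueError):
    """No foreground object found in the frame."""


@dataclass
class CellMask:
    frame_index: int
    mask: np.ndarray               # bool HxW
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptySegmentationError("empty cell mask")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @property
    def centroid_um(self) -> tuple[float, float]:
        """(x, y) centroid at pixel centers."""
        rr, cc = np.nonzero(self.mask)
        px = self.pixel_size_um
        return (float((cc + 0.5).mean() * px), float((rr + 0.5).mean() * px))


@dataclass(frozen=True)
class AspectRatio:
    major_axis_um: float
    minor_axis_um: float

    @property
    def ratio(self) -> float:
        return self.major_axis_um / self.minor_axis_um


@dataclass
class BlebRegion:
    """One bleb's footprint and shape features in a single frame."""

    frame_index: int
    mask: np.ndarray
    centroid_um: tuple[float, float]
    area_um2: float
    area_fraction_pct: float
    major_axis_diameter_um: float
    leading_edge: bool
    mean_actin: float


@dataclass
class BlebTrack:
    track_id: int
    regions: list[BlebRegion]

    @property
    def frames(self) -> list[int]:
        return [r.frame_index for r in self.regions]

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([r.area_um2 for r in self.regions])


class BlebDetectionParams(BaseModel):
    """Tunables of the bleb detector.

    ``opening_radius_um`` must exceed the expected bleb radius so the
    morphological opening removes bleb bumps from the cell outline;
    ``actin_void_quantile`` sets the actin-void cutoff as a quantile of the
    cortical-rim actin intensity distribution.
    """

    model_config = {"extra": "forbid", "frozen": True}

    actin_void_quantile: float = Field(0.5, gt=0, le=1)
    min_area_um2: float = Field(0.5, ge=0)
    max_area_fraction: float = Field(0.25, gt=0, le=1)
    rim_width_px: int = Field(2, ge=1)
    opening_radius_um: float = Field(2.5, gt=0)
    leading_edge_halfangle_deg: float = Field(60.0, gt=0, le=180)


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z-planes (first axis); channels preserved.

    Accepts (Z, H, W) or (Z, C, H, W); a list of planes is stacked first and
    mismatched plane shapes raise.
    """
    try:
        arr = np.asarray(stack)
        if arr.dtype == object:
            raise ValueError
    except ValueError as exc:
        raise ValueError("planes have mismatched shapes") from exc
    if arr.ndim not in (3, 4):
        raise ValueError("expected a (Z, H, W) or (Z, C, H, W) stack")
    return arr.max(axis=0)


def segment_cell(
    frame: np.ndarray,
    pixel_size_um: float,
    frame_index: int = 0,
    method: str = "otsu",
    min_area_um2: float = 5.0,
) -> CellMask:
    """Segment the cell from one (membrane-channel) frame.

    Otsu-thresholds the frame, keeps the largest connected component above
    ``min_area_um2`` and fills its holes.
    """
    frame = np.asarray(frame, dtype=float)
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    if np.ptp(frame) == 0:
        raise EmptySegmentationError("blank frame: no foreground to segment")
    fg = frame > threshold_otsu(frame)
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise EmptySegmentationError("no foreground component found")
    min_px = min_area_um2 / pixel_size_um**2
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_px:
        raise EmptySegmentationError("largest component below minimum area")
    mask = ndimage.binary_fill_holes(labels == best)
    return CellMask(frame_index=frame_index, mask=mask, pixel_size_um=pixel_size_um)


def aspect_ratio(mask: CellMask | np.ndarray, pixel_size_um: float | None = None) -> AspectRatio:
    """Major/minor axis ratio of the second-moment-equivalent ellipse.

    The ellipse with the same normalized second central moments as the binary
    mask; rotation invariant up to rasterization.
    """
    if isinstance(mask, CellMask):
        arr, px = mask.mask, mask.pixel_size_um
    else:
        arr = np.asarray(mask, dtype=bool)
        px = 1.0 if pixel_size_um is None else pixel_size_um
    if not arr.any():
        raise EmptySegmentationError("empty mask")
    props = measure.regionprops(arr.astype(np.uint8))[0]
    minor = props.axis_minor_length * px
    major = props.axis_major_length * px
    if minor <= 0:
        raise ValueError("degenerate (line-like) mask: minor axis is zero")
    return AspectRatio(major_axis_um=major, minor_axis_um=minor)


def _cortical_rim_values(
    actin: np.ndarray, body: np.ndarray, rim_width_px: int
) -> np.ndarray:
    inner = ndimage.binary_erosion(body, morphology.disk(rim_width_px))
    rim = body & ~inner
    return actin[rim]


def detect_blebs(
    membrane: np.ndarray,
    actin: np.ndarray,
    cell_mask: CellMask,
    params: BlebDetectionParams | None = None,
    heading_deg: float = 0.0,
    frame_index: int | None = None,
) -> list[BlebRegion]:
    """Detect actin-void peripheral protrusions (blebs) in one frame.

    Candidates are connected components of the cell mask minus its
    morphological opening, restricted to components touching the cell
    boundary with area between ``min_area_um2`` and ``max_area_fraction`` of
    the cell; a candidate qualifies as a bleb when its mean actin intensity
    lies below the ``actin_void_quantile`` quantile of the cortical-rim actin
    distribution. ``leading_edge`` is set when the direction from the cell
    centroid to the bleb centroid lies within the leading-edge cone around
    ``heading_deg``.
    """
    p = params or BlebDetectionParams()
    px = cell_mask.pixel_size_um
    mask = cell_mask.mask
    if frame_index is None:
        frame_index = cell_mask.frame_index
    open_r = max(1, round(p.opening_radius_um / px))
    body = ndimage.binary_opening(mask, morphology.disk(open_r))
    labels = measure.label(body, connectivity=2)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())[1:]
        body = labels == (int(np.argmax(sizes)) + 1)
    else:
        body = mask
    protrusions = mask & ~body
    rim_vals = _cortical_rim_values(np.asarray(actin, float), body, p.rim_width_px)
    cutoff = float(np.quantile(rim_vals, p.actin_void_quantile)) if rim_vals.size else np.inf

    boundary = mask & ~ndimage.binary_erosion(mask)
    cell_area = cell_mask.area_um2
    ccx, ccy = cell_mask.centroid_um
    heading = math.radians(heading_deg)
    out: list[BlebRegion] = []
    for region in measure.regionprops(measure.label(protrusions, connectivity=2)):
        region_mask = np.zeros_like(mask)
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        region_mask[rr, cc] = True
        area = region.area * px**2
        if area < p.min_area_um2 or area > p.max_area_fraction * cell_area:
            continue
        if not (region_mask & boundary).any():
            continue
        mean_act = float(np.asarray(actin, float)[region_mask].mean())
        if mean_act >= cutoff:
            continue
        cx = float((cc + 0.5).mean() * px)
        cy = float((rr + 0.5).mean() * px)
        ang = math.atan2(cy - ccy, cx - ccx)
        dang = math.atan2(math.sin(ang - heading), math.cos(ang - heading))
        leading = abs(math.degrees(dang)) <= p.leading_edge_halfangle_deg
        out.append(
            BlebRegion(
                frame_index=frame_index,
                mask=region_mask,
                centroid_um=(cx, cy),
                area_um2=area,
                area_fraction_pct=100.0 * area / cell_area,
                major_axis_diameter_um=region.axis_major_length * px,
                leading_edge=leading,
                mean_actin=mean_act,
            )
        )
    return out


def track_blebs(
    regions_by_frame: list[list[BlebRegion]], max_link_dist_um: float = 2.0
) -> list[BlebTrack]:
    """Link per-frame bleb regions into tracks by greedy nearest-centroid.

    Consecutive frame pairs are linked one-to-one in order of increasing
    centroid distance (up to ``max_link_dist_um``); unlinked regions start new
    tracks and a track ends when no region matches in the next frame.
    """
    tracks: list[BlebTrack] = []
    open_tracks: list[BlebTrack] = []
    next_id = 0
    for regions in regions_by_frame:
        assignments: dict[int, int] = {}
        if open_tracks and regions:
            cand = []
            for ti, trk in enumerate(open_tracks):
                hx, hy = trk.regions[-1].centroid_um
                for ri, reg in enumerate(regions):
                    d = math.hypot(reg.centroid_um[0] - hx, reg.centroid_um[1] - hy)
                    if d <= max_link_dist_um:
                        cand.append((d, ti, ri))
            used_t: set[int] = set()
            used_r: set[int] = set()
            for d, ti, ri in sorted(cand):
                if ti in used_t or ri in used_r:
                    continue
                assignments[ri] = ti
                used_t.add(ti)
                used_r.add(ri)
        still_open: list[BlebTrack] = []
        for ri, reg in enumerate(regions):
            if ri in assignments:
                trk = open_tracks[assignments[ri]]
                trk.regions.append(reg)
            else:
                trk = BlebTrack(track_id=next_id, regions=[reg])
                next_id += 1
                tracks.append(trk)
            still_open.append(trk)
        open_tracks = still_open
    return tracks


def bleb_kinetics(
    track: BlebTrack, timestamps_s: np.ndarray
) -> tuple[float, float]:
    """Expansion and retraction durations (s) from a bleb's area profile.

    Expansion runs from the track's first frame to the first frame of maximal
    area; retraction from the last frame of maximal area to the track's last
    frame. Plateau frames at maximal area belong to neither phase. A
    single-frame track has both durations zero.
    """
    ts = np.asarray(timestamps_s, dtype=float)
    frames = track.frames
    if len(frames) < 2:
        return 0.0, 0.0
    areas = track.areas_um2
    amax = areas.max()
    at_max = np.isclose(areas, amax, rtol=1e-9)
    first_max = int(np.argmax(at_max))
    last_max = len(areas) - 1 - int(np.argmax(at_max[::-1]))
    expansion = float(ts[frames[first_max]] - ts[frames[0]])
    retraction = float(ts[frames[-1]] - ts[frames[last_max]])
    return expansion, retraction


def bleb_summary(
    tracks: list[BlebTrack],
    timestamps_s: np.ndarray,
):
    """Tidy per-region table over all bleb tracks.

    Columns: track_id, frame, t_s, centroid_x_um, centroid_y_um, area_um2,
    area_fraction_pct, diameter_um, leading_edge. Empty input yields an empty
    table with the same columns.
    """
    import pandas as pd

    ts = np.asarray(timestamps_s, dtype=float)
    rows = []
    for trk in tracks:
        for reg in trk.regions:
            rows.append(
                {
                    "track_id": trk.track_id,
                    "frame": reg.frame_index,
                    "t_s": ts[reg.frame_index],
                    "centroid_x_um": reg.centroid_um[0],
                    "centroid_y_um": reg.centroid_um[1],
                    "area_um2": reg.area_um2,
                    "area_fraction_pct": reg.area_fraction_pct,
                    "diameter_um": reg.major_axis_diameter_um,
                    "leading_edge": reg.leading_edge,
                }
            )
    cols = ["track_id", "frame", "t_s", "centroid_x_um", "centroid_y_um",
            "area_um2", "area_fraction_pct", "diameter_um", "leading_edge"]
    return pd.DataFrame(rows, columns=cols)


def bleb_overlay(cell_masks: list[CellMask], tracks: list[BlebTrack]):
    """Overlay figure: cell outline colored by time plus '+' bleb centers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm

    fig, ax = plt.subplots(figsize=(5, 5))
    n = max(len(cell_masks), 1)
    cmap = cm.get_cmap("hot")
    for i, cm_ in enumerate(cell_masks):
        for contour in measure.find_contours(cm_.mask.astype(float), 0.5):
            px = cm_.pixel_size_um
            ax.plot((contour[:, 1] + 0.5) * px, (contour[:, 0] + 0.5) * px,
                    color=cmap(i / n), linewidth=0.8)
    for trk in tracks:
        for reg in trk.regions:
            ax.plot(*reg.centroid_um, marker="+", color="k", markersize=6)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return fig
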