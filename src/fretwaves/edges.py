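"""Cell-edge detection, section classification and montage construction.

Edge positions are measured along the central line of a rectangular region
of interest oriented along the outward normal of the local cell edge.  For
each frame the scan walks from outside the cell inward and takes the
outermost defined-to-undefined transition of the ratio image, with linear
sub-pixel interpolation between the bounding samples.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .correction import RatioMovie

__all__ = [
    "RegionOfInterest",
    "EdgeTrace",
    "Montage",
    "detect_edge",
    "classify_sections",
    "build_montage",
    "load_rois",
    "save_rois",
    "save_traces_csv",
    "rect_region_mask",
    "square_region_mask",
]

CLASS_LABELS = ("stalling", "protruding", "retracting")


@dataclass(frozen=True)
class RegionOfInterest:
    """A rectangle (edge scan) or square (activity trace) ROI in micrometres.

    For rectangles, ``orientation`` (degrees) is the outward edge normal and
    the length axis (default 20 um) is the scan axis; width is the tangential
    extent (default 10 um).  Squares are axis-aligned with ``area`` um^2.
    """

    id: str
    kind: str  # "rectangle" | "square"
    center: tuple[float, float]  # um (x, y)
    orientation: float = 0.0  # deg
    width: float = 10.0  # um
    length: float = 20.0  # um
    area: float = 4.0  # um^2, squares only

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "square"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))

    @property
    def side(self) -> float:
        """Side length of a square ROI (um)."""
        return math.sqrt(self.area)

    @property
    def normal(self) -> tuple[float, float]:
        a = math.radians(self.orientation)
        return (math.cos(a), math.sin(a))


@dataclass
class EdgeTrace:
    """Per-frame edge position along an ROI central line."""

    roi_id: str
    times: np.ndarray  # s
    position_um: np.ndarray  # signed along scan axis, positive outward; NaN = missing
    displacement_um: np.ndarray = field(init=False)
    velocity_um_s: np.ndarray = field(init=False)
    label: str | None = None
    smooth_frames: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)
        if self.times.shape != self.position_um.shape:
            raise ValueError("times and positions must align")
        ref = self.position_um[np.isfinite(self.position_um)]
        ref0 = ref[0] if ref.size else np.nan
        self.displacement_um = self.position_um - ref0
        self.velocity_um_s = self._velocity()

    def _velocity(self) -> np.ndarray:
        """Central-difference velocity on a smoothed position trace."""
        pos = self.position_um
        if pos.size < 2:
            return np.full_like(pos, np.nan)
        valid = np.isfinite(pos)
        filled = pos.copy()
        if valid.any() and not valid.all():
            filled[~valid] = np.interp(
                self.times[~valid], self.times[valid], pos[valid]
            )
        win = max(1, min(self.smooth_frames, pos.size))
        smooth = ndimage.uniform_filter1d(filled, size=win, mode="nearest")
        vel = np.gradient(smooth, self.times)
        vel[~valid] = np.nan
        return vel

    @property
    def span_s(self) -> float:
        valid = np.isfinite(self.position_um)
        if valid.sum() < 2:
            return 0.0
        t = self.times[valid]
        return float(t[-1] - t[0])

    @property
    def mean_velocity(self) -> float:
        """Least-squares slope of position vs time over valid frames (um/s)."""
        valid = np.isfinite(self.position_um)
        if valid.sum() < 2:
            return float("nan")
        slope = np.polyfit(self.times[valid], self.position_um[valid], 1)[0]
        return float(slope)


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------


def _sample_along_line(
    frame: np.ndarray, roi: RegionOfInterest, pixel_size: float, step_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples of ``frame`` along the ROI central scan line.

    Returns (signed coordinates along the outward normal, sampled values);
    out-of-grid samples read as 0 (undefined).
    """
    nx, ny = roi.normal
    half = roi.length / 2.0
    s = np.arange(-half, half + step_um / 2, step_um)
    px = (roi.center[0] + s * nx) / pixel_size
    py = (roi.center[1] + s * ny) / pixel_size
    vals = ndimage.map_coordinates(
        frame, np.vstack([py, px]), order=1, mode="constant", cval=0.0
    )
    return s, vals


def detect_edge(
    ratio: RatioMovie,
    roi: RegionOfInterest,
    step_frac: float = 0.25,
    max_missing_frac: float = 0.2,
    smooth_frames: int = 5,
) -> EdgeTrace:
    """Edge position per frame along the ROI central line (um, + outward).

    The defined-pixel indicator of the ratio movie is sampled along the scan
    line; scanning from the outward end inward, the outermost 0.5-crossing
    (undefined -> defined) is the edge, located by linear interpolation
    between the two bounding samples.  Raises if more than
    ``max_missing_frac`` of frames have no crossing, suggesting the ROI be
    re-placed.
    """
    if roi.kind != "rectangle":
        raise ValueError("edge detection requires a rectangle ROI")
    step = step_frac * ratio.pixel_size
    defined = ratio.defined.astype(np.float32)
    T = ratio.n_frames
    pos = np.full(T, np.nan)
    for t in range(T):
        s, vals = _sample_along_line(defined[t], roi, ratio.pixel_size, step)
        inside = vals >= 0.5
        # scanning inward from the outward end, the edge is the outermost
        # inside -> outside flip
        flips = np.nonzero(inside[:-1] & ~inside[1:])[0]
        if flips.size == 0:
            if inside.all():
                pos[t] = s[-1]  # cell fills the scan line
            continue
        crossing = int(flips[-1]) + 1
        v_in, v_out = vals[crossing - 1], vals[crossing]
        frac = (v_in - 0.5) / (v_in - v_out) if v_in != v_out else 0.5
        pos[t] = s[crossing - 1] + frac * (s[crossing] - s[crossing - 1])
    missing = np.isnan(pos).mean()
    if missing > max_missing_frac:
        raise ValueError(
            f"no edge crossing on {missing:.0%} of frames for ROI {roi.id!r}; "
            "re-place the ROI across the cell edge"
        )
    return EdgeTrace(
        roi_id=roi.id,
        times=ratio.times,
        position_um=pos,
        smooth_frames=smooth_frames,
    )


def classify_sections(
    traces: dict[str, EdgeTrace] | list[EdgeTrace],
    v0: float = 0.005,
    min_span_s: float = 60.0,
) -> dict[str, str]:
    """Label each edge trace stalling / protruding / retracting.

    The mean velocity is the least-squares slope of position vs time;
    ``|v| <= v0`` is stalling, above protruding, below retracting.  Traces
    spanning less than ``min_span_s`` are labelled ``"unclassified"``.
    """
    if isinstance(traces, dict):
        traces = list(traces.values())
    labels: dict[str, str] = {}
    for tr in traces:
        if tr.span_s < min_span_s:
            labels[tr.roi_id] = "unclassified"
        else:
            v = tr.mean_velocity
            if v > v0:
                labels[tr.roi_id] = "protruding"
            elif v < -v0:
                labels[tr.roi_id] = "retracting"
            else:
                labels[tr.roi_id] = "stalling"
        tr.label = labels[tr.roi_id]
    return labels


# ---------------------------------------------------------------------------
# region rasterization helpers
# ---------------------------------------------------------------------------


def rect_region_mask(
    shape: tuple[int, int], roi: RegionOfInterest, pixel_size: float
) -> np.ndarray:
    """Boolean pixel mask of a rotated rectangle ROI."""
    h, w = shape
    x = np.arange(w)[None, :] * pixel_size - roi.center[0]
    y = np.arange(h)[:, None] * pixel_size - roi.center[1]
    nx, ny = roi.normal
    along = x * nx + y * ny
    across = -x * ny + y * nx
    return (np.abs(along) <= roi.length / 2) & (np.abs(across) <= roi.width / 2)


def square_region_mask(
    shape: tuple[int, int], roi: RegionOfInterest, pixel_size: float
) -> np.ndarray:
    """Boolean pixel mask of an axis-aligned square ROI."""
    h, w = shape
    half = roi.side / 2
    x = np.arange(w)[None, :] * pixel_size
    y = np.arange(h)[:, None] * pixel_size
    return (np.abs(x - roi.center[0]) <= half) & (np.abs(y - roi.center[1]) <= half)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------


@dataclass
class Montage:
    """Tiled ROI crops at regular time intervals on a shared intensity scale."""

    image: np.ndarray  # (W_px, n_tiles * L_px) float, NaN = undefined
    tiles: list
    times: list  # s, one per tile
    vmin: float
    vmax: float


def build_montage(
    ratio: RatioMovie, roi: RegionOfInterest, interval_s: float
) -> Montage:
    """Crop the ROI at t = 0, interval, 2*interval, ... and tile left-to-right.

    Tiles share one intensity scale (no per-tile rescaling); undefined pixels
    stay NaN so renderers can map them to a reserved color.  ``interval_s``
    must be a multiple of the frame interval.
    """
    ratio_dt = ratio.frame_interval
    if interval_s <= 0 or abs(interval_s / ratio_dt - round(interval_s / ratio_dt)) > 1e-9:
        raise ValueError("montage interval must be a positive multiple of the frame interval")
    stride = int(round(interval_s / ratio_dt))
    frame_idx = list(range(0, ratio.n_frames, stride))

    nx, ny = roi.normal
    tx, ty = -ny, nx
    px = ratio.pixel_size
    n_l = max(int(round(roi.length / px)), 1)
    n_w = max(int(round(roi.width / px)), 1)
    l_coords = (np.arange(n_l) - (n_l - 1) / 2) * px
    w_coords = (np.arange(n_w) - (n_w - 1) / 2) * px
    xs = roi.center[0] + l_coords[None, :] * nx + w_coords[:, None] * tx
    ys = roi.center[1] + l_coords[None, :] * ny + w_coords[:, None] * ty
    coords = np.vstack([(ys / px).ravel(), (xs / px).ravel()])

    tiles = []
    for i in frame_idx:
        tile = ndimage.map_coordinates(
            ratio.data[i], coords, order=1, mode="constant", cval=np.nan
        ).reshape(n_w, n_l)
        tiles.append(tile.astype(np.float32))
    image = np.hstack(tiles) if tiles else np.empty((n_w, 0), dtype=np.float32)
    finite = image[np.isfinite(image)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    return Montage(
        image=image,
        tiles=tiles,
        times=[i * ratio_dt for i in frame_idx],
        vmin=vmin,
        vmax=vmax,
    )


def save_montage_png(montage: Montage, path: str | Path, cmap: str = "viridis") -> Path:
    """Render a montage to PNG; undefined pixels use a reserved gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.3")
    fig, ax = plt.subplots(figsize=(max(montage.image.shape[1] / 40, 2), 2))
    im = ax.imshow(montage.image, cmap=cm, vmin=montage.vmin, vmax=montage.vmax)
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, fraction=0.03)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# ROI + trace I/O
# ---------------------------------------------------------------------------

_ROI_FIELDS = ["id", "kind", "center_x_um", "center_y_um", "orientation_deg", "width_um", "length_um", "area_um2"]


def save_rois(rois: list[RegionOfInterest], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ROI_FIELDS)
        for r in rois:
            writer.writerow(
                [r.id, r.kind, r.center[0], r.center[1], r.orientation, r.width, r.length, r.area]
            )
    return path


def load_rois(path: str | Path) -> list[RegionOfInterest]:
    rois = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rois.append(
                RegionOfInterest(
                    id=row["id"],
                    kind=row["kind"],
                    center=(float(row["center_x_um"]), float(row["center_y_um"])),
                    orientation=float(row.get("orientation_deg") or 0.0),
                    width=float(row.get("width_um") or 10.0),
                    length=float(row.get("length_um") or 20.0),
                    area=float(row.get("area_um2") or 4.0),
                )
            )
    return rois


def save_traces_csv(traces: list[EdgeTrace], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["roi_id", "frame", "time_s", "position_um", "displacement_um", "velocity_um_s", "class"]
        )
        for tr in traces:
            for i, t in enumerate(tr.times):
                writer.writerow(
                    [
                        tr.roi_id,
                        i,
                        t,
                        tr.position_um[i],
                        tr.displacement_um[i],
                        tr.velocity_um_s[i],
                        tr.label or "",
                    ]
                )
    return path
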