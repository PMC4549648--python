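"""Forward simulator for two-channel sensitized-emission FRET movies.

Generates a circular cell whose edge sections protrude or retract on a
prescribed velocity schedule, carrying a dimensionless activity field
(baseline + hotspots + traveling cosine wave + stimulus ramp + per-section
edge bands), and renders donor and raw-acceptor channels through a nuisance
model: multiplicative shading, additive background, donor->acceptor spectral
bleedthrough, mono-exponential photobleaching, Poisson-Gaussian noise and
16-bit quantization.  A ground-truth sidecar records everything needed to
score parameter recovery.

Coordinates: pixel ``(row, col)`` sits at physical position
``(x, y) = (col * pixel_size, row * pixel_size)`` micrometres.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from skimage.draw import polygon2mask

from .stacks import ChannelStack, write_stack

__all__ = [
    "CellGeometrySpec",
    "EdgeScheduleItem",
    "HotspotSpec",
    "WaveSpec",
    "EdgeBandSpec",
    "StimulusSpec",
    "NuisanceSpec",
    "ActivitySpec",
    "ScenarioConfig",
    "Geometry",
    "GroundTruth",
    "simulate_geometry",
    "simulate_activity_field",
    "render_channels",
    "render_flatfield",
    "render_controls",
    "simulate_scenario",
    "write_scenario",
    "load_scenario_config",
    "load_truth",
]

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


def _build(cls, value: Any):
    """Construct dataclass ``cls`` from a mapping, rejecting unknown keys."""
    if value is None or isinstance(value, cls):
        return value
    if not isinstance(value, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {type(value).__name__}")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(value) - set(known)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, item in value.items():
        f = known[name]
        sub = _NESTED.get((cls, name))
        if sub is not None and item is not None:
            if isinstance(sub, tuple):  # list of dataclasses
                item = [_build(sub[0], v) for v in item]
            else:
                item = _build(sub, item)
        kwargs[name] = item
    return cls(**kwargs)


@dataclass
class CellGeometrySpec:
    """Circular cell body with angular edge sections, optional extra polygon."""

    center: tuple[float, float] = (16.0, 16.0)  # um (x, y)
    radius: float = 10.0  # um
    n_sections: int = 8
    section_start_deg: float = -180.0
    polygon: list | None = None  # optional static union polygon, um (x, y) pairs

    def __post_init__(self) -> None:
        self.center = tuple(float(v) for v in self.center)
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")


@dataclass
class EdgeScheduleItem:
    """Constant normal velocity applied to one edge section over [start, stop)."""

    section: int
    velocity: float  # um/s, positive outward
    start: float = 0.0  # s
    stop: float = math.inf  # s

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("schedule stop must exceed start")


@dataclass
class HotspotSpec:
    """Disk-shaped activity increment active during [t_on, t_off)."""

    center: tuple[float, float]
    radius: float
    amplitude: float
    t_on: float = 0.0
    t_off: float = math.inf

    def __post_init__(self) -> None:
        self.center = tuple(float(v) for v in self.center)
        if self.radius <= 0:
            raise ValueError("hotspot radius must be positive")
        if self.amplitude < 0:
            raise ValueError("hotspot amplitude must be >= 0")


@dataclass
class WaveSpec:
    """Traveling cosine wave ``A * cos(2*pi*(t/T - x/lambda))``.

    ``x`` is the coordinate along ``direction`` measured from the wave origin
    (cell centre unless ``region_center`` is given); crests therefore advance
    along ``direction`` at ``lambda / T``.
    """

    period: float  # s
    wavelength: float  # um
    amplitude: float
    direction: tuple[float, float] = (-1.0, 0.0)
    start_time: float = 0.0  # s
    region_center: tuple[float, float] | None = None  # um; default: cell centre
    region_radius: float | None = None  # um; default: whole cell

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("wave period must be positive")
        if self.wavelength <= 0:
            raise ValueError("wave wavelength must be positive")
        if self.amplitude < 0:
            raise ValueError("wave amplitude must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.hypot(*d))
        if n == 0:
            raise ValueError("wave direction must be nonzero")
        self.direction = (float(d[0] / n), float(d[1] / n))
        if self.region_center is not None:
            self.region_center = tuple(float(v) for v in self.region_center)


@dataclass
class EdgeBandSpec:
    """Per-section activity levels in a band of given depth behind the edge."""

    depth: float = 14.0  # um, measured inward from the section's current edge
    levels: dict = field(default_factory=dict)  # section id -> activity level

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("edge band depth must be positive")
        self.levels = {int(k): float(v) for k, v in self.levels.items()}
        if any(v < 0 for v in self.levels.values()):
            raise ValueError("edge band levels must be >= 0")


@dataclass
class StimulusSpec:
    """Local stimulus: linear activity ramp in a disk, delayed after delivery."""

    time: float  # s, delivery time
    position: tuple[float, float]  # um
    region_radius: float = 5.0  # um
    delay: float = 8.0  # s between delivery and ramp onset
    rate: float = 0.004  # activity units per second

    def __post_init__(self) -> None:
        self.position = tuple(float(v) for v in self.position)
        if self.region_radius <= 0:
            raise ValueError("stimulus region_radius must be positive")
        if self.delay < 0:
            raise ValueError("stimulus delay must be >= 0")
        if self.rate < 0:
            raise ValueError("stimulus rate must be >= 0")


@dataclass
class ActivitySpec:
    baseline: float = 1.0
    hotspots: list = field(default_factory=list)
    wave: WaveSpec | None = None
    edge_bands: EdgeBandSpec | None = None

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("activity baseline must be positive")


@dataclass
class NuisanceSpec:
    """Acquisition nuisances.  All rates and amplitudes must be nonnegative.

    The shading field is a smooth quadratic bowl of unit mean shared by both
    camera halves; ``shading_strength`` is its peak-to-edge relative depth.
    Noise follows ``Poisson(gain * I) / gain + N(0, read_noise)``.
    """

    shading_strength: float = 0.1
    shading_center_frac: tuple[float, float] = (0.5, 0.5)
    background_donor: float = 100.0
    background_acceptor: float = 100.0
    alpha: float = 0.35  # donor -> acceptor bleedthrough
    beta: float = 0.0  # direct acceptor excitation into the FRET channel
    bleach_donor: float = 0.0  # 1/s
    bleach_acceptor: float = 0.0  # 1/s
    gain: float = 0.5  # photoelectrons per ADU-equivalent
    read_noise: float = 2.0  # ADU
    noise: bool = True
    quantize: bool = True
    donor_brightness: float = 2000.0  # ADU at unit sensor density
    calibration: float = 1.0  # FRET ADU per (sensor density * activity)
    expression_gradient: tuple[float, float] = (0.0, 0.0)  # relative slope 1/um

    def __post_init__(self) -> None:
        for name in (
            "shading_strength",
            "background_donor",
            "background_acceptor",
            "alpha",
            "beta",
            "bleach_donor",
            "bleach_acceptor",
            "gain",
            "read_noise",
            "donor_brightness",
            "calibration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"nuisance parameter {name} must be >= 0")
        self.shading_center_frac = tuple(float(v) for v in self.shading_center_frac)
        self.expression_gradient = tuple(float(v) for v in self.expression_gradient)


@dataclass
class ScenarioConfig:
    """Full description of one synthetic two-channel movie."""

    height: int = 72
    width: int = 72
    pixel_size: float = 0.4  # um/pixel
    frame_interval: float = 1.0  # s
    n_frames: int = 120
    seed: int = 0
    cell: CellGeometrySpec = field(default_factory=CellGeometrySpec)
    schedule: list = field(default_factory=list)
    activity: ActivitySpec = field(default_factory=ActivitySpec)
    stimulus: StimulusSpec | None = None
    nuisance: NuisanceSpec = field(default_factory=NuisanceSpec)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        wave = self.activity.wave if self.activity else None
        if wave is not None and wave.period <= 2 * self.frame_interval:
            raise ValueError("wave period must exceed twice the frame interval")

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return _build(cls, dict(d))

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                obj = obj.item()
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            return obj

        return convert(self)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


_NESTED = {
    (ScenarioConfig, "cell"): CellGeometrySpec,
    (ScenarioConfig, "schedule"): (EdgeScheduleItem,),
    (ScenarioConfig, "activity"): ActivitySpec,
    (ScenarioConfig, "stimulus"): StimulusSpec,
    (ScenarioConfig, "nuisance"): NuisanceSpec,
    (ActivitySpec, "hotspots"): (HotspotSpec,),
    (ActivitySpec, "wave"): WaveSpec,
    (ActivitySpec, "edge_bands"): EdgeBandSpec,
}


def _parse_inf(d):
    if isinstance(d, dict):
        return {k: _parse_inf(v) for k, v in d.items()}
    if isinstance(d, list):
        return [_parse_inf(v) for v in d]
    if d == "inf":
        return math.inf
    return d


def load_scenario_config(source: str | Path | dict) -> ScenarioConfig:
    """Load a scenario config from a YAML path or plain dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(_parse_inf(source))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass
class Geometry:
    """Per-frame cell mask plus true (sub-pixel) edge positions.

    ``edge_positions[s, t]`` is the radial position (um from the cell centre)
    of section ``s`` at frame ``t``; the binary mask quantizes it to pixels.
    """

    mask: np.ndarray  # (T, H, W) bool
    edge_positions: np.ndarray  # (n_sections, T) um
    section_map: np.ndarray  # (H, W) int, angular section of each pixel
    dist: np.ndarray  # (H, W) um, distance from cell centre
    config: ScenarioConfig


def _pixel_coords(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    y = np.arange(config.height)[:, None] * config.pixel_size
    x = np.arange(config.width)[None, :] * config.pixel_size
    return x, y


def _section_offsets(config: ScenarioConfig) -> np.ndarray:
    """Integrated radial offset (um) per section per frame from the schedule."""
    times = config.times
    off = np.zeros((config.cell.n_sections, config.n_frames))
    for item in config.schedule:
        if not 0 <= item.section < config.cell.n_sections:
            raise ValueError(f"schedule refers to unknown section {item.section}")
        active = np.clip(times, item.start, item.stop) - item.start
        off[item.section] += item.velocity * active
    return off


def simulate_geometry(config: ScenarioConfig) -> Geometry:
    """Realize the per-frame cell mask and ground-truth edge positions.

    Each angular section's boundary moves radially (normal to a circular
    edge) at its scheduled velocity; unscheduled sections stay put.
    Raises if a schedule drives any section's edge outside the grid or
    through the cell centre, naming the offending section and frame.
    """
    cx, cy = config.cell.center
    x, y = _pixel_coords(config)
    dist = np.hypot(x - cx, y - cy)
    theta = np.arctan2(y - cy, x - cx)
    start = math.radians(config.cell.section_start_deg)
    dtheta = _TWO_PI / config.cell.n_sections
    section_map = (np.mod(theta - start, _TWO_PI) // dtheta).astype(int)
    section_map = np.clip(section_map, 0, config.cell.n_sections - 1)

    offsets = _section_offsets(config)
    radius = config.cell.radius + offsets  # (S, T)

    max_r = min(
        cx,
        cy,
        (config.width - 1) * config.pixel_size - cx,
        (config.height - 1) * config.pixel_size - cy,
    )
    for s in range(config.cell.n_sections):
        bad = np.nonzero(radius[s] > max_r)[0]
        if bad.size:
            raise ValueError(
                f"edge of section {s} leaves the grid at frame {bad[0]}"
            )
        bad = np.nonzero(radius[s] <= 0)[0]
        if bad.size:
            raise ValueError(
                f"edge of section {s} collapses through the centre at frame {bad[0]}"
            )

    extra = None
    if config.cell.polygon:
        poly = np.asarray(config.cell.polygon, dtype=float) / config.pixel_size
        # polygon given as (x, y) um; polygon2mask wants (row, col)
        extra = polygon2mask((config.height, config.width), poly[:, ::-1])

    mask = np.empty((config.n_frames, config.height, config.width), dtype=bool)
    for t in range(config.n_frames):
        m = dist <= radius[:, t][section_map]
        if extra is not None:
            m |= extra
        mask[t] = m
    return Geometry(
        mask=mask,
        edge_positions=radius,
        section_map=section_map,
        dist=dist,
        config=config,
    )


# ---------------------------------------------------------------------------
# activity field
# ---------------------------------------------------------------------------

_ACTIVITY_FLOOR = 1e-3


def simulate_activity_field(config: ScenarioConfig, geometry: Geometry) -> np.ndarray:
    """Dimensionless activity field (1 = baseline), shape ``(T, H, W)``.

    Composition order per frame: baseline, per-section edge-band levels
    (overriding the baseline in a band that tracks the moving edge),
    hotspots (+), traveling wave (+) inside its region after its start time,
    stimulus ramp (+), then a positivity clip.
    """
    act = config.activity
    wave = act.wave
    if wave is not None and wave.wavelength <= 2 * config.pixel_size:
        raise ValueError(
            "wave wavelength must exceed twice the pixel size to be resolvable"
        )

    x, y = _pixel_coords(config)
    xg = np.broadcast_to(x, (config.height, config.width))
    yg = np.broadcast_to(y, (config.height, config.width))
    times = config.times
    field_stack = np.empty(
        (config.n_frames, config.height, config.width), dtype=np.float32
    )

    if wave is not None:
        origin = wave.region_center or config.cell.center
        wx = (xg - origin[0]) * wave.direction[0] + (yg - origin[1]) * wave.direction[1]
        if wave.region_radius is not None:
            wregion = np.hypot(xg - origin[0], yg - origin[1]) <= wave.region_radius
        else:
            wregion = np.hypot(
                xg - config.cell.center[0], yg - config.cell.center[1]
            ) <= config.cell.radius + 1e-9

    if config.stimulus is not None:
        sx, sy = config.stimulus.position
        sregion = np.hypot(xg - sx, yg - sy) <= config.stimulus.region_radius

    for t_idx, t in enumerate(times):
        frame = np.full((config.height, config.width), act.baseline, dtype=np.float64)

        if act.edge_bands is not None:
            for sid, level in act.edge_bands.levels.items():
                edge = geometry.edge_positions[sid, t_idx]
                band = (
                    (geometry.section_map == sid)
                    & (geometry.dist <= edge)
                    & (geometry.dist >= edge - act.edge_bands.depth)
                )
                frame[band] = level

        for hs in act.hotspots:
            if hs.t_on <= t < hs.t_off:
                region = np.hypot(xg - hs.center[0], yg - hs.center[1]) <= hs.radius
                frame[region] += hs.amplitude

        if wave is not None and t >= wave.start_time:
            phase = _TWO_PI * (t / wave.period - wx / wave.wavelength)
            frame[wregion] += wave.amplitude * np.cos(phase[wregion])

        if config.stimulus is not None:
            onset = config.stimulus.time + config.stimulus.delay
            if t >= onset:
                frame[sregion] += config.stimulus.rate * (t - onset)

        field_stack[t_idx] = np.maximum(frame, _ACTIVITY_FLOOR)

    return field_stack


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def shading_field(config: ScenarioConfig) -> np.ndarray:
    """Unit-mean quadratic-bowl shading field, shape ``(H, W)``."""
    nu = config.nuisance
    if nu.shading_strength == 0:
        return np.ones((config.height, config.width))
    x, y = _pixel_coords(config)
    cxf, cyf = nu.shading_center_frac
    cx = cxf * (config.width - 1) * config.pixel_size
    cy = cyf * (config.height - 1) * config.pixel_size
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    r2 = r2 / r2.max()
    s = 1.0 - nu.shading_strength * r2
    return s / s.mean()


def _sensor_density(config: ScenarioConfig) -> np.ndarray:
    """Sensor density field rho (um grid); uniform unless a gradient is set."""
    nu = config.nuisance
    x, y = _pixel_coords(config)
    gx, gy = nu.expression_gradient
    rho = 1.0 + gx * (x - config.cell.center[0]) + gy * (y - config.cell.center[1])
    rho = np.maximum(np.broadcast_to(rho, (config.height, config.width)), 0.0)
    return nu.donor_brightness * rho


def _apply_noise(img: np.ndarray, nu: NuisanceSpec, rng: np.random.Generator) -> np.ndarray:
    out = img
    if nu.noise and nu.gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) * nu.gain).astype(np.float64) / nu.gain
        if nu.read_noise > 0:
            out = out + rng.normal(0.0, nu.read_noise, size=out.shape)
    return out


def render_channels(
    activity: np.ndarray,
    geometry: Geometry,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelStack, ChannelStack]:
    """Render donor and raw-acceptor stacks through the nuisance model.

    Per frame ``t`` (times ``t = i * frame_interval``), with shading ``S``,
    bleach factors ``B_c(t) = exp(-k_c t)`` and sensor density ``rho`` (zero
    outside the mask)::

        donor    = S * B_d(t) * rho                      + bg_d + noise
        acceptor = S * (B_a(t) * F + alpha * B_d(t) * rho
                        + beta * X_direct)               + bg_a + noise
        F        = calibration * rho * activity

    The bleedthrough term decays with the donor's bleach rate (it is donor
    emission).  ``X_direct`` (direct acceptor excitation) is zero by default.
    Output is quantized to 16-bit unless ``nuisance.quantize`` is false.
    """
    nu = config.nuisance
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if activity.shape != geometry.mask.shape:
        raise ValueError("activity and geometry stacks are not congruent")

    S = shading_field(config)
    rho0 = _sensor_density(config)
    times = config.times
    ceiling = float(2**16 - 1)

    dtype = np.uint16 if nu.quantize else np.float32
    donor = np.empty(geometry.mask.shape, dtype=dtype)
    acceptor = np.empty(geometry.mask.shape, dtype=dtype)

    for i, t in enumerate(times):
        rho = rho0 * geometry.mask[i]
        bd = math.exp(-nu.bleach_donor * t)
        ba = math.exp(-nu.bleach_acceptor * t)
        fret = nu.calibration * rho * activity[i]
        don = S * (bd * rho) + nu.background_donor
        acc = S * (ba * fret + nu.alpha * bd * rho) + nu.background_acceptor
        don = _apply_noise(don, nu, rng)
        acc = _apply_noise(acc, nu, rng)
        if nu.quantize:
            don = np.clip(np.rint(don), 0, ceiling)
            acc = np.clip(np.rint(acc), 0, ceiling)
        else:
            don = np.maximum(don, 0.0)
            acc = np.maximum(acc, 0.0)
        donor[i] = don
        acceptor[i] = acc

    kwargs = dict(
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        bit_depth=16,
    )
    return (
        ChannelStack(donor, role="donor", **kwargs),
        ChannelStack(acceptor, role="raw_acceptor", **kwargs),
    )


def render_flatfield(
    config: ScenarioConfig,
    n_frames: int = 20,
    level: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> ChannelStack:
    """Noise-averaged shading reference: mean of uniform-scene frames."""
    nu = config.nuisance
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    S = shading_field(config)
    acc = np.zeros_like(S)
    for _ in range(n_frames):
        acc += _apply_noise(S * level, nu, rng)
    flat = np.maximum(acc / n_frames, 1e-6)
    return ChannelStack(
        flat[None].astype(np.float32),
        role="flatfield",
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        bit_depth=16,
    )


def render_controls(
    config: ScenarioConfig,
    n_frames: int = 5,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[ChannelStack, ChannelStack]]:
    """Single-fluorophore control stacks for bleedthrough estimation.

    Returns ``{"donor_only": (donor, acceptor), "acceptor_only":
    (direct, acceptor)}`` rendered from the frame-0 geometry: the donor-only
    cell has no FRET (its acceptor channel is pure bleedthrough), while the
    acceptor-only cell contributes only direct acceptor excitation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    nu = config.nuisance
    base = dataclasses.replace(config, n_frames=n_frames, schedule=[])
    geom = simulate_geometry(base)
    S = shading_field(base)
    rho = _sensor_density(base) * geom.mask[0]
    kwargs = dict(
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        bit_depth=16,
    )
    ceiling = float(2**16 - 1)

    def finish(img):
        img = _apply_noise(img, nu, rng)
        if nu.quantize:
            img = np.clip(np.rint(img), 0, ceiling).astype(np.uint16)
        return np.maximum(img, 0.0)

    don_d = np.stack([finish(S * rho + nu.background_donor) for _ in range(n_frames)])
    don_a = np.stack(
        [finish(S * nu.alpha * rho + nu.background_acceptor) for _ in range(n_frames)]
    )
    acc_ref = np.stack([finish(S * rho + nu.background_acceptor) for _ in range(n_frames)])
    acc_a = np.stack(
        [finish(S * nu.beta * rho + nu.background_acceptor) for _ in range(n_frames)]
    )
    return {
        "donor_only": (
            ChannelStack(don_d, role="control_donor_only", **kwargs),
            ChannelStack(don_a, role="raw_acceptor", **kwargs),
        ),
        "acceptor_only": (
            ChannelStack(acc_ref, role="acceptor_direct", **kwargs),
            ChannelStack(acc_a, role="raw_acceptor", **kwargs),
        ),
    }


# ---------------------------------------------------------------------------
# ground truth + scenario orchestration
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Seeded parameters and realized fields of one synthetic scenario."""

    mask: np.ndarray  # (T, H, W) bool
    activity: np.ndarray  # (T, H, W) float32, 1 = baseline
    edge_positions: np.ndarray  # (n_sections, T) um
    section_labels: dict  # section id -> stalling|protruding|retracting
    class_levels: dict  # section id -> seeded band activity level
    wave_period: float | None  # s
    stimulus_time: float | None
    ramp_onset: float | None  # s, true start of the stimulus ramp
    nuisance: dict
    seed: int
    config: ScenarioConfig


def _truth_labels(config: ScenarioConfig, edge_positions: np.ndarray, v0: float = 0.005) -> dict:
    """Classify sections from the schedule over each section's active window."""
    labels = {}
    duration = (config.n_frames - 1) * config.frame_interval
    for s in range(config.cell.n_sections):
        items = [it for it in config.schedule if it.section == s]
        if not items:
            labels[s] = "stalling"
            continue
        t0 = min(it.start for it in items)
        t1 = min(max(min(it.stop, duration) for it in items), duration)
        i0 = int(round(t0 / config.frame_interval))
        i1 = int(round(t1 / config.frame_interval))
        if i1 <= i0:
            labels[s] = "stalling"
            continue
        vbar = (edge_positions[s, i1] - edge_positions[s, i0]) / (
            (i1 - i0) * config.frame_interval
        )
        if vbar > v0:
            labels[s] = "protruding"
        elif vbar < -v0:
            labels[s] = "retracting"
        else:
            labels[s] = "stalling"
    return labels


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[ChannelStack, ChannelStack, GroundTruth]:
    """Run geometry, activity and rendering for one config; fully seeded."""
    geom = simulate_geometry(config)
    activity = simulate_activity_field(config, geom)
    donor, acceptor = render_channels(activity, geom, config)
    bands = config.activity.edge_bands
    truth = GroundTruth(
        mask=geom.mask,
        activity=activity,
        edge_positions=geom.edge_positions,
        section_labels=_truth_labels(config, geom.edge_positions),
        class_levels=dict(bands.levels) if bands else {},
        wave_period=config.activity.wave.period if config.activity.wave else None,
        stimulus_time=config.stimulus.time if config.stimulus else None,
        ramp_onset=(
            config.stimulus.time + config.stimulus.delay if config.stimulus else None
        ),
        nuisance=dataclasses.asdict(config.nuisance),
        seed=config.seed,
        config=config,
    )
    return donor, acceptor, truth


def write_scenario(
    out_dir: str | Path,
    donor: ChannelStack,
    acceptor: ChannelStack,
    truth: GroundTruth,
    config: ScenarioConfig,
    flatfield: ChannelStack | None = None,
    controls: dict | None = None,
) -> Path:
    """Write a rendered scenario to disk (TIFF stacks + JSON/YAML sidecars)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(donor, out_dir / "donor.tif")
    write_stack(acceptor, out_dir / "acceptor.tif")
    write_stack(
        ChannelStack(
            truth.mask.astype(np.uint8),
            role="truth",
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        ),
        out_dir / "truth_mask.tif",
    )
    write_stack(
        ChannelStack(
            truth.activity.astype(np.float32),
            role="truth",
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        ),
        out_dir / "truth_activity.tif",
    )
    if flatfield is not None:
        write_stack(flatfield, out_dir / "flatfield.tif")
    if controls is not None:
        for name, (ref, acc) in controls.items():
            write_stack(ref, out_dir / f"control_{name}_ref.tif")
            write_stack(acc, out_dir / f"control_{name}_fret.tif")

    sidecar = {
        "seed": truth.seed,
        "pixel_size_um": config.pixel_size,
        "frame_interval_s": config.frame_interval,
        "n_frames": config.n_frames,
        "wave_period_s": truth.wave_period,
        "stimulus_time_s": truth.stimulus_time,
        "ramp_onset_s": truth.ramp_onset,
        "section_labels": {str(k): v for k, v in truth.section_labels.items()},
        "class_levels": {str(k): v for k, v in truth.class_levels.items()},
        "edge_positions_um": {
            str(s): [float(v) for v in truth.edge_positions[s]]
            for s in range(truth.edge_positions.shape[0])
        },
        "nuisance": {
            k: v for k, v in truth.nuisance.items() if not isinstance(v, np.ndarray)
        },
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    with open(out_dir / "scenario.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out_dir


def load_truth(scenario_dir: str | Path) -> dict:
    """Load the ground-truth sidecar of a written scenario."""
    with open(Path(scenario_dir) / "truth.json") as fh:
        return json.load(fh)
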