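"""Single-channel image stacks and multi-page TIFF I/O.

A :class:`ChannelStack` is a ``T x H x W`` array of nonnegative intensities
plus the physical metadata (pixel size in micrometres, frame interval in
seconds) needed to interpret it.  Stacks round-trip losslessly through
multi-page TIFF files; metadata travels in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_ROLES = frozenset(
    {
        "donor",
        "raw_acceptor",
        "corrected_fret",
        "control_donor_only",
        "control_acceptor_only",
        "acceptor_direct",
        "flatfield",
        "truth",
        "other",
    }
)


@dataclass
class ChannelStack:
    """One fluorescence channel as a ``T x H x W`` stack with metadata.

    Parameters
    ----------
    data : ndarray
        Intensities, shape ``(T, H, W)``, all values >= 0.
    role : str
        One of :data:`CHANNEL_ROLES`.
    pixel_size : float
        Pixel size in micrometres per pixel.
    frame_interval : float
        Time between frames in seconds.
    bit_depth : int
        Nominal acquisition bit depth (quantization ceiling is
        ``2**bit_depth - 1``).
    """

    data: np.ndarray
    role: str = "other"
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be T x H x W, got shape {self.data.shape}")
        if self.data.size == 0:
            raise ValueError("stack must contain at least one frame")
        if np.nanmin(self.data) < 0:
            raise ValueError("stack intensities must be nonnegative")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame ``i`` at ``i * frame_interval``)."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, role: str | None = None) -> "ChannelStack":
        """Return a copy carrying ``data`` (same metadata, optionally new role)."""
        return replace(self, data=data, role=self.role if role is None else role)


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a stack to a multi-page little-endian TIFF with JSON metadata."""
    path = Path(path)
    meta = {
        "role": stack.role,
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "bit_depth": stack.bit_depth,
    }
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        byteorder="<",
        description=json.dumps(meta, sort_keys=True),
    )
    return path


def read_stack(path: str | Path, role: str | None = None) -> ChannelStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Foreign TIFFs without the JSON description are accepted with default
    metadata so external movies can still enter the pipeline.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return ChannelStack(
        data=data,
        role=role or meta.get("role", "other"),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=float(meta.get("frame_interval_s", 1.0)),
        bit_depth=int(meta.get("bit_depth", 16)),
    )


def check_congruent(*stacks: ChannelStack) -> None:
    """Raise if the stacks do not share shape and physical metadata."""
    first = stacks[0]
    for other in stacks[1:]:
        if other.data.shape != first.data.shape:
            raise ValueError(
                f"stack shape mismatch: {other.data.shape} vs {first.data.shape}"
            )
        if not np.isclose(other.pixel_size, first.pixel_size):
            raise ValueError("stack pixel_size mismatch")
        if not np.isclose(other.frame_interval, first.frame_interval):
            raise ValueError("stack frame_interval mismatch")
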