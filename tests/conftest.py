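"""Shared fixtures: small synthetic scenarios and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fretwaves.correction import RatioMovie
from fretwaves.synthetic import ScenarioConfig


def make_config(**overrides) -> ScenarioConfig:
    """A small, fast scenario; keyword overrides are applied on top."""
    base = {
        "height": 64,
        "width": 64,
        "pixel_size": 0.5,
        "frame_interval": 1.0,
        "n_frames": 60,
        "seed": 0,
        "cell": {"center": [16.0, 16.0], "radius": 10.0, "n_sections": 8},
        "activity": {"baseline": 1.0},
        "nuisance": {
            "shading_strength": 0.1,
            "background_donor": 100.0,
            "background_acceptor": 100.0,
            "alpha": 0.35,
            "bleach_donor": 0.0002,
            "bleach_acceptor": 0.0002,
            "donor_brightness": 2000.0,
        },
    }

    def deep_update(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                deep_update(dst[k], v)
            else:
                dst[k] = v

    deep_update(base, overrides)
    return ScenarioConfig.from_dict(base)


def noise_free(**overrides) -> ScenarioConfig:
    """Same as make_config but with noise and quantization disabled."""
    nu = overrides.setdefault("nuisance", {})
    nu.setdefault("noise", False)
    nu.setdefault("quantize", False)
    return make_config(**overrides)


def ratio_from_mask(mask: np.ndarray, value: float = 1.0, pixel_size: float = 0.5,
                    frame_interval: float = 1.0) -> RatioMovie:
    """Ratio movie that is ``value`` inside the mask and undefined outside."""
    data = np.where(mask, np.float32(value), np.nan).astype(np.float32)
    return RatioMovie(data=data, pixel_size=pixel_size, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def autocorr_period(series: np.ndarray, dt: float) -> float:
    """Dominant period of a trace (oracle, independent of estimate_period).

    Locates the peak of the zero-padded periodogram — the Fourier dual of
    the autocorrelation peak (Wiener-Khinchin) — which is free of the
    finite-overlap bias that distorts the lag-domain peak of short records.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    x = x - x.mean()
    n = x.size
    n_pad = 1 << max(18, (2 * n - 1).bit_length())
    power = np.abs(np.fft.rfft(x, n_pad)) ** 2
    freqs = np.fft.rfftfreq(n_pad, dt)
    k = int(np.argmax(power[1:])) + 1
    return float(1.0 / freqs[k])


def ols_origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares slope through the origin with its SE (oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = float((x * y).sum() / (x * x).sum())
    resid = y - slope * x
    se = float(np.sqrt((resid**2).sum() / (x.size - 1) / (x * x).sum()))
    return slope, se


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
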