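"""Ratiometric correction chain for sensitized-emission FRET stacks.

The chain, in fixed order (recorded in provenance):

1. background subtraction + shading (flat-field) division,
2. optional per-channel photobleach correction,
3. bleedthrough subtraction (``FRET - alpha * donor - beta * direct``),
4. donor-threshold cell masking,
5. ratio = corrected FRET / donor, defined only inside the mask and above a
   donor intensity floor.

Bleedthrough coefficients come from single-fluorophore control stacks via a
robust (Theil-Sen through the origin) slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .stacks import ChannelStack, check_congruent

__all__ = [
    "CorrectionModel",
    "CellMask",
    "RatioMovie",
    "correct_shading_background",
    "correct_photobleach",
    "estimate_bleedthrough",
    "correct_fret",
    "compute_mask",
    "compute_ratio",
    "run_correction_chain",
    "CorrectionResult",
]

CHAIN_ORDER = (
    "background_subtraction",
    "shading_division",
    "masking",
    "photobleach",
    "bleedthrough",
    "ratio",
)


@dataclass
class CorrectionModel:
    """Estimated / configured nuisance parameters of the correction chain."""

    background: dict = field(default_factory=dict)  # channel role -> per-frame bg
    alpha: float = 0.0  # donor -> acceptor bleedthrough
    beta: float = 0.0  # direct acceptor excitation coefficient
    alpha_se: float | None = None
    beta_se: float | None = None
    bleach_rates: dict = field(default_factory=dict)  # channel role -> 1/s
    epsilon: float = 0.05  # donor floor, fraction of in-mask donor median

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("bleedthrough coefficients must be >= 0")
        if self.alpha >= 1 or self.beta >= 1:
            warnings.warn(
                "bleedthrough coefficient >= 1 is physically implausible",
                stacklevel=2,
            )


@dataclass
class CellMask:
    """Boolean per-frame cell mask with thresholding provenance."""

    mask: np.ndarray  # (T, H, W) bool
    thresholds: list  # per-frame threshold values (None where degenerate)
    method: str = "otsu"
    degenerate: list = field(default_factory=list)  # per-frame flags

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be T x H x W")
        if not self.degenerate:
            self.degenerate = [False] * self.mask.shape[0]

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]


@dataclass
class RatioMovie:
    """Activity ratio stack; NaN marks undefined (out-of-mask / dim) pixels."""

    data: np.ndarray  # (T, H, W) float32, NaN = undefined
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("ratio data must be T x H x W")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# shading + background
# ---------------------------------------------------------------------------


def _provisional_background(frame: np.ndarray, dilate_px: int = 5) -> float:
    """Median intensity outside a dilated Otsu foreground estimate."""
    if frame.max() == frame.min():
        return float(frame.ravel()[0])
    thr = threshold_otsu(frame)
    fg = ndimage.binary_dilation(frame > thr, iterations=dilate_px)
    outside = frame[~fg]
    if outside.size == 0:
        return 0.0
    return float(np.median(outside))


def correct_shading_background(
    stack: ChannelStack,
    flatfield: np.ndarray | ChannelStack | None = None,
    background: float | str = "auto",
) -> tuple[ChannelStack, dict]:
    """``(input - background) / shading``, clipped at zero.

    ``background="auto"`` estimates, per frame, the median of pixels outside
    a dilated provisional (Otsu) foreground mask.  The flat-field image is
    normalized to unit mean before division; non-positive flat-field pixels
    are an error.  Returns the corrected stack and a provenance dict.
    """
    data = stack.data.astype(np.float64)
    if flatfield is None:
        shading = np.ones(stack.frame_shape)
    else:
        shading = flatfield.data[0] if isinstance(flatfield, ChannelStack) else flatfield
        shading = np.asarray(shading, dtype=np.float64)
        if shading.shape != stack.frame_shape:
            raise ValueError("flatfield shape does not match the stack frames")
        if shading.min() <= 0:
            raise ValueError("flatfield contains non-positive pixels")
        shading = shading / shading.mean()

    if background == "auto":
        bgs = [_provisional_background(data[t]) for t in range(stack.n_frames)]
    else:
        bg = float(background)
        if bg < 0:
            raise ValueError("background must be >= 0")
        bgs = [bg] * stack.n_frames

    out = np.empty_like(data, dtype=np.float32)
    for t in range(stack.n_frames):
        out[t] = np.maximum((data[t] - bgs[t]) / shading, 0.0)
    prov = {
        "background": [float(b) for b in bgs],
        "background_mode": "auto" if background == "auto" else "fixed",
        "flatfield": flatfield is not None,
    }
    return stack.with_data(out), prov


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------


def correct_photobleach(
    stack: ChannelStack,
    mask: CellMask,
    min_variance_reduction: float = 0.05,
) -> tuple[ChannelStack, float]:
    """Fit and divide out a mono-exponential decay of the in-mask mean.

    The mean in-mask intensity is fit to ``I0 * exp(-k t)`` by least squares
    on the log-transformed means.  The correction is applied only when the
    fitted decay is an actual decay (``k > 0``) and reduces the residual
    variance of the means by more than ``min_variance_reduction`` relative to
    a constant fit; otherwise the stack is returned unchanged with ``k = 0``.
    """
    if stack.n_frames < 5:
        raise ValueError("photobleach correction needs at least 5 frames")
    empty = ~mask.mask.any(axis=(1, 2))
    if empty.any():
        raise ValueError(f"mask is empty on frame {int(np.nonzero(empty)[0][0])}")
    means = np.array(
        [stack.data[t][mask.mask[t]].mean() for t in range(stack.n_frames)],
        dtype=np.float64,
    )
    if np.any(means <= 0):
        return stack.with_data(stack.data.astype(np.float32)), 0.0
    t = stack.times
    slope, intercept = np.polyfit(t, np.log(means), 1)
    k = -slope
    fit = np.exp(intercept + slope * t)
    ss_exp = float(np.sum((means - fit) ** 2))
    ss_const = float(np.sum((means - means.mean()) ** 2))
    significant = k > 0 and (
        ss_const == 0.0 and ss_exp < ss_const
        or ss_const > 0
        and 1.0 - ss_exp / ss_const > min_variance_reduction
    )
    if ss_const == 0.0 and ss_exp == 0.0 and k > 0:
        # perfectly exponential, noiseless decay
        significant = True
    if not significant:
        return stack.with_data(stack.data.astype(np.float32)), 0.0
    corr = stack.data.astype(np.float64) / np.exp(-k * t)[:, None, None]
    return stack.with_data(corr.astype(np.float32)), float(k)


# ---------------------------------------------------------------------------
# bleedthrough
# ---------------------------------------------------------------------------


def _robust_origin_slope(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 200,
) -> tuple[float, float]:
    """Theil-Sen-style slope through the origin (median of y/x) + bootstrap SE."""
    ratios = y / x
    slope = float(np.median(ratios))
    idx = rng.integers(0, ratios.size, size=(n_boot, min(ratios.size, 5000)))
    boot = np.median(ratios[idx], axis=1)
    return slope, float(boot.std(ddof=1))


def estimate_bleedthrough(
    control_donor_only: tuple[ChannelStack, ChannelStack] | None,
    control_acceptor_only: tuple[ChannelStack, ChannelStack] | None = None,
    min_pixels: int = 100,
    min_signal: float = 50.0,
    seed: int = 0,
) -> CorrectionModel:
    """Bleedthrough coefficients from single-fluorophore control stacks.

    Each control is a ``(reference_channel, fret_channel)`` pair that has
    already been shading/background-corrected.  ``alpha`` is the robust slope
    through the origin of FRET-channel vs donor-channel intensity over bright
    pixels of the donor-only control; ``beta`` likewise from the
    acceptor-only control (0 when that control is absent, matching a
    two-image acquisition).  Negative slopes are clipped to 0 with a warning.
    """
    rng = np.random.default_rng(seed)
    model = CorrectionModel()

    def fit(pair):
        ref, fret = pair
        if isinstance(ref, ChannelStack):
            check_congruent(ref, fret)
            ref, fret = ref.data, fret.data
        x = np.asarray(ref, dtype=np.float64).ravel()
        y = np.asarray(fret, dtype=np.float64).ravel()
        keep = x > min_signal
        if keep.sum() < min_pixels:
            raise ValueError(
                f"too few bright control pixels ({int(keep.sum())} < {min_pixels})"
            )
        slope, se = _robust_origin_slope(x[keep], y[keep], rng)
        if slope < 0:
            warnings.warn("negative bleedthrough slope clipped to 0", stacklevel=3)
            slope = 0.0
        return slope, se

    if control_donor_only is not None:
        model.alpha, model.alpha_se = fit(control_donor_only)
    if control_acceptor_only is not None:
        model.beta, model.beta_se = fit(control_acceptor_only)
    return model


def correct_fret(
    raw_acceptor: ChannelStack,
    donor: ChannelStack,
    alpha: float,
    beta: float = 0.0,
    acceptor_direct: ChannelStack | None = None,
) -> ChannelStack:
    """Linear sensitized-emission correction, clipped at zero.

    ``corrected = raw_acceptor - alpha * donor - beta * acceptor_direct``.
    Without a direct-acceptor-excitation image (two-image protocol) the beta
    term is omitted.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("bleedthrough coefficients must be >= 0")
    check_congruent(raw_acceptor, donor)
    out = raw_acceptor.data.astype(np.float64) - alpha * donor.data.astype(np.float64)
    if acceptor_direct is not None and beta > 0:
        check_congruent(raw_acceptor, acceptor_direct)
        out -= beta * acceptor_direct.data.astype(np.float64)
    return raw_acceptor.with_data(
        np.maximum(out, 0.0).astype(np.float32), role="corrected_fret"
    )


# ---------------------------------------------------------------------------
# masking + ratio
# ---------------------------------------------------------------------------


def compute_mask(donor: ChannelStack) -> CellMask:
    """Per-frame Otsu threshold on the corrected donor, keeping the largest
    connected component with holes filled.

    Frames with no contrast (or nothing above threshold) are flagged
    degenerate and left empty.
    """
    T = donor.n_frames
    mask = np.zeros(donor.data.shape, dtype=bool)
    thresholds: list = []
    degenerate = []
    for t in range(T):
        frame = donor.data[t]
        if frame.max() == frame.min():
            thresholds.append(None)
            degenerate.append(True)
            continue
        thr = float(threshold_otsu(frame))
        fg = frame > thr
        if not fg.any():
            thresholds.append(thr)
            degenerate.append(True)
            continue
        labels, n = cc_label(fg, return_num=True)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            fg = labels == sizes.argmax()
        mask[t] = ndimage.binary_fill_holes(fg)
        thresholds.append(thr)
        degenerate.append(False)
    return CellMask(mask=mask, thresholds=thresholds, method="otsu", degenerate=degenerate)


def compute_ratio(
    corrected_fret: ChannelStack,
    donor: ChannelStack,
    mask: CellMask,
    epsilon: float = 0.05,
) -> RatioMovie:
    """Ratio = corrected FRET / donor inside the mask, above the donor floor.

    A pixel is defined where the mask is true AND the donor exceeds
    ``epsilon`` times the in-mask donor median of its frame (guards against
    ratio blow-up at the dim cell rim); elsewhere it is NaN.  Non-positive
    ratio values are also flagged undefined so that defined values are
    always finite and positive.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    check_congruent(corrected_fret, donor)
    ratio = np.full(donor.data.shape, np.nan, dtype=np.float32)
    for t in range(donor.n_frames):
        m = mask.mask[t]
        if not m.any():
            continue
        floor = epsilon * float(np.median(donor.data[t][m]))
        valid = m & (donor.data[t] > max(floor, 0.0))
        vals = corrected_fret.data[t][valid] / donor.data[t][valid]
        frame = np.full(donor.frame_shape, np.nan, dtype=np.float32)
        frame[valid] = vals
        frame[frame <= 0] = np.nan
        ratio[t] = frame
    return RatioMovie(
        data=ratio,
        pixel_size=donor.pixel_size,
        frame_interval=donor.frame_interval,
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


@dataclass
class CorrectionResult:
    ratio: RatioMovie
    mask: CellMask
    donor: ChannelStack
    fret: ChannelStack
    model: CorrectionModel
    provenance: dict


def run_correction_chain(
    donor: ChannelStack,
    raw_acceptor: ChannelStack,
    flatfield: np.ndarray | ChannelStack | None = None,
    background: float | str = "auto",
    photobleach: str = "auto",
    alpha: float | None = None,
    beta: float = 0.0,
    controls: dict | None = None,
    acceptor_direct: ChannelStack | None = None,
    epsilon: float = 0.05,
    seed: int = 0,
) -> CorrectionResult:
    """Run the full fixed-order correction chain and record provenance.

    ``photobleach`` is ``"auto"`` (apply when the fitted decay is
    significant) or ``"off"``.  ``alpha`` may be given directly; otherwise it
    is estimated from ``controls["donor_only"]`` (error if neither is
    available).
    """
    check_congruent(donor, raw_acceptor)
    don_c, prov_d = correct_shading_background(donor, flatfield, background)
    acc_c, prov_a = correct_shading_background(raw_acceptor, flatfield, background)

    model = CorrectionModel(epsilon=epsilon)
    if alpha is not None:
        model.alpha = float(alpha)
        model.beta = float(beta)
        alpha_source = "configured"
    elif controls and controls.get("donor_only") is not None:
        est = estimate_bleedthrough(
            controls.get("donor_only"), controls.get("acceptor_only"), seed=seed
        )
        model.alpha, model.alpha_se = est.alpha, est.alpha_se
        model.beta, model.beta_se = est.beta, est.beta_se
        alpha_source = "controls"
    else:
        raise ValueError("no bleedthrough coefficient: provide alpha or control stacks")

    mask = compute_mask(don_c)
    k_d = k_a = 0.0
    if photobleach == "auto":
        don_c, k_d = correct_photobleach(don_c, mask)
        acc_c, k_a = correct_photobleach(acc_c, mask)
    elif photobleach != "off":
        raise ValueError("photobleach must be 'auto' or 'off'")
    model.bleach_rates = {"donor": k_d, "raw_acceptor": k_a}
    model.background = {
        "donor": prov_d["background"],
        "raw_acceptor": prov_a["background"],
    }

    fret = correct_fret(acc_c, don_c, model.alpha, model.beta, acceptor_direct)
    ratio = compute_ratio(fret, don_c, mask, epsilon)

    provenance = {
        "chain_order": list(CHAIN_ORDER),
        "background_mode": prov_d["background_mode"],
        "flatfield": prov_d["flatfield"],
        "photobleach": photobleach,
        "bleach_rates": model.bleach_rates,
        "alpha": model.alpha,
        "alpha_se": model.alpha_se,
        "alpha_source": alpha_source,
        "beta": model.beta,
        "beta_term_applied": acceptor_direct is not None and model.beta > 0,
        "mask_method": mask.method,
        "mask_thresholds": [
            None if v is None else float(v) for v in mask.thresholds
        ],
        "epsilon": epsilon,
    }
    return CorrectionResult(
        ratio=ratio,
        mask=mask,
        donor=don_c,
        fret=fret,
        model=model,
        provenance=provenance,
    )
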