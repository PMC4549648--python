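"""End-to-end orchestration: simulate, analyze, recover.

``run_simulate`` renders a synthetic scenario to disk; ``run_analyze`` runs
channel registration, the correction chain and the edge/wave analytics on a
scenario directory and writes a machine-readable ``report.json``;
``run_recover`` scores a report against the scenario's ground-truth sidecar.
All outputs are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import shutil
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .correction import RatioMovie, run_correction_chain
from .edges import (
    EdgeTrace,
    RegionOfInterest,
    build_montage,
    classify_sections,
    detect_edge,
    load_rois,
    save_montage_png,
    save_rois,
    save_traces_csv,
)
from .stacks import ChannelStack, read_stack, write_stack
from .synthetic import (
    ScenarioConfig,
    load_scenario_config,
    load_truth,
    render_controls,
    render_flatfield,
    simulate_scenario,
    write_scenario,
)
from .waves import (
    delta_f_over_f,
    detect_maxima,
    detect_onset,
    estimate_period,
    roi_trace,
    summarize_classes,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_pipeline_config",
    "preset_path",
    "list_presets",
    "run_simulate",
    "run_analyze",
    "run_recover",
]

log = logging.getLogger("fretwaves")


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CORRECTION_KEYS = {
    "background": "auto",
    "photobleach": "auto",
    "epsilon": 0.05,
    "alpha": None,
    "beta": 0.0,
    "flatfield": True,
    "bleedthrough": "controls",  # "controls" | "configured"
}

_ANALYSIS_KEYS = {
    "m": 1,
    "smoothing_s": 5.0,
    "prominence_sd": 0.5,
    "onset_k": 3.0,
    "onset_sustain_s": 5.0,
    "v0": 0.005,
    "section_window_s": None,
    "period_intervals": 10,
    "wave_roi": None,  # {"center": [x, y], "area": 4.0}
    "onset_roi": None,
    "stimulus_time": None,
    "montage": None,  # {"roi": id, "interval_s": 60.0}
    "edge_roi_width": 10.0,
    "edge_roi_length": 20.0,
}

_TOLERANCE_KEYS = {
    "period_tol_s": 10.0,
    "class_tol": 0.03,
    "onset_max_s": 30.0,
    "edge_velocity_tol": 0.10,
    "jaccard_min": 0.95,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    scenario: ScenarioConfig | None = None
    correction: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    rois: str | None = "auto"  # "auto" or a ROI CSV path
    seed: int | None = None

    def __post_init__(self) -> None:
        self.correction = _merge("correction", _CORRECTION_KEYS, self.correction)
        self.analysis = _merge("analysis", _ANALYSIS_KEYS, self.analysis)
        self.tolerances = _merge("tolerances", _TOLERANCE_KEYS, self.tolerances)


def _merge(section: str, defaults: dict, given: dict) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise PipelineError(f"unknown {section} config keys: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


def load_pipeline_config(source: str | Path | dict, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML (path or preset name) or a dict.

    ``seed``, when given, overrides the scenario seed so one preset can be
    replicated across seeds.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            path = preset_path(str(source))
        with open(path) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise PipelineError("pipeline config must be a mapping")
    known = {"scenario", "correction", "analysis", "tolerances", "rois", "seed"}
    unknown = set(source) - known
    if unknown:
        raise PipelineError(f"unknown pipeline config keys: {sorted(unknown)}")
    scenario = source.get("scenario")
    if scenario is not None:
        scenario = load_scenario_config(scenario)
    cfg = PipelineConfig(
        scenario=scenario,
        correction=source.get("correction") or {},
        analysis=source.get("analysis") or {},
        tolerances=source.get("tolerances") or {},
        rois=source.get("rois", "auto"),
        seed=source.get("seed"),
    )
    if seed is not None:
        cfg.seed = seed
    if cfg.seed is not None and cfg.scenario is not None:
        cfg.scenario = dataclasses.replace(cfg.scenario, seed=int(cfg.seed))
    return cfg


def preset_path(name: str) -> Path:
    """Resolve a bundled preset name (with or without .yaml) to its path."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    ref = resources.files("fretwaves").joinpath("presets", name)
    with resources.as_file(ref) as p:
        if not p.exists():
            raise PipelineError(
                f"unknown preset {name!r}; available: {list_presets()}"
            )
        return Path(p)


def list_presets() -> list[str]:
    folder = resources.files("fretwaves").joinpath("presets")
    return sorted(p.name[:-5] for p in folder.iterdir() if p.name.endswith(".yaml"))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Render the configured scenario (with flatfield + controls) to disk."""
    if config.scenario is None:
        raise PipelineError("config has no scenario section to simulate")
    t0 = time.perf_counter()
    donor, acceptor, truth = simulate_scenario(config.scenario)
    flat = render_flatfield(config.scenario)
    controls = render_controls(config.scenario)
    out = write_scenario(
        out_dir, donor, acceptor, truth, config.scenario, flatfield=flat, controls=controls
    )
    log.info("simulate: wrote scenario to %s in %.1fs", out, time.perf_counter() - t0)
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def register_channels(
    donor: ChannelStack, acceptor: ChannelStack, min_correlation: float = 0.5
) -> tuple[ChannelStack, tuple[int, int], float]:
    """Rigid-translation registration of the acceptor onto the donor.

    The shift is estimated once by cross-correlation of frame 0 (the image
    splitter produces a fixed offset) and applied, rounded to whole pixels,
    to every acceptor frame.  Raises when the post-shift correlation of
    frame 0 falls below ``min_correlation``.
    """
    from skimage.registration import phase_cross_correlation

    a = donor.data[0].astype(np.float64)
    b = acceptor.data[0].astype(np.float64)
    shift, _, _ = phase_cross_correlation(a, b, normalization=None)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    shifted = np.roll(acceptor.data, (dy, dx), axis=(1, 2))
    bs = shifted[0].astype(np.float64)
    va = a - a.mean()
    vb = bs - bs.mean()
    denom = np.sqrt((va**2).sum() * (vb**2).sum())
    corr = float((va * vb).sum() / denom) if denom > 0 else 0.0
    if corr < min_correlation:
        raise PipelineError(
            f"channels appear unregistered (frame-0 correlation {corr:.2f} < "
            f"{min_correlation})"
        )
    return acceptor.with_data(shifted), (dy, dx), corr


# ---------------------------------------------------------------------------
# ROI generation
# ---------------------------------------------------------------------------


def auto_section_rois(
    scenario: ScenarioConfig, width: float = 10.0, length: float = 20.0
) -> list[RegionOfInterest]:
    """One edge-scan rectangle per angular section, centred on the initial
    edge and oriented along the outward radial normal."""
    cell = scenario.cell
    rois = []
    dtheta = 360.0 / cell.n_sections
    for s in range(cell.n_sections):
        ang = cell.section_start_deg + (s + 0.5) * dtheta
        rad = math.radians(ang)
        cx = cell.center[0] + cell.radius * math.cos(rad)
        cy = cell.center[1] + cell.radius * math.sin(rad)
        rois.append(
            RegionOfInterest(
                id=f"sec{s}",
                kind="rectangle",
                center=(cx, cy),
                orientation=ang,
                width=width,
                length=length,
            )
        )
    return rois


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _window_slice(ratio: RatioMovie, window_s: float | None) -> slice:
    if window_s is None:
        return slice(None)
    n = int(round(window_s / ratio.frame_interval)) + 1
    return slice(0, max(2, min(n, ratio.n_frames)))


def _windowed_ratio(ratio: RatioMovie, sl: slice) -> RatioMovie:
    if sl == slice(None):
        return ratio
    return RatioMovie(
        data=ratio.data[sl],
        pixel_size=ratio.pixel_size,
        frame_interval=ratio.frame_interval,
    )


def run_analyze(
    config: PipelineConfig, scenario_dir: str | Path, out_dir: str | Path
) -> Path:
    """Full analysis of a scenario directory; writes a report directory.

    Outputs: ``ratio.tif`` (float32, NaN sentinel), ``mask.tif``,
    ``edges.csv``, ``traces.csv``, ``class_summary.csv``, ``rois.csv``,
    ``provenance.json`` and ``report.json``.  Partial outputs are removed on
    failure.
    """
    scenario_dir = Path(scenario_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _analyze(config, scenario_dir, out_dir)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _analyze(config: PipelineConfig, scenario_dir: Path, out_dir: Path) -> Path:
    corr_cfg = config.correction
    ana = config.analysis
    t0 = time.perf_counter()

    donor = read_stack(scenario_dir / "donor.tif", role="donor")
    acceptor = read_stack(scenario_dir / "acceptor.tif", role="raw_acceptor")
    log.info("analyze: loaded %d frames of %s", donor.n_frames, donor.frame_shape)

    acceptor, shift, corr0 = register_channels(donor, acceptor)
    log.info("analyze: registration shift=%s corr=%.3f", shift, corr0)

    flatfield = None
    if corr_cfg["flatfield"] and (scenario_dir / "flatfield.tif").exists():
        flatfield = read_stack(scenario_dir / "flatfield.tif", role="flatfield")

    controls = None
    if corr_cfg["bleedthrough"] == "controls":
        pair = (
            scenario_dir / "control_donor_only_ref.tif",
            scenario_dir / "control_donor_only_fret.tif",
        )
        if pair[0].exists() and pair[1].exists():
            ref = read_stack(pair[0], role="control_donor_only")
            fr = read_stack(pair[1], role="raw_acceptor")
            # controls enter the slope fit shading/background-corrected
            from .correction import correct_shading_background

            ref_c, _ = correct_shading_background(ref, flatfield, corr_cfg["background"])
            fr_c, _ = correct_shading_background(fr, flatfield, corr_cfg["background"])
            controls = {"donor_only": (ref_c, fr_c)}

    result = run_correction_chain(
        donor,
        acceptor,
        flatfield=flatfield,
        background=corr_cfg["background"],
        photobleach=corr_cfg["photobleach"],
        alpha=corr_cfg["alpha"] if controls is None else None,
        beta=corr_cfg["beta"],
        controls=controls,
        epsilon=corr_cfg["epsilon"],
        seed=config.seed or 0,
    )
    ratio, mask = result.ratio, result.mask
    log.info(
        "analyze: correction chain done (alpha=%.4f, k=%s) in %.1fs",
        result.model.alpha,
        result.model.bleach_rates,
        time.perf_counter() - t0,
    )

    # ---- ROIs ----
    scenario_cfg = config.scenario
    if scenario_cfg is None and (scenario_dir / "scenario.yaml").exists():
        scenario_cfg = load_scenario_config(scenario_dir / "scenario.yaml")
    if config.rois not in (None, "auto"):
        rois = load_rois(config.rois)
    elif scenario_cfg is not None:
        rois = auto_section_rois(
            scenario_cfg, width=ana["edge_roi_width"], length=ana["edge_roi_length"]
        )
    else:
        rois = []
    rect_rois = [r for r in rois if r.kind == "rectangle"]

    # ---- edge dynamics over the section analysis window ----
    sl = _window_slice(ratio, ana["section_window_s"])
    ratio_win = _windowed_ratio(ratio, sl)
    traces: list[EdgeTrace] = []
    for roi in rect_rois:
        try:
            traces.append(detect_edge(ratio_win, roi))
        except ValueError as exc:
            log.warning("analyze: edge detection skipped for %s (%s)", roi.id, exc)
    labels = classify_sections(traces, v0=ana["v0"])

    section_means = {}
    for roi in rect_rois:
        if roi.id not in labels:
            continue
        try:
            tr = roi_trace(ratio_win, roi, interior_frac_warn=0.0)
        except ValueError:
            continue
        section_means[roi.id] = float(np.nanmean(tr.values))
    class_summary = None
    if section_means:
        try:
            class_summary = summarize_classes(section_means, labels)
        except ValueError as exc:
            log.warning("analyze: class summary unavailable (%s)", exc)

    # ---- wave / onset traces on the full movie ----
    wave_report = None
    if ana["wave_roi"]:
        wroi = RegionOfInterest(
            id="wave",
            kind="square",
            center=tuple(ana["wave_roi"]["center"]),
            area=float(ana["wave_roi"].get("area", 4.0)),
        )
        wtrace = roi_trace(ratio, wroi)
        dff = delta_f_over_f(wtrace, m=ana["m"])
        maxima = detect_maxima(
            dff,
            wtrace.times,
            smoothing_window_s=ana["smoothing_s"],
            min_prominence_sd=ana["prominence_sd"],
        )
        wave_report = {"n_maxima": int(maxima.size), "maxima_times_s": maxima.tolist()}
        try:
            est = estimate_period(maxima, max_intervals=ana["period_intervals"])
            wave_report.update(
                {
                    "mean_period_s": est.mean_period,
                    "sem_s": est.sem,
                    "n_intervals": est.n_intervals,
                }
            )
        except ValueError as exc:
            wave_report["error"] = str(exc)

    onset_report = None
    if ana["onset_roi"] and ana["stimulus_time"] is not None:
        oroi = RegionOfInterest(
            id="onset",
            kind="square",
            center=tuple(ana["onset_roi"]["center"]),
            area=float(ana["onset_roi"].get("area", 4.0)),
        )
        otrace = roi_trace(ratio, oroi)
        odff = delta_f_over_f(otrace, m=ana["m"])
        latency = detect_onset(
            odff,
            otrace.times,
            stimulus_time=float(ana["stimulus_time"]),
            k=ana["onset_k"],
            sustain_s=ana["onset_sustain_s"],
        )
        onset_report = {
            "stimulus_time_s": float(ana["stimulus_time"]),
            "latency_s": latency,
        }

    # ---- outputs ----
    write_stack(
        ChannelStack(
            ratio.data, role="other",
            pixel_size=ratio.pixel_size, frame_interval=ratio.frame_interval,
        ),
        out_dir / "ratio.tif",
    )
    write_stack(
        ChannelStack(
            mask.mask.astype(np.uint8), role="other",
            pixel_size=ratio.pixel_size, frame_interval=ratio.frame_interval,
        ),
        out_dir / "mask.tif",
    )
    save_rois(rois, out_dir / "rois.csv")
    save_traces_csv(traces, out_dir / "edges.csv")

    if class_summary is not None:
        import csv as _csv

        with open(out_dir / "class_summary.csv", "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["class", "mean_ratio", "normalized", "sem", "n_sections"])
            for label in sorted(class_summary.means):
                w.writerow(
                    [
                        label,
                        class_summary.means[label],
                        class_summary.normalized[label],
                        class_summary.sems[label],
                        class_summary.counts[label],
                    ]
                )

    if ana["montage"]:
        mroi = next((r for r in rois if r.id == ana["montage"]["roi"]), None)
        if mroi is not None:
            montage = build_montage(ratio, mroi, float(ana["montage"]["interval_s"]))
            write_stack(
                ChannelStack(
                    np.nan_to_num(montage.image[None], nan=0.0),
                    role="other",
                    pixel_size=ratio.pixel_size,
                    frame_interval=ratio.frame_interval,
                ),
                out_dir / "montage.tif",
            )
            save_montage_png(montage, out_dir / "montage.png")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "registration": {"shift_px": list(shift), "correlation": corr0},
        "correction": result.provenance,
        "analysis": {k: v for k, v in ana.items()},
        "rois": [r.id for r in rois],
    }
    report = {
        "n_frames": donor.n_frames,
        "pixel_size_um": donor.pixel_size,
        "frame_interval_s": donor.frame_interval,
        "alpha": result.model.alpha,
        "bleach_rates": result.model.bleach_rates,
        "section_labels": labels,
        "section_mean_ratios": section_means,
        "class_summary": None
        if class_summary is None
        else {
            "means": class_summary.means,
            "normalized": class_summary.normalized,
            "sems": class_summary.sems,
            "counts": class_summary.counts,
        },
        "edge_mean_velocities_um_s": {tr.roi_id: tr.mean_velocity for tr in traces},
        "wave": wave_report,
        "onset": onset_report,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, sort_keys=True, indent=1, default=_json_default)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=_json_default)
    log.info("analyze: report written to %s in %.1fs", out_dir, time.perf_counter() - t0)
    return out_dir


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# recover
# ---------------------------------------------------------------------------


def run_recover(
    config: PipelineConfig,
    scenario_dir: str | Path,
    report_dir: str | Path,
    out_path: str | Path | None = None,
) -> dict:
    """Score a report against the scenario ground truth; write scorecard."""
    scenario_dir = Path(scenario_dir)
    report_dir = Path(report_dir)
    if not (scenario_dir / "truth.json").exists():
        raise PipelineError(f"missing ground-truth sidecar in {scenario_dir}")
    truth = load_truth(scenario_dir)
    with open(report_dir / "report.json") as fh:
        report = json.load(fh)
    tol = config.tolerances

    card: dict = {"checks": {}, "passed": True}

    def check(name, value, ok):
        card["checks"][name] = {"value": value, "pass": bool(ok)}
        if not ok:
            card["passed"] = False

    # period
    true_period = truth.get("wave_period_s")
    if true_period is not None:
        wave = report.get("wave") or {}
        est = wave.get("mean_period_s")
        if est is None:
            check("period_error_s", None, False)
        else:
            check("period_error_s", abs(est - true_period), abs(est - true_period) <= tol["period_tol_s"])

    # class ratios
    levels = {int(k): v for k, v in (truth.get("class_levels") or {}).items()}
    tlabels = {int(k): v for k, v in (truth.get("section_labels") or {}).items()}
    summary = report.get("class_summary")
    if levels and summary:
        true_norm: dict[str, list[float]] = {}
        for sid, label in tlabels.items():
            true_norm.setdefault(label, []).append(levels.get(sid, 1.0))
        for label, vals in true_norm.items():
            if label == "stalling":
                continue
            est = (summary.get("normalized") or {}).get(label)
            true_val = float(np.mean(vals))
            if est is None:
                check(f"class_{label}_error", None, False)
            else:
                err = abs(est - true_val) / true_val
                check(f"class_{label}_error", err, err <= tol["class_tol"])

    # onset latency
    if truth.get("stimulus_time_s") is not None:
        onset = report.get("onset") or {}
        latency = onset.get("latency_s")
        check(
            "onset_latency_s",
            latency,
            latency is not None and latency <= tol["onset_max_s"],
        )

    # edge velocities of scheduled (moving) sections
    edge_pos = truth.get("edge_positions_um") or {}
    vels = report.get("edge_mean_velocities_um_s") or {}
    dt = truth.get("frame_interval_s", 1.0)
    window = config.analysis.get("section_window_s")
    for sid_str, pos in edge_pos.items():
        pos = np.asarray(pos)
        n = len(pos)
        if window is not None:
            n = min(n, int(round(window / dt)) + 1)
        if n < 2:
            continue
        t = np.arange(n) * dt
        v_true = float(np.polyfit(t, pos[:n], 1)[0])  # same estimator as measured
        if abs(v_true) < 1e-6:
            continue
        v_est = vels.get(f"sec{sid_str}")
        if v_est is None:
            check(f"edge_velocity_sec{sid_str}_error", None, False)
        else:
            err = abs(v_est - v_true) / abs(v_true)
            check(f"edge_velocity_sec{sid_str}_error", err, err <= tol["edge_velocity_tol"])

    # mask overlap
    mask_path = report_dir / "mask.tif"
    truth_mask_path = scenario_dir / "truth_mask.tif"
    if mask_path.exists() and truth_mask_path.exists():
        est_mask = read_stack(mask_path).data.astype(bool)
        true_mask = read_stack(truth_mask_path).data.astype(bool)
        n = min(est_mask.shape[0], true_mask.shape[0])
        inter = (est_mask[:n] & true_mask[:n]).sum()
        union = (est_mask[:n] | true_mask[:n]).sum()
        jac = float(inter / union) if union else 0.0
        check("mask_jaccard", jac, jac >= tol["jaccard_min"])

    if out_path is None:
        out_path = report_dir / "scorecard.json"
    with open(out_path, "w") as fh:
        json.dump(card, fh, sort_keys=True, indent=1, default=_json_default)
    log.info("recover: scorecard %s (passed=%s)", out_path, card["passed"])
    return card
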