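"""End-to-end orchestration of the method variants and the simulation study.

A method variant names the surface the disturbance registration runs on:

====== ========== ===========
name   filter     feature
====== ========== ===========
BM     none       intensity
PM     none       phase
SBM    srad_w1    intensity
SPM    srad_w1    phase
SWBM   srad_w2    intensity
SWPM   srad_w2    phase
SWOM   srad_w2    orientation
SWPOM  srad_w2    combined
====== ========== ===========

``run_variant`` executes filter -> feature -> register (both far-from-wall
bands against frame 1) -> average -> align -> track for one variant;
``run_study`` simulates a sequence with known wall motion and disturbance,
runs the requested variants, and reports disturbance-recovery errors,
wall-motion errors against the preset trajectory, and correlation /
Bland-Altman agreement against the disturbance-free tracking reference.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ArgumentError, ImageSequence, MotionTrajectory, RigidDisturbance
from . import evalstats, monogenic, register, track, ultrasim

logger = logging.getLogger("carostab")

#: variant name -> (filter_kind, feature_mode); the table is total.
VARIANTS = {
    "BM": ("none", "intensity"),
    "PM": ("none", "phase"),
    "SBM": ("srad_w1", "intensity"),
    "SPM": ("srad_w1", "phase"),
    "SWBM": ("srad_w2", "intensity"),
    "SWPM": ("srad_w2", "phase"),
    "SWOM": ("srad_w2", "orientation"),
    "SWPOM": ("srad_w2", "combined"),
}


@dataclass
class RunConfig:
    """Analysis-side parameters of a variant run (pixel units)."""

    subimage_spec: register.SubimageSpec = field(
        default_factory=register.SubimageSpec)
    bounds: register.SearchBounds = field(default_factory=register.SearchBounds)
    roi: track.ROISpec | None = None
    search: track.SearchSpec = field(default_factory=track.SearchSpec)
    sigma1: float | None = None  # None -> auto from band height
    region_offsets: object = None  # known (n, 2) px offsets, "auto", or None
    track_on: str = "intensity"  # or "combined": track feature images
    refine: bool = True

    def __post_init__(self) -> None:
        if self.track_on not in ("intensity", "combined"):
            raise ArgumentError("track_on must be 'intensity' or 'combined'")


def analysis_config(profile) -> RunConfig:
    """Default analysis geometry for a simulation profile.

    Bands are placed just clear of the moving vessel band, the tracking ROI
    straddles the deep blood/wall interface, and the registration bounds
    cover the profile's disturbance amplitudes with margin.
    """
    prof = ultrasim.PROFILES[profile] if isinstance(profile, str) else profile
    rows, cols = prof.shape
    s = prof.pixel_spacing_mm
    wall = prof.wall_model()
    reach_mm = wall.outer_reach_mm + prof.taper_mm
    wall_top = int(np.floor((wall.center_row_mm - reach_mm) / s))
    wall_bot = int(np.ceil((wall.center_row_mm + reach_mm) / s))
    frac = min(wall_top, rows - 1 - wall_bot) / rows
    frac = max(0.05, np.floor(frac * 100) / 100.0)
    spec = register.SubimageSpec(upper_frac=frac, lower_frac=frac,
                                 wall_band=(wall_top, wall_bot))

    # bounds cover drift plus two coincident glitches with margin
    max_long_mm = prof.drift_amp[0] + 2 * prof.glitch_amp[0]
    max_rad_mm = prof.drift_amp[1] + 2 * prof.glitch_amp[1]
    max_theta = prof.drift_amp[2] + 2 * prof.glitch_amp[2]
    bounds = register.SearchBounds(
        shift_row=float(np.ceil(max_rad_mm / s)) + 3,
        shift_col=float(np.ceil(max_long_mm / s)) + 3,
        theta=round(max_theta + 0.5, 1), theta_step=0.5)

    interface_row = int(round((wall.center_row_mm + wall.radius_mm) / s))
    roi_h = min(24, 2 * int(wall.radius_mm / s))
    roi_w = min(64, cols // 2)
    roi = track.ROISpec(row=interface_row - roi_h // 2 - 2,
                        col=(cols - roi_w) // 2, height=roi_h, width=roi_w)
    wall_motion_px = int(np.ceil(
        max(prof.amp_rad_mm, prof.amp_long_mm) / s)) + 4
    search = track.SearchSpec(max_displacement=min(
        wall_motion_px + int(np.ceil(max(max_long_mm, max_rad_mm) / s)),
        roi.row - 1, rows - roi.row - roi_h - 1,
        roi.col - 1, cols - roi.col - roi_w - 1))
    return RunConfig(subimage_spec=spec, bounds=bounds, roi=roi, search=search)


@dataclass
class VariantResult:
    """Outputs of one end-to-end variant run."""

    variant: str
    disturbance_px: list            # per-frame RegistrationResult
    disturbance: RigidDisturbance   # averaged estimate, physical units
    aligned: ImageSequence
    motion: MotionTrajectory
    n_boundary_hits: int


def run_variant(sequence: ImageSequence, variant: str,
                config: RunConfig | None = None) -> VariantResult:
    """Run one method variant end-to-end on a sequence.

    BM runs the registration directly on intensity (no filtering, no feature
    extraction); the S*/SW* variants insert standard / altered SRAD, and
    PM/…/SWPOM registration surfaces per the variant table.  Deterministic
    given its inputs.
    """
    key = variant.upper()
    if key not in VARIANTS:
        raise ArgumentError(f"unknown variant {variant!r}; "
                            f"expected one of {sorted(VARIANTS)}")
    config = config or RunConfig()
    t0 = time.perf_counter()
    results = register.estimate_disturbance(
        sequence, VARIANTS[key], spec=config.subimage_spec,
        bounds=config.bounds,
        mono_config=(None if config.sigma1 is None else
                     monogenic.MonogenicConfig(sigma1=config.sigma1)),
        region_offsets=config.region_offsets, refine=config.refine)
    logger.info("%s: registration done in %.1fs", key, time.perf_counter() - t0)
    est = register.results_to_disturbance(results, sequence.pixel_spacing_mm,
                                          sequence.times_s)
    aligned = register.align_sequence(sequence, results)
    if config.roi is None:
        raise ArgumentError("config.roi is required to track the wall")
    frames = aligned
    if config.track_on == "combined":
        mono_cfg = monogenic.MonogenicConfig(sigma1=config.sigma1 or 4.0)
        feat = np.stack([monogenic.make_feature_image(
            f, mono_cfg, "combined") for f in aligned.frames])
        frames = ImageSequence(feat, aligned.pixel_spacing_mm,
                               aligned.frame_interval_s)
    motion, n_hits = track.track_sequence(frames, config.roi, config.search)
    logger.info("%s: pipeline done in %.1fs", key, time.perf_counter() - t0)
    return VariantResult(key, results, est, aligned, motion, n_hits)


def _motion_metrics(est: MotionTrajectory, preset: MotionTrajectory,
                    reference: MotionTrajectory) -> dict:
    """Error vs the preset trajectory and agreement vs the tracking reference."""
    out = {
        "nrmse_amplitude_vs_preset": evalstats.nrmse(est.amplitude_mm,
                                                     preset.amplitude_mm),
        "nrmse_long_vs_preset": evalstats.nrmse(est.d_long_mm, preset.d_long_mm),
        "nrmse_rad_vs_preset": evalstats.nrmse(est.d_rad_mm, preset.d_rad_mm),
    }
    rep = evalstats.agreement_report(est.amplitude_mm, reference.amplitude_mm)
    out["agreement_vs_reference"] = rep.as_dict()
    return out


def run_study(profile="fast", variants=("BM", "SWPOM"), seed: int = 0,
              out_dir=None, config: RunConfig | None = None) -> dict:
    """Simulate one sequence and evaluate the requested variants on it.

    The report contains, per variant: RMSE/NRMSE of the extracted disturbance
    against the preset one (per component), wall-motion NRMSE against the
    preset trajectory, and regression/Bland-Altman agreement of the motion
    amplitude against the disturbance-free tracking reference.  A REF row
    (alignment by the ground-truth disturbance) and a NONE row (no
    suppression) are always included.  Deterministic per seed.
    """
    variants = [v.upper() for v in variants]
    if not variants:
        raise ArgumentError("need at least one variant")
    for v in variants:
        if v not in VARIANTS:
            raise ArgumentError(f"unknown variant {v!r}")
    prof = ultrasim.PROFILES[profile] if isinstance(profile, str) else profile
    config = config or analysis_config(prof)

    t0 = time.perf_counter()
    data = ultrasim.simulate_dataset(prof, seed=seed, with_clean=True)
    seq, clean = data["sequence"], data["clean_sequence"]
    motion_gt, dist_gt = data["motion"], data["disturbance"]
    logger.info("simulation done in %.1fs", time.perf_counter() - t0)

    reference, _ = track.track_sequence(clean, config.roi, config.search)

    s = seq.pixel_spacing_mm
    gt_transforms = register.disturbance_to_transforms(dist_gt, s)
    ref_aligned = register.align_sequence(seq, gt_transforms)
    ref_motion, _ = track.track_sequence(ref_aligned, config.roi, config.search)
    none_motion, _ = track.track_sequence(seq, config.roi, config.search)

    gt_offsets = np.column_stack([dist_gt.d_rad_mm / s, dist_gt.d_long_mm / s])
    report = {
        "profile": prof.name, "seed": seed, "n_frames": seq.n_frames,
        "pixel_spacing_mm": s, "frame_interval_s": seq.frame_interval_s,
        "disturbance_baseline_rmse": {
            comp: evalstats.rmse(np.zeros(seq.n_frames), vals)
            for comp, vals in dist_gt.components().items()},
        "rows": {},
    }
    report["rows"]["REF"] = _motion_metrics(ref_motion, motion_gt, reference)
    report["rows"]["NONE"] = _motion_metrics(none_motion, motion_gt, reference)

    results = {}
    for v in variants:
        cfg_v = config
        if config.region_offsets is None:
            # paper-style region propagation from the preset disturbance
            cfg_v = RunConfig(subimage_spec=config.subimage_spec,
                              bounds=config.bounds, roi=config.roi,
                              search=config.search, sigma1=config.sigma1,
                              track_on=config.track_on, refine=config.refine)
            cfg_v.region_offsets = gt_offsets
        res = run_variant(seq, v, cfg_v)
        results[v] = res
        row = _motion_metrics(res.motion, motion_gt, reference)
        row["disturbance_rmse"] = {
            comp: evalstats.rmse(est_vals, gt_vals)
            for (comp, gt_vals), est_vals in zip(
                dist_gt.components().items(),
                (res.disturbance.d_long_mm, res.disturbance.d_rad_mm,
                 res.disturbance.theta_deg))}
        row["disturbance_nrmse"] = {
            comp: evalstats.nrmse(est_vals, gt_vals)
            for (comp, gt_vals), est_vals in zip(
                dist_gt.components().items(),
                (res.disturbance.d_long_mm, res.disturbance.d_rad_mm,
                 res.disturbance.theta_deg))}
        row["n_boundary_hits"] = res.n_boundary_hits
        report["rows"][v] = row

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        rows = []
        for name, row in report["rows"].items():
            flat = {"method": name,
                    "motion_nrmse": row["nrmse_amplitude_vs_preset"],
                    "r_vs_reference": row["agreement_vs_reference"]["r"]}
            for comp, val in row.get("disturbance_nrmse", {}).items():
                flat[f"dist_nrmse_{comp}"] = val
            rows.append(flat)
        pd.DataFrame(rows).to_csv(out_dir / "summary.csv", index=False)
        motion_gt.to_csv(out_dir / "motion_gt.csv")
        dist_gt.to_csv(out_dir / "disturbance_gt.csv")
        for v, res in results.items():
            res.motion.to_csv(out_dir / f"motion_{v.lower()}.csv")
            res.disturbance.to_csv(out_dir / f"disturbance_{v.lower()}.csv")
    report["_results"] = results
    report["_reference_motion"] = reference
    report["_preset_motion"] = motion_gt
    report["_preset_disturbance"] = dist_gt
    return report
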