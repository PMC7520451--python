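"""End-to-end strike analysis: from marker trajectories and a raw pressure
record to joint kinematics, muscle strain, endocast volume and expansion
power, with per-strike summary scalars and per-individual mean ± s.e.m.
reporting.

Processing order for one strike:

1. interpolate short marker gaps; low-pass filter marker coordinates
   (distances and landmark animation downstream use the filtered markers);
2. fit per-frame rigid transforms for every bone and for the body plane
   (built from the designated trunk markers), then low-pass filter the pose
   sequences as quaternion + translation;
3. animate jaw-tip landmarks, compute gape, locate peak gape (t = 0) and
   the pre-strike baseline window;
4. decompose each joint's relative motion (intrinsic zyx) and re-zero to
   the baseline;
5. muscle lengths (intramuscular chains and fiber landmarks), mean initial
   lengths from the baseline, strain and strain rate;
6. dynamic-endocast volume and dV/dt;
7. pressure: filter at the native rate, re-zero to ambient, resample onto
   frame times; instantaneous power = (-p) * dV/dt; peak-power window
   (frames within 25% of maximum power); summary scalars and mass-/volume-
   normalized peak power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .endocast import EndocastDefinition, VolumeTrace, endocast_trace
from .io import TrajectorySet, read_pressure, read_trajectories, read_reference_geometry
from .kinematics import (AnatomicalCS, JointCS, KinematicTrace, baseline_slice,
                         find_peak_gape, gape_trace, jcs_decompose, rezero_trace)
from .power import (PressureTrace, instantaneous_power, normalize_power,
                    peak_power_mask, process_pressure, summarize_individuals,
                    synchronize)
from .rigid_body import (BoneDefinition, PoseSequence, animate_landmarks,
                         filter_pose_sequence, filter_trajectories,
                         fit_pose_sequence, interpolate_gaps, make_body_plane,
                         tracking_precision)
from .strain import (StrainTrace, chain_lengths, fiber_muscle_length,
                     mean_initial_length, peak_during_window, strain_and_rate)

log = logging.getLogger("suctionpower")

BODY_PLANE = "body_plane"


@dataclass
class StrikeResult:
    """Per-strike summary scalars."""

    individual: str
    peak_gape_frame: int
    peak_gape_time_s: float
    peak_pressure_pa: float          # most sub-ambient (minimum) pressure
    max_volume_cm3: float
    max_delta_volume_cm3: float
    max_dvdt_cm3_s: float
    max_power_w: float
    tracking_precision_mm: float | None
    peak_rotations_deg: dict[str, float] = field(default_factory=dict)
    peak_strains_pct: dict[str, float] = field(default_factory=dict)
    peak_rates_li_s: dict[str, float] = field(default_factory=dict)
    normalized_power: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "individual": self.individual,
            "peak_gape_frame": self.peak_gape_frame,
            "peak_gape_time_s": self.peak_gape_time_s,
            "peak_pressure_pa": self.peak_pressure_pa,
            "max_volume_cm3": self.max_volume_cm3,
            "max_delta_volume_cm3": self.max_delta_volume_cm3,
            "max_dvdt_cm3_s": self.max_dvdt_cm3_s,
            "max_power_w": self.max_power_w,
            "tracking_precision_mm": self.tracking_precision_mm,
        }
        row.update({f"rot_{k}_deg": v for k, v in self.peak_rotations_deg.items()})
        row.update({f"strain_{k}_pct": v for k, v in self.peak_strains_pct.items()})
        row.update({f"rate_{k}_Li_s": v for k, v in self.peak_rates_li_s.items()})
        row.update(self.normalized_power)
        return row


@dataclass
class StrikeAnalysis:
    """All intermediate traces of one analyzed strike plus its summary."""

    config: StudyConfig
    poses: dict[str, PoseSequence]
    kinematics: dict[str, KinematicTrace]
    gape_cm: np.ndarray
    peak_gape_frame: int
    baseline: slice
    strains: dict[str, StrainTrace]
    volume: VolumeTrace | None
    pressure: PressureTrace | None
    pressure_at_frames_pa: np.ndarray | None
    power_w: np.ndarray | None
    peak_mask: np.ndarray | None
    peak_block: slice | None
    result: StrikeResult


def _landmark_lookup(name: str, bones: dict[str, BoneDefinition],
                     poses: dict[str, PoseSequence],
                     trajectories: TrajectorySet) -> np.ndarray:
    """World trajectory of a named point: a tracked marker if present,
    otherwise a virtual landmark animated with its bone."""
    if name in trajectories.markers:
        return trajectories.get(name)
    for bone_name, bone in bones.items():
        if name in bone.landmarks:
            return animate_landmarks(poses[bone_name], bone, [name]).get(name)
    raise KeyError(f"point {name!r} is neither a marker nor a bone landmark")


def analyze_strike(config: StudyConfig, bones: dict[str, BoneDefinition],
                   trajectories: TrajectorySet,
                   pressure_time_s: np.ndarray | None = None,
                   pressure_pa: np.ndarray | None = None,
                   sync_offset_s: float = 0.0) -> StrikeAnalysis:
    """Run the full pipeline on one strike. ``pressure_pa`` must already be
    in pascals (apply the mV calibration when reading the CSV)."""
    config.validate()
    cutoff = config.filters.cutoff_kinematics_hz

    ts_gap = trajectories.with_coords(interpolate_gaps(trajectories.coords))
    ts_filt = filter_trajectories(trajectories, cutoff)

    # --- rigid bodies (poses fit on gap-filled raw markers, then the pose
    # sequences themselves are low-pass filtered)
    poses: dict[str, PoseSequence] = {}
    if config.body_plane_markers:
        bp_def, bp_pose = make_body_plane(ts_gap, config.body_plane_markers)
        bones = {**bones, BODY_PLANE: bp_def}
        poses[BODY_PLANE] = filter_pose_sequence(bp_pose, cutoff)
    for spec in config.bones:
        bone = bones[spec.name]
        poses[spec.name] = filter_pose_sequence(fit_pose_sequence(bone, ts_gap), cutoff)

    # --- tracking precision from intra-bone marker pairs
    pairs = []
    for spec in config.bones:
        mk = bones[spec.name].marker_names
        pairs += [(mk[i], mk[j]) for i in range(len(mk)) for j in range(i + 1, len(mk))]
    mk = config.body_plane_markers
    pairs += [(mk[i], mk[j]) for i in range(len(mk)) for j in range(i + 1, len(mk))]
    precision_mm = None
    if pairs:
        try:
            # coordinate units are cm by convention -> mm
            precision_mm = tracking_precision(trajectories, pairs) * 10.0
        except ValueError:
            log.warning("tracking precision unavailable: no co-visible pairs")

    # --- gape and timing
    if config.gape_landmarks is None:
        raise ValueError("config.gape_landmarks required to time the strike")
    upper = _landmark_lookup(config.gape_landmarks[0], bones, poses, ts_filt)
    lower = _landmark_lookup(config.gape_landmarks[1], bones, poses, ts_filt)
    gape = gape_trace(upper, lower)
    peak_frame, peak_time = find_peak_gape(gape, config.frame_rate_hz)
    baseline = baseline_slice(peak_frame, config.frame_rate_hz,
                              trajectories.n_frames,
                              config.baseline_window_s,
                              config.baseline_end_before_peak_s)

    # --- joint kinematics
    kinematics: dict[str, KinematicTrace] = {}
    for j in config.joints:
        jcs = JointCS(j.name, AnatomicalCS(np.asarray(j.origin, float),
                                           j.axes_matrix()),
                      j.proximal, j.distal)
        co_valid = poses[j.distal].valid & poses[j.proximal].valid
        if not co_valid.any():
            raise ValueError(f"joint {j.name!r}: no frame with both poses valid")
        trace = jcs_decompose(poses[j.distal], poses[j.proximal], jcs,
                              setup_frame=int(np.argmax(co_valid)))
        kinematics[j.name] = rezero_trace(trace, baseline)

    # --- muscle strain
    strains: dict[str, StrainTrace] = {}
    for m in config.muscles:
        for key, length in chain_lengths(ts_filt, m.markers).items():
            li = mean_initial_length([length], [baseline])
            strains[f"{m.name}/{key}"] = strain_and_rate(
                length, li, config.frame_rate_hz, name=f"{m.name}/{key}")
    for fm in config.fiber_muscles:
        fiber_trajs = [( _landmark_lookup(o, bones, poses, ts_filt),
                         _landmark_lookup(i, bones, poses, ts_filt))
                       for o, i in fm.fibers]
        length = fiber_muscle_length(fiber_trajs)
        li = mean_initial_length([length], [baseline])
        strains[fm.name] = strain_and_rate(length, li, config.frame_rate_hz,
                                           name=fm.name)

    # --- endocast volume
    volume = None
    if config.endocast is not None:
        coords = np.stack(
            [_landmark_lookup(n, bones, poses, ts_filt)
             for n in config.endocast.landmarks], axis=1)
        landmark_ts = TrajectorySet(list(config.endocast.landmarks), coords,
                                    config.frame_rate_hz)
        volume = endocast_trace(landmark_ts, EndocastDefinition(
            list(config.endocast.landmarks), config.endocast.alpha,
            config.endocast.bilateral_factor))

    # --- pressure, power, peak-power window
    pressure = p_frames = power = mask = block = None
    if pressure_time_s is not None and pressure_pa is not None and volume is not None:
        fr, pr = config.frame_rate_hz, config.pressure_rate_hz
        p_baseline = slice(int(baseline.start / fr * pr), int(baseline.stop / fr * pr))
        pressure = process_pressure(pressure_time_s, pressure_pa, pr,
                                    config.filters.cutoff_pressure_hz, p_baseline)
        frame_times = np.arange(trajectories.n_frames) / fr
        p_frames = synchronize(pressure, frame_times, sync_offset_s)
        power = instantaneous_power(p_frames, volume.dvdt_m3_s)
        mask, block = peak_power_mask(power)

    # --- summary scalars
    peak_rot = {}
    peak_str = {}
    peak_rate = {}
    if mask is not None:
        for name, tr in kinematics.items():
            peak_rot[name] = peak_during_window(tr.rz_deg, mask, mode="absmax")
        for name, st in strains.items():
            peak_str[name] = peak_during_window(st.strain_pct, mask, mode="max")
            peak_rate[name] = peak_during_window(st.rate_li_per_s, mask, mode="max")

    max_vol = float(np.nanmax(volume.total_cm3)) if volume is not None else np.nan
    min_vol = float(np.nanmin(volume.total_cm3)) if volume is not None else np.nan
    max_dv = float(np.nanmax(volume.dvdt_cm3_s)) if volume is not None else np.nan
    max_power = float(np.nanmax(power)) if power is not None else np.nan
    normalized = {}
    if power is not None and not np.isnan(max_power):
        normalized = normalize_power(max_power, config.masses_kg or None,
                                     max_vol - min_vol if volume is not None else None)

    result = StrikeResult(
        individual=config.individual,
        peak_gape_frame=peak_frame,
        peak_gape_time_s=peak_time,
        peak_pressure_pa=float(np.nanmin(p_frames)) if p_frames is not None else np.nan,
        max_volume_cm3=max_vol,
        max_delta_volume_cm3=max_vol - min_vol,
        max_dvdt_cm3_s=max_dv,
        max_power_w=max_power,
        tracking_precision_mm=precision_mm,
        peak_rotations_deg=peak_rot,
        peak_strains_pct=peak_str,
        peak_rates_li_s=peak_rate,
        normalized_power=normalized,
    )
    return StrikeAnalysis(config, poses, kinematics, gape, peak_frame, baseline,
                          strains, volume, pressure, p_frames, power, mask,
                          block, result)


def analyze_files(config_path, trajectories_path, pressure_path,
                  outdir=None) -> StrikeAnalysis:
    """File-based front end: load config, reference geometry, trajectories
    and pressure, run :func:`analyze_strike`, optionally write outputs."""
    config_path = Path(config_path)
    config = StudyConfig.from_yaml(config_path)
    if config.reference_geometry is None:
        raise ValueError("config must name a reference_geometry CSV")
    bones = read_reference_geometry(config_path.parent / config.reference_geometry)
    ts = read_trajectories(trajectories_path, config.frame_rate_hz, config.units)
    p_t, p_pa = read_pressure(pressure_path,
                              config.pressure_calibration_pa_per_mv,
                              config.pressure_rate_hz)
    analysis = analyze_strike(config, bones, ts, p_t, p_pa)
    if outdir is not None:
        write_outputs(analysis, outdir)
    return analysis


def write_outputs(analysis: StrikeAnalysis, outdir) -> None:
    """Write per-trace CSVs and the one-row per-strike summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pf = analysis.peak_gape_frame
    for name, tr in analysis.kinematics.items():
        tr.to_dataframe(pf).to_csv(outdir / f"kinematics_{name}.csv",
                                   index=False, float_format="%.9g")
    for name, st in analysis.strains.items():
        st.to_dataframe(pf).to_csv(
            outdir / f"strain_{name.replace('/', '_')}.csv",
            index=False, float_format="%.9g")
    if analysis.volume is not None:
        analysis.volume.to_dataframe(pf).to_csv(outdir / "volume.csv",
                                                index=False, float_format="%.9g")
    if analysis.power_w is not None:
        fr = analysis.config.frame_rate_hz
        n = len(analysis.power_w)
        pd.DataFrame({
            "frame": np.arange(n),
            "time_s": np.arange(n) / fr - pf / fr,
            "pressure_Pa": analysis.pressure_at_frames_pa,
            "vol_m3": analysis.volume.total_cm3 * 1e-6,
            "dVdt_m3s": analysis.volume.dvdt_m3_s,
            "power_W": analysis.power_w,
            "in_peak_mask": analysis.peak_mask.astype(int),
        }).to_csv(outdir / "power.csv", index=False, float_format="%.9g")
    pd.DataFrame([analysis.result.to_row()]).to_csv(
        outdir / "strike_summary.csv", index=False, float_format="%.9g")


def report(root) -> pd.DataFrame:
    """Aggregate every ``strike_summary.csv`` under ``root`` into a
    per-individual mean ± s.e.m. table (written as summary_by_individual.csv)."""
    root = Path(root)
    files = sorted(root.rglob("strike_summary.csv"))
    if not files:
        raise FileNotFoundError(f"no strike_summary.csv under {root}")
    per_strike = pd.concat([pd.read_csv(f) for f in files], ignore_index=True)
    summary = summarize_individuals(per_strike)
    summary.to_csv(root / "summary_by_individual.csv", index=False,
                   float_format="%.9g")
    return summary
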