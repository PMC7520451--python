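"""Joint coordinate systems and six-degree-of-freedom joint kinematics.

An anatomical coordinate system (ACS) is placed at a joint — e.g. the
craniovertebral joint or the cleithrum–post-temporal joint — with +x
midsagittal pointing rostrally, +y dorsal and +z transverse pointing to the
animal's right (the unique right-handed assignment under which rotation
dorsally and translation to the right are both positive). The ACS is
duplicated, one copy fixed to the proximal body (normally the body plane)
and one to the distal mobile bone; the two copies coincide in the reference
(setup) configuration. The relative motion of the distal copy expressed in
the proximal copy is decomposed as intrinsic z-y-x (body-fixed) Euler
rotations plus translations along the proximal axes.

Under this convention positive z-rotation of the neurocranium is cranial
elevation and negative z-rotation of the cleithrum is pectoral-girdle
retraction. Gape is the distance between jaw-tip landmarks, and all traces
can be timed relative to the frame of peak gape and re-zeroed to a
pre-strike baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .rigid_body import PoseSequence

GIMBAL_TOL_RAD = 1e-3


@dataclass
class AnatomicalCS:
    """A joint-anchored coordinate system in reference (CT/scene) space:
    ``axes`` columns are the x, y, z unit vectors."""

    origin: np.ndarray
    axes: np.ndarray = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.axes = np.eye(3) if self.axes is None else np.asarray(self.axes, float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("ACS axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("ACS axes must be right-handed (det=+1)")


@dataclass
class JointCS:
    """A duplicated-ACS joint between a proximal and a distal body."""

    name: str
    acs: AnatomicalCS
    proximal: str
    distal: str
    rotation_order: str = "zyx"


@dataclass
class KinematicTrace:
    """Per-frame 6-DoF joint motion: intrinsic z, y, x rotations (deg) and
    translations along the proximal ACS axes (coordinate units)."""

    joint: str
    rotations_deg: np.ndarray   # (F, 3) columns rz, ry, rx
    translations: np.ndarray    # (F, 3) columns tz, ty, tx
    gimbal_flag: np.ndarray     # (F,) bool
    valid: np.ndarray           # (F,) bool
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return len(self.rotations_deg)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def rz_deg(self) -> np.ndarray:
        return self.rotations_deg[:, 0]

    def to_dataframe(self, peak_frame: int | None = None):
        import pandas as pd
        t = self.times - (peak_frame / self.frame_rate_hz if peak_frame is not None else 0.0)
        rot = np.where(self.valid[:, None], self.rotations_deg, np.nan)
        tra = np.where(self.valid[:, None], self.translations, np.nan)
        return pd.DataFrame({
            "frame": np.arange(self.n_frames), "time_s": t,
            "rz_deg": rot[:, 0], "ry_deg": rot[:, 1], "rx_deg": rot[:, 2],
            "tz": tra[:, 0], "ty": tra[:, 1], "tx": tra[:, 2],
            "gimbal_flag": self.gimbal_flag.astype(int),
        })


def euler_zyx_from_matrix(rot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose rotation matrices as intrinsic z-then-y-then-x Euler angles.

    Returns ``(angles_deg, gimbal_flag)`` where angles columns are
    (rz, ry, rx) and the flag marks |ry| within ~1e-3 rad of 90 deg, where
    rz and rx are no longer separable.
    """
    rot = np.asarray(rot, float)
    single = rot.ndim == 2
    ang = Rotation.from_matrix(rot).as_euler("ZYX", degrees=True)
    ang = np.atleast_2d(ang)
    gimbal = np.abs(np.abs(np.deg2rad(ang[:, 1])) - np.pi / 2) < GIMBAL_TOL_RAD
    return (ang[0], gimbal[0]) if single else (ang, gimbal)


def matrix_from_euler_zyx(rz_deg: float, ry_deg: float, rx_deg: float) -> np.ndarray:
    """Compose the intrinsic z-y-x rotation (the inverse of
    :func:`euler_zyx_from_matrix`)."""
    return Rotation.from_euler("ZYX", [rz_deg, ry_deg, rx_deg], degrees=True).as_matrix()


def _localize_acs(pose: PoseSequence, origin: np.ndarray, axes: np.ndarray,
                  setup_frame: int):
    """Express a world-space ACS in the body's own reference space using the
    body's pose at the setup frame."""
    r0 = pose.rotations[setup_frame]
    t0 = pose.translations[setup_frame]
    return r0.T @ (origin - t0), r0.T @ axes


def jcs_decompose(pose_distal: PoseSequence, pose_proximal: PoseSequence,
                  joint: JointCS, setup_frame: int = 0) -> KinematicTrace:
    """Per-frame motion of the distal ACS expressed in the proximal ACS.

    The joint's ACS (origin and axes in world/scene coordinates at the setup
    frame) is duplicated: one copy is rigidly attached to the proximal body
    and one to the distal body, so the two copies coincide at setup and an
    identity relative pose decomposes to all zeros. Rotations follow the
    intrinsic zyx order; translations are the offset of the distal ACS
    origin along the proximal ACS axes.
    """
    if pose_distal.n_frames != pose_proximal.n_frames:
        raise ValueError("pose sequences must share frames")
    if not (pose_distal.valid[setup_frame] and pose_proximal.valid[setup_frame]):
        raise ValueError(f"setup frame {setup_frame} lacks a valid pose")
    op_ref, ap = _localize_acs(pose_proximal, joint.acs.origin, joint.acs.axes,
                               setup_frame)
    od_ref, ad = _localize_acs(pose_distal, joint.acs.origin, joint.acs.axes,
                               setup_frame)
    valid = pose_distal.valid & pose_proximal.valid
    # world-frame ACS per frame: R_w = R_pose @ a ; o_w = R_pose @ o + t
    rp = np.einsum("fij,jk->fik", pose_proximal.rotations, ap)
    rd = np.einsum("fij,jk->fik", pose_distal.rotations, ad)
    op = (np.einsum("fij,j->fi", pose_proximal.rotations, op_ref)
          + pose_proximal.translations)
    od = (np.einsum("fij,j->fi", pose_distal.rotations, od_ref)
          + pose_distal.translations)
    r_rel = np.einsum("fji,fjk->fik", rp, rd)             # rp^T rd
    t_rel = np.einsum("fji,fj->fi", rp, od - op)          # components on proximal axes
    angles, gimbal = euler_zyx_from_matrix(r_rel)
    # translations reported in (tz, ty, tx) column order to mirror rotations
    translations = t_rel[:, ::-1]
    angles = np.where(valid[:, None], angles, np.nan)
    translations = np.where(valid[:, None], translations, np.nan)
    return KinematicTrace(joint.name, angles, translations,
                          gimbal & valid, valid, pose_distal.frame_rate_hz)


# ---------------------------------------------------------------------------
# gape and trace timing

def gape_trace(upper_tip: np.ndarray, lower_tip: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distance between the jaw-tip landmarks."""
    upper = np.asarray(upper_tip, float)
    lower = np.asarray(lower_tip, float)
    if upper.shape != lower.shape:
        raise ValueError("jaw-tip trajectories must share frames")
    return np.linalg.norm(upper - lower, axis=-1)


def find_peak_gape(gape: np.ndarray, frame_rate_hz: float) -> tuple[int, float]:
    """Frame index and time of the global gape maximum (earliest frame on
    ties); the gape series is expected to be low-pass filtered already."""
    gape = np.asarray(gape, float)
    if np.isnan(gape).all():
        raise ValueError("gape trace has no valid samples")
    idx = int(np.nanargmax(gape))
    return idx, idx / frame_rate_hz


def baseline_slice(peak_frame: int, frame_rate_hz: float, n_frames: int,
                   window_s: float = 0.1, end_before_peak_s: float = 0.2) -> slice:
    """Pre-strike baseline window: ``window_s`` long, ending
    ``end_before_peak_s`` before peak gape, clamped into the record."""
    end = peak_frame - int(round(end_before_peak_s * frame_rate_hz))
    if end <= 0:
        raise ValueError("baseline window falls before the start of the record")
    start = max(end - int(round(window_s * frame_rate_hz)), 0)
    if start >= end or start >= n_frames:
        raise ValueError("baseline window is empty")
    return slice(start, min(end, n_frames))


def rezero_trace(trace: KinematicTrace, baseline: slice) -> KinematicTrace:
    """Subtract each channel's baseline-window mean so traces read relative
    to their pre-strike value. Idempotent for a fixed window."""
    rot_base = np.nanmean(trace.rotations_deg[baseline], axis=0)
    tra_base = np.nanmean(trace.translations[baseline], axis=0)
    if np.isnan(rot_base).any():
        raise ValueError("baseline window has no valid frames")
    return replace(trace,
                   rotations_deg=trace.rotations_deg - rot_base,
                   translations=trace.translations - tra_base)
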