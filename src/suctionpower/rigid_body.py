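"""Rigid-body pose estimation from implanted bone markers.

Each marked bone carries >=3 radio-opaque markers whose CT-space
(reference) coordinates are known. Per frame, the bone's rigid transform is
the proper orthogonal least-squares fit (Kabsch/Umeyama without scaling)
mapping the reference markers onto the tracked world coordinates. The same
machinery animates bone-attached virtual landmarks (jaw tips, fiber
attachment sites, endocast points) and builds the "body plane" — the trunk
treated as a single rigid object from its epaxial markers — that serves as
the proximal reference body for all joint kinematics.

Tracking precision is quantified as the mean over intra-bone marker pairs
of the standard deviation of their inter-marker distance: for a truly rigid
bone that distance is constant, so its spread is pure measurement noise.

Kinematic signals are smoothed with a zero-phase (forward-backward)
2nd-order Butterworth low-pass filter, 40 Hz cutoff by default. Filtering
is applied to marker coordinates before any distance computation, and to
pose sequences as quaternion + translation components (quaternions are
sign-aligned, filtered, then renormalized — filtering rotation-matrix
entries directly would break orthogonality).

Gap policy: missing marker samples (NaN) are linearly interpolated before
filtering when the gap is <=``max_gap`` frames (default 5); longer gaps are
left missing and propagate to dependent outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .io import TrajectorySet

log = logging.getLogger("suctionpower")


class DegenerateGeometryError(ValueError):
    """Marker configuration too degenerate (collinear / <3 points) to define
    a unique rigid transform."""


@dataclass
class BoneDefinition:
    """A rigid bone: reference (CT-space) marker coordinates plus named
    virtual landmarks that move with the bone."""

    name: str
    marker_names: list[str]
    reference: np.ndarray            # (n_markers, 3)
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    collinearity_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float)
        if self.reference.shape != (len(self.marker_names), 3):
            raise ValueError(f"bone {self.name!r}: reference shape mismatch")
        if len(self.marker_names) < 3:
            raise DegenerateGeometryError(f"bone {self.name!r}: needs >=3 markers")
        c = self.reference - self.reference.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] <= self.collinearity_tol:
            raise DegenerateGeometryError(
                f"bone {self.name!r}: reference markers are collinear")
        self.landmarks = {k: np.asarray(v, float) for k, v in self.landmarks.items()}


@dataclass
class PoseSequence:
    """Per-frame rigid transform of one bone: world = R @ reference + t.

    ``valid`` flags frames with enough usable markers; rotations on invalid
    frames are identity placeholders and must not be consumed.
    """

    bone: str
    rotations: np.ndarray       # (n_frames, 3, 3)
    translations: np.ndarray    # (n_frames, 3)
    residuals: np.ndarray       # (n_frames,) RMS marker distance
    valid: np.ndarray           # (n_frames,) bool
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return len(self.translations)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map reference-space ``points`` (n,3) through every frame's
        transform -> (n_frames, n, 3); invalid frames give NaN."""
        pts = np.asarray(points, float)
        out = np.einsum("fij,nj->fni", self.rotations, pts) + self.translations[:, None, :]
        out[~self.valid] = np.nan
        return out

    def as_matrices(self) -> np.ndarray:
        m = np.tile(np.eye(4), (self.n_frames, 1, 1))
        m[:, :3, :3] = self.rotations
        m[:, :3, 3] = self.translations
        m[~self.valid] = np.nan
        return m


def fit_rigid_transform(reference: np.ndarray, observed: np.ndarray,
                        collinearity_tol: float = 1e-6):
    """Least-squares proper rigid transform mapping ``reference`` onto
    ``observed`` (Kabsch/Umeyama, no scaling).

    Rows of ``observed`` containing NaN are dropped together with their
    reference partners. Returns ``(rotation, translation, rms_residual)``;
    the rotation always has determinant +1 (reflections are corrected via
    the SVD determinant trick). Raises :class:`DegenerateGeometryError` for
    <3 usable or collinear points.
    """
    ref = np.asarray(reference, float)
    obs = np.asarray(observed, float)
    usable = ~np.isnan(obs).any(axis=1) & ~np.isnan(ref).any(axis=1)
    ref, obs = ref[usable], obs[usable]
    if len(ref) < 3:
        raise DegenerateGeometryError(f"only {len(ref)} usable marker(s); need >=3")
    rc, oc = ref.mean(axis=0), obs.mean(axis=0)
    a, b = ref - rc, obs - oc
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] <= collinearity_tol:
        raise DegenerateGeometryError("usable markers are collinear")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = oc - rot @ rc
    resid = float(np.sqrt(np.mean(np.sum((ref @ rot.T + trans - obs) ** 2, axis=1))))
    return rot, trans, resid


def fit_pose_sequence(bone: BoneDefinition, trajectories: TrajectorySet) -> PoseSequence:
    """Fit the bone's rigid transform independently at every frame.

    Frames with <3 visible markers (or a collinear visible subset) are
    flagged invalid rather than raising.
    """
    obs = np.stack([trajectories.get(m) for m in bone.marker_names], axis=1)
    n = trajectories.n_frames
    rots = np.tile(np.eye(3), (n, 1, 1))
    trans = np.zeros((n, 3))
    resid = np.full(n, np.nan)
    valid = np.zeros(n, bool)
    for f in range(n):
        try:
            r, t, e = fit_rigid_transform(bone.reference, obs[f])
        except DegenerateGeometryError:
            continue
        rots[f], trans[f], resid[f], valid[f] = r, t, e, True
    if not valid.all():
        log.warning("bone %s: %d/%d frames lack a usable marker set",
                    bone.name, int((~valid).sum()), n)
    return PoseSequence(bone.name, rots, trans, resid, valid,
                        trajectories.frame_rate_hz)


def make_body_plane(trajectories: TrajectorySet, marker_names: list[str],
                    name: str = "body_plane") -> tuple[BoneDefinition, PoseSequence]:
    """Treat the designated trunk markers as one rigid object.

    The reference geometry is the marker configuration at the first frame on
    which all body-plane markers are visible, so the body-plane pose is the
    identity there.
    """
    sub = trajectories.subset(marker_names)
    visible = ~np.isnan(sub.coords).any(axis=(1, 2))
    if not visible.any():
        raise ValueError("body-plane markers are never simultaneously visible")
    f0 = int(np.argmax(visible))
    bone = BoneDefinition(name, list(marker_names), sub.coords[f0])
    return bone, fit_pose_sequence(bone, trajectories)


def tracking_precision(trajectories: TrajectorySet,
                       intra_bone_pairs: list[tuple[str, str]]) -> float:
    """Mean over intra-bone marker pairs of the standard deviation (over
    frames) of the pair's inter-marker distance, in coordinate units.

    Pairs with <2 co-visible frames are skipped with a warning; if all pairs
    are skipped a ``ValueError`` is raised.
    """
    stds = []
    for a, b in intra_bone_pairs:
        d = np.linalg.norm(trajectories.get(a) - trajectories.get(b), axis=1)
        d = d[~np.isnan(d)]
        if len(d) < 2:
            log.warning("precision pair (%s, %s) skipped: <2 co-visible frames", a, b)
            continue
        stds.append(float(np.std(d, ddof=1)))
    if not stds:
        raise ValueError("no marker pair with co-visible frames")
    return float(np.mean(stds))


# ---------------------------------------------------------------------------
# filtering

def interpolate_gaps(x: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap along axis 0;
    longer runs (and leading/trailing NaNs) are left missing."""
    x = np.array(x, float)
    flat = x.reshape(len(x), -1)
    idx = np.arange(len(x))
    for j in range(flat.shape[1]):
        col = flat[:, j]
        bad = np.isnan(col)
        if not bad.any() or bad.all():
            continue
        # find NaN runs
        edges = np.flatnonzero(np.diff(bad.astype(int)))
        starts = [0] if bad[0] else []
        starts += list(edges[~bad[edges]] + 1)
        for s in starts:
            e = s
            while e < len(col) and bad[e]:
                e += 1
            interior = s > 0 and e < len(col)
            if interior and (e - s) <= max_gap:
                col[s:e] = np.interp(idx[s:e], [s - 1, e], [col[s - 1], col[e]])
        flat[:, j] = col
    return x


def lowpass_filter(series: np.ndarray, cutoff_hz: float, rate_hz: float,
                   order: int = 2, max_gap: int = 5) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    A 2nd-order filter applied forward-backward (``filtfilt``) gives an
    effective 4th-order, zero-phase response. Gaps are interpolated per the
    gap policy first; contiguous finite segments are filtered independently
    and segments too short for the filter's padding are passed through
    unchanged with a warning.
    """
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {rate_hz / 2} Hz")
    x = interpolate_gaps(np.asarray(series, float), max_gap=max_gap)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    padlen = 3 * (2 * order + 1)
    out = np.array(x)
    flat_in = x.reshape(len(x), -1)
    flat_out = out.reshape(len(x), -1)
    for j in range(flat_in.shape[1]):
        col = flat_in[:, j]
        finite = ~np.isnan(col)
        if finite.all():
            flat_out[:, j] = signal.sosfiltfilt(sos, col)
            continue
        # filter each finite run separately
        f = 0
        n = len(col)
        while f < n:
            if not finite[f]:
                f += 1
                continue
            e = f
            while e < n and finite[e]:
                e += 1
            if e - f > padlen:
                flat_out[f:e, j] = signal.sosfiltfilt(sos, col[f:e])
            else:
                log.warning("segment of %d samples too short to filter; passed through", e - f)
            f = e
    return out


def filter_trajectories(ts: TrajectorySet, cutoff_hz: float | None,
                        max_gap: int = 5) -> TrajectorySet:
    """Low-pass filter every marker coordinate; ``cutoff_hz=None`` is a
    pass-through (gaps still interpolated per policy)."""
    if cutoff_hz is None:
        return ts.with_coords(interpolate_gaps(ts.coords, max_gap=max_gap))
    return ts.with_coords(lowpass_filter(ts.coords, cutoff_hz, ts.frame_rate_hz,
                                         max_gap=max_gap))


def filter_pose_sequence(pose: PoseSequence, cutoff_hz: float | None) -> PoseSequence:
    """Low-pass filter a pose sequence as quaternion + translation.

    Quaternions are sign-aligned frame to frame (q and -q encode the same
    rotation), filtered componentwise, renormalized, and converted back to
    rotation matrices. Invalid frames are treated as gaps.
    """
    if cutoff_hz is None:
        return pose
    quats = Rotation.from_matrix(pose.rotations[pose.valid]).as_quat()
    full = np.full((pose.n_frames, 4), np.nan)
    full[pose.valid] = quats
    # hemisphere alignment
    prev = None
    for f in range(pose.n_frames):
        if np.isnan(full[f, 0]):
            continue
        if prev is not None and np.dot(full[f], prev) < 0:
            full[f] = -full[f]
        prev = full[f]
    qf = lowpass_filter(full, cutoff_hz, pose.frame_rate_hz)
    tf = lowpass_filter(pose.translations.astype(float), cutoff_hz, pose.frame_rate_hz)
    rots = np.tile(np.eye(3), (pose.n_frames, 1, 1))
    ok = ~np.isnan(qf).any(axis=1)
    norms = np.linalg.norm(qf[ok], axis=1, keepdims=True)
    rots[ok] = Rotation.from_quat(qf[ok] / norms).as_matrix()
    return PoseSequence(pose.bone, rots, tf, pose.residuals, pose.valid & ok,
                        pose.frame_rate_hz)


def animate_landmarks(pose: PoseSequence, bone: BoneDefinition,
                      names: list[str]) -> TrajectorySet:
    """World-space trajectories of named virtual landmarks attached to a
    bone: per frame ``R @ reference + t``. Missing pose frames yield missing
    landmark frames."""
    missing = [n for n in names if n not in bone.landmarks]
    if missing:
        raise KeyError(f"bone {bone.name!r} has no landmark(s) {missing}")
    pts = np.stack([bone.landmarks[n] for n in names])
    coords = pose.transform_points(pts)
    return TrajectorySet(list(names), coords, pose.frame_rate_hz)
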