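"""Readers and writers for the pipeline's tabular and mesh formats.

Formats handled here:

* marker trajectory CSV (XMALab 3D-points dialect: one ``<name>_X, <name>_Y,
  <name>_Z`` column triple per marker, one row per video frame);
* reference-geometry CSV (``bone,marker,kind,x,y,z`` in CT/scene space,
  ``kind`` distinguishing tracked markers from virtual landmarks);
* two-column pressure CSV (``time_s,value``), optionally calibrated
  from millivolts to pascals;
* per-frame rigid-transform CSV (16 row-major homogeneous-matrix values);
* Wavefront OBJ export of per-frame endocast boundary meshes.

Missing samples (empty CSV cells) are represented as NaN throughout and are
never silently zero-filled; each downstream module documents its own gap
policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("suctionpower")

_AXES = ("X", "Y", "Z")


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory CSV does not follow the X/Y/Z-triple dialect."""


@dataclass
class TrajectorySet:
    """Per-frame 3D coordinates of named markers at a fixed frame rate.

    ``coords`` has shape ``(n_frames, n_markers, 3)``; missing samples are
    NaN. Coordinates are in ``units`` (cm by default, matching the
    convention that endocast volumes come out in cm^3).
    """

    markers: list[str]
    coords: np.ndarray
    frame_rate_hz: float
    units: str = "cm"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, markers, 3)")
        if self.coords.shape[1] != len(self.markers):
            raise ValueError(
                f"{len(self.markers)} marker names but coords holds "
                f"{self.coords.shape[1]} markers"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """Trajectory of one marker, shape ``(n_frames, 3)``."""
        return self.coords[:, self.index(name), :]

    def subset(self, names: list[str]) -> "TrajectorySet":
        idx = [self.index(n) for n in names]
        return TrajectorySet(list(names), self.coords[:, idx, :],
                             self.frame_rate_hz, self.units)

    def with_coords(self, coords: np.ndarray) -> "TrajectorySet":
        return TrajectorySet(list(self.markers), coords,
                             self.frame_rate_hz, self.units)

    def merged_with(self, other: "TrajectorySet") -> "TrajectorySet":
        if other.n_frames != self.n_frames:
            raise ValueError("frame counts differ")
        return TrajectorySet(list(self.markers) + list(other.markers),
                             np.concatenate([self.coords, other.coords], axis=1),
                             self.frame_rate_hz, self.units)


def read_trajectories(path, frame_rate_hz: float, units: str = "cm") -> TrajectorySet:
    """Read an XMALab-style 3D-points CSV.

    Header must contain one ``<name>_X,<name>_Y,<name>_Z`` triple per marker
    (suffix case-insensitive); rows are frames. Empty cells become NaN.
    Raises :class:`TrajectoryFormatError` for a malformed header and
    ``ValueError`` (naming the row) for a non-numeric cell.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(raw.columns)
    if len(cols) == 0 or len(cols) % 3 != 0:
        raise TrajectoryFormatError(
            f"{path}: {len(cols)} columns is not a whole number of X/Y/Z "
            f"triples (last column {cols[-1] if cols else '<none>'!r})"
        )
    markers: list[str] = []
    for i in range(0, len(cols), 3):
        trio = cols[i:i + 3]
        names, suffixes = [], []
        for c in trio:
            if "_" not in c:
                raise TrajectoryFormatError(f"{path}: column {c!r} lacks an _X/_Y/_Z suffix")
            stem, suffix = c.rsplit("_", 1)
            names.append(stem)
            suffixes.append(suffix.upper())
        if tuple(suffixes) != _AXES or len(set(names)) != 1:
            raise TrajectoryFormatError(
                f"{path}: columns {trio} do not form a <name>_X,<name>_Y,<name>_Z triple"
            )
        markers.append(names[0])

    values = np.full(raw.shape, np.nan)
    for j, c in enumerate(cols):
        col = raw[c]
        stripped = col.str.strip() if col.dtype == object else col
        num = pd.to_numeric(stripped, errors="coerce")
        bad = num.isna() & col.notna() & (stripped != "")
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {col.iloc[r]!r} in column {c!r}, row {r}"
            )
        values[:, j] = num.to_numpy()

    coords = values.reshape(len(raw), len(markers), 3)
    return TrajectorySet(markers, coords, frame_rate_hz, units)


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write a :class:`TrajectorySet` back to the 3D-points CSV dialect."""
    cols = {}
    for i, m in enumerate(ts.markers):
        for j, ax in enumerate(_AXES):
            cols[f"{m}_{ax}"] = ts.coords[:, i, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# reference geometry (CT-space marker and landmark coordinates)

def write_reference_geometry(bones, path) -> None:
    """Write ``bone,marker,kind,x,y,z`` rows for a list of BoneDefinitions."""
    rows = []
    for b in bones:
        for name, xyz in zip(b.marker_names, b.reference):
            rows.append((b.name, name, "marker", *xyz))
        for name, xyz in b.landmarks.items():
            rows.append((b.name, name, "landmark", *np.asarray(xyz, float)))
    pd.DataFrame(rows, columns=["bone", "marker", "kind", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.12g")


def read_reference_geometry(path):
    """Read ``bone,marker[,kind],x,y,z`` into a dict of BoneDefinitions.

    A missing ``kind`` column means every row is a tracked marker.
    """
    from .rigid_body import BoneDefinition

    df = pd.read_csv(path)
    if "kind" not in df.columns:
        df = df.assign(kind="marker")
    bones = {}
    for bone, grp in df.groupby("bone", sort=False):
        mk = grp[grp["kind"] == "marker"]
        lm = grp[grp["kind"] == "landmark"]
        landmarks = {r["marker"]: np.array([r.x, r.y, r.z], float)
                     for _, r in lm.iterrows()}
        bones[bone] = BoneDefinition(
            name=bone,
            marker_names=list(mk["marker"]),
            reference=mk[["x", "y", "z"]].to_numpy(float),
            landmarks=landmarks,
        )
    return bones


# ---------------------------------------------------------------------------
# pressure

def read_pressure(path, calibration_pa_per_mv: float | None = None,
                  expected_rate_hz: float | None = None):
    """Read a two-column ``time_s,value`` pressure CSV.

    With a calibration the value column is millivolts and is converted to
    pascals (``value * calibration_pa_per_mv``); without one the values are
    taken to be pascals already. Non-monotone time raises; a sample rate
    more than 1% off ``expected_rate_hz`` logs a warning.

    Returns ``(time_s, pressure_pa)`` arrays.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s,value)")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if expected_rate_hz is not None and len(t) >= 2:
        rate = 1.0 / float(np.median(np.diff(t)))
        if abs(rate - expected_rate_hz) / expected_rate_hz > 0.01:
            log.warning("pressure sample rate %.6g Hz differs from configured %.6g Hz by >1%%",
                        rate, expected_rate_hz)
    pa = v * calibration_pa_per_mv if calibration_pa_per_mv is not None else v
    return t, pa


def write_pressure(time_s: np.ndarray, values: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": time_s, "value": values}).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# rigid-transform CSV

def write_pose_csv(pose, path) -> None:
    """Export a PoseSequence as one row per frame: frame + 16 row-major
    homogeneous-matrix values (NaN for frames flagged missing)."""
    mats = pose.as_matrices()
    flat = mats.reshape(len(mats), 16)
    cols = [f"m{r}{c}" for r in range(4) for c in range(4)]
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "frame", np.arange(len(mats)))
    df.to_csv(path, index=False, float_format="%.12g")


def read_pose_csv(path) -> np.ndarray:
    """Read a rigid-transform CSV back into an ``(n_frames, 4, 4)`` array."""
    df = pd.read_csv(path)
    cols = [f"m{r}{c}" for r in range(4) for c in range(4)]
    return df[cols].to_numpy(float).reshape(-1, 4, 4)


# ---------------------------------------------------------------------------
# OBJ export

def write_endocast_obj(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    """Write a triangulated boundary mesh as Wavefront OBJ (1-based faces).

    Only vertices referenced by a face are written; an empty mesh produces a
    header-only file and logs a warning.
    """
    path = Path(path)
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# suctionpower endocast boundary mesh\n")
        if len(faces) == 0:
            log.warning("empty endocast mesh written to %s", path)
            return
        used = np.unique(faces)
        remap = {int(old): i + 1 for i, old in enumerate(used)}
        for v in vertices[used]:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in faces:
            fh.write(f"f {remap[int(f[0])]} {remap[int(f[1])]} {remap[int(f[2])]}\n")
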