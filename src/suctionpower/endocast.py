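"""Dynamic endocast: alpha-shape mouth-cavity volume through time.

The mouth cavity is landmarked on the medial surfaces of the left-side
bones and up to the midsagittal plane, with closure points at the caudal
(esophageal) boundary. Per frame, the volume enclosed by the landmark cloud
is the alpha shape of the points: the union of Delaunay tetrahedra whose
circumsphere radius is at most ``alpha`` (the "alpha radius" convention, in
coordinate units; default 2 with cm scenes). The unilateral volume is
multiplied by a bilateral factor (default 2, assuming bilateral symmetry)
to estimate total mouth volume, and dV/dt is taken by central differences
(one-sided at the record ends) without additional smoothing — the landmark
positions derive from already-filtered data.

As alpha grows the kept-tetrahedron set grows monotonically and the volume
converges to the convex-hull volume; alpha too small for the landmark
spacing yields holes and eventually zero volume (warned).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .io import TrajectorySet

log = logging.getLogger("suctionpower")

CM3_TO_M3 = 1e-6


@dataclass
class EndocastDefinition:
    landmarks: list[str]
    alpha: float = 2.0
    bilateral_factor: float = 2.0

    def __post_init__(self) -> None:
        if len(self.landmarks) < 4:
            raise ValueError("endocast needs >=4 landmarks")
        if self.alpha <= 0 or self.bilateral_factor <= 0:
            raise ValueError("alpha and bilateral_factor must be positive")


@dataclass
class VolumeTrace:
    """Per-frame unilateral and total (bilaterally doubled) endocast volume
    in cm^3, and its rate of change."""

    unilateral_cm3: np.ndarray
    total_cm3: np.ndarray
    dvdt_cm3_s: np.ndarray
    frame_rate_hz: float
    bilateral_factor: float

    @property
    def dvdt_m3_s(self) -> np.ndarray:
        return self.dvdt_cm3_s * CM3_TO_M3

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.total_cm3)) / self.frame_rate_hz

    def to_dataframe(self, peak_frame: int | None = None):
        import pandas as pd
        t = self.times - (peak_frame / self.frame_rate_hz if peak_frame is not None else 0.0)
        return pd.DataFrame({
            "frame": np.arange(len(self.total_cm3)), "time_s": t,
            "vol_unilateral_cm3": self.unilateral_cm3,
            "vol_total_cm3": self.total_cm3,
            "dVdt_cm3_s": self.dvdt_cm3_s,
        })


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    tets = points[simplices]
    e = tets[:, 1:] - tets[:, :1]
    return np.abs(np.linalg.det(e)) / 6.0


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron (inf for degenerate ones).

    The circumcenter c solves 2(v_i - v_0) . c = |v_i|^2 - |v_0|^2.
    """
    tets = points[simplices]
    a = 2.0 * (tets[:, 1:] - tets[:, :1])
    sq = np.einsum("tij,tij->ti", tets, tets)
    b = sq[:, 1:] - sq[:, :1]
    radii = np.full(len(simplices), np.inf)
    det = np.abs(np.linalg.det(a))
    ok = det > 1e-300
    if ok.any():
        centers = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - tets[ok, 0], axis=1)
    return radii


def alpha_shape_volume(points: np.ndarray, alpha: float):
    """Alpha-shape volume and boundary mesh of a 3D point cloud.

    Delaunay-tetrahedralizes the points, keeps tetrahedra whose circumsphere
    radius is <= ``alpha`` (degenerate slivers with volume below 1e-12 of
    the bounding-box volume are dropped first), and returns
    ``(volume, (vertices, faces))`` where the faces (indices into the input
    points) are those belonging to exactly one kept tetrahedron.

    Degenerate input (coplanar, <4 points) or an alpha too small to keep any
    tetrahedron returns zero volume with a warning.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(pts) < 4:
        log.warning("alpha shape: <4 points, volume 0")
        return 0.0, (pts, np.empty((0, 3), int))
    try:
        tri = Delaunay(pts)
    except Exception:
        log.warning("alpha shape: degenerate point cloud, volume 0")
        return 0.0, (pts, np.empty((0, 3), int))
    vols = _tet_volumes(pts, tri.simplices)
    bbox = np.prod(pts.max(axis=0) - pts.min(axis=0))
    nondegenerate = vols > 1e-12 * max(bbox, 1e-300)
    radii = _circumradii(pts, tri.simplices)
    keep = nondegenerate & (radii <= alpha)
    if not keep.any():
        log.warning("alpha shape: no tetrahedron kept at alpha=%g", alpha)
        return 0.0, (pts, np.empty((0, 3), int))
    volume = float(vols[keep].sum())
    faces = Counter()
    for simplex in tri.simplices[keep]:
        for omit in range(4):
            faces[tuple(sorted(np.delete(simplex, omit)))] += 1
    boundary = np.array([f for f, c in faces.items() if c == 1], int)
    if boundary.size == 0:
        boundary = np.empty((0, 3), int)
    return volume, (pts, boundary)


def endocast_trace(landmarks: TrajectorySet, defn: EndocastDefinition,
                   export_meshes: bool = False):
    """Per-frame alpha-shape volume of the animated endocast landmarks.

    The unilateral volume is multiplied by the bilateral factor; dV/dt is
    taken on the total volume by central differences. Frames with any
    missing landmark, or a degenerate cloud, become missing in the trace
    (logged). With ``export_meshes=True`` also returns the per-frame
    boundary meshes for visual confirmation of the endocast fit.
    """
    pts = np.stack([landmarks.get(n) for n in defn.landmarks], axis=1)
    n = landmarks.n_frames
    uni = np.full(n, np.nan)
    meshes = []
    for f in range(n):
        cloud = pts[f]
        if np.isnan(cloud).any():
            log.warning("endocast frame %d skipped: missing landmark", f)
            meshes.append(None)
            continue
        v, mesh = alpha_shape_volume(cloud, defn.alpha)
        uni[f] = v
        meshes.append(mesh)
    total = uni * defn.bilateral_factor
    dvdt = np.gradient(total, 1.0 / landmarks.frame_rate_hz)
    trace = VolumeTrace(uni, total, dvdt, landmarks.frame_rate_hz,
                        defn.bilateral_factor)
    return (trace, meshes) if export_meshes else trace
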