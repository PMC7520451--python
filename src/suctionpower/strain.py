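"""Fluoromicrometry: muscle length, strain and strain rate.

Axial muscle (epaxial/hypaxial) lengths are distances between implanted
intramuscular markers tracked in X-ray video; an ordered marker chain
defines subregions (adjacent pairs) and the whole region (cranial-most to
caudal-most marker, one straight-line distance). Cranial muscle lengths are
measured from bone-attached virtual landmarks at the origin and insertion
of three fibers, averaged per frame.

Strain is the percent length change relative to the mean initial length
L_i, *positive for shortening*:

    strain(t) = 100 * (L_i - L(t)) / L_i

L_i is the mean, across all strikes from one individual, of the length
averaged over each strike's pre-strike baseline window. Strain rate
(shortening velocity) is reported in initial lengths per second:

    rate(t) = -(dL/dt) / L_i

with the derivative taken by central differences (one-sided at the ends) on
already low-pass-filtered lengths; no further smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TrajectorySet


@dataclass
class StrainTrace:
    """Length, strain (% of L_i, positive = shortening) and strain rate
    (L_i per second, positive = shortening) for one muscle or subregion."""

    name: str
    length: np.ndarray
    strain_pct: np.ndarray
    rate_li_per_s: np.ndarray
    initial_length: float
    frame_rate_hz: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.length)) / self.frame_rate_hz

    @property
    def normalized_length(self) -> np.ndarray:
        """L / L_i — values below 1 indicate shortening."""
        return self.length / self.initial_length

    def to_dataframe(self, peak_frame: int | None = None):
        import pandas as pd
        t = self.times - (peak_frame / self.frame_rate_hz if peak_frame is not None else 0.0)
        return pd.DataFrame({
            "frame": np.arange(len(self.length)), "time_s": t,
            "length": self.length, "strain_pct": self.strain_pct,
            "rate_Li_per_s": self.rate_li_per_s,
        })


def pairwise_length(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distance between two marker trajectories
    (missing frames propagate as NaN)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("trajectories must share frames")
    return np.linalg.norm(a - b, axis=-1)


def chain_lengths(trajectories: TrajectorySet, markers: list[str]) -> dict[str, np.ndarray]:
    """Length series of every subregion of an ordered marker chain plus the
    whole region.

    Keys are ``sub1..subN`` for adjacent pairs and ``whole`` for the
    straight-line first-to-last distance.
    """
    if len(markers) < 2:
        raise ValueError("a chain needs >=2 markers")
    out: dict[str, np.ndarray] = {}
    for i in range(len(markers) - 1):
        out[f"sub{i + 1}"] = pairwise_length(trajectories.get(markers[i]),
                                             trajectories.get(markers[i + 1]))
    out["whole"] = pairwise_length(trajectories.get(markers[0]),
                                   trajectories.get(markers[-1]))
    return out


def mean_initial_length(length_traces: list[np.ndarray],
                        baselines: list[slice]) -> float:
    """Mean initial length L_i: average over strikes of each strike's
    baseline-window mean length."""
    if len(length_traces) != len(baselines) or not length_traces:
        raise ValueError("need one baseline window per strike")
    means = []
    for trace, window in zip(length_traces, baselines):
        seg = np.asarray(trace, float)[window]
        seg = seg[~np.isnan(seg)]
        if len(seg) == 0:
            continue
        means.append(float(np.mean(seg)))
    if not means:
        raise ValueError("no strike has a valid baseline window")
    return float(np.mean(means))


def strain_and_rate(length: np.ndarray, initial_length: float,
                    frame_rate_hz: float, name: str = "") -> StrainTrace:
    """Strain (% L_i, positive = shortening) and strain rate (L_i/s) from a
    length series."""
    if initial_length <= 0:
        raise ValueError("initial length must be positive")
    length = np.asarray(length, float)
    strain = 100.0 * (initial_length - length) / initial_length
    rate = -np.gradient(length, 1.0 / frame_rate_hz) / initial_length
    return StrainTrace(name, length, strain, rate, initial_length, frame_rate_hz)


def fiber_muscle_length(fiber_pairs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Whole-muscle length as the per-frame mean of the origin-insertion
    distances of the instrumented fibers (three in the standard protocol).
    A missing landmark frame makes that output frame missing."""
    if not fiber_pairs:
        raise ValueError("need at least one fiber")
    lengths = np.stack([pairwise_length(a, b) for a, b in fiber_pairs])
    return lengths.mean(axis=0)


def peak_during_window(values: np.ndarray, mask: np.ndarray,
                       mode: str = "max") -> float:
    """Extremum of a trace restricted to masked frames (e.g. the peak-power
    window): ``mode`` is ``max``, ``min`` or ``absmax``."""
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    if values.shape != mask.shape:
        raise ValueError("trace and mask must share frames")
    sel = values[mask]
    sel = sel[~np.isnan(sel)]
    if len(sel) == 0:
        raise ValueError("mask selects no valid frames")
    if mode == "max":
        return float(np.max(sel))
    if mode == "min":
        return float(np.min(sel))
    if mode == "absmax":
        return float(sel[np.argmax(np.abs(sel))])
    raise ValueError(f"unknown mode {mode!r}")
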