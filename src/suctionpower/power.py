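"""Intra-oral pressure processing and mouth-expansion power.

The pressure record (1000 Hz in the reference setup) is low-pass filtered
(zero-phase Butterworth, 300 Hz cutoff by default), converted to pascals
upstream, and re-zeroed to the ambient pressure of a pre-strike baseline so
that negative values mean sub-ambient intra-oral pressure. It is then
linearly interpolated onto the video frame times (filtering happens at the
native pressure rate, before resampling, to avoid aliasing).

Instantaneous expansion power at a frame is the product of the
(sign-flipped) pressure and the rate of mouth-volume change:

    P(t) = -p(t) [Pa] * dV/dt [m^3/s]   ->  watts

so sub-ambient pressure during expansion gives positive power. The signed
product is kept at all frames (supra-ambient pressure during expansion
shows up as negative power) rather than zeroing non-sub-ambient frames.
The peak-power window is the set of frames whose power is within 25% of the
strike maximum (power >= 0.75 * max); both the full qualifying set and the
maximal contiguous block containing the peak are reported. Maximum power is
normalized by muscle or body masses (W/kg) and by the maximum change in
mouth volume (W/cm^3) for cross-strike and cross-species comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid_body import lowpass_filter


@dataclass
class PressureTrace:
    """Filtered, baseline-re-zeroed pressure in Pa (negative = sub-ambient)."""

    time_s: np.ndarray
    pressure_pa: np.ndarray
    sample_rate_hz: float


def process_pressure(time_s: np.ndarray, pressure_pa: np.ndarray,
                     sample_rate_hz: float,
                     cutoff_hz: float | None = 300.0,
                     baseline: slice | None = None) -> PressureTrace:
    """Zero-phase low-pass filter and re-zero a raw pressure series.

    ``baseline`` selects the pre-strike samples whose mean defines ambient
    pressure (default: the first 10% of the record). ``cutoff_hz=None``
    skips filtering. Raises if the cutoff reaches the Nyquist frequency.
    """
    time_s = np.asarray(time_s, float)
    p = np.asarray(pressure_pa, float)
    if cutoff_hz is not None:
        p = lowpass_filter(p, cutoff_hz, sample_rate_hz)
    if baseline is None:
        baseline = slice(0, max(1, len(p) // 10))
    ambient = float(np.nanmean(p[baseline]))
    return PressureTrace(time_s, p - ambient, sample_rate_hz)


def synchronize(pressure: PressureTrace, frame_times_s: np.ndarray,
                offset_s: float = 0.0) -> np.ndarray:
    """Linearly interpolate the pressure record onto video frame times.

    ``offset_s`` shifts the pressure clock relative to the video clock
    (default 0: synchronized recordings). Frames outside the pressure record
    are NaN; no overlap at all raises.
    """
    frame_times_s = np.asarray(frame_times_s, float)
    t = pressure.time_s + offset_s
    lo, hi = t[0], t[-1]
    inside = (frame_times_s >= lo) & (frame_times_s <= hi)
    if not inside.any():
        raise ValueError("pressure record and video frames do not overlap")
    out = np.full(frame_times_s.shape, np.nan)
    out[inside] = np.interp(frame_times_s[inside], t, pressure.pressure_pa)
    return out


def instantaneous_power(pressure_pa: np.ndarray, dvdt_m3_s: np.ndarray) -> np.ndarray:
    """Expansion power series in watts: ``(-pressure) * dV/dt``."""
    p = np.asarray(pressure_pa, float)
    dv = np.asarray(dvdt_m3_s, float)
    if p.shape != dv.shape:
        raise ValueError("pressure and dV/dt must share the time base")
    return -p * dv


def peak_power_mask(power_w: np.ndarray, fraction: float = 0.75):
    """Frames within ``1 - fraction`` of maximum power.

    Returns ``(mask, block)``: the boolean mask of all frames with
    power >= fraction * max (possibly non-contiguous) and the maximal
    contiguous slice of qualifying frames containing the peak. Raises if
    maximum power is not positive.
    """
    power = np.asarray(power_w, float)
    if np.isnan(power).all():
        raise ValueError("power series has no valid samples")
    pmax = np.nanmax(power)
    if pmax <= 0:
        raise ValueError("maximum power is not positive; no peak-power window")
    mask = power >= fraction * pmax
    mask &= ~np.isnan(power)
    peak = int(np.nanargmax(power))
    lo = peak
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(power) - 1 and mask[hi + 1]:
        hi += 1
    return mask, slice(lo, hi + 1)


def normalize_power(max_power_w: float,
                    masses_kg: dict[str, float] | None = None,
                    max_delta_volume_cm3: float | None = None) -> dict[str, float]:
    """Mass-specific (W/kg) and volume-specific (W/cm^3) peak power.

    ``masses_kg`` maps divisor names (e.g. ``hypaxial``, ``cranial_total``,
    ``body``) to bilateral masses in kg. Non-positive divisors raise.
    """
    out: dict[str, float] = {}
    for name, mass in (masses_kg or {}).items():
        if mass <= 0:
            raise ValueError(f"mass {name!r} must be positive")
        out[f"power_W_per_kg_{name}"] = max_power_w / mass
    if max_delta_volume_cm3 is not None:
        if max_delta_volume_cm3 <= 0:
            raise ValueError("volume divisor must be positive")
        out["power_W_per_cm3"] = max_power_w / max_delta_volume_cm3
    return out


def mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    """Mean and standard error (sd/sqrt(n), ddof=1) of per-strike scalars;
    a single strike reports s.e.m. 0 with n = 1."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n == 0:
        raise ValueError("no values to summarize")
    mean = float(np.mean(v))
    sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def summarize_individuals(per_strike, group_col: str = "individual"):
    """Per-individual mean ± s.e.m. table from a per-strike scalar table.

    ``per_strike`` is a DataFrame with one row per strike; every numeric
    column is summarized per group. Empty groups are dropped with a warning.
    """
    import pandas as pd
    rows = []
    for indiv, grp in per_strike.groupby(group_col, sort=False):
        row = {group_col: indiv, "n_strikes": len(grp)}
        for col in grp.columns:
            if col == group_col or not np.issubdtype(grp[col].dtype, np.number):
                continue
            try:
                m, s, n = mean_sem(grp[col].to_numpy())
            except ValueError:
                continue
            row[f"{col}_mean"] = m
            row[f"{col}_sem"] = s
        rows.append(row)
    return pd.DataFrame(rows)
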