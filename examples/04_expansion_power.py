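"""Expansion power from pressure and volume: the closed-form check.

Instantaneous expansion power is (-p) * dV/dt in watts. For a sinusoidal
volume V(t) = V0 + A sin(wt) under constant sub-ambient pressure -P0, the
peak power is exactly P0 * A * w, which the sampled pipeline (volume ->
central-difference dV/dt -> product -> peak-power window) must reproduce.
"""

import numpy as np

import suctionpower as sp

fr = 300.0                      # video frame rate, Hz
t = np.arange(int(2 * fr)) / fr
amp_m3 = 20e-6                  # 20 cm^3 volume oscillation
omega = 2 * np.pi * 5.0         # 5 Hz
p0 = 5000.0                     # 5 kPa constant sub-ambient pressure

volume_m3 = 100e-6 + amp_m3 * np.sin(omega * t)
dvdt = np.gradient(volume_m3, 1.0 / fr)
power = sp.instantaneous_power(np.full_like(t, -p0), dvdt)
mask, block = sp.peak_power_mask(power)

analytic = p0 * amp_m3 * omega
print(f"peak power (pipeline): {np.max(power):.4f} W")
print(f"peak power (closed form P0*A*w): {analytic:.4f} W")
print(f"relative error: {abs(np.max(power) / analytic - 1) * 100:.3f}%")
print(f"peak-power window (power >= 75% of max): {mask.sum()} of {len(t)} frames")

norm = sp.normalize_power(np.max(power), {"hypaxial": 0.05},
                          max_delta_volume_cm3=2 * 20.0)
print(f"mass-specific:   {norm['power_W_per_kg_hypaxial']:.1f} W/kg "
      f"(if 50 g of hypaxial muscle supplied all of it)")
print(f"volume-specific: {norm['power_W_per_cm3']:.4f} W/cm^3 of volume change")
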