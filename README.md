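# suctionpower

Suction-feeding fishes expand the mouth cavity explosively, dropping
intra-oral pressure below ambient and accelerating water (and prey) into the
mouth. Whether that expansion is powered dorsally (epaxial muscles elevating
the neurocranium), ventrally (hypaxial muscles retracting the pectoral
girdle), or both, is a question about joint rotations, muscle strain and
where the mechanical power comes from. `suctionpower` is a Python library
for answering it from marker-based X-ray data: it turns per-frame 3D marker
trajectories (tracked upstream in biplanar X-ray video) and an intra-oral
pressure trace into

- **rigid-body bone kinematics** — per-frame least-squares (Kabsch) pose of
  each marked bone and of a "body plane" built from trunk markers, with
  tracking precision quantified as the mean standard deviation of intra-bone
  marker distances;
- **joint kinematics** — duplicated anatomical coordinate systems at each
  joint, relative motion decomposed as intrinsic *z-y-x* Euler rotations
  (positive *z* = cranial elevation / protraction, negative = depression /
  retraction), timed relative to peak gape;
- **muscle strain** — fluoromicrometry: lengths between intramuscular
  markers (subregions and whole region of the axial muscles) and between
  bone-attached fiber landmarks (cranial muscles), as strain
  `100·(L_i − L)/L_i` (positive = shortening) and strain rate in initial
  lengths per second;
- **mouth volume** — a dynamic endocast: the per-frame alpha-shape volume of
  mouth-cavity landmarks, doubled for bilateral symmetry, with dV/dt;
- **expansion power** — instantaneous power `P = (−p)·dV/dt` (watts), the
  peak-power window (frames within 25% of maximum power), and peak power
  normalized by muscle/body mass (W kg⁻¹) and by volume change (W cm⁻³).

A synthetic-strike generator (`suctionpower.synthetic`) produces complete,
ground-truthed strikes — prescribed joint-angle pulses, subregion strains,
an endocast cloud with analytically known volume, and a pressure trace built
to hit a target peak power — so every stage has a parameter-recovery test
without any recordings.

## Worked example

```sh
python examples/01_simulate_and_analyze.py
```

simulates a noisy strike (0.08 mm marker noise, 300 frames/s video, 1000 Hz
pressure) and recovers it through the full pipeline:

```
peak gape at t = 0.503 s (generator truth 0.500 s)
cranial elevation:  +3.13 deg (truth +3.00)
cleithrum retraction: -8.04 deg (truth -8.00)
hypaxial whole-region peak strain: 5.70 % (truth 5.75 %)
max mouth volume: 99.9 cm^3 (truth 100.0)
peak sub-ambient pressure: -21.33 kPa
peak expansion power: 10.03 W (truth 10.00 W)
  = 201 W/kg hypaxial muscle mass
tracking precision: 0.113 mm (noise sigma 0.08 mm on each marker -> ...)
```

The rotations are about the joint coordinate systems' *z* axes: the
neurocranium elevates ~3 deg, the pectoral girdle retracts ~8 deg. The
hypaxial chain shortens (positive strain) and the 10 W peak power, divided
by the hypaxial muscle mass, gives the mass-specific output those muscles
would need if they alone powered expansion. Further examples cover the
rigid-body fit and precision (`02`), alpha-shape volumes against closed
forms (`03`) and the power closed form (`04`).

The same pipeline runs from the shell on file inputs:

```sh
suctionpower simulate --seed 1 --out strike/
suctionpower analyze --config strike/config.yaml \
    --trajectories strike/trajectories.csv \
    --pressure strike/pressure.csv --out results/
suctionpower report --out results/
```

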