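# Methods

## Coordinate and sign conventions

Scene coordinates default to centimetres (so endocast volumes come out in
cm³); the config declares units and all outputs state them. The anatomical
axes are +x rostral (midsagittal), +y dorsal and +z toward the animal's
right — the unique right-handed assignment under which both "rotation
dorsally is positive" and "translation to the right is positive" hold.
Positive z-rotation of a rostrally pointing bone is therefore dorsal
rotation: cranial elevation for the neurocranium, and pectoral-girdle
retraction reads as negative z-rotation of the cleithrum. Muscle strain is
`100·(L_i − L)/L_i` and strain rate `−(dL/dt)/L_i`, both positive for
shortening. Pressure is re-zeroed to pre-strike ambient, so negative values
are sub-ambient; power `(−p)·dV/dt` is positive for sub-ambient expansion.

## Rigid-body poses

Each bone's per-frame transform is the proper orthogonal least-squares fit
(Kabsch/Umeyama, no scaling) of its CT-space reference markers to the
tracked positions, with the SVD determinant correction so a reflection is
never returned. Frames with fewer than three usable (non-missing,
non-collinear) markers are flagged missing rather than guessed. The body
plane is the same fit applied to the designated trunk markers, using their
configuration at the first fully visible frame as reference. The RMS fit
residual is kept per frame for auditing; tracking precision is reported as
the mean over intra-bone marker pairs of the standard deviation of the
pair's distance (≈ σ√2 for isotropic noise σ per marker).

## Filtering and gaps

Kinematic signals are smoothed with a 2nd-order Butterworth low-pass applied
forward–backward (`sosfiltfilt`): zero phase, effective 4th order, 40 Hz
default cutoff (300 Hz for pressure, filtered at the native pressure rate
*before* resampling to frame times to avoid aliasing). Marker gaps of ≤5
frames are linearly interpolated before filtering; longer gaps stay missing
and propagate. Because filtering rotation-matrix entries breaks
orthogonality, pose sequences are filtered as quaternion + translation:
quaternions are sign-aligned frame to frame, filtered componentwise and
renormalized. Poses are fit on gap-filled raw markers and then filtered
(rather than fit on filtered markers and filtered again); muscle-length
distances are computed on filtered marker coordinates.

## Joint coordinate systems

A joint's ACS (origin and axes in scene coordinates at a setup frame) is
duplicated onto the proximal and distal bodies by localizing it through each
body's setup-frame pose, so the two copies coincide at setup and an identity
relative pose decomposes to zeros. Per frame, the distal copy's pose in the
proximal copy's frame is decomposed as intrinsic z-then-y-then-x Euler
rotations (via quaternion conversion, not per-element trigonometry) plus
translations along the proximal axes. |ry| within ~1e-3 rad of 90° sets a
gimbal flag on the frame; values are still returned. This localization makes
every kinematic trace exactly invariant to re-expressing the whole scene
(markers plus scene-space joint definitions) in a different world frame.

Traces are timed relative to peak gape (global maximum of the filtered
jaw-tip distance, earliest frame on ties) and re-zeroed by subtracting the
mean over a pre-strike baseline window — by default 0.1 s ending 0.2 s
before peak gape, a choice made because "initial value" is otherwise
ambiguous; the window is configurable and shared with the initial-length
computation. Whether to re-zero to a single frame or a window mean was an
open choice; the window mean is robust to single-frame noise.

## Muscle lengths

Axial-muscle chains report each adjacent marker pair (subregion) and the
straight-line first-to-last distance (whole region; a summed-chain variant
would differ only for bent chains and the straight-line reading was
adopted). L_i is the mean over strikes of the baseline-window mean length.
Cranial muscles use the mean of three origin–insertion fiber-landmark
distances animated with their bones; for tendinous muscles this is
muscle–tendon-unit length, flagged as such in the config. Derivatives are
central differences (one-sided at the ends) on already-filtered lengths with
no extra smoothing.

## Dynamic endocast

The per-frame volume is the alpha shape of the mouth-cavity landmarks:
Delaunay tetrahedra kept when their circumsphere radius ≤ alpha ("alpha
radius" convention, default 2 in scene units — the upstream convention's
number; its units are a documented choice). Slivers below 1e-12 of the
bounding-box volume are dropped before the radius test for robustness. The
boundary mesh (faces on exactly one kept tetrahedron) can be exported per
frame as OBJ to confirm the fit visually. The unilateral volume is doubled
(bilateral symmetry) and dV/dt taken by central differences without further
smoothing. Volume is non-decreasing in alpha and converges to the
convex-hull volume; alpha too small for the landmark spacing yields holes
and a warning.

## Expansion power

Power is kept as the signed product `(−p)·dV/dt` at every frame — supra-
ambient pressure during expansion shows as negative power — rather than
zeroing non-sub-ambient frames; the maximum is searched over the signed
series, which reduces to the flip-sub-ambient-sign convention whenever
p ≤ 0. The peak-power window reports both all frames with power ≥ 0.75×max
and the maximal contiguous block containing the peak (the definition is
ambiguous between the two). Peak rotations, strains and strain rates are
extracted within the window. Normalizations divide peak power by configured
bilateral muscle masses, body mass, and the maximum change in mouth volume.
Per-individual tables report mean ± s.e.m. (sd/√n over strikes; a single
strike reports s.e.m. 0 with n = 1).

## Synthetic strikes

The generator emulates a ~30 cm fish striking at 300 frames/s video and
1000 Hz pressure: a static six-marker body plane; neurocranium (5 markers)
and cleithrum (4 markers) rotating about their joint z-axes with sin²
pulses (defaults: 3° elevation, 8° retraction over a 0.4 s strike starting
at 0.3 s, peak gape at 0.5 s); collinear epaxial (0% strain) and hypaxial
(4, 8, 6, 5% subregion strains) marker chains whose segment lengths follow
L₀(1 − strain/100) exactly; an endocast cloud (Fibonacci-sampled
half-ellipsoid shell, interior shells and midsagittal closure plane, ~370
landmarks) uniformly scaled about a point on the closure plane so its
alpha-shape volume tracks V(t) = 40 + 60·pulse cm³ (calibrated against the
base cloud's own alpha-shape volume, so scaling error is the residual
alpha-threshold dependence, ~0.06%); and a pressure trace proportional to
the clipped expansion rate, scaled so the analytic peak power equals the
10 W target (implying a ~21 kPa sub-ambient pulse). These scales sit inside
the ranges reported for suction-feeding fish of this size (retraction
6–11°, axial strains 4–8%, volumes ~70–120 cm³, powers 0.07–29 W,
pressures to −32 kPa); muscle and body masses (hypaxial 0.05 kg, summed
cranial 0.004 kg, body 0.5 kg) were chosen once so normalized powers land
in realistic ranges (~200 W kg⁻¹ hypaxial).

Noise is i.i.d. isotropic Gaussian per tracked-marker coordinate (default
σ = 0.08 mm, the precision scale of marker tracking); endocast and jaw-tip
landmarks are virtual and receive no direct noise (in real data their error
enters through pose error). Pressure noise defaults to 1% of the pulse
amplitude, white, added before filtering. With σ = 0 every stage reproduces
its truth to numerical tolerance, and the strike timing is laid on the
frame grid so noiseless amplitude recovery is exact rather than
interpolation-limited. Same seed ⇒ bit-identical bundles.

What the generator does **not** emulate: marker dropout by default
(configurable via gaps in the CSV), soft-tissue volume offsets (the real
endocast overestimates absolute volume), spatial pressure gradients in the
mouth, inertial/drag power terms, bent muscle chains, and anatomically
realistic sternohyoideus geometry — in the schematic two-bone skeleton the
bone-attached sternohyoideus lengthens slightly during the strike (as it
does in some catfishes) rather than shortening; the generator uses it to
cross-validate the intramuscular-marker and fiber-landmark measurement
routes, which agree to 1e-6 by construction. Passing tests therefore show
the computations are correct under these idealized conditions, not that
real recordings are free of the above effects.

## Numerical choices and problem sizes

Collinearity is rejected when the second singular value of centred markers
falls below 1e-6; quaternion filtering renormalizes to unit length;
degenerate endocast frames become missing values with a warning rather than
zeros. Test problem sizes (300-frame strikes, 10⁴-rotation Euler sweeps,
2×10³-draw Monte-Carlo residual checks, 50-cloud alpha sweeps) were chosen
as the smallest that make the statistical assertions stable across seeds.
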