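# Methods

## The model

A point target sits in direction `n = (cos θ cos φ, sin θ cos φ, sin φ)`,
with azimuth θ and elevation φ restricted to ±60°.  Each ear is modelled as
a rigid rectangular array of four omnidirectional microphones with
horizontal/vertical spacings δ_y, δ_z, summed coherently.  Under the
far-field plane-wave assumption the summed response factorises into the
closed form

    S_env(t; n) = 4 A cos(π δ_y ñ_y(t) / λ) · cos(π δ_z ñ_z(t) / λ),

where `ñ(t) = L(t)ᵀ n` is the target direction expressed in the rotating
ear frame.  This identity is verified in the test suite against an
independent phasor-sum oracle (explicit `Σ exp(2πi r_k·n/λ)` over the four
rotated receiver positions) to a relative error below 1e-9.

The ears rotate periodically.  Orientation histories follow the
roll–pitch–yaw convention `L(t) = R_z(θ_e(t)) R_y(−φ_e(t)) R_x(−ψ_e(t))`
with right-handed active rotations about fixed body axes.  Each axis is
assigned one of six left/right pairing types restricted to the 0th and 1st
Fourier modes: `0`, `CONST~` (constants of opposite sign), `SIN`, `SIN~`,
`COS`, `COS~` (a `~` marks anti-phase).  All oscillating functions share
amplitude C and frequency f_e.

The directional cue is the interaural level difference

    P(t; n) = 20 log₁₀ ( S_env_left(t; n) / S_env_right(t; n) )  [dB],

in which the source amplitude A, the target distance, the reflectivity and
the rigid placement of the two ears all cancel.  `P` is sampled at 1 ms over
one full motion period.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| echo wavelength λ | 5 mm | 70 kHz constant-frequency echo in air |
| motion period T | 66 ms | two 33 ms echo listening windows tile one period exactly; the silent gap carries no information, so the period is identified with the two concatenated windows |
| sampling interval | 1 ms | 66-sample ILD vectors |
| amplitude C | 15° | the observed anti-phase pitch excursion of horseshoe-bat pinnae is about ±15°; applied to every non-zero pairing |
| δ_y = δ_z | 0.49 λ (2.45 mm) | see calibration note below |
| direction domain | \|θ\|, \|φ\| ≤ 60° | the frontal field used throughout |
| evaluation grid | 23 × 23 (5.45° steps) | the same grid used to test the learned inverse map |

**Calibration of the microphone spacing.**  The spacing is only constrained
qualitatively ("slightly smaller than half the wavelength", with a
half-amplitude angle in the 40–90° reference band for constant-frequency
bats; 0.49 λ gives ≈ 59°).  Within that band the degree-of-injection values
are sensitive to the spacing because it sets the dB contrast of the ILD.
δ = 0.49 λ was selected once, as the value in the admissible band that
reproduces the four published showcase degrees of injection
(≲0.001 / 0.24 / 1.52 / 1.35) simultaneously; at 0.45 λ all dynamic-motion
values come out ~40% low.  All ordering- and counting-based results are
insensitive to this choice, which is exposed in the configuration.

## Degree of injection

`U_M` is evaluated on the grid with the discrete sup-norm over the sampled
period in the denominator and the Euclidean chord distance between unit
vectors in the numerator; the sup over the continuum is approximated by the
max over the grid.  Signal distances below `eps_db = 1e-9` dB indicate an
exact injectivity violation at grid resolution; the ratio is then replaced
by the cap `U_cap = 1e6` so that the integral in `I[M]` stays finite (the
definition prescribes +∞).  With the cap, a fully degenerate motion (both
ears moving identically, so `P ≡ 0`) yields the attainable minimum
`I = (U_cap · domain area)⁻¹ ≈ 2.7e-7`.  The quadrature is a per-cell
rule with weights `cos φ Δθ Δφ` in **radians**; the numerical value of
`I[M]` is tied to this convention.  Refining the grid lowers `I`
moderately (the max is taken over more candidate pairs) but preserves all
orderings; this is asserted in the tests.

## Learned inverse map

A fully connected network (input: the 66-sample ILD vector scaled by
1/20 dB⁻¹; three ReLU hidden layers; linear output: (θ, φ) scaled to
[−1, 1]) is trained with mean-squared error for 5000 steps.  Each step draws
a fresh batch of directions uniformly from the ±60° square.  During the last
250 steps the full 23×23 grid is evaluated after every step; the final guess
per direction is the coordinate-wise median of those 250 outputs, and

    E[M] = max over the grid of (|θ − θ_guess| + |φ − φ_guess|)   [degrees].

Choices the protocol leaves open were fixed as follows and are exposed in
`TrainingProtocol`:

- hidden sizes (128, 128, 128): at width 64 the well-designed motions
  plateau around 5–6° where ~2° is attainable; widths beyond 128 bring
  marginal gains at twice the cost;
- Adam, learning rate 5e-3 with cosine decay to zero, batch 128: the
  best-performing of a small design scan (rates 1e-3 to 5e-3, widths
  96–192, batches 64–256, input scales 1/10 and 1/20) evaluated on the
  showcase and near-criterion motions; the cosine decay keeps the high
  initial rate stable;
- weight initialisation is He-normal, seeded; the training-direction stream
  and the initial weights depend only on the seed, so a (motion, seed)
  result is bit-reproducible whether the network is trained alone or inside
  a stacked ensemble (the trainer batches any number of independent
  networks through stacked GEMMs; equality is asserted in the tests);
- the trainer runs in float32; the reference float64 acoustics path and the
  trainer's fused ILD generator agree to ~1e-4 dB, far below the 0.0003 dB
  float32 quantisation of the inputs themselves.

Degraded ILD resolution (the robustness experiments) is modelled by
rounding ILD values to the nearest multiple of the quantisation step
(half-up at midpoints) in **both** training and evaluation inputs: a
listener with a coarse intensity code hears coarse signals throughout.

## Motion taxonomy

Each ear's orbit is the closed curve `(ψ_e(t), φ_e(t), θ_e(t))` in angle
space, sampled uniformly over one period.  Orbit and hull dimensions are
affine ranks of (pooled) centred samples via singular values thresholded at
1e-8 relative to the largest — valid because for 0th+1st Fourier-mode
motions every orbit is a point, a segment or a planar closed curve, and the
convex hull of a union has the dimension of its affine span.  The four
conditions are evaluated as: hull dimension = 3; both orbit dimensions ≥ 2
("does not degenerate to one dimension", which in this family also excludes
point orbits); yaw functions not coincident; pitch functions not
coincident.  Coincidence is decided analytically from the pairing names
(left ≡ right exactly for `0`, `SIN`, `COS` with zero phase offset) and
numerically (max over sampled times) for phase-shifted motions.  This
reading reproduces both published counts — 5 of 36 pitch-anti-phase
patterns satisfy the first three conditions, 14 of 216 satisfy all four —
and both counts are invariant to C and f_e, which the tests assert.

Mirror symmetry about the midsagittal plane,
`ψ_l(t+T/2) = −ψ_r(t), φ_l(t+T/2) = φ_r(t), θ_l(t+T/2) = −θ_r(t)`,
is checked at sampled times; exactly one of the five high-performance
pitch-anti-phase patterns (`SIN,COS~,CONST~`) satisfies it.

## What the simulation does and does not capture

All inputs are generated by the model itself; there is no measured data.
The simulated conditions are an idealisation of constant-frequency bat
echolocation: a single stationary point target, noiseless far-field plane
waves, a separable anisotropic directivity with no side lobes, perfectly
rigid ears, and exactly periodic single-harmonic motions.  Passing tests
therefore demonstrate properties of the *model* — which ear-motion classes
make ILD-only direction detection well-posed — not of any measured bat.
Known omissions: soft-pinna deformation, measured head-related transfer
functions, Doppler cues, atmospheric attenuation, target strength and
glint, and FM-based ranging.

## Known quantitative gaps

- With the published protocol dimensions but calibrated spacing, the
  detection error of the dynamic-but-deficient motion `[0, COS~, CONST~]`
  converges to ≈ 20–22° against a reported 16.9°.  The value is set by the
  geometry of the pseudo-inverse (the level sets of a non-injective map at
  the network's effective ILD resolution) and is insensitive to network
  capacity, batch size and input scaling in our scans; it lies inside the
  8–35° band that the non-injectivity analysis itself predicts for this
  motion class.
- Printed degree-of-injection values are matched within ±20% after the
  spacing calibration; exact agreement would require the unpublished grid
  and spacing used for the originals.
- In the phase-difference family, the zero-offset motion (coincident pitch
  and yaw functions, opposite constant rolls) turns out to be *injective
  but severely ill-conditioned*: its degree of injection is ≈ 0.19, yet a
  noiseless network still inverts it to ≈ 3°.  Its deficiency appears
  exactly where the index says it should — under finite ILD resolution,
  where its error collapses to ~38° at a 1 dB step while the 180°-offset
  motion stays near 12°.  The phase-sweep tests assert the degradation in
  that finite-resolution form.

## Problem sizes

Default experiment sizes were chosen so that every driver runs on a single
CPU in minutes: the 23×23 grid (529 directions, 529² signal-pair distances
per motion), 5000-step training with batch 128, three seeds for every
reported detection error, and ensemble-batched training for the 36-motion
sweep.  The 216-pattern sweep computes `I[M]` for all motions but trains
networks only for the condition-satisfying candidates by default.
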