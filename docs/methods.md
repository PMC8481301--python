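# Methods

This note documents the models, numerical choices and limitations behind
`eitvent`.  It is written for users who need to judge what the synthetic
evaluation does and does not demonstrate about a real device.

## Forward model

The thorax cross-section is a unit-bounding-radius circle (optionally an
ellipse with semi-axes 1.0 × 0.8 as a thorax-like variant) meshed with
linear (P1) triangles on concentric node rings; ring `i` carries `16·i`
nodes so the 16 electrode centres fall exactly on mesh nodes.  The number
of rings is `4·refinement`, giving `256·refinement²` elements; a multiple
of four rings makes each discrete electrode exactly half the
inter-electrode arc at every refinement, so refinement studies converge
cleanly.  Conductivity is piecewise constant per element.

Electrode 1 is centred on the ventral midline and numbering proceeds in
order of increasing polar angle (ventral → subject's left → dorsal →
subject's right).  Reconstructed images put row 0 at the ventral edge and
column 0 on the subject's right, the radiological display convention.
Every orientation-dependent quantity downstream (right/left and
ventral/dorsal fractions, CoV) derives from this single declaration.

The boundary condition is the complete electrode model: each electrode is
a boundary patch with contact impedance `z` carrying a prescribed net
current, assembled as the standard symmetric block system with a Lagrange
multiplier enforcing ΣU = 0.  Electrode geometry is not specified by any
device datasheet we model, so the defaults are explicit choices: electrode
coverage 0.5 of the inter-electrode arc, contact impedance `z = 1e-4`
(unit-depth Ω·m).  The small default places the electrodes in the
near-shunt regime of well-gelled contacts.  This matters for two
identities used as oracles: exact Ohmic scaling (σ → 2σ implies v → v/2)
and the Euler identity Σₑ J[m,e]·σₑ = −v_m hold *exactly* only when the
contact admittance scales together with the medium, because the CEM Robin
term z·σ·∂u/∂n is not homogeneous in σ alone.  At `z = 1e-4` the σ-only
residual of both identities is ≈0.2%, inside the 1% oracle tolerance; at
a mid-range `z = 0.01` it would be 4–6%.  The test suite asserts the
joint-scaling identity to 1e-10 and the σ-only versions at 1%.

Stimulation is adjacent drive, adjacent measurement, skipping pairs that
share an electrode with the drive (16 × 13 = 208 measurements), at 5 mA.
The drive frequency (100 kHz) is metadata: the model is real-valued.

The measurement Jacobian uses the adjoint (lead-field) method:
∂V_m/∂σₑ = −∫ₑ ∇u_drive·∇u_lead, with the lead field solved for unit
current through the measurement pair.  It is verified against central
finite differences (1% on 20 random elements; observed ≈3e-5).

A point-electrode solve (currents injected at single boundary nodes) is
retained as a test-only fallback because the homogeneous unit disk then
has the closed-form boundary potential u = I/(πσ)·[ln|x−sink| −
ln|x−source|]; the FEM agrees within 1.7% at refinement 3 (tolerance 5%).

## Synthetic data

The phantom has two elliptic lungs (centres (±0.42, 0), semi-axes
0.28 × 0.45) in a background of 0.48 S/m, with end-expiration lung
conductivity 0.24 S/m — soft-tissue versus deflated-lung values on the
usual tissue scales.  Lung-element conductivity is linearly coupled to
regional volume, σ(t) = σ_exp − k·w_region·V_region(t) with
k = 0.05 S/m per litre; air lowers conductivity, and the linear coupling
makes every downstream ground truth unambiguous.  The regional weights
(`right_weight`, default 0.5) split ventilation between the lungs;
optional first-order lags (τ_right, τ_left) on the regional volume signal
inject regional ventilation delay, and an optional dorsal weighting skews
the swing along the ventral–dorsal axis without changing its total.

The breathing protocol is sinusoidal tidal cycles (default 3 × 0.5 L at
4 s) followed by one SVC: a half-cosine inspiration from FRC to
FRC + 0.6·VC and a half-cosine expiration to FRC − 0.4·VC (default VC
4 L, 8 s + 10 s), so the SVC peak-to-trough excursion equals VC exactly.
Tidal volume and VC are not dictated by any published protocol we model;
0.5 L and 4 L are ordinary adult values and fully config-exposed.  EIT
frames default to 50 Hz; spirometry is generated at 25 Hz deliberately so
that the interpolation step in the linearity measure is really exercised.

Measurement noise is multiplicative Gaussian per measurement — matching
the scale-relative SD-over-mean SNR definition used for bench QC — at a
default relative SD of 5×10⁻⁴ (≈66 dB), comfortably inside a ≥60 dB
channel spec.  The four-recording sequence (device A, B, A, B on the same
phantom) shares one noiseless core with four independent noise
realisations; device B may carry its own noise level.  The bench
recording is a constant 0.5 V baseline (100 Ω network × 5 mA) with the
same noise model plus a linear gain drift per hour.

What the generator does *not* emulate: cardiac-related impedance
oscillations, posture and electrode-movement artifacts, electrode
detachment, anatomical thorax contours, 3-D current spread, or
between-maneuver physiological variability.  Because both emulated
devices see the same phantom through the same forward model, the
synthetic study tests the *pipeline's* agreement behaviour (noise
propagation, estimator calibration), not hardware differences; observed
repeatability is correspondingly far tighter than in human measurements.

## GREIT reconstruction

Training targets are small conductivity decreases (radius 0.1 of the
domain radius, 1% contrast) at candidate centres on a uniform 32×32 grid
over the bounding box, kept when the whole target disk fits in the
domain (~650 of 1024 on the circle) — a deterministic grid rather than
random sampling, for reproducibility.  Target data are linearised through
the Jacobian at the homogeneous baseline and normalised by the baseline
frame; desired images are uniform disks of radius 0.1 with unit integral,
weighted by the target's conductivity-area moment so the amplitude
response is uniform per unit perturbation.  Conductivity *decreases* map
to *positive* images, so lung images are positive on inspiration.

R = X̃Yᵀ(YYᵀ + λ²Σₙ)⁻¹ with Σₙ = ε²I from the configured device noise.
The noise figure is the ratio of measurement-domain SNR to image-domain
SNR over the training set: NF(λ) = [mean|Y|/ε] / [mean|RY|/rms(Rn)].
NF decreases monotonically in λ (asserted by sampling), so the target
NF = 0.5 (with a 5% convergence tolerance) is found by bisection in
log λ over a 16-decade bracket; an unreachable request raises with the
achievable range.  The 32×32 pixel grid is masked to the domain; all
GREIT hyperparameters are function arguments, never hard-coded.

Image quality properties verified: single-target centre-of-gravity error
below 0.15 of the domain radius (observed ≈0.08 on a ring of test
positions), and ≥70% of reconstructed amplitude on the correct side for
a one-lung perturbation.

## Ventilation indices

The global curve is the per-frame sum of in-mask pixels.  Breath
segmentation uses prominence-filtered extrema (prominence 0.1 of the
curve's excursion, config-exposed), reduced to a strictly alternating
min/max sequence with both endpoints as candidate troughs; the SVC is the
trough→peak→trough triple of maximal amplitude.  The reference frame is
re-selected as the first detected end-expiration frame (fallback: frame
0) and the recording re-reconstructed against it.

Measures follow the standard definitions: TV images are end-inspiration
minus end-expiration; TV/SVC uses the mean TV of complete pre-SVC tidal
breaths over the SVC excursion; the volume–impedance r interpolates
spirometry linearly onto the EIT timestamps of the SVC segment only
(config-switchable to the whole recording was considered and rejected as
the SVC is where volume is controlled); impedance amplitudes may be
scaled to mL via SVC volume / ΔZ_SVC, which leaves every ratio-type index
unchanged.  The functional-lung ROI is TV ≥ 20% of max (a common
functional-lung convention; config-exposed).  GI uses the median over ROI
pixels only, per the dominant convention.  CoV is the amplitude-weighted
centroid of pixel-row centres ((row+0.5)/32) in percent, ventral = 0.
RVD is computed over the SVC inspiration as the low-flow surrogate:
per-pixel time to cross 40% of its inspiratory change, linearly
interpolated between frames, as % of inspiration time; pixels that never
cross are excluded and logged; RVD-SD is the population SD over the ROI.
Right/left and ventral/dorsal splits are image midlines, not segmented
lungs — the indices describe regions, not anatomy.

Known interaction: a first-order lag attenuates the tidal oscillation it
delays, so with lags ≳0.5 s and default volumes the tidal prominence can
fall under the 10% detection threshold; the multi-subject study therefore
runs detection at prominence 0.05.  Recovery performance at 66 dB noise:
configured right fraction 0.6 is recovered with ≈0.008 mean bias over 20
seeded runs; CoV within 0.1 percentage points of the phantom centroid.
The residual compression of the right fraction toward 0.5 (≈0.007) is
reconstruction blur across the midline, not noise.

## Agreement statistics

The equivalence test is a *paired* TOST on per-subject A−B differences
(both devices measure the same subjects; the reported p is the larger
one-sided p).  Margins are nowhere standardised, so the default is
0.2 × the across-subject SD of the device-B values per index,
overridable, and always reported with the p-value.  Bland–Altman uses
bias ± 1.96·SD with the sample (n−1) SD.  Repeatability is
100·|m₁−m₂|/mean per subject, summarised mean ± SD, with zero-mean
subjects recorded as missing.  TOST power uses the noncentral-t sum
P(reject lower) + P(reject upper) − 1, cross-checked against Monte-Carlo
(agreement within 0.01 at n = 50).  Calibration properties asserted by
simulation: type-I error at the margin ≤ α + 2% (5000 replicates), LoA
coverage 93–97% (10 000 normal differences).

The synthetic study draws per-subject phantoms from stated priors (right
fraction N(0.55, 0.02) truncated to (0.45, 0.65); tidal volume
N(0.5, 0.05) L; VC N(4.0, 0.4) L; lags |N(0, 0.1)| s), simulates the
A, B, A, B sequence, and emits per-index agreement and repeatability
summaries.  Per-subject failures are logged and skipped; the study
continues.

## Bench QC

Channel SNR is −20·log₁₀(sample SD / |mean|) with the (N−1) divisor; the
absolute value in the denominator is a deliberate hardening (the sign of
a mean voltage is representation-dependent) and is logged.  A zero-SD
channel reports +∞ with a flag.  Mean SNR is the arithmetic channel mean.
Drift over a window is the worst-channel relative difference between
first-minute and last-minute means — endpoint averaging rather than
endpoint samples, so an 80 dB noise floor moves the estimate by <0.01
percentage points.

## Problem sizes and determinism

Default analysis meshes are refinement 2 (1024 elements, ~560 nodes);
oracle comparisons run at refinement 1–3.  Full 50 Hz recordings (1501
frames) are used for the headline linearity computation; unit and
property tests run 10–25 Hz protocols on the same phantoms, which leaves
every index definition and code path identical while keeping forward
simulation cheap.  All stochastic steps take explicit integer seeds
(numpy `default_rng`); seeded generation is bit-reproducible, and the
acceptance script derives independent sub-seeds from its single `--seed`
via `SeedSequence`.

## Limitations

2-D only; real thorax contours, absolute imaging, complex (frequency-
dependent) conductivity, cardiac signals and electrode-movement
compensation are out of scope.  The printed human-subject agreement
numbers of a real device comparison cannot be reproduced from synthetic
phantoms — the study machinery reproduces the *methodology* (measures,
tests, report shapes) under controlled ground truth instead.
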