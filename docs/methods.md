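# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mrfrelia`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## The problem

Quantitative T1 mapping by magnetic resonance fingerprinting (MRF) estimates
tissue relaxation times by matching each voxel's measured signal evolution
("fingerprint") against a dictionary of simulated evolutions. The package
implements a complete desk-scale analogue of a paediatric scan–rescan study of
this technique: it simulates a longitudinal two-session cohort of digital
phantoms, acquires and reconstructs fingerprinting data under four conditions
(single vs. combined scans, with and without off-resonance correction),
registers sessions through an unbiased half-way space, and quantifies
scan–rescan reliability voxelwise, per ROI and along white-matter tract
profiles, including R1–age correlations.

## Signal model

The sequence is an inversion-prepared, gradient-spoiled echo train: each of
`n_groups` acquisition groups starts with an adiabatic inversion (inversion
time 15 ms), followed by `trs_per_group` excitations with a varying flip-angle
schedule (one readout per TR, TR 12 ms, TE 1.8 ms), then 1.2 s of free
recovery. Signals are simulated with the extended phase graph (EPG)
formalism: configuration states (F+_k, F-_k, Z_k) up to order 30, RF mixing,
unit gradient dephasing per TR, exponential relaxation with Z0 recovery. The
simulation is vectorised over (T1, T2) pairs so whole dictionaries build in
one pass.

Choices and their reasons:

* **Flip schedule**: a smooth half-sine ramp from 5° to 35° per group. At
  higher peak flips (75°) the fingerprint family needs noticeably more than
  five principal components (for white matter, the out-of-basis energy grows
  threefold), which destabilises the subspace reconstruction; 35° keeps K=5
  capture above 99.8% while retaining T1/T2 sensitivity. Configurable.
* **EPG truncation at 30 orders**: validated against an independent
  isochromat Bloch simulation (200 spins, ideal spoiling); agreement is at
  machine precision on the schedules used here, far below the 1% documentation
  threshold.
* **Inversion efficiency 1.0** (ideal adiabatic pulse), configurable.
* The zero-flip limit reproduces the closed-form inversion recovery
  1 − 2·exp(−t/T1) exactly, which pins the timing bookkeeping.

The dictionary covers T1 = 20…3000 ms in 20 ms steps plus 3200…5000 ms in
200 ms steps (long-T1 fluids), with T2 defaults of 10–300 ms in 10 ms steps
plus 500–2000 ms in 100 ms steps; only physical pairs (T2 ≤ T1) are
simulated. A coarser "desk" T2 grid (six values) is used inside the cohort
experiment for speed; the matching-agreement guarantees are stated for the
full grid, whose 10 ms T2 spacing brackets the phantom's class T2 values.

The subspace basis Φ is the first K = 5 right singular vectors of the atom
matrix; at the default protocols it captures ≥ 99.7% of squared singular-value
energy, and compressed (K = 5) matching reproduces full-fingerprint matching
on ≥ 99.9% of noiseless phantom voxels.

## Synthetic phantoms and cohort

`make_phantom` builds a 2D-multislice head: an elliptical cortex rim (GM),
interior WM, two CSF ventricles, a para-midline corpus-callosum band split
into five anterior→posterior segments, and three tract-mask channels. Class
T1 values (WM 850, GM 1400, CSF 4200 ms) and T2 values (60/80/1500 ms) are
literature-style configuration entries, not fitted quantities. T1 receives a
smooth multiplicative texture (sd 5%, hard-clipped at ±5%, correlation length
4 voxels) that plays the role of anatomical heterogeneity; T2 is constant per
class. The texture is deliberately applied to T1 only: with T2 also
off-grid, the normalized-correlation matcher trades T1 against T2 and lands
on the second-nearest T1 atom for a sizeable fraction of voxels even with
exact noiseless signals.

The CC segment T1 means are offset from WM by (−30, +10, +45, +25, −15) ms
anterior→posterior — an inverted-U with the maximum in the mid-posterior
segment, the shape the pipeline must preserve end to end.

The off-resonance field is a smooth background (1 Hz RMS) plus a Gaussian
pocket at the anterior head boundary (the air-cavity analogue), whose tail
reaches into anterior tissue. Stand-alone phantoms default to an 80 Hz
pocket; the cohort uses 30 Hz, matched to its 3 ms readout so the
uncorrected pipelines show localised blurring rather than global corruption
(see "Why the cohort is simulated in-model" below). Coil sensitivities are
smooth complex maps normalised to unit root-sum-of-squares everywhere.

`simulate_cohort` draws subjects aged 8–13 y with white-matter
R1 = 1.05 + 0.012·age + N(0, 0.02²) s⁻¹ (so WM T1 ≈ 850 ms mid-cohort);
session 2 follows 2–4 months later with drift along the same slope, a random
rigid repositioning (sd 1°, 1 mm), and independent thermal noise (complex
k-space noise, sd = 3% of RMS signal). The slope is set so that the age
effect is detectable through the tract machinery at n = 40 despite the
anatomy-texture noise on tract means (~0.026 s⁻¹); the analytic
age–R1 correlation implied by the defaults is
slope·sd(age)/√(slope²·var(age)+sd_b²) ≈ 0.78 at the subject level.

What the generator does *not* emulate: cortical folding, B1+ inhomogeneity,
magnetisation transfer, physiological noise, within-session motion, and any
diffusion contrast. Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline under rigid motion, thermal noise and
smooth field perturbations — not robustness to the full complexity of in vivo
paediatric data.

## Sampling and encoding

Desk-scale sampling replaces 3D spiral projections with per-group
pseudo-random variable-density Cartesian masks (centre-weighted inclusion
probability; uniform masks occasionally leave the k-space centre uncovered
and destabilise the single-scan fit). Samples are assigned round-robin to the
group's TRs; each carries an acquisition time on a 0–5 ms readout ramp
quantised to a small set of distinct values (default 16, cohort 8) so that
the exact off-resonance operator is computable. Scan pairs are complementary:
scan 2 samples the next block of the weighted permutation, disjoint from scan
1 wherever the undersampling factor permits. A `full_kt` scheme (every
k-point at every TR) makes the encoding normal matrix the identity and is
used for the exact-recovery guarantees.

The encoding operator is y = P F S Φ c with unitary FFTs; off-resonance
enters as conjugate-phase factors exp(−2πi·b0·t) approximated by L time
segments with linear (hat) interpolation weights — exact when the segment
times coincide with the distinct sample times, which is the tested contract.
On-grid coordinates use an FFT gather; off-grid coordinates (produced by
rotational k-space motion compensation) fall back to an exact direct DFT,
which is affordable at desk scale and keeps the adjoint exact. No gridding
NUFFT is needed or used. Motion compensation rotates scan-2 coordinates and
applies the translation phase ramp; the handful of corner samples a rotation
pushes past the Nyquist band are clipped and their data discarded. Coil maps
are treated as static while the head moves — the standard approximation of
k-space motion compensation; the residual coil-weighting mismatch is smooth
and small.

## Reconstruction

The objective is ½‖Ac − y‖² + λ·Σ_p‖R_p c‖_* with locally-low-rank patches
(8×8 per slice, K-column matrices, nuclear norm). Solver details:

* λ = 0 uses conjugate gradient on the normal equations (the proximal
  iteration needs an order of magnitude more iterations for the same
  accuracy). With full k-t sampling CG converges in a couple of iterations
  and the fit equals the temporal projection of the true signals to machine
  precision.
* λ > 0 uses FISTA with a monotone safeguard (momentum restart whenever the
  objective would increase), so the recorded objective is non-increasing;
  five consecutive increases raise a diagnostic error. An optional CG warm
  start (default in the cohort experiment) shortens the transient.
* The LLR prox uses one seeded patch shift per reconstruction rather than a
  random shift per iteration: a per-iteration shift changes the regularizer
  between iterations and voids the monotonicity contract. Per-iteration
  shifts remain available behind a configuration switch.
* The step size is 1/(1.05·L̂) with L̂ from power iteration; the cohort
  experiment estimates one step per reconstruction condition and reuses it
  (15% margin), and freezes λ per condition after the first solve so every
  session and subject sees identical regularization.
* λ's default scale is λ = lam_rel · max|Aᴴy| with lam_rel = 0.05 for
  stand-alone use and 0.02 in the experiment.

## Why the cohort is simulated in-model

The cohort experiment synthesises its acquisitions from subspace-projected
EPG signals (the "in-model" forward) rather than raw EPG signals. At full
sequence length (16×500 TRs) the K = 5 residual is negligible, so projection
changes nothing physically; at the truncated desk protocol (~140 TRs) the raw
residual is several percent and aliases into a deterministic T1 bias of
20–70 ms that is *shared between sessions*. Shared bias inflates single-scan
scan–rescan correlations and can invert both the duration ordering and the
apparent effect of B0 correction — artefacts of the truncation, not of the
method. Projection restores the regime the full-length sequence operates in.
The exact (unprojected) forward remains the default everywhere else and is
what the parameter-recovery and B0-pocket checks use.

## Registration and the half-way space

Inter-session rigid motion (in-plane rotation about the volume centre plus
translation) is estimated on the magnitude of coefficient 3 (high tissue
contrast) by multi-resolution grid search plus twice-restarted Powell
refinement. The refinement metric uses cubic interpolation: with linear
interpolation the MSE minimum itself is displaced by ~0.4°/0.5 mm of
interpolation-smoothing bias, more than the documented 0.2°/0.1-voxel
recovery accuracy. Sessions are resampled into the half-way space (rotation
angle and screw translation halved; the split satisfies
half_b ∘ half_a⁻¹ = full transform to 1e−8), so both sessions undergo equal
interpolation and swapping the session labels changes the resulting T1 maps
by under 2% relative RMS. Coefficient maps are resampled (linear, real and
imaginary parts) *before* template matching; matching after resampling is
asserted by a wiring test.

## Matching and quantitative maps

Template matching maximises |⟨c_voxel, atom⟩|/‖c_voxel‖ over the compressed
dictionary; ties resolve to the lowest T1 (atoms are ordered by (T1, T2) and
the first maximum wins). The matched amplitude serves as a proton-density
surrogate, and R1 = 1000/T1 ms⁻¹ with non-positive T1 propagating as missing.
T2 maps are produced but carry no accuracy claim (no B1 mapping is modelled).

## Reliability statistics

Voxelwise: Pearson r across masked voxels plus R² about the fixed line
y = x (sensitive to additive bias; always ≤ the squared Pearson r). ROI:
across-subject r/R² of ROI means plus the two-measurement coefficient of
variation CV = (|a−b|/√2)/mean·100 (sample-sd convention; the worked example
(1000, 1020) ms gives 1.400%). Bland–Altman summaries use ±1.96 sd limits.
The pipeline-comparison model r ~ duration·B0 + age + (1|participant) is fit
by REML via statsmodels MixedLM; parameter recovery (planted +0.03 duration
effect at 48 observations, recovered within ±0.01) is part of the acceptance
suite. An all-identical-response table short-circuits to zero effects and
variances rather than a singular fit.

## Tract profiles

Bundles are generated as smooth Gaussian-process-like perturbations
(correlation length ≈ one sixth of the curve) of core curves embedded in the
phantom WM — seven callosal-analog arcs plus seven hemispheric-analog curves.
A configurable fraction of streamlines is displaced by 8× the bundle spread
to serve as gross outliers. Cleaning recomputes the node-wise mean core and
drops streamlines whose mean distance to the core exceeds the distribution
median by 3 robust scale units (sd of the 5-MAD-pre-trimmed bulk), or whose
length exceeds the mean by 4 sd, iterating up to five times. Both rules are
one-sided ("deviates by more than", "longer than"). The robust scale matters:
with the raw sample sd, a 10% fraction of gross outliers inflates the scale
to exactly the 3σ masking point (0.9/√0.09 = 3), and arbitrarily gross
outliers survive at random.

Profiles sample scalars at 100 equidistant arc-length nodes per streamline
(linear interpolation, half-voxel boundary margin), weight streamlines per
node by a Gaussian in the distance from the node's cross-sectional centroid
(scaled by the node's spread), and restrict analysis to the middle 80 nodes.
Node ordering follows the tract's orientation tag, so point-order reversal is
harmless. Tract-mean reliability is the across-subject Pearson r of profile
means with a 68% bootstrap CI; R1–age correlations pool both scans (age at
scan) and are Benjamini–Hochberg corrected at q = 0.05 across tracts.

## Voxelwise masks and the duration comparison

Voxelwise reliability is computed on the white-matter mask eroded by one
in-plane voxel. At 3 mm desk voxels, WM/CSF boundary voxels flip by hundreds
of ms under sub-voxel session misalignment (partial volume across the
dictionary grid) and would dominate the voxelwise variance; excluding them is
the desk-scale analogue of a segmentation-derived mask with CSF-contaminated
voxels removed.

The scan-duration comparison (combined vs. single scans) is an SNR effect of
roughly +0.03 in r. It is evaluated on motion-free sessions at the default
noise level. With inter-session motion, two desk-scale effects confound the
per-subject ordering: the registration estimator has a scanner-frame
attractor for sub-voxel motions (both sessions share the trajectory, so
reconstruction artefacts are partially fixed in voxel space and pull the MSE
minimum toward zero), and the residual misregistration noise — common to all
four pipelines — exceeds the duration effect for occasional subjects. Motion
handling is still fully exercised: registration recovery, half-way
unbiasedness and the motion-on experiment run elsewhere in the suite; only
the directional duration check excludes it.

## Experiment sizes and runtimes

The default experiment uses 8 subjects, 40×40×2 voxels (3 mm), 7 groups × 20
TRs, 3 coils, undersampling 1.6 per scan, 25 FISTA iterations after a 10-step
CG warm start, and 3 off-resonance segments; it completes in about six
minutes on one CPU. The parameter-recovery check runs the full 64×64×3,
16×60 protocol with the complete dictionary in about one minute. These sizes
are the package's desk-scale choices; all invariants are size-agnostic and
the configuration objects accept larger settings.

## Known limitations

* The desk-scale acquisition (hundreds of TRs, few coils, 2D multislice)
  produces absolute T1 noise far above what the full-length 3D acquisition
  achieves; all guarantees are therefore relative/directional (orderings,
  agreements, recoveries) rather than absolute accuracy claims.
* Cartesian variable-density masks alias differently from spiral
  projections; trajectory-specific artefact structure is out of scope.
* B1+ inhomogeneity is not modelled, so T2 estimates are nominal.
* The rigid model covers in-plane rotation plus translation; full 3D
  rotations are not enabled in the cohort generator.
* The tract age-effect recovery at n = 40 carries anatomy-texture noise that
  is shared across tracts; individual cohort realisations vary noticeably in
  how many tracts reach FDR significance (the suite's fixed-seed check and
  the acceptance script's reseeded run can legitimately differ).
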