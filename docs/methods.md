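# Methods

`sodiumqa` turns a scanner-side quantitative ²³Na-MRI quality-assurance
protocol into a fully desk-testable pipeline.  Every stage a physicist would
run on a 3 T system — phantom preparation, 3D radial golden-angle
acquisition, gridding reconstruction, ROI regression calibration,
repeatability analysis, and coil bench tests — is replaced by a tested,
deterministic software stage.  This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
experiments do and do not demonstrate about real scanner data.

## Digital dilution phantom

The phantom models NaCl-filled cylindrical plastic vials in three sizes
(nominal fill volumes 50 / 15 / 7 mL).  Four concentrations — 77, 38.5,
19.25 and 9.625 mM, i.e. four exact two-fold dilutions of 154 mM saline —
appear in every size; a central small vial holds undiluted 154 mM saline as
the reference.  The dilution series is dyadic, so the concentration values
are floating-point exact.

Geometry defaults:

* small vial: 1.0 cm inner diameter × 8.5 cm (manufacturer values);
* large: 2.8 cm × 11.0 cm and medium: 1.5 cm × 11.8 cm — standard 50 mL /
  15 mL conical-tube dimensions chosen to match the stated fill volumes;
  both are config-overridable;
* the 12 ring vials sit at 30° steps on a 5 cm-radius circle with size
  classes interleaved (L, M, S, L, …), all axes parallel to z, the central
  vial at the origin.  The true bench phantom is only known to be "roughly
  circular and symmetric"; this layout realizes that symmetry (every ring
  vial has a same-size partner at the mirrored position) with no overlap —
  overlaps are checked and rejected by vial pair.

Rasterization assigns a voxel a vial's concentration iff the voxel center
lies inside the vial cylinder (0-based indices, voxel-center sampling,
center voxel at index `n//2`).  Rasterized vial volumes converge to the
analytic cylinder volume πr²L as the voxel shrinks; a warning is raised
when the voxel exceeds the smallest vial radius.

Relaxation defaults model aqueous saline: mono-exponential T2 (50 ms) and
T1 = 60 ms — the built phantom contains no gel, so the bi-exponential decay
seen in tissue does not apply.  An agarose-like preset (fast fraction 0.6,
T2 3 / 25 ms) is provided for tissue-mimicking simulations.

## Acquisition simulation

The signal model is the one the reconstruction chain implicitly assumes: an
RF-spoiled gradient-echo (FLASH) steady state with ideal hard-pulse
excitation and uniform coil reception,

    S(k, t) = Σ_v C(v) · A(α, TR, T1) · D(t) · exp(−2πi k·x_v) · ΔV,

with `A = sin α (1−E1)/(1−E1 cos α)`, `E1 = exp(−TR/T1)`, and `D(t)` the
(bi-)exponential transverse decay at time `t` after excitation.  Protocol
defaults: FOV 38.4 cm, nominal resolution 1.86 mm (kmax = 268.8 cycles/m),
15,460 spokes, TR 5 ms, TE 0.5 ms, FA 30°, 5 ms readout, 12 averages.
Maximum gradient (33 mT/m) and slab thickness (20 cm) are carried as
metadata only: gradient waveforms, slab profiles, B0 inhomogeneity,
off-resonance and B1 mapping are out of scope.

Spoke directions follow the 2D-golden-means (phyllotaxis) scheme
`cos θ_m = 1 − 2 frac(m φ₁)`, `φ_m = 2π frac(m φ₂)` with φ₁ ≈ 0.46557,
φ₂ ≈ 0.68233 — the standard 3D generalization of golden-angle ordering,
giving near-uniform spherical coverage for any spoke count.  Each spoke is
sampled center-out, uniformly in k from 0 to kmax with
`ceil(kmax·FOV) × 2` samples (104 × 2 at protocol scale; the oversampling
factor is configurable), sample j acquired at `t = TE + j·T_read/S`.
Ramp sampling is not modelled: the reconstruction consumes k-coordinates,
not waveforms.

Transverse decay during the readout is applied piecewise-constant over 8
readout time segments by default (each segment uses the decay at its
midpoint); the exact per-sample decay is available (`exact_decay=True`) and
is what the brute-force oracle uses when validating the segmented path.
For saline (T2 = 50 ms, 5 ms readout) the segmentation error is far below
the noise floor.

The forward DFT is evaluated exactly (no NUFFT approximation on the
simulation side).  For uniform center-out sampling the per-voxel phase
factors along a spoke form a geometric sequence, so the implementation
needs one complex exponential per (spoke, voxel) and accumulates the rest
by multiplication; the accumulated rounding (~S·ε) is orders below the
1e-10 tolerance at which the vectorized path is tested against an
independent double-loop DFT.

Noise is i.i.d. complex Gaussian per sample and per repeat, with per-repeat
streams spawned deterministically from the session seed
(`numpy.random.SeedSequence`); a dataset records its seed, σ and repeat
ids.  `calibrate_noise_sigma` finds the σ that produces a target
reconstructed image SNR (default 79 in the large 77 mM vial) by simulating
the full pipeline at a probe σ and applying the SNR ∝ 1/σ linearity of the
reconstruction, with two refinement iterations.  Each probe SNR is averaged
over four noise draws because the background-SD estimator from the four
22.5 mm noise ROIs carries ~10% sampling error per draw; the calibrated σ
then lands the long-run mean SNR within ~5–10% of target.

## Reconstruction

Density-compensated gridding (adjoint NUFFT), written against the numerical
contract rather than any library: samples × weights are convolved onto a
2× oversampled Cartesian grid with a width-4 Kaiser–Bessel kernel (Beatty
shape parameter), inverse-FFTed, deapodized by the kernel's analytic
Fourier transform, and cropped to the reconstruction grid
(`round(FOV/1.5 mm)` per axis by default).  Density compensation is the
analytic 3D radial law: weight ∝ k² with the k = 0 sample carrying the
central Nyquist cell, normalized to the sampled k-space ball volume — the
analytic form was chosen over iterative schemes for determinism and
testability.

Accuracy bookkeeping: a width-4 kernel at 2× oversampling carries ~1e-3
aliasing error, so the gridding image is validated against a brute-force
adjoint DFT at NRMSE ≤ 1e-3 on small instances, while the exact adjoint
itself is checked against the forward simulator through the inner-product
identity ⟨Ax, y⟩ = ⟨x, Aᴴy⟩ at 1e-6 (two independent code paths in
different modules).  Keeping both routes — approximate production path and
exact small-scale path — is a deliberate design choice: the 1e-6 adjoint
identity is unattainable for any finite-support gridding kernel and is the
property of the exact pair.

Repeats are averaged in complex k-space before gridding (noise SD drops by
√n; identical repeats are returned exactly rather than through a rounding
mean).  Magnitude images feed quantification, matching ROI statistics on
scanner magnitude images.  Session alignment is translation-only at integer
voxels via FFT circular cross-correlation of mean-subtracted magnitudes;
the normalized correlation peak (1 for identical images, ≪1 for unrelated
noise) flags low-confidence registrations below 0.2.  Sub-voxel and
rotational registration are out of scope because simulated sessions are
aligned by construction; the operation exists to exercise the workflow and
to undo deliberately injected shifts.

## Quantification

ROIs are placed automatically from the vial registry on the central axial
slice: one circle per vial at the vial center (12 mm diameter for large
vials, 8 mm for the others), plus four 22.5 mm background circles at
±0.35·FOV corner positions.  Automatic placement removes operator variance
relative to drawing ROIs on a co-registered ¹H image; ROIs are verified to
lie inside their vial footprint and background ROIs to touch no vial.

SNR = mean magnitude in the large 77 mM vial ROI divided by the SD of the
pooled background magnitude voxels, with no Rician correction — the
scanner-style definition.  Zero background SD (a noiseless simulation) is
flagged as infinite.

Calibration regresses mean ROI intensity on concentration by unweighted OLS
over five points: the four large vials (77, 38.5, 19.25, 9.625 mM) and the
pooled-background mean as the 0 mM anchor (a single-ROI anchor mode is
provided).  The background mean of a magnitude image is Rayleigh-biased
upward; this is documented, not corrected, because the anchor is meant to
mimic what is measured on a scanner.  The fitted line is inverted voxelwise,
`C = (I − intercept)/slope`, preserving negative values (they occur for
small low-concentration vials and are diagnostically meaningful).  Medium,
small and the 154 mM central vial are test points only — the central vial
is a genuine extrapolation beyond the fitted range.

Because the calibration is per-session and linear, concentration estimates
are invariant to any global intensity scale — a property tested directly.
One consequence worth noting: a per-day multiplicative intensity drift
(modelled below) cannot inflate inter-day CoV; only noise realizations and
nonlinearity (Rician floors) differ between days.

## Repeatability analysis

The experiment design mirrors the QA protocol: 3 scans within a session
(intra-day) × 3 weekly sessions (inter-day), both configurable.  Each
session draws fresh noise from a deterministic seed; days additionally
apply a ±2% global intensity drift (uniform, seeded per day) — retained for
realism even though, per the invariance above, it is absorbed by the
calibration.

CoV = 100 × sample SD (n−1) / mean.  Intra-day CoV per vial is computed
within each day and reported as the mean over days (the standard pooled
form; the protocol's single-session n = 3 definition is the one-day special
case).  Inter-day CoV uses the first scan of each day (n = 3).  Zero means
yield an undefined-CoV flag; reported tables render CoV > 50% as ">50.0"
while machine-readable output keeps raw values.  The report is a pure
function of the session results and never re-runs simulations.

The flip-angle sweep simulates one session per FA (default 10°–50°, five
values) at a fixed seed, so the same noise realization underlies every FA
and the SNR ordering reflects the steady-state amplitude alone.  For
T1 = 60 ms and TR = 5 ms the steady-state optimum (Ernst angle) is
arccos(e^(−1/12)) = 23.07°, so the best sampled FA is 20° or 30°.

## Coil bench module

Protocol arithmetic (scan time = spokes × TR × averages, Larmor frequency
γB₀, Q = f₀/bandwidth, Ernst angle) is definitional.  The
perturbing-sphere sensitivity is

    η = c_pol √( μ₀ (f₁² − f₀²) / (π² B_w,eff r_s³ f₀²) )   [T·W^(−1/2)]

with c_pol = 1/2 (linear) or 1/√2 (quadrature drive, where the power splits
between two channels) and B_w,eff = 2 × measured bandwidth when the coil
ports are open during the bench measurement (a flag, since closed-port
measurements are also valid).  Published renderings of this formula are
frequently typeset ambiguously; the placement of the π² and bandwidth
factors used here is fixed by dimensional analysis (η² must carry
T²·s·J⁻¹) and by the perturbing-sphere literature, and the module's
contract is defined by its invariants: η = 0 at zero shift,
quadrature/linear ratio √2, η ∝ r_s^(−3/2), monotone in shift and inverse
in bandwidth.

## Desk scaling and problem sizes

`RunConfig.scaled(s)` shrinks grid shapes and the spoke count by `s` while
preserving the FOV; voxel sizes grow by 1/s so `kmax = 1/(2·resolution)`
remains self-consistent and the trajectory stays representable on the
reconstruction grid.  (Keeping the full-scale kmax with a reduced grid
would alias the gridding reconstruction, so the scale factor is defined to
scale spatial frequency along with the grid.)

The standard desk scale is s = 0.25: a 64³ reconstruction (6 mm voxels),
3,865 spokes × 52 samples, 12 averages.  At this size a full 9-session
repeatability experiment, including noise calibration, runs in well under a
minute on one CPU; the default test suite and the acceptance script use it
throughout.  Full protocol scale (256³ recon, 15,460 spokes × 208 samples)
is one flag away (`--scale 1.0`) but takes tens of minutes and several GB.

## What the synthetic experiments show — and what they do not

The simulator reproduces the statistical structure the analysis assumes:
steady-state amplitudes, transverse decay during readout, golden-angle
radial sampling, complex Gaussian noise at a calibrated SNR (~60–90 in the
large 77 mM vial, the regime of the bench protocol), partial-volume
underestimation of small vials, and the concentration-dependence of CoV
(high-concentration vials repeat within a few percent; small
low-concentration vials degrade sharply).  Passing tests therefore
demonstrate the correctness and self-consistency of the analysis chain, and
that the protocol's repeatability claims follow from its stated SNR regime.

They do not capture scanner physics absent from the model: B₀/B₁
inhomogeneity, off-resonance and susceptibility near air interfaces,
gradient-delay and eddy-current trajectory errors, physical temperature or
positioning drift between weekly sessions, or operator variance in ROI
placement.  Real inter-day CoVs therefore carry variance sources this
pipeline cannot exhibit; simulated inter-day CoV is structurally close to
intra-day CoV.

One desk-scale artifact deserves explicit mention: at s = 0.25 the
reconstructed resolution (~7.4 mm nominal) is comparable to the medium-vial
diameter (15 mm), and the unwindowed sharp kmax cutoff produces Gibbs
overshoot at the medium-vial centers — their estimates can exceed both
nominal and the large-vial estimates.  The small-vial underestimation trend
(small < large at matched concentration) is robust at desk scale and is the
property tested; the full small ≤ medium ≤ large ordering is a
full-resolution statement and is not asserted at s = 0.25.

## Numerical choices and degenerate inputs

* Gridding: Kaiser–Bessel width 4, oversampling 2, Beatty β; circular index
  wrap (exact for integer image positions); deapodization by the analytic
  kernel transform with the removable singularity handled explicitly.
* Density weights: k² law with the k = 0 sample assigned the central
  Nyquist cell volume; global normalization to the k-space ball volume.
* Ties and degenerate cases: zero-concentration phantoms simulate to
  exactly zero; empty ROIs, zero-bandwidth or reversed (f₁ < f₀) bench
  measurements, TE ≥ TR, degenerate single-concentration fits, and
  incomplete session designs all raise typed errors naming the offender.
* Determinism: every stochastic quantity derives from an explicit seed;
  sessions are bit-reproducible given (config, seed); config hashes are
  embedded in CLI outputs for replay.
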