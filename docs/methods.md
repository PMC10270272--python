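# Methods

`cdgram` implements the cardiodynamicsgram (CDG): a screening statistic for
suspected coronary artery disease computed from a resting 12-lead ECG alone.
The premise is electrophysiological: myocardial ischemia perturbs ventricular
repolarization subtly and, above all, *inconsistently* — the ST-T segment of
each beat stops repeating itself exactly.  The CDG quantifies that
beat-to-beat repolarization heterogeneity even when every individual beat
still looks normal to a reader.

## Pipeline

1. **Denoising** (`cdgram.io.denoise`).  Zero-phase Butterworth bandpass
   0.5–45 Hz (order 4, forward–backward) plus a mains notch (default 50 Hz,
   Q = 30).  Zero phase matters: any group delay would bias the J-point and
   T-end estimates downstream.  The passband edges are package defaults, not
   published values; they remove baseline drift and EMG while leaving the
   ST-T band (< 10 Hz) untouched.

2. **Vectorcardiogram** (`cdgram.vcg`).  The 8 independent leads
   (I, II, V1–V6) are mapped to orthogonal (X, Y, Z) with the Kors
   regression matrix.  The matrix is shipped as a versioned constant and can
   be overridden from CSV (`vcg.matrix_file`); derived limb leads are ignored
   even when present, and the mapping is keyed by lead name, never by column
   position.

3. **Fiducials and ST-T loops** (`cdgram.fiducials`).  R peaks come from a
   Pan–Tompkins-style detector (5–15 Hz bandpass, derivative, squaring,
   150 ms integration, adaptive threshold, 200 ms refractory) on the VCG
   magnitude, refined to the local magnitude maximum; a config option
   substitutes a single VCG lead.  Per beat, the J point is the first time
   the magnitude slope stays below 5% of the peak QRS slope for 10 ms
   (searched R+20..R+80 ms), and the T end is located by the tangent method
   on the dominant T lead against the PR-segment baseline.  All windows are
   configurable; beats whose fiducials do not resolve (typically a truncated
   final beat) are dropped and logged.  Each [J, T-end) segment is uniformly
   resampled to L = 100 points; records are expected to supply at least
   8 usable beats (a 20 s resting record at normal rates gives 15–20).

4. **Deterministic learning** (`cdgram.model`).  The concatenated loops form
   a recurrent orbit `x(k)` in 3-D loop space.  A Gaussian RBF network on a
   regular lattice (spacing = bounding-box extent / 5, expanded one spacing
   per side, width 1.5 × spacing) is trained with the observer/update pair

       x̂(k+1) = x̂(k) − a·(x̂(k) − x(k)) + W(k)ᵀ S(x(k))
       W(k+1)  = W(k) − g(k)·S(x(k)) e(k)ᵀ − g(k)·σ·W(k)

   with `e = x̂ − x`, a = 0.5, γ = 0.5, σ = 1e-4, 20 epochs, and a
   normalized step g(k) = γ / (1 + ‖S(x(k))‖²).  Two numerical choices are
   deliberate and isolated here:

   * **Step normalization.**  The raw gradient update is only stable when
     γ‖S‖² is small; a dense lattice activates many overlapping kernels at
     once and the unnormalized recursion diverges at practical γ.  The
     NLMS-style normalization makes stability independent of lattice
     density.
   * **Per-loop observer passes.**  The jump from one beat's T end to the
     next beat's J point is an artifact of concatenation, not repolarization
     dynamics, and it shares state space with the slow ST points; learning
     it corrupts the field exactly where loops begin and end.  The observer
     therefore restarts at each loop's first point and no weight update
     spans the seam.

   The emitted CDG is `W̄ᵀS(x(k))` along the orbit, with `W̄` the time
   average of W over the final epoch — for a well-learned orbit this is the
   one-step state change of the repolarization loop, verified on closed
   noiseless limit cycles to < 0.1% relative RMSE (the test tolerance is
   5%).  Whether a published CDG uses the averaged or final weights is not
   recoverable; the average is pinned here as configuration.  Training is
   fully deterministic; the `seed` field is reserved for optional center
   jitter.

5. **Heterogeneity indices** (`cdgram.heterogeneity`).

   * **SHI** (spatial): mean log divergence ratio
     `SHI = (1/N′) Σ ln(d_n2/d_n1)` with `d_n1` the distance from point n to
     its nearest neighbor j and `d_n2` the distance between the same pair
     10 steps later.  Temporal neighbors within a Theiler window (default:
     one loop length) are excluded, exact duplicates are skipped in favor of
     the nearest distinct neighbor, and points whose 10-step successors fall
     off the end are dropped (N′ counts the rest).  SHI is invariant to
     uniform scaling and translation; an exactly periodic trajectory gives
     SHI = 0.
   * **THI** (temporal): `argmin_λ |F(λ)|·exp(−0.1·λ)` with F the magnitude
     spectrum of the trajectory.  The spectrum is taken over the Euclidean
     norm series after mean removal, evaluated at integer bins
     λ ∈ {1, …, ⌊N/2⌋}, ties broken to the smallest λ.  Whether λ indexes a
     bin, a frequency in Hz, or a damped dictionary is not decidable from
     the defining expression; this bin-index reading is a documented package
     convention, pinned by regression tests and swappable
     (`thi.spectrum_mode = "axes"` averages per-axis spectra instead).

6. **Decision function** (`cdgram.classifier`).  The shipped frozen
   classifier (version `paper-2023`) is

       CDG value = −0.0556·THI + 30.8131·SHI − 2.7719,   positive iff ≥ 0.

   `train_classifier` reproduces the training *procedure* (linear-kernel SVM
   on (THI, SHI) features) for research use; the cohort behind the frozen
   coefficients is not available, so retraining cannot reproduce them.

7. **Cohort evaluation** (`cdgram.cohort`).  CAD positivity is a composite
   reference standard: stenosis category ≥ cut (50% or 70%) OR CT-FFR ≤ cut
   (0.8 or 0.7); occluded vessels are assigned CT-FFR 0.5 before comparison,
   so they are positive under every standard.  Stenosis is stored as ordered
   bands (0, 1–24, 25–49, 50–69, 70–99, 100) compared by lower edge.
   Metrics are percentages rounded half-up to 2 decimals; undefined ratios
   are reported missing, never 0.  AUC is the trapezoidal area over all
   score thresholds (identical to normalized Mann–Whitney U) with a DeLong
   (default) or stratified-bootstrap CI; CDG–CT-FFR association uses
   Spearman rank correlation with average ranks.

## The synthetic generator

`cdgram.synth` exists because no patient recordings are distributable.  ECGs
are sums of per-wave Gaussians (P, Q, R, S, T) per lead on a fixed
heart-rate grid — acquisition matches the targeted setting: 1000 Hz, 20 s
records, amplitudes in mV.  T-wave centers are staggered across leads by
±15 ms: lead-dependent repolarization timing is what makes the VCG T loop a
genuine open loop (with identical timing it degenerates to a line traversed
out and back, whose two-valued step dynamics no static field can represent).
Derived limb leads are computed from I and II, so the 12-lead set is
internally consistent.  Post-R wave timing compresses by √RR at faster
rates.

Ground truth emitted per beat: R peak (R-wave center), J point (end of the
S wave, ≈ R+40 ms for the default template), T apex (|amplitude|-weighted
mean of per-lead T centers) and T end (latest per-lead Gaussian tangent
endpoint, center + 2 widths — the tangent method on a Gaussian lands exactly
there, which is what makes the T-end accuracy tests well-posed).

The dispersion knobs: `stt_jitter` scales per-beat multiplicative T
amplitude/width noise (the repolarization-inconsistency axis the CDG is
supposed to measure), `st_shift_mv` adds a systematic ST deviation,
`alternans` toggles deterministic every-other-beat T alternation, plus
additive white noise and sinusoidal baseline wander.  What the generator
does **not** emulate: real QRS morphology variety, respiratory modulation,
rate variability, ectopy, electrode artifacts, or any physiological
ischemia mechanism — "CAD-like" synthesis is a labeled convention.  Passing
tests therefore demonstrate that the pipeline measures what the generator
varies, not clinical performance.

Cohort tables are drawn jointly: class labels at a configurable prevalence
(default 0.4641), CDG values separated by `effect` standard deviations,
CT-FFR coupled to the CDG value through a shared latent Gaussian
(`rho_target`, default −0.4), stenosis bands consistent with the class
definition, and an ECG reading with realistic sensitivity/specificity.

## Frozen count tables and the reference cohort

`crosstab_counts()`/`confusion_rows()` ship the published cross-tabulation and
confusion rows as constants.  `reference_cohort()` reconstructs a synthetic
362-row cohort exactly consistent with all of them: the cross-tab fixes each
(CDG sign × stenosis ≥ 50 × CT-FFR ≤ 0.8) cell, and the finer splits needed
by the other standards (CT-FFR ≤ 0.7; stenosis ≥ 70%) are uniquely
determined by those standards' confusion counts.  Rows carry representative
in-band values (CT-FFR 0.88/0.75/0.65; class-median CDG values); it is a
synthetic stand-in, not patient data.

## Validation strategy and problem sizes

Every estimator is scored against either generator ground truth or an
independent brute-force oracle: SHI against an exhaustive nearest-neighbor
scan (agreement to 1e-12 on 50 random trajectories, N ≤ 200), THI against a
direct grid scan, AUC against the Mann–Whitney statistic, learning against
one-step self-consistency on closed limit cycles (8 × 100-point cycles),
and the end-to-end chain against a dispersion sweep: `stt_jitter` ∈
{0, 0.2, 0.4, 0.8, 1.2} × 10 seeds of 20 s, 1000 Hz records with 0.01 mV
additive noise, requiring the median SHI and median CDG value to increase
strictly with the level.

The sweep levels probe the regime above the estimator's noise floor — a
known limitation: the mean-log-divergence formula has an extreme-value bias
when beat segments coincide up to noise (the minimized `d_n1` falls far
below the typical `d_n2`), so SHI does not respond monotonically to
dispersion changes *below* the additive-noise floor.  SHI magnitudes on
synthetic data carry the same bias and should be compared within, not
across, noise conditions.

## Other limitations

* Atrial fibrillation and paced rhythms are out of scope (the detector and
  the recurrent-orbit premise both assume a repeating sinus beat).
* J-point/T-end localization rules are implementer's defaults behind the
  `FiducialSet` interface; no published CDG localization spec exists to
  compare against.
* Absolute SHI/THI scales depend on the lattice, width, and spectrum
  conventions above; the frozen decision boundary is meaningful for inputs
  processed with the same conventions it was trained under, which are not
  recoverable.  The package therefore reproduces the *procedure* and its
  printed constants; cross-validating absolute index scales against the
  original software is not possible.
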