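# Methods

`cohnet` implements a frequency-domain source-analysis chain for concurrent
EEG/MEG/EMG recordings during rhythmic movement: DICS beamforming by
corticomuscular coherence, pooled source-signal reconstruction, and directed
connectivity by renormalized partial directed coherence (RPDC).  Because no
public recordings of this kind exist, the package ships a first-class
synthetic-data generator whose default configuration defines the study
conditions under which the pipeline is validated.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Forward model

The head is a set of concentric spheres (brain/skull/scalp radii
80/85/92 mm; conductivities 0.33/0.0042/0.33 S/m).  MEG fields use the
closed-form solution for a current dipole in a spherically symmetric
conductor; the field is independent of the conductivity profile and exactly
zero for radially oriented dipoles.  Magnetometers measure the field along
the (radial) coil normal; planar gradiometers are two-point finite
differences over a 16.8 mm tangential baseline whose direction is drawn
once per sensor at fixture construction.  EEG potentials use the
concentric-shell series solution: per harmonic degree *n* a small linear
system enforces potential and radial-current continuity at the interfaces
and the insulating outer boundary, giving a transfer factor `f_n` (equal to
the analytic `(2n+1)/n` for a homogeneous sphere, which serves as an
independent oracle in the tests).  The series is truncated at 60 degrees;
for the most superficial sources used anywhere in the package the
truncation error is below 1e-4 relative.  EEG rows are average-referenced,
and the same average reference is applied to EEG data during
pre-processing so data and model share a reference.

Sensor fixtures place electrodes quasi-uniformly (Fibonacci spiral) on the
scalp cap above z/R = -0.15 and MEG sensors on a helmet 2 cm above the
scalp; the electrode nearest the left superior-lateral direction is flagged
as the C3-analog.  A real cap reaches further down than a spherical cap
does; the consequence — poor coverage of the cerebellar region — is part of
what the study design probes.

MEG correctness is checked against a numeric oracle: free-space dipole
field plus the volume-current contribution written as a surface integral of
the single-sphere surface potential, evaluated by Gauss-Legendre x
trapezoid quadrature.

## Synthetic study

Six dipoles sit at the printed finger-tapping reference coordinates (MNI
mm), mapped into the head frame by subtracting the fitted-sphere center
(taken 25 mm below the MNI origin — a fitted sphere centers below the
anterior commissure, and without the offset the thalamic source would sit
unrealistically close to the sphere center, where MEG is blind) and scaling
by 0.75 so every source lies strictly inside the brain shell.

Each source is an independent white-innovation stream band-passed to
2-4 Hz, scaled by a per-source amplitude; directed edges add pure lagged
copies of the source series (solved in the frequency domain with edge
padding).  Orientations are tangential with a 0.5 radial admixture; the
tangent-plane azimuth differs per source, as cortical folding would make
it, because near-parallel moments of nearby correlated sources produce
nearly collinear field patterns that a beamformer cancels jointly.

Three generator choices matter and were calibrated once so that the full
pipeline reproduces the qualitative modality contrast the method is known
for (MEG resolves the deep sources; EEG resolves the cortical ones on full
data and reaches deeper only on high-coherence segments):

- **Amplitudes and gains.**  Deep sources carry larger moments (TH 6.5,
  CER 1.5 vs. cortical 0.55-1.6) to offset depth attenuation.  Incoming
  gains are scaled against the source amplitude so no single afferent
  dominates its target and inter-source coherence stays moderate (the
  beamformer's linear-independence assumption).  Coupling lags are 10-50 ms;
  the lags of the weakest links sit near quadrature phase at 3 Hz because
  the real-valued band CSD used by the spatial filter cancels in-phase
  correlated sources far more strongly than quadrature ones.
- **EMG.**  A 30-200 Hz carrier noise amplitude-modulated by the half-wave
  rectified, normalized driver signal: one burst per oscillation cycle
  (2-4 bursts/s), burst amplitude linear in the driver.  The modulation
  depth alternates between 0.95 and 0.02 in blocks of 40 epochs (30% high):
  tapping vigor drifting on a tens-of-seconds scale, the nonstationarity
  that high-coherence segment selection exploits.
- **Background activity.**  Ongoing task-unrelated brain activity is
  modeled as radially oriented band-limited dipoles distributed through the
  brain volume (shell amplitude 0.5, deep cluster 4.5).  Radial sources are
  exactly silent for spherical MEG, so the background structures the EEG
  noise floor — particularly over deep source space — without touching MEG.
  This, together with the lower EEG scalp SNR (target 1.0 vs. 14 for MEG),
  is what makes the deep sources EEG-invisible on full data.  Sensor white
  noise tops up each modality's noise budget to the target band SNR
  (task-band power over rest-band power at 2-4 Hz).

A matched rest recording (background plus sensor noise, no task sources)
accompanies every simulation for noise-amplitude estimation.

What the generator does *not* emulate: 1/f broadband background spectra,
sensor drifts and artifacts, head movement, physiological motor-unit EMG
statistics, and non-spherical anatomy.  Passing tests therefore demonstrate
the correctness and calibration of the estimators under the stated model,
not performance on real recordings.

## Pre-processing and spectral estimation

Zero-phase Butterworth band-passes per modality (EEG/MEG 0.05-200 Hz, EMG
30-200 Hz), EMG full-wave rectification after filtering (demeaned),
segmentation into 1-s epochs, and amplitude-based artifact rejection: an
epoch is dropped when a brain channel's peak robust z-score (vs. the
channel's MAD over the whole recording) exceeds 5.  EMG is excluded from
rejection because its bursts are the signal of interest and heavy-tailed by
design.

All spectra are Slepian multitaper estimates with K = 7 tapers at
time-bandwidth NW = 4, averaged over tapers and epochs.  With 1-s epochs
this smears +/-4 Hz around each bin; the 2-4 Hz band summaries are means
over the 1-Hz bins at 2, 3 and 4 Hz.  Coherence is magnitude-squared;
pooled coherence follows the weighted cross-/auto-spectral pooling rule
with epoch-taper counts as default weights.  The sliding time-frequency
estimator uses 1000-ms windows every 50 ms (1 Hz bins, 50 ms hop).  When
pooling time-frequency coherence over many sensors against the common EMG
reference, each channel is first sign-aligned to the reference (sensors on
opposite lobes of a dipolar field pattern would otherwise cancel in the
pooled numerator).

High-coherence segment selection thresholds the band-averaged pooled time
course at mean + 1 sample standard deviation (strict inequality; windows
contribute to the epoch containing their center).  The pipeline smooths
the course with a 15-s moving average first — a pure variance-reduction
step, appropriate because the simulated coupling strength drifts in blocks;
the unsmoothed rule is the function's default.

## DICS beamforming

Spatial filters are `W = (L^T C~^-1 L)^+ L^T C~^-1` with
`C~ = Re C(band mean) + alpha * (mean eigenvalue) * I`.  The 3x3 normal
matrix is inverted rank-aware (eigenvalue cutoff), because spherical MEG
gains span only the tangential plane; unit gain then holds on the retained
orientation subspace.  The default regularization is alpha = 0.05; the
study configuration uses 0.3 because its six sources are mutually coherent
and a sharply adaptive filter partially cancels correlated sources.

Voxel coherence fixes the dipole orientation per voxel (dominant
eigenvector of the real band-averaged 3x3 source CSD), computes squared
coherence between the oriented source component and the EMG per bin, and
averages over the band.  Significance uses epoch-permutation surrogates:
the EMG's epochs are permuted relative to the brain channels 100 times and
the threshold is the 99th percentile of the per-permutation map maxima
(filters and orientations depend only on the brain CSD and are reused; all
permutations batch into one matrix product per bin).

The sequential search records the map peak, its above-threshold
6-connected cluster, and the peak orientation, then projects data and lead
field onto the orthogonal complement of the found source's oriented gain
subspace and repeats until the map maximum stays below the (recomputed)
threshold.  Nulling uses the peak voxel plus its six grid neighbors for
superficial peaks; deep peaks (inside half the brain radius) null the peak
column only, because deep gain patterns are spatially smooth and a
neighborhood null there swallows the patterns of shallow sources above.  A
residual sidelobe that re-peaks within 1.6 grid steps of an already-found
source is suppressed and not recorded again.

Source signals pool the member voxels' orientation-fixed projections,
sign-aligned to the peak voxel, with weights proportional to squared
voxel-reference coherence (power weights overweight noise-amplified fringe
voxels; peak-only pooling discards real averaging gain).  Orientation
classes follow the angle-bin convention with the tangential reference axis:
60-120 degrees counts as radial, boundaries belong to the tangential bins;
a local-radial-axis convention is available as an option.

## Directed connectivity

Pooled source signals are resampled to 100 Hz (polyphase FIR; the same
linear-phase delay on every channel preserves relative lags) — 2-4 Hz
dynamics at 1 kHz would require very high AR orders.  MVAR models are fit
by least squares with epochs as independent realizations; AIC
(`log det Sigma + 2 p d^2 / N`) selects the order once on the original
data, floored at 2 because the RPDC renormalization needs two lags for a
full-rank estimator covariance.  Narrow-band data put AR poles on the unit
circle, so marginally unstable fits (spectral radius below 1.05) warn
rather than fail.

RPDC for edge j -> i stacks the real and imaginary parts of the
frequency-transformed coefficient `Abar_ij(f)` and renormalizes by its
estimator covariance built from the residual variance and the inverse
lagged-process covariance; under the null the statistic is chi-square with
2 degrees of freedom (verified by simulation, KS < 0.05).  Band statistics
are means over 2-4 Hz at 0.5 Hz steps.  Significance uses the
segment-shuffle bootstrap: epochs shuffled independently per channel
(destroying cross-channel structure while preserving every per-segment
spectrum), the model refit at the same order 100 times, and the 99th
percentile per ordered pair taken as threshold.

The time-reversal check separates lagged interactions from symmetric
zero-lag mixing.  An edge whose forward statistic dominates its opposite
(factor 2) is confirmed only if that dominance does not persist on the
time-reversed series; a pair with comparable statistics both ways counts
as bidirectional and is kept when both directions are significant forward
and persist under reversal.  A plain "reversed statistic below threshold"
rule was tried first and discarded: strong genuine couplings leak enough
into the reversed fit to fail it, while the dominance flip is the actual
signature of a lagged drive.

## Numerical choices and degenerate inputs

- Frequency bins inside a band are selected inclusively with a 1e-9 Hz
  tolerance; a band with no bins raises.
- Rank decisions (beamformer normal matrix, nulling QR, MVAR design) use
  relative thresholds of 1e-10-1e-12; singular CSDs with alpha = 0 raise
  with a message suggesting regularization.
- Epoch selection returning fewer than 20 epochs falls back to the full
  recording (logged), because surrogate thresholds need at least 20 epochs.
- All randomness flows from one root seed, split per stage; two runs with
  identical inputs and seed are bit-identical.

## Known limitations

- The full-pipeline modality contrast is a calibrated, stochastically
  fragile property: the MEG run robustly recovers all six sources at the
  canonical scenario seed, but which of the weaker cortical sources the
  EEG run resolves varies with the noise realization, and the
  segment-selection recovery of the cerebellar source sits at the edge of
  the detection window (see the repository-external decisions ledger for
  the acceptance status).  The underlying tension is physical: with
  per-channel whitening, spherical-head EEG sees deep sources about as well
  as cortical ones, so hiding them from EEG while keeping them visible to
  MEG requires structured background at just the right strength.
- Directed-edge recovery is quantified at the connectivity stage with
  observation noise at 20% of source RMS (about the reconstruction quality
  the beamformer achieves at high SNR).  Running the connectivity stage on
  actual beamformer outputs adds zero-lag leakage between reconstructed
  signals, which inflates false edges beyond what the time-reversal check
  removes; full-pipeline edge metrics are reported by the acceptance script
  but are substantially below the stage-level figures.
- Group-level inferential statistics (Friedman, ANOVA, chi-square variance
  tests) are deliberately not reimplemented; the SNR module emits tidy
  tables ready for any standard statistics package.
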