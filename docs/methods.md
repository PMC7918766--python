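# Methods

This note records the model, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot establish.

## Problem setting

During fascial therapy the pain source is external and unpredictable: the
therapist modulates force, plane and duration on neck/arm tissue, and the
patient's reaction appears in several physiological channels at once with
subject-specific strength. The pipeline therefore fuses five channels into
per-frame features and classifies pain-related reaction level per 4 s
frame, with labels derived from the patient's own 0–10 call-outs rather
than a calibrated stimulus scale.

## Preprocessing

Channels are resampled with rational polyphase FIR filters (Kaiser window,
β = 14) to EMG 256 Hz, BVP 64 Hz, EDA 8 Hz, RSP 8 Hz, GRIP 75 Hz. The
cutoff sits at the lower of the two Nyquist frequencies. Signals are
reflect-padded past the filter transient before resampling so that edge
error stays at the filter's ripple level (~1e−7 for DC); edge extension of
a finite record is inherently ill-posed, so round-trip accuracy is
specified for tapered band-limited signals. The EDA channel is additionally
smoothed with a Gaussian-weighted moving average (default window 1 s of
samples, σ = window/5; the width is a package choice).

## EDA decomposition

Skin conductance y is modeled as tonic + phasic + white noise. The phasic
component is a Bateman impulse response, h(t) = e^(−t/τ₁) − e^(−t/τ₀) with
defaults τ₀ = 0.7 s, τ₁ = 2.0 s (conventional skin-conductance constants),
driven by sparse non-negative sudomotor activity p. The Bateman convolution
is discretized by mapping its Laplace transfer function
(1/τ₀ − 1/τ₁)/((s + 1/τ₀)(s + 1/τ₁)) to a digital ARMA filter with the
bilinear transform at 8 Hz. The tonic part is a cubic B-spline on 10 s
knots plus offset and linear drift. Estimation solves

    min ½‖y − Mp − Bℓ − Cd‖² + α‖p‖₁ + ½λ‖ℓ‖²,  p ≥ 0,

with α = 8e−4 and λ = 1e−2 by default. On the feasible set the ℓ1 term is
linear, so the problem is a smooth bound-constrained QP solved with
L-BFGS-B and analytic gradients (deterministic; convergence guarded by a
residual sanity check and the solver status). Reconstruction
tonic + phasic + noise = y holds exactly by construction; recovery tests
require phasic correlation r > 0.95 and driver peaks within ±2 samples on
noiseless planted SCR trains. The hyperparameters are package choices and
configurable — recovery tests guard their sanity. Only the phasic component
enters the feature set.

## Scattering transform

Morlet filters are defined directly in the frequency domain as Gaussian
bumps with a zero-mean admissibility correction. Centers descend
geometrically from 0.4·fs by 2^(1/Q); the relative bandwidth is
(2^(1/Q) − 1)/√(2 ln 2), capped at 0.4 so the Q = 1 filters remain
admissible. The averaging window ϕ is a Gaussian with σ_t = T/4 for
invariance scale T = 4 s; the lowest wavelet center sits one octave above
ϕ's half-power frequency. Each layer's gain is normalized so the
Littlewood–Paley sum |ϕ̂|² + Σ|ψ̂|² stays within (0, 1] (0.5 % safety
margin against grid effects), which makes the cascade provably
nonexpansive; the property tests check this empirically on random pairs.

Paths are truncated to frequency-decreasing sequences (λ_{n+1} < λ_n), the
standard deep-scattering convention. Boundary handling is reflection
padding of one window, cropped after filtering. Between layers, envelopes
are decimated to the smallest dyadic rate whose Nyquist still covers
2.5× the parent's center frequency — a pure efficiency measure; the next
layer's filters all lie below the parent frequency. Scattergrams are
sampled at the centers of the shared 4 s / 2 s frame grid; scalograms are
Fourier-interpolated to a common time axis (4 points per frame by default)
and `align_frames` brings any matrix to the frame grid, mirroring the
equal-coefficient-count interpolation the deeper layers need. Both Sₙ and
Uₙ energies enter the feature set, giving 6 energy features per three-layer
transform and 4 per two-layer transform (20 in total over the four
channels used).

## Features and labels

All features share the frame rule floor((D − 4)/2) + 1. Spectral entropy
uses a Hann-windowed periodogram per frame, normalized to a probability
distribution, entropy in bits; all-zero frames define H = 0. "Absolute
amplitude" is read as peak-to-peak range (max |x| available via the same
statistics on rectified input if wanted); standard deviations are sample
(n−1) throughout. The statistic-to-signal allocation (4 windowed stats on
EDA-phasic and RSP, 3 derivative stats on EDA-phasic, entropy on EMG and
RSP) is the one consistent with the 33-element total; GRIP consequently
contributes no default features, though the allocation is configurable.
Features are z-scored per subject; zero-variance columns become zeros.

Labels: reports shifted 2 s backward (floored at 0), zero-order hold, max
per frame, double threshold with the convention no-pain ⇔ rating < t_low
and severe ⇔ rating ≥ t_high. The thresholds default to 4 and 7 but are
deliberately parameters: pain resistance is subject-dependent and no
universal cut points exist. Thresholds are global by default; per-subject
thresholds can be emulated by labeling subjects separately.

## Classification and validation

AdaBoost uses SAMME weight updates over decision trees limited to 20
branch (split) nodes, i.e. 21 leaves; 100 learners, learning rate 1.0
(counts are package defaults). For two classes SAMME reduces to the
classic binary algorithm. The SVM is a soft-margin RBF machine with box
constraint 1 and kernel scale from the median pairwise distance heuristic;
it is restricted to binary tasks, where multiclass SVM performance is not
competitive on this problem. Balancing undersamples to the minority class
among the task's classes, re-drawn per run. 10-fold CV splits the balanced
pool with stratification; one-patient-out holds each subject's frames out
in turn and rebalances the training pool, skipping (with a logged warning)
a test subject missing one of the task's classes. Metrics with zero
denominators are reported as 0 and flagged. The ± spread is reported as
the sd over all fold×run evaluations.

## Synthetic cohorts

The simulator emulates the study protocol: a 30 s no-pain baseline, then
2–3 minutes of therapy (session length drawn uniformly from 150–210 s
unless fixed). Pain episodes arrive Poisson-like (default 3/min, 6 s
refractory gap) with latent intensities uniform on [1.5, 10]; the latent
pain rises in ~0.5 s and decays with an 8 s constant, capped at 10. Every
channel is modulated by the latent intensity through a per-subject
log-uniform reactivity gain: EDA adds a Bateman SCR per episode on a slow
tonic drift, EMG amplitude-modulates 20–150 Hz corrugator-like noise, RSP
speeds and deepens a sinusoidal breathing model, BVP raises pulse rate and
slightly damps amplitude, and GRIP adds squeeze transients for episodes of
intensity ≥ 6. Reports are integer call-outs delayed by 2 s (±0.4 s
jitter) at each episode, followed by call-outs every 5 s while the pain
fades — so the report track is a set of increasing and decreasing values
and the zero-order-hold label model tracks the latent intensity instead of
freezing at the last peak. Everything is reproducible from (config, seed,
subject index).

What the simulator does **not** model: measurement artifacts (motion,
electrode lift), emotional (non-nociceptive) EDA responses, heart-rate
variability structure, breathing irregularity, inter-episode sensitization
or habituation, and any correlation between a patient's reporting style and
physiology. Passing recovery tests therefore shows the pipeline extracts
the multichannel structure it assumes; it does not certify performance on
clinical recordings, which are not distributed with this package.

The "easy regime" used for parameter-recovery checks fixes 6 subjects,
3.5 episodes/min, gains in [1.5, 2.5] and noise at 30 % of the defaults —
scaled so the full check suite runs in minutes on one CPU. Under it, the
multiclass AdaBoost macro-F1 must reach 0.8 under pooled 10-fold CV,
permuted labels must fall to chance, and no-pain F1 must exceed
moderate-pain F1 (the moderate class, squeezed between both thresholds, is
structurally hardest — mild pain is the hardest level for automatic
severity assessment in general).

## Known limitations

- The scattering implementation targets the desk-scale problem sizes used
  here; it is single-threaded NumPy FFT code, not a GPU or streaming
  implementation, and processes a 3-minute 256 Hz channel in seconds.
- The one-patient-out scheme rebalances training pools per split, so
  training-set sizes vary slightly across held-out subjects.
- Fourier interpolation of scalograms assumes smooth envelopes; for
  strongly impulsive content the per-frame U energies are approximations.
- The convex EDA solver's sparsity is approximate (quasi-Newton iterate,
  not an interior-point optimum); driver supports are localized to within
  a couple of samples, which is what the pipeline needs.
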