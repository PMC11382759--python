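# Methods

This note documents the models, parameter choices and numerical decisions
behind `speechffr`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Forward model and estimation

The neural response is modelled as a lagged linear combination of two
stimulus features (fundamental waveform *f*ₜ, envelope modulation *e*ₜ):

    y_t(v) = Σ_τ [ α_τ(v) f_{t−τ} + β_τ(v) e_{t−τ} ]

with latencies τ from −20 ms to 120 ms in 1 ms steps at a 1000 Hz neural
rate (141 lags per feature, 282 design columns). Negative lags pair the
response with future stimulus samples; genuine auditory responses are
causal, so coefficient mass at negative lags indicates artefact or noise.

Coefficients are estimated per channel by ridge regression,
`w = (XᵀX + λI)⁻¹ Xᵀy`, solved through a Cholesky factorisation of the
Gram matrix. λ = 1 by default, applied to the raw (unstandardised) lagged
features; an optional unpenalised intercept is available but off by
default since all signals are zero-mean. Boundary samples whose lagged
features fall outside the recording are zero-filled and retained in the
fit. For fixed-stimulus experiments `RidgeSolver` factorises the Gram
matrix once and refits each subject with two triangular solves; results
are identical to the one-shot path.

### Feature amplitude reference

The effect of a *fixed* λ depends on the feature amplitude through the
design spectrum. The lagged design of a 70–120 Hz narrowband feature is
strongly anisotropic: a few tens of strong in-band eigendirections and a
weak continuum below them. A single fixed λ is near-optimal only when it
falls between the two groups, so `extract_features` scales each feature
stream to a fixed reference RMS of 3×10⁻³. At that scale, for records of
roughly a minute, the strong directions sit two or more orders of
magnitude above λ = 1 (kernel shapes pass essentially unshrunk) while the
weak continuum sits well below it (noise and noise-model coefficients are
suppressed). The reference was calibrated once by a scale sweep on
synthetic data and is a package constant; pass `normalize_rms=None` for
raw filter outputs, in which case λ should be chosen accordingly.

## Feature extraction

**f0 tracking** is a simplified YIN: per-frame cumulative-mean-normalised
difference function, first dip below an absolute threshold of 0.15
(falling back to the band minimum), parabolic interpolation of the period,
5-frame median smoothing, linear interpolation to per-sample resolution.
Frames whose normalised-difference minimum stays above the threshold —
noise or silence — are unvoiced. Defaults: 40 ms frames, 10 ms hop, search
band 60–250 Hz. The full probabilistic-YIN HMM is deliberately not
reproduced: downstream results depend only on the f0 band, and an
externally computed track can be injected wherever an `F0Track` is
accepted.

**Fundamental waveform**: 65–120 Hz Butterworth band-pass, design order 4,
applied forward–backward (zero phase; orders quoted are pre-reflection
design orders throughout). **Envelope modulation**: constant-Q band-pass
filterbank (24 bands, geometric spacing 150 Hz to min(4 kHz, 0.45·rate),
Q = 4, 2nd-order Butterworth per band), analytic-signal magnitude per
band, power-law compression with exponent 0.3, equal-weight sum, then a
70–120 Hz 4th-order zero-phase band-pass. The compression exponent and the
omission of any cross-scale derivative stage are package decisions: the
auditory-periphery literature specifies the pipeline shape (filterbank →
compression → envelope → f0-band selection) more firmly than its
constants, and the extracted feature is insensitive to them beyond overall
scale. All filters are second-order-section Butterworth designs for
numerical stability.

## Neural preprocessing

Operations compose in the order notch → resample → band-pass → align, and
each appends to the recording's provenance chain. The notch is a
windowed-sinc FIR band-stop (2 Hz stop width, 0.5 Hz transition band)
applied by centred convolution, hence zero phase; resampling is polyphase
rational resampling with the rational ratio approximated to 1/10000;
the FFR band-pass is a 2nd-order zero-phase Butterworth at 70–120 Hz.
Alignment delays the feature stream by the acoustic travel delay (default
6 ms — the sound-delivery tube delay of a typical shielded-room setup) and
trims both series to common support. The first/last 100 ms of zero-phase
filtered output can carry edge transients; analyses here are long enough
that this is negligible, but `EDGE_GUARD_MS` records the guard width.

## TRF summaries

Per-lag magnitude is the channel-averaged |coefficient| (for 3-component
source-point triplets, the Euclidean norm across the triplet is taken
first; pass the triplets in `component_groups`). The envelope is the
analytic-signal magnitude of the magnitude curve, low-passed at 70 Hz
(5th-order zero-phase Butterworth, the lag axis treated at the neural
rate), clipped at zero. Magnitudes are averaged across channels before the
envelope is computed; computing per-channel envelopes first and averaging
after is available by applying `trf_envelope` per channel. Peak finding
restricts the envelope to Bonferroni-significant lags and breaks exact
ties toward the earliest lag; with no significant lag the subject is
flagged rather than assigned a latency.

## Significance testing

Noise models are TRFs fitted after reversing both feature streams in time;
model *k* of *K* (default 10) additionally applies a circular shift of
`k·n/K` samples. Reversal and circular shifting preserve the features'
second-order statistics, so each noise model is exchangeable with the
genuine fit when the response carries no stimulus-locked component. The
bootstrap draws one noise-model envelope per permutation (10,000 by
default); the empirical p at each lag is `(1 + #{null ≥ observed}) /
(n_perm + 1)` — never exactly zero — and Bonferroni correction multiplies
by the number of lags.

A discreteness consequence worth knowing: the smallest attainable p is
`1/(n_perm+1)`, so with 1,000 permutations and 141 lags no lag can reach
corrected significance and the family-wise null error rate is zero by
construction; at 10,000 permutations the corrected floor is ≈ 0.014 and
genuine responses are detectable. The number of permutations therefore
acts as a sensitivity switch, not merely a precision knob.

## Attention and cohort statistics

Population peak latency per condition/feature = mean of the individual
significant peak latencies after Tukey-fence (1.5·IQR) outlier exclusion;
subjects without significant peaks are excluded from the latency estimate
only and rejoin for the magnitude analysis at that latency. Q = (a−i)/(a+i)
is computed from the envelope magnitudes at the condition-specific
population latencies; a+i = 0 is reported missing. Location comparisons
pass a Shapiro–Wilk gate at α = 0.05 (assumed, and exposed in config,
where the source procedure leaves the gate level unstated): both samples
normal → Student's t (unpaired by default), otherwise Mann–Whitney-U
(Wilcoxon signed-rank when paired); constant samples are routed to the
nonparametric branch. Variances use the Brown-Forsythe test. The four
musical-training scores (starting age, total years, current weekly hours,
lifetime instruments) are normalised by the cohort maximum; the
starting-age component rewards an earlier start, `(max_age − age)/max_age`
over participants who played, with never-players contributing no value to
that component. The five Spearman tests (four scores + aggregate) are
Benjamini–Hochberg corrected as a family.

## Synthetic-data generator

The generator emulates the study conditions: a voice with f0 wandering in
70–120 Hz (low-pass-filtered Gaussian noise squashed by tanh into the
range, wander rate 0.5 Hz), five harmonics with 1/k amplitudes, the
harmonics above the fundamental amplitude-modulated at the f0 rate
(modulation depth 1). The modulation phase detunes at 0.7 Hz and both the
modulation and each higher harmonic carry a slow random phase drift
(π radians RMS, 2 Hz bandwidth), standing in for the changing harmonic
phase relations of a real vocal tract; without it the adjacent-harmonic
beating would stay phase-locked to the fundamental and the two extracted
features would be artificially correlated. The fundamental itself stays
phase-coherent so its instantaneous frequency follows the track exactly.

Neural responses are generated through the same lagged design used for
estimation — generation and fitting are exactly consistent — from
Gabor-shaped kernels (Gaussian envelope at 35 ms, 10 ms width, 95 Hz
carrier; β kernel at 0.6 relative amplitude), scaled by the attention gain
(default 1.5) when the voice is attended, plus white (optionally
1/f-shaped) Gaussian noise, independent per channel. SNR is specified
broadband against the clean ignored-condition response; the default
operating point is 0 dB. Inter-subject variability (latency jitter SD
2 ms, gain jitter SD 0) is a free parameter: the statistical structure of
real between-subject TRF variability is unknown, and no value is asserted
for it. Cohort profiles are drawn to satisfy the musician /
non-musician questionnaire criteria by construction, with behavioural
comprehension scores from one common distribution for all groups.

What passing tests show — and what they do not: parameter recovery on this
generator verifies the estimation, significance and statistics machinery
end to end, including their interaction with narrowband features and a
fixed λ. It does not certify performance on real MEG, where the noise is
structured and non-stationary, source leakage correlates channels, the
response is weaker (real speech-FFR SNRs are far below 0 dB, compensated
by ~40 min of data), and the two speakers' features are not perfectly
separable.

## Problem sizes

Defaults in the test-suite and acceptance runs were chosen as the smallest
sizes at which the measured properties stabilise: 60 s stimuli for kernel
recovery and feature decorrelation (a 30 s pipeline check uses
correspondingly looser recovery expectations), 20 subjects for
attention-score recovery, and 200 repeats × 1,000 permutations × 4 s
records for the null calibration. The demo pipeline (8 subjects, 60 s)
runs in well under a minute on one CPU.

## Known limitations

* Recorded-data mode consumes already source-reconstructed (or
  sensor-level) time series; beamforming and head modelling are out of
  scope.
* The auditory-periphery model is a documented caricature (no cross-scale
  derivative stage, fixed compression exponent).
* The simplified YIN has no octave-cost HMM; extreme octave errors on real
  speech would need the injection point for an external f0 track.
* The bootstrap's empirical-p floor couples sensitivity to the permutation
  count (see above).
* Drum training is handled upstream: instrument eligibility is left to the
  data preparer when building cohort tables.
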