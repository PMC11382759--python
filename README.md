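# speechffr

Analysis of the **cortical speech frequency-following response (speech-FFR)**
from continuous-speech experiments: feature extraction in the
fundamental-frequency band, temporal response functions (TRFs) by lagged
ridge regression, significance against time-reversed noise models,
attentional-modulation scoring, and cohort statistics comparing musicians
and non-musicians. A synthetic-data generator with known ground truth makes
every stage verifiable by parameter recovery.

The package is aimed at auditory neuroscientists working with continuous
MEG/EEG recordings of listeners attending running speech, and at anyone who
wants a tested, reproducible reference implementation of the speech-FFR
forward-model pipeline.

## The model

A listener hears a voice whose fundamental frequency f0 lies in the 70–120 Hz
range. Two stimulus features are extracted per sample:

* the **fundamental waveform** *f*ₜ — the speech signal band-passed 65–120 Hz
  (4th-order Butterworth, forward–backward);
* the **envelope modulation** *e*ₜ — the amplitude-envelope fluctuation of the
  higher harmonics at the f0 rate, via a constant-Q filterbank with
  compressive envelope detection, band-passed 70–120 Hz.

The neural response *y*ₜ(*v*) in channel/source *v* is modelled as a lagged
linear combination of both features:

    y_t(v) = Σ_τ [ α_τ(v) f_{t−τ} + β_τ(v) e_{t−τ} ],   τ = −20 … 120 ms (1 ms steps)

The coefficient curves α and β are the TRFs, estimated per channel by ridge
regression with a fixed regularisation λ = 1. Because the features are
narrowband, the TRFs oscillate near f0; their smooth **envelope** (analytic
signal magnitude + zero-phase low-pass) is used for peak analysis. The
cortical speech-FFR appears as an envelope peak at ≈ 30–40 ms latency.

Genuineness is tested against **noise TRFs** fitted with time-reversed
features: a bootstrap (10,000 permutations) over a subject's noise-model
envelopes yields per-lag empirical p-values, Bonferroni-corrected across
lags. Attentional modulation is quantified per subject as

    Q = (a − i) / (a + i)

from the envelope magnitudes at the peak latency when the voice is attended
(*a*) versus ignored (*i*). Cohort statistics follow a Shapiro–Wilk gate
(t-test if both samples normal, Mann–Whitney-U otherwise), Brown-Forsythe
for variances, Spearman correlations with Benjamini–Hochberg correction for
the musical-training scores, and Kruskal–Wallis for behaviour.

## Worked example

```sh
speechffr demo --seed 5 --out demo_out --subjects 8 --duration 60
```

runs an all-synthetic experiment — one 60 s voice, 8 subjects (3 musicians,
3 non-musicians, 2 neutral) with known TRF kernels peaking at 35 ms and an
attention gain of 1.5 — and prints:

```
speech-FFR pipeline (8 subjects, 60 s stimulus)
  feature correlation r = -0.0149 (p = 7.6e-25)
  f0 tracking MAE = 0.34 Hz
  fundamental/attended: population peak latency 33.6 ms (8/8 significant)
  fundamental/ignored: population peak latency 34.0 ms (8/8 significant)
  envelope_mod/attended: population peak latency 33.5 ms (8/8 significant)
  envelope_mod/ignored: population peak latency 33.6 ms (8/8 significant)
  kernel recovery r = 0.979, latency error = 0.40 ms
  median Q (envelope_mod) = +0.197
  median Q (fundamental) = +0.201
```

Reading the output: the two extracted features are essentially uncorrelated
(they capture different aspects of the stimulus); the f0 tracker follows the
generating trajectory to a fraction of a Hz; every subject's TRF envelope is
significant against its noise models and the population peak latencies
recover the generating 35 ms kernel; and the median attention score matches
the generative prediction Q = (1.5−1)/(1.5+1) = 0.2. The output directory
holds the per-subject peak table (`peaks.csv`), envelopes, Q scores,
group-level statistics (JSON), the serialized config and a provenance
record.

The same pipeline runs stage-by-stage (`simulate`, `features`, `fit`,
`significance`, `stats`, `all`) from a YAML config; see
`speechffr <stage> --help`.

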