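"""End-to-end orchestration of the speech-FFR analysis.

``run_pipeline`` sequences the stages stimulus → features → preprocessing →
TRF fit → significance → cohort statistics from a single
:class:`PipelineConfig`, persisting every stage's output together with a
provenance record.  In synthetic mode the stimulus, the neural recordings
and the cohort come from :mod:`speechffr.synthdata` with known ground
truth, so a complete run doubles as a parameter-recovery check.

Randomness is controlled by one master seed fanned out per stage and
subject through ``numpy.random.SeedSequence``, so any stage can be rerun
in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort as cohort_mod, features as features_mod
from . import inference, neuralprep, synthdata, trf as trf_mod

log = logging.getLogger("speechffr")

STAGES = ("simulate", "features", "fit", "significance", "stats")
CONDITIONS = ("attended", "ignored")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, serialisable to YAML."""

    seed: int = 0
    out_dir: str | None = "speechffr_out"
    mode: str = "synthetic"

    # stimulus / synthesis
    duration_s: float = 60.0
    audio_rate_hz: float = 8000.0
    f0_range_hz: tuple[float, float] = (70.0, 120.0)
    f0_wander_hz: float = 0.5
    n_harmonics: int = 5

    # cohort
    n_musicians: int = 3
    n_nonmusicians: int = 3
    n_neutral: int = 2

    # neural generation
    neural_rate_hz: float = 1000.0
    n_channels: int = 1
    peak_latency_ms: float = 35.0
    latency_jitter_sd_ms: float = 2.0
    kernel_carrier_hz: float = 95.0
    kernel_width_ms: float = 10.0
    beta_amplitude: float = 0.6
    attention_gain: float = 1.5
    gain_jitter_sd: float = 0.0
    snr_db: float = 0.0
    noise_exponent: float = 0.0
    tube_delay_ms: float = 6.0

    # preprocessing
    notch_hz: float = 50.0
    fundamental_band_hz: tuple[float, float] = (65.0, 120.0)
    ffr_band_hz: tuple[float, float] = (70.0, 120.0)

    # TRF estimation
    tau_min_ms: float = -20.0
    tau_max_ms: float = 120.0
    tau_step_ms: float = 1.0
    ridge_lambda: float = 1.0

    # significance
    n_noise_models: int = 10
    n_permutations: int = 10000
    alpha: float = 0.05

    save_trfs: bool = False

    @property
    def lag_axis(self) -> trf_mod.LagAxis:
        return trf_mod.LagAxis(self.tau_min_ms, self.tau_max_ms, self.tau_step_ms)

    @property
    def n_subjects(self) -> int:
        return self.n_musicians + self.n_nonmusicians + self.n_neutral

    def validate(self) -> None:
        if self.mode != "synthetic":
            raise ValueError("only synthetic mode is implemented; provide "
                             "precomputed features/recordings through the "
                             "library API for recorded data")
        if self.duration_s <= 0 or self.n_subjects < 1:
            raise ValueError("need a positive duration and at least one subject")
        _ = self.lag_axis  # validates ordering
        if self.ridge_lambda < 0 or self.n_permutations < 1 or self.n_noise_models < 1:
            raise ValueError("invalid estimation/significance parameters")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["f0_range_hz"] = list(d["f0_range_hz"])
        d["fundamental_band_hz"] = list(d["fundamental_band_hz"])
        d["ffr_band_hz"] = list(d["ffr_band_hz"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("f0_range_hz", "fundamental_band_hz", "ffr_band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def stage_seed(master: int, *key: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# stage indices for the seed fan-out
_SEED_STIMULUS, _SEED_COHORT, _SEED_SUBJECT, _SEED_BOOT = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# result container


@dataclass
class PipelineResult:
    config: PipelineConfig
    feature_diagnostics: dict = field(default_factory=dict)
    cohort_frame: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    envelopes: pd.DataFrame | None = None
    population: dict = field(default_factory=dict)
    qscores: pd.DataFrame | None = None
    group_stats: dict = field(default_factory=dict)
    score_correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"speech-FFR pipeline ({self.config.n_subjects} subjects, "
                 f"{self.config.duration_s:.0f} s stimulus)"]
        fd = self.feature_diagnostics
        if fd:
            lines.append(f"  feature correlation r = {fd['feature_r']:+.4f} "
                         f"(p = {fd['feature_p']:.2g})")
            if "f0_mae_hz" in fd:
                lines.append(f"  f0 tracking MAE = {fd['f0_mae_hz']:.2f} Hz")
        for feat, pops in self.population.items():
            for cond, d in pops.items():
                lines.append(f"  {feat}/{cond}: population peak latency "
                             f"{d['latency_ms']:.1f} ms "
                             f"({d['n_significant']}/{d['n_subjects']} significant)")
        if self.recovery:
            lines.append(f"  kernel recovery r = {self.recovery['kernel_corr_mean']:.3f}, "
                         f"latency error = {self.recovery['latency_mae_ms']:.2f} ms")
        if self.qscores is not None and len(self.qscores):
            for feat, g in self.qscores.groupby("feature"):
                lines.append(f"  median Q ({feat}) = {g['Q'].median():+.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stages


def _simulate_stimulus(config: PipelineConfig):
    seed = stage_seed(config.seed, _SEED_STIMULUS)
    track = synthdata.gen_f0_trajectory(config.duration_s, config.f0_range_hz,
                                        config.f0_wander_hz, seed=seed,
                                        sample_rate_hz=config.audio_rate_hz)
    voice = synthdata.gen_voice(track, config.n_harmonics,
                                config.audio_rate_hz, seed=seed)
    return track, voice


def _extract_features(config: PipelineConfig, voice, track):
    feats = features_mod.extract_features(voice, config.audio_rate_hz,
                                          fundamental_band_hz=config.fundamental_band_hz)
    r, p = features_mod.feature_correlation(feats.fundamental, feats.envelope_mod)
    diag = {"feature_r": r, "feature_p": p}
    if track is not None:
        est = feats.f0_track
        ok = est.voiced & track.voiced
        diag["f0_mae_hz"] = float(np.mean(np.abs(est.f0_hz[ok] - track.f0_hz[ok])))
        diag["f0_voiced_fraction"] = float(est.voiced.mean())
    return feats.resample(config.neural_rate_hz), diag


def _subject_truth(config: PipelineConfig, subject_index: int) -> synthdata.GroundTruth:
    rng = np.random.default_rng(stage_seed(config.seed, _SEED_SUBJECT, subject_index))
    latency = config.peak_latency_ms + rng.normal(0, config.latency_jitter_sd_ms) \
        if config.latency_jitter_sd_ms > 0 else config.peak_latency_ms
    gain = max(1.0, config.attention_gain + (rng.normal(0, config.gain_jitter_sd)
                                             if config.gain_jitter_sd > 0 else 0.0))
    return synthdata.make_ground_truth(
        lag_axis=config.lag_axis, sample_rate_hz=config.neural_rate_hz,
        peak_latency_ms=float(latency), carrier_hz=config.kernel_carrier_hz,
        width_ms=config.kernel_width_ms, beta_amplitude=config.beta_amplitude,
        attention_gain=float(gain), noise_sd=0.0,
        noise_exponent=config.noise_exponent,
        seed=stage_seed(config.seed, _SEED_SUBJECT, subject_index, 99))


def _preprocess(config: PipelineConfig, recording, feats_neural):
    rec = neuralprep.notch(recording, config.notch_hz)
    rec = neuralprep.resample(rec, config.neural_rate_hz)
    rec = neuralprep.ffr_bandpass(rec, *config.ffr_band_hz)
    return neuralprep.align(rec, feats_neural, config.tube_delay_ms)


def _env_at(envelope: np.ndarray, lags_ms: np.ndarray, latency_ms: float) -> float:
    if not np.isfinite(latency_ms):
        return float("nan")
    return float(envelope[int(np.argmin(np.abs(lags_ms - latency_ms)))])


def run_pipeline(config: PipelineConfig, through: str = "stats") -> PipelineResult:
    """Run the pipeline up to and including stage ``through``.

    Stages: simulate → features → fit → significance → stats.  Outputs are
    written to ``config.out_dir`` (skipped when it is None) together with
    the config, a provenance record and a log file.
    """
    config.validate()
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    last = STAGES.index(through)
    out = Path(config.out_dir).resolve() if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "pipeline.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    result = PipelineResult(config=config)
    try:
        _run_stages(config, result, last, out)
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        if out is not None:
            log.removeHandler(fh)
            fh.close()
    return result


def _run_stages(config, result, last, out):
    lag_axis = config.lag_axis
    lags_ms = lag_axis.lags_ms()

    log.info("stage simulate: stimulus + cohort (seed %d)", config.seed)
    track, voice = _simulate_stimulus(config)
    cohort = synthdata.gen_cohort(config.n_musicians, config.n_nonmusicians,
                                  config.n_neutral,
                                  seed=stage_seed(config.seed, _SEED_COHORT))
    result.cohort_frame = cohort_mod.cohort_to_frame(cohort)
    if out is not None:
        config.to_yaml(out / "config.yaml")
        _write_provenance(config, out)
        synthdata.write_wav(out / "stimulus.wav", voice, config.audio_rate_hz)
        result.cohort_frame.to_csv(out / "cohort.csv", index=False)
    if last < 1:
        return

    log.info("stage features: f0 tracking and the two f0-band features")
    feats_neural, diag = _extract_features(config, voice, track)
    result.feature_diagnostics = diag
    if out is not None:
        np.savetxt(out / "features.tsv",
                   np.column_stack([feats_neural.fundamental,
                                    feats_neural.envelope_mod]),
                   delimiter="\t", header="fundamental\tenvelope_mod")
        (out / "feature_diagnostics.json").write_text(json.dumps(diag, indent=1))
    if last < 2:
        return

    log.info("stage fit: per-subject TRFs (%d subjects)", config.n_subjects)
    # generate, preprocess and fit per subject; the aligned features (and
    # hence the factorised designs) are shared across subjects
    subjects = []
    analyzer = None
    feats_aligned = None
    for s, profile in enumerate(cohort):
        truth = _subject_truth(config, s)
        clean = synthdata.gen_neural_response(feats_neural, truth, attended=False,
                                              n_channels=1, seed=0)
        truth.noise_sd = synthdata.noise_sd_for_snr(clean.samples, config.snr_db)
        recs = {}
        for c, cond in enumerate(CONDITIONS):
            rec = synthdata.gen_neural_response(
                feats_neural, truth, attended=(cond == "attended"),
                n_channels=config.n_channels,
                seed=stage_seed(config.seed, _SEED_SUBJECT, s, c),
                acoustic_delay_ms=config.tube_delay_ms)
            rec_a, feats_a = _preprocess(config, rec, feats_neural)
            recs[cond] = rec_a
            if feats_aligned is None:
                feats_aligned = feats_a
        if analyzer is None:
            analyzer = inference.TRFAnalyzer(feats_aligned, lag_axis,
                                             config.ridge_lambda,
                                             config.n_noise_models)
        models = {cond: analyzer.genuine(recs[cond]) for cond in CONDITIONS}
        subjects.append({"profile": profile, "truth": truth, "recordings": recs,
                         "models": models,
                         "envelopes": {cond: trf_mod.model_envelopes(m)
                                       for cond, m in models.items()}})
        if out is not None and config.save_trfs:
            trf_dir = out / "trf"
            trf_dir.mkdir(exist_ok=True)
            for cond, m in models.items():
                trf_mod.save_trf(m, trf_dir / f"{profile.subject_id}_{cond}.tsv")

    # recovery diagnostics against the generating kernels
    kernel_corrs, latency_errors = [], []
    for sub in subjects:
        m = sub["models"]["attended"]
        est = m.alpha.mean(axis=1)
        kernel_corrs.append(float(np.corrcoef(est, sub["truth"].kernel_alpha)[0, 1]))
        env = sub["envelopes"]["attended"]["fundamental"]
        latency_errors.append(abs(float(lags_ms[int(np.argmax(env))])
                                  - sub["truth"].peak_latency_ms))
    result.recovery = {"kernel_corr_mean": float(np.mean(kernel_corrs)),
                       "kernel_corr_min": float(np.min(kernel_corrs)),
                       "latency_mae_ms": float(np.mean(latency_errors))}

    env_rows = []
    for sub in subjects:
        for cond in CONDITIONS:
            for feat in trf_mod.FEATURE_NAMES:
                env = sub["envelopes"][cond][feat]
                env_rows.append(pd.DataFrame({
                    "subject_id": sub["profile"].subject_id, "condition": cond,
                    "feature": feat, "lag_ms": lags_ms, "envelope": env}))
    result.envelopes = pd.concat(env_rows, ignore_index=True)
    if out is not None:
        result.envelopes.to_csv(out / "envelopes.csv", index=False)
    if last < 3:
        return

    log.info("stage significance: %d noise models, %d permutations",
             config.n_noise_models, config.n_permutations)
    peak_rows = []
    for s, sub in enumerate(subjects):
        for cond in CONDITIONS:
            noise_models = analyzer.noise(sub["recordings"][cond])
            noise_envs = inference.noise_envelopes(noise_models)
            for feat in trf_mod.FEATURE_NAMES:
                sig = inference.bootstrap_significance(
                    sub["envelopes"][cond][feat], noise_envs[feat],
                    config.n_permutations, config.alpha,
                    seed=stage_seed(config.seed, _SEED_BOOT, s,
                                    CONDITIONS.index(cond),
                                    list(trf_mod.FEATURE_NAMES).index(feat)))
                peak = inference.find_peak(sub["envelopes"][cond][feat], sig, lags_ms)
                sub.setdefault("peaks", {})[(cond, feat)] = peak
                peak_rows.append({
                    "subject_id": sub["profile"].subject_id, "group":
                        sub["profile"].group, "condition": cond, "feature": feat,
                    "latency_ms": peak.latency_ms, "magnitude": peak.magnitude,
                    "significant": peak.is_significant,
                    "min_p_corrected": float(sig.p_corrected.min())})
    result.peaks = pd.DataFrame(peak_rows)
    if out is not None:
        result.peaks.to_csv(out / "peaks.csv", index=False)
    if last < 4:
        return

    log.info("stage stats: population latencies, attention and cohort statistics")
    _stats_stage(config, result, subjects, lags_ms)
    if out is not None:
        _write_stats(result, out)
    log.info("pipeline complete")


def _stats_stage(config, result, subjects, lags_ms):
    population: dict = {}
    for feat in trf_mod.FEATURE_NAMES:
        population[feat] = {}
        for cond in CONDITIONS:
            lat = np.array([sub["peaks"][(cond, feat)].latency_ms
                            for sub in subjects])
            sig = np.isfinite(lat)
            kept, excluded, keep_mask = inference.iqr_exclude(lat[sig]) \
                if sig.sum() >= 1 else (lat[sig], lat[:0], np.array([], bool))
            pop_latency = float(np.mean(kept)) if kept.size else float("nan")
            population[feat][cond] = {
                "latency_ms": pop_latency, "n_subjects": len(subjects),
                "n_significant": int(sig.sum()),
                "n_latency_outliers": int(excluded.size)}
    # per-subject magnitudes at the population latency (all subjects rejoin)
    mags = {(feat, cond): np.array([
        _env_at(sub["envelopes"][cond][feat], lags_ms,
                population[feat][cond]["latency_ms"]) for sub in subjects])
        for feat in trf_mod.FEATURE_NAMES for cond in CONDITIONS}

    attention_tests: dict = {}
    q_rows = []
    for feat in trf_mod.FEATURE_NAMES:
        a, i = mags[(feat, "attended")], mags[(feat, "ignored")]
        ok = np.isfinite(a) & np.isfinite(i)
        _, _, keep_a = inference.iqr_exclude(a[ok])
        _, _, keep_i = inference.iqr_exclude(i[ok])
        if ok.sum() >= 3:
            attention_tests[feat] = {
                "magnitude": inference.compare_conditions(a[ok][keep_a],
                                                          i[ok][keep_i]),
            }
            lat_a = np.array([sub["peaks"][("attended", feat)].latency_ms
                              for sub in subjects])
            lat_i = np.array([sub["peaks"][("ignored", feat)].latency_ms
                              for sub in subjects])
            la, li = lat_a[np.isfinite(lat_a)], lat_i[np.isfinite(lat_i)]
            if la.size >= 3 and li.size >= 3:
                attention_tests[feat]["latency"] = inference.compare_conditions(
                    inference.iqr_exclude(la)[0], inference.iqr_exclude(li)[0])
        for s, sub in enumerate(subjects):
            score = inference.attention_score(
                max(a[s], 0.0) if np.isfinite(a[s]) else 0.0,
                max(i[s], 0.0) if np.isfinite(i[s]) else 0.0)
            q_rows.append({"subject_id": sub["profile"].subject_id,
                           "group": sub["profile"].group, "feature": feat,
                           "a": score.a, "i": score.i, "Q": score.Q})
    result.population = population
    result.qscores = pd.DataFrame(q_rows)

    # musicians vs non-musicians
    groups = np.array([sub["profile"].group for sub in subjects])
    mus, non = groups == "musician", groups == "non-musician"
    group_stats: dict = {"attention": attention_tests, "musicianship": {}}
    for feat in trf_mod.FEATURE_NAMES:
        group_stats["musicianship"][feat] = {}
        for cond in CONDITIONS:
            x, y = mags[(feat, cond)][mus], mags[(feat, cond)][non]
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if x.size >= 3 and y.size >= 3:
                x, y = inference.iqr_exclude(x)[0], inference.iqr_exclude(y)[0]
                group_stats["musicianship"][feat][cond] = {
                    "mean": inference.compare_conditions(x, y),
                    "variance": inference.compare_variances(x, y)}
        qf = result.qscores[result.qscores["feature"] == feat]
        qx = qf[qf["group"] == "musician"]["Q"].dropna().to_numpy()
        qy = qf[qf["group"] == "non-musician"]["Q"].dropna().to_numpy()
        if qx.size >= 3 and qy.size >= 3:
            group_stats["musicianship"][feat]["Q"] = {
                "mean": inference.compare_conditions(qx, qy),
                "variance": inference.compare_variances(qx, qy)}
    result.group_stats = group_stats

    # musical-training scores and behaviour
    cohort = [sub["profile"] for sub in subjects]
    scores = cohort_mod.compute_scores(cohort)
    frame = result.cohort_frame.set_index("subject_id")
    for feat in trf_mod.FEATURE_NAMES:
        result.score_correlations[feat] = cohort_mod.correlate_scores(
            mags[(feat, "attended")], scores)
        frame[f"mag_{feat}_attended"] = mags[(feat, "attended")]
    result.behavior = cohort_mod.behavior_stats(
        frame.reset_index(),
        [f"mag_{feat}_attended" for feat in trf_mod.FEATURE_NAMES])
    result.cohort_frame = frame.reset_index()


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_stats(result: PipelineResult, out: Path) -> None:
    (out / "population.json").write_text(
        json.dumps(_sanitize(result.population), indent=1))
    (out / "group_stats.json").write_text(
        json.dumps(_sanitize(result.group_stats), indent=1))
    (out / "behavior.json").write_text(
        json.dumps(_sanitize(result.behavior), indent=1))
    (out / "recovery.json").write_text(
        json.dumps(_sanitize(result.recovery), indent=1))
    result.qscores.to_csv(out / "qscores.csv", index=False)
    for feat, table in result.score_correlations.items():
        table.to_csv(out / f"score_correlations_{feat}.csv")
    result.cohort_frame.to_csv(out / "cohort.csv", index=False)


def _write_provenance(config: PipelineConfig, out: Path) -> None:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    (out / "provenance.json").write_text(json.dumps({
        "package": "speechffr", "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "stages": list(STAGES)}, indent=1))
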