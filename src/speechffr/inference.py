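"""Significance testing, peak extraction and attention statistics.

The genuineness of a subject's TRF is assessed against *noise models*:
TRFs fitted after reversing the stimulus features in time.  Reversal (and
the circular shifts used to obtain several distinct noise models) preserves
the features' autocorrelation, so a noise model is exchangeable with the
genuine fit whenever the response carries no stimulus-locked component.  A
bootstrap over the noise-model envelopes builds a per-lag null
distribution; empirical p-values are Bonferroni-corrected across lags.

Attentional modulation is quantified per subject by

    Q = (a - i) / (a + i),

the normalised difference of the envelope-TRF magnitudes at the peak
latency between the attended (a) and ignored (i) condition: Q = 0 means no
modulation, Q -> 1 means the response vanishes when the voice is ignored.

Group comparisons follow a Shapiro-Wilk gate: Student's t-test when both
samples are normal, Mann-Whitney-U otherwise; variance homogeneity uses
the Brown-Forsythe (median-centred Levene) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .features import StimulusFeatures
from .neuralprep import NeuralRecording
from .trf import (FEATURE_NAMES, LagAxis, RidgeSolver, TRFModel,
                  estimate_trf, model_envelopes)

__all__ = [
    "SignificanceProfile",
    "PeakResult",
    "AttentionScore",
    "noise_trf",
    "noise_feature_sets",
    "TRFAnalyzer",
    "noise_envelopes",
    "bootstrap_significance",
    "find_peak",
    "iqr_exclude",
    "attention_score",
    "compare_conditions",
    "compare_variances",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SignificanceProfile:
    """Per-lag empirical p-values with Bonferroni correction."""

    p_per_lag: np.ndarray
    p_corrected: np.ndarray
    significant_mask: np.ndarray
    n_permutations: int
    alpha: float
    noise_quantiles: dict[str, np.ndarray]  # per-lag summary of the null

    @property
    def any_significant(self) -> bool:
        return bool(self.significant_mask.any())


@dataclass
class PeakResult:
    """Envelope peak of one subject in one condition."""

    latency_ms: float
    magnitude: float
    is_significant: bool
    excluded_as_outlier: bool = False


@dataclass
class AttentionScore:
    """Attended (a) and ignored (i) envelope magnitudes with Q = (a-i)/(a+i)."""

    a: float
    i: float
    Q: float


# ---------------------------------------------------------------------------
# noise models


def noise_feature_sets(features: StimulusFeatures,
                       n_reversals: int) -> list[StimulusFeatures]:
    """Time-reversed feature streams for the noise models.

    Both streams are reversed together; set ``k`` additionally applies a
    deterministic circular shift of ``k * n / n_reversals`` samples
    (``k = 0`` is the plain reversal).  Reversal and circular shifting both
    preserve the features' second-order statistics, so each noise model is
    exchangeable with the genuine fit under the null of no stimulus-locked
    response.
    """
    if n_reversals < 1:
        raise ValueError("need at least one noise model")
    rev = features.reversed()
    n = rev.n_samples
    out = []
    for k in range(n_reversals):
        shift = (k * n) // n_reversals
        out.append(StimulusFeatures(np.roll(rev.fundamental, shift),
                                    np.roll(rev.envelope_mod, shift),
                                    rev.sample_rate_hz))
    return out


class TRFAnalyzer:
    """Genuine and noise-model TRF fits sharing pre-factorised designs.

    All subjects of a fixed-stimulus experiment share the genuine design
    and the reversed-feature noise designs, so the expensive Gram
    factorisations are done once here and each subject's recording only
    needs cheap refits.
    """

    def __init__(self, features: StimulusFeatures, lag_axis: LagAxis = LagAxis(),
                 ridge_lambda: float = 1.0, n_reversals: int = 10):
        self.lag_axis = lag_axis
        self.genuine_solver = RidgeSolver(features, lag_axis, ridge_lambda)
        self.noise_solvers = [RidgeSolver(f, lag_axis, ridge_lambda)
                              for f in noise_feature_sets(features, n_reversals)]

    def genuine(self, recording: NeuralRecording) -> TRFModel:
        return self.genuine_solver.fit(recording)

    def noise(self, recording: NeuralRecording) -> list[TRFModel]:
        return [s.fit(recording) for s in self.noise_solvers]


def noise_trf(
    features: StimulusFeatures,
    recording: NeuralRecording,
    lag_axis: LagAxis = LagAxis(),
    ridge_lambda: float = 1.0,
    n_reversals: int = 10,
) -> list[TRFModel]:
    """Fit noise TRFs from time-reversed stimulus features.

    Convenience one-shot form of :class:`TRFAnalyzer`; the genuine
    response is left untouched.
    """
    return [estimate_trf(f, recording, lag_axis, ridge_lambda)
            for f in noise_feature_sets(features, n_reversals)]


def noise_envelopes(models: list[TRFModel],
                    component_groups: list[list[int]] | None = None
                    ) -> dict[str, np.ndarray]:
    """Stack the magnitude envelopes of noise models, per feature (K x lags)."""
    out = {name: [] for name in FEATURE_NAMES}
    for m in models:
        envs = model_envelopes(m, component_groups)
        for name in FEATURE_NAMES:
            out[name].append(envs[name])
    return {name: np.vstack(v) for name, v in out.items()}


def bootstrap_significance(
    genuine_envelope: np.ndarray,
    noise_envs: np.ndarray,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SignificanceProfile:
    """Bootstrap the noise models into a per-lag null distribution.

    Each permutation draws one noise-model envelope with replacement; the
    empirical p-value at each lag is the (+1-corrected) proportion of null
    values at or above the genuine envelope,
    ``p = (1 + #{null >= observed}) / (n_permutations + 1)``, so p is never
    exactly zero.  Bonferroni correction multiplies by the number of lags.
    """
    obs = np.asarray(genuine_envelope, dtype=float)
    null_pool = np.atleast_2d(np.asarray(noise_envs, dtype=float))
    if null_pool.shape[1] != obs.size:
        raise ValueError("noise envelopes must share the genuine lag axis")
    if null_pool.shape[0] < 1:
        raise ValueError("empty noise-model set")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, null_pool.shape[0], size=n_permutations)
    # count, per lag, how many drawn noise envelopes reach the observed value
    exceed = np.zeros(obs.size)
    counts = np.bincount(draws, minlength=null_pool.shape[0]).astype(float)
    exceed = counts @ (null_pool >= obs[None, :])
    p = (1.0 + exceed) / (n_permutations + 1.0)
    m = obs.size
    p_corr = np.minimum(1.0, p * m)
    quantiles = {f"q{q}": np.quantile(null_pool, q / 100, axis=0)
                 for q in (5, 25, 50, 75, 95)}
    return SignificanceProfile(p_per_lag=p, p_corrected=p_corr,
                               significant_mask=p_corr < alpha,
                               n_permutations=n_permutations, alpha=alpha,
                               noise_quantiles=quantiles)


# ---------------------------------------------------------------------------
# peaks and attention


def find_peak(
    envelope: np.ndarray,
    significance: SignificanceProfile,
    lags_ms: np.ndarray,
) -> PeakResult:
    """Global envelope maximum restricted to significant lags.

    With an empty significant mask no latency is fabricated: the result is
    flagged insignificant with NaN latency and magnitude.  Exact ties are
    resolved to the earliest lag.
    """
    env = np.asarray(envelope, dtype=float)
    mask = significance.significant_mask
    if env.size != mask.size or env.size != np.asarray(lags_ms).size:
        raise ValueError("envelope, mask and lag axis must share length")
    if not mask.any():
        return PeakResult(latency_ms=float("nan"), magnitude=float("nan"),
                          is_significant=False)
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(env[idx])]  # argmax returns the first maximum
    return PeakResult(latency_ms=float(np.asarray(lags_ms)[best]),
                      magnitude=float(env[best]), is_significant=True)


def iqr_exclude(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tukey-fence outlier exclusion.

    Values strictly below ``Q1 - 1.5 IQR`` or above ``Q3 + 1.5 IQR`` are
    excluded.  Returns ``(kept, excluded, keep_mask)``.  With fewer than
    four values no exclusion is performed (warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values: no outlier exclusion applied")
        return v, v[:0], np.ones(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep], keep


def attention_score(a: float, i: float) -> AttentionScore:
    """Normalised attended/ignored difference Q = (a - i) / (a + i).

    Swapping the conditions flips the sign.  With ``a + i = 0`` the score
    is undefined and reported as NaN.
    """
    if a < 0 or i < 0:
        raise ValueError("envelope magnitudes must be non-negative")
    if a + i == 0:
        return AttentionScore(a=a, i=i, Q=float("nan"))
    return AttentionScore(a=float(a), i=float(i), Q=float((a - i) / (a + i)))


# ---------------------------------------------------------------------------
# gated group statistics


def _is_normal(x: np.ndarray, alpha: float) -> tuple[bool, float]:
    if np.ptp(x) == 0:
        return False, 0.0  # constant sample: treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(x)
    return p >= alpha, float(p)


def compare_conditions(
    group_x: np.ndarray,
    group_y: np.ndarray,
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> dict:
    """Location comparison behind a Shapiro-Wilk normality gate.

    Both samples normal at ``normality_alpha`` -> Student's t-test
    (unpaired by default); otherwise Mann-Whitney-U (Wilcoxon signed-rank
    when paired).  The report records which branch fired.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    nx, px = _is_normal(x, normality_alpha)
    ny, py = _is_normal(y, normality_alpha)
    if nx and ny:
        branch = "parametric"
        if paired:
            name, (statistic, p) = "t-test (paired)", stats.ttest_rel(x, y)
        else:
            name, (statistic, p) = "t-test (unpaired)", stats.ttest_ind(x, y)
    else:
        branch = "nonparametric"
        if paired:
            name = "Wilcoxon signed-rank"
            if np.any(x != y):
                statistic, p = stats.wilcoxon(x, y)
            else:
                statistic, p = 0.0, 1.0  # identical pairs: no difference
        else:
            name, (statistic, p) = "Mann-Whitney-U", stats.mannwhitneyu(
                x, y, alternative="two-sided")
    return {"test": name, "branch": branch, "statistic": float(statistic),
            "p": float(p), "shapiro_p": (px, py), "n": (int(x.size), int(y.size))}


def compare_variances(group_x: np.ndarray, group_y: np.ndarray) -> dict:
    """Brown-Forsythe test (median-centred Levene) for variance homogeneity."""
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return {"test": "Brown-Forsythe", "statistic": 0.0, "p": 1.0,
                "n": (int(x.size), int(y.size))}
    statistic, p = stats.levene(x, y, center="median")
    return {"test": "Brown-Forsythe", "statistic": float(statistic),
            "p": float(p), "n": (int(x.size), int(y.size))}
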