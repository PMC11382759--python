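"""Musicianship classification, training scores and cohort statistics.

Participants are classified from a musical-training questionnaire:

========================  ===========  =====================  ==================
group                     starting age total years of training presently training
========================  ===========  =====================  ==================
musician                  <= 7         >= 10                  yes
non-musician              >= 7         <= 3                   no
========================  ===========  =====================  ==================

Someone who never played an instrument is a non-musician; everyone meeting
neither column is "neutral".  Four graded scores of musical training
(starting age, total years, current weekly hours, lifetime instrument
count) are normalised by their cohort maximum and summed into an aggregate
score; neural response strength is related to the scores by Spearman
correlation with Benjamini-Hochberg correction across the five tests, and
behavioural comprehension is compared across groups with a Kruskal-Wallis
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParticipantProfile",
    "classify_participant",
    "compute_scores",
    "correlate_scores",
    "behavior_stats",
    "cohort_to_frame",
    "cohort_from_frame",
]

SCORE_COLUMNS = ["starting_age_score", "total_years_score",
                 "current_hours_score", "n_instruments_score"]


@dataclass
class ParticipantProfile:
    """Questionnaire attributes and per-condition results of one participant.

    ``starting_age_years`` is ``None`` for someone who never played an
    instrument (which forces zero training years).  ``peaks`` and
    ``attention`` are filled by the pipeline: peak results per
    (condition, feature) and attention scores per feature.
    """

    subject_id: str
    starting_age_years: Optional[float]
    total_training_years: float
    currently_training: bool
    hours_per_week: float
    n_instruments_lifetime: int
    percent_correct: float = np.nan
    group: Optional[str] = None
    peaks: dict = field(default_factory=dict)
    attention: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.starting_age_years is None and self.total_training_years != 0:
            raise ValueError(f"{self.subject_id}: never played but has "
                             "nonzero training years")
        if self.currently_training and self.total_training_years == 0:
            raise ValueError(f"{self.subject_id}: currently training with "
                             "zero total years")
        if self.total_training_years < 0 or self.hours_per_week < 0:
            raise ValueError(f"{self.subject_id}: negative training amount")
        if self.n_instruments_lifetime < 0:
            raise ValueError(f"{self.subject_id}: negative instrument count")
        if not np.isnan(self.percent_correct) and not 0 <= self.percent_correct <= 100:
            raise ValueError(f"{self.subject_id}: percent_correct out of [0, 100]")


def classify_participant(profile: ParticipantProfile) -> str:
    """Apply the questionnaire criteria; returns the group label.

    A participant who never played qualifies as non-musician even though a
    starting-age criterion cannot apply to them.
    """
    profile.validate()
    age = profile.starting_age_years
    if age is not None and age <= 7 and profile.total_training_years >= 10 \
            and profile.currently_training:
        return "musician"
    if age is None:
        return "non-musician"
    if age >= 7 and profile.total_training_years <= 3 \
            and not profile.currently_training:
        return "non-musician"
    return "neutral"


def compute_scores(cohort: list[ParticipantProfile]) -> pd.DataFrame:
    """Four normalised musical-training scores plus their aggregate.

    Each component is normalised to [0, 1] by the cohort maximum.  The
    starting-age component rewards an earlier start,
    ``(max_age - age) / max_age`` over participants who played; who never
    played contributes no value there (NaN) and their aggregate sums the
    remaining components.  An all-zero component contributes 0 for
    everyone, with a warning.
    """
    if not cohort:
        raise ValueError("empty cohort")
    idx = [p.subject_id for p in cohort]
    ages = np.array([np.nan if p.starting_age_years is None
                     else p.starting_age_years for p in cohort])
    years = np.array([p.total_training_years for p in cohort], dtype=float)
    hours = np.array([p.hours_per_week for p in cohort], dtype=float)
    instruments = np.array([p.n_instruments_lifetime for p in cohort], dtype=float)

    def _norm(v: np.ndarray, name: str) -> np.ndarray:
        top = np.nanmax(v) if np.isfinite(v).any() else 0.0
        if top == 0:
            warnings.warn(f"all-zero component {name!r}: contributes 0")
            return np.zeros_like(v)
        return v / top

    if np.isfinite(ages).any():
        max_age = np.nanmax(ages)
        age_score = (max_age - ages) / max_age if max_age > 0 else np.zeros_like(ages)
    else:
        warnings.warn("no participant ever played: starting-age score empty")
        age_score = np.full_like(ages, np.nan)
    frame = pd.DataFrame({
        "starting_age_score": age_score,
        "total_years_score": _norm(years, "total_years"),
        "current_hours_score": _norm(hours, "current_hours"),
        "n_instruments_score": _norm(instruments, "n_instruments"),
    }, index=pd.Index(idx, name="subject_id"))
    frame["aggregate"] = frame[SCORE_COLUMNS].sum(axis=1, skipna=True)
    return frame


def correlate_scores(
    neural_magnitudes: np.ndarray,
    scores: pd.DataFrame,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of neural strength with each training score.

    One test per score column plus the aggregate; the Benjamini-Hochberg
    false-discovery-rate adjustment is applied across the raw p-values of
    all tests actually computed.  Scores with fewer than ``min_pairs``
    complete pairs are skipped with a notice.
    """
    y = np.asarray(neural_magnitudes, dtype=float)
    if y.size != len(scores):
        raise ValueError("one neural magnitude per scored participant required")
    rows = []
    for col in SCORE_COLUMNS + ["aggregate"]:
        x = scores[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            warnings.warn(f"score {col!r}: fewer than {min_pairs} complete "
                          "pairs, skipped")
            rows.append((col, int(ok.sum()), np.nan, np.nan))
            continue
        r, p = stats.spearmanr(x[ok], y[ok])
        rows.append((col, int(ok.sum()), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["score", "n", "spearman_r", "p_raw"]
                       ).set_index("score")
    computed = out["p_raw"].notna()
    out["p_bh"] = np.nan
    if computed.any():
        out.loc[computed, "p_bh"] = stats.false_discovery_control(
            out.loc[computed, "p_raw"].to_numpy(), method="bh")
    return out


def behavior_stats(
    cohort: pd.DataFrame,
    neural_cols: list[str],
    behavior_col: str = "percent_correct",
    group_col: str = "group",
) -> dict:
    """Behavioural comprehension vs neural strength and group membership.

    Spearman correlation between each neural column and the percentage of
    correctly answered comprehension questions, and a Kruskal-Wallis test
    of the behavioural scores across the three groups.
    """
    out: dict = {"spearman": {}, "kruskal": None}
    b = cohort[behavior_col].to_numpy(dtype=float)
    for col in neural_cols:
        x = cohort[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(b)
        r, p = stats.spearmanr(x[ok], b[ok])
        out["spearman"][col] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    groups = [g[behavior_col].dropna().to_numpy()
              for _, g in cohort.groupby(group_col)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("Kruskal test needs at least two non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0  # identical behaviour everywhere: no group effect
    else:
        h, p = stats.kruskal(*groups)
    out["kruskal"] = {"H": float(h), "p": float(p),
                      "n_groups": len(groups),
                      "n": int(sum(len(g) for g in groups))}
    return out


# ---------------------------------------------------------------------------
# CSV round trip
#
# column dictionary: subject_id (str); starting_age_years (float, empty =
# never played); total_training_years (float, years); currently_training
# (0/1); hours_per_week (float); n_instruments_lifetime (int);
# percent_correct (float, %); group (musician | non-musician | neutral)


def cohort_to_frame(cohort: list[ParticipantProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id,
        "starting_age_years": p.starting_age_years,
        "total_training_years": p.total_training_years,
        "currently_training": int(p.currently_training),
        "hours_per_week": p.hours_per_week,
        "n_instruments_lifetime": p.n_instruments_lifetime,
        "percent_correct": p.percent_correct,
        "group": p.group if p.group is not None else classify_participant(p),
    } for p in cohort])


def cohort_from_frame(frame: pd.DataFrame) -> list[ParticipantProfile]:
    cohort = []
    for _, row in frame.iterrows():
        age = row["starting_age_years"]
        p = ParticipantProfile(
            subject_id=str(row["subject_id"]),
            starting_age_years=None if pd.isna(age) else float(age),
            total_training_years=float(row["total_training_years"]),
            currently_training=bool(row["currently_training"]),
            hours_per_week=float(row["hours_per_week"]),
            n_instruments_lifetime=int(row["n_instruments_lifetime"]),
            percent_correct=float(row.get("percent_correct", np.nan)),
            group=row.get("group"))
        p.validate()
        cohort.append(p)
    return cohort
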