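"""Trial- and subject-level exclusion rules and signed error computation.

Rules, applied in order: drop skipped trials, then per subject remove
trials whose estimation time exceeds the subject mean by more than
``trial_sd_threshold`` sample SDs (one-sided upper, strict inequality,
single pass), then exclude whole subjects whose mean estimation time
exceeds their group mean by more than ``subject_sd_threshold`` group SDs.
Means and SDs are computed once, including candidate outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import TrialRecord


@dataclass
class ExclusionReport:
    """Per-subject accounting of every exclusion decision."""

    subject_id: str
    n_trials_in: int
    n_skipped: int
    n_slow_excluded: int
    subject_excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.n_slow_excluded > self.n_trials_in - self.n_skipped:
            raise ValueError("cannot exclude more trials than retained")


def compute_errors(trial) -> tuple[float, float]:
    """Signed (performance_error, estimation_error) for one trial.

    performance_error = stop_x - target_x; estimation_error =
    point_x - stop_x.  Accepts a :class:`TrialRecord` or any mapping/row
    with the trial-table columns.  Raises on skipped trials.
    """
    if isinstance(trial, TrialRecord):
        if trial.skipped:
            raise ValueError("cannot compute errors for a skipped trial")
        return trial.performance_error, trial.estimation_error
    if bool(trial["skipped"]):
        raise ValueError("cannot compute errors for a skipped trial")
    perf = float(trial["stop_x"]) - float(trial["target_x"])
    est = float(trial["point_x"]) - float(trial["stop_x"])
    return perf, est


def add_error_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with performance_error / estimation_error columns."""
    out = trials.copy()
    out["performance_error"] = out["stop_x"] - out["target_x"]
    out["estimation_error"] = out["point_x"] - out["stop_x"]
    return out


def drop_skipped(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove skipped rows, preserving order; warns if nothing remains."""
    kept = trials.loc[~trials["skipped"].astype(bool)].copy()
    if len(kept) == 0 and len(trials) > 0:
        warnings.warn("all trials were skipped; empty table returned")
    return kept


def exclude_slow_trials(
    trials: pd.DataFrame, sd_threshold: float = 2.0
) -> tuple[pd.DataFrame, int]:
    """Single-pass upper exclusion of slow estimation times for one subject.

    Removes rows with ``estimation_time > mean + sd_threshold * SD`` where
    mean and sample SD (n-1) are computed once over the input.  Fewer than
    two trials: no exclusion, with a warning.
    """
    if trials["subject_id"].nunique() > 1:
        raise ValueError("exclude_slow_trials operates on a single subject")
    times = trials["estimation_time"].to_numpy(dtype=float)
    if len(times) < 2:
        warnings.warn(
            "fewer than 2 trials; slow-trial exclusion not applied"
        )
        return trials.copy(), 0
    mean = float(np.mean(times))
    sd = float(np.std(times, ddof=1))
    keep = times <= mean + sd_threshold * sd
    return trials.loc[keep].copy(), int((~keep).sum())


def exclude_outlier_subjects(
    mean_times: pd.Series,
    groups: pd.Series,
    sd_threshold: float = 3.0,
) -> list[str]:
    """Subjects whose mean estimation time is an upper outlier in their group.

    ``mean_times`` and ``groups`` are aligned, indexed by subject_id.
    Within each group: excluded when mean time > group mean +
    ``sd_threshold`` * group sample SD (strict).  Groups smaller than 3
    are left untouched with a warning.
    """
    excluded: list[str] = []
    for g in pd.unique(groups):
        ids = groups.index[groups == g]
        vals = mean_times.loc[ids].to_numpy(dtype=float)
        if len(ids) < 3:
            warnings.warn(
                f"group {g!r} has fewer than 3 subjects; no exclusion applied"
            )
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        cutoff = mean + sd_threshold * sd
        excluded.extend(str(s) for s, v in zip(ids, vals) if v > cutoff)
    return excluded


@dataclass
class PreprocessResult:
    trials: pd.DataFrame
    reports: list[ExclusionReport] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.reports])


def preprocess_trials(
    trials: pd.DataFrame,
    trial_sd_threshold: float = 2.0,
    subject_sd_threshold: float = 3.0,
) -> PreprocessResult:
    """Full exclusion pipeline over a multi-subject trial table.

    Returns the cleaned table (with error columns added) plus one
    :class:`ExclusionReport` per input subject.  Subject-level exclusion
    uses mean estimation times computed from trials retained after the
    slow-trial rule.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    per_subject: dict[str, pd.DataFrame] = {}
    reports: list[ExclusionReport] = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        n_in = len(sub)
        kept = drop_skipped(sub)
        n_skipped = n_in - len(kept)
        if len(kept) >= 2:
            kept, n_slow = exclude_slow_trials(kept, trial_sd_threshold)
        else:
            n_slow = 0
        per_subject[str(sid)] = kept
        reports.append(
            ExclusionReport(
                subject_id=str(sid),
                n_trials_in=n_in,
                n_skipped=n_skipped,
                n_slow_excluded=n_slow,
            )
        )
    mean_times = pd.Series(
        {
            sid: float(df["estimation_time"].mean())
            for sid, df in per_subject.items()
            if len(df) > 0
        }
    )
    group_of = pd.Series(
        {
            sid: str(df["group"].iloc[0])
            for sid, df in per_subject.items()
            if len(df) > 0
        }
    )
    outliers = set(exclude_outlier_subjects(mean_times, group_of, subject_sd_threshold))
    for rep in reports:
        if rep.subject_id in outliers:
            rep.subject_excluded = True
            rep.reason = (
                f"mean estimation time > group mean + {subject_sd_threshold} SD"
            )
    kept_frames = [
        df for sid, df in per_subject.items() if sid not in outliers and len(df) > 0
    ]
    clean = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else trials.iloc[0:0].copy()
    )
    if len(clean):
        clean = add_error_columns(clean)
    return PreprocessResult(
        trials=clean, reports=reports, excluded_subjects=sorted(outliers)
    )
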