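"""Per-subject regression of estimation on performance errors and the
derived prior-width metrics (normalized prior, prior accuracy)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

NormalizationVariant = Literal["sd", "variance"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    resid_sd_ml: float
    r: float


@dataclass
class SubjectMeasures:
    """Derived per-subject quantities used by the group-level statistics."""

    subject_id: str
    group: str
    n_trials: int
    perf_sd: float
    perf_mean: float
    slope: float
    intercept: float
    resid_sd_ml: float
    mean_est_time: float
    normalized_prior: Optional[float] = None
    prior_accuracy: Optional[float] = None
    lde: Optional[float] = None


def fit_subject_regression(
    perf_errors: np.ndarray, est_errors: np.ndarray
) -> RegressionFit:
    """OLS of estimation error on performance error for one subject.

    ``resid_sd_ml`` is the maximum-likelihood residual SD, sqrt(RSS/n).
    Requires >= 3 trials and a non-degenerate predictor.
    """
    p = np.asarray(perf_errors, dtype=float)
    e = np.asarray(est_errors, dtype=float)
    if p.shape != e.shape:
        raise ValueError("error vectors must have equal length")
    # two points define an exact line; allow them for the arithmetic checks
    if len(p) < 2:
        raise ValueError("need at least 2 trials for a regression")
    if np.ptp(p) == 0:
        raise ValueError("performance errors are all identical; cannot regress")
    res = sps.linregress(p, e)
    resid = e - (res.intercept + res.slope * p)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        resid_sd_ml=float(np.sqrt(np.mean(resid**2))),
        r=float(res.rvalue),
    )


def performance_sd(perf_errors: np.ndarray) -> float:
    """Sample SD (n-1 denominator) of performance errors; needs >= 2 trials."""
    p = np.asarray(perf_errors, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 trials for a sample SD")
    return float(np.std(p, ddof=1))


def normalized_prior(
    sigma_prior_hat: float,
    perf_sd: float,
    variant: NormalizationVariant = "sd",
) -> float:
    """Prior width scaled against the subject's own performance spread.

    Default ("sd") variant: sigma_prior / (sigma_prior + perf_sd), which
    maps (0, inf) onto (0, 1) and equals 0.5 exactly when the fitted prior
    SD matches the performance-error SD.  The "variance" variant uses the
    squared ratio and satisfies the same two constraints.
    """
    if sigma_prior_hat <= 0 or perf_sd <= 0:
        raise ValueError("both SDs must be strictly positive")
    if variant == "sd":
        return sigma_prior_hat / (sigma_prior_hat + perf_sd)
    if variant == "variance":
        return sigma_prior_hat**2 / (sigma_prior_hat**2 + perf_sd**2)
    raise ValueError(f"unknown normalization variant: {variant!r}")


def prior_accuracy(normalized_prior_value: float) -> float:
    """Absolute deviation of the normalized prior from 0.5.

    0 means the prior width matches the true performance spread; 0.5 is
    maximal mismatch in either direction.
    """
    if not (0.0 < normalized_prior_value < 1.0):
        raise ValueError("normalized prior must lie in (0, 1)")
    return abs(normalized_prior_value - 0.5)


def subject_measures(
    clean_trials: pd.DataFrame,
    sigma_prior_by_subject: Optional[dict[str, float]] = None,
    lde_by_subject: Optional[dict[str, float]] = None,
    variant: NormalizationVariant = "sd",
) -> pd.DataFrame:
    """Compute :class:`SubjectMeasures` for every subject in a cleaned table.

    ``clean_trials`` must carry performance_error / estimation_error
    columns (see :func:`selfprior.preprocess.add_error_columns`).  When a
    subject's fitted prior SD is supplied, normalized prior and prior
    accuracy are filled in; boundary-flagged subjects can simply be left
    out of the mapping.
    """
    rows = []
    for sid, sub in clean_trials.groupby("subject_id", sort=False):
        sid = str(sid)
        perf = sub["performance_error"].to_numpy(dtype=float)
        est = sub["estimation_error"].to_numpy(dtype=float)
        reg = fit_subject_regression(perf, est)
        m = SubjectMeasures(
            subject_id=sid,
            group=str(sub["group"].iloc[0]),
            n_trials=len(sub),
            perf_sd=performance_sd(perf),
            perf_mean=float(np.mean(perf)),
            slope=reg.slope,
            intercept=reg.intercept,
            resid_sd_ml=reg.resid_sd_ml,
            mean_est_time=float(sub["estimation_time"].mean()),
        )
        if sigma_prior_by_subject and sid in sigma_prior_by_subject:
            m.normalized_prior = normalized_prior(
                sigma_prior_by_subject[sid], m.perf_sd, variant
            )
            m.prior_accuracy = prior_accuracy(m.normalized_prior)
        if lde_by_subject and sid in lde_by_subject:
            m.lde = lde_by_subject[sid]
        rows.append(vars(m))
    table = pd.DataFrame(rows)
    for col in ("normalized_prior", "prior_accuracy", "lde"):
        table[col] = table[col].astype(float)
    return table
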