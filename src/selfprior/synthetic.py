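"""Simulation of the visuomotor stop task.

Generates per-trial tables with the statistical structure the analysis
pipeline assumes: subject-specific Gaussian performance errors, pointing
estimates produced by reliability-weighted integration of a goal-centred
prior with shifted sensory evidence, log-normal estimation times and
occasional skipped trials.

Coordinate convention: positions are absolute screen pixels, rightward
positive.  The target sits at the horizontal screen centre.  All model
equations operate on target-centred errors; the simulator writes absolute
positions so that downstream code exercises the same arithmetic as real
data would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

Group = Literal["patient", "control"]

#: Column order of the trial table CSV.
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "trial_index",
    "target_x",
    "stop_x",
    "point_x",
    "stop_time",
    "estimation_time",
    "skipped",
    "n_sweeps",
]


class ScreenGeometry(BaseModel):
    """Display geometry; the target is horizontally centred."""

    width_px: int = Field(default=1024, gt=0)
    height_px: int = Field(default=768, gt=0)
    px_per_cm: float = Field(default=26.0, gt=0)

    @property
    def target_x(self) -> float:
        return self.width_px / 2.0


class SubjectParams(BaseModel):
    """Generative ground truth for one simulated subject.

    ``sigma_performance``/``mu_performance`` describe where the ball
    actually stops relative to the target; ``sigma_prior``,
    ``sigma_evidence`` and ``shift_evidence`` parameterise the observer
    model that produces the pointing estimate.  The leftward pointing
    bias is a *negative* shift.
    """

    subject_id: str
    group: Group
    sigma_performance: float = Field(gt=0)
    mu_performance: float = -10.0
    sigma_prior: float = Field(gt=0)
    sigma_evidence: float = Field(gt=0)
    shift_evidence: float = -20.0
    skip_prob: float = Field(default=0.0, ge=0, lt=1)
    est_time_median: float = Field(default=1.0, gt=0)
    est_time_sigma_log: float = Field(default=0.0, ge=0)
    lde: Optional[float] = Field(default=None, ge=0)

    @property
    def weight(self) -> float:
        """Reliability weight on the prior: sigma_e^2/(sigma_p^2+sigma_e^2)."""
        ve = self.sigma_evidence**2
        return ve / (self.sigma_prior**2 + ve)

    @model_validator(mode="after")
    def _check_weight(self) -> "SubjectParams":
        if not (0.0 < self.weight < 1.0):
            raise ValueError("implied weight must lie strictly in (0, 1)")
        return self


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.  ``point_x``/``estimation_time`` are None when skipped."""

    subject_id: str
    group: str
    block: int
    trial_index: int
    target_x: float
    stop_x: float
    point_x: Optional[float]
    stop_time: float
    estimation_time: Optional[float]
    skipped: bool
    n_sweeps: int

    @property
    def performance_error(self) -> float:
        return self.stop_x - self.target_x

    @property
    def estimation_error(self) -> float:
        if self.skipped or self.point_x is None:
            raise ValueError("skipped trial has no estimation error")
        return self.point_x - self.stop_x


_SWEEP_PERIOD_S = 1.6  # nominal time for one horizontal sweep; label only


def simulate_subject(
    params: SubjectParams,
    n_trials: int,
    seed: int,
    *,
    screen: ScreenGeometry | None = None,
    trials_per_block: int = 52,
    fill_skipped: bool = False,
) -> list[TrialRecord]:
    """Simulate one subject's trial list.

    Per non-skipped trial: the stopping offset ``p`` is drawn from
    ``Normal(mu_performance, sigma_performance^2)``; noisy evidence ``e ~
    Normal(p + shift_evidence, sigma_evidence^2)``; the pointing estimate
    is the posterior-mean combination ``w * 0 + (1 - w) * e`` in
    target-centred coordinates.  Estimation times are log-normal.

    With ``fill_skipped=True`` extra trials are appended until ``n_trials``
    non-skipped trials exist, mirroring a task that replaces skipped
    trials to equalise dataset sizes.

    Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    screen = screen or ScreenGeometry()
    rng = np.random.default_rng(seed)
    w = params.weight
    target = screen.target_x
    mu_log = math.log(params.est_time_median)

    records: list[TrialRecord] = []
    n_kept = 0
    i = 0
    while True:
        i += 1
        if fill_skipped:
            if n_kept >= n_trials:
                break
        elif i > n_trials:
            break
        p = rng.normal(params.mu_performance, params.sigma_performance)
        skipped = bool(rng.random() < params.skip_prob)
        n_sweeps = int(rng.integers(1, 4))
        stop_time = (n_sweeps - rng.uniform(0.0, 1.0)) * _SWEEP_PERIOD_S
        point_x: Optional[float] = None
        est_time: Optional[float] = None
        if not skipped:
            e = rng.normal(p + params.shift_evidence, params.sigma_evidence)
            point_x = target + (1.0 - w) * e
            est_time = float(
                rng.lognormal(mu_log, params.est_time_sigma_log)
            )
            n_kept += 1
        block = (i - 1) // trials_per_block + 1
        records.append(
            TrialRecord(
                subject_id=params.subject_id,
                group=params.group,
                block=block,
                trial_index=i,
                target_x=target,
                stop_x=target + p,
                point_x=point_x,
                stop_time=stop_time,
                estimation_time=est_time,
                skipped=skipped,
                n_sweeps=n_sweeps,
            )
        )
    return records


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the canonical trial table."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "block": r.block,
                "trial_index": r.trial_index,
                "target_x": r.target_x,
                "stop_x": r.stop_x,
                "point_x": r.point_x,
                "stop_time": r.stop_time,
                "estimation_time": r.estimation_time,
                "skipped": r.skipped,
                "n_sweeps": r.n_sweeps,
            }
            for r in records
        ],
        columns=TRIAL_COLUMNS,
    )


class UniformRange(BaseModel):
    """Closed uniform sampling range for a subject-level parameter."""

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "UniformRange":
        if self.high < self.low:
            raise ValueError("high must be >= low")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        if self.high == self.low:
            return self.low
        return float(rng.uniform(self.low, self.high))


class LdePriorLink(BaseModel):
    """Monotone map from a subject's daily dose to their prior width.

    The prior SD is set to ``ratio(lde) * sigma_performance`` plus Gaussian
    jitter, where ``ratio`` interpolates linearly from ``ratio_low`` at the
    group's minimum dose to ``ratio_high`` at the maximum.  With
    ``ratio_high > ratio_low`` this yields, by construction, a positive
    monotone relation between dose and normalized prior width.
    """

    ratio_low: float = Field(default=0.4, gt=0)
    ratio_high: float = Field(default=1.2, gt=0)
    jitter_sd: float = Field(default=0.0, ge=0)


class GroupSpec(BaseModel):
    """Sampling distributions for one group of subjects."""

    n_subjects: int = Field(gt=0)
    sigma_performance: UniformRange = UniformRange(low=25.0, high=45.0)
    mu_performance: UniformRange = UniformRange(low=-15.0, high=-5.0)
    sigma_prior: UniformRange = UniformRange(low=15.0, high=35.0)
    sigma_evidence: UniformRange = UniformRange(low=15.0, high=30.0)
    shift_evidence: UniformRange = UniformRange(low=-25.0, high=-15.0)
    skip_prob: float = Field(default=0.04, ge=0, lt=1)
    est_time_median: float = Field(default=1.0, gt=0)
    est_time_sigma_log: float = Field(default=0.25, ge=0)
    lde: Optional[UniformRange] = None


class CohortSpec(BaseModel):
    """Specification of a simulated cohort (the demo study design)."""

    patients: GroupSpec
    controls: GroupSpec
    blocks: int = Field(default=2, gt=0)
    trials_per_block: int = Field(default=52, gt=0)
    fill_skipped: bool = False
    lde_prior_link: Optional[LdePriorLink] = None
    screen: ScreenGeometry = ScreenGeometry()

    @property
    def n_trials(self) -> int:
        return self.blocks * self.trials_per_block


def default_demo_spec() -> CohortSpec:
    """Demo cohort: 20 patients + 20 controls, 2 x 52 trials, dose-linked
    prior widths in patients and group-specific estimation-time medians."""
    return CohortSpec(
        patients=GroupSpec(
            n_subjects=20,
            est_time_median=1.07,
            lde=UniformRange(low=200.0, high=1800.0),
        ),
        controls=GroupSpec(n_subjects=20, est_time_median=0.88),
        lde_prior_link=LdePriorLink(ratio_low=0.4, ratio_high=1.2, jitter_sd=0.0),
    )


def _sample_subject(
    spec: CohortSpec,
    group_spec: GroupSpec,
    group: Group,
    subject_id: str,
    rng: np.random.Generator,
) -> SubjectParams:
    sigma_perf = group_spec.sigma_performance.sample(rng)
    lde = group_spec.lde.sample(rng) if group_spec.lde is not None else None
    link = spec.lde_prior_link
    if link is not None and lde is not None and group_spec.lde is not None:
        lo, hi = group_spec.lde.low, group_spec.lde.high
        frac = 0.5 if hi == lo else (lde - lo) / (hi - lo)
        ratio = link.ratio_low + frac * (link.ratio_high - link.ratio_low)
        sigma_prior = ratio * sigma_perf
        if link.jitter_sd > 0:
            sigma_prior += rng.normal(0.0, link.jitter_sd)
        sigma_prior = max(sigma_prior, 1.0)
    else:
        sigma_prior = group_spec.sigma_prior.sample(rng)
    return SubjectParams(
        subject_id=subject_id,
        group=group,
        sigma_performance=sigma_perf,
        mu_performance=group_spec.mu_performance.sample(rng),
        sigma_prior=sigma_prior,
        sigma_evidence=group_spec.sigma_evidence.sample(rng),
        shift_evidence=group_spec.shift_evidence.sample(rng),
        skip_prob=group_spec.skip_prob,
        est_time_median=group_spec.est_time_median,
        est_time_sigma_log=group_spec.est_time_sigma_log,
        lde=lde,
    )


def simulate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(trial_table, truth_table)`` where the truth table retains
    the generative :class:`SubjectParams` of every subject for parameter
    recovery tests.  Reproducible given ``seed``.
    """
    if spec.patients.n_subjects < 1 or spec.controls.n_subjects < 1:
        raise ValueError("both groups must contain at least one subject")
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    truths: list[dict] = []
    for group, gspec, prefix in (
        ("patient", spec.patients, "P"),
        ("control", spec.controls, "C"),
    ):
        for j in range(gspec.n_subjects):
            sid = f"{prefix}{j + 1:02d}"
            params = _sample_subject(spec, gspec, group, sid, rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            recs = simulate_subject(
                params,
                spec.n_trials,
                sub_seed,
                screen=spec.screen,
                trials_per_block=spec.trials_per_block,
                fill_skipped=spec.fill_skipped,
            )
            frames.append(trials_to_frame(recs))
            truth = params.model_dump()
            truth["weight"] = params.weight
            truth["seed"] = sub_seed
            truths.append(truth)
    trials = pd.concat(frames, ignore_index=True)
    truth_table = pd.DataFrame(truths)
    return trials, truth_table
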