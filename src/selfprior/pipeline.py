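"""End-to-end orchestration: preprocess -> fit -> metrics -> statistics.

Every run is deterministic given (config, seed); the bundle records the
config hash, seed and library versions alongside all artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .bayes import SubjectFit, fit_subject
from .metrics import normalized_prior, prior_accuracy, subject_measures
from .preprocess import PreprocessResult, preprocess_trials
from .stats import StatResult, ancova, partial_spearman, sign_test_exact, spearman, t_test
from .synthetic import CohortSpec, ScreenGeometry, simulate_cohort


class PipelineConfig(BaseModel):
    """Analysis settings; all exclusion thresholds and model-selection
    conventions are explicit and recorded with every output."""

    screen: ScreenGeometry = ScreenGeometry()
    trial_sd_threshold: float = Field(default=2.0, gt=0)
    subject_sd_threshold: float = Field(default=3.0, gt=0)
    normalization_variant: str = "sd"
    strong_threshold: float = Field(default=6.0, gt=0)
    include_boundary_fits: bool = False
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


@dataclass
class PipelineBundle:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    trials: pd.DataFrame
    preprocess: PreprocessResult
    fits: list[SubjectFit]
    measures: pd.DataFrame
    stats: dict[str, StatResult]
    truth: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def stats_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "results": {k: v.to_dict() for k, v in sorted(self.stats.items())},
        }

    def fits_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "subjects": [f.to_dict() for f in self.fits],
        }


def fit_all_subjects(
    clean: pd.DataFrame,
) -> list[SubjectFit]:
    """Fit both observer models to every subject in a cleaned trial table."""
    fits = []
    for sid, sub in clean.groupby("subject_id", sort=False):
        perf = sub["performance_error"].to_numpy(dtype=float)
        est = sub["estimation_error"].to_numpy(dtype=float)
        fits.append(fit_subject(perf, est, subject_id=str(sid)))
    return fits


def build_measures(
    clean: pd.DataFrame,
    fits: list[SubjectFit],
    config: PipelineConfig,
    lde_by_subject: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Per-subject table merging regression metrics with the winning-model
    parameters; boundary-flagged subjects get no normalized prior unless
    configured otherwise."""
    sigma_prior_map: dict[str, float] = {}
    fit_rows = []
    for f in fits:
        win = f.winning
        usable = config.include_boundary_fits or not win.boundary
        if usable:
            sigma_prior_map[f.subject_id] = win.params.sigma_prior
        fit_rows.append(
            {
                "subject_id": f.subject_id,
                "model_winner": f.choice.winner,
                "delta_bic": f.choice.delta_bic,
                "strong": f.choice.strong,
                "sigma_prior_hat": win.params.sigma_prior,
                "sigma_evidence_hat": win.params.sigma_evidence,
                "shift_hat": f.fit2.params.shift_evidence,
                "boundary": win.boundary,
            }
        )
    measures = subject_measures(
        clean,
        sigma_prior_by_subject=sigma_prior_map,
        lde_by_subject=lde_by_subject,
        variant=config.normalization_variant,  # type: ignore[arg-type]
    )
    return measures.merge(pd.DataFrame(fit_rows), on="subject_id", how="left")


def run_analysis(
    measures: pd.DataFrame,
    covariates: tuple[str, ...] = ("lde",),
    strong_threshold: float = 6.0,
) -> dict[str, StatResult]:
    """The inferential battery over a subject-measures table.

    Group comparisons of slopes, estimation times and normalized priors
    (ANCOVA with estimation time as nuisance covariate), the model-2 sign
    test, and dose correlations (plain and partial Spearman) within the
    patient group.
    """
    out: dict[str, StatResult] = {}
    pats = measures[measures["group"] == "patient"]
    ctls = measures[measures["group"] == "control"]

    for label, grp in (("patient", pats), ("control", ctls)):
        if len(grp) >= 2:
            out[f"slope_vs_zero_{label}"] = t_test(
                grp["slope"], null_value=0.0, name=f"slope_vs_zero_{label}"
            )
    if len(pats) >= 2 and len(ctls) >= 2:
        out["slope_group"] = t_test(pats["slope"], ctls["slope"], name="slope_group")
        out["est_time_group"] = t_test(
            pats["mean_est_time"], ctls["mean_est_time"], name="est_time_group"
        )
        out["perf_sd_group"] = t_test(
            pats["perf_sd"], ctls["perf_sd"], name="perf_sd_group"
        )
        if "sigma_evidence_hat" in measures:
            out["evidence_sd_group"] = t_test(
                pats["sigma_evidence_hat"],
                ctls["sigma_evidence_hat"],
                name="evidence_sd_group",
            )
        if "shift_hat" in measures:
            out["shift_vs_zero"] = t_test(
                measures["shift_hat"], null_value=0.0, name="shift_vs_zero"
            )

    if "model_winner" in measures:
        k = int((measures["model_winner"] == 2).sum())
        out["model2_sign_test"] = sign_test_exact(
            k, len(measures), name="model2_sign_test"
        )

    np_col = measures["normalized_prior"]
    valid = measures[np_col.notna()]
    vp = valid[valid["group"] == "patient"]
    vc = valid[valid["group"] == "control"]
    for label, grp in (("patient", vp), ("control", vc)):
        if len(grp) >= 2:
            out[f"normalized_prior_vs_half_{label}"] = t_test(
                grp["normalized_prior"],
                null_value=0.5,
                name=f"normalized_prior_vs_half_{label}",
            )
    if len(vp) >= 3 and len(vc) >= 3:
        for res in ancova(
            valid["normalized_prior"], valid["group"], valid["mean_est_time"]
        ):
            out[f"normalized_prior_{res.test_name}"] = res

    lde_pats = vp[vp["lde"].notna()] if "lde" in vp else vp.iloc[0:0]
    if len(lde_pats) >= 4:
        out["np_lde_spearman"] = spearman(
            lde_pats["normalized_prior"], lde_pats["lde"], name="np_lde_spearman"
        )
        out["prior_sd_lde_spearman"] = spearman(
            lde_pats["sigma_prior_hat"], lde_pats["lde"],
            name="prior_sd_lde_spearman",
        )
        out["accuracy_lde_spearman"] = spearman(
            lde_pats["prior_accuracy"], lde_pats["lde"],
            name="accuracy_lde_spearman",
        )
        for cov in covariates:
            if cov in ("lde",) or cov not in lde_pats.columns:
                continue
            sub = lde_pats[lde_pats[cov].notna()]
            if len(sub) > 4:
                out[f"np_lde_partial_{cov}"] = partial_spearman(
                    sub["normalized_prior"],
                    sub["lde"],
                    sub[cov].to_numpy(),
                    name=f"np_lde_partial_{cov}",
                )
    return out


def run_pipeline(
    config: PipelineConfig,
    trials: Optional[pd.DataFrame] = None,
    cohort_spec: Optional[CohortSpec] = None,
    covariates: tuple[str, ...] = ("lde", "mean_est_time"),
) -> PipelineBundle:
    """Run preprocess -> fit -> metrics -> stats on measured or simulated
    trials.  Exactly one of ``trials``/``cohort_spec`` must be given."""
    if (trials is None) == (cohort_spec is None):
        raise ValueError("provide exactly one of trials or cohort_spec")
    truth = None
    if cohort_spec is not None:
        trials, truth = simulate_cohort(cohort_spec, config.seed)
    assert trials is not None
    if len(trials) == 0:
        raise ValueError("preprocess: empty trial table")
    pre = preprocess_trials(
        trials,
        trial_sd_threshold=config.trial_sd_threshold,
        subject_sd_threshold=config.subject_sd_threshold,
    )
    fits = fit_all_subjects(pre.trials)
    lde_map = None
    if truth is not None and "lde" in truth.columns:
        lde_map = {
            str(r["subject_id"]): float(r["lde"])
            for _, r in truth.iterrows()
            if pd.notna(r["lde"])
        }
    measures = build_measures(pre.trials, fits, config, lde_by_subject=lde_map)
    stats = run_analysis(
        measures, covariates=covariates, strong_threshold=config.strong_threshold
    )
    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "selfprior_version": __version__,
        "n_subjects_in": int(trials["subject_id"].nunique()),
        "n_subjects_retained": int(measures.shape[0]),
        "excluded_subjects": pre.excluded_subjects,
    }
    return PipelineBundle(
        config=config,
        trials=trials,
        preprocess=pre,
        fits=fits,
        measures=measures,
        stats=stats,
        truth=truth,
        provenance=provenance,
    )


def report(bundle: PipelineBundle) -> str:
    """Human-readable markdown summary of a pipeline bundle."""
    lines = [
        "# Self-prior analysis report",
        "",
        f"- config hash: `{bundle.provenance.get('config_hash', '')}`",
        f"- seed: {bundle.provenance.get('seed', '')}",
        f"- subjects in / retained: "
        f"{bundle.provenance.get('n_subjects_in', '?')} / "
        f"{bundle.provenance.get('n_subjects_retained', '?')}",
        "",
        "## Per-subject measures",
        "",
    ]
    cols = [
        "subject_id", "group", "n_trials", "slope", "sigma_prior_hat",
        "sigma_evidence_hat", "shift_hat", "model_winner",
        "normalized_prior", "prior_accuracy",
    ]
    present = [c for c in cols if c in bundle.measures.columns]
    header = " | ".join(present)
    lines.append(f"| {header} |")
    lines.append("|" + "---|" * len(present))
    for _, row in bundle.measures.iterrows():
        cells = []
        for c in present:
            v = row[c]
            cells.append(f"{v:.4g}" if isinstance(v, (int, float, np.floating)) and pd.notna(v) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    excluded = bundle.preprocess.excluded_subjects
    lines += ["", "## Exclusions", ""]
    if excluded:
        for sid in excluded:
            lines.append(f"- subject {sid}: mean estimation time outlier")
    else:
        lines.append("- no subjects excluded")
    for rep in bundle.preprocess.reports:
        lines.append(
            f"- {rep.subject_id}: {rep.n_skipped} skipped, "
            f"{rep.n_slow_excluded} slow trials removed"
        )
    lines += ["", "## Group statistics", ""]
    for name, res in sorted(bundle.stats.items()):
        df = res.df
        df_s = (
            f"df={df[0]:g},{df[1]:g}" if isinstance(df, tuple)
            else (f"df={df:g}" if df is not None else "exact")
        )
        es = (
            f", {res.effect_size_name}={res.effect_size:.3f}"
            if res.effect_size is not None
            else ""
        )
        lines.append(
            f"- {name}: statistic={res.statistic:.4g} ({df_s}), "
            f"p={res.p_value:.4g}{es}"
        )
    return "\n".join(lines) + "\n"
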