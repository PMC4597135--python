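"""Gaussian observer model: likelihood, closed-form and numerical MLE,
and BIC model comparison.

Model.  In target-centred coordinates the prior over the stopping
position is Normal(0, sigma_prior^2) and the sensory evidence on a trial
with true stopping offset ``p`` is Normal(p + shift, sigma_evidence^2).
The reported estimate is the reliability-weighted posterior mean

    x_estimate = w * 0 + (1 - w) * (p + shift + noise),
    w = sigma_evidence^2 / (sigma_prior^2 + sigma_evidence^2),

so the estimation error e = x_estimate - p is Gaussian with

    mean = -w * p + (1 - w) * shift,     sd = (1 - w) * sigma_evidence.

Model 1 fixes shift = 0 (2 free parameters); model 2 frees it (3).
Because the conditional mean is linear in p, the MLE has a closed form
via ordinary least squares; the numerical optimiser exists to honour the
generic fitting contract and is verified against the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

_LOG_2PI = math.log(2.0 * math.pi)

#: Bounds on the fitted SDs, in pixels.
SIGMA_MIN = 1e-3
SIGMA_MAX = 1e4
#: Clipping range for the weight when the regression slope leaves (-1, 0).
W_EPS = 1e-3


@dataclass(frozen=True)
class BayesParams:
    """Observer-model parameters; model 1 keeps ``shift_evidence`` at 0."""

    sigma_prior: float
    sigma_evidence: float
    shift_evidence: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0 or self.sigma_evidence <= 0:
            raise ValueError("SDs must be strictly positive")

    @property
    def weight(self) -> float:
        ve = self.sigma_evidence**2
        return ve / (self.sigma_prior**2 + ve)


@dataclass
class FitResult:
    model_id: int
    params: BayesParams
    loglik: float
    bic: float
    n_trials: int
    k_params: int
    boundary: bool = False
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "sigma_prior": self.params.sigma_prior,
            "sigma_evidence": self.params.sigma_evidence,
            "shift_evidence": self.params.shift_evidence,
            "weight": self.params.weight,
            "loglik": self.loglik,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "boundary": self.boundary,
            "converged": self.converged,
        }


@dataclass
class ModelChoice:
    winner: int
    delta_bic: float  # bic(model 1) - bic(model 2); positive favours model 2
    strong: bool


def predictive_law(p, params: BayesParams) -> tuple[np.ndarray, float]:
    """Mean and SD of the estimation error given performance error(s) ``p``."""
    w = params.weight
    mean = -w * np.asarray(p, dtype=float) + (1.0 - w) * params.shift_evidence
    sd = (1.0 - w) * params.sigma_evidence
    return mean, sd


def loglik(
    params: BayesParams,
    perf_errors: np.ndarray,
    est_errors: np.ndarray,
    model_id: int = 2,
) -> float:
    """Gaussian log-likelihood (nats) of the estimation errors.

    Model 1 requires ``params.shift_evidence == 0``.
    """
    if model_id == 1 and params.shift_evidence != 0.0:
        raise ValueError("model 1 fixes shift_evidence at 0")
    p = np.asarray(perf_errors, dtype=float)
    e = np.asarray(est_errors, dtype=float)
    if p.shape != e.shape or p.size == 0:
        raise ValueError("need equal-length, non-empty error vectors")
    mean, sd = predictive_law(p, params)
    if sd < 1e-12:
        raise ValueError(
            "predictive SD underflow; enforce sigma bounds before evaluating"
        )
    z = (e - mean) / sd
    return float(-0.5 * np.sum(z**2) - p.size * (math.log(sd) + 0.5 * _LOG_2PI))


def bic(loglik_value: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, natural-log convention."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * math.log(n) - 2.0 * loglik_value


def _params_from_regression(w: float, c: float, sd_ml: float) -> BayesParams:
    """Invert (w, (1-w)*shift, (1-w)*sigma_e) -> (sigma_p, sigma_e, shift)."""
    sigma_e = max(sd_ml / (1.0 - w), SIGMA_MIN)
    sigma_p = max(sigma_e * math.sqrt((1.0 - w) / w), SIGMA_MIN)
    return BayesParams(
        sigma_prior=min(sigma_p, SIGMA_MAX),
        sigma_evidence=min(sigma_e, SIGMA_MAX),
        shift_evidence=c / (1.0 - w),
    )


def closed_form_fit(
    perf_errors: np.ndarray, est_errors: np.ndarray, model_id: int
) -> FitResult:
    """Analytic MLE via the regression parameterisation.

    The conditional mean -w*p + (1-w)*shift is linear in p, so the MLE of
    (w, (1-w)*shift) is OLS (with intercept for model 2, through the
    origin for model 1) and the ML noise scale is the RSS/n residual SD.
    Slopes outside (-1, 0) have no interior preimage: the weight is
    clipped into [W_EPS, 1 - W_EPS] and the fit flagged ``boundary``.
    """
    p = np.asarray(perf_errors, dtype=float)
    e = np.asarray(est_errors, dtype=float)
    n = p.size
    if n < 4:
        raise ValueError("need at least 4 trials to fit")
    if np.ptp(p) == 0:
        raise ValueError("performance errors are all identical; cannot fit")
    if model_id == 2:
        b, a = np.polyfit(p, e, 1)
    elif model_id == 1:
        b = float(np.dot(p, e) / np.dot(p, p))
        a = 0.0
    else:
        raise ValueError("model_id must be 1 or 2")
    boundary = not (-1.0 < b < 0.0)
    w = float(np.clip(-b, W_EPS, 1.0 - W_EPS))
    # conditional MLE of the intercept and noise scale at the (clipped) w
    c = float(np.mean(e + w * p)) if model_id == 2 else 0.0
    resid = e + w * p - c
    sd_ml = float(np.sqrt(np.mean(resid**2)))
    params = _params_from_regression(w, c, sd_ml)
    ll = loglik(params, p, e, model_id)
    k = 2 if model_id == 1 else 3
    return FitResult(
        model_id=model_id,
        params=params,
        loglik=ll,
        bic=bic(ll, k, n),
        n_trials=n,
        k_params=k,
        boundary=boundary,
    )


@dataclass
class FitOptions:
    """Deterministic optimiser settings for :func:`fit_mle`."""

    sigma_min: float = SIGMA_MIN
    sigma_max: float = SIGMA_MAX
    shift_bound: float = 1e4
    gtol: float = 1e-10
    maxiter: int = 500


def fit_mle(
    perf_errors: np.ndarray,
    est_errors: np.ndarray,
    model_id: int,
    opts: Optional[FitOptions] = None,
) -> FitResult:
    """Numerical MLE over (log sigma_prior, log sigma_evidence[, shift]).

    Initialised from :func:`closed_form_fit` and bounded L-BFGS-B; fully
    deterministic.  The returned log-likelihood is never allowed below
    the closed-form value (the better of the two fits is returned).
    """
    opts = opts or FitOptions()
    p = np.asarray(perf_errors, dtype=float)
    e = np.asarray(est_errors, dtype=float)
    start = closed_form_fit(p, e, model_id)

    def unpack(x: np.ndarray) -> BayesParams:
        shift = x[2] if model_id == 2 else 0.0
        return BayesParams(
            sigma_prior=math.exp(x[0]),
            sigma_evidence=math.exp(x[1]),
            shift_evidence=float(shift),
        )

    def objective(x: np.ndarray) -> float:
        try:
            return -loglik(unpack(x), p, e, model_id)
        except ValueError:
            return 1e300

    x0 = [
        math.log(start.params.sigma_prior),
        math.log(start.params.sigma_evidence),
    ]
    bounds = [(math.log(opts.sigma_min), math.log(opts.sigma_max))] * 2
    if model_id == 2:
        x0.append(start.params.shift_evidence)
        bounds.append((-opts.shift_bound, opts.shift_bound))
    res = optimize.minimize(
        objective,
        np.asarray(x0),
        method="L-BFGS-B",
        bounds=bounds,
        options={"gtol": opts.gtol, "maxiter": opts.maxiter},
    )
    params = unpack(res.x)
    ll = loglik(params, p, e, model_id)
    if ll < start.loglik:  # optimiser must never degrade the analytic fit
        params, ll = start.params, start.loglik
    k = 2 if model_id == 1 else 3
    return FitResult(
        model_id=model_id,
        params=params,
        loglik=ll,
        bic=bic(ll, k, p.size),
        n_trials=p.size,
        k_params=k,
        boundary=start.boundary,
        converged=bool(res.success) or ll >= start.loglik - 1e-9,
        message=str(res.message),
    )


def select_model(
    fit1: FitResult, fit2: FitResult, strong_threshold: float = 6.0
) -> ModelChoice:
    """Lower-BIC winner; ties favour the 2-parameter model.

    ``strong`` marks |delta BIC| above the threshold (default 6).
    """
    if fit1.n_trials != fit2.n_trials:
        raise ValueError("fits must come from the same dataset")
    delta = fit1.bic - fit2.bic
    winner = 2 if fit2.bic < fit1.bic else 1
    return ModelChoice(
        winner=winner, delta_bic=delta, strong=abs(delta) > strong_threshold
    )


@dataclass
class SubjectFit:
    """Both model fits plus the BIC choice for one subject."""

    subject_id: str
    fit1: FitResult
    fit2: FitResult
    choice: ModelChoice = field(init=False)

    def __post_init__(self) -> None:
        self.choice = select_model(self.fit1, self.fit2)

    @property
    def winning(self) -> FitResult:
        return self.fit2 if self.choice.winner == 2 else self.fit1

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "model1": self.fit1.to_dict(),
            "model2": self.fit2.to_dict(),
            "winner": self.choice.winner,
            "delta_bic": self.choice.delta_bic,
            "strong": self.choice.strong,
        }


def fit_subject(
    perf_errors: np.ndarray,
    est_errors: np.ndarray,
    subject_id: str = "",
    opts: Optional[FitOptions] = None,
) -> SubjectFit:
    """Fit both models to one subject and compare them by BIC."""
    return SubjectFit(
        subject_id=subject_id,
        fit1=fit_mle(perf_errors, est_errors, 1, opts),
        fit2=fit_mle(perf_errors, est_errors, 2, opts),
    )
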