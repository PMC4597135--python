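"""Group-level inference: t-tests, exact sign test, Spearman and partial
Spearman correlations, two-group ANCOVA with Type-III sums of squares,
Bonferroni correction and demographic-table summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One statistical test: statistic, degrees of freedom, p, effect size."""

    test_name: str
    statistic: float
    df: Union[float, tuple[float, float], None]
    p_value: float
    effect_size: Optional[float] = None
    effect_size_name: str = ""
    n: int = 0
    correction: str = "none"
    tails: str = "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = vars(self).copy()
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


def _cohens_d_two(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    return float((np.mean(a) - np.mean(b)) / sp) if sp > 0 else float("nan")


def t_test(
    sample_a: Sequence[float],
    sample_b: Optional[Sequence[float]] = None,
    null_value: float = 0.0,
    paired: bool = False,
    name: str = "t_test",
) -> StatResult:
    """One-sample (vs ``null_value``), paired, or two-sample pooled-variance
    t-test; two-tailed, with Cohen's d."""
    a = np.asarray(sample_a, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    if sample_b is None:
        if np.var(a, ddof=1) == 0 and np.mean(a) == null_value:
            raise ValueError("zero variance with mean equal to null value")
        res = sps.ttest_1samp(a, null_value)
        d = float((np.mean(a) - null_value) / np.std(a, ddof=1))
        return StatResult(
            name, float(res.statistic), float(len(a) - 1), float(res.pvalue),
            effect_size=d, effect_size_name="cohens_d", n=len(a),
        )
    b = np.asarray(sample_b, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diff = a - b
        return t_test(diff, null_value=0.0, name=name)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("zero variance with equal means")
    res = sps.ttest_ind(a, b, equal_var=True)
    return StatResult(
        name,
        float(res.statistic),
        float(len(a) + len(b) - 2),
        float(res.pvalue),
        effect_size=_cohens_d_two(a, b),
        effect_size_name="cohens_d",
        n=len(a) + len(b),
    )


def sign_test_exact(k_successes: int, n: int, name: str = "sign_test") -> StatResult:
    """Exact two-sided binomial sign test at p0 = 0.5.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) by exact tail enumeration.
    """
    if not (0 <= k_successes <= n) or n < 1:
        raise ValueError("require 0 <= k <= n and n >= 1")
    dist = sps.binom(n, 0.5)
    lower = float(dist.cdf(k_successes))
    upper = float(dist.sf(k_successes - 1))
    p = min(1.0, 2.0 * min(lower, upper))
    return StatResult(name, float(k_successes), None, p, n=n)


def spearman(
    x: Sequence[float], y: Sequence[float], name: str = "spearman"
) -> StatResult:
    """Spearman rank correlation (Pearson on mid-ranks); p from the
    t-distribution approximation with n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rho, p = sps.spearmanr(x, y)
    return StatResult(
        name, float(rho), float(len(x) - 2), float(p),
        effect_size=float(rho), effect_size_name="rho", n=len(x),
    )


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray,
    name: str = "partial_spearman",
) -> StatResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (mid-ranks); the ranks of x and y
    are residualised on the covariate ranks (with intercept) by least
    squares and the Pearson correlation of the residuals is returned.  p
    comes from the t approximation with n - 2 - n_covariates df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, m = cov.shape
    if len(x) != n or len(y) != n:
        raise ValueError("inputs must share the same length")
    if n <= m + 3:
        raise ValueError("need n > n_covariates + 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack(
        [np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(m)]
    )
    if np.linalg.matrix_rank(rc) < rc.shape[1]:
        raise ValueError("collinear covariates")
    resid_x = rx - rc @ np.linalg.lstsq(rc, rx, rcond=None)[0]
    resid_y = ry - rc @ np.linalg.lstsq(rc, ry, rcond=None)[0]
    rho = float(np.corrcoef(resid_x, resid_y)[0, 1])
    df = n - 2 - m
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        name, rho, float(df), p, effect_size=rho, effect_size_name="rho", n=n
    )


def _ancova_design(
    groups: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Effects-coded (sum-to-zero) design: intercept, group, covariate,
    group x covariate."""
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("ancova requires exactly two groups")
    g = np.where(groups == levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(g)), g, covariate, g * covariate])
    return X, ["intercept", "group", "covariate", "group:covariate"]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def ancova(
    values: Sequence[float],
    group_labels: Sequence[str],
    covariate: Sequence[float],
    eta_variant: str = "partial",
) -> list[StatResult]:
    """Two-group ANCOVA: value ~ group + covariate + group x covariate.

    Effects (sum-to-zero) coding with Type-III sums of squares: each
    effect's SS is the RSS increase from dropping its column(s) from the
    full model.  Returns one :class:`StatResult` per effect (group,
    covariate, interaction) with partial eta^2 (or classical eta^2 =
    SS_effect/SS_total when ``eta_variant='classical'``).
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    cov = np.asarray(covariate, dtype=float)
    if not (len(y) == len(groups) == len(cov)):
        raise ValueError("inputs must share the same length")
    counts = pd.Series(groups).value_counts()
    if len(counts) != 2 or counts.min() < 3:
        raise ValueError("need two groups with n >= 3 each")
    X, names = _ancova_design(groups, cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant covariate?)")
    n, k = X.shape
    df_err = n - k
    rss_full = _rss(X, y)
    ms_err = rss_full / df_err
    ss_total = float(np.sum((y - y.mean()) ** 2))
    results = []
    for j, effect in enumerate(names):
        if effect == "intercept":
            continue
        X_red = np.delete(X, j, axis=1)
        ss = _rss(X_red, y) - rss_full
        ss = max(ss, 0.0)
        if ms_err > 0:
            F = (ss / 1.0) / ms_err
        else:
            F = 0.0 if ss == 0 else float("inf")
        p = float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0
        if eta_variant == "partial":
            denom = ss + rss_full
            eta = ss / denom if denom > 0 else 0.0
        else:
            eta = ss / ss_total if ss_total > 0 else 0.0
        results.append(
            StatResult(
                f"ancova_{effect}", float(F), (1.0, float(df_err)), p,
                effect_size=float(eta), effect_size_name=f"eta2_{eta_variant}",
                n=n,
            )
        )
    return results


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni-corrected p-values: min(1, m * p).  ``m`` defaults to the
    family size and may not be smaller than it."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of tests")
    return [min(1.0, m * float(pi)) for pi in p]


#: Canonical numeric columns of the demographics fixture.
TABLE1_COLUMNS = ["age", "duration_years", "stage", "updrs_iii", "mmse", "acer", "lde"]


def table1_summary(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-column mean (rounded to integer), SD, min and max of a
    demographics table.  SD is absent for single-row tables."""
    columns = list(columns) if columns is not None else TABLE1_COLUMNS
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"missing required column: {col!r}")
    rows = {}
    for col in columns:
        vals = table[col].astype(float)
        rows[col] = {
            "mean": float(vals.mean()),
            "mean_rounded": int(round(float(vals.mean()))),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(len(vals)),
        }
    return pd.DataFrame(rows).T


def load_table1() -> pd.DataFrame:
    """The packaged patient demographics fixture."""
    from importlib.resources import files

    path = files("selfprior.data").joinpath("table1.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)
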