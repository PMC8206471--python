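"""Scale scoring, EM imputation, moderator transformation and reliability.

Raw questionnaire items become scale scores here: weighted sums for the
four job-characteristic scales (ranges 24-96, 12-48, 4-16, 4-16) and
subscale means for the three burnout outcomes (range 1-7).  The module
also owns the log transform of the cortisol moderator, the normality
audit (skewness/kurtosis with closed-form standard errors plus a
Lilliefors-style Kolmogorov-Smirnov test), multivariate-normal EM
imputation, and Cronbach's alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    CohortTable,
    JCQ_ITEM_COLUMNS,
    MBI_ITEM_COLUMNS,
    MODERATOR_COLUMNS,
    OUTCOME_COLUMNS,
    OutOfRangeError,
    SCALE_COLUMNS,
)

# Item layout within the 22 JCQ responses.
SKILL_DISCRETION = slice(0, 6)
DECISION_AUTHORITY = slice(6, 9)
PSYCH_DEMANDS = slice(9, 14)
SUPERVISOR_SUPPORT = slice(14, 18)
COWORKER_SUPPORT = slice(18, 22)

# Subscale layout within the 16 MBI responses.
MBI_EE = slice(0, 5)
MBI_DP = slice(5, 10)
MBI_PE = slice(10, 16)

JOB_CONTROL_RANGE = (24.0, 96.0)
PSYCH_DEMANDS_RANGE = (12.0, 48.0)


@dataclass(frozen=True)
class ScoringWeights:
    """Item weights for the weighted-sum job-characteristic scales.

    Defaults double the six skill-discretion items and quadruple the
    three decision-authority items (job control range 24-96 on 4-point
    items) and triple the first two / double the remaining three demand
    items (range 12-48).  Alternative weightings can be declared without
    code change.
    """

    skill_discretion: float = 2.0
    decision_authority: float = 4.0
    demands_first_two: float = 3.0
    demands_rest: float = 2.0


DEFAULT_WEIGHTS = ScoringWeights()


class ZeroVarianceError(ValueError):
    """A variable is constant where variation is required."""


class MissingnessCapError(ValueError):
    """Per-variable missing fraction exceeds the configured cap."""


class MissingModeratorError(ValueError):
    """The moderating variable has missing values (never imputable)."""


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _check_items(items: Sequence[float], k: int, lo: int, hi: int, label: str):
    arr = np.asarray(items, dtype=float)
    if arr.shape != (k,):
        raise OutOfRangeError(f"{label}: expected {k} items, got {arr.shape}")
    if np.isnan(arr).any():
        raise OutOfRangeError(f"{label}: missing responses not allowed here")
    if ((arr < lo) | (arr > hi)).any():
        raise OutOfRangeError(f"{label}: responses must lie in {lo}..{hi}")
    return arr


def score_jcq(
    items: Sequence[float], weights: ScoringWeights = DEFAULT_WEIGHTS
) -> dict[str, float]:
    """Score 22 JCQ responses (1..4) into the four scale scores."""
    arr = _check_items(items, 22, 1, 4, "JCQ")
    w = weights
    job_control = w.skill_discretion * arr[SKILL_DISCRETION].sum() + (
        w.decision_authority * arr[DECISION_AUTHORITY].sum()
    )
    demands = arr[PSYCH_DEMANDS]
    psych_demands = (
        w.demands_first_two * demands[:2].sum() + w.demands_rest * demands[2:].sum()
    )
    return {
        "job_control": float(job_control),
        "psych_demands": float(psych_demands),
        "supervisor_support": float(arr[SUPERVISOR_SUPPORT].sum()),
        "coworker_support": float(arr[COWORKER_SUPPORT].sum()),
    }


def score_mbi(items: Sequence[float]) -> dict[str, float]:
    """Score 16 MBI responses (1..7) into subscale means (ee, dp, pe)."""
    arr = _check_items(items, 16, 1, 7, "MBI")
    return {
        "ee": float(arr[MBI_EE].mean()),
        "dp": float(arr[MBI_DP].mean()),
        "pe": float(arr[MBI_PE].mean()),
    }


def job_control_standard(score):
    """Map the 24-96 weighted sum onto the unit interval."""
    return (np.asarray(score, dtype=float) - 24.0) / 72.0


def job_control_from_standard(std):
    return np.asarray(std, dtype=float) * 72.0 + 24.0


def psych_demands_standard(score):
    """Map the 12-48 weighted sum onto the unit interval."""
    return (np.asarray(score, dtype=float) - 12.0) / 36.0


def psych_demands_from_standard(std):
    return np.asarray(std, dtype=float) * 36.0 + 12.0


def score_table(
    table: CohortTable, weights: ScoringWeights = DEFAULT_WEIGHTS
) -> CohortTable:
    """Fill scale-score columns from item columns where items exist."""
    df = table.data.copy()
    if all(c in df.columns for c in JCQ_ITEM_COLUMNS):
        items = df[list(JCQ_ITEM_COLUMNS)].to_numpy(dtype=float)
        scored = [score_jcq(row, weights) for row in items]
        for key in SCALE_COLUMNS:
            df[key] = [s[key] for s in scored]
    if all(c in df.columns for c in MBI_ITEM_COLUMNS):
        items = df[list(MBI_ITEM_COLUMNS)].to_numpy(dtype=float)
        scored = [score_mbi(row) for row in items]
        for key in OUTCOME_COLUMNS:
            df[key] = [s[key] for s in scored]
    return CohortTable(df, table.provenance)


@dataclass
class ReliabilityReport:
    scale: str
    cronbach_alpha: float
    k_items: int


def cronbach_alpha(item_matrix, scale: str = "") -> ReliabilityReport:
    """Cronbach's alpha with n-1 sample variances."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("cronbach_alpha needs a subjects x items matrix, k >= 2")
    if np.isnan(X).any():
        raise ValueError("cronbach_alpha requires complete data")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ZeroVarianceError("total score has zero variance")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityReport(scale=scale, cronbach_alpha=float(alpha), k_items=k)


def transform_hcc(hcc_raw):
    """Base-10 log of the raw cortisol concentration (pg/mg)."""
    arr = np.asarray(hcc_raw, dtype=float)
    if (arr <= 0).any() or np.isnan(arr).any():
        raise OutOfRangeError("hcc_raw must be strictly positive")
    out = np.log10(arr)
    return float(out) if np.isscalar(hcc_raw) or arr.ndim == 0 else out


def skewness_se(n: int) -> float:
    """Closed-form standard error of sample skewness."""
    if n < 8:
        raise ValueError("n must be >= 8")
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def kurtosis_se(n: int) -> float:
    """Closed-form standard error of sample (excess) kurtosis."""
    if n < 8:
        raise ValueError("n must be >= 8")
    return 2.0 * skewness_se(n) * math.sqrt(
        (n * n - 1.0) / ((n - 3.0) * (n + 5.0))
    )


def lilliefors_statistic(values) -> float:
    """KS distance to a normal with mean/SD estimated from the sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("constant vector")
    F = stats.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    return float(max((i / n - F).max(), (F - (i - 1) / n).max()))


def _lilliefors_mc_p(d: float, n: int, n_mc: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    # Null distribution of D with estimated parameters: simulate standard
    # normal samples, re-fit, recompute D.  Block the simulation to bound
    # memory at ~8 MB.
    count = 0
    block = max(1, min(n_mc, 4_000_000 // max(n, 1)))
    done = 0
    i = np.arange(1, n + 1)
    while done < n_mc:
        b = min(block, n_mc - done)
        Z = rng.standard_normal((b, n))
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
        Z.sort(axis=1)
        F = stats.norm.cdf(Z)
        dplus = (i / n - F).max(axis=1)
        dminus = (F - (i - 1) / n).max(axis=1)
        dsim = np.maximum(dplus, dminus)
        count += int((dsim >= d).sum())
        done += b
    return (count + 1) / (n_mc + 1)


@dataclass
class NormalityReport:
    n: int
    skewness: float
    se_skewness: float
    kurtosis: float
    se_kurtosis: float
    ks_statistic: float
    ks_p: float
    ks_p_capped: float = field(init=False)

    def __post_init__(self) -> None:
        # Conventional display caps the estimated-parameter KS p at 0.200.
        self.ks_p_capped = min(self.ks_p, 0.200)


def normality_report(
    values, *, n_mc: int = 10_000, seed: int = 0
) -> NormalityReport:
    """Skewness/kurtosis with SEs and a seeded Monte-Carlo Lilliefors test.

    Skewness and kurtosis use the small-sample adjusted (Fisher-Pearson)
    estimators; kurtosis is excess (normal = 0).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 8:
        raise ValueError(f"normality_report needs n >= 8, got {n}")
    if x.std(ddof=1) == 0:
        raise ZeroVarianceError("constant vector")
    d = lilliefors_statistic(x)
    return NormalityReport(
        n=n,
        skewness=float(stats.skew(x, bias=False)),
        se_skewness=skewness_se(n),
        kurtosis=float(stats.kurtosis(x, bias=False)),
        se_kurtosis=kurtosis_se(n),
        ks_statistic=d,
        ks_p=_lilliefors_mc_p(d, n, n_mc, seed),
    )


def _em_mvnormal(
    X: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, list[float]]:
    """EM for a multivariate normal with missing entries.

    Returns the conditional-mean-imputed matrix, the ML mean and
    covariance, the iteration count and the convergence trace.
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    filled = np.where(miss, mu, X)
    S = np.cov(filled, rowvar=False, bias=True)
    S = np.atleast_2d(S) + 1e-10 * np.eye(p)

    patterns: dict[tuple[bool, ...], np.ndarray] = {}
    for key in map(tuple, np.unique(miss, axis=0)):
        patterns[key] = np.where((miss == np.array(key)).all(axis=1))[0]

    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, idx in patterns.items():
            m = np.array(key)
            rows = X[idx]
            if not m.any():
                sum_x += rows.sum(axis=0)
                sum_xx += rows.T @ rows
                continue
            o = ~m
            Soo = S[np.ix_(o, o)]
            Smo = S[np.ix_(m, o)]
            K = Smo @ np.linalg.inv(Soo)
            cond_mean = mu[m] + (rows[:, o] - mu[o]) @ K.T
            C = S[np.ix_(m, m)] - K @ Smo.T
            Xhat = rows.copy()
            Xhat[:, m] = cond_mean
            sum_x += Xhat.sum(axis=0)
            sum_xx += Xhat.T @ Xhat
            block = np.zeros((p, p))
            block[np.ix_(m, m)] = len(idx) * C
            sum_xx += block
        mu_new = sum_x / n
        S_new = sum_xx / n - np.outer(mu_new, mu_new)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(S_new - S).max()
        )
        trace.append(float(delta))
        mu, S = mu_new, S_new
        if delta < tol:
            break
    else:
        raise EMConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last delta {trace[-1]:.3g})",
            trace,
        )
    # Final conditional-mean imputation under the converged parameters.
    X_imp = X.copy()
    for key, idx in patterns.items():
        m = np.array(key)
        if not m.any():
            continue
        o = ~m
        K = S[np.ix_(m, o)] @ np.linalg.inv(S[np.ix_(o, o)])
        X_imp[np.ix_(idx, np.where(m)[0])] = mu[m] + (
            (X[idx][:, o] - mu[o]) @ K.T
        )
    return X_imp, mu, S, it, trace


def em_impute(
    table: CohortTable,
    variables: Sequence[str] | None = None,
    *,
    max_missing: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CohortTable:
    """Impute missing scale/outcome values by multivariate-normal EM.

    The moderator is never imputed and must be complete; observed cells
    are left untouched.  Deterministic given the input.
    """
    df = table.data.copy()
    if variables is None:
        variables = [
            c for c in SCALE_COLUMNS + OUTCOME_COLUMNS if c in df.columns
        ]
    variables = list(variables)
    for mod in MODERATOR_COLUMNS:
        if mod in variables:
            raise MissingModeratorError(
                f"the moderator ({mod}) is never imputed"
            )
        if mod in df.columns and df[mod].isna().any():
            raise MissingModeratorError(
                f"moderator column {mod} has missing values"
            )
    X = df[variables].to_numpy(dtype=float)
    frac = np.isnan(X).mean(axis=0)
    over = [v for v, f in zip(variables, frac) if f > max_missing]
    if over:
        raise MissingnessCapError(
            f"missing fraction exceeds cap {max_missing:.0%} for {over}"
        )
    if not np.isnan(X).any():
        return table.copy()
    X_imp, _, _, _, _ = _em_mvnormal(X, tol, max_iter)
    df[variables] = X_imp
    return CohortTable(df, table.provenance)


def center_and_standardize(
    df: pd.DataFrame, variables: Sequence[str], mode: str = "center"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center (or z-score) variables; returns the new frame and per-variable
    (mean, SD) so the transform can be inverted exactly.  SD uses n-1."""
    if mode not in ("center", "zscore"):
        raise ValueError(f"unknown mode {mode!r}")
    out = df.copy()
    stats_out: dict[str, tuple[float, float]] = {}
    for var in variables:
        x = out[var].to_numpy(dtype=float)
        m = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ZeroVarianceError(f"{var} has zero variance")
        out[var] = (x - m) / (sd if mode == "zscore" else 1.0)
        stats_out[var] = (m, sd)
    return out, stats_out
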