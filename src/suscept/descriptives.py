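"""Descriptive layer: correlations, ANOVAs, common-method-bias checks,
and dependent-correlation comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import ZeroVarianceError


@dataclass
class CorrelationEntry:
    var_a: str
    var_b: str
    r: float
    p: float
    n: int


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ZeroVarianceError("constant variable in correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def correlation_matrix(
    df: pd.DataFrame, variables: Sequence[str]
) -> list[CorrelationEntry]:
    """Pairwise-complete Pearson correlations with two-sided t-based p."""
    entries = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            r, p, n = _pearson(
                df[a].to_numpy(dtype=float), df[b].to_numpy(dtype=float)
            )
            entries.append(CorrelationEntry(a, b, r, p, n))
    return entries


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def oneway_anova(df: pd.DataFrame, outcome: str, group: str) -> AnovaResult:
    """Classical one-way between/within decomposition."""
    groups = [
        g[outcome].to_numpy(dtype=float) for _, g in df.groupby(group, observed=True)
    ]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        F = math.inf if ssb > 0 else 0.0
    else:
        F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w)) if math.isfinite(F) else 0.0
    return AnovaResult(float(F), df_b, df_w, p)


@dataclass
class HarmanResult:
    first_factor_fraction: float
    eigenvalues: np.ndarray
    exceeds_40pct: bool


def harman_efa(item_matrix) -> HarmanResult:
    """Single-factor screen: share of variance on the first unrotated
    principal component of the item correlation matrix."""
    X = np.asarray(item_matrix, dtype=float)
    n, k = X.shape
    if k < 3:
        raise ValueError("need at least 3 items")
    if n <= k:
        raise ValueError("need more subjects than items")
    R = np.corrcoef(X, rowvar=False)
    w = np.sort(np.linalg.eigvalsh(R))[::-1]
    frac = float(w[0] / k)
    return HarmanResult(frac, w, frac > 0.40)


@dataclass
class FitIndices:
    chi2: float
    df: int
    chi2_over_df: float
    gfi: float
    cfi: float
    tli: float
    rmsea: float


@dataclass
class CfaResult:
    fit: FitIndices
    loadings: np.ndarray
    uniquenesses: np.ndarray
    converged: bool
    heywood: bool
    n: int


class CfaConvergenceError(RuntimeError):
    pass


def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return math.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(
        logdet_sigma + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - p
    )


def single_factor_cfa(item_matrix=None, *, cov=None, n=None) -> CfaResult:
    """Fit a one-factor model by maximum likelihood and report fit indices.

    Accepts either a raw subjects x items matrix or a covariance matrix
    with its sample size.  The baseline for CFI/TLI is the independence
    model with free variances.
    """
    if item_matrix is not None:
        X = np.asarray(item_matrix, dtype=float)
        n = X.shape[0]
        if n <= X.shape[1]:
            raise ValueError("need more subjects than items")
        S = np.cov(X, rowvar=False, ddof=1)
    else:
        S = np.asarray(cov, dtype=float)
        if n is None:
            raise ValueError("n is required with a covariance input")
    p = S.shape[0]
    df = p * (p + 1) // 2 - 2 * p
    if df <= 0:
        raise ValueError("need at least 4 items for positive df")

    diag = np.diag(S).copy()
    w, V = np.linalg.eigh(S)
    lam0 = V[:, -1] * math.sqrt(max(w[-1], 1e-6))
    psi0 = np.clip(diag - lam0**2, 0.05 * diag, None)
    x0 = np.concatenate([lam0, psi0])

    def objective(x):
        lam, psi = x[:p], x[p:]
        Sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            Sigma_inv = np.linalg.inv(Sigma)
        except np.linalg.LinAlgError:
            return math.inf, np.zeros_like(x)
        F = _ml_discrepancy(S, Sigma)
        if not math.isfinite(F):
            return math.inf, np.zeros_like(x)
        G = Sigma_inv @ (Sigma - S) @ Sigma_inv  # dF/dSigma
        return F, np.concatenate([2.0 * G @ lam, np.diag(G)])

    bounds = [(None, None)] * p + [(1e-6, None)] * p
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    grad_norm = float(np.abs(res.jac).max())
    if not res.success and grad_norm > 1e-4:
        raise CfaConvergenceError(
            f"one-factor ML fit did not converge (max |grad| {grad_norm:.3g})"
        )
    lam, psi = res.x[:p], res.x[p:]
    heywood = bool((psi <= 1.1e-6).any())

    F_model = max(float(res.fun), 0.0)
    chi2 = (n - 1) * F_model
    Sigma0 = np.diag(diag)
    F0 = _ml_discrepancy(S, Sigma0)
    df0 = p * (p + 1) // 2 - p
    chi2_0 = (n - 1) * F0

    d_model = max(chi2 - df, 0.0)
    d_base = max(chi2_0 - df0, 0.0)
    cfi = 1.0 if d_base == 0 else 1.0 - d_model / max(d_base, d_model)
    cfi = min(max(cfi, 0.0), 1.0)
    if chi2_0 / df0 > 1.0:
        tli = ((chi2_0 / df0) - (chi2 / df)) / ((chi2_0 / df0) - 1.0)
    else:
        tli = 1.0
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    Sigma_hat = np.outer(lam, lam) + np.diag(psi)
    A = np.linalg.solve(Sigma_hat, S)
    I = np.eye(p)
    gfi = 1.0 - np.trace((A - I) @ (A - I)) / np.trace(A @ A)
    fit = FitIndices(
        chi2=float(chi2),
        df=df,
        chi2_over_df=float(chi2 / df),
        gfi=float(gfi),
        cfi=float(cfi),
        tli=float(tli),
        rmsea=float(rmsea),
    )
    return CfaResult(fit, lam, psi, bool(res.success or grad_norm <= 1e-4), heywood, n)


@dataclass
class DependentRComparison:
    r12: float
    r13: float
    r23: float
    n: int
    z: float
    p: float
    variant: str


def compare_dependent_r(
    r12: float, r13: float, r23: float, n: int, variant: str = "meng"
) -> DependentRComparison:
    """Compare two correlations sharing a variable (r12 vs r13).

    ``meng``: Meng-Rosenthal-Rubin Z with the pooled correlation
    (r12+r13)/2 entering the heteroscedasticity correction.  ``steiger``:
    Steiger's Z* with the pooled estimate.  Two-sided p from the normal.
    """
    if variant not in ("meng", "steiger"):
        raise ValueError(f"unknown variant {variant!r}")
    if not (abs(r12) < 1 and abs(r13) < 1 and abs(r23) < 1):
        raise ValueError("all correlations must satisfy |r| < 1")
    if n <= 10:
        raise ValueError("n must exceed 10")
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], dtype=float)
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("the three correlations do not form a PSD matrix")
    z12, z13 = math.atanh(r12), math.atanh(r13)
    rm = (r12 + r13) / 2.0
    rm2 = rm * rm
    if variant == "meng":
        f = min(1.0, (1.0 - r23) / (2.0 * (1.0 - rm2)))
        h = (1.0 - f * rm2) / (1.0 - rm2)
        z = (z12 - z13) * math.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    else:
        cov = (
            r23 * (1.0 - 2.0 * rm2)
            - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r23 * r23)
        ) / ((1.0 - rm2) ** 2)
        z = (z12 - z13) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return DependentRComparison(r12, r13, r23, n, float(z), float(p), variant)
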