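"""Four-step hierarchical moderated regression with F-change tests.

Step 1 enters dummy-coded demographics, step 2 the environment scale,
step 3 the moderator, step 4 their product.  Predictors are centered
before the product is formed; each cumulative step is ordinary least
squares and the increment in explained variance is tested with the
F-change statistic.  The final model's coefficient covariance is kept so
interaction probing can compute simple-slope and group-difference
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class RankDeficiencyError(ValueError):
    """The design matrix is rank-deficient; lists the aliased columns."""

    def __init__(self, aliased: list[str]):
        super().__init__(f"design is rank deficient; aliased terms: {aliased}")
        self.aliased = aliased


class UnseenLevelError(ValueError):
    pass


def dummy_code(
    df: pd.DataFrame,
    variable: str,
    reference_level: str,
    levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """g-1 indicator columns; reference-level rows are all-zero."""
    values = df[variable]
    if levels is None:
        levels = sorted(values.unique().tolist())
    if reference_level not in levels:
        raise UnseenLevelError(
            f"reference level {reference_level!r} not among levels {levels}"
        )
    unseen = set(values.unique()) - set(levels)
    if unseen:
        raise UnseenLevelError(
            f"{variable} holds level(s) {sorted(unseen)} absent from the "
            "declared level set"
        )
    out = pd.DataFrame(index=df.index)
    for lev in levels:
        if lev == reference_level:
            continue
        out[f"{variable}[{lev}]"] = (values == lev).astype(float)
    return out


@dataclass
class CoefficientEstimate:
    term: str
    B: float
    SE: float
    beta: float
    t: float
    p: float


@dataclass
class StepSummary:
    step_index: int
    terms_entered: list[str]
    r2_cumulative: float
    delta_r2: float
    f_change: float
    df1: int
    df2: int
    p: float
    coefficients: list[CoefficientEstimate]


@dataclass
class InteractionModel:
    """The slice of a fit that interaction probing needs."""

    b_env: float
    b_mod: float
    b_int: float
    var_env: float
    var_mod: float
    var_int: float
    cov_env_int: float
    cov_mod_int: float
    df_resid: int
    env_sd: float
    mod_sd: float


@dataclass
class ModerationFit:
    outcome: str
    env: str
    moderator: str
    steps: list[StepSummary]
    coefficients: list[CoefficientEstimate]
    param_names: list[str]
    cov_params: np.ndarray
    n: int
    df_resid: int
    r2: float
    env_mean: float
    mod_mean: float
    env_sd: float
    mod_sd: float
    outcome_sd: float
    interaction_term: str
    env_values_centered: np.ndarray = field(repr=False, default=None)

    def _coef(self, term: str) -> CoefficientEstimate:
        for c in self.coefficients:
            if c.term == term:
                return c
        raise KeyError(term)

    def _cov(self, a: str, b: str) -> float:
        i, j = self.param_names.index(a), self.param_names.index(b)
        return float(self.cov_params[i, j])

    def interaction_model(self) -> InteractionModel:
        env, mod, inter = self.env, self.moderator, self.interaction_term
        return InteractionModel(
            b_env=self._coef(env).B,
            b_mod=self._coef(mod).B,
            b_int=self._coef(inter).B,
            var_env=self._cov(env, env),
            var_mod=self._cov(mod, mod),
            var_int=self._cov(inter, inter),
            cov_env_int=self._cov(env, inter),
            cov_mod_int=self._cov(mod, inter),
            df_resid=self.df_resid,
            env_sd=self.env_sd,
            mod_sd=self.mod_sd,
        )


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    """OLS with intercept; returns (beta, cov, r2, df_resid, sigma2)."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(Xd, pivoting=True, mode="economic")
        aliased = sorted(
            (["(intercept)"] + names)[j] for j in piv[rank:]
        )
        raise RankDeficiencyError(aliased)
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    df_resid = n - Xd.shape[1]
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    cov = sigma2 * XtX_inv
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return beta, cov, r2, df_resid, sigma2


def f_change(
    r2_prev: float, r2_full: float, df1: int, n: int, params_at_step: int
) -> tuple[float, int, float]:
    """F test of the R^2 increment; df2 = n - params_at_step - 1."""
    df2 = n - params_at_step - 1
    delta = r2_full - r2_prev
    denom = (1.0 - r2_full) / df2
    F = (delta / df1) / denom if denom > 0 else math.inf
    p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return float(F), df2, p


def _coef_table(
    names: list[str], beta, cov, df_resid, X: np.ndarray, y: np.ndarray
) -> list[CoefficientEstimate]:
    sd_y = y.std(ddof=1)
    out = []
    for j, name in enumerate(["(intercept)"] + names):
        B = float(beta[j])
        SE = float(math.sqrt(cov[j, j]))
        t = B / SE if SE > 0 else math.inf
        p = 2.0 * float(stats.t.sf(abs(t), df_resid))
        if name == "(intercept)":
            b_std = math.nan
        else:
            b_std = B * X[:, j - 1].std(ddof=1) / sd_y
        out.append(CoefficientEstimate(name, B, SE, float(b_std), float(t), p))
    return out


def fit_hierarchical(
    df: pd.DataFrame,
    outcome: str,
    env: str,
    moderator: str,
    covariates: Sequence[str] = (),
    *,
    center: bool = True,
    categorical_refs: Mapping[str, str] | None = None,
) -> ModerationFit:
    """Fit the four-step moderated hierarchical regression.

    Categorical covariates are dummy-coded (reference level from
    ``categorical_refs`` or the modal level).  With ``center=True`` the
    environment and moderator are mean-centered before the product term
    is formed; pass ``center=False`` if they are already centered.
    """
    categorical_refs = dict(categorical_refs or {})
    n = len(df)
    y = df[outcome].to_numpy(dtype=float)

    blocks: list[tuple[list[str], np.ndarray]] = []
    cov_names: list[str] = []
    cov_cols: list[np.ndarray] = []
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = categorical_refs.get(c, col.mode().iloc[0])
            dummies = dummy_code(df, c, ref)
            for name in dummies.columns:
                cov_names.append(name)
                cov_cols.append(dummies[name].to_numpy(dtype=float))
        else:
            cov_names.append(c)
            cov_cols.append(col.to_numpy(dtype=float))
    if cov_names:
        blocks.append((cov_names, np.column_stack(cov_cols)))

    e = df[env].to_numpy(dtype=float)
    m = df[moderator].to_numpy(dtype=float)
    env_mean = float(e.mean()) if center else 0.0
    mod_mean = float(m.mean()) if center else 0.0
    e_c = e - env_mean
    m_c = m - mod_mean
    inter_name = f"{env}_x_{moderator}"
    blocks.append(([env], e_c[:, None]))
    blocks.append(([moderator], m_c[:, None]))
    blocks.append(([inter_name], (e_c * m_c)[:, None]))

    min_n = sum(b[1].shape[1] for b in blocks) + 10
    if n <= min_n:
        raise ValueError(f"n = {n} too small for {min_n - 10} parameters")

    steps: list[StepSummary] = []
    names: list[str] = []
    X = np.empty((n, 0))
    r2_prev = 0.0
    beta = cov = None
    df_resid = n - 1
    for step_idx, (new_names, new_cols) in enumerate(blocks, start=1):
        names = names + list(new_names)
        X = np.column_stack([X, new_cols])
        beta, cov, r2, df_resid, _ = _ols(X, y, names)
        F, df2, p = f_change(r2_prev, r2, len(new_names), n, X.shape[1])
        steps.append(
            StepSummary(
                step_index=step_idx,
                terms_entered=list(new_names),
                r2_cumulative=float(r2),
                delta_r2=float(r2 - r2_prev),
                f_change=F,
                df1=len(new_names),
                df2=df2,
                p=p,
                coefficients=_coef_table(names, beta, cov, df_resid, X, y),
            )
        )
        r2_prev = r2

    final_coefs = steps[-1].coefficients
    return ModerationFit(
        outcome=outcome,
        env=env,
        moderator=moderator,
        steps=steps,
        coefficients=final_coefs,
        param_names=["(intercept)"] + names,
        cov_params=cov,
        n=n,
        df_resid=df_resid,
        r2=steps[-1].r2_cumulative,
        env_mean=env_mean,
        mod_mean=mod_mean,
        env_sd=float(e_c.std(ddof=1)),
        mod_sd=float(m_c.std(ddof=1)),
        outcome_sd=float(y.std(ddof=1)),
        interaction_term=inter_name,
        env_values_centered=e_c,
    )


@dataclass
class CollinearityEntry:
    term: str
    tolerance: float
    vif: float
    flagged: bool


def collinearity_report(
    fit_or_df,
    terms: Sequence[str] | None = None,
    *,
    tol_threshold: float = 0.2,
    vif_threshold: float = 5.0,
) -> list[CollinearityEntry]:
    """Tolerance (1 - R^2 of each predictor on the rest) and VIF.

    Accepts a ModerationFit (final-step design rebuilt from its stored
    step terms is not retained, so pass the data frame route for custom
    designs) or a data frame plus term list.
    """
    if isinstance(fit_or_df, ModerationFit):
        raise TypeError(
            "pass the predictor data frame and term names; the fit does not "
            "retain its design matrix"
        )
    df = fit_or_df
    if terms is None:
        terms = list(df.columns)
    X = df[list(terms)].to_numpy(dtype=float)
    n = X.shape[0]
    out = []
    for j, term in enumerate(terms):
        others = np.delete(X, j, axis=1)
        Xd = np.column_stack([np.ones(n), others])
        beta, _, _, _ = np.linalg.lstsq(Xd, X[:, j], rcond=None)
        resid = X[:, j] - Xd @ beta
        ss_tot = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"constant predictor {term!r}")
        r2 = 1.0 - float(resid @ resid) / ss_tot
        tol = max(1.0 - r2, 1e-12)
        vif = 1.0 / tol
        out.append(
            CollinearityEntry(
                term, float(tol), float(vif),
                bool(tol <= tol_threshold or vif >= vif_threshold),
            )
        )
    return out


def design_frame(
    df: pd.DataFrame,
    env: str,
    moderator: str,
    covariates: Sequence[str] = (),
    *,
    center: bool = True,
    categorical_refs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Final-step predictor frame (for collinearity diagnostics)."""
    categorical_refs = dict(categorical_refs or {})
    parts = []
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = categorical_refs.get(c, col.mode().iloc[0])
            parts.append(dummy_code(df, c, ref))
        else:
            parts.append(col.to_frame())
    e = df[env].to_numpy(dtype=float)
    m = df[moderator].to_numpy(dtype=float)
    if center:
        e = e - e.mean()
        m = m - m.mean()
    parts.append(pd.DataFrame({env: e, moderator: m,
                               f"{env}_x_{moderator}": e * m}, index=df.index))
    return pd.concat(parts, axis=1)
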