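"""Interaction probing and pattern classification.

Given a fitted moderated regression, this module computes simple slopes
at moderator M±1SD, the region of significance on the environment axis
(the env values where the high-vs-low moderator group difference is
exactly significant), the crossover point, the proportion-of-interaction
(PoI) and proportion-affected (PA) indices, and finally classifies the
interaction against the three susceptibility models by which ends of the
evaluation range are significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .moderation import InteractionModel, ModerationFit

PATTERN_LABELS = (
    "differential_susceptibility",
    "vantage_sensitivity",
    "diathesis_stress",
    "none",
)


def _model(fit) -> InteractionModel:
    if isinstance(fit, ModerationFit):
        return fit.interaction_model()
    if isinstance(fit, InteractionModel):
        return fit
    raise TypeError("expected a ModerationFit or InteractionModel")


@dataclass
class SimpleSlope:
    at_moderator_sd: float  # moderator offset in moderator-SD units
    slope: float
    se: float
    t: float
    p: float


def _slope_at(m: InteractionModel, z: float) -> SimpleSlope:
    """Slope of outcome on env at moderator offset z (raw moderator units)."""
    slope = m.b_env + m.b_int * z
    var = m.var_env + z * z * m.var_int + 2.0 * z * m.cov_env_int
    se = math.sqrt(max(var, 0.0))
    t = slope / se if se > 0 else math.inf
    p = 2.0 * float(stats.t.sf(abs(t), m.df_resid))
    return SimpleSlope(z / m.mod_sd if m.mod_sd else 0.0, slope, se, float(t), p)


def simple_slopes(
    fit, moderator_sd: float | None = None
) -> tuple[SimpleSlope, SimpleSlope]:
    """Simple slopes at moderator M+1SD and M-1SD (high, low)."""
    m = _model(fit)
    sd = m.mod_sd if moderator_sd is None else moderator_sd
    return _slope_at(m, +sd), _slope_at(m, -sd)


@dataclass
class JNRegion:
    """Johnson-Neyman solution on the environment axis (SD units)."""

    ros_lower: float | None
    ros_upper: float | None
    segments: list[tuple[float, float, bool]]  # (lo, hi, significant)
    t_crit: float
    alpha: float
    eval_range: tuple[float, float]
    all_significant: bool
    none_significant: bool

    def significant_at(self, x_sd: float) -> bool:
        for lo, hi, sig in self.segments:
            if lo - 1e-12 <= x_sd <= hi + 1e-12:
                return sig
        return False


def _diff_t(m: InteractionModel, x_raw: float, eps: float = 0.0) -> float:
    """t-ratio of the high-vs-low moderator group difference at env x.

    The difference is 2*SD_mod*(b_mod + b_int*x); the 2*SD_mod factor
    cancels from the ratio.
    """
    num = m.b_mod + m.b_int * x_raw
    var = m.var_mod + x_raw * x_raw * m.var_int + 2.0 * x_raw * m.cov_mod_int
    return num / math.sqrt(max(var, eps if eps > 0 else 1e-300))


def jn_region(
    fit,
    moderator_sd: float | None = None,
    alpha: float = 0.05,
    eval_range: tuple[float, float] = (-2.0, 2.0),
) -> JNRegion:
    """Solve for the env values where the group difference is exactly
    significant at alpha, and classify sub-intervals of eval_range."""
    m = _model(fit)
    if m.var_int <= 0:
        raise ValueError("zero interaction variance; cannot probe")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, m.df_resid))
    t2 = t_crit * t_crit
    a = m.b_int**2 - t2 * m.var_int
    b = 2.0 * (m.b_mod * m.b_int - t2 * m.cov_mod_int)
    c = m.b_mod**2 - t2 * m.var_mod
    env_sd = m.env_sd

    roots_sd: list[float] = []
    if abs(a) > 1e-300:
        disc = b * b - 4.0 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots_sd = sorted(((-b - sq) / (2 * a) / env_sd,
                               (-b + sq) / (2 * a) / env_sd))
    elif abs(b) > 1e-300:
        roots_sd = [(-c / b) / env_sd]

    L, U = eval_range
    cuts = [L] + [r for r in roots_sd if L < r < U] + [U]
    segments = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (lo + hi)
        sig = abs(_diff_t(m, mid * env_sd)) > t_crit
        segments.append((lo, hi, sig))

    # The non-significance band, when the quadratic has two real roots and
    # the region between them is non-significant.
    ros_lower = ros_upper = None
    if len(roots_sd) == 2:
        mid = 0.5 * (roots_sd[0] + roots_sd[1])
        if abs(_diff_t(m, mid * env_sd)) <= t_crit:
            ros_lower, ros_upper = roots_sd
    all_sig = all(s for _, _, s in segments)
    none_sig = not any(s for _, _, s in segments)
    return JNRegion(
        ros_lower, ros_upper, segments, t_crit, alpha, (L, U), all_sig, none_sig
    )


def crossover_point(fit) -> float:
    """Env value where the moderator-group lines meet, in env-SD units."""
    m = _model(fit)
    if m.b_int == 0:
        raise ZeroDivisionError("b_int = 0: lines are parallel")
    return (-m.b_mod / m.b_int) / m.env_sd


def susceptible_group(fit) -> str:
    """The moderator level whose outcomes span the wider range across env."""
    high, low = simple_slopes(fit)
    return "high_moderator" if abs(high.slope) >= abs(low.slope) else "low_moderator"


def vantage_side(fit, outcome_polarity: int) -> int:
    """+1 if the susceptible group is better off to the right of the
    crossover, -1 if to the left."""
    m = _model(fit)
    s = 1.0 if susceptible_group(fit) == "high_moderator" else -1.0
    side = s * m.b_int * outcome_polarity
    return 1 if side > 0 else -1


def poi_from_geometry(
    crossover_x: float, eval_range: tuple[float, float], side: int
) -> float:
    """Closed-form PoI for straight lines: squared-distance ratio of the
    vantage-side span to the total between-line area over the range."""
    L, U = eval_range
    x = min(max(crossover_x, L), U)
    d_right = U - x
    d_left = x - L
    d_v, d_r = (d_right, d_left) if side > 0 else (d_left, d_right)
    denom = d_v * d_v + d_r * d_r
    if denom == 0:
        return 0.5
    return d_v * d_v / denom


def poi_index(fit, outcome_polarity: int,
              eval_range: tuple[float, float] = (-2.0, 2.0)) -> float:
    """Share of the between-line area lying on the 'better-off' side of
    the crossover for the susceptible group."""
    return poi_from_geometry(
        crossover_point(fit), eval_range, vantage_side(fit, outcome_polarity)
    )


def pa_index(fit, env_values_sd: Sequence[float],
             outcome_polarity: int) -> float:
    """Empirical fraction of subjects on the vantage side of the crossover.

    ``env_values_sd``: the analyzed sample's centered env scores in SD
    units.
    """
    x = np.asarray(env_values_sd, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    cx = crossover_point(fit)
    side = vantage_side(fit, outcome_polarity)
    return float((x > cx).mean() if side > 0 else (x < cx).mean())


@dataclass
class ProbeResult:
    slope_high: SimpleSlope
    slope_low: SimpleSlope
    crossover_x: float | None
    ros_lower: float | None
    ros_upper: float | None
    eval_range: tuple[float, float]
    poi: float | None
    pa: float | None
    alpha: float
    region: JNRegion = field(repr=False, default=None)
    susceptible_group: str | None = None
    supportive_end_significant: bool | None = None
    adverse_end_significant: bool | None = None


def probe_interaction(
    fit,
    *,
    alpha: float = 0.05,
    eval_range: tuple[float, float] = (-2.0, 2.0),
    env_polarity: int = 1,
    outcome_polarity: int = 1,
    env_values_sd: Sequence[float] | None = None,
) -> ProbeResult:
    """Full probe of one interaction: slopes, RoS, crossover, PoI, PA."""
    m = _model(fit)
    high, low = simple_slopes(fit)
    region = jn_region(fit, alpha=alpha, eval_range=eval_range)
    if env_values_sd is None and isinstance(fit, ModerationFit):
        env_values_sd = fit.env_values_centered / fit.env_sd
    if m.b_int != 0:
        cx = crossover_point(fit)
        poi = poi_index(fit, outcome_polarity, eval_range)
        pa = (
            pa_index(fit, env_values_sd, outcome_polarity)
            if env_values_sd is not None
            else None
        )
    else:
        cx = poi = pa = None
    L, U = eval_range
    supportive_end = U if env_polarity > 0 else L
    adverse_end = L if env_polarity > 0 else U
    t_crit = region.t_crit
    # A bound exactly at an eval_range edge counts as inside (>=).
    sup_sig = abs(_diff_t(m, supportive_end * m.env_sd)) >= t_crit
    adv_sig = abs(_diff_t(m, adverse_end * m.env_sd)) >= t_crit
    return ProbeResult(
        slope_high=high,
        slope_low=low,
        crossover_x=cx,
        ros_lower=region.ros_lower,
        ros_upper=region.ros_upper,
        eval_range=eval_range,
        poi=poi,
        pa=pa,
        alpha=alpha,
        region=region,
        susceptible_group=susceptible_group(fit) if m.b_int != 0 else None,
        supportive_end_significant=bool(sup_sig),
        adverse_end_significant=bool(adv_sig),
    )


@dataclass
class PatternClassification:
    label: str
    susceptible_group: str | None
    interaction_p: float
    evidence: dict
    poi_gate_applied: bool


def classify_pattern(
    probe: ProbeResult,
    interaction_p: float,
    *,
    env_polarity: int = 1,
    outcome_polarity: int = 1,
    alpha: float = 0.05,
    poi_gate: bool = False,
    poi_band: tuple[float, float] = (0.40, 0.60),
) -> PatternClassification:
    """Classify the interaction against the three susceptibility models.

    Rules: a non-significant interaction (or no significant region end) is
    ``none``; significance at both the supportive and adverse ends with
    the group ordering reversing across the crossover is differential
    susceptibility; only the supportive end, vantage sensitivity; only the
    adverse end, diathesis stress.  PoI/PA are descriptive unless the
    optional PoI gate is enabled.
    """
    if env_polarity not in (1, -1) or outcome_polarity not in (1, -1):
        raise ValueError("polarities must be declared as +1 or -1")
    sup = bool(probe.supportive_end_significant)
    adv = bool(probe.adverse_end_significant)
    evidence = {
        "supportive_end_significant": sup,
        "adverse_end_significant": adv,
        "crossover_x": probe.crossover_x,
        "ros_lower": probe.ros_lower,
        "ros_upper": probe.ros_upper,
        "poi": probe.poi,
        "pa": probe.pa,
        "env_polarity": env_polarity,
        "outcome_polarity": outcome_polarity,
    }
    label = "none"
    if interaction_p < alpha and (sup or adv):
        L, U = probe.eval_range
        crossover_inside = (
            probe.crossover_x is not None and L < probe.crossover_x < U
        )
        if sup and adv:
            label = (
                "differential_susceptibility" if crossover_inside else "none"
            )
        elif sup:
            label = "vantage_sensitivity"
        else:
            label = "diathesis_stress"
    if (
        poi_gate
        and label == "differential_susceptibility"
        and not (poi_band[0] <= (probe.poi or 0.0) <= poi_band[1])
    ):
        evidence["poi_gate_failed"] = True
        label = "none"
    return PatternClassification(
        label=label,
        susceptible_group=probe.susceptible_group if label != "none" else None,
        interaction_p=float(interaction_p),
        evidence=evidence,
        poi_gate_applied=poi_gate,
    )


def plot_data(
    fit, *, eval_range: tuple[float, float] = (-2.0, 2.0),
    alpha: float = 0.05, n_grid: int = 81,
):
    """Grid export sufficient to redraw the interaction figure.

    Returns a list of dicts with the env grid (SD units), predicted
    outcome offsets at moderator M±1SD, the group-difference t-ratio and
    a significance flag.
    """
    m = _model(fit)
    region = jn_region(fit, alpha=alpha, eval_range=eval_range)
    xs = np.linspace(eval_range[0], eval_range[1], n_grid)
    rows = []
    for x in xs:
        x_raw = x * m.env_sd
        pred_high = (m.b_env + m.b_int * m.mod_sd) * x_raw + m.b_mod * m.mod_sd
        pred_low = (m.b_env - m.b_int * m.mod_sd) * x_raw - m.b_mod * m.mod_sd
        t = _diff_t(m, x_raw)
        rows.append(
            {
                "env_sd": float(x),
                "pred_high_moderator": float(pred_high),
                "pred_low_moderator": float(pred_low),
                "diff_t": float(t),
                "significant": bool(abs(t) > region.t_crit),
            }
        )
    return rows
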