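"""One-command pipeline: ingest or simulate, score, impute, describe,
run the 12 moderated regressions, probe significant interactions and
classify their patterns, then export paper-shaped tables."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import descriptives, moderation, probing, schema, scoring, synthetic
from .schema import CohortTable, OUTCOME_COLUMNS, SCALE_COLUMNS
from .synthetic import SyntheticSpec

#: (label used in reports, regression column, polarity: +1 higher=supportive)
ENV_SPECS = (
    ("job_control", "job_control_std", 1),
    ("psych_demands", "psych_demands_std", -1),
    ("supervisor_support", "supervisor_support", 1),
    ("coworker_support", "coworker_support", 1),
)
#: +1: higher outcome is better (pe); -1: higher is worse (ee, dp).
OUTCOME_POLARITY = {"ee": -1, "dp": -1, "pe": 1}

COVARIATES = ("department", "shift_pattern", "tenure_years")
CATEGORICAL_REFS = {"department": "other", "shift_pattern": "three_shift_8h"}

CORR_VARS = list(SCALE_COLUMNS) + ["log_hcc"] + list(OUTCOME_COLUMNS)


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    column_map: Mapping[str, str] | None = None
    sep: str = ","
    alpha: float = 0.05
    eval_range: tuple[float, float] = (-2.0, 2.0)
    env_polarity: dict[str, int] = field(
        default_factory=lambda: {label: pol for label, _, pol in ENV_SPECS}
    )
    outcome_polarity: dict[str, int] = field(
        default_factory=lambda: dict(OUTCOME_POLARITY)
    )
    probe_all: bool = False
    poi_gate: bool = False
    out_dir: str | None = None
    seed: int = 0
    normality_mc: int = 2000

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic_spec is None):
            raise ConfigError(
                "exactly one of input_path / synthetic_spec must be given"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        spec = payload.pop("synthetic_spec", None)
        if spec is not None:
            spec = SyntheticSpec.from_dict(spec)
        payload.update(overrides)
        if "eval_range" in payload and payload["eval_range"] is not None:
            payload["eval_range"] = tuple(payload["eval_range"])
        return cls(synthetic_spec=spec, **payload)


@dataclass
class RegressionReport:
    env_label: str
    outcome: str
    fit: moderation.ModerationFit
    collinearity: list[moderation.CollinearityEntry]
    interaction_p: float


@dataclass
class ProbeReport:
    env_label: str
    outcome: str
    probe: probing.ProbeResult
    classification: probing.PatternClassification


@dataclass
class ReportBundle:
    n: int
    provenance: str
    alpha: float
    seed: int
    reliability: list[scoring.ReliabilityReport]
    normality_raw: scoring.NormalityReport
    normality_log: scoring.NormalityReport
    correlations: list[descriptives.CorrelationEntry]
    means: dict[str, float]
    sds: dict[str, float]
    anovas: dict[str, dict[str, descriptives.AnovaResult]]
    regressions: list[RegressionReport]
    probes: list[ProbeReport]
    log: list[str]


def _prepare(config: AnalysisConfig) -> tuple[CohortTable, list[str]]:
    log: list[str] = []
    if config.synthetic_spec is not None:
        spec = dataclasses.replace(config.synthetic_spec, seed=config.seed)
        table = synthetic.generate_cohort(spec)
        log.append(f"simulated cohort n={table.n} seed={config.seed}")
    else:
        table = schema.read_cohort(
            config.input_path, sep=config.sep, column_map=config.column_map
        )
        log.append(f"read cohort n={table.n} from {config.input_path}")
    return table, log


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    table, log = _prepare(config)

    # Scoring: items -> scales when items are present.
    df = table.data
    reliability: list[scoring.ReliabilityReport] = []
    if all(c in df.columns for c in schema.JCQ_ITEM_COLUMNS):
        table = scoring.score_table(table)
        df = table.data
        log.append("scored JCQ/MBI items into scale scores")
        layout = {
            "job_control": list(schema.JCQ_ITEM_COLUMNS[0:9]),
            "psych_demands": list(schema.JCQ_ITEM_COLUMNS[9:14]),
            "supervisor_support": list(schema.JCQ_ITEM_COLUMNS[14:18]),
            "coworker_support": list(schema.JCQ_ITEM_COLUMNS[18:22]),
            "ee": list(schema.MBI_ITEM_COLUMNS[0:5]),
            "dp": list(schema.MBI_ITEM_COLUMNS[5:10]),
            "pe": list(schema.MBI_ITEM_COLUMNS[10:16]),
        }
        for name, cols in layout.items():
            reliability.append(
                scoring.cronbach_alpha(df[cols].to_numpy(dtype=float), name)
            )

    # EM imputation of scale/outcome missingness.
    n_missing = int(
        df[[c for c in SCALE_COLUMNS + OUTCOME_COLUMNS if c in df.columns]]
        .isna()
        .sum()
        .sum()
    )
    if n_missing:
        table = scoring.em_impute(table)
        df = table.data
        log.append(f"EM-imputed {n_missing} missing cells")

    df = df.copy()
    if "log_hcc" not in df.columns:
        df["log_hcc"] = scoring.transform_hcc(df["hcc_raw"].to_numpy())
    df["job_control_std"] = scoring.job_control_standard(df["job_control"])
    df["psych_demands_std"] = scoring.psych_demands_standard(df["psych_demands"])

    normality_raw = scoring.normality_report(
        df["hcc_raw"].to_numpy(), n_mc=config.normality_mc, seed=config.seed
    )
    normality_log = scoring.normality_report(
        df["log_hcc"].to_numpy(), n_mc=config.normality_mc, seed=config.seed
    )
    log.append(
        f"moderator normality: raw KS p={normality_raw.ks_p:.4f}, "
        f"log KS p={normality_log.ks_p:.4f}"
    )

    correlations = descriptives.correlation_matrix(df, CORR_VARS)
    means = {v: float(df[v].mean()) for v in CORR_VARS}
    sds = {v: float(df[v].std(ddof=1)) for v in CORR_VARS}
    anovas: dict[str, dict[str, descriptives.AnovaResult]] = {}
    for group in ("department", "shift_pattern"):
        anovas[group] = {
            v: descriptives.oneway_anova(df, v, group) for v in CORR_VARS
        }

    regressions: list[RegressionReport] = []
    probes: list[ProbeReport] = []
    for env_label, env_col, env_pol in ENV_SPECS:
        for outcome in OUTCOME_COLUMNS:
            fit = moderation.fit_hierarchical(
                df,
                outcome,
                env_col,
                "log_hcc",
                covariates=COVARIATES,
                categorical_refs=CATEGORICAL_REFS,
            )
            design = moderation.design_frame(
                df, env_col, "log_hcc", COVARIATES,
                categorical_refs=CATEGORICAL_REFS,
            )
            collin = moderation.collinearity_report(design)
            for entry in collin:
                if entry.flagged:
                    log.append(
                        f"collinearity flag [{env_label}->{outcome}]: "
                        f"{entry.term} tolerance={entry.tolerance:.3f}"
                    )
            p_int = fit.steps[-1].p
            regressions.append(
                RegressionReport(env_label, outcome, fit, collin, p_int)
            )
            if config.probe_all or p_int < config.alpha:
                out_pol = config.outcome_polarity[outcome]
                probe = probing.probe_interaction(
                    fit,
                    alpha=config.alpha,
                    eval_range=config.eval_range,
                    env_polarity=env_pol,
                    outcome_polarity=out_pol,
                )
                if probe.region.all_significant or probe.region.none_significant:
                    log.append(
                        f"degenerate RoS [{env_label}->{outcome}]: "
                        f"{'all' if probe.region.all_significant else 'no'} "
                        "env values significant"
                    )
                cls = probing.classify_pattern(
                    probe,
                    interaction_p=p_int,
                    env_polarity=env_pol,
                    outcome_polarity=out_pol,
                    alpha=config.alpha,
                    poi_gate=config.poi_gate,
                )
                probes.append(ProbeReport(env_label, outcome, probe, cls))
                log.append(
                    f"probed [{env_label}->{outcome}]: p_int={p_int:.4f} "
                    f"label={cls.label}"
                )

    return ReportBundle(
        n=table.n,
        provenance=table.provenance,
        alpha=config.alpha,
        seed=config.seed,
        reliability=reliability,
        normality_raw=normality_raw,
        normality_log=normality_log,
        correlations=correlations,
        means=means,
        sds=sds,
        anovas=anovas,
        regressions=regressions,
        probes=probes,
        log=log,
    )


def _round(x, nd):
    return None if x is None else round(float(x), nd)


def _fit_rows(report: RegressionReport) -> list[dict[str, Any]]:
    rows = []
    fit = report.fit
    for step in fit.steps:
        entered = set(step.terms_entered)
        for coef in step.coefficients:
            if coef.term not in entered:
                continue
            rows.append(
                {
                    "env": report.env_label,
                    "outcome": report.outcome,
                    "step": step.step_index,
                    "term": coef.term,
                    "delta_r2": _round(step.delta_r2, 3),
                    "beta": _round(coef.beta, 3),
                    "B": _round(coef.B, 3),
                    "SE": _round(coef.SE, 3),
                    "p": _round(coef.p, 4),
                    "f_change": _round(step.f_change, 3),
                    "f_change_p": _round(step.p, 4),
                }
            )
    return rows


def _probe_rows(report: ProbeReport) -> dict[str, Any]:
    p = report.probe
    return {
        "env": report.env_label,
        "outcome": report.outcome,
        "slope_high": _round(p.slope_high.slope, 3),
        "slope_high_p": _round(p.slope_high.p, 4),
        "slope_low": _round(p.slope_low.slope, 3),
        "slope_low_p": _round(p.slope_low.p, 4),
        "crossover_sd": _round(p.crossover_x, 3),
        "ros_lower_sd": _round(p.ros_lower, 3),
        "ros_upper_sd": _round(p.ros_upper, 3),
        "PoI": _round(p.poi, 2),
        "PA": _round(p.pa, 2),
        "label": report.classification.label,
        "susceptible_group": report.classification.susceptible_group,
    }


def export_report(
    bundle: ReportBundle, out_dir: str | Path, fmt: str = "both"
) -> dict[str, Path]:
    """Write the machine-readable report and/or rounded text tables.

    The structured rendition keeps every number at full stored
    precision; text tables use the display rounding (B/SE/beta and RoS
    bounds to 3 decimals, PoI/PA to 2).
    """
    if fmt not in ("text", "structured", "both"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if fmt in ("structured", "both"):
        payload = schema._jsonable(bundle)
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        written["report"] = path

    if fmt in ("text", "both"):
        reg_rows = [r for rep in bundle.regressions for r in _fit_rows(rep)]
        reg_path = out_dir / "regressions.csv"
        pd.DataFrame(reg_rows).to_csv(reg_path, index=False)
        written["regressions"] = reg_path

        corr_path = out_dir / "correlations.csv"
        pd.DataFrame(
            [
                {
                    "var_a": e.var_a,
                    "var_b": e.var_b,
                    "r": _round(e.r, 3),
                    "p": _round(e.p, 4),
                    "n": e.n,
                }
                for e in bundle.correlations
            ]
        ).to_csv(corr_path, index=False)
        written["correlations"] = corr_path

        probe_path = out_dir / "probes.csv"
        if bundle.probes:
            pd.DataFrame([_probe_rows(p) for p in bundle.probes]).to_csv(
                probe_path, index=False
            )
        else:
            probe_path.write_text(
                "no interaction significant at alpha="
                f"{bundle.alpha}; nothing probed\n"
            )
        written["probes"] = probe_path

        plot_rows = []
        for rep in bundle.probes:
            fit = next(
                r.fit
                for r in bundle.regressions
                if r.env_label == rep.env_label and r.outcome == rep.outcome
            )
            for row in probing.plot_data(
                fit, eval_range=rep.probe.eval_range, alpha=rep.probe.alpha
            ):
                plot_rows.append(
                    {"env": rep.env_label, "outcome": rep.outcome, **row}
                )
        if plot_rows:
            plot_path = out_dir / "plot_data.csv"
            pd.DataFrame(plot_rows).to_csv(plot_path, index=False)
            written["plot_data"] = plot_path

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(bundle.log) + "\n", encoding="utf-8")
    written["log"] = log_path
    return written
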