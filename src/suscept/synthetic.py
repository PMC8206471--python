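"""Synthetic cohorts with plantable moderator-by-environment interactions.

Generates per-subject tables whose continuous block matches configurable
means, SDs and an 8x8 correlation target (scales + log moderator +
outcomes), whose moderator is lognormal, and whose demographics follow
declared category probabilities.  A planted interaction regime rewrites
one outcome from a moderated linear model with a configurable crossover
location, so every downstream stage can be tested against known truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import (
    CohortTable,
    DEPARTMENTS,
    MODERATOR_COLUMNS,
    OUTCOME_COLUMNS,
    SCALE_COLUMNS,
    SHIFT_PATTERNS,
)

CONTINUOUS_VARS = SCALE_COLUMNS + ("log_hcc",) + OUTCOME_COLUMNS

DEFAULT_MEANS = {
    "job_control": 62.38,
    "psych_demands": 33.69,
    "supervisor_support": 11.84,
    "coworker_support": 12.51,
    "ee": 3.42,
    "dp": 2.45,
    "pe": 4.12,
}
DEFAULT_SDS = {
    "job_control": 8.38,
    "psych_demands": 6.93,
    "supervisor_support": 1.84,
    "coworker_support": 1.50,
    "ee": 1.51,
    "dp": 1.33,
    "pe": 1.24,
}

# Lower triangle of the default correlation target, variable order as in
# CONTINUOUS_VARS.
_DEFAULT_CORR_LOWER = {
    ("psych_demands", "job_control"): -0.202,
    ("supervisor_support", "job_control"): 0.404,
    ("supervisor_support", "psych_demands"): -0.075,
    ("coworker_support", "job_control"): 0.268,
    ("coworker_support", "psych_demands"): 0.061,
    ("coworker_support", "supervisor_support"): 0.510,
    ("log_hcc", "job_control"): 0.079,
    ("log_hcc", "psych_demands"): -0.040,
    ("log_hcc", "supervisor_support"): 0.039,
    ("log_hcc", "coworker_support"): 0.000,
    ("ee", "job_control"): -0.250,
    ("ee", "psych_demands"): 0.470,
    ("ee", "supervisor_support"): -0.147,
    ("ee", "coworker_support"): -0.089,
    ("ee", "log_hcc"): -0.045,
    ("dp", "job_control"): -0.315,
    ("dp", "psych_demands"): 0.298,
    ("dp", "supervisor_support"): -0.223,
    ("dp", "coworker_support"): -0.179,
    ("dp", "log_hcc"): -0.040,
    ("dp", "ee"): 0.658,
    ("pe", "job_control"): 0.240,
    ("pe", "psych_demands"): -0.062,
    ("pe", "supervisor_support"): 0.116,
    ("pe", "coworker_support"): 0.120,
    ("pe", "log_hcc"): 0.034,
    ("pe", "ee"): -0.034,
    ("pe", "dp"): -0.163,
}


def default_correlation() -> np.ndarray:
    C = np.eye(len(CONTINUOUS_VARS))
    idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
    for (a, b), r in _DEFAULT_CORR_LOWER.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


#: Department probabilities in DEPARTMENTS order (ICU, EICU, emergency,
#: radiotherapy, psychology, rehabilitation, other).
DEFAULT_DEPARTMENT_PROBS = (0.1525, 0.0762, 0.3255, 0.0792, 0.0880, 0.1202, 0.1584)
DEFAULT_SHIFT_PROBS = (0.9003, 0.0997)
#: Tenure bands (<5, 5-15, >15 years) and their probabilities.
TENURE_BANDS = ((0.5, 5.0), (5.0, 15.0), (15.0, 30.0))
TENURE_BAND_PROBS = (0.4899, 0.3226, 0.1877)

DEFAULT_HCC_LOGMEAN = math.log10(3.3)
#: Log10-scale moderator SD consistent with the printed simple-slope pairs.
DEFAULT_HCC_LOGSD = 0.334

PATTERNS = (
    "differential_susceptibility",
    "vantage_sensitivity",
    "diathesis_stress",
    "null",
)


class SpecValidationError(ValueError):
    """A synthetic-cohort spec violates its invariants."""


class NonPSDCorrelationError(SpecValidationError):
    """The target correlation matrix is not positive semi-definite."""

    def __init__(self, smallest_eigenvalue: float):
        super().__init__(
            "correlation target is not positive semi-definite "
            f"(smallest eigenvalue {smallest_eigenvalue:.6g})"
        )
        self.smallest_eigenvalue = smallest_eigenvalue


@dataclass
class SyntheticSpec:
    """Full generative description of a synthetic cohort."""

    n: int = 341
    department_probs: tuple[float, ...] = DEFAULT_DEPARTMENT_PROBS
    shift_probs: tuple[float, ...] = DEFAULT_SHIFT_PROBS
    scale_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS)
    )
    scale_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SDS)
    )
    correlation: np.ndarray = field(default_factory=default_correlation)
    hcc_logmean: float = DEFAULT_HCC_LOGMEAN
    hcc_logsd: float = DEFAULT_HCC_LOGSD
    pattern: str | None = None
    pattern_env: str = "job_control"
    pattern_outcome: str = "pe"
    env_polarity: int = 1  # +1: higher env is supportive; -1: adverse
    coefficients: tuple[float, float, float, float] | None = None
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n < 1:
            raise SpecValidationError("n must be positive")
        for name, probs, k in (
            ("department_probs", self.department_probs, len(DEPARTMENTS)),
            ("shift_probs", self.shift_probs, len(SHIFT_PATTERNS)),
        ):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-6:
                raise SpecValidationError(
                    f"{name} must be {k} probabilities summing to 1"
                )
            if any(p < 0 for p in probs):
                raise SpecValidationError(f"{name} must be non-negative")
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (len(CONTINUOUS_VARS),) * 2:
            raise SpecValidationError(
                f"correlation must be {len(CONTINUOUS_VARS)}x{len(CONTINUOUS_VARS)}"
            )
        if not np.allclose(C, C.T, atol=1e-12):
            raise SpecValidationError("correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise SpecValidationError("correlation must have unit diagonal")
        if np.abs(C).max() > 1.0 + 1e-12:
            raise SpecValidationError("correlation entries must lie in [-1, 1]")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise NonPSDCorrelationError(float(w.min()))
        if self.noise_sd <= 0:
            raise SpecValidationError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 0.5:
            raise SpecValidationError("missing_rate must lie in [0, 0.5)")
        if self.pattern is not None and self.pattern not in PATTERNS:
            raise SpecValidationError(
                f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}"
            )
        if self.pattern_env not in SCALE_COLUMNS:
            raise SpecValidationError(f"unknown env {self.pattern_env!r}")
        if self.pattern_outcome not in OUTCOME_COLUMNS:
            raise SpecValidationError(f"unknown outcome {self.pattern_outcome!r}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["correlation"] = np.asarray(self.correlation).tolist()
        payload["department_probs"] = list(self.department_probs)
        payload["shift_probs"] = list(self.shift_probs)
        if self.coefficients is not None:
            payload["coefficients"] = list(self.coefficients)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticSpec":
        kwargs = dict(payload)
        if "correlation" in kwargs and kwargs["correlation"] is not None:
            kwargs["correlation"] = np.asarray(kwargs["correlation"], dtype=float)
        for key in ("department_probs", "shift_probs", "coefficients"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()


def _symmetric_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise NonPSDCorrelationError(float(w.min()))
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def plant_interaction(
    spec: SyntheticSpec,
    pattern: str | None = None,
    *,
    b_env_std: float = 0.5,
    b_int_std: float = 0.3,
) -> SyntheticSpec:
    """Return a spec with (b0, b_env, b_mod, b_int) set for a named regime.

    Effects are declared in per-SD units (``b_env_std`` outcome units per
    env SD, ``b_int_std`` per env-SD-by-moderator-SD) and converted to raw
    centered-predictor coefficients.  The implied crossover −b_mod/b_int
    sits at 0 env SD for differential susceptibility, at the supportive
    edge (+2 SD × polarity) for diathesis stress — so the planted group
    difference vanishes there and grows toward adversity — and at the
    adverse edge (−2 SD × polarity) for vantage sensitivity.  ``null``
    sets the interaction to zero.
    """
    pattern = pattern or spec.pattern
    if pattern not in PATTERNS:
        raise SpecValidationError(
            f"unknown pattern {pattern!r}; expected one of {PATTERNS}"
        )
    env_sd = spec.scale_sds[spec.pattern_env]
    mod_sd = spec.hcc_logsd
    b_env = b_env_std / env_sd
    b_int = b_int_std / (env_sd * mod_sd)
    b0 = spec.scale_means[spec.pattern_outcome]
    if pattern == "null":
        b_int = 0.0
        b_mod = 0.1 / mod_sd
    elif pattern == "differential_susceptibility":
        b_mod = 0.0  # crossover at the env mean
    elif pattern == "diathesis_stress":
        # crossover at the supportive edge: zero group difference there
        b_mod = -2.0 * spec.env_polarity * env_sd * b_int
    else:  # vantage_sensitivity
        # crossover at the adverse edge
        b_mod = 2.0 * spec.env_polarity * env_sd * b_int
    return dataclasses.replace(
        spec, pattern=pattern, coefficients=(b0, b_env, b_mod, b_int)
    )


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a cohort from the spec; fully reproducible from its seed."""
    spec.validate()
    if spec.pattern is not None and spec.coefficients is None:
        spec = plant_interaction(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    L = _symmetric_sqrt(np.asarray(spec.correlation, dtype=float))
    Z = rng.standard_normal((n, len(CONTINUOUS_VARS))) @ L.T

    df = pd.DataFrame({"subject_id": [f"S{i:05d}" for i in range(1, n + 1)]})
    df["department"] = rng.choice(DEPARTMENTS, size=n, p=spec.department_probs)
    df["shift_pattern"] = rng.choice(
        SHIFT_PATTERNS, size=n, p=spec.shift_probs
    )
    # printed band percentages sum to 100.02 from rounding; normalize
    band_p = np.asarray(TENURE_BAND_PROBS) / sum(TENURE_BAND_PROBS)
    band_idx = rng.choice(len(TENURE_BANDS), size=n, p=band_p)
    lo = np.array([TENURE_BANDS[i][0] for i in band_idx])
    hi = np.array([TENURE_BANDS[i][1] for i in band_idx])
    df["tenure_years"] = np.round(lo + (hi - lo) * rng.random(n), 2)

    for j, var in enumerate(CONTINUOUS_VARS):
        if var == "log_hcc":
            df[var] = spec.hcc_logmean + spec.hcc_logsd * Z[:, j]
        else:
            df[var] = spec.scale_means[var] + spec.scale_sds[var] * Z[:, j]
    df["hcc_raw"] = 10.0 ** df["log_hcc"]

    if spec.pattern is not None:
        b0, b_env, b_mod, b_int = spec.coefficients
        e_c = df[spec.pattern_env] - spec.scale_means[spec.pattern_env]
        m_c = df["log_hcc"] - spec.hcc_logmean
        df[spec.pattern_outcome] = (
            b0
            + b_env * e_c
            + b_mod * m_c
            + b_int * e_c * m_c
            + rng.normal(0.0, spec.noise_sd, n)
        )

    cols = (
        ["subject_id", "department", "shift_pattern", "tenure_years"]
        + list(SCALE_COLUMNS)
        + ["hcc_raw", "log_hcc"]
        + list(OUTCOME_COLUMNS)
    )
    table = CohortTable(df[cols], provenance=f"synthetic(seed={spec.seed})")
    table.validate()
    if spec.missing_rate > 0:
        table = inject_missing(table, spec.missing_rate, seed=spec.seed + 1)
    return table


def inject_missing(
    table: CohortTable,
    rate: float,
    seed: int,
    columns: tuple[str, ...] | None = None,
) -> CohortTable:
    """Mask eligible cells MCAR with the given probability (seeded).

    The moderator columns are never eligible.
    """
    if not 0.0 <= rate < 0.5:
        raise SpecValidationError("missing rate must lie in [0, 0.5)")
    if columns is None:
        columns = tuple(
            c
            for c in SCALE_COLUMNS + OUTCOME_COLUMNS
            if c in table.data.columns
        )
    for col in columns:
        if col in MODERATOR_COLUMNS:
            raise SpecValidationError(
                f"moderator column {col!r} may not be masked"
            )
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    mask = rng.random((len(df), len(columns))) < rate
    for j, col in enumerate(columns):
        df.loc[mask[:, j], col] = np.nan
    return CohortTable(df, table.provenance)


def default_spec_path() -> Path:
    return Path(__file__).parent / "data" / "default_spec.yaml"
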