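"""Synthetic cohort generator.

Emulates the data constellation the pipeline is built for: one or two
randomized cardiovascular-outcome-trial cohorts, a large cross-sectional
real-world target population with shifted covariates (older, lower HbA1c,
far lower prevalence of prior myocardial infarction/stroke), and a
longitudinal real-world new-user cohort with confounded exposure.

Covariates are drawn from a Gaussian copula: a latent multivariate normal
with the configured correlation matrix, transformed to the configured
normal marginals (continuous, clipped to schema range; the configured
standard deviations keep clipping mass negligible) or thresholded at the
configured prevalence (binary). Event times follow a Weibull
proportional-hazards model: S(t | x, a) = exp(-((rate * t)^shape) * m) with
subject multiplier m = exp(covariate terms + rule-based risk offsets +
a * (beta_t + rule-based effect modifiers)); observed time is the minimum
of event time, exponential dropout, and the administrative horizon.

All randomness is driven by named substreams derived from a single seed,
one per (source, stage), so adding a stage never reshuffles another
stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .schema import CovariateSchema, default_schema


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic named substream: one generator per (seed, key path)."""
    spawn = [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31, spawn_key=spawn))


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceSpec:
    """Marginal covariate model and follow-up design for one source."""

    n: int
    continuous: dict[str, tuple[float, float]]  # name -> (mean, sd)
    binary: dict[str, float]  # name -> prevalence in [0, 1]
    assignment: str | dict[str, float] | None = "randomized"
    # None => cross-sectional (no arm, no follow-up)
    baseline_shape: float = 1.0
    baseline_rate: float = 0.02  # per-year; S0(t) = exp(-(rate*t)^shape)
    horizon: float = 4.0  # administrative censoring, years
    dropout_rate: float = 0.02  # exponential dropout per year


@dataclass(frozen=True)
class OutcomeSpec:
    """Shared proportional-hazards outcome model."""

    treatment_loghr: float = 0.0
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    risk_rules: tuple[tuple[str, float], ...] = ()  # (pandas query, log-HR on hazard)
    effect_modifiers: tuple[tuple[str, float], ...] = ()  # (rule, extra treated log-HR)


@dataclass(frozen=True)
class ScenarioSpec:
    sources: dict[str, SourceSpec]
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    correlation: tuple[tuple[str, str, float], ...] = ()
    schema: CovariateSchema = field(default_factory=default_schema)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, src in self.sources.items():
            for name, prev in src.binary.items():
                if name not in self.schema:
                    raise ValueError(f"{label}: unknown covariate {name!r}")
                if not 0.0 <= prev <= 1.0:
                    raise ValueError(f"{label}: prevalence of {name!r} outside [0,1]")
            for name in src.continuous:
                if name not in self.schema:
                    raise ValueError(f"{label}: unknown covariate {name!r}")
            if src.baseline_shape <= 0 or src.baseline_rate <= 0:
                raise ValueError(f"{label}: Weibull shape and rate must be > 0")
            if src.horizon <= 0:
                raise ValueError(f"{label}: horizon must be > 0")
        for a, b, _ in self.correlation:
            for nm in (a, b):
                if nm not in self.schema:
                    raise ValueError(f"correlation references unknown covariate {nm!r}")
        # PSD check happens here, at validation time, not at sampling time
        names = self.schema.names
        R = self._corr_matrix(names)
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        for rule, _ in self.outcome.risk_rules + self.outcome.effect_modifiers:
            _validate_rule(rule, self.schema)

    def _corr_matrix(self, names: list[str]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(names)}
        R = np.eye(len(names))
        for a, b, rho in self.correlation:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        return R


def _validate_rule(rule: str, schema: CovariateSchema) -> None:
    probe = pd.DataFrame({n: [0.0] for n in schema.names})
    try:
        res = probe.eval(rule)
    except Exception as exc:  # noqa: BLE001 - surface any bad expression
        raise ValueError(f"invalid rule {rule!r}: {exc}") from exc
    if not np.issubdtype(np.asarray(res).dtype, np.bool_):
        raise ValueError(f"rule {rule!r} is not a boolean expression")


# ---------------------------------------------------------------------------
# sampling stages
# ---------------------------------------------------------------------------


def generate_covariates(
    spec: ScenarioSpec, source: str, n: int | None = None, seed: int | None = None
) -> CohortTable:
    """Draw baseline covariates for one source via the Gaussian copula."""
    src = spec.sources[source]
    n = src.n if n is None else n
    seed = spec.seed if seed is None else seed
    rng = rng_for(seed, source, "covariates")
    names = spec.schema.names
    R = spec._corr_matrix(names)
    # eigendecomposition is robust to semi-definite R
    vals, vecs = np.linalg.eigh(R)
    A = vecs * np.sqrt(np.clip(vals, 0, None))
    Z = rng.standard_normal((n, len(names))) @ A.T

    from scipy.stats import norm

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        cov = spec.schema[name]
        z = Z[:, j]
        if cov.kind == "continuous":
            mean, sd = src.continuous.get(name, (np.nan, np.nan))
            if np.isnan(mean):
                raise ValueError(f"{source}: no marginal for {name!r}")
            x = np.clip(mean + sd * z, cov.lo, cov.hi)
        else:
            prev = src.binary.get(name)
            if prev is None:
                raise ValueError(f"{source}: no marginal for {name!r}")
            x = (z < norm.ppf(np.clip(prev, 1e-300, 1.0))).astype(float)
            if prev == 0.0:
                x = np.zeros(n)
        data[name] = x

    df = pd.DataFrame(data)
    df.insert(0, "subject_id", [f"{source}-{i:06d}" for i in range(n)])
    df.insert(1, "source", source)
    df.insert(2, "arm", "none")
    return CohortTable(df, spec.schema)


def assign_treatment(
    cohort: CohortTable,
    mode: str | dict[str, float] = "randomized",
    seed: int = 0,
    stream: str = "assign",
) -> CohortTable:
    """Set the treatment arm: randomized 1:1 or confounded logistic.

    `mode` is either ``"randomized"`` (P(treated)=0.5 independent of
    covariates) or a coefficient dict ``{"intercept": a, cov: b, ...}``
    giving P(treated) = logistic(a + sum b * x).
    """
    df = cohort.df.copy()
    if (df["arm"] != "none").any():
        raise ValueError("arm already assigned")
    rng = rng_for(seed, str(df["source"].iloc[0]), stream)
    n = len(df)
    if mode == "randomized":
        p = np.full(n, 0.5)
    else:
        unknown = [k for k in mode if k != "intercept" and k not in cohort.schema]
        if unknown:
            raise ValueError(f"assignment coefficients reference unknown covariates: {unknown}")
        lp = np.full(n, float(mode.get("intercept", 0.0)))
        for name, coef in mode.items():
            if name == "intercept":
                continue
            lp += coef * df[name].to_numpy(dtype=float)
        p = 1.0 / (1.0 + np.exp(-lp))
    treated = rng.random(n) < p
    df["arm"] = np.where(treated, "treated", "control")
    return CohortTable(df, cohort.schema)


def hazard_multiplier(df: pd.DataFrame, outcome: OutcomeSpec) -> np.ndarray:
    """Per-subject log hazard multiplier under the PH outcome model."""
    lp = np.zeros(len(df))
    for name, coef in outcome.covariate_coefs.items():
        lp += coef * df[name].to_numpy(dtype=float)
    for rule, loghr in outcome.risk_rules:
        lp += loghr * df.eval(rule).to_numpy(dtype=float)
    treated = (df["arm"] == "treated").to_numpy(dtype=float)
    eff = np.full(len(df), outcome.treatment_loghr)
    for rule, extra in outcome.effect_modifiers:
        eff += extra * df.eval(rule).to_numpy(dtype=float)
    return lp + treated * eff


def true_loghr(df: pd.DataFrame, outcome: OutcomeSpec) -> np.ndarray:
    """Each subject's true conditional treatment log hazard ratio."""
    eff = np.full(len(df), outcome.treatment_loghr)
    for rule, extra in outcome.effect_modifiers:
        eff += extra * df.eval(rule).to_numpy(dtype=float)
    return eff


def simulate_survival(
    cohort: CohortTable, spec: ScenarioSpec, seed: int | None = None
) -> CohortTable:
    """Draw follow-up time and event flag from the Weibull PH model."""
    df = cohort.df.copy()
    source = str(df["source"].iloc[0])
    src = spec.sources[source]
    seed = spec.seed if seed is None else seed
    rng = rng_for(seed, source, "survival")
    n = len(df)
    if (df["arm"] == "none").any():
        raise ValueError("arm must be assigned before simulating survival")

    m = np.exp(hazard_multiplier(df, spec.outcome))
    u = rng.random(n)
    # S(t) = exp(-((rate t)^shape) m)  =>  T = (1/rate) (-ln u / m)^(1/shape)
    t_event = (1.0 / src.baseline_rate) * (-np.log(u) / m) ** (1.0 / src.baseline_shape)
    if src.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / src.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, src.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df["time"] = np.maximum(time, 1e-12)
    df["event"] = event
    return CohortTable(df, cohort.schema)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Trial covariate marginals: trial participants are younger, have higher
# HbA1c, and a much higher prevalence of prior MI/stroke than the target
# real-world population (~15% prior events, mean age ~70).
_TRIAL_CONT = {
    "age": (65.0, 8.3),
    "bmi": (31.8, 5.0),
    "hba1c": (8.7, 1.4),
    "diabetes_duration": (11.8, 5.5),
    "egfr": (77.0, 19.0),
}
# Non-anchored marginals (medication use, comorbidity flags) shift only
# moderately: the joint trial/target overlap is calibrated so the
# effective sample size after inverse-odds weighting lands near 15-25%
# of the trial, the regime the transposition workflow operates in.
_TRIAL_BIN = {
    "sex_male": 0.60,
    "prior_mi_stroke": 0.55,
    "prior_cvd": 0.78,
    "heart_failure": 0.14,
    "hypertension": 0.84,
    "pad": 0.10,
    "metformin": 0.78,
    "sulphonylurea": 0.40,
    "insulin": 0.35,
    "statin": 0.64,
    "antiplatelet": 0.48,
    "ras_blocker": 0.70,
    "beta_blocker": 0.45,
    "diuretic": 0.34,
    "ccb": 0.28,
    "dpp4i": 0.08,
}
# Continuous SDs are kept close to the trial's: grossly unequal variances
# would make the true log membership odds strongly quadratic, which the
# linear-logistic weight model is not meant to absorb.
# P(no prior event & age > 71) = 0.85 * P(z > (71-70.8)/9.5) = 0.41.
_TARGET_CONT = {
    "age": (70.8, 9.5),
    "bmi": (30.5, 5.0),
    "hba1c": (7.7, 1.3),
    "diabetes_duration": (10.5, 5.5),
    "egfr": (78.0, 19.0),
}
_TARGET_BIN = {
    "sex_male": 0.57,
    "prior_mi_stroke": 0.15,
    "prior_cvd": 0.25,
    "heart_failure": 0.10,
    "hypertension": 0.75,
    "pad": 0.08,
    "metformin": 0.80,
    "sulphonylurea": 0.30,
    "insulin": 0.25,
    "statin": 0.55,
    "antiplatelet": 0.35,
    "ras_blocker": 0.60,
    "beta_blocker": 0.35,
    "diuretic": 0.30,
    "ccb": 0.25,
    "dpp4i": 0.15,
}

# mild, shared dependence structure on the latent scale; age and
# prior_mi_stroke are kept independent so the subgroup-share calibration
# is exactly the product of the two marginals
_CORRELATION = (
    ("age", "egfr", -0.35),
    ("age", "hypertension", 0.20),
    ("age", "diabetes_duration", 0.30),
    ("bmi", "hba1c", 0.10),
    ("prior_cvd", "prior_mi_stroke", 0.60),
    ("prior_cvd", "statin", 0.25),
    ("prior_cvd", "antiplatelet", 0.30),
    ("insulin", "diabetes_duration", 0.30),
    ("heart_failure", "diuretic", 0.30),
)

# Control-arm 3.6-year risks calibrated to ~0.16 / 0.096 / 0.054 for the
# prior-event (A), no-prior-event >71y (B), and no-prior-event <=71y (C)
# groups; exponential baseline with group-C rate 0.01542/y.
_RATE_C = -np.log(1 - 0.054) / 3.6  # 0.015420
_RATE_B = -np.log(1 - 0.096) / 3.6  # 0.028034
_RATE_A = -np.log(1 - 0.160) / 3.6  # 0.048427

RULE_A = "prior_mi_stroke == 1"
RULE_B = "(prior_mi_stroke == 0) & (age > 71)"

_PAPER_LIKE_OUTCOME = OutcomeSpec(
    treatment_loghr=float(np.log(0.95)),
    risk_rules=(
        (RULE_A, float(np.log(_RATE_A / _RATE_C))),
        (RULE_B, float(np.log(_RATE_B / _RATE_C))),
    ),
    effect_modifiers=(
        (RULE_A, float(np.log(0.85 / 0.95))),
        (RULE_B, float(np.log(0.55 / 0.95))),
    ),
)


def _trial_source(n: int, rate: float = _RATE_C) -> SourceSpec:
    return SourceSpec(
        n=n,
        continuous=dict(_TRIAL_CONT),
        binary=dict(_TRIAL_BIN),
        assignment="randomized",
        baseline_rate=rate,
        horizon=4.0,
        dropout_rate=0.02,
    )


def _target_source(n: int) -> SourceSpec:
    return SourceSpec(
        n=n,
        continuous=dict(_TARGET_CONT),
        binary=dict(_TARGET_BIN),
        assignment=None,
    )


# Real-world new users: confounded channelling — younger, heavier, worse
# glycaemia and prior events push toward the exposed drug class.
RW_ASSIGNMENT = {
    "intercept": -2.4,
    "age": -0.03,
    "bmi": 0.06,
    "hba1c": 0.25,
    "prior_mi_stroke": 0.35,
    "heart_failure": 0.25,
}


def _rw_source(n: int, rate_factor: float = 1.66) -> SourceSpec:
    return SourceSpec(
        n=n,
        continuous=dict(_TARGET_CONT),
        binary=dict(_TARGET_BIN),
        assignment=dict(RW_ASSIGNMENT),
        baseline_rate=_RATE_C * rate_factor,
        horizon=5.0,
        dropout_rate=0.33,
    )


def preset(
    name: str,
    seed: int = 0,
    n_trial: int = 8000,
    n_target: int = 20000,
    n_rw: int = 10000,
) -> ScenarioSpec:
    """Named scenario presets.

    ``shifted_subgroups``
        Trial/target covariate shift with three benefit subgroups
        (prior MI/stroke; no prior event and age > 71; the rest) carrying
        hazard ratios 0.85 / 0.55 / 0.95 and distinct baseline risks, plus
        a confounded real-world new-user cohort.
    ``null_homogeneous``
        Same populations, zero treatment effect, no effect modification.
    ``no_shift``
        Trial and target identically distributed; homogeneous HR 0.87.
    ``confounded_rw``
        Matching test-bed: a single real-world cohort with confounded
        exposure and a homogeneous true exposure HR of 0.70.
    """
    n1 = int(round(n_trial * 0.73))  # larger trial ~73% of pooled n
    n2 = n_trial - n1
    if name == "shifted_subgroups":
        return ScenarioSpec(
            sources={
                "trial_1": _trial_source(n1, rate=_RATE_C),
                "trial_2": _trial_source(n2, rate=_RATE_C * 1.1),
                "target": _target_source(n_target),
                "rw": _rw_source(n_rw),
            },
            outcome=_PAPER_LIKE_OUTCOME,
            correlation=_CORRELATION,
            seed=seed,
        )
    if name == "null_homogeneous":
        return ScenarioSpec(
            sources={
                "trial_1": _trial_source(n1, rate=_RATE_B),
                "trial_2": _trial_source(n2, rate=_RATE_B),
                "target": _target_source(n_target),
                "rw": _rw_source(n_rw),
            },
            outcome=OutcomeSpec(
                treatment_loghr=0.0,
                risk_rules=_PAPER_LIKE_OUTCOME.risk_rules,
            ),
            correlation=_CORRELATION,
            seed=seed,
        )
    if name == "no_shift":
        trial = _trial_source(n1, rate=_RATE_B)
        return ScenarioSpec(
            sources={
                "trial_1": trial,
                "trial_2": replace(trial, n=n2),
                "target": SourceSpec(
                    n=n_target,
                    continuous=dict(_TRIAL_CONT),
                    binary=dict(_TRIAL_BIN),
                    assignment=None,
                ),
                "rw": _rw_source(n_rw),
            },
            outcome=OutcomeSpec(treatment_loghr=float(np.log(0.87))),
            correlation=_CORRELATION,
            seed=seed,
        )
    if name == "confounded_rw":
        return ScenarioSpec(
            sources={"rw": _rw_source(n_rw)},
            outcome=OutcomeSpec(
                treatment_loghr=float(np.log(0.70)),
                risk_rules=_PAPER_LIKE_OUTCOME.risk_rules,
            ),
            correlation=_CORRELATION,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------


@dataclass
class ScenarioBundle:
    """Generated cohorts keyed by source, plus the generating spec."""

    cohorts: dict[str, CohortTable]
    spec: ScenarioSpec

    def __getitem__(self, source: str) -> CohortTable:
        return self.cohorts[source]

    @property
    def trial(self) -> CohortTable:
        """All trial sources stacked into one cohort."""
        parts = [c.df for s, c in self.cohorts.items() if s.startswith("trial")]
        if not parts:
            raise KeyError("bundle has no trial sources")
        return CohortTable(pd.concat(parts, ignore_index=True), self.spec.schema)

    @property
    def target(self) -> CohortTable:
        return self.cohorts["target"]

    @property
    def rw(self) -> CohortTable:
        return self.cohorts["rw"]


def generate_scenario(
    spec: ScenarioSpec | str, seed: int | None = None, **preset_kwargs
) -> ScenarioBundle:
    """Generate every source of a scenario under one master seed."""
    if isinstance(spec, str):
        spec = preset(spec, seed=0 if seed is None else seed, **preset_kwargs)
    seed = spec.seed if seed is None else seed
    cohorts: dict[str, CohortTable] = {}
    for label in spec.sources:
        src = spec.sources[label]
        cohort = generate_covariates(spec, label, seed=seed)
        if src.assignment is not None:
            cohort = assign_treatment(cohort, src.assignment, seed=seed)
            cohort = simulate_survival(cohort, spec, seed=seed)
        cohorts[label] = cohort
    return ScenarioBundle(cohorts, replace(spec, seed=seed))
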