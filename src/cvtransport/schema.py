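"""Covariate schema: the variable dictionary shared by every cohort.

A :class:`CovariateSchema` names each baseline covariate, declares whether it
is continuous or binary, and carries the plausible range used for validation.
The default schema mirrors the variable set used for transferability and
heterogeneity analyses in cardiovascular outcome studies of glucose-lowering
drugs: demographics, glycaemic and renal measures, cardiovascular history
flags, and co-medication flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str  # "continuous" | "binary"
    unit: str = ""
    lo: float = float("-inf")
    hi: float = float("inf")

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate dictionary plus the outcome definition.

    Parameters
    ----------
    covariates : tuple of CovariateSpec
        Ordered covariate entries; names must be unique.
    outcome : str
        Name of the composite endpoint, ``"3P-MACE"`` for trial cohorts or
        ``"modified 3P-MACE"`` when all-cause death substitutes
        cardiovascular death (longitudinal real-world cohorts).
    """

    covariates: tuple[CovariateSpec, ...]
    outcome: str = "3P-MACE"

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate covariate names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def continuous(self) -> list[str]:
        return [c.name for c in self.covariates if c.kind == "continuous"]

    @property
    def binary(self) -> list[str]:
        return [c.name for c in self.covariates if c.kind == "binary"]

    def __getitem__(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.covariates)

    # -- plain key=value serialization ------------------------------------
    def to_config(self) -> str:
        lines = [f"outcome = {self.outcome}"]
        for c in self.covariates:
            lines.append(
                f"covariate = {c.name} : {c.kind} : {c.unit} : {c.lo} : {c.hi}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "CovariateSchema":
        outcome = "3P-MACE"
        covs: list[CovariateSpec] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "outcome":
                outcome = value
            elif key == "covariate":
                name, kind, unit, lo, hi = [p.strip() for p in value.split(":")]
                covs.append(CovariateSpec(name, kind, unit, float(lo), float(hi)))
            else:
                raise ValueError(f"unknown schema config key {key!r}")
        return cls(tuple(covs), outcome=outcome)


_CONTINUOUS = [
    ("age", "years", 18.0, 110.0),
    ("bmi", "kg/m2", 12.0, 80.0),
    ("hba1c", "%", 3.5, 20.0),
    ("diabetes_duration", "years", 0.0, 80.0),
    ("egfr", "mL/min/1.73m2", 1.0, 250.0),
]

_BINARY = [
    "sex_male",
    "prior_mi_stroke",
    "prior_cvd",
    "heart_failure",
    "hypertension",
    "pad",
    "metformin",
    "sulphonylurea",
    "insulin",
    "statin",
    "antiplatelet",
    "ras_blocker",
    "beta_blocker",
    "diuretic",
    "ccb",
    "dpp4i",
]


def default_schema(outcome: str = "3P-MACE") -> CovariateSchema:
    """The default variable dictionary (5 continuous + 16 binary covariates)."""
    covs = [
        CovariateSpec(n, "continuous", unit=u, lo=lo, hi=hi)
        for (n, u, lo, hi) in _CONTINUOUS
    ]
    covs += [CovariateSpec(n, "binary") for n in _BINARY]
    return CovariateSchema(tuple(covs), outcome=outcome)
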