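"""Reproducible multi-stage runs: simulate -> transpose -> discover ->
benefit -> match -> report.

A :class:`RunConfig` (round-trippable through YAML) fixes every stage's
settings and a single master seed; per-stage seeds are derived through a
fixed name-keyed scheme (`stage_seed`), so adding or removing a stage
never reshuffles another stage's random stream. Every stage writes plain
CSV/TXT artifacts plus a log with resolved settings, seeds and file
checksums; `emit_report` regenerates the human-readable summary from the
artifacts alone and is idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benefit import BenefitModel, BootstrapPlan
from .cohort import CohortTable, read_cohort, write_cohort
from .matching import MatchingModel
from .schema import default_schema
from .simulate import ScenarioBundle, generate_scenario, preset
from .subgroups import SubgroupDiscoveryModel
from .transport import TranspositionModel

logger = logging.getLogger("cvtransport")

ALL_STAGES = ("simulate", "transpose", "discover", "benefit", "match", "report")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(int(master) % 2**31, spawn_key=[zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    preset: str = "shifted_subgroups"
    seed: int = 0
    outdir: str = "cvtransport_run"
    stages: tuple[str, ...] = ALL_STAGES
    n_trial: int = 8000
    n_target: int = 20000
    n_rw: int = 10000
    cohort_paths: dict[str, str] = field(default_factory=dict)
    transpose_methods: tuple[str, ...] = ("LR", "BN")
    transpose_covariates: tuple[str, ...] = ()
    clip: tuple[float, float] = (0.005, 0.995)
    bn_bins: int = 5
    discover_covariates: tuple[str, ...] = ()
    max_depth: int = 2
    min_leaf: int = 200
    t_star: float = 3.6
    t_star_rw: float = 2.1
    n_resamples: int = 1000
    with_replacement: bool = True
    caliper: float | None = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(getattr(cls, f.name, None), tuple):
                d[f.name] = tuple(d[f.name])
        for key in ("stages", "transpose_methods", "transpose_covariates", "discover_covariates", "clip"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_artifact(path: Path) -> None:
    logger.info("wrote %s (sha256:%s)", path, _checksum(path))


def _load_cohorts(config: RunConfig) -> ScenarioBundle:
    if config.cohort_paths:
        schema = default_schema()
        cohorts = {
            label: read_cohort(p, schema) for label, p in config.cohort_paths.items()
        }
        spec = preset(config.preset, seed=config.seed)
        return ScenarioBundle(cohorts, spec)
    return generate_scenario(
        preset(
            config.preset,
            seed=stage_seed(config.seed, "simulate"),
            n_trial=config.n_trial,
            n_target=config.n_target,
            n_rw=config.n_rw,
        )
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; returns in-memory artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", dataclasses.asdict(config))
    artifacts: dict = {}

    stage = "simulate"
    try:
        bundle = _load_cohorts(config)
        artifacts["bundle"] = bundle
        if stage in config.stages and not config.cohort_paths:
            for label, cohort in bundle.cohorts.items():
                p = out / f"cohort_{label}.csv"
                write_cohort(cohort, p)
                _log_artifact(p)
            prov = {
                "preset": config.preset,
                "seed": config.seed,
                "stage_seed": stage_seed(config.seed, "simulate"),
                "n": {s: spec.n for s, spec in bundle.spec.sources.items()},
            }
            p = out / "provenance.yaml"
            p.write_text(yaml.safe_dump(prov))
            _log_artifact(p)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    trial_sources = sorted(s for s in bundle.cohorts if s.startswith("trial"))

    if "transpose" in config.stages:
        stage = "transpose"
        try:
            seed = stage_seed(config.seed, stage)
            covs = list(config.transpose_covariates) or None
            rows = []
            for src in trial_sources:
                for method in config.transpose_methods:
                    res = TranspositionModel(
                        bundle[src],
                        bundle.target,
                        covariates=covs,
                        method=method,
                        clip=config.clip,
                        bn_settings={"bins": config.bn_bins} if method == "BN" else None,
                    ).fit(seed=seed)
                    for est in (res.unweighted, res.transposed):
                        lo, hi = est.ci
                        rows.append(
                            {
                                "trial": src,
                                "method": est.method,
                                "HR": est.hr,
                                "CI_low": lo,
                                "CI_high": hi,
                                "n": est.n,
                                "events": est.events,
                                "ESS": est.ess if est.ess is not None else est.n,
                                "interaction_p": res.interaction_p,
                            }
                        )
            table = pd.DataFrame(rows).drop_duplicates(subset=["trial", "method"])
            artifacts["transposition"] = table
            p = out / "transposition.csv"
            table.to_csv(p, index=False)
            _log_artifact(p)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "discover" in config.stages:
        stage = "discover"
        try:
            seed = stage_seed(config.seed, stage)
            covs = list(config.discover_covariates) or None
            model = SubgroupDiscoveryModel(
                [bundle[s] for s in trial_sources],
                covariates=covs,
                max_depth=config.max_depth,
                min_leaf=config.min_leaf,
                extra_cohorts={"target": bundle.target},
            )
            disc = model.fit(seed=seed)
            artifacts["discovery"] = disc
            (out / "subgroup_tree.txt").write_text(disc.tree.to_text())
            _log_artifact(out / "subgroup_tree.txt")
            disc.ranking.table.to_csv(out / "modifier_ranking.csv", index=False)
            _log_artifact(out / "modifier_ranking.csv")
            disc.summary().to_csv(out / "subgroup_effects.csv", index=False)
            _log_artifact(out / "subgroup_effects.csv")
            disc.proportions.to_csv(out / "subgroup_proportions.csv")
            _log_artifact(out / "subgroup_proportions.csv")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "benefit" in config.stages:
        stage = "benefit"
        try:
            seed = stage_seed(config.seed, stage)
            tree = artifacts.get("discovery").tree if "discovery" in artifacts else None
            ben = BenefitModel(
                bundle.trial,
                tree,
                t_star=config.t_star,
                adjustments=tuple(bundle.spec.schema.names),
                plan=BootstrapPlan(n_resamples=config.n_resamples, seed=seed),
            ).fit()
            artifacts["benefit"] = ben
            ben.summary().to_csv(out / "benefit_report.csv", index=False)
            _log_artifact(out / "benefit_report.csv")
            trace = pd.DataFrame(
                {g: be.bootstrap_arrs for g, be in ben.benefits.items()}
            )
            trace.index.name = "resample"
            trace.to_csv(out / "benefit_bootstrap_trace.csv")
            _log_artifact(out / "benefit_bootstrap_trace.csv")
            extras = {}
            if ben.gail_simon_arr is not None:
                extras = {
                    "gail_simon_quantitative_p": ben.gail_simon_arr.p_quantitative,
                    "gail_simon_qualitative_p": ben.gail_simon_arr.p_qualitative,
                    "relative_interaction_p": ben.relative_interaction_p,
                }
            (out / "benefit_tests.json").write_text(json.dumps(extras, indent=1))
            _log_artifact(out / "benefit_tests.json")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "match" in config.stages and "rw" in bundle.cohorts:
        stage = "match"
        try:
            tree = artifacts.get("discovery").tree if "discovery" in artifacts else None
            mm = MatchingModel(
                bundle.rw,
                with_replacement=config.with_replacement,
                caliper=config.caliper,
                tree=tree,
            ).fit()
            artifacts["matching"] = mm
            mm.match.pairs.to_csv(out / "matched_pairs.csv", index=False)
            _log_artifact(out / "matched_pairs.csv")
            mm.balance.table.to_csv(out / "balance.csv", index=False)
            _log_artifact(out / "balance.csv")
            mm.summary().to_csv(out / "matched_effects.csv", index=False)
            _log_artifact(out / "matched_effects.csv")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "report" in config.stages:
        stage = "report"
        try:
            artifacts["report"] = emit_report(out)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    return artifacts


def emit_report(outdir) -> str:
    """Assemble the plain-text summary from saved stage artifacts.

    Sections whose artifacts are missing are marked "not run"; every
    number shown is read back from a CSV cell, so regeneration is
    idempotent.
    """
    out = Path(outdir)
    lines = ["cvtransport run summary", "=" * 40]

    def section(title: str, filename: str, render) -> None:
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        p = out / filename
        if not p.exists():
            lines.append("not run")
            return
        render(p)

    section(
        "Transposition (trial -> target population)",
        "transposition.csv",
        lambda p: lines.append(pd.read_csv(p).to_string(index=False)),
    )

    def _tree(p: Path) -> None:
        lines.append(p.read_text().rstrip())
        eff = out / "subgroup_effects.csv"
        if eff.exists():
            lines.append(pd.read_csv(eff).to_string(index=False))
        prop = out / "subgroup_proportions.csv"
        if prop.exists():
            lines.append("subgroup shares by population:")
            lines.append(pd.read_csv(prop, index_col=0).to_string())

    section("Subgroup discovery", "subgroup_tree.txt", _tree)

    def _benefit(p: Path) -> None:
        lines.append(pd.read_csv(p).to_string(index=False))
        tests = out / "benefit_tests.json"
        if tests.exists():
            for k, v in json.loads(tests.read_text()).items():
                lines.append(f"{k} = {v}")

    section("Clinical benefit (ARR / NNT)", "benefit_report.csv", _benefit)

    def _match(p: Path) -> None:
        lines.append(pd.read_csv(p).to_string(index=False))
        bal = out / "balance.csv"
        if bal.exists():
            t = pd.read_csv(bal)
            lines.append(
                f"balance: max after-SMD = {t['smd_after'].max():.3f} "
                f"({'pass' if bool((t['smd_after'] < 0.10).all()) else 'FAIL'})"
            )

    section("External-validation matching", "matched_effects.csv", _match)

    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
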