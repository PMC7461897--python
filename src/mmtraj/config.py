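"""Run configuration: YAML serialization of cohort, hazard and analysis specs.

The config file mirrors the simulation and analysis parameters::

    cohort:
      n_persons: 20000
      followup_years: 9.0
      baseline_lookback_years: 2.0
      p_female: 0.565
      p_age_55_64: 0.41
      covariates:
        income: {low: 0.3, mid: 0.4, high: 0.3}
    hazards:
      baseline_rate: {CANCER: 0.006, CVD: 0.008, ...}   # omitted -> defaults
      covariate_loghr:
        gender: {M: {CVD: 0.22}}
      progression_multiplier:
        uniform: 2.0                # every off-diagonal multiplier
        overrides:
          HYPERTENSION: {CVD: 4.0}  # applied on top of `uniform`
    analysis:
      window_years: 5.0
      fdr_q: 0.05
      tie_rule: canonical
      min_cell: 5
      covariates: [gender, age_band]
    seed: 1
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .conditions import CONDITIONS, Condition, as_condition
from .simulate import ILLUSTRATIVE_RATES, CohortSpec, HazardSpec, uniform_progression

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AnalysisSpec:
    """Parameters of the downstream analysis stages."""

    window_years: float = 5.0
    fdr_q: float = 0.05
    tie_rule: str = "canonical"
    min_cell: int = 5
    covariates: Sequence[str] = field(default_factory=tuple)

    def validate(self, cohort: CohortSpec | None = None) -> None:
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.tie_rule not in ("canonical", "collapse"):
            raise ValueError(f"unknown tie_rule: {self.tie_rule!r}")
        if self.min_cell < 0:
            raise ValueError("min_cell must be nonnegative")
        if cohort is not None:
            known = {"gender", "age_band", *cohort.covariates}
            for c in self.covariates:
                if c not in known:
                    raise ValueError(f"analysis covariate {c!r} not in cohort spec")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for a deterministic end-to-end pipeline run."""

    cohort: CohortSpec
    hazards: HazardSpec
    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.hazards.validate(self.cohort)
        self.analysis.validate(self.cohort)


def _hazards_from_dict(d: Mapping[str, Any]) -> HazardSpec:
    rates = {
        as_condition(k): float(v)
        for k, v in (d.get("baseline_rate") or dict(ILLUSTRATIVE_RATES)).items()
    }
    loghr: dict[tuple[str, str], dict[Condition, float]] = {}
    for cov, levels in (d.get("covariate_loghr") or {}).items():
        for level, per_cond in levels.items():
            loghr[(cov, str(level))] = {
                as_condition(c): float(v) for c, v in per_cond.items()
            }
    pm_cfg = d.get("progression_multiplier") or {}
    uniform = pm_cfg.get("uniform")
    mult: dict[Condition, dict[Condition, float]] = (
        uniform_progression(float(uniform)) if uniform is not None else {}
    )
    for a, row in (pm_cfg.get("overrides") or {}).items():
        ca = as_condition(a)
        mult.setdefault(ca, {})
        for c, v in row.items():
            mult[ca][as_condition(c)] = float(v)
    return HazardSpec(
        baseline_rate=rates, covariate_loghr=loghr, progression_multiplier=mult
    )


def _hazards_to_dict(h: HazardSpec) -> dict[str, Any]:
    loghr: dict[str, dict[str, dict[str, float]]] = {}
    for (cov, level), per_cond in h.covariate_loghr.items():
        loghr.setdefault(cov, {})[level] = {
            as_condition(c).value: float(v) for c, v in per_cond.items()
        }
    overrides = {
        as_condition(a).value: {
            as_condition(c).value: float(v) for c, v in row.items()
        }
        for a, row in h.progression_multiplier.items()
    }
    return {
        "baseline_rate": {
            c.value: float(h.baseline_rate.get(c, 0.0)) for c in CONDITIONS
        },
        "covariate_loghr": loghr,
        "progression_multiplier": {"overrides": overrides},
    }


def config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    cohort_d = dict(d.get("cohort") or {})
    if "n_persons" not in cohort_d:
        raise ValueError("config must set cohort.n_persons")
    cohort = CohortSpec(
        n_persons=int(cohort_d["n_persons"]),
        followup_years=float(cohort_d.get("followup_years", 9.0)),
        baseline_lookback_years=float(cohort_d.get("baseline_lookback_years", 2.0)),
        p_female=float(cohort_d.get("p_female", 0.565)),
        p_age_55_64=float(cohort_d.get("p_age_55_64", 0.41)),
        covariates={
            str(k): {str(l): float(p) for l, p in v.items()}
            for k, v in (cohort_d.get("covariates") or {}).items()
        },
        seed=int(d.get("seed", 0)),
    )
    analysis_d = dict(d.get("analysis") or {})
    analysis = AnalysisSpec(
        window_years=float(analysis_d.get("window_years", 5.0)),
        fdr_q=float(analysis_d.get("fdr_q", 0.05)),
        tie_rule=str(analysis_d.get("tie_rule", "canonical")),
        min_cell=int(analysis_d.get("min_cell", 5)),
        covariates=tuple(analysis_d.get("covariates") or ()),
    )
    cfg = RunConfig(
        cohort=cohort,
        hazards=_hazards_from_dict(d.get("hazards") or {}),
        analysis=analysis,
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    cohort = dataclasses.asdict(cfg.cohort)
    cohort.pop("seed", None)
    cohort["covariates"] = {
        k: dict(v) for k, v in cfg.cohort.covariates.items()
    }
    return {
        "cohort": cohort,
        "hazards": _hazards_to_dict(cfg.hazards),
        "analysis": {
            "window_years": cfg.analysis.window_years,
            "fdr_q": cfg.analysis.fdr_q,
            "tie_rule": cfg.analysis.tie_rule,
            "min_cell": cfg.analysis.min_cell,
            "covariates": list(cfg.analysis.covariates),
        },
        "seed": cfg.seed,
        "schema_version": SCHEMA_VERSION,
    }


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} is not a mapping")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the config."""
    canon = json.dumps(config_to_dict(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
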