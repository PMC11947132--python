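"""Shared data containers.

Pydantic models are used for objects that are read from / written to disk
(aggregate-data summaries and their components); plain dataclasses hold
computed results that carry numpy state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

Kind = Literal["continuous", "binary"]
ContrastScale = Literal["difference", "log_odds"]


class BaselineTarget(BaseModel):
    """One pooled baseline summary from the comparator (AgD) trial."""

    name: str
    kind: Kind
    value: float
    sd: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_proportion(self) -> "BaselineTarget":
        if self.kind == "binary" and not 0.0 <= self.value <= 1.0:
            raise ValueError(
                f"binary target {self.name!r} must be a proportion in [0, 1], got {self.value}"
            )
        return self


class ArmContrast(BaseModel):
    """An arm-vs-anchor effect estimate on a declared scale.

    ``scale='difference'`` carries an adjusted mean difference in endpoint
    units; ``scale='log_odds'`` a log-odds ratio. ``source`` distinguishes
    contrasts computed from (weighted) IPD from ones transcribed from a
    publication, which by construction carry no model terms.
    """

    endpoint: str
    scale: ContrastScale
    estimate: float
    se: float = Field(gt=0)
    source: Literal["ipd_weighted", "published"] = "published"
    n_or_ess: Optional[float] = None
    model_terms: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _published_has_no_terms(self) -> "ArmContrast":
        if self.source == "published" and self.model_terms:
            raise ValueError("published contrasts carry no model_terms")
        return self


class AgDSummary(BaseModel):
    """Aggregate-data view of the comparator trial.

    Holds the pooled baseline targets used for weighting plus the published
    arm-vs-placebo contrasts that enter the Bucher combination.
    """

    label: str = "comparator"
    n_active: int = Field(ge=1)
    n_anchor: int = Field(ge=1)
    baseline_targets: list[BaselineTarget] = Field(default_factory=list)
    published_contrasts: list[ArmContrast] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_targets(self) -> "AgDSummary":
        names = [t.name for t in self.baseline_targets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate baseline targets: {dupes}")
        return self

    @property
    def n_total(self) -> int:
        return self.n_active + self.n_anchor

    def target(self, name: str) -> BaselineTarget:
        for t in self.baseline_targets:
            if t.name == name:
                return t
        available = [t.name for t in self.baseline_targets]
        raise KeyError(f"covariate {name!r} absent from aggregate targets {available}")

    def contrast(self, endpoint: str) -> Optional[ArmContrast]:
        for c in self.published_contrasts:
            if c.endpoint == endpoint:
                return c
        return None


@dataclass
class WeightSet:
    """MAIC weights with solver state and effective sample sizes."""

    weights: np.ndarray
    beta: np.ndarray
    covariate_names: list[str]
    converged: bool
    iterations: int
    objective_value: float
    ess_total: float
    ess_by_arm: dict[str, float] = field(default_factory=dict)
    gradient_norm: float = math.nan
    rescale_mode: str = "raw"

    @property
    def n(self) -> int:
        return int(self.weights.shape[0])

    def diagnostics(self) -> dict:
        return {
            "beta": {k: float(b) for k, b in zip(self.covariate_names, self.beta)},
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "gradient_max_norm": float(self.gradient_norm),
            "objective_value": float(self.objective_value),
            "ess_total": float(self.ess_total),
            "ess_by_arm": {k: float(v) for k, v in self.ess_by_arm.items()},
            "n_patients": self.n,
            "rescale_mode": self.rescale_mode,
        }


@dataclass
class BalanceRow:
    """One covariate's before- or after-matching comparison line."""

    covariate: str
    kind: Kind
    ipd_value: dict[str, float]       # active / anchor / pooled
    ipd_sd: dict[str, float | None]
    agd_value: float
    agd_sd: float | None
    n_or_ess: dict[str, float]        # active / anchor / pooled / agd
    test_name: str
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "kind": self.kind,
            "ipd_active": self.ipd_value["active"],
            "ipd_anchor": self.ipd_value["anchor"],
            "ipd_pooled": self.ipd_value["pooled"],
            "ipd_sd_pooled": self.ipd_sd["pooled"],
            "agd_value": self.agd_value,
            "agd_sd": self.agd_sd,
            "ess_active": self.n_or_ess["active"],
            "ess_anchor": self.n_or_ess["anchor"],
            "ess_pooled": self.n_or_ess["pooled"],
            "n_agd": self.n_or_ess["agd"],
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


@dataclass
class IndirectResult:
    """Bucher-combined indirect estimate for one endpoint.

    ``scale='difference'`` reports a mean difference in endpoint units;
    ``scale='odds_ratio'`` reports the exponentiated combined log-OR, with
    ``se_combined`` kept on the log scale.
    """

    endpoint: str
    scale: Literal["difference", "odds_ratio"]
    estimate: float
    ci_low: float
    ci_high: float
    se_combined: float
    z: float
    p_value: float
    components: tuple[ArmContrast, ArmContrast]

    def to_dict(self) -> dict:
        c1, c2 = self.components
        return {
            "endpoint": self.endpoint,
            "scale": self.scale,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se_combined": self.se_combined,
            "z": self.z,
            "p_value": self.p_value,
            "ipd_estimate": c1.estimate,
            "ipd_se": c1.se,
            "comparator_estimate": c2.estimate,
            "comparator_se": c2.se,
        }
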