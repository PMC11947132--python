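"""Model/Results surface for the anchored MAIC.

``AnchoredMAIC`` is constructed from a patient-level trial table and the
comparator's aggregate summary; ``fit()`` estimates the matching weights,
fits the weighted outcome models, combines each endpoint with its published
comparator contrast, and returns an :class:`AnchoredMAICResults` carrying
estimates, standard errors, balance diagnostics and a ``summary()`` table.
"""
from __future__ import annotations

import logging
from functools import cached_property
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .balance import balance_frame, balance_table
from .bucher import compare_all
from .containers import AgDSummary, ArmContrast, IndirectResult, WeightSet
from .exceptions import MAICError
from .outcomes import (
    DEFAULT_ADJUSTERS,
    bootstrap_ancova_se,
    weighted_ancova,
    weighted_logodds,
)
from .scenarios import MATCHABLE_COVARIATES
from .weights import center_covariates, estimate_weights, rescale_weights

logger = logging.getLogger(__name__)


class AnchoredMAIC:
    """Anchored matching-adjusted indirect comparison of two trials.

    Parameters
    ----------
    ipd : DataFrame
        Patient-level table of the index trial (one row per patient; see
        :data:`anchormaic.io.IPD_REQUIRED` for the column schema).
    agd : AgDSummary
        Aggregate baselines and published arm-vs-placebo contrasts of the
        comparator trial.
    covariates : sequence of str
        Baseline covariates whose weighted pooled means/proportions must
        match the aggregate targets exactly.
    endpoints : sequence of (name, scale) pairs, optional
        Endpoints to compare; scale is ``'difference'`` or ``'log_odds'``.
        Defaults to every published comparator endpoint present in the IPD.
    adjusters : sequence of str
        Terms of the outcome ANCOVA (treatment indicator, center fixed
        effects, baseline OFF time).
    """

    def __init__(
        self,
        ipd: pd.DataFrame,
        agd: AgDSummary,
        covariates: Sequence[str] = MATCHABLE_COVARIATES,
        endpoints: Optional[Sequence[tuple[str, str]]] = None,
        adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    ):
        if not list(covariates):
            raise MAICError("at least one matched covariate is required")
        complete = ipd.dropna(subset=list(covariates))
        dropped = len(ipd) - len(complete)
        if dropped:
            logger.warning(
                "complete-case analysis: dropped %d patient(s) with missing "
                "matched covariates", dropped,
            )
        self.ipd = complete.reset_index(drop=True)
        self.agd = agd
        self.covariates = list(covariates)
        self.adjusters = list(adjusters)
        if endpoints is None:
            endpoints = [
                (c.endpoint, c.scale)
                for c in agd.published_contrasts
                if c.endpoint in self.ipd.columns
            ]
        self.endpoints = list(endpoints)
        self.n_dropped = dropped

    @classmethod
    def from_files(cls, ipd_path, agd_path, **kwargs) -> "AnchoredMAIC":
        return cls(_io.read_ipd(ipd_path), _io.read_agd(agd_path), **kwargs)

    def fit(
        self,
        se_method: str = "sandwich",
        rescale: str = "mean_one",
        bootstrap_resamples: int = 1000,
        seed: Optional[int] = None,
    ) -> "AnchoredMAICResults":
        """Estimate weights, fit outcome models, and combine with Bucher."""
        if se_method not in ("sandwich", "bootstrap"):
            raise MAICError(f"unknown se_method {se_method!r}")
        arms = self.ipd["arm"].to_numpy()
        centered = center_covariates(self.ipd, self.agd, self.covariates)
        ws = estimate_weights(centered, self.covariates, arms=arms)
        ws = rescale_weights(ws, rescale)

        contrasts: list[ArmContrast] = []
        for name, scale in self.endpoints:
            if scale == "difference":
                c = weighted_ancova(self.ipd, ws.weights, name, self.adjusters)
                if se_method == "bootstrap":
                    se = bootstrap_ancova_se(
                        self.ipd, self.agd, self.covariates, name,
                        self.adjusters, bootstrap_resamples,
                        seed=0 if seed is None else seed,
                    )
                    c = c.model_copy(
                        update={"se": se, "model_terms": c.model_terms + ["bootstrap_se"]}
                    )
            elif scale == "log_odds":
                c = weighted_logodds(self.ipd, ws.weights, name)
            else:
                raise MAICError(f"unknown endpoint scale {scale!r} for {name!r}")
            contrasts.append(c)

        indirect = compare_all(contrasts, self.agd)
        return AnchoredMAICResults(self, ws, contrasts, indirect)


class AnchoredMAICResults:
    """Fitted anchored-MAIC results: weights, contrasts, combined estimates."""

    def __init__(
        self,
        model: AnchoredMAIC,
        weightset: WeightSet,
        ipd_contrasts: list[ArmContrast],
        indirect_results: list[IndirectResult],
    ):
        self.model = model
        self.weightset = weightset
        self.ipd_contrasts = ipd_contrasts
        self.indirect_results = indirect_results

    # balance tables are computed on demand: the calibration studies fit
    # thousands of models and never look at them.
    @cached_property
    def balance_before(self):
        return balance_table(self.model.ipd, None, self.model.agd, self.model.covariates)

    @cached_property
    def balance_after(self):
        return balance_table(
            self.model.ipd, self.weightset.weights, self.model.agd, self.model.covariates
        )

    @property
    def ess(self) -> float:
        return self.weightset.ess_total

    def result(self, endpoint: str) -> IndirectResult:
        for r in self.indirect_results:
            if r.endpoint == endpoint:
                return r
        raise KeyError(endpoint)

    def frame(self) -> pd.DataFrame:
        """Indirect results, one row per endpoint."""
        return pd.DataFrame([r.to_dict() for r in self.indirect_results])

    def weights_frame(self) -> pd.DataFrame:
        w = self.weightset
        raw = np.exp(
            center_covariates(self.model.ipd, self.model.agd, self.model.covariates)
            @ w.beta
        )
        return pd.DataFrame(
            {"id": self.model.ipd["id"], "raw_weight": raw, "weight": w.weights}
        )

    def summary(self) -> str:
        m, w = self.model, self.weightset
        n = len(m.ipd)
        lines = [
            "Anchored matching-adjusted indirect comparison",
            "=" * 78,
            f"IPD trial: n = {n} (active {int((m.ipd['arm'] == 'active').sum())}, "
            f"anchor {int((m.ipd['arm'] == 'anchor').sum())})",
            f"Comparator ({m.agd.label}): n = {m.agd.n_total} "
            f"(active {m.agd.n_active}, anchor {m.agd.n_anchor})",
            f"Matched covariates: {', '.join(m.covariates)}",
            f"ESS after weighting: {w.ess_total:.1f} of {n} "
            f"({100 * w.ess_total / n:.1f}%)"
            + (
                "  [active {a:.1f} / anchor {b:.1f}]".format(
                    a=w.ess_by_arm.get("active", float("nan")),
                    b=w.ess_by_arm.get("anchor", float("nan")),
                )
                if w.ess_by_arm
                else ""
            ),
            f"Weight solver: converged={w.converged} in {w.iterations} iteration(s), "
            f"gradient max-norm {w.gradient_norm:.2e}",
            "-" * 78,
            f"{'endpoint':<24}{'scale':<12}{'IPD (SE)':<17}{'AgD (SE)':<17}"
            f"{'combined [95% CI]':<26}{'p':>6}",
        ]
        for r in self.indirect_results:
            c1, c2 = r.components
            if r.scale == "odds_ratio":
                ipd_s = f"{np.exp(c1.estimate):.2f} ({c1.se:.2f})"
                agd_s = f"{np.exp(c2.estimate):.2f} ({c2.se:.2f})"
            else:
                ipd_s = f"{c1.estimate:.2f} ({c1.se:.2f})"
                agd_s = f"{c2.estimate:.2f} ({c2.se:.2f})"
            comb = f"{r.estimate:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
            lines.append(
                f"{r.endpoint:<24}{r.scale:<12}{ipd_s:<17}{agd_s:<17}{comb:<26}"
                f"{r.p_value:>6.3f}"
            )
        lines.append("=" * 78)
        return "\n".join(lines)

    def save(self, outdir, stamp: Optional[dict] = None) -> dict[str, str]:
        """Write weights CSV, balance tables, contrasts and results; returns paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        stamp = stamp or {}
        paths = {}

        def _p(name):
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        self.weights_frame().to_csv(_p("weights.csv"), index=False)
        _io.write_json(
            {**stamp, "diagnostics": self.weightset.diagnostics()}, _p("weights.json")
        )
        balance_frame(self.balance_before).to_csv(
            _p("balance_before.tsv"), sep="\t", index=False
        )
        balance_frame(self.balance_after).to_csv(
            _p("balance_after.tsv"), sep="\t", index=False
        )
        _io.write_json(
            {
                **stamp,
                "before": [r.to_dict() for r in self.balance_before],
                "after": [r.to_dict() for r in self.balance_after],
            },
            _p("balance.json"),
        )
        _io.write_json(
            {**stamp, "contrasts": [c.model_dump() for c in self.ipd_contrasts]},
            _p("contrasts.json"),
        )
        self.frame().to_csv(_p("indirect_results.tsv"), sep="\t", index=False)
        _io.write_json(
            {**stamp, "results": [r.to_dict() for r in self.indirect_results]},
            _p("indirect_results.json"),
        )
        with open(_p("summary.txt"), "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
        return paths

    def plot_weights(self, ax=None):
        """Histogram of the rescaled weights (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.weightset.weights, bins=30, color="#4477aa")
        ax.set_xlabel("MAIC weight")
        ax.set_ylabel("patients")
        ax.set_title(f"ESS = {self.ess:.1f} of {self.weightset.n}")
        return ax
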