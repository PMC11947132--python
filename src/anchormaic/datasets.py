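"""Published summary statistics of the two source trials.

These are the aggregate numbers printed in the safinamide (XINDI,
NCT03881371) and rasagiline (Study 1, NCT01479530) trial reports and in the
published MAIC of the two: pooled baselines, and the per-trial
active-vs-placebo least-squares-mean contrasts (SE) at week 16. They are
inputs to the recombination analyses; the patient-level XINDI data are
proprietary and are emulated by :mod:`anchormaic.scenarios`.

Safety rows: the published per-trial safety values (e.g. AEs 1.9 (0.26))
are stored under the odds-ratio reading — the printed value is the arm-vs-
placebo OR and the bracketed value its log-scale SE. That reading
reproduces the published combined SAE and discontinuation ORs (1.1, 0.7)
but gives 1.73 rather than the printed 1.6 for AEs; the original safety
pipeline cannot be pinned down from the report, so no test forces the AE
row.
"""
from __future__ import annotations

import math

from .containers import AgDSummary, ArmContrast, BaselineTarget

# Pooled XINDI baselines (N = 305): mean, SD (None for proportions), n.
XINDI_POOLED_BASELINE: dict[str, tuple[float, float | None, int]] = {
    "age": (61.6, 9.3, 305),
    "male": (0.580, None, 305),
    "bmi": (23.9, 3.0, 305),
    "off_baseline": (5.7, 3.0, 305),
}

_STUDY1_TARGETS = [
    BaselineTarget(name="age", kind="continuous", value=62.2, sd=9.4),
    BaselineTarget(name="male", kind="binary", value=0.660),
    BaselineTarget(name="bmi", kind="continuous", value=23.1, sd=3.2),
    BaselineTarget(name="off_baseline", kind="continuous", value=6.1, sd=2.6),
]

# (endpoint, LSM difference vs placebo, SE) at week 16.
_XINDI_EFFICACY = [
    ("off_change", -1.2, 0.28),
    ("updrs3_change", -4.5, 0.96),
    ("pdq39_summary_change", -4.0, 1.08),
    ("adl_change", -6.7, 1.74),
    ("emotional_change", -5.6, 1.69),
    ("mobility_change", -6.0, 1.57),
    ("stigma_change", -6.4, 1.99),
]
_STUDY1_EFFICACY = [
    ("off_change", -0.5, 0.22),
    ("updrs3_change", -1.6, 0.74),
    ("pdq39_summary_change", -1.8, 1.12),
    ("adl_change", -6.1, 1.76),
    ("emotional_change", -2.4, 2.00),
    ("mobility_change", -2.5, 1.56),
    ("stigma_change", -2.5, 1.92),
]
# (endpoint, printed OR vs placebo, log-scale SE) under the OR reading.
_XINDI_SAFETY = [("ae", 1.9, 0.26), ("sae", 1.5, 0.62), ("dcae", 0.8, 0.52)]
_STUDY1_SAFETY = [("ae", 1.1, 0.23), ("sae", 1.4, 0.60), ("dcae", 1.2, 0.62)]


def _contrasts(efficacy, safety) -> list[ArmContrast]:
    out = [
        ArmContrast(endpoint=e, scale="difference", estimate=est, se=se)
        for e, est, se in efficacy
    ]
    out += [
        ArmContrast(endpoint=e, scale="log_odds", estimate=math.log(orr), se=se)
        for e, orr, se in safety
    ]
    return out


def study1_aggregate() -> AgDSummary:
    """Study 1 as the aggregate-data comparator: baselines plus published contrasts."""
    return AgDSummary(
        label="study1_rasagiline",
        n_active=163,
        n_anchor=158,
        baseline_targets=[t.model_copy() for t in _STUDY1_TARGETS],
        published_contrasts=_contrasts(_STUDY1_EFFICACY, _STUDY1_SAFETY),
    )


def xindi_weighted_contrasts() -> list[ArmContrast]:
    """The published post-matching safinamide-vs-placebo contrasts."""
    return _contrasts(_XINDI_EFFICACY, _XINDI_SAFETY)
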