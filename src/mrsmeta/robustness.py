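"""Leave-one-out robustness, CI-overlap outliers, and outlier reporting rules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .datasets import RegionalCollection
from .effects import EffectSize, hedges_g
from .meta import MetaResult, pool_random_effects

__all__ = [
    "RobustnessReport",
    "ExclusionDecision",
    "leave_one_out",
    "detect_outliers",
    "outlier_exclusion_policy",
    "outlier_report",
]


@dataclass
class RobustnessReport:
    """Leave-one-out refits plus outlier bookkeeping for one meta-analysis.

    ``robust`` is True when the full model is significant and every
    leave-one-out refit stays significant; False when some refit loses
    significance; None when the full model is not significant (robustness
    undefined).
    """

    loo_results: list[MetaResult]
    left_out_ids: list[str]
    robust: bool | None
    outliers: list[str] = field(default_factory=list)
    result_without_outliers: MetaResult | None = None


@dataclass(frozen=True)
class ExclusionDecision:
    report: bool
    reason: str


def leave_one_out(
    collection: RegionalCollection,
    full_result: MetaResult | None = None,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Refit the pooled model k times, leaving out one dataset each time.

    A significant result is robust iff it stays significant in every refit.
    """
    datasets = list(collection)
    k = len(datasets)
    if k < 3:
        raise ValueError("leave-one-out needs at least 3 datasets")
    effects = [hedges_g(d) for d in datasets]
    if full_result is None:
        full_result = pool_random_effects(effects)
    loo = [
        pool_random_effects(effects[:i] + effects[i + 1 :])
        for i in range(k)
    ]
    if full_result.p_omnibus < alpha:
        robust = all(r.p_omnibus < alpha for r in loo)
    else:
        robust = None  # not applicable
    return RobustnessReport(
        loo_results=loo,
        left_out_ids=[d.study_id for d in datasets],
        robust=robust,
    )


def detect_outliers(
    collection: RegionalCollection,
    full_result: MetaResult,
    effects: Sequence[EffectSize] | None = None,
) -> list[str]:
    """Datasets whose 95% CI does not overlap the pooled 95% CI.

    Intervals touching at an endpoint count as overlapping.  Outlier status
    is always relative to the model the result came from, so moderator
    analyses re-derive their own outliers.
    """
    datasets = list(collection)
    if effects is None:
        effects = [hedges_g(d) for d in datasets]
    out = []
    for d, e in zip(datasets, effects):
        if e.ci_hi < full_result.ci_lo or e.ci_lo > full_result.ci_hi:
            out.append(d.study_id)
    return out


def outlier_exclusion_policy(
    full_result: MetaResult,
    reduced_result: MetaResult,
    alpha: float = 0.05,
) -> ExclusionDecision:
    """Decide whether the outlier-excluded result must also be reported.

    Reported iff excluding outliers flips significance at ``alpha``, or the
    full model is significant and the effect size changes by at least one
    third of its magnitude.
    """
    full_sig = full_result.p_omnibus < alpha
    red_sig = reduced_result.p_omnibus < alpha
    if full_sig != red_sig:
        return ExclusionDecision(True, "significance status changed")
    if full_sig:
        if full_result.pooled_g == 0:
            return ExclusionDecision(False, "full effect is zero; only the significance criterion applies")
        rel = abs(reduced_result.pooled_g - full_result.pooled_g) / abs(full_result.pooled_g)
        if rel >= 1.0 / 3.0:
            return ExclusionDecision(True, f"effect size changed by {100 * rel:.1f}% (>= 1/3)")
        return ExclusionDecision(False, f"effect size changed by {100 * rel:.1f}% (< 1/3)")
    return ExclusionDecision(False, "not significant before or after exclusion")


def outlier_report(
    collection: RegionalCollection,
    full_result: MetaResult,
    alpha: float = 0.05,
) -> RobustnessReport:
    """Full robustness pass: leave-one-out, outliers, and the reduced refit."""
    report = leave_one_out(collection, full_result, alpha=alpha)
    report.outliers = detect_outliers(collection, full_result)
    if report.outliers and len(collection) - len(report.outliers) >= 2:
        reduced = collection.without(report.outliers)
        report.result_without_outliers = pool_random_effects(
            [hedges_g(d) for d in reduced]
        )
    return report
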