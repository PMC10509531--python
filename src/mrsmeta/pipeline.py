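"""Full analysis orchestration: one pass per region x metabolite.

Stage order per analysis: eligibility -> effect sizes -> Egger test (with
optional single-study removal) -> primary random-effects pool -> weighted
percent difference -> outlier pass + exclusion-reporting rule ->
leave-one-out robustness -> quality-threshold scans (each metric with >= 14
reporting datasets) -> moderator analyses (ln TE, field split at 3 T,
normalization split, age, % male, % medicated, illness-duration split at
36 months).  Stage failures are logged and the remaining analyses continue.
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datasets import (
    Exclusion,
    Metabolite,
    Region,
    RegionalCollection,
    StudyDataset,
    apply_eligibility,
    read_corpus,
    resolve_duplicates,
    write_exclusion_log,
)
from .effects import hedges_g, weighted_percent_difference
from .meta import (
    EggerResult,
    MetaResult,
    RegressionResult,
    egger_test,
    meta_regress,
    pool_random_effects,
    remove_small_study_bias,
    subgroup_compare,
)
from .quality import QualityMetric, compute_profiles
from .robustness import RobustnessReport, outlier_exclusion_policy, outlier_report
from .threshold import InsufficientData, MIN_DATASETS_FOR_STRATIFICATION, ThresholdScan, quality_threshold_scan, scan_table

__all__ = ["AnalysisConfig", "AnalysisResult", "ResultBundle", "run_full_analysis"]

_P_FLOOR = sys.float_info.epsilon

SHORT_TE_MS = 35.0          # short vs long echo-time split
RECENT_ONSET_MONTHS = 36.0  # recent-onset vs chronic split
HIGH_FIELD_T = 3.0


@dataclass
class AnalysisConfig:
    input_path: str | Path
    out_dir: str | Path
    regions: tuple[str, ...] | None = None        # None = all present
    metabolites: tuple[str, ...] | None = None
    quality_metrics: tuple[str, ...] = ("cov", "crlb", "fwhm", "snr")
    alpha: float = 0.05
    run_egger_removal: bool = True
    run_outlier_pass: bool = True
    run_loo: bool = True
    run_threshold_scans: bool = True
    run_moderators: bool = True
    bh_correction: bool = False
    min_group_n: int = 8
    min_region_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass
class ModeratorOutcome:
    name: str
    kind: str                      # "meta_regression" | "subgroup"
    result: RegressionResult | None
    skipped_reason: str | None = None


@dataclass
class AnalysisResult:
    region: Region
    metabolite: Metabolite
    collection: RegionalCollection
    primary: MetaResult
    pct_diff: float
    egger: EggerResult | None
    egger_removed: list[dict]
    robustness: RobustnessReport | None
    outlier_decision: object | None
    scans: dict[str, ThresholdScan]
    moderators: list[ModeratorOutcome]


@dataclass
class ResultBundle:
    analyses: list[AnalysisResult]
    exclusions: list[Exclusion]
    log: list[str]


def _clamp_p(p: float) -> float:
    return max(float(p), _P_FLOOR)


def _moderator_analyses(
    collection: RegionalCollection, alpha: float, log: list[str]
) -> list[ModeratorOutcome]:
    tag = f"{collection.region.value}/{collection.metabolite.value}"
    datasets = list(collection)
    effects = [hedges_g(d) for d in datasets]
    outcomes: list[ModeratorOutcome] = []

    def metareg(name: str, values: list[float | None]):
        present = [(d, e, v) for d, e, v in zip(datasets, effects, values) if v is not None]
        if len(present) < 4:
            outcomes.append(ModeratorOutcome(name, "meta_regression", None,
                                             f"only {len(present)} datasets report {name}"))
            return
        try:
            res = meta_regress([e for _, e, _ in present], {name: [v for *_, v in present]})
            outcomes.append(ModeratorOutcome(name, "meta_regression", res))
        except ValueError as exc:
            outcomes.append(ModeratorOutcome(name, "meta_regression", None, str(exc)))
            log.append(f"{tag}: moderator {name} skipped: {exc}")

    def subgroup(name: str, labels: list[str | None]):
        present = [(d, e, l) for d, e, l in zip(datasets, effects, labels) if l is not None]
        counts = pd.Series([l for *_, l in present]).value_counts()
        if len(counts) != 2 or counts.min() < 2:
            outcomes.append(ModeratorOutcome(name, "subgroup", None,
                                             f"subgroup sizes unsuitable: {counts.to_dict()}"))
            return
        try:
            res = subgroup_compare([d for d, *_ in present], [l for *_, l in present],
                                   effects=[e for _, e, _ in present])
            outcomes.append(ModeratorOutcome(name, "subgroup", res))
        except ValueError as exc:
            outcomes.append(ModeratorOutcome(name, "subgroup", None, str(exc)))
            log.append(f"{tag}: moderator {name} skipped: {exc}")

    metareg("ln_te", [math.log(d.te_ms) for d in datasets])
    subgroup("field_ge_3T", ["high" if d.field_T >= HIGH_FIELD_T else "low" for d in datasets])
    subgroup("normalization", [d.normalization.value for d in datasets])
    metareg("mean_age", [d.mean_age for d in datasets])
    metareg("pct_male", [d.pct_male for d in datasets])
    metareg("pct_medicated", [d.pct_medicated for d in datasets])
    subgroup(
        "duration_ge_36mo",
        [None if d.duration_months is None
         else ("chronic" if d.duration_months >= RECENT_ONSET_MONTHS else "recent")
         for d in datasets],
    )
    return outcomes


def _analyze_collection(
    collection: RegionalCollection, config: AnalysisConfig, log: list[str]
) -> AnalysisResult:
    tag = f"{collection.region.value}/{collection.metabolite.value}"
    egger_removed: list[dict] = []
    egger = None
    if config.run_egger_removal:
        try:
            collection, egger_removed, egger = remove_small_study_bias(
                collection, alpha=config.alpha
            )
            for entry in egger_removed:
                log.append(f"{tag}: egger_removal {entry['study_id']}: {entry['reason']}")
        except ValueError as exc:
            log.append(f"{tag}: Egger stage failed: {exc}")
    else:
        try:
            egger = egger_test([hedges_g(d) for d in collection])
        except ValueError as exc:
            log.append(f"{tag}: Egger test failed: {exc}")

    effects = [hedges_g(d) for d in collection]
    primary = pool_random_effects(effects)
    pct = weighted_percent_difference(collection)

    robustness = None
    decision = None
    if config.run_outlier_pass or config.run_loo:
        try:
            robustness = outlier_report(collection, primary, alpha=config.alpha)
            if robustness.result_without_outliers is not None:
                decision = outlier_exclusion_policy(
                    primary, robustness.result_without_outliers, alpha=config.alpha
                )
        except ValueError as exc:
            log.append(f"{tag}: robustness stage failed: {exc}")

    scans: dict[str, ThresholdScan] = {}
    if config.run_threshold_scans:
        for mname in config.quality_metrics:
            metric = QualityMetric(mname)
            n_reporting = sum(1 for p in compute_profiles(collection, metric) if not p.missing)
            if n_reporting < MIN_DATASETS_FOR_STRATIFICATION:
                log.append(
                    f"{tag}: {metric.value} scan skipped: {n_reporting} reporting datasets "
                    f"(< {MIN_DATASETS_FOR_STRATIFICATION})"
                )
                continue
            try:
                scans[metric.value] = quality_threshold_scan(
                    collection, metric, alpha=config.alpha
                )
            except (InsufficientData, ValueError) as exc:
                log.append(f"{tag}: {metric.value} scan failed: {exc}")

    moderators = _moderator_analyses(collection, config.alpha, log) if config.run_moderators else []

    return AnalysisResult(
        region=collection.region,
        metabolite=collection.metabolite,
        collection=collection,
        primary=primary,
        pct_diff=pct,
        egger=egger,
        egger_removed=egger_removed,
        robustness=robustness,
        outlier_decision=decision,
        scans=scans,
        moderators=moderators,
    )


def _results_rows(a: AnalysisResult) -> list[dict]:
    def row(label: str, res: MetaResult, pct, n_out) -> dict:
        return {
            "region": a.region.value,
            "metabolite": a.metabolite.value,
            "model": label,
            "k": res.k,
            "n_pt": sum(d.n_pt for d in a.collection) if label == "primary" else "",
            "n_con": sum(d.n_con for d in a.collection) if label == "primary" else "",
            "g": res.pooled_g,
            "ci_lo": res.ci_lo,
            "ci_hi": res.ci_hi,
            "p": _clamp_p(res.p_omnibus),
            "pct_diff": pct,
            "tau2": res.tau2,
            "i2": res.i2,
            "p_het": _clamp_p(res.p_het),
            "egger_p": _clamp_p(a.egger.p) if a.egger is not None else "",
            "egger_removed": ";".join(e["study_id"] for e in a.egger_removed),
            "n_outliers": n_out,
            "outliers_change_result": "",
            "robust_loo": "" if a.robustness is None or a.robustness.robust is None
                          else ("Y" if a.robustness.robust else "N"),
        }

    n_out = len(a.robustness.outliers) if a.robustness is not None else 0
    main = row("primary", a.primary, a.pct_diff, n_out)
    if a.outlier_decision is not None:
        main["outliers_change_result"] = "Y" if a.outlier_decision.report else "N"
    rows = [main]
    if a.outlier_decision is not None and a.outlier_decision.report:
        reduced = a.collection.without(a.robustness.outliers)
        rows.append(
            row("excl_outliers", a.robustness.result_without_outliers,
                weighted_percent_difference(reduced), 0)
        )
    return rows


def _moderator_rows(a: AnalysisResult) -> list[dict]:
    rows = []
    for m in a.moderators:
        if m.result is None:
            continue
        res = m.result
        base = {
            "region": a.region.value,
            "metabolite": a.metabolite.value,
            "moderator": m.name,
            "kind": m.kind,
            "k": res.k,
            "estimate": res.coef[1],
            "se": res.se[1],
            "p": _clamp_p(res.p_qm),
        }
        rows.append(base)
        if res.subgroups:
            for level, sub in res.subgroups.items():
                rows.append({
                    "region": a.region.value,
                    "metabolite": a.metabolite.value,
                    "moderator": f"{m.name}={level}",
                    "kind": "subgroup_pool",
                    "k": sub.k,
                    "estimate": sub.pooled_g,
                    "se": sub.se_pooled,
                    "p": _clamp_p(sub.p_omnibus),
                })
    return rows


def run_full_analysis(config: AnalysisConfig) -> ResultBundle:
    """Run every requested region x metabolite analysis and write outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "scans").mkdir(exist_ok=True)
    log: list[str] = []

    datasets = read_corpus(config.input_path)
    datasets, dup_log = resolve_duplicates(datasets)
    if config.regions is not None:
        datasets = [d for d in datasets if d.region.value in config.regions]
    if config.metabolites is not None:
        datasets = [d for d in datasets if d.metabolite.value in config.metabolites]
    collections, exclusions = apply_eligibility(
        datasets, min_group_n=config.min_group_n, min_region_k=config.min_region_k
    )
    exclusions = list(dup_log) + list(exclusions)
    for e in exclusions:
        log.append(f"excluded {e.study_id} [{e.stage}]: {e.reason}")

    analyses: list[AnalysisResult] = []
    for coll in collections:
        tag = f"{coll.region.value}/{coll.metabolite.value}"
        try:
            analyses.append(_analyze_collection(coll, config, log))
        except Exception as exc:  # keep going on per-analysis failure
            log.append(f"{tag}: analysis failed: {exc}")

    results_rows = [r for a in analyses for r in _results_rows(a)]
    pd.DataFrame(results_rows).to_csv(out_dir / "results.tsv", sep="\t", index=False)
    mod_rows = [r for a in analyses for r in _moderator_rows(a)]
    mod_cols = ["region", "metabolite", "moderator", "kind", "k", "estimate", "se", "p"]
    mod_df = pd.DataFrame(mod_rows, columns=mod_cols)
    if config.bh_correction and len(mod_df):
        # adjust the moderator tests only, not the per-level subgroup pools
        from statsmodels.stats.multitest import multipletests

        mask = mod_df["kind"] != "subgroup_pool"
        mod_df["p_bh"] = np.nan
        if mask.any():
            mod_df.loc[mask, "p_bh"] = multipletests(
                mod_df.loc[mask, "p"].to_numpy(), method="fdr_bh"
            )[1]
    mod_df.to_csv(out_dir / "moderators.tsv", sep="\t", index=False)
    for a in analyses:
        for metric, scan in a.scans.items():
            path = out_dir / "scans" / f"{a.region.value}_{a.metabolite.value}_{metric}.tsv"
            scan_table(scan).to_csv(path, sep="\t", index=False)
    write_exclusion_log(exclusions, out_dir / "exclusions.tsv")
    (out_dir / "run.log").write_text("\n".join(log) + ("\n" if log else ""))
    meta = dataclasses.asdict(config)
    meta["input_path"] = str(meta["input_path"])
    meta["out_dir"] = str(meta["out_dir"])
    meta["mrsmeta_version"] = __version__
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))

    return ResultBundle(analyses=analyses, exclusions=exclusions, log=log)
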