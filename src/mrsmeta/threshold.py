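"""Quality-threshold detection via moving sub-meta-analyses.

The procedure tests whether a true group difference is only evident in
studies with good enough measurement quality, and locates the quality level
at which it emerges:

1. rank datasets from lowest to highest measurement quality on one metric;
2. pool a sliding window of k' = max(7, ceil(k/5)) consecutive ranks
   (window i covers ranks i..i+k'-1), giving a series of pooled effects;
3. fit a 4-parameter logistic y(i) = d + (a-d)/(1 + exp(b*(i-c))) to that
   series by multistart nonlinear least squares;
4. when the fit beats a constant model (F test, alpha = 0.05) and the
   inflection c lies within the window range, map the inflection to
   quality-metric units: the threshold T is the metric value at rank
   r* = c + k' - 1 (linear interpolation between adjacent ranks);
5. stratify datasets by their own metric value versus T (better side
   inclusive) and compare the two subgroups, provided at least 14 datasets
   report the metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import Exclusion, RegionalCollection, StudyDataset
from .effects import EffectSize, hedges_g
from .meta import MetaResult, RegressionResult, pool_random_effects, subgroup_compare
from .quality import QualityMetric, QualityProfile, compute_profiles

__all__ = [
    "InsufficientData",
    "Window",
    "LogisticFit",
    "ThresholdScan",
    "window_size",
    "rank_by_quality",
    "moving_windows",
    "fit_logistic",
    "fit_4pl_series",
    "derive_threshold",
    "compare_quality_subgroups",
    "quality_threshold_scan",
    "scan_table",
]

MIN_DATASETS_FOR_STRATIFICATION = 14


class InsufficientData(ValueError):
    """Raised when a procedure's minimum dataset count is not met."""


@dataclass(frozen=True)
class Window:
    index: int                  # 1-based
    study_ids: tuple[str, ...]
    pooled_g: float


@dataclass(frozen=True)
class LogisticFit:
    """4-parameter logistic fit to the window series (index space).

    ``a`` is the asymptote on the low-quality side (small window index),
    ``d`` on the high-quality side, ``b`` the steepness, ``c`` the
    inflection location in window-index units.  The 4PL is invariant under
    (a, d, b) -> (d, a, -b); fits are canonicalized to b >= 0 so that ``a``
    is always the left asymptote.  ``p_value`` is from the F test against
    the intercept-only model.
    """

    a: float
    d: float
    b: float
    c: float
    sse: float
    r2: float
    p_value: float
    converged: bool = True


@dataclass
class ThresholdScan:
    metric: QualityMetric
    k: int
    k_prime: int
    windows: list[Window]
    ranked_ids: list[str]
    ranked_values: list[float]
    excluded: list[Exclusion] = field(default_factory=list)
    fit: LogisticFit | None = None
    inflection_index: float | None = None
    threshold_value: float | None = None
    subgroup_low: MetaResult | None = None    # lower-quality side
    subgroup_high: MetaResult | None = None   # higher-quality side
    p_subgroup_diff: float | None = None
    comparison: RegressionResult | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def threshold_declared(self) -> bool:
        return self.threshold_value is not None


def window_size(k: int) -> int:
    """Moving sub-meta-analysis size k' = max(7, ceil(k/5))."""
    return max(7, math.ceil(k / 5))


def rank_by_quality(
    collection: RegionalCollection | Sequence[StudyDataset],
    profiles: Sequence[QualityProfile],
) -> tuple[list[StudyDataset], list[QualityProfile], list[Exclusion]]:
    """Order datasets from lowest to highest measurement quality.

    Rank 1 is the worst measurement (highest COV/CRLB/FWHM, or lowest SNR);
    ties break lexicographically on study_id.  Datasets without a profile
    value are excluded with a log entry.
    """
    datasets = list(collection)
    if len(profiles) != len(datasets):
        raise ValueError("profile count does not match dataset count")
    excluded = [
        Exclusion(d.study_id, "quality_rank", f"no {p.metric.value} value reported")
        for d, p in zip(datasets, profiles)
        if p.missing
    ]
    pairs = [(d, p) for d, p in zip(datasets, profiles) if not p.missing]
    sign = 1.0 if profiles[0].metric.higher_is_better else -1.0
    pairs.sort(key=lambda dp: (sign * dp[1].value, dp[0].study_id))
    ranked = [d for d, _ in pairs]
    ranked_profiles = [p for _, p in pairs]
    return ranked, ranked_profiles, excluded


def moving_windows(
    ranked: Sequence[StudyDataset],
    ranked_profiles: Sequence[QualityProfile],
    weights: str = "random",
    excluded: Sequence[Exclusion] = (),
) -> ThresholdScan:
    """Pool every k'-wide window of consecutive quality ranks."""
    k = len(ranked)
    if k < 7:
        raise InsufficientData(f"insufficient datasets for a moving scan (k={k} < 7)")
    kp = window_size(k)
    effects = [hedges_g(d) for d in ranked]
    windows = []
    for i in range(1, k - kp + 2):
        members = ranked[i - 1 : i - 1 + kp]
        pooled = pool_random_effects(effects[i - 1 : i - 1 + kp], weights=weights)
        windows.append(Window(i, tuple(d.study_id for d in members), pooled.pooled_g))
    return ThresholdScan(
        metric=ranked_profiles[0].metric,
        k=k,
        k_prime=kp,
        windows=windows,
        ranked_ids=[d.study_id for d in ranked],
        ranked_values=[p.value for p in ranked_profiles],
        excluded=list(excluded),
    )


def _logistic(x: np.ndarray, a: float, d: float, b: float, c: float) -> np.ndarray:
    z = np.clip(b * (x - c), -500.0, 500.0)
    return d + (a - d) / (1.0 + np.exp(z))


def _logistic_jac(x: np.ndarray, a: float, d: float, b: float, c: float) -> np.ndarray:
    z = np.clip(b * (x - c), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    ds = -s * (1.0 - s)          # d s / d z
    return np.column_stack([
        s,                        # d y / d a
        1.0 - s,                  # d y / d d
        (a - d) * ds * (x - c),   # d y / d b
        (a - d) * ds * (-b),      # d y / d c
    ])


def fit_logistic(scan: ThresholdScan) -> ThresholdScan:
    """Fit the 4-parameter logistic to the window series by multistart NLS.

    Eight deterministic starts (both signs of the steepness crossed with
    four interior quantiles of the inflection) are run; the fit with the
    smallest residual sum of squares is kept.  Asymptotes are bounded to the
    data range padded by one span and the inflection to an interval around
    the observed windows, which excludes the degenerate quasi-exponential
    optima (runaway asymptote, inflection far outside the data) that an
    unconstrained 4PL admits.  Significance is the F test of the
    4-parameter model against the intercept-only model:
    F = ((SStot - SSres)/3) / (SSres/(n-4)).
    """
    n = scan.n_windows
    if n < 5:
        raise InsufficientData(f"need >= 5 windows to fit a logistic, got {n}")
    scan.fit = fit_4pl_series(np.array([w.pooled_g for w in scan.windows]))
    return scan


def fit_4pl_series(y: np.ndarray) -> LogisticFit:
    """Fit the 4PL to an arbitrary series over x = 1..n (see fit_logistic)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise InsufficientData(f"need >= 5 points to fit a logistic, got {n}")
    x = np.arange(1, n + 1, dtype=float)
    sstot = float(np.sum((y - y.mean()) ** 2))

    span = max(float(y.max() - y.min()), 1e-6)
    lo_b = (y.min() - span, y.min() - span, -20.0, 1.0 - n)
    hi_b = (y.max() + span, y.max() + span, 20.0, 2.0 * n)
    a0 = float(np.mean(y[: max(2, n // 4)]))
    d0 = float(np.mean(y[-max(2, n // 4):]))
    best = None
    for b0 in (0.5, -0.5):
        for frac in (0.2, 0.4, 0.6, 0.8):
            p0 = np.clip(
                (a0, d0, b0, 1.0 + frac * (n - 1)),
                np.array(lo_b) + 1e-9,
                np.array(hi_b) - 1e-9,
            )
            try:
                res = optimize.least_squares(
                    lambda p: _logistic(x, *p) - y,
                    p0,
                    jac=lambda p: _logistic_jac(x, *p),
                    bounds=(lo_b, hi_b),
                    method="trf",
                    xtol=1e-8,
                    ftol=1e-10,
                    gtol=1e-6,
                    max_nfev=100,
                )
            except Exception:
                continue
            sse = float(2.0 * res.cost)
            if np.all(np.isfinite(res.x)) and (best is None or sse < best[0] - 1e-14):
                best = (sse, res.x)

    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.0, converged=False)

    sse, (a, d, b, c) = best
    if b < 0:  # canonical labeling: a is the left asymptote
        a, d, b = d, a, -b
    if sstot <= 1e-12 * max(1.0, float(np.sum(y * y))):  # constant series
        r2, p_value = 0.0, 1.0
    else:
        r2 = max(0.0, 1.0 - sse / sstot)
        if sse <= 0:
            p_value = 0.0
        else:
            f_stat = ((sstot - sse) / 3.0) / (sse / (n - 4))
            p_value = float(stats.f.sf(f_stat, 3, n - 4)) if f_stat > 0 else 1.0
    return LogisticFit(float(a), float(d), float(b), float(c), sse, r2, p_value)


def derive_threshold(scan: ThresholdScan, alpha: float = 0.05) -> ThresholdScan:
    """Map a significant inflection to quality-metric units.

    Requires the logistic fit to be significant at ``alpha`` with the
    inflection c inside [1, n_windows].  The threshold T is the metric value
    at rank r* = c + k' - 1, linearly interpolated between adjacent ranked
    datasets for fractional r*.  Otherwise no threshold is declared.
    """
    if scan.fit is None:
        raise ValueError("fit_logistic must run before derive_threshold")
    fit = scan.fit
    if not fit.converged or not (fit.p_value < alpha) or not (1.0 <= fit.c <= scan.n_windows):
        scan.inflection_index = None
        scan.threshold_value = None
        return scan
    r_star = fit.c + scan.k_prime - 1
    vals = scan.ranked_values
    lo_idx = int(math.floor(r_star))
    frac = r_star - lo_idx
    if lo_idx >= scan.k:
        t_val = vals[-1]
    else:
        t_val = vals[lo_idx - 1] + frac * (vals[lo_idx] - vals[lo_idx - 1]) if frac else vals[lo_idx - 1]
    scan.inflection_index = float(fit.c)
    scan.threshold_value = float(t_val)
    return scan


def _high_quality_mask(scan: ThresholdScan) -> list[bool]:
    t = scan.threshold_value
    if scan.metric.higher_is_better:
        return [v >= t for v in scan.ranked_values]
    return [v <= t for v in scan.ranked_values]


def compare_quality_subgroups(
    scan: ThresholdScan,
    ranked: Sequence[StudyDataset],
    alpha: float = 0.05,
) -> ThresholdScan:
    """Pool and compare the low- and high-quality subgroups defined by T.

    Each dataset's own metric value (not its window membership) decides its
    subgroup, with the better side inclusive of T.  The procedure refuses to
    run with fewer than 14 reporting datasets, and requires >= 2 datasets on
    each side of the threshold.
    """
    if scan.k < MIN_DATASETS_FOR_STRATIFICATION:
        raise InsufficientData(
            f"quality stratification needs >= {MIN_DATASETS_FOR_STRATIFICATION} "
            f"reporting datasets, got {scan.k}"
        )
    if not scan.threshold_declared:
        return scan
    mask = _high_quality_mask(scan)
    if sum(mask) < 2 or sum(not m for m in mask) < 2:
        return scan
    labels = ["high" if m else "low" for m in mask]
    comparison = subgroup_compare(list(ranked), labels)
    scan.comparison = comparison
    scan.subgroup_low = comparison.subgroups["low"]
    scan.subgroup_high = comparison.subgroups["high"]
    scan.p_subgroup_diff = comparison.p_qm
    return scan


def quality_threshold_scan(
    collection: RegionalCollection | Sequence[StudyDataset],
    metric: QualityMetric,
    alpha: float = 0.05,
    weights: str = "random",
    compare: bool = True,
) -> ThresholdScan:
    """Run the full threshold procedure for one collection and metric."""
    datasets = list(collection)
    profiles = compute_profiles(datasets, metric)
    ranked, ranked_profiles, excluded = rank_by_quality(datasets, profiles)
    scan = moving_windows(ranked, ranked_profiles, weights=weights, excluded=excluded)
    scan = fit_logistic(scan)
    scan = derive_threshold(scan, alpha=alpha)
    if compare:
        scan = compare_quality_subgroups(scan, ranked, alpha=alpha)
    return scan


def scan_table(scan: ThresholdScan) -> pd.DataFrame:
    """Window series with fitted values (window_index, pooled_g, fitted_g)."""
    x = np.arange(1, scan.n_windows + 1, dtype=float)
    fitted = (
        _logistic(x, scan.fit.a, scan.fit.d, scan.fit.b, scan.fit.c)
        if scan.fit is not None and scan.fit.converged
        else np.full(scan.n_windows, np.nan)
    )
    return pd.DataFrame(
        {
            "window_index": x.astype(int),
            "pooled_g": [w.pooled_g for w in scan.windows],
            "fitted_g": fitted,
        }
    )
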