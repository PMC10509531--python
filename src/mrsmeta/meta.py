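"""Random-effects meta-analysis engine.

Pooling uses the inverse-variance-weighted random-effects model with the
between-study variance tau^2 estimated by restricted maximum likelihood
(REML).  The omnibus test is the Wald chi-square on the pooled coefficient
(df = 1); residual heterogeneity is Cochran's Q at fixed-effect weights and
I^2 is computed from the REML tau^2 with the "typical within-study variance"
formula.  Meta-regression fits the same model with a moderator design matrix
(mixed-effects REML).  Small-study bias is assessed with the Egger weighted
regression of the effect on its standard error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .datasets import RegionalCollection, StudyDataset
from .effects import Z_95, EffectSize, hedges_g

__all__ = [
    "MetaResult",
    "RegressionResult",
    "EggerResult",
    "pool_random_effects",
    "meta_regress",
    "subgroup_compare",
    "egger_test",
    "remove_small_study_bias",
    "forest_table",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    k: int
    pooled_g: float
    se_pooled: float
    ci_lo: float
    ci_hi: float
    tau2: float
    qm: float            # Wald chi-square on the pooled coefficient, df = 1
    p_omnibus: float
    qe: float            # Cochran Q at fixed-effect weights, df = k - 1
    p_het: float
    i2: float            # percent

    @property
    def significant(self) -> bool:
        return self.p_omnibus < 0.05

    def to_dict(self) -> dict:
        return {
            "k": self.k, "pooled_g": self.pooled_g, "se_pooled": self.se_pooled,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "tau2": self.tau2,
            "qm": self.qm, "p_omnibus": self.p_omnibus,
            "qe": self.qe, "p_het": self.p_het, "i2": self.i2,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class RegressionResult:
    """Mixed-effects meta-regression fit.

    ``coef`` includes the intercept first; ``qm`` jointly tests all
    non-intercept coefficients (df = number of moderators).  For a single
    dichotomous moderator the df = 1 QM test is the subgroup comparison.
    ``subgroups`` holds a per-level random-effects pool when the fit was
    built from a categorical split.
    """

    k: int
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    qm: float
    df_qm: int
    p_qm: float
    tau2: float
    subgroups: dict[str, MetaResult] | None = None


@dataclass(frozen=True)
class EggerResult:
    """Egger weighted-regression test for funnel-plot asymmetry."""

    k: int
    statistic: float     # t statistic of the SE coefficient, df = k - 2
    p: float
    slope: float         # coefficient on the standard error
    intercept: float
    influence: np.ndarray  # externally studentized residual per dataset


def _as_arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    return y, v


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Negative restricted log-likelihood (constants dropped)."""
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray, tol: float = 1e-10) -> float:
    """Maximize the restricted likelihood over tau^2 >= 0 (1-D bounded search)."""
    upper = max(10.0 * float(np.var(y)) + float(np.max(v)), 1e-3)
    res = optimize.minimize_scalar(
        _restricted_nll,
        bounds=(0.0, upper),
        args=(y, v, X),
        method="bounded",
        options={"xatol": tol, "maxiter": 200},
    )
    tau2 = float(res.x)
    # the bounded search can stall a hair inside the boundary
    if _restricted_nll(0.0, y, v, X) <= res.fun:
        tau2 = 0.0
    return max(tau2, 0.0)


def _gls(y: np.ndarray, v: np.ndarray, X: np.ndarray, tau2: float):
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * y))
    return beta, cov


def pool_random_effects(effects: Sequence[EffectSize], weights: str = "random") -> MetaResult:
    """Pool effect sizes with inverse-variance weights.

    ``weights="random"`` estimates tau^2 by REML; ``weights="fixed"`` forces
    tau^2 = 0, giving the fixed-effect inverse-variance estimate.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("need at least 2 effects to pool")
    if weights not in ("random", "fixed"):
        raise ValueError(f"unknown weights {weights!r}")
    y, v = _as_arrays(effects)
    X = np.ones((k, 1))
    tau2 = _reml_tau2(y, v, X) if weights == "random" else 0.0

    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    qm = (pooled / se) ** 2
    p_omnibus = float(stats.chi2.sf(qm, 1))

    w_fe = 1.0 / v
    g_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    qe = float(np.sum(w_fe * (y - g_fe) ** 2))
    p_het = float(stats.chi2.sf(qe, k - 1))

    s2 = (k - 1) * np.sum(w_fe) / (np.sum(w_fe) ** 2 - np.sum(w_fe**2))
    i2 = 100.0 * tau2 / (tau2 + s2)

    return MetaResult(
        k=k, pooled_g=pooled, se_pooled=se,
        ci_lo=pooled - Z_95 * se, ci_hi=pooled + Z_95 * se,
        tau2=tau2, qm=qm, p_omnibus=p_omnibus,
        qe=qe, p_het=p_het, i2=float(i2),
    )


def _build_design(moderators: Mapping[str, Sequence[float]] | pd.DataFrame, k: int):
    if isinstance(moderators, pd.DataFrame):
        cols = list(moderators.columns)
        mat = moderators.to_numpy(dtype=float)
    else:
        cols = list(moderators.keys())
        mat = np.column_stack([np.asarray(moderators[c], dtype=float) for c in cols])
    if mat.shape[0] != k:
        raise ValueError("moderator length does not match number of effects")
    for j, c in enumerate(cols):
        if np.ptp(mat[:, j]) == 0:
            raise ValueError(f"moderator '{c}' is constant")
    X = np.column_stack([np.ones(k), mat])
    # name the first column whose addition fails to raise the rank
    rank = 1
    for j, c in enumerate(cols):
        new_rank = np.linalg.matrix_rank(X[:, : j + 2])
        if new_rank == rank:
            raise ValueError(f"design is rank-deficient: moderator '{c}' is collinear")
        rank = new_rank
    return X, ["intercept"] + cols


def meta_regress(
    effects: Sequence[EffectSize],
    moderators: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> RegressionResult:
    """Mixed-effects meta-regression (REML tau^2, Wald z per coefficient)."""
    k = len(effects)
    y, v = _as_arrays(effects)
    X, names = _build_design(moderators, k)
    p_mod = X.shape[1] - 1
    if k < p_mod + 2:
        raise ValueError(f"need k >= {p_mod + 2} effects for {p_mod} moderator(s)")

    tau2 = _reml_tau2(y, v, X)
    beta, cov = _gls(y, v, X, tau2)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    b_mod = beta[1:]
    cov_mod = cov[1:, 1:]
    qm = float(b_mod @ np.linalg.solve(cov_mod, b_mod))
    p_qm = float(stats.chi2.sf(qm, p_mod))

    return RegressionResult(
        k=k, names=names, coef=beta, se=se, z=z, p=p,
        qm=qm, df_qm=p_mod, p_qm=p_qm, tau2=tau2,
    )


def subgroup_compare(
    collection: RegionalCollection | Sequence[StudyDataset],
    split: Callable[[StudyDataset], object] | Sequence[object],
    effects: Sequence[EffectSize] | None = None,
) -> RegressionResult:
    """Compare two subgroups of a collection via an indicator moderator.

    ``split`` either maps each dataset to one of exactly two labels or is a
    precomputed label sequence.  The QM (df = 1) p-value is the subgroup
    comparison; per-subgroup random-effects pools are attached as
    ``subgroups``.
    """
    datasets = list(collection)
    labels = [split(d) for d in datasets] if callable(split) else list(split)
    if len(labels) != len(datasets):
        raise ValueError("label count does not match dataset count")
    levels = sorted(set(map(str, labels)))
    labels = [str(l) for l in labels]
    if len(levels) != 2:
        raise ValueError(f"split must produce exactly 2 non-empty subgroups, got {levels}")
    if effects is None:
        effects = [hedges_g(d) for d in datasets]
    indicator = [1.0 if l == levels[1] else 0.0 for l in labels]
    result = meta_regress(effects, {f"is_{levels[1]}": indicator})
    result.subgroups = {}
    for lev in levels:
        idx = [i for i, l in enumerate(labels) if l == lev]
        if len(idx) < 2:
            raise ValueError(f"subgroup '{lev}' has fewer than 2 datasets")
        result.subgroups[lev] = pool_random_effects([effects[i] for i in idx])
    return result


def egger_test(effects: Sequence[EffectSize]) -> EggerResult:
    """Egger regression test: weighted regression of g on its SE (weights 1/v).

    The test statistic is the t test (df = k - 2) of the SE coefficient;
    a significant positive slope indicates that smaller (noisier) studies
    report systematically larger effects.  Influence scores are the
    externally studentized residuals of the weighted fit.

    Fitted in the algebraically identical precision form — OLS of g/se on
    1/se plus a constant, whose constant term is the SE coefficient of the
    weighted regression — so ordinary regression influence measures apply
    directly.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Egger test needs at least 3 effects")
    y, v = _as_arrays(effects)
    se = np.sqrt(v)
    X = np.column_stack([1.0 / se, np.ones(k)])
    fit = sm.OLS(y / se, X).fit()
    influence = fit.get_influence().resid_studentized_external
    return EggerResult(
        k=k,
        statistic=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        influence=np.asarray(influence, dtype=float),
    )


def remove_small_study_bias(
    collection: RegionalCollection,
    effects: Sequence[EffectSize] | None = None,
    alpha: float = 0.05,
) -> tuple[RegionalCollection, list[dict], EggerResult]:
    """Remove at most one small study driving a significant Egger test.

    When the Egger test is significant at ``alpha``, the dataset with the
    largest absolute influence score among datasets whose total n is below
    the corpus median is removed (ties: smaller total n, then study_id), and
    the Egger test is re-run on the remainder.  Otherwise the collection is
    returned unchanged.
    """
    datasets = list(collection)
    if effects is None:
        effects = [hedges_g(d) for d in datasets]
    before = egger_test(effects)
    if before.p >= alpha:
        return collection, [], before

    totals = np.array([d.total_n for d in datasets])
    median_n = float(np.median(totals))
    candidates = [i for i in range(len(datasets)) if totals[i] < median_n]
    if not candidates:  # degenerate: all sizes equal
        candidates = list(range(len(datasets)))
    candidates.sort(
        key=lambda i: (-abs(before.influence[i]), totals[i], datasets[i].study_id)
    )
    drop = candidates[0]
    removed = datasets[drop]
    reduced = RegionalCollection(
        collection.region, collection.metabolite,
        [d for i, d in enumerate(datasets) if i != drop],
    )
    after = egger_test([e for i, e in enumerate(effects) if i != drop])
    log = [{
        "study_id": removed.study_id,
        "stage": "egger_removal",
        "reason": (
            f"Egger p={before.p:.4g} < {alpha}; largest |influence| "
            f"{abs(before.influence[drop]):.3f} among small studies (n={removed.total_n})"
        ),
    }]
    return reduced, log, after


def forest_table(
    collection: RegionalCollection | Sequence[StudyDataset],
    result: MetaResult,
    effects: Sequence[EffectSize] | None = None,
) -> pd.DataFrame:
    """Per-study forest-plot table (study_id, g, CI, % random-effects weight)."""
    datasets = list(collection)
    if effects is None:
        effects = [hedges_g(d) for d in datasets]
    w = np.array([1.0 / (e.var_g + result.tau2) for e in effects])
    w = 100.0 * w / w.sum()
    return pd.DataFrame(
        {
            "study_id": [d.study_id for d in datasets],
            "g": [e.g for e in effects],
            "ci_lo": [e.ci_lo for e in effects],
            "ci_hi": [e.ci_hi for e in effects],
            "weight_pct": w,
        }
    )
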