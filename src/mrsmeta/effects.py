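"""Standardized effect sizes and the weighted mean percent difference.

The per-dataset effect is Hedges' g: the patient-minus-control mean
difference divided by the pooled within-group SD, multiplied by the
small-sample correction J = 1 - 3/(4m - 1) with m = n_pt + n_con - 2.
Negative g means patients lower than controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .datasets import RegionalCollection, StudyDataset

__all__ = ["Z_95", "EffectSize", "hedges_g", "hedges_g_from_stats", "weighted_percent_difference"]

Z_95 = 1.959964


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g with its large-sample variance and 95% Wald interval."""

    g: float
    var_g: float

    @property
    def se_g(self) -> float:
        return math.sqrt(self.var_g)

    @property
    def ci_lo(self) -> float:
        return self.g - Z_95 * self.se_g

    @property
    def ci_hi(self) -> float:
        return self.g + Z_95 * self.se_g


def hedges_g_from_stats(
    mean_pt: float,
    sd_pt: float,
    n_pt: int,
    mean_con: float,
    sd_con: float,
    n_con: int,
) -> EffectSize:
    if n_pt < 2 or n_con < 2:
        raise ValueError("need n >= 2 per group for a pooled SD")
    m = n_pt + n_con - 2
    s_p = math.sqrt(((n_pt - 1) * sd_pt**2 + (n_con - 1) * sd_con**2) / m)
    if s_p == 0:
        raise ValueError("degenerate variance: pooled SD is zero")
    d = (mean_pt - mean_con) / s_p
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = j * d
    n_tot = n_pt + n_con
    var_g = n_tot / (n_pt * n_con) + g**2 / (2.0 * n_tot)
    return EffectSize(g=g, var_g=var_g)


def hedges_g(ds: StudyDataset) -> EffectSize:
    """Hedges' g (patient minus control) for one dataset."""
    return hedges_g_from_stats(ds.mean_pt, ds.sd_pt, ds.n_pt, ds.mean_con, ds.sd_con, ds.n_con)


def weighted_percent_difference(datasets: RegionalCollection | Sequence[StudyDataset]) -> float:
    """Patient-vs-control weighted mean percent difference across datasets.

    Per-dataset relative differences (pt_mean - con_mean)/con_mean are
    weighted by total sample size n_pt + n_con; the result is in percent.
    """
    ds = list(datasets)
    if not ds:
        raise ValueError("empty dataset list")
    num = 0.0
    den = 0.0
    for d in ds:
        if d.mean_con == 0:
            raise ValueError(f"dataset {d.study_id}: control mean is zero")
        w = d.n_pt + d.n_con
        num += (d.mean_pt - d.mean_con) / d.mean_con * w
        den += w
    return 100.0 * num / den
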