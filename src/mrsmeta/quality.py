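"""Measurement-quality metrics for study-level MRS summaries.

Four per-dataset quality proxies:

* COV  — group-averaged coefficient of variation of the metabolite values,
  SD/mean per group averaged over patients and controls, in percent
  (lower is better).
* CRLB — mean Cramer-Rao lower bound of the spectral fit, already averaged
  over groups in the schema, in percent (lower is better).
* FWHM — per-group mean + 2 SD of the singlet linewidth, averaged over
  groups (lower is better); ~97.5% of subjects fall below this linewidth.
* SNR  — per-group mean - 2 SD of the spectral signal-to-noise, averaged
  over groups (higher is better).

When a group reports only a mean for FWHM/SNR, its SD is imputed as
mean x median(SD/mean ratios) over the studies in the same analysis that
report both.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import RegionalCollection, StudyDataset

__all__ = [
    "QualityMetric",
    "QualityProfile",
    "compute_cov",
    "compute_crlb",
    "compute_tail_metric",
    "sd_mean_ratio_pool",
    "compute_profiles",
    "quality_table",
]


class QualityMetric(str, Enum):
    COV = "cov"
    CRLB = "crlb"
    FWHM = "fwhm"
    SNR = "snr"

    @property
    def higher_is_better(self) -> bool:
        return self is QualityMetric.SNR


@dataclass(frozen=True)
class QualityProfile:
    """One quality-metric value for one dataset.

    ``value`` is None when the dataset does not report the metric.
    ``imputed_pt``/``imputed_con`` flag a median-ratio SD imputation for the
    respective group (FWHM/SNR only).
    """

    study_id: str
    metric: QualityMetric
    value: float | None
    imputed_pt: bool = False
    imputed_con: bool = False

    @property
    def higher_is_better(self) -> bool:
        return self.metric.higher_is_better

    @property
    def missing(self) -> bool:
        return self.value is None


def compute_cov(ds: StudyDataset) -> QualityProfile:
    """Group-averaged COV in percent: 100 * (sd/mean averaged over groups)."""
    return QualityProfile(ds.study_id, QualityMetric.COV, ds.cov_pct())


def compute_crlb(ds: StudyDataset) -> QualityProfile:
    """Mean CRLB (%) as reported; SDs are too rarely published to adjust."""
    return QualityProfile(ds.study_id, QualityMetric.CRLB, ds.crlb_mean)


_METRIC_FIELDS = {
    QualityMetric.FWHM: ("fwhm_mean_pt", "fwhm_sd_pt", "fwhm_mean_con", "fwhm_sd_con"),
    QualityMetric.SNR: ("snr_mean_pt", "snr_sd_pt", "snr_mean_con", "snr_sd_con"),
}


def sd_mean_ratio_pool(
    datasets: RegionalCollection | Sequence[StudyDataset], metric: QualityMetric
) -> list[float]:
    """SD/mean ratios from every group reporting both mean and SD for ``metric``.

    This pool, scoped to the analysis at hand, supplies the median used to
    impute missing SDs.
    """
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"ratio pool only applies to FWHM/SNR, not {metric}")
    m_pt, s_pt, m_con, s_con = _METRIC_FIELDS[metric]
    ratios: list[float] = []
    for d in datasets:
        for m_field, s_field in ((m_pt, s_pt), (m_con, s_con)):
            mean, sd = getattr(d, m_field), getattr(d, s_field)
            if mean is not None and sd is not None and mean != 0:
                ratios.append(sd / mean)
    return ratios


def compute_tail_metric(
    ds: StudyDataset, metric: QualityMetric, ratio_pool: Sequence[float]
) -> QualityProfile:
    """Group-averaged mean + 2 SD (FWHM) or mean - 2 SD (SNR).

    Missing group SDs are imputed as mean x median(ratio_pool); a dataset
    without the metric's group means yields a missing profile, not an error.
    """
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"compute_tail_metric applies to FWHM/SNR, not {metric}")
    m_pt, s_pt, m_con, s_con = _METRIC_FIELDS[metric]
    sign = -2.0 if metric is QualityMetric.SNR else 2.0
    values = []
    imputed = []
    for m_field, s_field in ((m_pt, s_pt), (m_con, s_con)):
        mean, sd = getattr(ds, m_field), getattr(ds, s_field)
        if mean is None:
            return QualityProfile(ds.study_id, metric, None)
        was_imputed = False
        if sd is None:
            if not ratio_pool:
                return QualityProfile(ds.study_id, metric, None)
            sd = mean * float(np.median(ratio_pool))
            was_imputed = True
        values.append(mean + sign * sd)
        imputed.append(was_imputed)
    return QualityProfile(
        ds.study_id, metric, float(np.mean(values)),
        imputed_pt=imputed[0], imputed_con=imputed[1],
    )


def compute_profiles(
    datasets: RegionalCollection | Sequence[StudyDataset], metric: QualityMetric
) -> list[QualityProfile]:
    """Quality profiles for every dataset in a collection, in input order."""
    ds = list(datasets)
    if metric is QualityMetric.COV:
        return [compute_cov(d) for d in ds]
    if metric is QualityMetric.CRLB:
        return [compute_crlb(d) for d in ds]
    pool = sd_mean_ratio_pool(ds, metric)
    return [compute_tail_metric(d, metric, pool) for d in ds]


def quality_table(profiles: Sequence[QualityProfile]) -> pd.DataFrame:
    """TSV-ready table: study_id, metric, value, imputed flags."""
    return pd.DataFrame(
        {
            "study_id": [p.study_id for p in profiles],
            "metric": [p.metric.value for p in profiles],
            "value": [p.value for p in profiles],
            "imputed_pt": [p.imputed_pt for p in profiles],
            "imputed_con": [p.imputed_con for p in profiles],
        }
    )
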