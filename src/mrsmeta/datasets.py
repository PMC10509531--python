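"""Study-level data schema, tabular I/O, and eligibility filtering.

The unit of analysis is a *dataset*: one patient-versus-control comparison of
one metabolite in one brain region, summarised by group sample sizes, means
and standard deviations, plus acquisition parameters, clinical covariates and
optional measurement-quality summaries (CRLB, FWHM, SNR).

Files are plain CSV/TSV with a header row, UTF-8, "." decimal separator, one
row per dataset.  Missing optional values are empty cells, never sentinel
numbers.
"""

from __future__ import annotations

import dataclasses
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Region",
    "Metabolite",
    "Normalization",
    "StudyDataset",
    "RegionalCollection",
    "Exclusion",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "resolve_duplicates",
    "apply_eligibility",
    "write_exclusion_log",
]


class Region(str, Enum):
    """Brain regions with enough literature coverage to pool."""

    MPFC = "MPFC"
    DLPFC = "DLPFC"
    HC = "HC"
    THAL = "THAL"
    BG = "BG"
    FRWM = "FrWM"
    OTHER = "OTHER"


class Metabolite(str, Enum):
    NAA = "NAA"
    CHO = "CHO"
    CRE = "CRE"


class Normalization(str, Enum):
    WATER = "water"
    CREATINE = "creatine"


class CorpusFormatError(ValueError):
    """Raised when a corpus file row fails schema validation."""


def _check_pct(name: str, value: float | None) -> None:
    if value is not None and not (0.0 <= value <= 100.0):
        raise ValueError(f"{name} must lie in [0, 100], got {value}")


@dataclass
class StudyDataset:
    """One patient-vs-control comparison for one region and one metabolite.

    Metabolite means/SDs are in institutional units (their scale cancels in
    the standardized effect size).  ``field_T`` is the scanner field strength
    in Tesla; ``te_ms`` the echo time in milliseconds.  Optional quality
    summaries: ``crlb_mean`` is the mean Cramer-Rao lower bound (%) already
    averaged over groups; FWHM (spectral linewidth) and SNR carry per-group
    mean and SD when reported.  ``duplicate_group`` marks rows that describe
    the same underlying sample under different normalizations, to be resolved
    by :func:`resolve_duplicates`.
    """

    study_id: str
    region: Region
    metabolite: Metabolite
    n_pt: int
    n_con: int
    mean_pt: float
    sd_pt: float
    mean_con: float
    sd_con: float
    normalization: Normalization
    field_T: float
    te_ms: float
    pct_medicated: float | None = None
    pct_male: float | None = None
    mean_age: float | None = None
    duration_months: float | None = None
    crlb_mean: float | None = None
    fwhm_mean_pt: float | None = None
    fwhm_sd_pt: float | None = None
    fwhm_mean_con: float | None = None
    fwhm_sd_con: float | None = None
    snr_mean_pt: float | None = None
    snr_sd_pt: float | None = None
    snr_mean_con: float | None = None
    snr_sd_con: float | None = None
    snr_method: str | None = None
    duplicate_group: str | None = None

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        self.metabolite = Metabolite(self.metabolite)
        self.normalization = Normalization(self.normalization)
        if int(self.n_pt) != self.n_pt or int(self.n_con) != self.n_con:
            raise ValueError("group sizes must be integers")
        self.n_pt = int(self.n_pt)
        self.n_con = int(self.n_con)
        if self.n_pt < 1 or self.n_con < 1:
            raise ValueError("n_pt and n_con must be >= 1")
        if self.sd_pt <= 0:
            raise ValueError(f"sd_pt must be > 0, got {self.sd_pt}")
        if self.sd_con <= 0:
            raise ValueError(f"sd_con must be > 0, got {self.sd_con}")
        if self.te_ms <= 0:
            raise ValueError(f"te_ms must be > 0, got {self.te_ms}")
        if self.field_T <= 0:
            raise ValueError(f"field_T must be > 0, got {self.field_T}")
        _check_pct("pct_medicated", self.pct_medicated)
        _check_pct("pct_male", self.pct_male)

    @property
    def total_n(self) -> int:
        return self.n_pt + self.n_con

    def cov_pct(self) -> float:
        """Group-averaged coefficient of variation of the metabolite, in %."""
        if self.mean_pt == 0 or self.mean_con == 0:
            raise ValueError("COV undefined for zero group mean")
        return 100.0 * (self.sd_pt / self.mean_pt + self.sd_con / self.mean_con) / 2.0


@dataclass
class RegionalCollection:
    """All datasets entering one region x metabolite meta-analysis."""

    region: Region
    metabolite: Metabolite
    datasets: list[StudyDataset]

    def __post_init__(self) -> None:
        ids = [d.study_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("study_ids must be unique within a collection")
        for d in self.datasets:
            if d.region != self.region or d.metabolite != self.metabolite:
                raise ValueError(
                    f"dataset {d.study_id} does not match collection "
                    f"{self.region.value}/{self.metabolite.value}"
                )

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def without(self, study_ids: Iterable[str]) -> "RegionalCollection":
        drop = set(study_ids)
        return RegionalCollection(
            self.region,
            self.metabolite,
            [d for d in self.datasets if d.study_id not in drop],
        )


@dataclass(frozen=True)
class Exclusion:
    study_id: str
    stage: str
    reason: str


_OPTIONAL_STR_FIELDS = {"snr_method", "duplicate_group"}
_ENUM_FIELDS = {"region": Region, "metabolite": Metabolite, "normalization": Normalization}
_INT_FIELDS = {"n_pt", "n_con"}

_COLUMNS = [f.name for f in dataclasses.fields(StudyDataset)]
_REQUIRED = [
    "study_id", "region", "metabolite", "n_pt", "n_con",
    "mean_pt", "sd_pt", "mean_con", "sd_con",
    "normalization", "field_T", "te_ms",
]


def _cell(row: pd.Series, name: str):
    val = row.get(name)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    if isinstance(val, str) and val.strip() == "":
        return None
    return val


def read_corpus(path: str | Path, dialect: str = "csv") -> list[StudyDataset]:
    """Read a study corpus from a CSV (``dialect="csv"``) or TSV file.

    Raises :class:`CorpusFormatError` naming the row number (1-based, data
    rows) and the offending field on any malformed or invariant-violating
    value.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype={"study_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"header missing required columns: {missing}")
    out: list[StudyDataset] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        kwargs = {}
        for name in _COLUMNS:
            val = _cell(row, name)
            if val is None:
                if name in _REQUIRED:
                    raise CorpusFormatError(f"row {i}: missing required field '{name}'")
                kwargs[name] = None
                continue
            try:
                if name in _ENUM_FIELDS:
                    val = _ENUM_FIELDS[name](str(val))
                elif name in _INT_FIELDS:
                    val = int(val)
                elif name == "study_id" or name in _OPTIONAL_STR_FIELDS:
                    val = str(val)
                else:
                    val = float(val)
            except (ValueError, TypeError) as exc:
                raise CorpusFormatError(f"row {i}: bad value for '{name}': {exc}") from None
            kwargs[name] = val
        try:
            out.append(StudyDataset(**kwargs))
        except ValueError as exc:
            # re-raise with row context; message already names the field
            raise CorpusFormatError(f"row {i}: {exc}") from None
    return out


def write_corpus(datasets: Sequence[StudyDataset], path: str | Path, dialect: str = "csv") -> None:
    """Write datasets to the same tabular schema ``read_corpus`` accepts."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    for d in datasets:
        rec = dataclasses.asdict(d)
        for key in _ENUM_FIELDS:
            rec[key] = rec[key].value
        records.append(rec)
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, sep=sep, index=False)


def resolve_duplicates(
    datasets: Sequence[StudyDataset],
) -> tuple[list[StudyDataset], list[Exclusion]]:
    """Resolve duplicate reports of the same sample under two normalizations.

    Within each ``duplicate_group`` the row with the lowest group-averaged
    COV is kept.  Ties keep the first-listed row and are logged.
    """
    kept: list[StudyDataset] = []
    log: list[Exclusion] = []
    groups: "OrderedDict[str, list[StudyDataset]]" = OrderedDict()
    for d in datasets:
        if d.duplicate_group is None:
            kept.append(d)
        else:
            groups.setdefault(d.duplicate_group, []).append(d)
    for gid, members in groups.items():
        covs = [m.cov_pct() for m in members]
        best = min(range(len(members)), key=lambda j: covs[j])
        n_best = sum(1 for c in covs if c == covs[best])
        kept.append(members[best])
        for j, m in enumerate(members):
            if j == best:
                if n_best > 1:
                    log.append(Exclusion(m.study_id, "duplicate", f"tie on COV in group '{gid}'; kept first listed"))
                continue
            log.append(
                Exclusion(
                    m.study_id,
                    "duplicate",
                    f"group '{gid}': COV {covs[j]:.3f}% > kept {covs[best]:.3f}%",
                )
            )
    return kept, log


def apply_eligibility(
    datasets: Sequence[StudyDataset],
    min_group_n: int = 8,
    min_region_k: int = 10,
) -> tuple[list[RegionalCollection], list[Exclusion]]:
    """Apply the programmatic eligibility rules and group by region x metabolite.

    Datasets with either group smaller than ``min_group_n`` are dropped, then
    any region x metabolite group with fewer than ``min_region_k`` survivors
    is dropped whole.  Region ``OTHER`` is never pooled.  Returns surviving
    collections (in first-appearance order) and the exclusion log; every
    input dataset appears either in exactly one collection or in the log.
    """
    survivors: list[StudyDataset] = []
    log: list[Exclusion] = []
    for d in datasets:
        if d.n_pt < min_group_n or d.n_con < min_group_n:
            log.append(
                Exclusion(
                    d.study_id,
                    "group_size",
                    f"group n below minimum {min_group_n} (n_pt={d.n_pt}, n_con={d.n_con})",
                )
            )
        else:
            survivors.append(d)

    groups: "OrderedDict[tuple[Region, Metabolite], list[StudyDataset]]" = OrderedDict()
    for d in survivors:
        groups.setdefault((d.region, d.metabolite), []).append(d)

    collections: list[RegionalCollection] = []
    for (region, metabolite), members in groups.items():
        if region is Region.OTHER:
            for m in members:
                log.append(Exclusion(m.study_id, "region", "region OTHER is never pooled"))
            continue
        if len(members) < min_region_k:
            for m in members:
                log.append(
                    Exclusion(
                        m.study_id,
                        "region_count",
                        f"{region.value}/{metabolite.value}: only {len(members)} datasets "
                        f"(< {min_region_k})",
                    )
                )
            continue
        collections.append(RegionalCollection(region, metabolite, members))
    return collections, log


def write_exclusion_log(log: Sequence[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [(e.study_id, e.stage, e.reason) for e in log],
        columns=["study_id", "stage", "reason"],
    ).to_csv(path, sep="\t", index=False)
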