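"""Exam-level screening cohort: data model, CSV I/O, validation, filtering.

A cohort is one row per screening exam, carrying the continuous AI risk
score, the radiologist's recall decision under standard practice (no
triage), and the cancer outcome within the follow-up window.  Optional
labels record cancer type (invasive vs in situ) and the biopsy outcome
for recalled exams.  All downstream metrics are computed from these
four-to-six columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

#: canonical column order of the cohort CSV dialect
COLUMNS = ["exam_id", "ai_score", "recall", "cancer", "cancer_type", "biopsy_outcome"]

CANCER_TYPES = frozenset({"invasive", "in_situ"})
BIOPSY_OUTCOMES = frozenset({"benign", "high_risk", "malignant", "none"})


@dataclass(frozen=True)
class ExamRecord:
    """A single screening exam.

    Parameters
    ----------
    exam_id
        Opaque identifier; uniqueness is checked but not enforced.
    ai_score
        Continuous AI risk score in [0, 1].
    recall
        Whether the radiologist recalled the exam under standard practice.
    cancer
        Whether cancer was histopathologically confirmed within the
        follow-up window.
    cancer_type
        ``"invasive"`` or ``"in_situ"``; only permitted when ``cancer``.
    biopsy_outcome
        ``"benign"``, ``"high_risk"``, ``"malignant"`` or ``"none"``.
    """

    exam_id: str
    ai_score: float
    recall: bool
    cancer: bool
    cancer_type: str | None = None
    biopsy_outcome: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.ai_score) or not 0.0 <= self.ai_score <= 1.0:
            raise ValidationError(
                f"exam {self.exam_id!r}: ai_score {self.ai_score!r} outside [0, 1]"
            )
        if self.cancer_type is not None:
            if self.cancer_type not in CANCER_TYPES:
                raise ValidationError(
                    f"exam {self.exam_id!r}: unknown cancer_type {self.cancer_type!r}"
                )
            if not self.cancer:
                raise ValidationError(
                    f"exam {self.exam_id!r}: cancer_type set on a non-cancer exam"
                )
        if self.biopsy_outcome is not None and self.biopsy_outcome not in BIOPSY_OUTCOMES:
            raise ValidationError(
                f"exam {self.exam_id!r}: unknown biopsy_outcome {self.biopsy_outcome!r}"
            )

    @property
    def screen_detected(self) -> bool:
        """Cancer found at the index exam (recalled and positive)."""
        return self.cancer and self.recall

    @property
    def interval_cancer(self) -> bool:
        """Cancer missed by radiology at the index exam (not recalled)."""
        return self.cancer and not self.recall


@dataclass
class Cohort:
    """Ordered collection of screening exams backed by a DataFrame.

    ``df`` always carries the canonical :data:`COLUMNS`; optional label
    columns hold ``None``/NaN where absent.  ``metadata`` is free-form
    provenance (source, follow-up window, applied filters, seed).
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"cohort frame missing columns: {missing}")
        if self.df.empty:
            raise InputError("cohort must contain at least one exam")
        self.df = self.df.loc[:, COLUMNS].reset_index(drop=True)

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[ExamRecord], metadata: dict | None = None) -> "Cohort":
        rows = [
            (r.exam_id, r.ai_score, r.recall, r.cancer, r.cancer_type, r.biopsy_outcome)
            for r in records
        ]
        if not rows:
            raise InputError("cohort must contain at least one exam")
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, metadata or {})

    # -- basic properties ---------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cancer(self) -> int:
        return int(self.df["cancer"].sum())

    @property
    def prevalence(self) -> float:
        """Fraction of exams with confirmed cancer (derived, never stored)."""
        return self.n_cancer / len(self)

    @property
    def scores(self) -> np.ndarray:
        return self.df["ai_score"].to_numpy(dtype=float)

    def records(self) -> list[ExamRecord]:
        return [
            ExamRecord(
                str(t.exam_id),
                float(t.ai_score),
                bool(t.recall),
                bool(t.cancer),
                None if pd.isna(t.cancer_type) else str(t.cancer_type),
                None if pd.isna(t.biopsy_outcome) else str(t.biopsy_outcome),
            )
            for t in self.df.itertuples(index=False)
        ]

    # -- I/O ------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        """Write in the canonical dialect (UTF-8, '.' decimal, header)."""
        out = self.df.copy()
        out["recall"] = out["recall"].astype(int)
        out["cancer"] = out["cancer"].astype(int)
        out.to_csv(path, index=False, encoding="utf-8")


def _check_frame(df: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` with row indices on any invariant breach."""
    score = pd.to_numeric(df["ai_score"], errors="coerce")
    bad = df.index[~(np.isfinite(score) & (score >= 0) & (score <= 1))].tolist()
    if bad:
        raise ValidationError(
            f"ai_score outside [0, 1] or unparseable at rows {bad[:20]}"
            + (" ..." if len(bad) > 20 else ""),
            rows=bad,
        )
    ct = df["cancer_type"]
    bad = df.index[ct.notna() & ~ct.isin(CANCER_TYPES)].tolist()
    if bad:
        raise ValidationError(f"unknown cancer_type at rows {bad}", rows=bad)
    bad = df.index[ct.notna() & ~df["cancer"].astype(bool)].tolist()
    if bad:
        raise ValidationError(f"cancer_type set on non-cancer rows {bad}", rows=bad)
    bo = df["biopsy_outcome"]
    bad = df.index[bo.notna() & ~bo.isin(BIOPSY_OUTCOMES)].tolist()
    if bad:
        raise ValidationError(f"unknown biopsy_outcome at rows {bad}", rows=bad)


def _parse_bool(s: pd.Series, name: str) -> pd.Series:
    mapped = s.map(
        {
            "0": False, "1": True, 0: False, 1: True,
            False: False, True: True,
            "false": False, "true": True, "False": False, "True": True,
        }
    )
    bad = s.index[mapped.isna()].tolist()
    if bad:
        raise ValidationError(f"column {name!r} not boolean at rows {bad[:20]}", rows=bad)
    return mapped.astype(bool)


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps canonical names (``ai_score`` ...) to the file's column
        names; unmapped canonical names are looked up verbatim.
    strict
        If true, duplicated ``exam_id`` values raise instead of warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype={"exam_id": str})
    except pd.errors.EmptyDataError:
        raise InputError(f"cohort file is empty: {path}") from None
    if raw.empty:
        raise InputError(f"cohort file has a header but no rows: {path}")

    column_map = dict(column_map or {})
    df = pd.DataFrame(index=raw.index)
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            df[canon] = raw[src]
        elif canon in ("cancer_type", "biopsy_outcome"):
            df[canon] = None
        else:
            raise ConfigurationError(
                f"required column {src!r} (for {canon!r}) not in {list(raw.columns)}"
            )

    df["exam_id"] = df["exam_id"].astype(str)
    _check_frame(df)
    df["ai_score"] = pd.to_numeric(df["ai_score"])
    df["recall"] = _parse_bool(df["recall"], "recall")
    df["cancer"] = _parse_bool(df["cancer"], "cancer")
    df["cancer_type"] = df["cancer_type"].where(df["cancer_type"].notna(), None)
    df["biopsy_outcome"] = df["biopsy_outcome"].where(df["biopsy_outcome"].notna(), None)

    dup = df["exam_id"].duplicated().sum()
    if dup:
        msg = f"{dup} duplicated exam_id value(s) in {path.name}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    return Cohort(df, metadata={"source": str(path)})


# -- filtering ----------------------------------------------------------


def filter_cohort(cohort: Cohort, where: Mapping[str, object] | None = None) -> Cohort:
    """Return the sub-cohort matching the conjunction of field conditions.

    ``where`` maps field names to a required value or a set of accepted
    values; an empty/None spec returns an identical cohort.  The applied
    filter is recorded in the result's metadata.
    """
    if not where:
        return Cohort(cohort.df.copy(), dict(cohort.metadata))
    mask = pd.Series(True, index=cohort.df.index)
    for fld, accepted in where.items():
        if fld not in COLUMNS:
            raise ConfigurationError(f"filter references unknown field {fld!r}")
        col = cohort.df[fld]
        if isinstance(accepted, (set, frozenset, list, tuple)):
            mask &= col.isin(list(accepted))
        else:
            mask &= col == accepted
    meta = dict(cohort.metadata)
    meta.setdefault("filters", []).append({str(k): repr(v) for k, v in where.items()})
    out = cohort.df[mask]
    if out.empty:
        raise InputError("filter matched no records")
    return Cohort(out, meta)


def invasive_only(cohort: Cohort, mode: str = "recode") -> Cohort:
    """Restrict the cancer outcome to invasive cancers.

    ``mode="recode"`` (default) keeps every exam but relabels in-situ
    cancers as negative, so denominators stay comparable with the
    all-cancers analysis.  ``mode="drop"`` removes in-situ exams.
    Requires ``cancer_type`` on every cancer record.
    """
    if mode not in ("recode", "drop"):
        raise ConfigurationError(f"invasive_only mode must be 'recode' or 'drop', got {mode!r}")
    df = cohort.df
    unlabeled = df["cancer"].astype(bool) & df["cancer_type"].isna()
    if unlabeled.any():
        raise InputError(
            "invasive-only analysis requires cancer_type on every cancer record; "
            f"{int(unlabeled.sum())} cancer record(s) lack it"
        )
    meta = dict(cohort.metadata)
    meta.setdefault("filters", []).append({"invasive_only": mode})
    in_situ = df["cancer_type"] == "in_situ"
    if mode == "drop":
        out = df[~in_situ]
        if out.empty:
            raise InputError("invasive-only drop removed every record")
        return Cohort(out, meta)
    out = df.copy()
    out.loc[in_situ, "cancer"] = False
    out.loc[in_situ, "cancer_type"] = None
    return Cohort(out, meta)


# -- validation report --------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Per-rule pass/fail counts from :func:`validate` (report-only)."""

    n_records: int
    score_out_of_range: int
    cancer_type_on_negative: int
    unknown_cancer_type: int
    unknown_biopsy_outcome: int
    duplicate_exam_ids: int

    @property
    def ok(self) -> bool:
        return not any(
            (
                self.score_out_of_range,
                self.cancer_type_on_negative,
                self.unknown_cancer_type,
                self.unknown_biopsy_outcome,
                self.duplicate_exam_ids,
            )
        )


def validate(cohort: Cohort) -> ValidationReport:
    """Audit a cohort against every record-level rule without raising."""
    df = cohort.df
    score = pd.to_numeric(df["ai_score"], errors="coerce")
    ct, bo = df["cancer_type"], df["biopsy_outcome"]
    return ValidationReport(
        n_records=len(df),
        score_out_of_range=int((~(np.isfinite(score) & (score >= 0) & (score <= 1))).sum()),
        cancer_type_on_negative=int((ct.notna() & ~df["cancer"].astype(bool)).sum()),
        unknown_cancer_type=int((ct.notna() & ~ct.isin(CANCER_TYPES)).sum()),
        unknown_biopsy_outcome=int((bo.notna() & ~bo.isin(BIOPSY_OUTCOMES)).sum()),
        duplicate_exam_ids=int(df["exam_id"].duplicated().sum()),
    )
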