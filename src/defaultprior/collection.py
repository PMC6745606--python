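"""Reading, validating and filtering collections of published p-values.

A collection is a CSV of two-sided p-values harvested from articles, one row
per reported coefficient, with the article identifier in ``study_id``.
Optional flag columns mark rows that the eligibility rules exclude:
intercept p-values (no reason the intercept should be near zero, so the
zero-centred prior is inapplicable), F-test p-values (not convertible to a
signed z-value), p-values below 0.001 (prior-data conflict territory, and
typically reported only as "p < 0.001"), and outcomes beyond the first when
an article reports several.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ebayes import ZDataset

__all__ = [
    "StudyRecord",
    "ReadProblem",
    "SchemaError",
    "read_collection",
    "apply_collection_filters",
    "to_zdataset",
    "P_EXCLUSION_THRESHOLD",
]

#: p-values strictly below this are excluded (p = 0.001 exactly is kept).
P_EXCLUSION_THRESHOLD = 0.001

_REQUIRED_COLUMNS = ("study_id", "p_value")
_FLAG_COLUMNS = ("is_intercept", "is_f_test")
_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class StudyRecord:
    """One reported two-sided p-value with its eligibility flags."""

    study_id: str
    p_value: float
    is_intercept: bool = False
    is_f_test: bool = False
    outcome_rank: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.outcome_rank < 1:
            raise ValueError(f"outcome_rank must be >= 1, got {self.outcome_rank}")


@dataclass(frozen=True)
class ReadProblem:
    """A malformed row: its 1-based line number in the file and the reason."""

    line: int
    message: str


class SchemaError(ValueError):
    """The file is missing required columns (not a row-level problem)."""


def _parse_bool(raw: object, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"column {column!r} has non-boolean value {raw!r}")


def read_collection(
    path: str | Path,
) -> "tuple[list[StudyRecord], list[ReadProblem]]":
    """Read a p-value collection CSV, validating row by row.

    Required columns: ``study_id``, ``p_value``.  Optional columns
    ``is_intercept``, ``is_f_test`` (boolean-ish) and ``outcome_rank``
    (positive integer) default to false / 1.  Malformed rows -- a
    non-numeric p (articles often print only "NS" or "p < 0.05"; such
    summaries cannot be used), p outside (0, 1], bad flags -- are collected
    as :class:`ReadProblem` with their line numbers, never silently dropped.
    Missing required columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    problems: list[ReadProblem] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based, after the header line
        try:
            raw_p = str(row["p_value"]).strip()
            try:
                p = float(raw_p)
            except ValueError:
                raise ValueError(
                    f"p_value {raw_p!r} is not a number (imprecise summaries "
                    'such as "NS" or "p < 0.05" cannot be used)'
                ) from None
            if not (0.0 < p <= 1.0) or not math.isfinite(p):
                raise ValueError(f"p_value {p} outside (0, 1]")
            flags = {
                col: _parse_bool(row[col], col) if col in df.columns else False
                for col in _FLAG_COLUMNS
            }
            if "outcome_rank" in df.columns and str(row["outcome_rank"]).strip() != "":
                rank = int(str(row["outcome_rank"]).strip())
            else:
                rank = 1
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]).strip(),
                    p_value=p,
                    is_intercept=flags["is_intercept"],
                    is_f_test=flags["is_f_test"],
                    outcome_rank=rank,
                )
            )
        except ValueError as exc:
            problems.append(ReadProblem(line=line, message=str(exc)))
    return records, problems


def apply_collection_filters(
    records: "list[StudyRecord]",
) -> "tuple[list[StudyRecord], list[tuple[StudyRecord, str]]]":
    """Apply the eligibility rules; every drop is labelled with its rule.

    Drops, in order of precedence: intercept rows, F-test rows, p-values
    strictly below 0.001 (``p = 0.001`` exactly is kept), and rows for
    outcomes beyond the first.  Returns ``(kept, dropped)`` with
    ``len(kept) + len(dropped) == len(records)``; idempotent on the kept
    list.
    """
    kept: list[StudyRecord] = []
    dropped: list[tuple[StudyRecord, str]] = []
    for rec in records:
        if rec.is_intercept:
            dropped.append((rec, "intercept"))
        elif rec.is_f_test:
            dropped.append((rec, "f-test"))
        elif rec.p_value < P_EXCLUSION_THRESHOLD:
            dropped.append((rec, "p<0.001"))
        elif rec.outcome_rank > 1:
            dropped.append((rec, "secondary-outcome"))
        else:
            kept.append(rec)
    return kept, dropped


def to_zdataset(records: "list[StudyRecord]") -> ZDataset:
    """Convert filtered records to squared z-values grouped by study.

    Each two-sided p maps to ``z^2 = (Phi^{-1}(p/2))^2``.  The sign of the
    underlying z is unknown and irrelevant: only symmetric priors are under
    consideration, and the hierarchical model is fitted to ``z^2``.
    """
    if not records:
        raise ValueError("no records to convert")
    p = np.array([r.p_value for r in records])
    sids = np.array([r.study_id for r in records])
    z2 = np.square(norm.isf(p / 2.0))
    return ZDataset(study_ids=sids, z2=z2)
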