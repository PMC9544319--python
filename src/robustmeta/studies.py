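"""Study outcome tables and Cochrane risk-of-bias tables.

A meta-analysis dataset is a table of K two-arm studies with binary
outcomes: per study, responder counts and arm sizes for the control
(j=1) and treatment (j=2) arms.  The companion risk-of-bias table rates
each study as low / unclear / high on the six Cochrane bias domains.
Row order is significant throughout: quality vectors are positional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError

#: Ordered Cochrane risk-of-bias domains; CSV column names.
ROB_DOMAINS: tuple[str, ...] = (
    "d1_sequence",      # random sequence generation (selection bias)
    "d2_allocation",    # allocation concealment (selection bias)
    "d3_blinding",      # blinding of participants and personnel (performance bias)
    "d4_attrition",     # incomplete outcome data (attrition bias)
    "d5_reporting",     # selective outcome reporting (reporting bias)
    "d6_other",         # other potential sources of bias
)

RATINGS = ("low", "unclear", "high")

STUDY_COLUMNS = ("study_id", "r_control", "n_control", "r_treatment", "n_treatment")


@dataclass(frozen=True)
class StudyOutcome:
    """One two-arm study with binary outcome counts."""

    study_id: str
    r_control: int
    n_control: int
    r_treatment: int
    n_treatment: int

    def __post_init__(self) -> None:
        if not self.study_id:
            raise DataValidationError("study_id must be nonempty")
        for r, n, arm in (
            (self.r_control, self.n_control, "control"),
            (self.r_treatment, self.n_treatment, "treatment"),
        ):
            if n < 1:
                raise DataValidationError(
                    f"study {self.study_id!r}: {arm} arm size must be >= 1, got {n}"
                )
            if not 0 <= r <= n:
                raise DataValidationError(
                    f"study {self.study_id!r}: {arm} responders {r} outside [0, {n}]"
                )


@dataclass(frozen=True)
class StudyTable:
    """Ordered collection of studies; the unit of analysis."""

    studies: tuple[StudyOutcome, ...]

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise DataValidationError("StudyTable needs at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate study_ids: {dup}")

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (r_control, n_control, r_treatment, n_treatment), shape (K,)."""
        r1 = np.array([s.r_control for s in self.studies], dtype=float)
        n1 = np.array([s.n_control for s in self.studies], dtype=float)
        r2 = np.array([s.r_treatment for s in self.studies], dtype=float)
        n2 = np.array([s.n_treatment for s in self.studies], dtype=float)
        return r1, n1, r2, n2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.study_id, s.r_control, s.n_control, s.r_treatment, s.n_treatment)
                for s in self.studies
            ],
            columns=list(STUDY_COLUMNS),
        )


@dataclass(frozen=True)
class RobTable:
    """Risk-of-bias ratings per study and domain, aligned to a StudyTable.

    ``ratings[study_id][domain]`` is one of ``'low'``, ``'unclear'``,
    ``'high'``.
    """

    study_ids: tuple[str, ...]
    ratings: Mapping[str, Mapping[str, str]]
    domains: tuple[str, ...] = ROB_DOMAINS

    def __post_init__(self) -> None:
        for sid in self.study_ids:
            if sid not in self.ratings:
                raise DataValidationError(f"no risk-of-bias row for study {sid!r}")
            for dom in self.domains:
                val = self.ratings[sid].get(dom)
                if val not in RATINGS:
                    raise DataValidationError(
                        f"study {sid!r}, domain {dom!r}: rating {val!r} "
                        f"not one of {RATINGS}"
                    )

    def rating(self, study_id: str, domain: str) -> str:
        return self.ratings[study_id][domain]

    def column(self, domain: str) -> tuple[str, ...]:
        """Ratings for one domain in study order."""
        if domain not in self.domains:
            raise SchemaError(f"unknown domain {domain!r}; expected one of {self.domains}")
        return tuple(self.ratings[sid][domain] for sid in self.study_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            [sid] + [self.ratings[sid][dom] for dom in self.domains]
            for sid in self.study_ids
        ]
        return pd.DataFrame(rows, columns=["study_id", *self.domains])


def read_studies(path: str | Path) -> StudyTable:
    """Read a study outcome table from CSV, preserving row order."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    studies = []
    for _, row in df.iterrows():
        studies.append(
            StudyOutcome(
                study_id=str(row["study_id"]),
                r_control=int(row["r_control"]),
                n_control=int(row["n_control"]),
                r_treatment=int(row["r_treatment"]),
                n_treatment=int(row["n_treatment"]),
            )
        )
    return StudyTable(studies=tuple(studies))


def write_studies(table: StudyTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_rob_table(path: str | Path, studies: StudyTable) -> RobTable:
    """Read a risk-of-bias CSV and align it to ``studies``.

    Rating tokens are matched case-insensitively.  The set of study ids
    must match the study table exactly.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "study_id" not in df.columns:
        raise SchemaError(f"{path}: missing column 'study_id'")
    missing = [c for c in ROB_DOMAINS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing domain columns {missing}")
    file_ids = [str(x) for x in df["study_id"]]
    want = set(studies.study_ids)
    have = set(file_ids)
    if want != have:
        raise DataValidationError(
            f"{path}: study mismatch; missing {sorted(want - have)}, "
            f"unexpected {sorted(have - want)}"
        )
    ratings: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        sid = str(row["study_id"])
        ratings[sid] = {}
        for dom in ROB_DOMAINS:
            token = str(row[dom]).strip().lower()
            if token not in RATINGS:
                raise DataValidationError(
                    f"{path}: study {sid!r}, domain {dom!r}: "
                    f"unknown rating token {row[dom]!r}"
                )
            ratings[sid][dom] = token
    return RobTable(study_ids=studies.study_ids, ratings=ratings)


def write_rob_table(rob: RobTable, path: str | Path) -> None:
    rob.to_frame().to_csv(path, index=False)


def empirical_log_or(study: StudyOutcome) -> tuple[float, float]:
    """Classical log-odds-ratio estimate and standard error for one study.

    Uses the four 2x2 cells (responders / non-responders per arm).  If
    any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe
    continuity correction).  Display statistic only; the Bayesian model
    never uses it.
    """
    a = float(study.r_control)
    b = float(study.n_control - study.r_control)
    c = float(study.r_treatment)
    d = float(study.n_treatment - study.r_treatment)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = math.log((c * b) / (a * d))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return est, se
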