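"""Cohort encoding and the fixed 11-column design matrix.

The regression design is shared by every voxel: four base covariates —
sex (1 = male), years of cocaine use (YCU), and two binary SNP carrier
indicators (GAD1a = rs1978340, GAD1b = rs769390) — plus all two-way
interactions and the YCU|GAD1a|GAD1b three-way interaction, eleven
columns in total. Interaction columns are elementwise products of the
raw (uncentered) parent columns; any centering for the prior happens in
the BMA engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed column order of the design matrix. Bit i of a model mask refers
#: to COLUMN_NAMES[i] everywhere in this package.
COLUMN_NAMES: tuple[str, ...] = (
    "Sex",
    "YCU",
    "GAD1a",
    "GAD1b",
    "Sex|YCU",
    "Sex|GAD1a",
    "Sex|GAD1b",
    "YCU|GAD1a",
    "YCU|GAD1b",
    "GAD1a|GAD1b",
    "YCU|GAD1a|GAD1b",
)

N_COVARIATES: int = len(COLUMN_NAMES)

_BASE_FIELDS = ("sex", "ycu", "gad1a", "gad1b")
_GROUPS = ("CUD", "control")


@dataclass(frozen=True)
class SubjectCovariates:
    """One study participant.

    Parameters
    ----------
    subject_id:
        Opaque identifier; must be unique within a cohort.
    group:
        ``"CUD"`` (cocaine use disorder) or ``"control"``.
    sex:
        1 = male, 0 = female.
    ycu:
        Years of cocaine use; 0 for controls by inclusion criteria.
    gad1a, gad1b:
        Binary SNP carrier indicators.
    """

    subject_id: str
    group: str
    sex: int
    ycu: float
    gad1a: int
    gad1b: int

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: group must be one of {_GROUPS}, "
                f"got {self.group!r}"
            )
        for name in ("sex", "gad1a", "gad1b"):
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValueError(
                    f"subject {self.subject_id!r}: {name} must be 0 or 1, got {value!r}"
                )
        if not np.isfinite(self.ycu) or self.ycu < 0:
            raise ValueError(
                f"subject {self.subject_id!r}: ycu must be a non-negative real, "
                f"got {self.ycu!r}"
            )
        if self.group == "control" and self.ycu != 0:
            raise ValueError(
                f"subject {self.subject_id!r}: controls must have ycu = 0, "
                f"got {self.ycu!r}"
            )


@dataclass(frozen=True)
class DesignMatrix:
    """An n x 11 design matrix in the fixed column order.

    ``values[:, i]`` corresponds to ``column_names[i]``; rows follow the
    subject input order exactly (no hidden sorting).
    """

    values: np.ndarray
    column_names: tuple[str, ...] = COLUMN_NAMES
    subject_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("design values must be a 2-D array")
        if values.shape[1] != len(self.column_names):
            raise ValueError(
                f"{values.shape[1]} columns but {len(self.column_names)} names"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("design matrix contains non-finite values")
        object.__setattr__(self, "values", values)


def build_design_matrix(subjects: Sequence[SubjectCovariates]) -> DesignMatrix:
    """Construct the fixed 11-column design matrix from a cohort.

    Columns follow :data:`COLUMN_NAMES`; interaction columns are products
    of the raw parent columns. Deterministic given the input order.

    Raises
    ------
    ValueError
        If fewer than two subjects are supplied or ids are duplicated.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError(f"need at least 2 subjects, got {len(subjects)}")
    ids = [s.subject_id for s in subjects]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(dupes)}")

    sex = np.array([s.sex for s in subjects], dtype=float)
    ycu = np.array([s.ycu for s in subjects], dtype=float)
    g1a = np.array([s.gad1a for s in subjects], dtype=float)
    g1b = np.array([s.gad1b for s in subjects], dtype=float)

    values = np.column_stack(
        [
            sex,
            ycu,
            g1a,
            g1b,
            sex * ycu,
            sex * g1a,
            sex * g1b,
            ycu * g1a,
            ycu * g1b,
            g1a * g1b,
            ycu * g1a * g1b,
        ]
    )
    return DesignMatrix(values=values, column_names=COLUMN_NAMES, subject_ids=tuple(ids))


def validate_cohort(subjects: Sequence[SubjectCovariates]) -> dict:
    """Report-only cohort sanity check.

    Returns a dict with group sizes, covariate ranges, carrier
    frequencies, a list of warning flags (constant covariates), and a
    list of fatal flags (empty cohort, n < 2). Never raises.
    """
    subjects = list(subjects)
    report: dict = {
        "n": len(subjects),
        "group_sizes": {},
        "ranges": {},
        "carrier_frequencies": {},
        "flags": [],
        "fatal": [],
    }
    if not subjects:
        report["fatal"].append("empty cohort (n = 0)")
        return report
    if len(subjects) < 2:
        report["fatal"].append("fewer than 2 subjects")

    for grp in _GROUPS:
        report["group_sizes"][grp] = sum(1 for s in subjects if s.group == grp)

    for name in _BASE_FIELDS:
        col = np.array([getattr(s, name) for s in subjects], dtype=float)
        report["ranges"][name] = (float(col.min()), float(col.max()))
        if np.all(col == col[0]):
            report["flags"].append(f"{name_for_flag(name)} is constant")
    for snp in ("gad1a", "gad1b"):
        col = np.array([getattr(s, snp) for s in subjects], dtype=float)
        report["carrier_frequencies"][snp] = float(col.mean())
    return report


def name_for_flag(field_name: str) -> str:
    """Map an internal field name to its display name in reports."""
    return {"sex": "Sex", "ycu": "YCU", "gad1a": "GAD1a", "gad1b": "GAD1b"}[field_name]


def read_covariates_tsv(path: str | Path) -> list[SubjectCovariates]:
    """Read a cohort from TSV with columns subject_id, group, sex, ycu, gad1a, gad1b."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    required = ["subject_id", "group", "sex", "ycu", "gad1a", "gad1b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table {path} missing columns: {missing}")
    subjects = []
    for row in df.itertuples(index=False):
        if pd.isna(row.sex) or pd.isna(row.ycu) or pd.isna(row.gad1a) or pd.isna(row.gad1b):
            raise ValueError(f"subject {row.subject_id!r}: missing covariate field")
        subjects.append(
            SubjectCovariates(
                subject_id=str(row.subject_id),
                group=str(row.group),
                sex=int(row.sex),
                ycu=float(row.ycu),
                gad1a=int(row.gad1a),
                gad1b=int(row.gad1b),
            )
        )
    return subjects


def write_covariates_tsv(subjects: Iterable[SubjectCovariates], path: str | Path) -> None:
    """Write a cohort to the TSV format read by :func:`read_covariates_tsv`."""
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "ycu": s.ycu,
                "gad1a": s.gad1a,
                "gad1b": s.gad1b,
            }
            for s in subjects
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
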