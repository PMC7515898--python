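"""Methylation table I/O, pooling, QC exclusions and train/test splitting.

Tables are thin wrappers around :class:`pandas.DataFrame` with the fixed
column layout ``sample_id, age, study, cpg1..cpg7`` (plus an optional
``role`` column). Methylation is kept on the percent (0-100) scale
throughout; fraction-scale (0-1) input is rejected unless rescaling is
requested explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

N_CPGS = 7
CPG_COLUMNS = tuple(f"cpg{i}" for i in range(1, N_CPGS + 1))
REQUIRED_COLUMNS = ("sample_id", "age", "study") + CPG_COLUMNS
ROLES = ("unassigned", "training", "testing", "independent")
MISSING_MARKERS = ("", "NA", "na", "NaN", "nan")


@dataclass(frozen=True)
class MethylationSample:
    """One individual's age, study label and 7-CpG methylation vector.

    Missing methylation values are carried as ``nan``.
    """

    sample_id: str
    age: float
    study: str
    methylation: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"sample {self.sample_id!r}: age must be >= 0, got {self.age}")
        if len(self.methylation) != N_CPGS:
            raise ValidationError(
                f"sample {self.sample_id!r}: methylation vector must have length {N_CPGS}"
            )
        for i, v in enumerate(self.methylation, start=1):
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: cpg{i} value {v} outside [0, 100]"
                )

    @property
    def has_missing(self) -> bool:
        return any(math.isnan(v) for v in self.methylation)


class CohortTable:
    """Ordered collection of samples with a dataset role.

    Wraps a DataFrame; sample ids must be unique. ``role`` applies to the
    table as a whole (per-sample roles live in an optional ``role`` column
    used when reproducing a pre-assigned split).
    """

    def __init__(self, frame: pd.DataFrame, role: str = "unassigned"):
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}; expected one of {ROLES}")
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise FormatError(f"table is missing required column(s): {', '.join(missing_cols)}")
        frame = frame.reset_index(drop=True)
        ids = frame["sample_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if (frame["age"] < 0).any():
            bad = frame.index[frame["age"] < 0][0]
            raise ValidationError(f"row {bad}: negative age")
        meth = frame[list(CPG_COLUMNS)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (meth < 0) | (meth > 100)
        if np.any(out_of_range & ~np.isnan(meth)):
            row = int(np.argwhere(out_of_range & ~np.isnan(meth))[0, 0])
            raise ValidationError(f"row {row}: methylation outside [0, 100]")
        self._frame = frame
        self.role = role

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def n_samples(self) -> int:
        return len(self._frame)

    @property
    def sample_ids(self) -> list[str]:
        return self._frame["sample_id"].astype(str).tolist()

    @property
    def ages(self) -> np.ndarray:
        return self._frame["age"].to_numpy(dtype=float)

    @property
    def studies(self) -> list[str]:
        return self._frame["study"].astype(str).tolist()

    @property
    def methylation(self) -> np.ndarray:
        """(n, 7) array of percentages, nan marking missing values."""
        return self._frame[list(CPG_COLUMNS)].to_numpy(dtype=float)

    @property
    def samples(self) -> list[MethylationSample]:
        return [
            MethylationSample(
                sample_id=str(r.sample_id),
                age=float(r.age),
                study=str(r.study),
                methylation=tuple(float(getattr(r, c)) for c in CPG_COLUMNS),
            )
            for r in self._frame.itertuples(index=False)
        ]

    def with_role(self, role: str) -> "CohortTable":
        return CohortTable(self._frame.copy(), role=role)

    def subset(self, mask: Sequence[bool], role: str | None = None) -> "CohortTable":
        sub = self._frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return CohortTable(sub, role=role or self.role)

    def __len__(self) -> int:
        return self.n_samples

    def __repr__(self) -> str:
        return f"CohortTable(n={self.n_samples}, role={self.role!r})"


@dataclass
class ExclusionReport:
    """Bookkeeping for QC exclusions; counts must reconcile."""

    excluded_outliers: list[str] = field(default_factory=list)
    excluded_missing: list[str] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        expected = self.n_input - len(self.excluded_outliers) - len(self.excluded_missing)
        if self.n_retained != expected:
            raise ValidationError(
                f"exclusion report does not reconcile: {self.n_retained} != {expected}"
            )


def pool_tables(tables: Iterable[CohortTable]) -> CohortTable:
    """Concatenate study tables into one pooled table."""
    frames = [t.frame for t in tables]
    if not frames:
        raise ValidationError("no tables to pool")
    return CohortTable(pd.concat(frames, ignore_index=True))


def read_methylation_table(
    path: str | Path,
    dialect: str = "csv",
    rescale_fractions: bool = False,
) -> CohortTable:
    """Read a methylation table from CSV/TSV.

    Header must contain ``sample_id, age, study, cpg1..cpg7``
    (case-insensitive); missing methylation is an empty field or ``NA``.
    If every non-missing methylation value is <= 1.0 the file is assumed to
    be on the fraction scale and rejected unless ``rescale_fractions`` is
    set, in which case values are multiplied by 100.
    """
    path = Path(path)
    if dialect not in ("csv", "tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    frame = pd.read_csv(path, sep=sep, na_values=list(MISSING_MARKERS), keep_default_na=False)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if "sample_id" in frame.columns:
        frame["sample_id"] = frame["sample_id"].astype(str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing_cols)}"
        )
    meth = frame[list(CPG_COLUMNS)].to_numpy(dtype=float)
    nonmissing = meth[~np.isnan(meth)]
    if nonmissing.size and np.all(nonmissing <= 1.0):
        if rescale_fractions:
            frame[list(CPG_COLUMNS)] = meth * 100.0
        else:
            raise ValidationError(
                f"{path.name}: all methylation values are <= 1.0; input looks like the "
                "0-1 fraction scale. Pass rescale_fractions=True to convert to percent."
            )
    with np.errstate(invalid="ignore"):
        bad = (meth < 0) | (meth > 100)
    bad &= ~np.isnan(meth)
    if not rescale_fractions and np.any(bad):
        row = int(np.argwhere(bad)[0, 0])
        raise ValidationError(f"{path.name}: row {row}: methylation outside [0, 100]")
    role = "unassigned"
    if "role" in frame.columns:
        roles = set(frame["role"].astype(str).unique())
        if len(roles) == 1 and roles <= set(ROLES):
            role = roles.pop()
    return CohortTable(frame, role=role)


def write_methylation_table(table: CohortTable, path: str | Path, dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    table.frame.to_csv(path, sep=sep, index=False)


def read_exclusion_list(path: str | Path) -> list[str]:
    """Plain-text exclusion list: one sample_id per line, '#' comments."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def apply_exclusions(
    table: CohortTable, outlier_ids: Sequence[str]
) -> tuple[CohortTable, ExclusionReport]:
    """Drop listed outliers plus every sample with a missing methylation value.

    Unknown outlier ids are logged and ignored. A sample missing any of the
    7 CpGs is excluded entirely (no per-combination rescue).
    """
    known = set(table.sample_ids)
    outliers = []
    for sid in outlier_ids:
        if sid in known:
            outliers.append(sid)
        else:
            logger.warning("unknown outlier sample_id %r ignored", sid)
    outlier_set = set(outliers)
    meth = table.methylation
    ids = table.sample_ids
    missing_ids = [
        sid
        for sid, row in zip(ids, np.isnan(meth).any(axis=1))
        if row and sid not in outlier_set
    ]
    keep = [sid not in outlier_set and sid not in set(missing_ids) for sid in ids]
    retained = table.subset(keep)
    report = ExclusionReport(
        excluded_outliers=sorted(outlier_set),
        excluded_missing=missing_ids,
        n_input=table.n_samples,
        n_retained=retained.n_samples,
    )
    return retained, report


def random_split(
    table: CohortTable, n_training: int, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint partition into training/testing of sizes (n_training, rest)."""
    n = table.n_samples
    if not 0 < n_training < n:
        raise ValidationError(f"n_training must be in (0, {n}), got {n_training}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_mask = np.zeros(n, dtype=bool)
    train_mask[perm[:n_training]] = True
    training = table.subset(train_mask, role="training")
    testing = table.subset(~train_mask, role="testing")
    training.frame["role"] = "training"
    testing.frame["role"] = "testing"
    return training, testing


def split_by_role(table: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Reproduce a pre-assigned split from the table's ``role`` column."""
    if "role" not in table.frame.columns:
        raise FormatError("table has no 'role' column to split by")
    roles = table.frame["role"].astype(str)
    bad = set(roles.unique()) - {"training", "testing"}
    if bad:
        raise ValidationError(f"role column contains values other than training/testing: {bad}")
    training = table.subset((roles == "training").to_numpy(), role="training")
    testing = table.subset((roles == "testing").to_numpy(), role="testing")
    return training, testing


def write_predictions(
    table: CohortTable, predictions: Sequence[float], path: str | Path
) -> None:
    """Write per-sample predictions as CSV (sample_id, age, predicted_age, residual)."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (table.n_samples,):
        raise ValidationError(
            f"got {predictions.size} predictions for {table.n_samples} samples"
        )
    out = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "age": table.ages,
            "predicted_age": predictions,
            "residual": predictions - table.ages,
        }
    )
    out.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("sample_id", "age", "predicted_age", "residual") if c not in frame.columns]
    if missing:
        raise FormatError(f"prediction file missing column(s): {', '.join(missing)}")
    return frame
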