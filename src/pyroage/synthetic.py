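"""Synthetic cohorts and technical-replicate grids.

Generates methylation tables with the statistical structure the downstream
analysis assumes: per-CpG quadratic mean curves in age, a shared latent
factor inducing inter-CpG correlation, per-study batch offsets, and a
3-PCR x 2-PSQ replicate hierarchy whose same-PCR cells correlate more
strongly than cross-PCR cells.

The cohort-level methylation of a sample is its latent value; replicate
grids add PCR- and PSQ-level noise around that same latent value, so
replicate averaging converges back to the cohort value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_qc import CPG_COLUMNS, N_CPGS, CohortTable

PCR_LABELS = ("A", "B", "C")
PSQ_LABELS = (1, 2)
GRID_CELLS = tuple((p, q) for p in PCR_LABELS for q in PSQ_LABELS)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Mean methylation of CpG i at age y is ``a[i] + b[i]*y + c[i]*y**2``;
    a latent factor with SD ``shared_factor_sd`` is added to all 7 CpGs of
    a sample (inducing inter-CpG correlation beyond the age signal) and
    independent noise with SD ``residual_sd`` per CpG. ``batch_offsets``
    maps study label -> 7-vector of additive percent shifts; studies are
    assigned uniformly at random among its keys. All values are clipped to
    [0, 100] after every additive term.
    """

    n_samples: int
    age_range: tuple[float, float] = (0.0, 91.0)
    curve_a: tuple[float, ...] = (7.0, 10.0, 12.0, 9.0, 8.0, 6.0, 11.0)
    curve_b: tuple[float, ...] = (0.55, 0.50, 0.45, 0.60, 0.65, 0.70, 0.50)
    curve_c: tuple[float, ...] = (0.0015, 0.0010, 0.0008, 0.0012, 0.0005, 0.0010, 0.0020)
    shared_factor_sd: float = 2.5
    residual_sd: float = 2.0
    batch_offsets: Mapping[str, Sequence[float]] = field(default_factory=dict)
    pcr_sd: float = 1.5
    psq_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        lo, hi = self.age_range
        if lo < 0 or hi < lo:
            raise ValidationError(f"invalid age_range {self.age_range}")
        for name in ("curve_a", "curve_b", "curve_c"):
            if len(getattr(self, name)) != N_CPGS:
                raise ValidationError(f"{name} must have length {N_CPGS}")
        for name in ("shared_factor_sd", "residual_sd", "pcr_sd", "psq_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for study, offs in self.batch_offsets.items():
            if len(offs) != N_CPGS:
                raise ValidationError(f"batch_offsets[{study!r}] must have length {N_CPGS}")

    def mean_curve(self, ages: np.ndarray) -> np.ndarray:
        """Noiseless (n, 7) mean methylation at the given ages."""
        y = np.asarray(ages, dtype=float)[:, None]
        a = np.asarray(self.curve_a)
        b = np.asarray(self.curve_b)
        c = np.asarray(self.curve_c)
        return a[None, :] + b[None, :] * y + c[None, :] * y**2


def default_cohort_config(n_samples: int = 1000, seed: int = 0) -> SyntheticConfig:
    """Documented defaults emulating the pooled pyrosequencing cohorts.

    The noiseless curves are increasing on [0, 91] and stay inside
    [0, 100]; at n = 1000 every CpG correlates with age at r > 0.7 and all
    pairwise inter-CpG correlations exceed 0.7.
    """
    return SyntheticConfig(n_samples=n_samples, seed=seed)


@dataclass(frozen=True)
class ReplicateGrid:
    """One sample's methylation on the 3-PCR x 2-PSQ grid."""

    sample_id: str
    methylation_by_replicate: Mapping[tuple[str, int], tuple[float, ...]]

    def __post_init__(self) -> None:
        cells = set(self.methylation_by_replicate)
        if cells != set(GRID_CELLS):
            missing = sorted(set(GRID_CELLS) - cells)
            raise ValidationError(f"replicate grid {self.sample_id!r} missing cells: {missing}")
        for cell, values in self.methylation_by_replicate.items():
            if len(values) != N_CPGS:
                raise ValidationError(f"grid {self.sample_id!r} cell {cell}: need {N_CPGS} values")
            arr = np.asarray(values, dtype=float)
            if np.any((arr < 0) | (arr > 100)):
                raise ValidationError(f"grid {self.sample_id!r} cell {cell}: value outside [0, 100]")

    def cell(self, pcr: str, psq: int) -> np.ndarray:
        return np.asarray(self.methylation_by_replicate[(pcr, psq)], dtype=float)

    def mean_over(self, cells: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.mean([self.cell(p, q) for p, q in cells], axis=0)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a cohort with true ages; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    studies = sorted(config.batch_offsets) or ["pooled"]
    study = rng.choice(studies, size=n) if len(studies) > 1 else np.full(n, studies[0])
    meth = config.mean_curve(ages)
    meth += rng.normal(0.0, config.shared_factor_sd, size=(n, 1))
    meth += rng.normal(0.0, config.residual_sd, size=(n, N_CPGS))
    for label, offsets in config.batch_offsets.items():
        meth[study == label] += np.asarray(offsets, dtype=float)[None, :]
    meth = np.clip(meth, 0.0, 100.0)
    frame = pd.DataFrame({"sample_id": [f"S{i:05d}" for i in range(n)],
                          "age": ages, "study": study})
    for j, col in enumerate(CPG_COLUMNS):
        frame[col] = meth[:, j]
    return CohortTable(frame)


def generate_replicate_grids(
    cohort: CohortTable, config: SyntheticConfig
) -> list[ReplicateGrid]:
    """Emit one 6-cell grid per cohort sample.

    Cell value = cohort (latent) methylation + per-PCR effect shared by
    both PSQs of that PCR + per-PSQ noise, clipped to [0, 100]. Uses a
    seed stream derived from ``config.seed`` so grids are reproducible and
    decoupled from cohort generation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    grids: list[ReplicateGrid] = []
    latent = cohort.methylation
    if np.isnan(latent).any():
        raise ValidationError("cohort has missing methylation; cannot build replicate grids")
    for sid, row in zip(cohort.sample_ids, latent):
        cells: dict[tuple[str, int], tuple[float, ...]] = {}
        for pcr in PCR_LABELS:
            pcr_effect = rng.normal(0.0, config.pcr_sd, size=N_CPGS)
            for psq in PSQ_LABELS:
                value = row + pcr_effect + rng.normal(0.0, config.psq_sd, size=N_CPGS)
                cells[(pcr, psq)] = tuple(np.clip(value, 0.0, 100.0))
        grids.append(ReplicateGrid(sample_id=sid, methylation_by_replicate=cells))
    return grids


def grids_to_frame(grids: Sequence[ReplicateGrid]) -> pd.DataFrame:
    """Long-format replicate table: sample_id, pcr, psq, cpg1..cpg7."""
    rows = []
    for g in grids:
        for (pcr, psq) in GRID_CELLS:
            row = {"sample_id": g.sample_id, "pcr": pcr, "psq": psq}
            row.update(dict(zip(CPG_COLUMNS, g.cell(pcr, psq))))
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_grids(frame: pd.DataFrame) -> list[ReplicateGrid]:
    required = {"sample_id", "pcr", "psq", *CPG_COLUMNS}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"replicate table missing column(s): {sorted(missing)}")
    grids = []
    for sid, sub in frame.groupby("sample_id", sort=False):
        cells = {}
        for r in sub.itertuples(index=False):
            cells[(str(r.pcr), int(r.psq))] = tuple(
                float(getattr(r, c)) for c in CPG_COLUMNS
            )
        grids.append(ReplicateGrid(sample_id=str(sid), methylation_by_replicate=cells))
    return grids


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
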