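"""Exhaustive combination search, accuracy metrics, replicate schemes and
multicollinearity diagnostics.

The search fits every (family, combination) pair — the quadratic-regression
family over all non-empty subsets of its 14 variables (16,383), every other
family over all non-empty subsets of the 7 CpGs (127 each) — and records
Pearson R, MAD and RMSE on both the training and the testing set. Best
combinations are always reported under BOTH reference sets; the caller
must name which one drives selection.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imputation import MmdaConfig, build_imputation_matrix, mmda_impute
from .io_qc import CPG_COLUMNS, N_CPGS, CohortTable
from .models import (
    FittedModel,
    ModelSpec,
    PredictorCombination,
    _FITTERS,
    _fingerprint,
    expand_design,
    zp1_combination,
)
from .synthetic import GRID_CELLS, PCR_LABELS, PSQ_LABELS, ReplicateGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValidationError(
            f"predicted/observed must be equal-length non-empty vectors, got {p.shape} vs {o.shape}"
        )
    return p, o


def compute_mad(predicted, observed) -> float:
    """Mean absolute deviation of predicted from observed ages, in years."""
    p, o = _paired(predicted, observed)
    return float(np.mean(np.abs(p - o)))


def compute_rmse(predicted, observed) -> float:
    """Root mean square error, in years."""
    p, o = _paired(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def compute_pearson_r(x, y) -> float:
    """Product-moment correlation; raises on degenerate (constant) input."""
    a, b = _paired(x, y)
    if a.size < 2:
        raise ValidationError("pearson r needs n >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("pearson r undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class MetricSet:
    pearson_r: float
    mad: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.mad < 0 or self.rmse < 0:
            raise ValidationError("mad and rmse must be >= 0")
        if self.rmse < self.mad - 1e-9:
            raise ValidationError(f"rmse {self.rmse} < mad {self.mad} violates the power-mean inequality")

    @classmethod
    def evaluate(cls, predicted, observed) -> "MetricSet":
        p, o = _paired(predicted, observed)
        return cls(
            pearson_r=compute_pearson_r(p, o),
            mad=compute_mad(p, o),
            rmse=compute_rmse(p, o),
            n=int(p.size),
        )


# ---------------------------------------------------------------------------
# combination enumeration
# ---------------------------------------------------------------------------

def scope_variables(scope: str) -> list:
    if scope == "cpg7":
        return list(range(1, N_CPGS + 1))
    if scope == "mqr14":
        return [(i, 1) for i in range(1, N_CPGS + 1)] + [(i, 2) for i in range(1, N_CPGS + 1)]
    raise ValidationError(f"unknown scope {scope!r}")


def enumerate_combinations(scope: str) -> list[PredictorCombination]:
    """All non-empty variable subsets, ordered by size then lexicographically.

    cpg7 -> 127 combinations; mqr14 -> 16,383.
    """
    variables = scope_variables(scope)
    out = []
    for size in range(1, len(variables) + 1):
        for subset in iter_combinations(variables, size):
            out.append(PredictorCombination(scope=scope, variables=subset))
    return out


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------

@dataclass
class SearchRecord:
    family: str
    combination_label: str
    n_variables: int
    metrics_training: MetricSet | None
    metrics_testing: MetricSet | None
    hyperparameter_fingerprint: str
    failed: bool = False
    reason: str = ""


def family_scope(family: str) -> str:
    return "mqr14" if family == "mqr" else "cpg7"


def search_plan(specs: Sequence[ModelSpec]) -> dict[str, int]:
    """Per-family combination counts for a search, plus the grand total.

    ``zp1_mlr`` contributes its single fixed combination; every other
    family contributes the full enumeration of its scope.
    """
    plan: dict[str, int] = {}
    for spec in specs:
        if spec.family == "zp1_mlr":
            plan[spec.family] = 1
        else:
            plan[spec.family] = 2 ** len(scope_variables(family_scope(spec.family))) - 1
    plan["total"] = sum(plan.values())
    return plan


def _checkpoint_path(checkpoint_dir: Path, family: str) -> Path:
    return checkpoint_dir / f"records_{family}.csv"


_CHECKPOINT_FIELDS = (
    "family", "combination_label", "n_variables",
    "r_train", "mad_train", "rmse_train", "n_train",
    "r_test", "mad_test", "rmse_test", "n_test",
    "hyperparameter_fingerprint", "failed", "reason",
)


def _record_to_row(rec: SearchRecord) -> dict:
    row = {
        "family": rec.family,
        "combination_label": rec.combination_label,
        "n_variables": rec.n_variables,
        "hyperparameter_fingerprint": rec.hyperparameter_fingerprint,
        "failed": int(rec.failed),
        "reason": rec.reason,
    }
    for tag, m in (("train", rec.metrics_training), ("test", rec.metrics_testing)):
        row[f"r_{tag}"] = "" if m is None else repr(m.pearson_r)
        row[f"mad_{tag}"] = "" if m is None else repr(m.mad)
        row[f"rmse_{tag}"] = "" if m is None else repr(m.rmse)
        row[f"n_{tag}"] = "" if m is None else m.n
    return row


def _row_to_record(row: dict) -> SearchRecord:
    def metrics(tag: str) -> MetricSet | None:
        if row[f"mad_{tag}"] in ("", None):
            return None
        return MetricSet(
            pearson_r=float(row[f"r_{tag}"]),
            mad=float(row[f"mad_{tag}"]),
            rmse=float(row[f"rmse_{tag}"]),
            n=int(row[f"n_{tag}"]),
        )

    return SearchRecord(
        family=row["family"],
        combination_label=row["combination_label"],
        n_variables=int(row["n_variables"]),
        metrics_training=metrics("train"),
        metrics_testing=metrics("test"),
        hyperparameter_fingerprint=row["hyperparameter_fingerprint"],
        failed=bool(int(row["failed"])),
        reason=row.get("reason", ""),
    )


def _search_one_family(
    spec: ModelSpec,
    training: CohortTable,
    testing: CohortTable,
    checkpoint_dir: Path | None,
    progress: Callable[[str, int, int], None] | None,
) -> list[SearchRecord]:
    if spec.family == "zp1_mlr":
        combos = [zp1_combination()]
    else:
        combos = enumerate_combinations(family_scope(spec.family))

    done: dict[str, SearchRecord] = {}
    writer = None
    handle = None
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        path = _checkpoint_path(checkpoint_dir, spec.family)
        if path.exists():
            with open(path, newline="") as fh:
                for row in csv.DictReader(fh):
                    rec = _row_to_record(row)
                    done[rec.combination_label] = rec
        handle = open(path, "a", newline="")
        writer = csv.DictWriter(handle, fieldnames=_CHECKPOINT_FIELDS)
        if path.stat().st_size == 0:
            writer.writeheader()

    # full design matrices once; per-combination slicing avoids pandas churn
    scope = family_scope(spec.family) if spec.family != "zp1_mlr" else "cpg7"
    full = PredictorCombination(scope=scope, variables=scope_variables(scope))
    X_tr_full, y_tr = expand_design(training, full)
    X_te_full, y_te = expand_design(testing, full)
    col_of = {term: j for j, term in enumerate(full.design_terms())}

    mmda_cfg = None
    if spec.family == "mmda":
        hp = spec.hyperparameters
        mmda_cfg = MmdaConfig(
            ncp=int(hp["ncp"]),
            regularization=str(hp["regularization"]),
            tol=float(hp["tol"]),
            max_iter=int(hp["max_iter"]),
            scale_columns=bool(hp["scale_columns"]),
        )

    records: list[SearchRecord] = []
    total = len(combos)
    for idx, combo in enumerate(combos):
        if combo.label in done:
            records.append(done[combo.label])
            continue
        cols = [col_of[t] for t in combo.design_terms()]
        X_tr = X_tr_full[:, cols]
        X_te = X_te_full[:, cols]
        try:
            if spec.family == "mmda":
                ncp = min(mmda_cfg.ncp, len(cols))  # joint matrix has len(cols)+1 columns
                cfg = MmdaConfig(ncp=ncp, regularization=mmda_cfg.regularization,
                                 tol=mmda_cfg.tol, max_iter=mmda_cfg.max_iter,
                                 scale_columns=mmda_cfg.scale_columns)
                pred_te = _mmda_predict(X_tr, y_tr, X_te, cfg)
                pred_tr = _mmda_predict(X_te, y_te, X_tr, cfg)
            else:
                params = _FITTERS[spec.family](X_tr, y_tr, spec)
                model = FittedModel(
                    spec=spec, combination=combo, parameters=params,
                    training_fingerprint=_fingerprint(X_tr, y_tr, spec),
                )
                pred_tr = model.predict_design(X_tr)
                pred_te = model.predict_design(X_te)
            rec = SearchRecord(
                family=spec.family,
                combination_label=combo.label,
                n_variables=combo.n_variables,
                metrics_training=MetricSet.evaluate(pred_tr, y_tr),
                metrics_testing=MetricSet.evaluate(pred_te, y_te),
                hyperparameter_fingerprint=spec.fingerprint(),
            )
        except Exception as exc:  # noqa: BLE001 - one bad fit must not kill the search
            rec = SearchRecord(
                family=spec.family,
                combination_label=combo.label,
                n_variables=combo.n_variables,
                metrics_training=None,
                metrics_testing=None,
                hyperparameter_fingerprint=spec.fingerprint(),
                failed=True,
                reason=f"{type(exc).__name__}: {exc}",
            )
        records.append(rec)
        if writer is not None:
            writer.writerow(_record_to_row(rec))
            handle.flush()
        if progress is not None and ((idx + 1) % 500 == 0 or idx + 1 == total):
            progress(spec.family, idx + 1, total)
    if handle is not None:
        handle.close()
    return records


def _mmda_predict(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mask: np.ndarray, cfg: MmdaConfig
) -> np.ndarray:
    from .imputation import ImputationMatrix

    n_obs, n_mask = len(y_obs), len(X_mask)
    values = np.column_stack(
        [np.vstack([X_obs, X_mask]), np.concatenate([y_obs, np.full(n_mask, np.nan)])]
    )
    mask = np.concatenate([np.zeros(n_obs, dtype=bool), np.ones(n_mask, dtype=bool)])
    matrix = ImputationMatrix(
        values=values,
        age_missing=mask,
        sample_ids=[f"o{i}" for i in range(n_obs)] + [f"m{i}" for i in range(n_mask)],
        columns=[f"v{j}" for j in range(X_obs.shape[1])] + ["age"],
    )
    return mmda_impute(matrix, cfg).imputed_ages


def run_exhaustive_search(
    training: CohortTable,
    testing: CohortTable,
    specs: Sequence[ModelSpec],
    checkpoint_dir: str | Path | None = None,
    progress: Callable[[str, int, int], None] | None = None,
) -> list[SearchRecord]:
    """Fit every (family, combination) pair and score it on both sets.

    mMDA is transductive: its testing metrics come from pooling the
    training rows (ages observed) with the testing rows (ages masked), and
    its training metrics from the role-swapped pooling. Individual fit
    failures are recorded, not raised. With a checkpoint directory the
    search resumes past already-recorded combinations.
    """
    if set(training.sample_ids) & set(testing.sample_ids):
        raise ValidationError("training and testing sets overlap")
    records: list[SearchRecord] = []
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    for spec in specs:
        logger.info("searching family %s", spec.family)
        records.extend(_search_one_family(spec, training, testing, ckpt, progress))
    return records


def records_to_frame(records: Sequence[SearchRecord]) -> pd.DataFrame:
    return pd.DataFrame([_record_to_row(r) for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[SearchRecord]:
    return [_row_to_record({k: row[k] for k in _CHECKPOINT_FIELDS}) for _, row in frame.iterrows()]


def select_best_combination(
    records: Sequence[SearchRecord], family: str, reference: str
) -> SearchRecord:
    """Minimal-MAD record for a family on the named reference set.

    Ties break to fewer variables, then lexicographic label, so selection
    is deterministic and invariant to record order.
    """
    if reference not in ("training", "testing"):
        raise ValidationError("reference must be 'training' or 'testing'")
    pool = [
        r for r in records
        if r.family == family and not r.failed
        and (r.metrics_training if reference == "training" else r.metrics_testing) is not None
    ]
    if not pool:
        raise ValidationError(f"no successful records for family {family!r}")

    def key(r: SearchRecord):
        m = r.metrics_training if reference == "training" else r.metrics_testing
        return (m.mad, r.n_variables, r.combination_label)

    return min(pool, key=key)


def summarize_best(
    records: Sequence[SearchRecord], families: Sequence[str]
) -> pd.DataFrame:
    """Per-family best rows under both references (layout of a results table)."""
    rows = []
    for family in families:
        for reference, tag in (("training", "T"), ("testing", "V")):
            rec = select_best_combination(records, family, reference)
            rows.append(
                {
                    "family": family,
                    "reference": tag,
                    "n_variables": rec.n_variables,
                    "combination": rec.combination_label,
                    "r_train": rec.metrics_training.pearson_r,
                    "mad_train": rec.metrics_training.mad,
                    "rmse_train": rec.metrics_training.rmse,
                    "r_test": rec.metrics_testing.pearson_r,
                    "mad_test": rec.metrics_testing.mad,
                    "rmse_test": rec.metrics_testing.rmse,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model averaging
# ---------------------------------------------------------------------------

def average_model_predictions(
    models: Sequence[FittedModel],
    table: CohortTable,
    clip: tuple[float, float] | None = None,
) -> np.ndarray:
    """Unweighted per-sample mean of member-model predictions."""
    from .models import predict

    if not models:
        raise ValidationError("need at least one model to average")
    preds = np.vstack([predict(m, table, clip=clip) for m in models])
    return preds.mean(axis=0)


# ---------------------------------------------------------------------------
# replicate schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateScheme:
    """Rule selecting cells of the 3-PCR x 2-PSQ grid to average."""

    scheme_id: str
    n_measurements: int
    choices: tuple[tuple[tuple[str, int], ...], ...]

    def __post_init__(self) -> None:
        for choice in self.choices:
            if len(choice) != self.n_measurements:
                raise ValidationError(
                    f"scheme {self.scheme_id}: choice {choice} has "
                    f"{len(choice)} cells, expected {self.n_measurements}"
                )


def _build_schemes() -> dict[str, ReplicateScheme]:
    one_each = [((p, q),) for p in PCR_LABELS for q in PSQ_LABELS]
    same_pcr = [(((p, 1)), ((p, 2))) for p in PCR_LABELS]
    cross_pcr = [
        ((p1, q1), (p2, q2))
        for p1, p2 in iter_combinations(PCR_LABELS, 2)
        for q1 in PSQ_LABELS
        for q2 in PSQ_LABELS
    ]
    three_pcr = [
        ((PCR_LABELS[0], q1), (PCR_LABELS[1], q2), (PCR_LABELS[2], q3))
        for q1 in PSQ_LABELS
        for q2 in PSQ_LABELS
        for q3 in PSQ_LABELS
    ]
    schemes = [
        ReplicateScheme("S1_1pcr1psq", 1, tuple(one_each)),
        ReplicateScheme("S2_1pcr2psq", 2, tuple(same_pcr)),
        ReplicateScheme("S2_2pcr1psq", 2, tuple(cross_pcr)),
        ReplicateScheme("S3_3pcr1psq", 3, tuple(three_pcr)),
        ReplicateScheme("S6_3pcr2psq", 6, (tuple(GRID_CELLS),)),
    ]
    return {s.scheme_id: s for s in schemes}


REPLICATE_SCHEMES: dict[str, ReplicateScheme] = _build_schemes()
SCHEME_ORDER = tuple(REPLICATE_SCHEMES)  # Table-3 column order


def _grid_table(
    grids: Sequence[ReplicateGrid],
    ages: np.ndarray,
    cells_per_sample: Sequence[Sequence[tuple[str, int]]],
) -> CohortTable:
    rows = []
    for g, age, cells in zip(grids, ages, cells_per_sample):
        meth = g.mean_over(list(cells))
        row = {"sample_id": g.sample_id, "age": float(age), "study": "independent"}
        row.update(dict(zip(CPG_COLUMNS, meth)))
        rows.append(row)
    return CohortTable(pd.DataFrame(rows), role="independent")


def evaluate_replicate_scheme(
    grids: Sequence[ReplicateGrid],
    ages: Sequence[float],
    model: FittedModel,
    scheme: ReplicateScheme | str,
    assignment: str = "exhaustive_mean",
    seed: int | None = None,
    average_predictions: bool = False,
) -> MetricSet:
    """Score one model under one replicate scheme.

    Methylation is averaged over the scheme's selected cells per CpG, then
    predicted once per sample (set ``average_predictions`` to average
    per-cell predictions instead). For schemes with several symmetric cell
    choices, ``assignment="exhaustive_mean"`` averages the metric over all
    choices; ``"random"`` draws one choice per sample under ``seed``.
    """
    from .models import predict

    if isinstance(scheme, str):
        scheme = REPLICATE_SCHEMES[scheme]
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(grids):
        raise ValidationError("ages must align with grids")

    def score(cells_per_sample) -> MetricSet:
        if average_predictions:
            preds = []
            for g, cells in zip(grids, cells_per_sample):
                per_cell = []
                for cell in cells:
                    t = _grid_table([g], np.zeros(1), [[cell]])
                    per_cell.append(predict(model, t)[0])
                preds.append(float(np.mean(per_cell)))
            return MetricSet.evaluate(np.asarray(preds), ages)
        table = _grid_table(grids, ages, cells_per_sample)
        return MetricSet.evaluate(predict(model, table), ages)

    if assignment == "exhaustive_mean":
        per_choice = [score([choice] * len(grids)) for choice in scheme.choices]
        return MetricSet(
            pearson_r=float(np.mean([m.pearson_r for m in per_choice])),
            mad=float(np.mean([m.mad for m in per_choice])),
            rmse=float(np.mean([m.rmse for m in per_choice])),
            n=len(grids),
        )
    if assignment == "random":
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(scheme.choices), size=len(grids))
        return score([scheme.choices[i] for i in picks])
    raise ValidationError(f"unknown assignment {assignment!r}")


def evaluate_all_schemes(
    grids: Sequence[ReplicateGrid],
    ages: Sequence[float],
    model: FittedModel,
    assignment: str = "exhaustive_mean",
    seed: int | None = None,
) -> pd.DataFrame:
    rows = []
    for sid in SCHEME_ORDER:
        m = evaluate_replicate_scheme(grids, ages, model, sid, assignment=assignment, seed=seed)
        rows.append(
            {"scheme": sid, "n_measurements": REPLICATE_SCHEMES[sid].n_measurements,
             "pearson_r": m.pearson_r, "mad": m.mad, "rmse": m.rmse, "n": m.n}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multicollinearity diagnostics
# ---------------------------------------------------------------------------

def compute_vif(X: np.ndarray, flag_threshold: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Variance inflation factor per design column.

    VIF_j = 1/(1 - R^2_j) from regressing column j (with intercept) on all
    other columns. Perfect collinearity yields ``inf``, never an exception.
    Returns (vif values, boolean flags for VIF > threshold).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValidationError("VIF needs at least 2 columns")
    if n <= k:
        raise ValidationError(f"VIF needs n > k, got n={n}, k={k}")
    vifs = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs, vifs > flag_threshold
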