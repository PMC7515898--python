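"""Age prediction by matrix completion (iterative principal-component imputation).

Training and testing samples are pooled into one (methylation + age)
matrix; testing-set ages are the only missing cells. Missing cells are
initialized at the observed column mean and refined by alternating a
truncated rank-``ncp`` SVD reconstruction (optionally with ridge-shrunken
singular values) with re-imputation of the missing cells, until the
imputed values stabilize.

With ``regularization="none"`` each sweep is an exact alternating
minimization of the observed-cell reconstruction objective, which is
therefore non-increasing; this is asserted at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_qc import CohortTable
from .models import PredictorCombination, expand_design

AGE_COLUMN = "age"


@dataclass(frozen=True)
class MmdaConfig:
    ncp: int = 2
    regularization: str = "ridge-shrinkage"  # or "none"
    tol: float = 1e-6
    max_iter: int = 1000
    scale_columns: bool = True

    def __post_init__(self) -> None:
        if self.ncp < 1:
            raise ValidationError("ncp must be >= 1")
        if self.regularization not in ("none", "ridge-shrinkage"):
            raise ValidationError(f"unknown regularization {self.regularization!r}")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class ImputationMatrix:
    """Pooled samples x (CpG variables + age) matrix with an age-cell mask.

    ``values`` carries nan exactly where ``age_missing`` is True (age cells
    of testing-role rows); methylation cells are never missing.
    """

    values: np.ndarray            # (n, k) with age as the last column
    age_missing: np.ndarray       # (n,) bool
    sample_ids: list[str]
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.age_missing = np.asarray(self.age_missing, dtype=bool)
        n, k = self.values.shape
        if self.age_missing.shape != (n,):
            raise ValidationError("age_missing mask length must match row count")
        if self.columns[-1] != AGE_COLUMN:
            raise ValidationError("last column must be the age column")
        if np.isnan(self.values[:, :-1]).any():
            raise ValidationError("methylation cells must not be missing (QC should have run)")
        age = self.values[:, -1]
        if np.isnan(age[~self.age_missing]).any():
            raise ValidationError("observed age cells contain nan")
        self.values[self.age_missing, -1] = np.nan

    @property
    def n_observed_ages(self) -> int:
        return int((~self.age_missing).sum())


def build_imputation_matrix(
    training: CohortTable,
    testing: CohortTable,
    combination: PredictorCombination,
) -> ImputationMatrix:
    """Pool training (ages observed) and testing (ages masked) rows."""
    X_tr, y_tr = expand_design(training, combination)
    X_te, y_te = expand_design(testing, combination)
    values = np.column_stack(
        [np.vstack([X_tr, X_te]), np.concatenate([y_tr, y_te])]
    )
    mask = np.concatenate(
        [np.zeros(len(y_tr), dtype=bool), np.ones(len(y_te), dtype=bool)]
    )
    cols = [f"cpg{i}^{p}" if p > 1 else f"cpg{i}" for i, p in combination.design_terms()]
    return ImputationMatrix(
        values=values,
        age_missing=mask,
        sample_ids=training.sample_ids + testing.sample_ids,
        columns=cols + [AGE_COLUMN],
    )


@dataclass
class ImputationResult:
    imputed_ages: np.ndarray      # aligned with the masked rows, matrix row order
    masked_sample_ids: list[str]
    n_iter: int
    converged: bool
    final_change: float
    objective_history: list[float] = field(default_factory=list)
    ncp: int = 0


def mmda_impute(matrix: ImputationMatrix, config: MmdaConfig | None = None) -> ImputationResult:
    """Impute masked age cells; observed cells are never modified."""
    config = config or MmdaConfig()
    if matrix.n_observed_ages < 1:
        raise ValidationError("need at least one observed age")
    n, k = matrix.values.shape
    if not config.ncp < min(n - 1, k):
        raise ValidationError(f"ncp must be < min(n-1, k) = {min(n - 1, k)}")
    mask = matrix.age_missing
    if not mask.any():
        return ImputationResult(
            imputed_ages=np.empty(0),
            masked_sample_ids=[],
            n_iter=0,
            converged=True,
            final_change=0.0,
            ncp=config.ncp,
        )

    X = matrix.values.copy()
    obs_age_mean = np.nanmean(X[:, -1])
    X[mask, -1] = obs_age_mean

    # Column scales are frozen at initialization (a fixed weighting of the
    # objective); column centers are re-estimated every sweep.
    scale = X.std(axis=0, ddof=0) if config.scale_columns else np.ones(k)
    scale = np.where(scale == 0, 1.0, scale)

    history: list[float] = []
    change = np.inf
    it = 0
    while it < config.max_iter and change > config.tol:
        it += 1
        center = X.mean(axis=0)
        Z = (X - center) / scale
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        if config.regularization == "ridge-shrinkage" and len(s) > config.ncp:
            sigma2 = float(np.mean(s[config.ncp:] ** 2))
            s_use = np.maximum((s[: config.ncp] ** 2 - sigma2) / s[: config.ncp], 0.0)
        else:
            s_use = s[: config.ncp]
        recon = (U[:, : config.ncp] * s_use) @ Vt[: config.ncp]
        fitted = recon * scale + center

        obs_cells = np.ones_like(X, dtype=bool)
        obs_cells[mask, -1] = False
        resid = (X - fitted) / scale
        objective = float(np.sum(resid[obs_cells] ** 2))
        if config.regularization == "none" and history and objective > history[-1] + 1e-9:
            raise AssertionError(
                f"observed-cell objective increased: {history[-1]} -> {objective}"
            )
        history.append(objective)

        new_vals = fitted[mask, -1]
        change = float(np.max(np.abs(new_vals - X[mask, -1])))
        X[mask, -1] = new_vals

    converged = change <= config.tol
    if not converged:
        warnings.warn(
            f"mmda_impute did not converge in {config.max_iter} iterations "
            f"(last change {change:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    masked_ids = [sid for sid, m in zip(matrix.sample_ids, mask) if m]
    return ImputationResult(
        imputed_ages=X[mask, -1].copy(),
        masked_sample_ids=masked_ids,
        n_iter=it,
        converged=converged,
        final_change=change,
        objective_history=history,
        ncp=config.ncp,
    )


def impute_test_ages(
    training: CohortTable,
    testing: CohortTable,
    combination: PredictorCombination,
    config: MmdaConfig | None = None,
) -> np.ndarray:
    """Convenience: pooled imputation returning ages aligned with ``testing``."""
    matrix = build_imputation_matrix(training, testing, combination)
    result = mmda_impute(matrix, config)
    return result.imputed_ages


@dataclass
class MmdaPredictor:
    """Duck-typed stand-in for a fitted model backed by pooled imputation.

    Carries the observed (training) block; ``predict_design`` masks the
    incoming rows' ages and imputes them jointly with the stored block, so
    mMDA can be used wherever a fitted model is expected (prediction,
    model averaging, replicate-scheme evaluation).
    """

    spec: object
    combination: PredictorCombination
    X_train: np.ndarray
    y_train: np.ndarray
    config: MmdaConfig

    def predict_design(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n_obs, n_mask = len(self.y_train), len(X)
        values = np.column_stack(
            [
                np.vstack([self.X_train, X]),
                np.concatenate([self.y_train, np.full(n_mask, np.nan)]),
            ]
        )
        mask = np.concatenate([np.zeros(n_obs, dtype=bool), np.ones(n_mask, dtype=bool)])
        matrix = ImputationMatrix(
            values=values,
            age_missing=mask,
            sample_ids=[f"o{i}" for i in range(n_obs)] + [f"m{i}" for i in range(n_mask)],
            columns=[f"v{j}" for j in range(X.shape[1])] + [AGE_COLUMN],
        )
        cfg = self.config
        if not cfg.ncp < min(len(values) - 1, values.shape[1]):
            cfg = MmdaConfig(ncp=values.shape[1] - 1, regularization=cfg.regularization,
                             tol=cfg.tol, max_iter=cfg.max_iter, scale_columns=cfg.scale_columns)
        return mmda_impute(matrix, cfg).imputed_ages


def make_mmda_model(
    training: CohortTable,
    combination: PredictorCombination,
    config: MmdaConfig | None = None,
) -> MmdaPredictor:
    from .models import ModelSpec

    config = config or MmdaConfig()
    if config.ncp > combination.n_variables:
        config = MmdaConfig(ncp=combination.n_variables, regularization=config.regularization,
                            tol=config.tol, max_iter=config.max_iter,
                            scale_columns=config.scale_columns)
    X, y = expand_design(training, combination)
    return MmdaPredictor(
        spec=ModelSpec(family="mmda"),
        combination=combination,
        X_train=X,
        y_train=y,
        config=config,
    )


def select_ncp(
    matrix: ImputationMatrix,
    candidate_ncps: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    config: MmdaConfig | None = None,
) -> int:
    """Pick ncp by cross-validated imputation RMSE on held-out observed ages.

    Random observed age cells are masked fold by fold; the candidate
    minimizing mean RMSE wins (ties to the smaller ncp). A single
    candidate is returned without running CV.
    """
    candidates = list(candidate_ncps)
    if not candidates:
        raise ValidationError("candidate_ncps is empty")
    if len(candidates) == 1:
        return candidates[0]
    base = config or MmdaConfig()
    observed_rows = np.flatnonzero(~matrix.age_missing)
    if len(observed_rows) < folds:
        raise ValidationError(
            f"need at least {folds} observed ages for {folds}-fold CV, have {len(observed_rows)}"
        )
    rng = np.random.default_rng(seed)
    # CV runs on the observed-age rows only; originally-masked rows carry
    # no truth and are left out of the CV matrices.
    obs_values = matrix.values[observed_rows]
    obs_ids = [matrix.sample_ids[i] for i in observed_rows]
    order = rng.permutation(len(observed_rows))
    fold_assign = np.array_split(order, folds)
    scores: dict[int, float] = {}
    for ncp in candidates:
        cfg = MmdaConfig(
            ncp=ncp,
            regularization=base.regularization,
            tol=base.tol,
            max_iter=base.max_iter,
            scale_columns=base.scale_columns,
        )
        errors: list[float] = []
        for held in fold_assign:
            if len(held) == 0:
                continue
            mask = np.zeros(len(observed_rows), dtype=bool)
            mask[held] = True
            truth = obs_values[held, -1]
            sub = ImputationMatrix(
                values=obs_values.copy(),
                age_missing=mask,
                sample_ids=list(obs_ids),
                columns=list(matrix.columns),
            )
            result = mmda_impute(sub, cfg)
            masked_rows = np.flatnonzero(mask)
            pos = {row: j for j, row in enumerate(masked_rows)}
            pred = result.imputed_ages[[pos[row] for row in held]]
            errors.append(float(np.sqrt(np.mean((pred - truth) ** 2))))
        scores[ncp] = float(np.mean(errors))
    return min(candidates, key=lambda c: (scores[c], c))
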