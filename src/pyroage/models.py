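"""Regression families for age prediction.

Four routes share one interface:

* ``zp1_mlr`` — the two-CpG (5, 7) multiple-linear-regression baseline,
  refit on the active training set by default (published coefficients may
  be injected instead via :func:`make_linear_model`);
* ``mqr`` — ordinary least squares over any subset of the 14 variables
  (7 CpG methylation values and their squares);
* ``svm_r`` / ``svm_l`` / ``svm_p`` — epsilon-insensitive support-vector
  regression on standardized features;
* ``gbr`` — gradient-boosted regression trees, seeded.

Fitted models are pure functions of their stored parameters; ``predict``
never touches the training data.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.svm import SVR

from .errors import ValidationError
from .io_qc import CPG_COLUMNS, N_CPGS, CohortTable

FAMILIES = ("zp1_mlr", "mqr", "svm_r", "svm_l", "svm_p", "gbr", "mmda")
LINEAR_FAMILIES = ("zp1_mlr", "mqr")
SVM_FAMILIES = ("svm_r", "svm_l", "svm_p")
SCOPES = ("cpg7", "mqr14")

_SQ = "²"  # superscript two used in combination labels


# ---------------------------------------------------------------------------
# predictor combinations
# ---------------------------------------------------------------------------

def _canonical_variables(scope: str, variables) -> tuple:
    if scope == "cpg7":
        vars_ = tuple(sorted({int(v) for v in variables}))
        if not vars_ or any(v < 1 or v > N_CPGS for v in vars_):
            raise ValidationError(f"cpg7 variables must be a non-empty subset of 1..7, got {variables}")
        return vars_
    if scope == "mqr14":
        vars_ = tuple(sorted({(int(i), int(p)) for i, p in variables}, key=lambda v: (v[1], v[0])))
        if not vars_ or any(i < 1 or i > N_CPGS or p not in (1, 2) for i, p in vars_):
            raise ValidationError(
                f"mqr14 variables must be non-empty (cpg, power) pairs with power in {{1,2}}, got {variables}"
            )
        return vars_
    raise ValidationError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def _format_runs(indices: Sequence[int], suffix: str = "") -> str:
    parts = []
    for _, grp in groupby(enumerate(indices), key=lambda t: t[1] - t[0]):
        run = [v for _, v in grp]
        if len(run) == 1:
            parts.append(f"{run[0]}{suffix}")
        else:
            parts.append(f"{run[0]}{suffix}-{run[-1]}{suffix}")
    return ",".join(parts)


def _parse_runs(text: str) -> list[int]:
    out: list[int] = []
    for token in text.split(","):
        token = token.replace(_SQ, "")
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", token)
        if not m:
            raise ValidationError(f"cannot parse combination token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        out.extend(range(lo, hi + 1))
    return out


@dataclass(frozen=True)
class PredictorCombination:
    """A subset of predictor variables with a canonical human-readable label.

    ``cpg7`` scope: variables are CpG indices (ints in 1..7).
    ``mqr14`` scope: variables are ``(cpg_index, power)`` pairs, power 1 or 2,
    ordered linear terms first then squared terms.
    """

    scope: str
    variables: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", _canonical_variables(self.scope, self.variables))

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def label(self) -> str:
        if self.scope == "cpg7":
            return "CpG_" + _format_runs(self.variables)
        linear = [i for i, p in self.variables if p == 1]
        squared = [i for i, p in self.variables if p == 2]
        parts = []
        if linear:
            parts.append("CpG_" + _format_runs(linear))
        if squared:
            parts.append("CpG_" + _format_runs(squared, suffix=_SQ))
        return " & ".join(parts)

    @classmethod
    def from_label(cls, label: str, scope: str | None = None) -> "PredictorCombination":
        parts = [p.strip() for p in label.split("&")]
        linear: list[int] = []
        squared: list[int] = []
        for part in parts:
            if not part.startswith("CpG_"):
                raise ValidationError(f"combination label must start with 'CpG_': {label!r}")
            body = part[len("CpG_"):]
            if _SQ in body:
                squared.extend(_parse_runs(body))
            else:
                linear.extend(_parse_runs(body))
        if scope is None:
            scope = "mqr14" if (squared or len(parts) > 1) else "cpg7"
        if scope == "cpg7":
            if squared:
                raise ValidationError(f"cpg7 combination cannot contain squared terms: {label!r}")
            return cls(scope="cpg7", variables=tuple(linear))
        variables = tuple((i, 1) for i in linear) + tuple((i, 2) for i in squared)
        return cls(scope="mqr14", variables=variables)

    def design_terms(self) -> list[tuple[int, int]]:
        """(cpg_index, power) per design column, in canonical column order."""
        if self.scope == "cpg7":
            return [(i, 1) for i in self.variables]
        return list(self.variables)

    def cpg_indices(self) -> tuple[int, ...]:
        return tuple(sorted({i for i, _ in self.design_terms()}))


def zp1_combination() -> PredictorCombination:
    """The two-CpG baseline predictor set (CpGs 5 and 7)."""
    return PredictorCombination(scope="cpg7", variables=(5, 7))


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "zp1_mlr": {"allow_rank_deficient": False},
    "mqr": {"allow_rank_deficient": False},
    "svm_r": {"C": 1.0, "epsilon": 0.1, "gamma": "scale"},
    "svm_l": {"C": 1.0, "epsilon": 0.1},
    "svm_p": {"C": 1.0, "epsilon": 0.1, "gamma": "scale", "degree": 3, "coef0": 0.0},
    "gbr": {"n_estimators": 500, "learning_rate": 0.1, "max_depth": 3, "random_state": 0},
    "mmda": {"ncp": 2, "regularization": "ridge-shrinkage", "tol": 1e-6,
             "max_iter": 1000, "scale_columns": True},
}


@dataclass(frozen=True)
class ModelSpec:
    """Family plus a complete hyperparameter mapping.

    Feature standardization defaults on for kernel (SVM) families only;
    linear and tree families are scale-equivariant/invariant and run on
    raw percentages.
    """

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    standardize_features: bool | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown:
            raise ValidationError(f"unknown hyperparameter(s) for {self.family}: {sorted(unknown)}")
        merged.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", merged)
        if self.standardize_features is None:
            object.__setattr__(self, "standardize_features", self.family in SVM_FAMILIES)

    @property
    def scope(self) -> str:
        return "mqr14" if self.family == "mqr" else "cpg7"

    def fingerprint(self) -> str:
        items = ",".join(f"{k}={self.hyperparameters[k]}" for k in sorted(self.hyperparameters))
        return f"{self.family}[std={int(bool(self.standardize_features))};{items}]"


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ModelSpec
    combination: PredictorCombination
    parameters: dict
    training_fingerprint: dict

    def predict_design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mean = self.parameters.get("feature_mean")
        scale = self.parameters.get("feature_scale")
        if mean is not None:
            X = (X - np.asarray(mean)) / np.asarray(scale)
        family = self.spec.family
        if family in LINEAR_FAMILIES:
            return X @ np.asarray(self.parameters["coef"]) + self.parameters["intercept"]
        return self.parameters["estimator"].predict(X)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _fingerprint(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> dict:
    return {"n": int(len(y)), "spec": spec.fingerprint(), "data_hash": _data_hash(X, y)}


def expand_design(
    table: CohortTable, combination: PredictorCombination
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (n, k) and aligned age vector for a combination.

    Column j holds methylation of CpG i raised to the combination's power,
    in canonical order (linear terms CpG1..7, then squared terms).
    """
    meth = table.methylation
    terms = combination.design_terms()
    for i, _ in terms:
        col = meth[:, i - 1]
        if np.isnan(col).any():
            sid = table.sample_ids[int(np.argmax(np.isnan(col)))]
            raise ValidationError(f"missing value for cpg{i} in sample {sid!r}")
    X = np.column_stack([meth[:, i - 1] ** p for i, p in terms])
    return X, table.ages.copy()


def fit_linear_family(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> dict:
    """Ordinary least squares with intercept; serves zp1_mlr and mqr.

    Raises on rank-deficient designs unless ``allow_rank_deficient`` is
    set, in which case the minimum-norm solution is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need n > k for least squares, got n={n}, k={k}")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < k + 1 and not spec.hyperparameters.get("allow_rank_deficient", False):
        raise ValidationError(
            f"design is rank deficient (rank {rank} < {k + 1}); remove collinear "
            "variables or set allow_rank_deficient to accept the minimum-norm solution"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    return {
        "intercept": float(beta[0]),
        "coef": beta[1:].copy(),
        "training_predictions": fitted,
        "training_residuals": y - fitted,
    }


def _standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        j = int(np.argmax(scale == 0))
        raise ValidationError(f"feature column {j} has zero variance; cannot standardize")
    return mean, scale


def fit_svm(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> dict:
    if spec.family not in SVM_FAMILIES:
        raise ValidationError(f"fit_svm got family {spec.family!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValidationError("SVR needs at least 2 samples")
    params: dict = {}
    if spec.standardize_features:
        mean, scale = _standardization(X)
        params["feature_mean"] = mean
        params["feature_scale"] = scale
        X = (X - mean) / scale
    hp = spec.hyperparameters
    kernel = {"svm_r": "rbf", "svm_l": "linear", "svm_p": "poly"}[spec.family]
    est = SVR(
        kernel=kernel,
        C=float(hp["C"]),
        epsilon=float(hp["epsilon"]),
        gamma=hp.get("gamma", "scale"),
        degree=int(hp.get("degree", 3)),
        coef0=float(hp.get("coef0", 0.0)),
    )
    est.fit(X, y)
    params["estimator"] = est
    params["training_predictions"] = est.predict(X)
    return params


def fit_gbr(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> dict:
    hp = spec.hyperparameters
    if int(hp["n_estimators"]) <= 0:
        raise ValidationError(f"n_estimators must be positive, got {hp['n_estimators']}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValidationError("GBR needs at least 2 samples")
    if int(hp["max_depth"]) == 0:
        # depth-0 limit: constant mean predictor (legal degenerate model)
        from sklearn.dummy import DummyRegressor

        est = DummyRegressor(strategy="mean")
        est.fit(X, y)
        return {"estimator": est, "training_predictions": est.predict(X)}
    est = GradientBoostingRegressor(
        n_estimators=int(hp["n_estimators"]),
        learning_rate=float(hp["learning_rate"]),
        max_depth=int(hp["max_depth"]),
        random_state=int(hp["random_state"]),
    )
    est.fit(X, y)
    return {"estimator": est, "training_predictions": est.predict(X)}


_FITTERS = {
    "zp1_mlr": fit_linear_family,
    "mqr": fit_linear_family,
    "svm_r": fit_svm,
    "svm_l": fit_svm,
    "svm_p": fit_svm,
    "gbr": fit_gbr,
}


def fit_model(
    table: CohortTable, spec: ModelSpec, combination: PredictorCombination
) -> FittedModel:
    """Fit one family on one combination; mMDA has no fit step and is rejected."""
    if spec.family == "mmda":
        raise ValidationError("mmda is transductive; use pyroage.imputation instead of fit_model")
    if spec.family == "mqr" and combination.scope != "mqr14":
        raise ValidationError("mqr requires an mqr14-scope combination")
    X, y = expand_design(table, combination)
    params = _FITTERS[spec.family](X, y, spec)
    return FittedModel(
        spec=spec,
        combination=combination,
        parameters=params,
        training_fingerprint=_fingerprint(X, y, spec),
    )


def make_linear_model(
    combination: PredictorCombination,
    intercept: float,
    coef: Sequence[float],
    family: str = "zp1_mlr",
) -> FittedModel:
    """Build a linear model from externally supplied (published) coefficients."""
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (combination.n_variables,):
        raise ValidationError(
            f"need {combination.n_variables} coefficients, got {coef.size}"
        )
    spec = ModelSpec(family=family)
    return FittedModel(
        spec=spec,
        combination=combination,
        parameters={"intercept": float(intercept), "coef": coef},
        training_fingerprint={"n": 0, "spec": spec.fingerprint(), "data_hash": "injected"},
    )


def predict(
    model: FittedModel, table: CohortTable, clip: tuple[float, float] | None = None
) -> np.ndarray:
    """Predicted ages for every sample in the table; optional clamping."""
    X, _ = expand_design(table, model.combination)
    pred = model.predict_design(X)
    if clip is not None:
        pred = np.clip(pred, clip[0], clip[1])
    return pred


def save_model(model: FittedModel, path: str | Path) -> None:
    """Self-describing archive: spec, combination label, parameters, provenance."""
    payload = {
        "format": "pyroage-model-v1",
        "family": model.spec.family,
        "hyperparameters": dict(model.spec.hyperparameters),
        "standardize_features": model.spec.standardize_features,
        "combination_scope": model.combination.scope,
        "combination_label": model.combination.label,
        "parameters": model.parameters,
        "training_fingerprint": model.training_fingerprint,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    if payload.get("format") != "pyroage-model-v1":
        raise ValidationError(f"{path}: not a pyroage model archive")
    spec = ModelSpec(
        family=payload["family"],
        hyperparameters=payload["hyperparameters"],
        standardize_features=payload["standardize_features"],
    )
    combination = PredictorCombination.from_label(
        payload["combination_label"], scope=payload["combination_scope"]
    )
    return FittedModel(
        spec=spec,
        combination=combination,
        parameters=payload["parameters"],
        training_fingerprint=payload["training_fingerprint"],
    )
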