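"""Inter-laboratory optimization recipe and provenance helpers.

``optimize_lab`` implements the recommended local-deployment protocol:
retrain each candidate family on the reference training set, score every
combination on the lab's own validation set, select the best (family,
combination), then — if replicate grids are available — evaluate the five
replicate schemes and recommend one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .imputation import MmdaConfig, make_mmda_model
from .io_qc import CohortTable
from .models import FittedModel, ModelSpec, PredictorCombination, fit_model
from .search import (
    REPLICATE_SCHEMES,
    SCHEME_ORDER,
    SearchRecord,
    evaluate_all_schemes,
    run_exhaustive_search,
    select_best_combination,
)
from .synthetic import ReplicateGrid

logger = logging.getLogger(__name__)

MIN_VALIDATION_N = 20


def write_provenance(out_dir: str | Path, config: dict, seeds: dict | None = None) -> Path:
    """Drop the resolved config, seeds and software version into an output dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "software": "pyroage",
        "version": __version__,
        "seeds": seeds or {},
        "config": config,
    }
    path = out_dir / "run_config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def refit_model(
    training: CohortTable,
    spec: ModelSpec,
    combination: PredictorCombination,
):
    """Fit (or, for mMDA, wrap) one family on one combination."""
    if spec.family == "mmda":
        hp = spec.hyperparameters
        cfg = MmdaConfig(
            ncp=int(hp["ncp"]), regularization=str(hp["regularization"]),
            tol=float(hp["tol"]), max_iter=int(hp["max_iter"]),
            scale_columns=bool(hp["scale_columns"]),
        )
        return make_mmda_model(training, combination, cfg)
    return fit_model(training, spec, combination)


@dataclass
class OptimizeLabResult:
    best_by_family: dict[str, SearchRecord]
    recommended_family: str
    recommended_combination: str
    recommended_model: object
    scheme_table: pd.DataFrame | None
    recommended_scheme: str | None
    notes: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "recommended_family": self.recommended_family,
            "recommended_combination": self.recommended_combination,
            "recommended_scheme": self.recommended_scheme or "not evaluated",
            "best_by_family": {
                fam: {
                    "combination": rec.combination_label,
                    "validation_mad": rec.metrics_testing.mad,
                    "validation_rmse": rec.metrics_testing.rmse,
                    "validation_r": rec.metrics_testing.pearson_r,
                }
                for fam, rec in self.best_by_family.items()
            },
            "notes": list(self.notes),
        }


def optimize_lab(
    training: CohortTable,
    validation: CohortTable,
    specs: Sequence[ModelSpec],
    grids: Sequence[ReplicateGrid] | None = None,
) -> OptimizeLabResult:
    """Local re-selection of the best (family, combination, scheme).

    ``validation`` is the lab's own known-age sample set and plays the
    testing role during the search; selection is driven by validation MAD.
    Replicate grids, when supplied, must align with validation sample ids.
    """
    notes: list[str] = []
    if validation.n_samples < MIN_VALIDATION_N:
        msg = (
            f"validation set has only {validation.n_samples} samples (< {MIN_VALIDATION_N}); "
            "combination selection carries wide uncertainty"
        )
        warnings.warn(msg, UserWarning, stacklevel=2)
        notes.append(msg)

    records = run_exhaustive_search(training, validation, specs)
    best_by_family: dict[str, SearchRecord] = {}
    for spec in specs:
        best_by_family[spec.family] = select_best_combination(
            records, spec.family, reference="testing"
        )
    recommended_family = min(
        best_by_family,
        key=lambda fam: (
            best_by_family[fam].metrics_testing.mad,
            best_by_family[fam].n_variables,
            fam,
        ),
    )
    best = best_by_family[recommended_family]
    spec = next(s for s in specs if s.family == recommended_family)
    combination = PredictorCombination.from_label(
        best.combination_label,
        scope="mqr14" if recommended_family == "mqr" else "cpg7",
    )
    model = refit_model(training, spec, combination)

    scheme_table = None
    recommended_scheme = None
    if grids is not None and len(grids) > 0:
        by_id = {g.sample_id: g for g in grids}
        missing = [sid for sid in validation.sample_ids if sid not in by_id]
        if missing:
            raise ValidationError(f"no replicate grid for validation sample(s): {missing[:5]}")
        aligned = [by_id[sid] for sid in validation.sample_ids]
        scheme_table = evaluate_all_schemes(aligned, validation.ages, model)
        mads = dict(zip(scheme_table["scheme"], scheme_table["mad"]))
        recommended_scheme = min(SCHEME_ORDER, key=lambda s: (mads[s], REPLICATE_SCHEMES[s].n_measurements))
        if min(mads["S2_2pcr1psq"], mads["S3_3pcr1psq"]) < mads["S1_1pcr1psq"]:
            notes.append(
                "replicate data confirm improvement: use two or three methylation "
                "measures from independent PCR experiments"
            )
    else:
        notes.append("replicate schemes not evaluated (no replicate grids supplied)")

    return OptimizeLabResult(
        best_by_family=best_by_family,
        recommended_family=recommended_family,
        recommended_combination=best.combination_label,
        recommended_model=model,
        scheme_table=scheme_table,
        recommended_scheme=recommended_scheme,
        notes=notes,
    )
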