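"""Cohort CSV reading/writing and model persistence.

The cohort file is a plain comma-separated, UTF-8, '.'-decimal table
with a mandatory header.  Fixed columns come first (participant_code,
weight_kg, height_cm, body_area_m2, age_years, sex, diuresis_ml), then
per metal M ∈ {zn, cr, cu, pb}: M_blood_ugml, M_urine_ugml, M_water_mgl,
M_soil_mgkg and the optional M_retention.  Unknown columns warn; missing
required columns error; rows violating subject invariants are rejected
with their row numbers logged.

Models persist as a single versioned JSON document embedding both
blocks' weights, activation specs, the confidence weights, and all
normalisation constants, so a reloaded model reproduces forward passes
bit-identically.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from metalret.double_loop import ConfidenceWeights, DoubleLoopModel
from metalret.mlp import ActivationSpec, MLPModel
from metalret.preprocessing import NormalizationParams
from metalret.retention import SubjectRecord

logger = logging.getLogger(__name__)

METALS = ("zn", "cr", "cu", "pb")

MODEL_FORMAT = "metalret-double-loop"
MODEL_VERSION = 1

_FIXED_COLUMNS = (
    "participant_code",
    "weight_kg",
    "height_cm",
    "body_area_m2",
    "age_years",
    "sex",
    "diuresis_ml",
)

_METAL_SUFFIXES = ("blood_ugml", "urine_ugml", "water_mgl", "soil_mgkg")


def cohort_columns(metals: tuple[str, ...] = METALS) -> list[str]:
    """Full ordered header of the cohort CSV schema."""
    cols = list(_FIXED_COLUMNS)
    for metal in metals:
        cols.extend(f"{metal}_{suffix}" for suffix in _METAL_SUFFIXES)
        cols.append(f"{metal}_retention")
    return cols


def write_cohort(records: list[SubjectRecord], path: str | Path) -> None:
    """Write subject records as a cohort CSV (empty cells for missing data)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_code": r.participant_code,
            "weight_kg": r.weight_kg,
            "height_cm": r.height_cm,
            "body_area_m2": r.body_area_m2,
            "age_years": r.age_years,
            "sex": r.sex,
            "diuresis_ml": r.diuresis_ml,
        }
        for metal in METALS:
            row[f"{metal}_blood_ugml"] = r.blood_ugml.get(metal)
            row[f"{metal}_urine_ugml"] = r.urine_ugml.get(metal)
            row[f"{metal}_water_mgl"] = r.water_mgl.get(metal)
            row[f"{metal}_soil_mgkg"] = r.soil_mgkg.get(metal)
            row[f"{metal}_retention"] = r.retention.get(metal)
        rows.append(row)
    pd.DataFrame(rows, columns=cohort_columns()).to_csv(path, index=False)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV; invalid rows are rejected and logged."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"participant_code": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    if frame.empty:
        raise ValueError(f"{path}: cohort file has a header but no rows")

    required = {"participant_code", "weight_kg", "height_cm", "age_years", "sex"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    unknown = set(frame.columns) - set(cohort_columns())
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, sorted(unknown))

    numeric_cols = [c for c in frame.columns if c != "participant_code"]
    for col in numeric_cols:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed numeric in column {col!r}") from exc

    records: list[SubjectRecord] = []
    rejected: list[int] = []
    for idx, row in frame.iterrows():
        try:
            record = SubjectRecord(
                participant_code=str(row["participant_code"]),
                weight_kg=float(row["weight_kg"]),
                height_cm=float(row["height_cm"]),
                age_years=int(row["age_years"]),
                sex=int(row["sex"]),
                body_area_m2=_opt(row.get("body_area_m2")),
                diuresis_ml=_opt(row.get("diuresis_ml")),
            )
            for metal in METALS:
                for suffix, store in (
                    ("blood_ugml", record.blood_ugml),
                    ("urine_ugml", record.urine_ugml),
                    ("water_mgl", record.water_mgl),
                    ("soil_mgkg", record.soil_mgkg),
                    ("retention", record.retention),
                ):
                    value = _opt(row.get(f"{metal}_{suffix}"))
                    if value is not None:
                        store[metal] = value
            record.validate()
        except (ValueError, KeyError) as exc:
            rejected.append(int(idx) + 2)  # 1-based file line incl. header
            logger.warning("%s: rejecting line %d: %s", path, int(idx) + 2, exc)
            continue
        records.append(record)
    if rejected:
        logger.info("%s: rejected %d row(s): lines %s", path, len(rejected), rejected)
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records


def _params_to_json(params: NormalizationParams) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "feature_names": list(params.feature_names),
        "col_min": arr(params.col_min),
        "col_max": arr(params.col_max),
        "mean": arr(params.mean),
        "std": arr(params.std),
    }


def _params_from_json(doc: dict) -> NormalizationParams:
    def arr(a):
        return None if a is None else np.asarray(a, dtype=float)

    return NormalizationParams(
        feature_names=tuple(doc["feature_names"]),
        col_min=arr(doc["col_min"]),
        col_max=arr(doc["col_max"]),
        mean=arr(doc["mean"]),
        std=arr(doc["std"]),
        fitted=True,
    )


def _block_to_json(block: MLPModel) -> dict:
    return {
        "layer_sizes": [block.n_inputs, block.n_hidden, 1],
        "w_hidden": block.w_hidden.tolist(),
        "b_hidden": block.b_hidden.tolist(),
        "w_out": block.w_out.tolist(),
        "b_out": block.b_out.tolist(),
        "hidden_activation": vars(block.hidden_activation) | {},
        "output_activation": vars(block.output_activation) | {},
        "seed": block.seed,
    }


def _block_from_json(doc: dict) -> MLPModel:
    return MLPModel(
        w_hidden=np.asarray(doc["w_hidden"], dtype=float),
        b_hidden=np.asarray(doc["b_hidden"], dtype=float),
        w_out=np.asarray(doc["w_out"], dtype=float),
        b_out=np.asarray(doc["b_out"], dtype=float),
        hidden_activation=ActivationSpec(**doc["hidden_activation"]),
        output_activation=ActivationSpec(**doc["output_activation"]),
        seed=doc.get("seed"),
    )


def save_model(model: DoubleLoopModel, path: str | Path) -> None:
    """Persist a trained double-loop model as one JSON document."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "metal": model.metal,
        "weights": {
            "a_long": model.weights.a_long,
            "a_short": model.weights.a_short,
            "err_long": model.weights.err_long,
            "err_short": model.weights.err_short,
        },
        "long_block": _block_to_json(model.long_block),
        "short_block": _block_to_json(model.short_block),
        "long_feature_params": _params_to_json(model.long_feature_params),
        "short_feature_params": _params_to_json(model.short_feature_params),
        "long_target_params": _params_to_json(model.long_target_params),
        "short_target_params": _params_to_json(model.short_target_params),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> DoubleLoopModel:
    """Load a model JSON; refuses unknown formats or schema versions."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: unrecognised model format {doc.get('format')!r}")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version {doc.get('version')!r} "
            f"(this build reads version {MODEL_VERSION})"
        )
    w = doc["weights"]
    return DoubleLoopModel(
        metal=doc["metal"],
        long_block=_block_from_json(doc["long_block"]),
        short_block=_block_from_json(doc["short_block"]),
        long_feature_params=_params_from_json(doc["long_feature_params"]),
        short_feature_params=_params_from_json(doc["short_feature_params"]),
        long_target_params=_params_from_json(doc["long_target_params"]),
        short_target_params=_params_from_json(doc["short_target_params"]),
        weights=ConfidenceWeights(
            a_long=w["a_long"],
            a_short=w["a_short"],
            err_long=w["err_long"],
            err_short=w["err_short"],
            metal=doc["metal"],
        ),
        metadata=doc.get("metadata", {}),
    )
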