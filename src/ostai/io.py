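"""Cohort CSV reading/writing, QC-log TSV, and index-model JSON.

CSV schema (header required): id, sex, menopausal, age, height_cm,
weight_kg, menopause_age, t_lumbar, t_femoral_neck, t_total_hip, then the
seven tri-state risk factors. Missing values are empty fields; booleans are
0/1. Malformed numeric cells reject the whole row into a rejects report
rather than being silently dropped or coerced.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, RISK_FACTORS, SCHEMA_COLUMNS
from .derivation import IndexModel
from .errors import SchemaError

NUMERIC_COLUMNS = (
    "age", "height_cm", "weight_kg", "menopause_age",
    "t_lumbar", "t_femoral_neck", "t_total_hip",
)
CATEGORICAL = {"sex": {"female", "male"}, "menopausal": {"pre", "post", "unknown"}}


def read_cohort(path) -> Cohort:
    """Read a cohort CSV; reject malformed rows into ``cohort.rejects``."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring extra columns {extra}")
    if len(raw) == 0:
        raise SchemaError(f"{path}: no data rows")

    reject_rows = []
    bad = pd.Series(False, index=raw.index)

    def _flag(mask, column):
        for i in raw.index[mask & ~bad]:
            reject_rows.append(
                {"id": raw.loc[i, "id"], "column": column, "value": raw.loc[i, column]}
            )
        return mask

    out = pd.DataFrame(index=raw.index)
    out["id"] = raw["id"].astype(str)
    for col, allowed in CATEGORICAL.items():
        vals = raw[col].str.strip()
        bad |= _flag(~vals.isin(allowed), col)
        out[col] = vals
    for col in NUMERIC_COLUMNS:
        vals = raw[col].str.strip()
        num = pd.to_numeric(vals.replace("", np.nan), errors="coerce")
        bad |= _flag(vals.ne("") & num.isna(), col)
        out[col] = num
    for col in RISK_FACTORS:
        vals = raw[col].str.strip()
        bad |= _flag(~vals.isin({"", "0", "1"}), col)
        out[col] = pd.to_numeric(vals.replace("", np.nan).where(vals.isin({"", "0", "1"})),
                                 errors="coerce")

    rejects = pd.DataFrame(reject_rows, columns=["id", "column", "value"])
    kept = out.loc[~bad].reset_index(drop=True)
    if len(kept) == 0:
        raise SchemaError(f"{path}: every row malformed ({len(rejects)} rejects)")
    cohort = Cohort(data=kept[list(SCHEMA_COLUMNS)])
    cohort.rejects = rejects
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV (missing values as empty fields, booleans as 0/1)."""
    df = cohort.data.copy()
    for col in RISK_FACTORS:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False, na_rep="")


def write_qc_log(cohort: Cohort, path) -> None:
    cohort.qc_log.to_csv(path, sep="\t", index=False)


def write_model(model: IndexModel, path, extra: dict = None) -> None:
    payload = model.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model(path) -> IndexModel:
    return IndexModel.from_dict(json.loads(Path(path).read_text()))
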