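"""TSV readers/writers for matrices, sample sheets, truth and rankings.

Matrix files are tab-delimited with the gene id in the first column and
one column per array; censored cells are coded "NA".  Every matrix file
starts with a comment line declaring the natural-log scale so files
cannot silently change scale.  The sample sheet has columns
(array, condition, replicate, detection_limit).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (ArrayMismatchError, CensoredExpressionMatrix,
                   DataValidationError, DuplicateGeneIdError)

SCALE_HEADER = "# log scale: natural"
_SHEET_COLUMNS = ["array", "condition", "replicate", "detection_limit"]


def read_expression(matrix_path, sample_sheet_path) -> CensoredExpressionMatrix:
    """Load and validate a matrix + sample sheet pair."""
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise DuplicateGeneIdError(f"duplicated gene ids: {dupes}")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#")
    missing_cols = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise DataValidationError(f"sample sheet missing columns: {missing_cols}")
    sheet = sheet.copy()
    sheet["array"] = sheet["array"].astype(str)
    matrix_arrays = [str(c) for c in mat.columns]
    if sorted(matrix_arrays) != sorted(sheet["array"].tolist()):
        raise ArrayMismatchError(
            f"matrix columns {matrix_arrays} do not match sample sheet arrays "
            f"{sheet['array'].tolist()}"
        )
    sheet = sheet.set_index("array").loc[matrix_arrays].reset_index()
    values = mat.to_numpy(dtype=float)
    censored = np.isnan(values)
    return CensoredExpressionMatrix(
        values=values,
        censored=censored,
        condition=sheet["condition"].to_numpy(dtype=int),
        replicate=sheet["replicate"].to_numpy(dtype=int),
        detection_limit=sheet["detection_limit"].to_numpy(dtype=float),
        gene_ids=[str(i) for i in mat.index],
        array_ids=matrix_arrays,
    )


def write_expression(data: CensoredExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    """Write a matrix + sample sheet pair (lossless round trip)."""
    frame = pd.DataFrame(data.values, index=pd.Index(data.gene_ids, name="gene_id"),
                         columns=data.array_ids)
    with open(matrix_path, "w") as fh:
        fh.write(SCALE_HEADER + "\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", float_format="%.10g")
    sheet = pd.DataFrame({
        "array": data.array_ids,
        "condition": data.condition,
        "replicate": data.replicate,
        "detection_limit": data.detection_limit,
    })
    sheet.to_csv(sample_sheet_path, sep="\t", index=False, float_format="%.10g")


def write_truth(truth, gene_ids, array_ids, gene_path, array_path) -> None:
    pd.DataFrame({
        "gene_id": gene_ids,
        "alpha": truth.alpha,
        "delta": truth.delta,
        "sigma2": truth.sigma2,
        "de_label": truth.de_label,
    }).to_csv(gene_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame({
        "array": array_ids,
        "a0": truth.a0,
        "a1": truth.a1,
    }).to_csv(array_path, sep="\t", index=False, float_format="%.10g")


def read_truth_labels(gene_path) -> pd.DataFrame:
    # keep_default_na=False so the label "null" survives the round trip
    return pd.read_csv(gene_path, sep="\t", keep_default_na=False, na_values=[""])


def write_summary(summary, path, metadata_path=None, extra_metadata=None) -> None:
    """Posterior summary TSV plus a JSON run-metadata sidecar."""
    summary.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if metadata_path is not None:
        meta = {
            "hyper_mean": {k: float(v) for k, v in summary.hyper_mean.items()},
            "diagnostics": _jsonable(summary.diagnostics),
        }
        if extra_metadata:
            meta.update(_jsonable(extra_metadata))
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_ranking(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
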