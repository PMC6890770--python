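"""Tab-separated readers and writers for the pipeline's tables.

All files are UTF-8 TSV with header rows: event streams, enrollment tables,
estimate tables, long-format curve files, square dissimilarity/shift
matrices, embedding tables, and feature tables with a JSON schema sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .archetypes import N_AGES
from .curves import PrevalenceCurve
from .embedding import DiseaseEmbedding
from .features import FeatureSchema
from .shapes import ShapeDissimilarityMatrix
from .synthetic import ENROLLMENT_COLUMNS, ESTIMATE_COLUMNS, EVENT_COLUMNS

_CURVE_COLUMNS = ["disease", "sex", "country", "analysis", "age", "value"]


def _check_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing columns: {missing}")


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, EVENT_COLUMNS, "events")
    df["age"] = df["age"].astype(int)
    return df


def write_enrollment(enrollment: pd.DataFrame, path) -> None:
    enrollment[ENROLLMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_enrollment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ENROLLMENT_COLUMNS, "enrollment")
    return df


def write_estimates(estimates: pd.DataFrame, path) -> None:
    estimates[ESTIMATE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    _check_columns(df, ESTIMATE_COLUMNS, "estimates")
    df["value"] = df["value"].astype(float)
    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    return df


def write_curves(curves: list[PrevalenceCurve], path) -> None:
    rows = []
    for c in curves:
        for age, value in enumerate(c.values):
            rows.append((c.disease, c.sex, c.country, c.analysis, age, repr(float(value))))
    pd.DataFrame(rows, columns=_CURVE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_curves(path) -> list[PrevalenceCurve]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _check_columns(df, _CURVE_COLUMNS, "curves")
    out = []
    keys = ["disease", "sex", "country", "analysis"]
    for (disease, sex, country, analysis), g in df.groupby(keys, sort=False):
        g = g.sort_values("age")
        values = np.zeros(N_AGES)
        values[g["age"].to_numpy()] = g["value"].to_numpy(float)
        out.append(PrevalenceCurve(disease, sex, country, values, analysis))
    return out


def write_matrix(dmat: ShapeDissimilarityMatrix, path, shifts_path=None) -> None:
    labels = ["|".join(map(str, l)) if isinstance(l, tuple) else str(l) for l in dmat.labels]
    pd.DataFrame(dmat.D, index=labels, columns=labels).to_csv(path, sep="\t")
    if shifts_path is not None:
        pd.DataFrame(dmat.shifts, index=labels, columns=labels).to_csv(shifts_path, sep="\t")


def read_matrix(path, shifts_path=None) -> ShapeDissimilarityMatrix:
    D = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(D.index)
    shifts = np.zeros(D.shape, dtype=int)
    if shifts_path is not None:
        shifts = pd.read_csv(shifts_path, sep="\t", index_col=0).to_numpy(dtype=int)
    return ShapeDissimilarityMatrix(labels, D.to_numpy(float), shifts)


def write_embedding(embedding: DiseaseEmbedding, path) -> None:
    embedding.to_frame().to_csv(path, sep="\t")


def read_embedding(path, dim: int | None = None) -> DiseaseEmbedding:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dim is not None and df.shape[1] != dim:
        raise ValueError(f"embedding file has {df.shape[1]} dimensions, expected {dim}")
    vectors = {code: row.to_numpy(float) for code, row in df.iterrows()}
    return DiseaseEmbedding(dim=df.shape[1], vectors=vectors)


def write_feature_table(X: np.ndarray, schema: FeatureSchema, path, schema_path) -> None:
    pd.DataFrame(np.asarray(X, float)).to_csv(path, sep="\t", index=False, float_format="%.17g")
    Path(schema_path).write_text(schema.to_json())


def read_feature_table(path, schema_path) -> tuple[np.ndarray, FeatureSchema]:
    X = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(float)
    schema = FeatureSchema.from_json(Path(schema_path).read_text())
    if X.shape[1] != schema.length:
        raise ValueError("feature table width does not match schema")
    return X, schema
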