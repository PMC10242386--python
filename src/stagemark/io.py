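"""Delimited-text readers/writers and JSON model persistence.

Expression matrices are genes x samples with a gene-id first column and a
sample-id header; tab and comma delimiters are auto-detected.  Trained
models persist as a versioned JSON document holding the PCA (feature ids,
training means, loadings, eigenvalues, component count) and the k-means
classifier (centroids, cluster-to-class map), so prediction needs no
original data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, StageDesign
from .errors import ConfigurationError, ParseError
from .pc_cluster import KMeansClassifier, PCAModel
from .preprocess import SplitIndex

MODEL_FORMAT_VERSION = 1


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ParseError(f"{path}: could not detect a tab or comma delimiter in line 1")


def read_expression(path) -> ExpressionMatrix:
    """Parse a delimited expression matrix, validating ids and values."""
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pandas reports the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            if bad:
                lines = [int(df.index.get_loc(b)) + 2 for b in bad[:5]]
                raise ParseError(
                    f"{path}: non-numeric values in column '{col}' (lines {lines})"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ParseError(f"{path}: missing/ragged values in rows {rows}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return ExpressionMatrix(df)
    except ConfigurationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    m.values.to_csv(path, sep=sep, index_label="gene")


def read_annotation(path) -> StageDesign:
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return StageDesign(df)
    except ConfigurationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_annotation(d: StageDesign, path, sep: str = "\t") -> None:
    d.table.to_csv(path, sep=sep, index=False)


def write_table(df: pd.DataFrame, path, sep: str = "\t", index: bool = True) -> None:
    df.to_csv(path, sep=sep, index=index)


def write_split(split: SplitIndex, path, sep: str = "\t") -> None:
    rows = [(s, "train") for s in split.train_ids] + [(s, "test") for s in split.test_ids]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(path, sep=sep, index=False)


def read_split(path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)))
    train = df.loc[df["partition"] == "train", "sample_id"].astype(str).tolist()
    test = df.loc[df["partition"] == "test", "sample_id"].astype(str).tolist()
    return train, test


def save_model(path, pca: PCAModel, clf: KMeansClassifier, input_scale: str = "linear") -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "input_scale": input_scale,
        "pca": {
            "feature_ids": pca.feature_ids,
            "means": pca.means.tolist(),
            "loadings": pca.loadings.tolist(),
            "eigenvalues": pca.eigenvalues.tolist(),
            "n_components": pca.q,
        },
        "classifier": {
            "k": clf.k,
            "centroids": clf.centroids.tolist(),
            "cluster_to_class": {str(c): cls for c, cls in clf.cluster_to_class.items()},
            "inertia": clf.inertia,
            "seed": clf.seed,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> tuple[PCAModel, KMeansClassifier, str]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid model JSON: {exc}") from exc
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported model format {doc.get('format_version')}")
    p, c = doc["pca"], doc["classifier"]
    pca = PCAModel(
        feature_ids=list(p["feature_ids"]),
        means=np.asarray(p["means"], float),
        loadings=np.asarray(p["loadings"], float),
        eigenvalues=np.asarray(p["eigenvalues"], float),
        n_components=int(p["n_components"]),
    )
    clf = KMeansClassifier(
        k=int(c["k"]),
        centroids=np.asarray(c["centroids"], float),
        cluster_to_class={int(k): v for k, v in c["cluster_to_class"].items()},
        inertia=float(c["inertia"]),
        seed=int(c["seed"]),
    )
    return pca, clf, doc.get("input_scale", "linear")


def metrics_report(records: dict) -> pd.DataFrame:
    """One row per dataset, columns mirroring the standard diagnosis report.

    Percentages are rounded to two decimals with round-half-even.
    """
    rows = []
    for name, rec in records.items():
        rows.append({
            "dataset": name,
            "bal_acc": round(rec.balanced_accuracy, 2),
            "specificity": round(rec.specificity, 2),
            "precision": round(rec.precision, 2),
            "recall": round(rec.recall, 2),
            "f1": round(rec.f1, 2),
            "auroc": round(rec.auroc, 3) if rec.auroc is not None else "",
            "mcc": round(rec.mcc, 2),
        })
    return pd.DataFrame(rows)
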