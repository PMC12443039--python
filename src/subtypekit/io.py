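"""Plain-text readers/writers for the pipeline's file formats.

Expression matrices travel as gene x sample TSV (first column ``gene_id``,
header row of sample ids); gene annotations as a TSV with ``gene_id``,
``is_mito`` and optional ``lineage_set`` columns; clinical tables as TSV
indexed by ``sample_id``; signatures and gene sets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, LineageGeneSets
from .signature import CentroidSignature

__all__ = [
    "read_counts", "write_counts",
    "read_expression", "write_expression",
    "read_annotation", "write_annotation",
    "read_clinical", "write_clinical",
    "read_signature_json", "write_signature_json",
    "read_gene_sets_json", "write_gene_sets_json",
]


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_counts(counts_path, annotation_path=None) -> CountMatrix:
    df = _read_matrix(counts_path)
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        is_mito = ann["is_mito"].reindex(df.index)
    else:
        is_mito = pd.Series(False, index=df.index)
    return CountMatrix(df, is_mito)


def write_counts(cm: CountMatrix, path) -> None:
    cm.values.to_csv(path, sep="\t")


def read_expression(path, annotation_path=None) -> ExpressionMatrix:
    df = _read_matrix(path)
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        is_mito = ann["is_mito"].reindex(df.index)
    else:
        is_mito = pd.Series(False, index=df.index)
    return ExpressionMatrix(df, is_mito)


def write_expression(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "is_mito" in ann.columns:
        ann["is_mito"] = ann["is_mito"].astype(bool)
    return ann


def write_annotation(is_mito: pd.Series, path,
                     lineage_sets: LineageGeneSets | None = None) -> None:
    ann = pd.DataFrame({"is_mito": is_mito.astype(bool)})
    ann.index.name = "gene_id"
    if lineage_sets is not None:
        col = pd.Series("", index=ann.index)
        for name, genes in lineage_sets.sets.items():
            col.loc[[g for g in genes if g in ann.index]] = name
        ann["lineage_set"] = col
    ann.to_csv(path, sep="\t")


def lineage_sets_from_annotation(ann: pd.DataFrame) -> LineageGeneSets:
    if "lineage_set" not in ann.columns:
        raise ValueError("annotation lacks a lineage_set column")
    col = ann["lineage_set"].fillna("")
    sets = {name: list(col.index[col == name])
            for name in sorted(col.unique()) if name}
    return LineageGeneSets(sets)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_signature_json(sig: CentroidSignature, path,
                         provenance: dict | None = None) -> None:
    payload = {
        "classes": [str(c) for c in sig.classes],
        "n_per_class": sig.n_per_class,
        "genes": list(sig.genes),
        "class_of_gene": {g: str(c) for g, c in sig.class_of_gene.items()},
        "centroids": {str(c): sig.centroids.loc[c, sig.genes].tolist()
                      for c in sig.classes},
        "training_stats": {
            "mean": sig.training_stats["mean"].loc[sig.genes].tolist(),
            "sd": sig.training_stats["sd"].loc[sig.genes].tolist()},
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_signature_json(path) -> CentroidSignature:
    payload = json.loads(Path(path).read_text())
    genes = payload["genes"]
    classes = payload["classes"]
    if all(isinstance(c, str) and c.isdigit() for c in classes):
        classes = [int(c) for c in classes]   # integer subtype labels
    centroids = pd.DataFrame(
        [payload["centroids"][str(c)] for c in classes],
        index=classes, columns=genes)
    stats = pd.DataFrame({"mean": payload["training_stats"]["mean"],
                          "sd": payload["training_stats"]["sd"]},
                         index=genes)
    return CentroidSignature(
        classes=classes, n_per_class=payload["n_per_class"], genes=genes,
        class_of_gene=pd.Series(payload["class_of_gene"]),
        centroids=centroids, training_stats=stats)


def write_gene_sets_json(sets: LineageGeneSets, path) -> None:
    Path(path).write_text(json.dumps(sets.sets, indent=1, sort_keys=True))


def read_gene_sets_json(path) -> LineageGeneSets:
    return LineageGeneSets(json.loads(Path(path).read_text()))
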