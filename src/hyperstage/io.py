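"""Readers, normalization and model serialization."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import ExpressionDataset, Hyperedge, Hypergraph, StageStats

__all__ = [
    "read_expression_pair",
    "write_expression_pair",
    "normalize_dataset",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "hyperstage-model"
MODEL_VERSION = 1
_SIGMA_FLOOR = 1e-6


def _read_matrix(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dup[:5]}")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc


def read_expression_pair(mirna_path, mrna_path, labels_path) -> ExpressionDataset:
    """Load matched miRNA/mRNA matrices (features x samples) plus labels.

    Sample columns are aligned across the three files by id, independent of
    order; any mismatch raises with the offending sample ids spelled out.
    """
    mirna = _read_matrix(mirna_path)
    mrna = _read_matrix(mrna_path)
    sep = "," if str(labels_path).endswith(".csv") else "\t"
    lab = pd.read_csv(labels_path, sep=sep, index_col=0).iloc[:, 0]
    lab.index = lab.index.astype(str)
    sets = {"miRNA": set(mirna.columns), "mRNA": set(mrna.columns), "labels": set(lab.index)}
    common = sets["miRNA"] & sets["mRNA"] & sets["labels"]
    problems = [
        f"{name} file is missing samples {sorted(sets[name2] - sets[name])[:10]}"
        for name in sets
        for name2 in sets
        if sets[name2] - sets[name]
    ]
    if problems:
        raise ValueError("sample sets differ: " + "; ".join(sorted(set(problems))))
    order = [c for c in mirna.columns if c in common]
    return ExpressionDataset(
        mirna=mirna[order], mrna=mrna[order], labels=lab.loc[order].astype(str)
    )


def write_expression_pair(dataset: ExpressionDataset, mirna_path, mrna_path, labels_path) -> None:
    dataset.mirna.to_csv(mirna_path, sep="\t")
    dataset.mrna.to_csv(mrna_path, sep="\t")
    dataset.labels.rename("stage").to_frame().to_csv(labels_path, sep="\t", index_label="sample")


def _zscore(values: np.ndarray, axis: int) -> np.ndarray:
    mean = values.mean(axis=axis, keepdims=True)
    sd = np.maximum(values.std(axis=axis, ddof=0, keepdims=True), _SIGMA_FLOOR)
    return (values - mean) / sd


def normalize_dataset(dataset: ExpressionDataset, mode: str = "sample_feature") -> ExpressionDataset:
    """Z-score normalization; miRNA and mRNA blocks are treated separately.

    ``"sample_feature"`` (default): per-sample z-score within each block,
    then per-feature z-score across samples.  Also available: ``"feature"``,
    ``"sample"``, ``"feature_sample"`` and ``"none"``.  All steps use the
    population SD with a small floor, so constant features map to zeros.
    """
    steps = {
        "sample_feature": ("sample", "feature"),
        "feature_sample": ("feature", "sample"),
        "feature": ("feature",),
        "sample": ("sample",),
        "none": (),
    }
    if mode not in steps:
        raise ValueError(f"unknown normalization mode {mode!r}")

    def run(df: pd.DataFrame) -> pd.DataFrame:
        values = df.to_numpy(float)
        for step in steps[mode]:
            # matrices are features x samples: sample-wise means along axis 0
            values = _zscore(values, axis=0 if step == "sample" else 1)
        return pd.DataFrame(values, index=df.index, columns=df.columns)

    return ExpressionDataset(
        mirna=run(dataset.mirna), mrna=run(dataset.mrna), labels=dataset.labels.copy()
    )


def save_model(model: Hypergraph, path) -> None:
    """Serialize a model to canonical JSON (sorted keys, full precision)."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "stages": list(model.stages),
        "config": asdict(model.config) if is_dataclass(model.config) else model.config,
        "hyperedges": [
            {
                "mirna_members": list(e.mirna_members),
                "mrna_members": list(e.mrna_members),
                "mmi": e.mmi,
                "weights": {y: e.weights[y] for y in model.stages},
                "stats": {
                    y: {
                        "mean": e.stats[y].mean.tolist(),
                        "sd": e.stats[y].sd.tolist(),
                        "cov": e.stats[y].cov.tolist(),
                    }
                    for y in model.stages
                },
            }
            for e in model.hyperedges
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_model(path) -> Hypergraph:
    """Load a model saved by :func:`save_model` (bit-stable round trip)."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
    config = doc.get("config")
    if isinstance(config, dict):
        from .learning import LearningConfig

        known = {f for f in LearningConfig.__dataclass_fields__}
        config = LearningConfig(**{k: v for k, v in config.items() if k in known})
    edges = [
        Hyperedge(
            mirna_members=tuple(e["mirna_members"]),
            mrna_members=tuple(e["mrna_members"]),
            mmi=float(e["mmi"]),
            weights={y: float(w) for y, w in e["weights"].items()},
            stats={
                y: StageStats(
                    mean=np.asarray(s["mean"], float),
                    sd=np.asarray(s["sd"], float),
                    cov=np.asarray(s["cov"], float),
                )
                for y, s in e["stats"].items()
            },
        )
        for e in doc["hyperedges"]
    ]
    return Hypergraph(hyperedges=edges, stages=list(doc["stages"]), config=config)
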