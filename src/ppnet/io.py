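"""Readers, writers and core containers for feature matrices, labels and gene sets.

All tabular files are plain delimited text (tab or comma, auto-detected on
read, tab on write).  Feature matrices are stored samples-in-rows with a
header row of feature identifiers and the sample identifier in the first
column.  Downstream modules always match samples by identifier, never by
position.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureMatrix:
    """A samples x features numeric matrix for one data modality.

    ``values`` is a pandas DataFrame indexed by sample identifier with
    feature identifiers as columns.  All values must be finite and both
    index and columns must be unique.
    """

    values: pd.DataFrame
    modality: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()].astype(str)))
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()].astype(str)))
            raise ValidationError(f"duplicate feature IDs: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("feature matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at sample {idx[r]!r}, feature {cols[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features: Sequence[str]) -> "FeatureMatrix":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown features: {missing[:5]}")
        return FeatureMatrix(self.values.loc[:, list(features)], self.modality)

    def subset_samples(self, samples: Sequence[str]) -> "FeatureMatrix":
        missing = [s for s in samples if s not in self.values.index]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:5]}")
        return FeatureMatrix(self.values.loc[list(samples)], self.modality)


@dataclasses.dataclass
class LabelVector:
    """Class labels for a set of samples, stored as a pandas Series."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in label vector")
        self.labels = self.labels.astype(str)
        if len(self.label_set) < 2:
            raise ValidationError("label vector must contain at least 2 classes")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.labels.index]

    @property
    def label_set(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset(self, samples: Sequence[str]) -> pd.Series:
        return self.labels.loc[list(samples)]


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets, e.g. read from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run (see :func:`read_config`)."""

    modalities: dict  # name -> {"train": path, "test": path}
    labels: dict      # {"train": path, "test": path (optional)}
    level: str = "edges"                     # nodes | edges | nodes_and_edges
    node_similarity: str = "spearman"        # affinity | gaussian | spearman
    edge_method: str = "node_product"        # node_product | lioness
    fusion: str = "none"                     # none | early | intermediate_average
    #                                          | intermediate_snf | late
    selection: dict | None = None            # name -> {"n_nodes": int, "t_edge": float}
    node_grid: list | None = None
    edge_grid: list | None = None
    C_grid: list = dataclasses.field(default_factory=lambda: [10.0 ** k for k in range(1, 6)])
    folds: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if len(self.C_grid) == 0:
            raise ValidationError("C grid must be non-empty")


# ---------------------------------------------------------------------------
# feature matrices and labels
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_feature_matrix(path, modality: str = "") -> FeatureMatrix:
    """Read a delimited samples x features matrix.

    The header row holds feature IDs and the first column sample IDs.
    Tab or comma delimiters are auto-detected; any non-numeric or missing
    cell is an error.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r} in {path}"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureMatrix(df, modality=modality or path.stem)


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="sample_id")


def read_labels(path) -> LabelVector:
    """Read a two-column (sample_id, label) table."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValidationError(f"label file {path} needs a label column")
    return LabelVector(df.iloc[:, 0])


def write_labels(labels: LabelVector, path) -> None:
    labels.labels.rename("label").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g, None)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# PPN matrices
# ---------------------------------------------------------------------------

def write_ppn(ppn, path) -> None:
    """Write a PPN as delimited text with row/column sample IDs."""
    df = pd.DataFrame(ppn.values, index=ppn.row_ids, columns=ppn.col_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_ppn(path, kind: str = "node"):
    from .ppn import PPNMatrix  # local import avoids a cycle

    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0).astype(float)
    return PPNMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=df.to_numpy(),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# predictions, metrics, run configuration and logging
# ---------------------------------------------------------------------------

def write_predictions(path, sample_ids, predicted, truth=None) -> None:
    df = pd.DataFrame({"sample_id": list(sample_ids), "predicted": list(predicted)})
    if truth is not None:
        df["true"] = list(truth)
    df.to_csv(path, sep="\t", index=False)


def write_metrics(report, path) -> None:
    """Write per-class and macro F1 as a two-column table."""
    rows = [("macro_f1", report.macro_f1)]
    rows += [(f"f1_{cls}", v) for cls, v in sorted(report.per_class_f1.items())]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    for name, paths in cfg.modalities.items():
        for split, p in paths.items():
            if not Path(p).exists():
                raise ValidationError(f"modality {name!r} {split} file not found: {p}")
    for split, p in cfg.labels.items():
        if p is not None and not Path(p).exists():
            raise ValidationError(f"label {split} file not found: {p}")
    return cfg


def write_run_log(path, config: Mapping, results: Mapping) -> None:
    payload = {"config": dict(config), "results": dict(results)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_edge_list(path, edges: Iterable, weights, colors=None) -> None:
    """Export a network as (node_a, node_b, weight[, group_color]) rows."""
    rows = []
    colors = list(colors) if colors is not None else None
    for k, ((a, b), w) in enumerate(zip(edges, weights)):
        row = {"node_a": a, "node_b": b, "weight": w}
        if colors is not None:
            row["group_color"] = colors[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
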