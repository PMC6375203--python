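"""Readers and writers for the pipeline's plain-text formats.

Expression, clinical, eigengene and risk tables are tab-separated UTF-8
with a header row; modules travel as GMT (label, description, then gene
symbols, one module per line); reports are JSON; affinity matrices are
TSV with a sample-id header row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lmqcm import GeneModule

__all__ = ["read_expression", "write_expression", "read_clinical",
           "write_clinical", "read_modules_gmt", "write_modules_gmt",
           "read_matrix_tsv", "write_matrix_tsv", "write_report"]


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples expression TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols in {path}: {dups}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression file {path}")
    df.index.name = "gene"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, event[, group]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    bad_time = df.index[df["time"] <= 0].tolist()
    if bad_time:
        raise ValueError(f"non-positive survival time in rows {bad_time}")
    bad_event = df.index[~df["event"].isin([0, 1])].tolist()
    if bad_event:
        raise ValueError(f"event indicator not in {{0,1}} in rows {bad_event}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_modules_gmt(path) -> list[GeneModule]:
    modules = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        label, desc, genes = parts[0], parts[1], parts[2:]
        platform = desc or None
        modules.append(GeneModule(label, list(genes), platform))
    return modules


def write_modules_gmt(modules, path) -> None:
    lines = []
    for m in modules:
        desc = m.platform or ""
        lines.append("\t".join([m.label, desc] + list(m.genes)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path, index_name=None) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_report(obj, path) -> None:
    """Write a JSON report, converting numpy scalars/arrays along the way."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def check_sample_alignment(expr: pd.DataFrame, clinical: pd.DataFrame) -> None:
    """Raise when expression columns and clinical sample ids disagree."""
    e = set(expr.columns)
    c = set(clinical["sample_id"])
    if e != c:
        only_e = sorted(e - c)[:5]
        only_c = sorted(c - e)[:5]
        raise ValueError(
            "expression and clinical sample ids disagree; "
            f"only in expression: {only_e}; only in clinical: {only_c}")
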