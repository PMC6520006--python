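"""Readers and writers for the pipeline's on-disk formats.

Expression matrices, metadata and per-gene result tables travel as UTF-8
tab-separated text with "." decimals and no quoting; gene sets travel as
standard GMT. Readers enforce the container invariants up front (unique gene
ids, numeric cells, mandatory age column) so later stages never see malformed
input. Counts of dropped or filtered entities go to the logger; results never
do.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import AnalysisConfig, ExpressionMatrix, GeneSetCollection, SampleMetadata

log = logging.getLogger(__name__)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy())
        g, s = bad[0]
        raise ValueError(
            f"non-numeric expression cell in {path} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}: {df.iat[g, s]!r}"
        ) from None
    return ExpressionMatrix(values.astype(float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> SampleMetadata:
    """Read per-sample metadata TSV; ``age`` is required, extras retained."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "age" not in df.columns:
        raise ValueError(f"age required: no 'age' column in {path}")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def align(expr: ExpressionMatrix, meta: SampleMetadata
          ) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Restrict both containers to shared samples, in expression order."""
    shared = [s for s in expr.sample_ids if s in set(meta.sample_ids)]
    if not shared:
        raise ValueError("no sample ids shared between expression and metadata")
    dropped = (expr.n_samples - len(shared)) + (len(meta.sample_ids) - len(shared))
    if dropped:
        log.info("align: dropped %d unmatched samples", dropped)
    return expr.subset_samples(shared), meta.subset(shared)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (set id, description, members, tab-separated)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_dedup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (set id, description, members)")
            sid, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                n_dedup += len(members) - len(unique)
            sets[sid] = unique
            descriptions[sid] = desc
    if n_dedup:
        log.info("read_gene_sets: removed %d duplicate members", n_dedup)
    if not sets:
        log.warning("read_gene_sets: %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, members in collection:
            desc = collection.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *members]) + "\n")


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a result table as TSV with a fixed column order."""
    if columns is not None:
        df = df.loc[:, columns]
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat key: value YAML mapping."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    for key in ("young_range", "old_range"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return AnalysisConfig(**raw)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
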