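"""Plain-text readers and writers: gene-by-sample TSV, metadata TSV, GMT.

All stage artifacts are plain text so any stage can be rerun or replaced by
an external implementation for differential testing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dataset import ExpressionDataset

_FLOAT_FMT = "%.10g"


def write_expression_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    """Write genes in rows, header row of sample ids, first column gene ids."""
    ds.values.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_expression_tsv(path: str | Path, metadata: pd.DataFrame | None = None,
                        scale: str = "log", name: str = "") -> ExpressionDataset:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return ExpressionDataset(values, metadata, scale=scale, name=name)


def write_metadata_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    ds.metadata.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0)
    md.index = md.index.astype(str)
    return md


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """GMT: one set per line — name, description, then member genes, tab-separated."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
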