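"""Expression data container shared by every analysis stage.

An :class:`ExpressionDataset` couples a gene-by-sample value matrix with the
per-sample metadata the downstream stages need (subject, tissue, batch, TIN,
progression status, ...).  The matrix lives in a pandas DataFrame with gene
identifiers as the index and sample identifiers as columns; metadata is a
DataFrame indexed by sample identifier, row-aligned with the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allowed values of the scale tag
SCALES = ("counts", "log2cpm", "residual", "zscore", "log")


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression values plus aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids.
    metadata
        DataFrame indexed by sample id, aligned 1:1 with ``values.columns``.
    scale
        One of ``counts``, ``log2cpm``, ``residual``, ``zscore`` or ``log``
        (generic log-scale values, e.g. simulated data).
    name
        Optional dataset name (e.g. ``"biopsy"``).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    scale: str = "log"
    name: str = ""

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.values.columns)
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not self.metadata.index.equals(self.values.columns):
            # allow same set in different order: realign
            if set(self.metadata.index) == set(self.values.columns):
                self.metadata = self.metadata.loc[self.values.columns]
            else:
                raise ValueError("metadata rows do not align with sample ids")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        """Values as a float ndarray (genes × samples)."""
        return self.values.to_numpy(dtype=float)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionDataset(self.values.loc[genes], self.metadata.copy(),
                                 scale=self.scale, name=self.name)

    def subset_samples(self, samples: list[str]) -> "ExpressionDataset":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionDataset(self.values[samples], self.metadata.loc[samples],
                                 scale=self.scale, name=self.name)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionDataset":
        """Return a copy carrying new values (same samples, any gene subset)."""
        return ExpressionDataset(values, self.metadata.loc[values.columns],
                                 scale=scale or self.scale, name=self.name)


def zscore_genes(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, sd 1; constant rows become 0."""
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mu) / sd, index=values.index, columns=values.columns)
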