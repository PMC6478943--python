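"""Cross-dataset module conservation selection.

Every detected module (from every dataset) becomes a gene set in a
compendium.  For each gene set and each dataset, PC1 of the z-scored member
genes present in that dataset is computed.  Per dataset, the absolute
Pearson correlation matrix between all PC1 vectors is binarized at a
threshold (strictly greater than; default 0.85) and the binary matrices are
summed across datasets.  A biopsy-derived module is retained when some
non-biopsy set correlates above threshold with it in every dataset (summed
entry equal to the number of datasets).  Genes of a retained module are then
filtered to those also present in at least one correlated partner set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .network import GeneModule, module_eigengene


@dataclass
class ModuleCompendium:
    """Gene sets from all datasets with per-dataset PC1 vectors."""

    gene_sets: dict[str, list[str]]
    source: dict[str, str]                       # set id -> source dataset
    pc1: dict[tuple[str, str], pd.Series]        # (set id, dataset) -> PC1
    datasets: list[str]

    def defined(self, set_id: str, dataset: str) -> bool:
        return (set_id, dataset) in self.pc1


@dataclass
class ConservationDecision:
    """Outcome of the summed-binarized-correlation retention rule."""

    summed_matrix: pd.DataFrame
    retained_biopsy_modules: list[str]
    partners: dict[str, list[str]]
    filtered_genes: dict[str, list[str]] = field(default_factory=dict)
    threshold: float = 0.85
    biopsy_dataset: str = "biopsy"


def build_compendium(modules: dict[str, list[GeneModule]],
                     datasets: dict[str, ExpressionDataset]) -> ModuleCompendium:
    """Combine per-dataset module lists and compute PC1 per (set, dataset).

    A set's PC1 in a dataset is defined over the intersection of its genes
    with that dataset's genes and requires at least 2 present genes;
    otherwise the (set, dataset) pair carries no PC1 (undefined marker).
    """
    gene_sets: dict[str, list[str]] = {}
    source: dict[str, str] = {}
    for dname, mods in modules.items():
        for m in mods:
            gene_sets[m.label] = list(m.genes)
            source[m.label] = dname
    if not gene_sets:
        raise ValueError("no modules supplied")
    pc1: dict[tuple[str, str], pd.Series] = {}
    for sid, genes in gene_sets.items():
        found_anywhere = False
        for dname, ds in datasets.items():
            present = [g for g in genes if g in ds.values.index]
            if len(present) < 2:
                continue
            e, _ = module_eigengene(ds, present)
            pc1[(sid, dname)] = e
            found_anywhere = True
        if not found_anywhere:
            raise ValueError(f"gene set {sid!r} absent from all datasets")
    return ModuleCompendium(gene_sets, source, pc1, list(datasets))


def conservation_select(comp: ModuleCompendium, threshold: float = 0.85,
                        biopsy_dataset: str = "biopsy") -> ConservationDecision:
    """Retain biopsy modules conserved (same partner) across all datasets."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if len(comp.datasets) < 2:
        raise ValueError("need at least 2 datasets")
    set_ids = list(comp.gene_sets)
    biopsy_sets = [s for s in set_ids if comp.source[s] == biopsy_dataset]
    if not biopsy_sets:
        raise ValueError(f"no modules from biopsy dataset {biopsy_dataset!r}")
    n = len(set_ids)
    summed = np.zeros((n, n), dtype=int)
    for dname in comp.datasets:
        vecs = np.full((n, 1), np.nan)
        defined = [i for i, s in enumerate(set_ids) if comp.defined(s, dname)]
        if len(defined) >= 2:
            mat = np.vstack([comp.pc1[(set_ids[i], dname)].to_numpy() for i in defined])
            r = np.abs(np.corrcoef(mat))
            binary = (r > threshold).astype(int)
            np.fill_diagonal(binary, 1)
            summed[np.ix_(defined, defined)] += binary
        # undefined PC1 pairs contribute 0 (below threshold by convention)
    summed_df = pd.DataFrame(summed, index=set_ids, columns=set_ids)
    n_datasets = len(comp.datasets)
    retained, partners = [], {}
    for b in biopsy_sets:
        p = [s for s in set_ids
             if comp.source[s] != biopsy_dataset and summed_df.loc[b, s] == n_datasets]
        if p:
            retained.append(b)
            partners[b] = p
    return ConservationDecision(summed_df, retained, partners,
                                threshold=threshold, biopsy_dataset=biopsy_dataset)


def filter_module_genes(decision: ConservationDecision,
                        comp: ModuleCompendium) -> ConservationDecision:
    """Keep module genes also present in at least one partner set."""
    filtered: dict[str, list[str]] = {}
    kept_modules, kept_partners = [], {}
    for m in decision.retained_biopsy_modules:
        union: set[str] = set()
        for p in decision.partners[m]:
            union |= set(comp.gene_sets[p])
        genes = [g for g in comp.gene_sets[m] if g in union]
        if not genes:
            warnings.warn(f"module {m}: no genes shared with partners; dropped")
            continue
        filtered[m] = genes
        kept_modules.append(m)
        kept_partners[m] = decision.partners[m]
    return ConservationDecision(decision.summed_matrix, kept_modules, kept_partners,
                                filtered_genes=filtered, threshold=decision.threshold,
                                biopsy_dataset=decision.biopsy_dataset)
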