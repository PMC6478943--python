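"""Weighted co-expression network analysis: soft threshold, topological
overlap, tree-cut module detection, and module eigengenes.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the soft
power beta chosen by the scale-free fit criterion.  Gene similarity is the
topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and modules are branches of the average-linkage dendrogram of 1 - TOM,
obtained by a static cut followed by recursive branch splitting and scatter
peeling.  Modules with highly correlated eigengenes (correlation above
1 - merge_cut) are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset, zscore_genes

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
DEFAULT_POWER = 6


@dataclass
class TomMatrix:
    """Topological overlap similarity (genes x genes) and the power used."""

    values: pd.DataFrame
    power: float

    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values.to_numpy()


@dataclass
class GeneModule:
    """A detected co-expression module with its eigengene summary."""

    label: str
    genes: list[str]
    eigengene: pd.Series          # per-sample, unit variance
    var_explained: float
    source_dataset: str = ""


def adjacency_matrix(expr: ExpressionDataset, power: float) -> pd.DataFrame:
    """Unsigned adjacency |Pearson r|^power with zero diagonal."""
    arr = expr.matrix()
    r = np.corrcoef(arr)
    r = np.nan_to_num(r, nan=0.0)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.values.index, columns=expr.values.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of binned connectivity frequency.

    Bins the connectivities into equal-width bins, regresses log10 frequency
    on log10 mean bin connectivity; the fit is negated when the slope is
    positive (scale-free topology requires a decreasing relationship).
    Returns NaN when fewer than 2 usable bins remain.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            dk.append(k[mask].mean())
            freq.append(mask.mean())
    if len(dk) < 2:
        return np.nan
    lx, ly = np.log10(dk), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = np.sum((ly - fitted) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_power(expr: ExpressionDataset,
                    candidate_powers: tuple[float, ...] = DEFAULT_POWERS,
                    fit_target: float = 0.80) -> float:
    """Smallest power reaching the scale-free fit target, else the best fit."""
    if expr.n_genes < 3:
        warnings.warn("fewer than 3 genes: returning default power")
        return DEFAULT_POWER
    arr = expr.matrix()
    r = np.abs(np.nan_to_num(np.corrcoef(arr), nan=0.0))
    np.fill_diagonal(r, 0.0)
    fits = {}
    for beta in candidate_powers:
        k = (r ** beta).sum(axis=1)
        fits[beta] = scale_free_fit(k)
    usable = {b: f for b, f in fits.items() if np.isfinite(f)}
    if not usable:
        warnings.warn("scale-free fit undefined for all powers: returning default")
        return DEFAULT_POWER
    for beta in candidate_powers:
        if np.isfinite(fits[beta]) and fits[beta] >= fit_target:
            return beta
    return max(usable, key=usable.get)


def tom_similarity(adjacency: pd.DataFrame, power: float = np.nan) -> TomMatrix:
    """Topological overlap matrix from an adjacency matrix (diagonal forced 1)."""
    a = adjacency.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TomMatrix(pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns),
                     power)


def module_eigengene(expr: ExpressionDataset, genes: list[str]
                     ) -> tuple[pd.Series, float]:
    """PC1 of the z-scored module block, unit variance, sign-aligned.

    The eigengene's sign is fixed so that its correlation with the module's
    mean (z-scored) expression profile is non-negative.  Returns the
    eigengene and the fraction of variance it explains.
    """
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    if len(genes) == 0:
        raise ValueError("empty gene list")
    z = zscore_genes(expr.values.loc[genes]).to_numpy()     # genes x samples
    if len(genes) == 1:
        e = z[0]
        var_exp = 1.0
    else:
        u, s, _ = np.linalg.svd(z.T, full_matrices=False)   # samples x genes
        e = u[:, 0] * s[0]
        var_exp = float(s[0] ** 2 / np.sum(s ** 2))
    sd = e.std(ddof=1)
    if sd > 0:
        e = (e - e.mean()) / sd
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile - mean_profile.mean()) < 0:
        e = -e
    return pd.Series(e, index=expr.values.columns), var_exp


# -- tree cutting --------------------------------------------------------------

def _cluster_tree(linkage: np.ndarray, n_leaves: int):
    """Per-node children, heights, sizes and core heights for a linkage matrix.

    The core height of a node is the mean merge height inside its subtree
    (0 for leaves) — a measure of how tight the branch is.
    """
    n_internal = linkage.shape[0]
    n_nodes = n_leaves + n_internal
    children: list[tuple[int, int] | None] = [None] * n_nodes
    heights = np.zeros(n_nodes)
    sizes = np.ones(n_nodes, dtype=int)
    h_sum = np.zeros(n_nodes)
    h_cnt = np.zeros(n_nodes, dtype=int)
    for i, (a, b, h, _) in enumerate(linkage):
        node = n_leaves + i
        a, b = int(a), int(b)
        children[node] = (a, b)
        heights[node] = h
        sizes[node] = sizes[a] + sizes[b]
        h_sum[node] = h_sum[a] + h_sum[b] + h
        h_cnt[node] = h_cnt[a] + h_cnt[b] + 1
    core = np.where(h_cnt > 0, h_sum / np.maximum(h_cnt, 1), 0.0)
    return children, heights, sizes, core


def _subtree_leaves(node: int, children) -> list[int]:
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if children[v] is None:
            out.append(v)
        else:
            stack.extend(children[v])
    return out


def _collect_branches(root: int, children, heights, sizes, core,
                      min_size: int, descend_frac: float) -> list[int]:
    """Top-down branch collection: descend through loose joins, accept tight ones.

    A node is descended (its children examined independently) when its join
    height sits far above its subtree's core relative to the remaining
    headroom: (h - core) / (1 - core) >= descend_frac.  Nodes that fail the
    descent criterion are accepted as candidate module branches; branches
    smaller than ``min_size`` are dropped as scatter.
    """
    accepted: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        if sizes[v] < min_size or children[v] is None:
            continue
        headroom = 1.0 - core[v]
        loose = headroom <= 0 or (heights[v] - core[v]) >= descend_frac * headroom
        if loose:
            stack.extend(children[v])
        else:
            accepted.append(v)
    return accepted


def detect_modules(tom: TomMatrix, expr: ExpressionDataset,
                   min_module_size: int = 30, merge_cut: float = 0.25,
                   descend_frac: float = 0.5, core_scatter_max: float = 0.95
                   ) -> list[GeneModule]:
    """Detect modules by tree cutting the TOM dendrogram, then merge.

    Average-linkage clustering of 1 - TOM is traversed top-down: branches
    joined far above their own internal structure (relative height excess at
    least ``descend_frac`` of the remaining headroom to dissimilarity 1) are
    split and their children examined independently; tight branches are
    accepted as candidate modules.  Candidates smaller than
    ``min_module_size`` or with core scatter (mean internal merge height)
    above ``core_scatter_max`` are left unassigned.  Modules whose
    eigengenes correlate above ``1 - merge_cut`` are merged iteratively
    until stable.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom.values.index)
    d = tom.dissimilarity()
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    children, heights, sizes, core = _cluster_tree(z, len(genes))
    nodes = _collect_branches(len(children) - 1, children, heights, sizes, core,
                              min_module_size, descend_frac)
    clusters = [_subtree_leaves(v, children) for v in nodes
                if sizes[v] >= min_module_size and core[v] <= core_scatter_max]
    if not clusters:
        return []

    # order by size for stable labels, then merge correlated eigengenes
    clusters.sort(key=lambda c: (-len(c), min(c)))
    current = [[genes[i] for i in sorted(c)] for c in clusters]
    while True:
        eig = [module_eigengene(expr, g)[0].to_numpy() for g in current]
        if len(eig) < 2:
            break
        c = np.corrcoef(np.vstack(eig))
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= 1.0 - merge_cut:
            break
        merged = sorted(set(current[i]) | set(current[j]))
        current = [g for k2, g in enumerate(current) if k2 not in (i, j)] + [merged]
        current.sort(key=lambda g: (-len(g), g[0]))
    modules = []
    for idx, gset in enumerate(current, start=1):
        e, ve = module_eigengene(expr, gset)
        modules.append(GeneModule(label=f"{expr.name or 'dataset'}_mod{idx}",
                                  genes=gset, eigengene=e, var_explained=ve,
                                  source_dataset=expr.name))
    return modules


def run_wgcna(expr: ExpressionDataset, min_module_size: int = 30,
              merge_cut: float = 0.25,
              candidate_powers: tuple[float, ...] = DEFAULT_POWERS,
              power: float | None = DEFAULT_POWER) -> tuple[list[GeneModule], TomMatrix]:
    """Full per-dataset module detection: adjacency, TOM, tree cut, merge.

    Uses the canonical unsigned soft power (6) by default; pass
    ``power=None`` to select it by the scale-free fit criterion instead.
    """
    beta = power if power is not None else pick_soft_power(expr, candidate_powers)
    adj = adjacency_matrix(expr, beta)
    tom = tom_similarity(adj, power=beta)
    modules = detect_modules(tom, expr, min_module_size=min_module_size,
                             merge_cut=merge_cut)
    return modules, tom
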