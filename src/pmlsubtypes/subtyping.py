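"""Consensus clustering of biopsy samples and subtype annotation.

Samples are clustered with partitioning around medoids (PAM: deterministic
BUILD initialization followed by SWAP to a local optimum) on the distance
1 - Pearson correlation between sample profiles.  Consensus clustering
repeats PAM on random 80% subsamples; the consensus matrix entry for a
sample pair is the fraction of co-sampled iterations in which the pair
co-clustered.  The number of clusters k is chosen from the relative change
Delta(k) of the area A(k) under the empirical CDF of consensus values:
the largest k whose Delta(k) still exceeds a threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF areas, chosen k and assignments."""

    consensus: dict[int, pd.DataFrame]
    sample_ids: list[str]
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    assignments: pd.Series | None = None
    subtype_names: dict[int, str] = field(default_factory=dict)
    never_cosampled_pairs: int = 0
    provenance: dict = field(default_factory=dict)


# -- PAM -----------------------------------------------------------------------

def pam(dist: np.ndarray, k: int, max_swap_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a distance matrix.

    Deterministic BUILD initialization, then SWAP moves (best improving swap
    per iteration, all (medoid, candidate) pairs scored vectorized) until no
    swap lowers the total deviation.  Returns integer labels 0..k-1.
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if k == 1:
        return np.zeros(n, dtype=int)

    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    d1 = dist[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d1[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        d1 = np.minimum(d1, dist[c])

    medoids = np.array(medoids)
    for _ in range(max_swap_iter):
        dm = dist[medoids]                        # k x n
        order = np.argsort(dm, axis=0)
        nearest = order[0]                        # index into medoid list
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)]
        # delta TD for swapping medoid i out and candidate h in
        dh = dist                                  # n x n: dh[h, j]
        base = np.minimum(dh - d1[None, :], 0.0)   # contribution when i != nearest(j)
        base_sum = base.sum(axis=1)                # per candidate h
        corr_term = np.minimum(dh, d2[None, :]) - d1[None, :] - base
        onehot = np.zeros((n, len(medoids)))
        onehot[np.arange(n), nearest] = 1.0
        delta = base_sum[:, None] + corr_term @ onehot      # n x k
        delta[medoids, :] = np.inf
        h, i = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[h, i] > -1e-12:
            break
        medoids[i] = h
    else:
        log.info("PAM swap phase hit max iterations (%d)", max_swap_iter)

    labels_by_medoid = np.argmin(dist[medoids], axis=0)
    return labels_by_medoid


def pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample columns (profiles: genes x samples)."""
    r = np.corrcoef(profiles.T)
    r = np.nan_to_num(r, nan=0.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def consensus_cluster(expr: ExpressionDataset, genes: list[str],
                      k_max: int = 10, iters: int = 1000,
                      subsample: float = 0.8, seed: int = 0) -> ConsensusResult:
    """Consensus matrices for k = 2..k_max from PAM on resampled samples."""
    n = expr.n_samples
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    if n < 2 * k_max:
        raise ValueError("need at least 2*k_max samples")
    sub = expr.subset_genes(genes)
    dist = pearson_distance(sub.matrix())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x636f6e73]))
    m = int(np.ceil(subsample * n))
    sample_ids = expr.sample_ids

    consensus: dict[int, pd.DataFrame] = {}
    never = 0
    cosample = np.zeros((n, n))
    draws = [rng.choice(n, size=m, replace=False) for _ in range(iters)]
    for idx in draws:
        cosample[np.ix_(idx, idx)] += 1.0
    for k in range(2, k_max + 1):
        cocluster = np.zeros((n, n))
        for idx in draws:
            labels = pam(dist[np.ix_(idx, idx)], k)
            eq = labels[:, None] == labels[None, :]
            cocluster[np.ix_(idx, idx)] += eq
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
        nc = int(((cosample == 0).sum() - 0) // 2)
        if nc and k == 2:
            never = nc
            log.warning("%d sample pairs never co-sampled; consensus set to 0", nc)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        consensus[k] = pd.DataFrame(cons, index=sample_ids, columns=sample_ids)
    return ConsensusResult(consensus=consensus, sample_ids=sample_ids,
                           never_cosampled_pairs=never,
                           provenance={"k_max": k_max, "iters": iters,
                                       "subsample": subsample, "seed": seed,
                                       "distance": "1 - Pearson", "algorithm": "PAM"})


def cdf_area(consensus: pd.DataFrame) -> float:
    """Area under the empirical CDF of upper-triangle consensus entries on [0, 1]."""
    m = consensus.to_numpy()
    iu = np.triu_indices(m.shape[0], k=1)
    vals = np.sort(m[iu])
    n = vals.size
    # step-function integration: CDF jumps at each sorted value
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf_on_interval = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    return float(np.sum(np.diff(xs) * cdf_on_interval))


def select_k(result: ConsensusResult, delta_threshold: float = 0.10) -> int:
    """Choose k from the relative change in CDF area.

    A(k) is the CDF area of the consensus matrix at k; Delta(2) = A(2) and
    Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.  The chosen k is the
    largest k with Delta(k) >= delta_threshold.  The default threshold 0.10
    reflects that splitting one crisp cluster of proportion p inflates the
    area by roughly p^2/2 relative terms (below 0.10 for realistic cluster
    proportions), whereas resolving a further true cluster contributes more.
    """
    ks = sorted(result.consensus)
    if len(ks) < 3:
        raise ValueError("need at least 3 k values")
    for k in ks:
        result.cdf_area[k] = cdf_area(result.consensus[k])
    for i, k in enumerate(ks):
        if i == 0:
            result.delta[k] = result.cdf_area[k]
        else:
            prev = result.cdf_area[ks[i - 1]]
            if prev == 0:
                log.warning("A(%d) = 0; Delta(%d) undefined, skipped", ks[i - 1], k)
                continue
            result.delta[k] = (result.cdf_area[k] - prev) / prev
    passing = [k for k, d in result.delta.items() if d >= delta_threshold]
    chosen = max(passing) if passing else ks[0]
    result.chosen_k = chosen
    result.provenance["delta_threshold"] = delta_threshold
    result.provenance["rule"] = "largest k with Delta(k) >= threshold"
    return chosen


def finalize_assignments(result: ConsensusResult, chosen_k: int | None = None) -> pd.Series:
    """Final partition: average-linkage clustering of 1 - consensus at chosen k."""
    k = chosen_k if chosen_k is not None else result.chosen_k
    if k is None or k not in result.consensus:
        raise ValueError("no consensus matrix for the chosen k")
    d = 1.0 - result.consensus[k].to_numpy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    result.assignments = pd.Series(labels, index=result.sample_ids, name="cluster")
    return result.assignments


def annotate_subtypes(assignments: pd.Series, module_scores: pd.DataFrame,
                      association_fn, expected_pattern: dict[str, dict[str, int]],
                      fdr: float = 0.05) -> tuple[dict[int, str], pd.DataFrame]:
    """Name clusters by their module up/down signature.

    For each cluster, each module is marked up (+1), down (-1) or neutral (0)
    from the sign of significant (BH FDR < ``fdr``) one-vs-rest associations
    of its score, computed by ``association_fn(scores, in_cluster)`` which
    must return a DataFrame with ``estimate`` and ``qvalue`` per module.
    Cluster labels are assigned by best agreement with ``expected_pattern``
    (label -> module -> direction); ties or duplicate matches are reported,
    not silently broken.
    """
    clusters = sorted(assignments.unique())
    modules = list(module_scores.index)
    directions = pd.DataFrame(0, index=clusters, columns=modules, dtype=int)
    for c in clusters:
        in_cluster = (assignments == c).to_numpy()
        res = association_fn(module_scores, in_cluster)
        sig = res["qvalue"] < fdr
        directions.loc[c] = np.where(sig, np.sign(res["estimate"]).astype(int), 0)

    names: dict[int, str] = {}
    scores = {}
    for c in clusters:
        best_label, best_score = "unmatched", 0
        for label, pat in expected_pattern.items():
            vec = np.array([pat.get(m, 0) for m in modules])
            agree = int(np.sum((vec != 0) & (directions.loc[c].to_numpy() == vec)))
            disagree = int(np.sum((vec != 0) & (directions.loc[c].to_numpy() == -vec)))
            s = agree - disagree
            if s > best_score:
                best_label, best_score = label, s
        names[c] = best_label
        scores[c] = best_score
    # duplicate matches: report both, keep the mapping (no silent tie-break)
    seen: dict[str, list[int]] = {}
    for c, lbl in names.items():
        seen.setdefault(lbl, []).append(c)
    for lbl, cs in seen.items():
        if lbl != "unmatched" and len(cs) > 1:
            log.warning("label %r matched by clusters %s", lbl, cs)
    return names, directions
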