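"""Single-sample gene-set scoring, batch adjustment, and association tests.

* :func:`gsva_scores` — gene-set variation scores per sample: a Gaussian
  kernel CDF estimate per gene across samples, symmetric rank statistics,
  and a weighted Kolmogorov–Smirnov random walk per set and sample, scored
  by the max-difference rule (maximum positive deviation plus minimum
  negative deviation).
* :func:`combat_adjust` — parametric empirical-Bayes location/scale batch
  adjustment (batch means and variances shrunk toward their batch-wide
  priors by the iterative posterior solution).
* :func:`mixed_association` — repeated-measures association of responses
  with a two-level group: an exchangeable within-subject correlation is
  REML-profiled per response, atanh-averaged to a consensus rho, and each
  response is tested by generalized least squares at that rho.
* Plus BH-FDR, rank-based AUC, exact Fisher tests (2x2 and r×c), and a
  Fisher-based gene-set enrichment replacing web-service queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class GsvaMatrix:
    """Gene-set-by-sample score matrix with the parameters that produced it."""

    scores: pd.DataFrame
    gene_sets: dict[str, list[str]]
    parameters: dict = field(default_factory=dict)
    undefined_sets: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    """Per-response effect estimates, t-tests and BH q-values; consensus rho."""

    table: pd.DataFrame
    rho: float
    group_coding: str = ""


# -- GSVA ----------------------------------------------------------------------

def gsva_scores(expr: ExpressionDataset | pd.DataFrame, gene_sets: dict[str, list[str]],
                tau: float = 1.0, max_diff: bool = True) -> GsvaMatrix:
    """Gene-set variation scores (random-walk statistic) per set and sample."""
    values = expr.values if isinstance(expr, ExpressionDataset) else expr
    x = values.to_numpy(dtype=float)
    p, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    # Gaussian-kernel CDF estimate per gene, bandwidth sd/4
    sd = x.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    z = np.empty_like(x)
    for i in range(p):
        z[i] = sps.norm.cdf((x[i, :, None] - x[i, None, :]) / h[i]).mean(axis=1)
    # per-sample gene ranks by z, descending; symmetric rank statistic
    order = np.argsort(-z, axis=0, kind="stable")               # p x n
    ranks = np.empty_like(order)
    col = np.arange(n)
    ranks[order, col] = np.arange(1, p + 1)[:, None]
    r_stat = np.abs(p / 2.0 - ranks).astype(float)

    gene_index = {g: i for i, g in enumerate(values.index)}
    scores = {}
    undefined = []
    for name, genes in gene_sets.items():
        rows = [gene_index[g] for g in genes if g in gene_index]
        if len(rows) < 2:
            undefined.append(name)
            scores[name] = np.full(n, np.nan)
            continue
        in_set = np.zeros(p, dtype=bool)
        in_set[rows] = True
        set_mask = in_set[order]                                # p x n, walk order
        w = (r_stat ** tau)[order, col]
        w = np.where(set_mask, w, 0.0)
        denom_in = w.sum(axis=0)
        step_out = 1.0 / (p - len(rows))
        walk = np.cumsum(w / denom_in[None, :] - np.where(set_mask, 0.0, step_out), axis=0)
        vpos = np.maximum(walk.max(axis=0), 0.0)
        vneg = np.minimum(walk.min(axis=0), 0.0)
        scores[name] = vpos + vneg if max_diff else \
            np.where(vpos > -vneg, vpos, vneg)
    df = pd.DataFrame(scores, index=values.columns).T
    return GsvaMatrix(df, gene_sets,
                      parameters={"tau": tau, "kernel": "gaussian", "bandwidth": "sd/4",
                                  "combination": "max-difference" if max_diff else "two-sided-max"},
                      undefined_sets=undefined)


# -- ComBat --------------------------------------------------------------------

def _combat_frame(values: pd.DataFrame, batch: pd.Series, tol: float = 1e-6,
                  max_iter: int = 500) -> pd.DataFrame:
    batch = batch.loc[values.columns]
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        return values.copy()
    counts = batch.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batch with a single sample: {list(small.index)}")
    x = values.to_numpy(dtype=float)
    g, n = x.shape
    idx = {b: np.where((batch == b).to_numpy())[0] for b in levels}
    nb = np.array([len(idx[b]) for b in levels], dtype=float)

    batch_means = np.stack([x[:, idx[b]].mean(axis=1) for b in levels], axis=1)  # g x B
    grand = batch_means @ (nb / n)
    resid = x - np.concatenate([np.repeat(batch_means[:, [j]], int(nb[j]), axis=1)
                                for j in range(len(levels))], axis=1)[:, _inv_order(idx, n)]
    pooled_var = (resid ** 2).mean(axis=1)
    pooled_var[pooled_var == 0] = 1e-12
    sigma = np.sqrt(pooled_var)
    zdat = (x - grand[:, None]) / sigma[:, None]

    adjusted = zdat.copy()
    for j, b in enumerate(levels):
        cols = idx[b]
        zb = zdat[:, cols]
        ghat = zb.mean(axis=1)
        dhat = zb.var(axis=1, ddof=1)
        gbar, t2 = ghat.mean(), ghat.var(ddof=1)
        m, s2 = dhat.mean(), dhat.var(ddof=1)
        if s2 == 0:
            a_pr, b_pr = 2.0, m
        else:
            a_pr = (2 * s2 + m ** 2) / s2
            b_pr = (m * s2 + m ** 3) / s2
        gstar, dstar = ghat.copy(), dhat.copy()
        nbj = nb[j]
        for _ in range(max_iter):
            g_new = (nbj * t2 * ghat + dstar * gbar) / (nbj * t2 + dstar)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ss + b_pr) / (nbj / 2.0 + a_pr - 1.0)
            change = max(np.max(np.abs(g_new - gstar) / (np.abs(gstar) + 1e-12)),
                         np.max(np.abs(d_new - dstar) / (np.abs(dstar) + 1e-12)))
            gstar, dstar = g_new, d_new
            if change < tol:
                break
        adjusted[:, cols] = (zb - gstar[:, None]) / np.sqrt(dstar)[:, None]
    out = adjusted * sigma[:, None] + grand[:, None]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _inv_order(idx: dict, n: int) -> np.ndarray:
    """Column permutation mapping batch-blocked order back to original order."""
    blocked = np.concatenate([idx[b] for b in idx])
    inv = np.empty(n, dtype=int)
    inv[blocked] = np.arange(n)
    return inv


def combat_adjust(expr: ExpressionDataset | pd.DataFrame,
                  batch: pd.Series | None = None, batch_col: str = "batch"):
    """Empirical-Bayes batch adjustment; accepts a dataset or a bare DataFrame."""
    if isinstance(expr, ExpressionDataset):
        b = batch if batch is not None else expr.metadata[batch_col]
        adj = _combat_frame(expr.values, b)
        return expr.with_values(adj)
    if batch is None:
        raise ValueError("batch labels required")
    return _combat_frame(expr, batch)


# -- mixed-model association ---------------------------------------------------

def _whiten_blocks(subject_codes: np.ndarray, rho: float) -> tuple[np.ndarray, float]:
    """Per-sample whitening weights for compound symmetry; returns (W, logdet V).

    V is block diagonal with blocks (1-rho) I + rho J.  Whitening is applied
    analytically per block: the within-block mean direction is scaled by
    1/sqrt(1 + (s-1) rho) and the orthogonal complement by 1/sqrt(1 - rho).
    Returns a dense whitening matrix (n x n, block diagonal).
    """
    n = subject_codes.shape[0]
    w = np.zeros((n, n))
    logdet = 0.0
    for s in np.unique(subject_codes):
        rows = np.where(subject_codes == s)[0]
        m = rows.size
        lam1 = 1.0 + (m - 1) * rho
        lam2 = 1.0 - rho
        if lam1 <= 0 or lam2 <= 0:
            raise ValueError("rho outside positive-definite range")
        j = np.full((m, m), 1.0 / m)
        block = j / np.sqrt(lam1) + (np.eye(m) - j) / np.sqrt(lam2)
        w[np.ix_(rows, rows)] = block
        logdet += np.log(lam1) + (m - 1) * np.log(lam2)
    return w, logdet


def _reml_profile(y: np.ndarray, x: np.ndarray, subject_codes: np.ndarray,
                  grid: np.ndarray) -> np.ndarray:
    """REML log-likelihood profile over rho for every response (columns of y)."""
    n, p = x.shape
    out = np.full((grid.size, y.shape[1]), -np.inf)
    for gi, rho in enumerate(grid):
        w, logdet_v = _whiten_blocks(subject_codes, rho)
        xw = w @ x
        yw = w @ y
        q, r = np.linalg.qr(xw)
        resid = yw - q @ (q.T @ yw)
        rss = (resid ** 2).sum(axis=0)
        sign, logdet_xtx = np.linalg.slogdet(r.T @ r)
        if sign <= 0:
            continue
        out[gi] = -0.5 * (logdet_v + logdet_xtx + (n - p) * np.log(np.maximum(rss, 1e-300)))
    return out


def mixed_association(responses: pd.DataFrame, group, subject,
                      covariates: pd.DataFrame | None = None,
                      rho_grid: np.ndarray | None = None) -> AssociationResult:
    """Two-level group association with a per-subject exchangeable correlation.

    ``responses``: response-by-sample matrix.  ``group``: two-level factor per
    sample (the second sorted level is coded 1).  ``subject``: subject id per
    sample.  Returns estimates, SEs, t, p and BH q-values per response plus
    the consensus within-subject correlation rho.
    """
    y = responses.to_numpy(dtype=float).T                     # samples x responses
    n = y.shape[0]
    group = np.asarray(group)
    subj = np.asarray(subject)
    if len(np.unique(subj)) < 2:
        raise ValueError("all samples from one subject")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels.size}")
    gcode = (group == levels[1]).astype(float)
    cols = [np.ones(n), gcode]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype.kind in "OUSb":
                d = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
                cols.extend(d[cc].to_numpy() for cc in d)
            else:
                cols.append(col.to_numpy(dtype=float))
    x = np.column_stack(cols)
    p = x.shape[1]
    _, counts = np.unique(subj, return_counts=True)
    max_block = counts.max()

    if max_block == 1:
        rho = 0.0
    else:
        lo = max(-1.0 / (max_block - 1) + 0.02, -0.5)
        grid = rho_grid if rho_grid is not None else np.arange(lo, 0.96, 0.01)
        codes = pd.factorize(subj)[0]
        prof = _reml_profile(y, x, codes, grid)
        best = grid[np.argmax(prof, axis=0)]
        finite = np.isfinite(prof).any(axis=0)
        if not finite.any():
            raise ValueError("REML profile failed for every response")
        if (~finite).any():
            log.warning("rho estimation failed for %d responses; excluded from consensus",
                        int((~finite).sum()))
        rho = float(np.tanh(np.mean(np.arctanh(np.clip(best[finite], -0.999, 0.999)))))

    codes = pd.factorize(subj)[0]
    w, _ = _whiten_blocks(codes, rho)
    xw, yw = w @ x, w @ y
    xtx_inv = np.linalg.inv(xw.T @ xw)
    beta = xtx_inv @ xw.T @ yw                                # p x responses
    resid = yw - xw @ beta
    df_resid = n - p
    s2 = (resid ** 2).sum(axis=0) / df_resid
    se = np.sqrt(xtx_inv[1, 1] * s2)
    est = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df_resid)
    q = bh_fdr(pvals)
    table = pd.DataFrame({"estimate": est, "se": se, "tstat": t,
                          "pvalue": pvals, "qvalue": q}, index=responses.index)
    return AssociationResult(table, rho,
                             group_coding=f"{levels[1]} vs {levels[0]} (reference)")


# -- small inference utilities -------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _log_table_prob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    return float(lr.sum() + lc.sum() - ln - sum(lgamma(v + 1) for v in table.ravel()))


def fisher_tests(contingency, seed: int = 0, mc_draws: int = 100_000,
                 max_total_exact: int = 500, max_tables: int = 2_000_000) -> float:
    """Two-sided exact test of independence for an r×c count table.

    2×2 tables use the hypergeometric exact test; larger tables are
    enumerated exactly over all tables with the observed margins when the
    total is at most ``max_total_exact``, otherwise estimated by Monte Carlo
    over Patefield-sampled tables (fixed seed, reported via log).
    Degenerate margins give p = 1.
    """
    t = np.asarray(contingency, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        log.info("degenerate margin: p = 1")
        return 1.0
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    n = int(t.sum())
    lr = np.array([lgamma(v + 1) for v in rows])
    lc = np.array([lgamma(v + 1) for v in cols])
    ln = lgamma(n + 1)
    logp_obs = _log_table_prob(t, lr, lc, ln)
    if n <= max_total_exact:
        r, c = t.shape

        def row_fills(rem: int, col_rem: tuple[int, ...]):
            """All ways to fill one row summing to rem within column budgets."""
            if len(col_rem) == 1:
                if rem <= col_rem[0]:
                    yield (rem,)
                return
            for v in range(min(rem, col_rem[0]) + 1):
                for rest in row_fills(rem - v, col_rem[1:]):
                    yield (v, *rest)

        def tables(row_idx: int, col_rem: tuple[int, ...]):
            if row_idx == r - 1:
                yield (col_rem,)
                return
            for fill in row_fills(int(rows[row_idx]), col_rem):
                rest_cols = tuple(cr - f for cr, f in zip(col_rem, fill))
                for rest in tables(row_idx + 1, rest_cols):
                    yield (fill, *rest)

        total, count = 0.0, 0
        overflow = False
        for tab in tables(0, tuple(int(v) for v in cols)):
            count += 1
            if count > max_tables:
                overflow = True
                break
            lp = _log_table_prob(np.array(tab), lr, lc, ln)
            if lp <= logp_obs + 1e-7:
                total += np.exp(lp)
        if not overflow:
            return float(min(total, 1.0))
        log.warning("exact enumeration too large; falling back to Monte Carlo")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(rows, cols)
    sims = dist.rvs(mc_draws, random_state=rng)
    lps = np.array([_log_table_prob(s.astype(np.int64), lr, lc, ln) for s in sims])
    hits = int((lps <= logp_obs + 1e-7).sum())
    log.info("Monte-Carlo Fisher: %d draws, seed %d", mc_draws, seed)
    return float((hits + 1) / (mc_draws + 1))


def enrichment(module_genes: list[str], pathway_sets: dict[str, list[str]],
               universe: list[str]) -> pd.DataFrame:
    """One-sided Fisher enrichment of a gene module against pathway sets."""
    uni = set(universe)
    mod = set(module_genes)
    if not mod <= uni:
        raise ValueError("module genes must be a subset of the universe")
    n = len(uni)
    m = len(mod)
    rows = []
    for name, genes in pathway_sets.items():
        path = set(genes) & uni
        if not path:
            log.info("pathway %s has no genes in the universe; skipped", name)
            continue
        k = len(mod & path)
        kk = len(path)
        pval = float(sps.hypergeom.sf(k - 1, n, kk, m))
        a, b = k, m - k
        c, d = kk - k, n - kk - (m - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"pathway": name, "overlap": k, "pathway_size": kk,
                     "odds_ratio": odds, "pvalue": pval})
    df = pd.DataFrame(rows).set_index("pathway") if rows else \
        pd.DataFrame(columns=["overlap", "pathway_size", "odds_ratio", "pvalue"])
    if len(df):
        df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    return df
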