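"""Count normalization, gene filtering, sample QC, sex check, residualization.

Normalization follows the trimmed mean of M-values (TMM) procedure: the
reference sample is the one whose upper-quartile CPM is closest to the mean
upper quartile; each sample's factor is the inverse-variance-weighted mean of
gene-wise log ratios (M-values) after trimming the 30% most extreme M-values
and 5% most extreme average abundances (A-values); factors are rescaled to
geometric mean 1, and log2 counts per million are computed against effective
library sizes with a prior count of 2.

Sample QC evaluates three criteria — mean inter-sample correlation, the first
two expression principal components, and the transcript integrity number
(TIN) — and excludes a sample only when more than one criterion is more than
2 standard deviations from the mean.  z-scores are computed once on the full
candidate set (single pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset


@dataclass
class TmmResult:
    """TMM normalization factors and the trim inputs behind them."""

    factors: pd.Series                 # per-sample, geometric mean 1
    reference_sample: str
    m_values: dict[str, pd.Series] = field(default_factory=dict)
    a_values: dict[str, pd.Series] = field(default_factory=dict)


@dataclass
class QcReport:
    """Per-sample QC metrics, z-scores, failed criteria and exclusion flags."""

    table: pd.DataFrame                # metrics + z-scores per sample
    criteria_failed: dict[str, list[str]]
    excluded: pd.Series                # bool per sample
    warnings: list[str] = field(default_factory=list)

    def kept_samples(self) -> list[str]:
        return list(self.excluded.index[~self.excluded])


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     logratio_trim: float = 0.3, sum_trim: float = 0.05
                     ) -> tuple[float, pd.Series, pd.Series]:
    """TMM factor of one library against the reference (log2 scale internally)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs_k, ref_k = obs[keep], ref[keep]
    with np.errstate(divide="ignore"):
        m = np.log2((obs_k / n_obs) / (ref_k / n_ref))
        a = 0.5 * np.log2((obs_k / n_obs) * (ref_k / n_ref))
    # inverse asymptotic variance of M
    w = (n_obs - obs_k) / (n_obs * obs_k) + (n_ref - ref_k) / (n_ref * ref_k)
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0, pd.Series(m), pd.Series(a)
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0, pd.Series(m), pd.Series(a)
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f), pd.Series(m), pd.Series(a)


def tmm_normalize(counts: ExpressionDataset, prior_count: float = 2.0
                  ) -> tuple[TmmResult, ExpressionDataset]:
    """TMM normalization factors and log2-CPM values.

    Returns the :class:`TmmResult` and a new dataset on the ``log2cpm``
    scale using effective library sizes (library x factor) and the given
    prior count (scaled per library, so depth-identical libraries get
    identical prior-adjusted values).
    """
    if counts.scale != "counts":
        raise ValueError("tmm_normalize expects a counts-scale dataset")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.matrix()
    if (arr < 0).any():
        raise ValueError("negative counts")
    libs = arr.sum(axis=0)
    zero = np.where(libs == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[counts.sample_ids[i] for i in zero]}")
    if counts.n_genes == 1:
        warnings.warn("single gene: TMM factors set to 1")
        factors = pd.Series(1.0, index=counts.sample_ids)
        ref = counts.sample_ids[0]
        mres = TmmResult(factors, ref)
    else:
        cpm = arr / libs[None, :] * 1e6
        q75 = np.quantile(cpm, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
        ref = counts.sample_ids[ref_idx]
        raw = np.empty(counts.n_samples)
        m_values, a_values = {}, {}
        for j, sid in enumerate(counts.sample_ids):
            fj, mj, aj = _tmm_pair_factor(arr[:, j], arr[:, ref_idx])
            raw[j] = fj
            m_values[sid] = mj
            a_values[sid] = aj
        raw /= np.exp(np.mean(np.log(raw)))
        factors = pd.Series(raw, index=counts.sample_ids)
        mres = TmmResult(factors, ref, m_values, a_values)
    eff_lib = libs * mres.factors.to_numpy()
    pc = prior_count * eff_lib / eff_lib.mean()
    log2cpm = np.log2((arr + pc[None, :]) / (eff_lib + 2 * pc)[None, :] * 1e6)
    values = pd.DataFrame(log2cpm, index=counts.values.index, columns=counts.values.columns)
    return mres, counts.with_values(values, scale="log2cpm")


def filter_genes(expr: ExpressionDataset) -> ExpressionDataset:
    """Drop genes with zero interquartile range or row sum <= 1 (order preserved)."""
    arr = expr.matrix()
    iqr = np.quantile(arr, 0.75, axis=1) - np.quantile(arr, 0.25, axis=1)
    keep = (iqr > 0) & (arr.sum(axis=1) > 1)
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return expr.with_values(expr.values.loc[keep])


def qc_outlier_filter(expr: ExpressionDataset) -> QcReport:
    """Multi-criterion sample outlier report; excluded iff >1 criterion fails."""
    arr = expr.matrix()
    n = expr.n_samples
    warns: list[str] = []

    corr = np.corrcoef(arr.T)
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)

    centered = (arr - arr.mean(axis=1, keepdims=True)).T       # samples x genes
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pcs = centered @ vt[:2].T                                   # sample scores

    table = pd.DataFrame({
        "mean_correlation": mean_corr,
        "pc1": pcs[:, 0],
        "pc2": pcs[:, 1],
    }, index=expr.sample_ids)
    have_tin = "tin" in expr.metadata.columns and expr.metadata["tin"].notna().all()
    if have_tin:
        table["tin"] = expr.metadata["tin"].to_numpy(dtype=float)
    else:
        warns.append("TIN missing: criterion skipped")

    def z(col: np.ndarray) -> np.ndarray:
        sd = col.std(ddof=1)
        return np.zeros_like(col) if sd == 0 else (col - col.mean()) / sd

    for c in [c for c in ("mean_correlation", "pc1", "pc2", "tin") if c in table]:
        table[f"z_{c}"] = z(table[c].to_numpy())

    criteria_failed: dict[str, list[str]] = {}
    fails = pd.DataFrame(index=table.index)
    fails["correlation"] = np.abs(table["z_mean_correlation"]) > 2
    fails["principal_components"] = (np.abs(table["z_pc1"]) > 2) | (np.abs(table["z_pc2"]) > 2)
    if have_tin:
        fails["tin"] = np.abs(table["z_tin"]) > 2
    for sid in table.index:
        criteria_failed[sid] = [c for c in fails.columns if fails.loc[sid, c]]
    excluded = fails.sum(axis=1) > 1
    table["n_criteria_failed"] = fails.sum(axis=1)
    table["excluded"] = excluded
    return QcReport(table, criteria_failed, excluded, warns)


def sex_check(expr: ExpressionDataset, y_genes: list[str]) -> pd.Series:
    """Flag samples whose annotated sex disagrees with Y-chromosome expression.

    Predicted sex is a two-group split (exact 1-D 2-means) of mean Y-gene
    expression; the higher group is called male.  Returns a boolean Series
    (True = mismatch); all-NA with a warning when no Y genes are present.
    """
    present = [g for g in y_genes if g in expr.values.index]
    if "sex" not in expr.metadata.columns:
        raise ValueError("metadata lacks annotated sex")
    if not present:
        warnings.warn("no Y genes present: sex undetermined")
        return pd.Series(pd.NA, index=expr.sample_ids, dtype="boolean")
    score = expr.values.loc[present].mean(axis=0).to_numpy()
    order = np.argsort(score, kind="stable")
    s = score[order]
    n = len(s)
    # exact 1-D 2-means: scan all split points, minimize within-cluster SS
    best_cut, best_ss = 1, np.inf
    csum = np.concatenate([[0.0], np.cumsum(s)])
    csq = np.concatenate([[0.0], np.cumsum(s ** 2)])
    for cut in range(1, n):
        ss_lo = csq[cut] - csum[cut] ** 2 / cut
        ss_hi = (csq[n] - csq[cut]) - (csum[n] - csum[cut]) ** 2 / (n - cut)
        if ss_lo + ss_hi < best_ss - 1e-12:
            best_ss, best_cut = ss_lo + ss_hi, cut
    predicted = np.empty(n, dtype=object)
    predicted[order[:best_cut]] = "female"
    predicted[order[best_cut:]] = "male"
    annotated = expr.metadata["sex"].to_numpy()
    return pd.Series(predicted != annotated, index=expr.sample_ids)


def residualize(expr: ExpressionDataset, covariates: list[str]) -> ExpressionDataset:
    """Per-gene OLS residuals on intercept + the named metadata covariates.

    Categorical covariates (object/category dtype) are one-hot encoded with
    the first level dropped.  Raises on missing values or a rank-deficient
    design, naming the collinear columns.
    """
    md = expr.metadata[covariates]
    if md.isna().any().any():
        bad = md.columns[md.isna().any()].tolist()
        raise ValueError(f"covariates with missing values: {bad}")
    cols = [pd.Series(1.0, index=md.index, name="intercept")]
    for c in covariates:
        col = md[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True, dtype=float)
            cols.extend(dummies[c2] for c2 in dummies)
        else:
            cols.append(col.astype(float))
    design = pd.concat(cols, axis=1)
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        dep = design.columns[np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()].tolist()
        raise ValueError(f"rank-deficient design; collinear columns: {dep}")
    y = expr.matrix().T                                # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T
    values = pd.DataFrame(resid, index=expr.values.index, columns=expr.values.columns)
    return expr.with_values(values, scale="residual")
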