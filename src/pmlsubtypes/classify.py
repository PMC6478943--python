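"""Nearest-centroid subtype classifier and the brush presence classifier.

Marker selection: per module, genes are retained when their squared Pearson
correlation (r^2) to their own module's eigengene exceeds that to every other
module's eigengene; the number of panel genes drawn from each module is
inversely proportional to the module's mean retained r^2 (largest-remainder
rounding, at least one gene per represented module), and the top-r^2 genes
of each module fill its allocation.  The default panel holds 22 genes.

Classification is an unshrunken nearest-centroid rule on z-scored marker
expression: class score

    delta_c(x) = sum_g (x_g - centroid_cg)^2 / s_g^2  -  2 log prior_c

with pooled within-class standard deviations s_g; the predicted class
minimizes delta.  Before prediction, training and test cohorts are combined,
batch-adjusted (cohort as batch, empirical-Bayes location/scale), and
z-scored per gene across the combined set.

The presence classifier is the same machinery restricted to the panel genes
of modules 4-7, collapsed to Proliferative vs not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, zscore_genes
from .network import GeneModule
from .stats import combat_adjust

log = logging.getLogger(__name__)


@dataclass
class MarkerAllocation:
    """Marker panel with per-module provenance and allocation arithmetic."""

    retained: dict[str, pd.Series]       # module -> r^2 of retained genes
    mean_r2: dict[str, float]
    n_alloc: dict[str, int]
    panel: list[str]
    panel_module: dict[str, str]         # gene -> module


@dataclass
class CentroidModel:
    """Serialized nearest-centroid classifier."""

    panel: list[str]
    class_centroids: pd.DataFrame        # class x gene, z-scale
    pooled_sd: pd.Series                 # per gene
    priors: pd.Series                    # per class, sums to 1
    normalization: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "panel": self.panel,
            "class_centroids": self.class_centroids.to_dict(orient="split"),
            "pooled_sd": self.pooled_sd.to_dict(),
            "priors": self.priors.to_dict(),
            "normalization": self.normalization,
        }


def _largest_remainder(weights: np.ndarray, total: int, floor_one: bool) -> np.ndarray:
    """Integer allocation proportional to weights summing exactly to total."""
    share = weights / weights.sum() * total
    alloc = np.floor(share).astype(int)
    if floor_one:
        alloc = np.maximum(alloc, 1)
    # adjust to the exact total: add by largest remainder, remove by smallest
    rem = share - np.floor(share)
    while alloc.sum() < total:
        order = np.argsort(-rem, kind="stable")
        for i in order:
            if alloc.sum() == total:
                break
            alloc[i] += 1
            rem[i] = -1
    while alloc.sum() > total:
        order = np.argsort(rem, kind="stable")
        for i in order:
            if alloc.sum() == total:
                break
            if not floor_one or alloc[i] > 1:
                alloc[i] -= 1
                rem[i] = 2
    return alloc


def allocate_genes_per_module(expr: ExpressionDataset, modules: list[GeneModule],
                              panel_size: int = 22) -> MarkerAllocation:
    """Select the marker panel by inverse-proportional module allocation."""
    eigs = {m.label: m.eigengene.loc[expr.sample_ids].to_numpy() for m in modules}
    retained: dict[str, pd.Series] = {}
    for m in modules:
        rows = expr.values.loc[m.genes].to_numpy()
        r2 = {}
        for lbl, e in eigs.items():
            with np.errstate(invalid="ignore"):
                c = _rowwise_corr(rows, e)
            r2[lbl] = c ** 2
        own = r2[m.label]
        best_is_own = np.ones(len(m.genes), dtype=bool)
        for lbl, v in r2.items():
            if lbl != m.label:
                best_is_own &= own >= v
        kept = pd.Series(own[best_is_own], index=np.array(m.genes)[best_is_own])
        if kept.empty:
            warnings.warn(f"module {m.label}: no retained genes; allocated 0")
        retained[m.label] = kept.sort_values(ascending=False)

    active = [lbl for lbl, s in retained.items() if not s.empty]
    if panel_size < len(active):
        raise ValueError(f"panel_size {panel_size} < {len(active)} modules with retained genes")
    mean_r2 = {lbl: float(retained[lbl].mean()) for lbl in active}
    weights = np.array([1.0 / mean_r2[lbl] for lbl in active])
    alloc = _largest_remainder(weights, panel_size, floor_one=True)
    # a module cannot contribute more genes than it retained
    caps = np.array([len(retained[lbl]) for lbl in active])
    over = alloc > caps
    while over.any():
        excess = int((alloc - np.minimum(alloc, caps)).sum())
        alloc = np.minimum(alloc, caps)
        room = caps - alloc
        order = np.argsort(-weights, kind="stable")
        for i in order:
            take = min(excess, room[i])
            alloc[i] += take
            excess -= take
            if excess == 0:
                break
        over = alloc > caps
    n_alloc = {lbl: int(a) for lbl, a in zip(active, alloc)}
    panel, panel_module = [], {}
    for lbl in active:
        for g in retained[lbl].index[:n_alloc[lbl]]:
            panel.append(g)
            panel_module[g] = lbl
    return MarkerAllocation(retained, mean_r2, n_alloc, panel, panel_module)


def _rowwise_corr(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    denom[denom == 0] = np.inf
    return rc @ vc / denom


def train_nearest_centroid(expr: ExpressionDataset, labels: pd.Series,
                           panel: list[str], sd_floor: float = 1e-6) -> CentroidModel:
    """Train the unshrunken (threshold-0) nearest-centroid model on z-scored markers."""
    labels = labels.loc[expr.sample_ids]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    z = zscore_genes(expr.values.loc[panel])
    centroids = {}
    ss = np.zeros(len(panel))
    n = z.shape[1]
    for c in classes:
        cols = labels.index[labels == c]
        block = z[cols].to_numpy()
        centroids[c] = block.mean(axis=1)
        ss += ((block - centroids[c][:, None]) ** 2).sum(axis=1)
    pooled = np.sqrt(ss / (n - len(classes)))
    if (pooled < sd_floor).any():
        warnings.warn("pooled SD floored for some panel genes")
        pooled = np.maximum(pooled, sd_floor)
    centroid_df = pd.DataFrame(centroids, index=panel).T
    priors = (counts.loc[classes] / n).astype(float)
    return CentroidModel(panel=list(panel), class_centroids=centroid_df,
                         pooled_sd=pd.Series(pooled, index=panel),
                         priors=priors,
                         normalization={"zscore": "per gene across training set",
                                        "shrinkage_threshold": 0.0})


def _discriminant(z: pd.DataFrame, model: CentroidModel) -> pd.DataFrame:
    """delta_c(x) per sample (columns of z) and class; lower is better."""
    x = z.loc[model.panel].to_numpy()
    sd = model.pooled_sd.to_numpy()[:, None]
    out = {}
    for c in model.class_centroids.index:
        mu = model.class_centroids.loc[c].to_numpy()[:, None]
        out[c] = (((x - mu) / sd) ** 2).sum(axis=0) - 2.0 * np.log(model.priors[c])
    return pd.DataFrame(out, index=z.columns)


def classify(z: pd.DataFrame, model: CentroidModel) -> tuple[pd.Series, pd.DataFrame]:
    scores = _discriminant(z, model)
    arr = scores.to_numpy()
    best = arr.argmin(axis=1)
    ties = (arr == arr.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.warning("%d tied classifications broken by class order", int(ties.sum()))
    labels = pd.Series(scores.columns[best], index=scores.index, name="predicted")
    return labels, scores


def predict_subtype(model: CentroidModel, test: ExpressionDataset,
                    train: ExpressionDataset, batch_col: str = "cohort"
                    ) -> tuple[pd.Series, pd.DataFrame]:
    """Predict classes for test samples after joint batch adjustment.

    The combined train+test panel matrix is batch-adjusted with the cohort
    label as batch, then z-scored per gene across the combined set; the
    model's discriminant is evaluated on the test columns.
    """
    missing = [g for g in model.panel if g not in test.values.index]
    if missing:
        raise KeyError(f"panel genes missing from test set: {missing}")
    tr = train.values.loc[model.panel].copy()
    te = test.values.loc[model.panel].copy()
    # keep columns unique even when test is the training set (resubstitution)
    tr.columns = [f"train::{c}" for c in tr.columns]
    te.columns = [f"test::{c}" for c in te.columns]
    combined = pd.concat([tr, te], axis=1)
    batches = pd.Series(
        list(train.metadata[batch_col]) + list(test.metadata[batch_col]),
        index=combined.columns)
    if batches.nunique() > 1:
        adjusted = combat_adjust(combined, batches)
    else:
        adjusted = combined
    z = zscore_genes(adjusted)
    labels, scores = classify(z[te.columns], model)
    labels.index = test.sample_ids
    scores.index = test.sample_ids
    return labels, scores


def train_presence_classifier(expr: ExpressionDataset, labels: pd.Series,
                              allocation: MarkerAllocation,
                              positive_class: str = "Proliferative",
                              module_subset: list[str] | None = None) -> CentroidModel:
    """Two-class (positive vs not) model on the sub-panel of the given modules."""
    if module_subset is None:
        module_subset = sorted({allocation.panel_module[g] for g in allocation.panel})
    sub_panel = [g for g in allocation.panel if allocation.panel_module[g] in module_subset]
    if not sub_panel:
        raise ValueError("sub-panel is empty for the requested modules")
    binary = labels.loc[expr.sample_ids].map(
        lambda v: positive_class if v == positive_class else f"not {positive_class}")
    model = train_nearest_centroid(expr, pd.Series(binary, index=expr.sample_ids), sub_panel)
    model.normalization["presence_modules"] = list(module_subset)
    model.normalization["positive_class"] = positive_class
    return model


def evaluate_brush_prediction(brush_predictions: pd.Series, brush_meta: pd.DataFrame,
                              biopsy_subtypes: pd.Series, biopsy_meta: pd.DataFrame,
                              positive_class: str = "Proliferative") -> dict:
    """Sensitivity/specificity of brush calls against matched-biopsy truth.

    A brush's ground truth is positive iff at least one biopsy from the same
    subject and timepoint is of the positive class.  Brushes with no matched
    biopsy are excluded and counted.
    """
    biopsy_keys = {}
    for sid, subtype in biopsy_subtypes.items():
        key = (biopsy_meta.loc[sid, "subject"], biopsy_meta.loc[sid, "timepoint"])
        biopsy_keys.setdefault(key, []).append(subtype)
    tp = fp = tn = fn = excluded = 0
    for sid, pred in brush_predictions.items():
        key = (brush_meta.loc[sid, "subject"], brush_meta.loc[sid, "timepoint"])
        if key not in biopsy_keys:
            excluded += 1
            continue
        truth_pos = positive_class in biopsy_keys[key]
        pred_pos = pred == positive_class
        if truth_pos and pred_pos:
            tp += 1
        elif truth_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {"sensitivity": sens, "specificity": spec,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp, "excluded": excluded}
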