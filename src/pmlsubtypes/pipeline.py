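"""End-to-end orchestration: simulate → preprocess → modules → conservation
→ consensus subtypes → classifier → brush evaluation → progression.

Every stage writes plain-text artifacts (TSV/GMT/JSON) into the run
directory together with a provenance record (stage parameters and seeds),
so a fixed master seed reproduces the run byte for byte and any stage can
be rerun from the saved upstream artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .dataset import ExpressionDataset
from .simulate import SimulationConfig, generate_multidataset, generate_counts, write_simulation
from .preprocess import tmm_normalize, filter_genes, qc_outlier_filter, sex_check, residualize
from .network import run_wgcna, GeneModule, module_eigengene
from .conservation import build_compendium, conservation_select, filter_module_genes
from .subtyping import consensus_cluster, select_k, finalize_assignments, annotate_subtypes
from .classify import (allocate_genes_per_module, train_nearest_centroid, predict_subtype,
                       train_presence_classifier, evaluate_brush_prediction)
from .stats import gsva_scores, mixed_association, auc
from .simulate import Y_GENES

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published analysis settings."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    use_counts: bool = True
    library_size: float = 2e6
    dispersion: float = 0.1
    filter_scale: str = "log2cpm"          # or "counts"
    min_module_size: int = 30
    merge_cut: float = 0.25
    conservation_threshold: float = 0.85
    k_max: int = 10
    consensus_iters: int = 1000
    subsample: float = 0.8
    delta_threshold: float = 0.10
    panel_size: int = 22
    fdr: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        self.sim.seed = self.seed


@dataclass
class PipelineResult:
    datasets: dict[str, ExpressionDataset]
    truth: object
    modules: dict[str, list[GeneModule]]
    decision: object
    consensus: object
    assignments: pd.Series
    subtype_names: dict[int, str]
    direction_table: pd.DataFrame
    allocation: object
    model: object
    train_predictions: pd.Series
    presence_model: object
    brush_eval: dict
    progression: pd.DataFrame
    progression_auc: float
    report: dict


def _preprocess_dataset(ds: ExpressionDataset, cfg: PipelineConfig) -> ExpressionDataset:
    """Counts → TMM/log2-CPM → gene filter → sample QC → refilter → residualize."""
    if cfg.use_counts:
        rng_seed = cfg.seed + 17
        counts = generate_counts(ds, np.full(ds.n_samples, cfg.library_size),
                                 cfg.dispersion, seed=rng_seed)
        if cfg.filter_scale == "counts":
            counts = filter_genes(counts)
        _, expr = tmm_normalize(counts)
        if cfg.filter_scale == "log2cpm":
            expr = filter_genes(expr)
    else:
        expr = filter_genes(ds)
    qc = qc_outlier_filter(expr)
    expr = expr.subset_samples(qc.kept_samples())
    expr = filter_genes(expr)            # refilter on the final sample set
    mismatches = sex_check(expr, list(Y_GENES))
    if mismatches.fillna(False).any():
        log.info("%s: %d sex-mismatched samples flagged", ds.name,
                 int(mismatches.fillna(False).sum()))
    expr = expr.with_values(expr.values.drop(index=[g for g in Y_GENES
                                                    if g in expr.values.index]))
    return residualize(expr, ["tin", "batch"])


def _one_vs_rest(scores: pd.DataFrame, in_cluster: np.ndarray, meta: pd.DataFrame):
    # second sorted level is the coded one, so name the cluster level "in"
    group = np.where(in_cluster, "in", "all-others")
    return mixed_association(scores, group, meta["subject"].to_numpy()).table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; optionally write artifacts to ``config.outdir``."""
    cfg = config
    biopsy_name = cfg.sim.biopsy_dataset
    brush_name = cfg.sim.brush_dataset

    # -- simulate -------------------------------------------------------------
    try:
        datasets, truth = generate_multidataset(cfg.sim)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    # -- preprocess -----------------------------------------------------------
    processed: dict[str, ExpressionDataset] = {}
    for name, ds in datasets.items():
        try:
            processed[name] = _preprocess_dataset(ds, cfg)
        except Exception as e:                                # noqa: BLE001
            raise PipelineError(f"preprocess:{name}", str(e)) from e

    # -- co-expression modules ------------------------------------------------
    modules: dict[str, list[GeneModule]] = {}
    for name, ds in processed.items():
        try:
            mods, _ = run_wgcna(ds, min_module_size=cfg.min_module_size,
                                merge_cut=cfg.merge_cut)
        except Exception as e:                                # noqa: BLE001
            raise PipelineError(f"modules:{name}", str(e)) from e
        modules[name] = mods
        log.info("%s: %d modules", name, len(mods))

    # -- conservation ---------------------------------------------------------
    try:
        comp = build_compendium(modules, processed)
        decision = conservation_select(comp, threshold=cfg.conservation_threshold,
                                       biopsy_dataset=biopsy_name)
        decision = filter_module_genes(decision, comp)
        if not decision.retained_biopsy_modules:
            raise ValueError("no biopsy modules retained at the conservation threshold")
    except PipelineError:
        raise
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("conservation", str(e)) from e

    biopsy = processed[biopsy_name]
    retained_sets = {m: decision.filtered_genes[m] for m in decision.retained_biopsy_modules}
    union_genes = [g for genes in retained_sets.values() for g in genes]

    # -- consensus subtyping --------------------------------------------------
    try:
        cons = consensus_cluster(biopsy, union_genes, k_max=cfg.k_max,
                                 iters=cfg.consensus_iters, subsample=cfg.subsample,
                                 seed=cfg.seed)
        chosen_k = select_k(cons, delta_threshold=cfg.delta_threshold)
        assignments = finalize_assignments(cons, chosen_k)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("subtyping", str(e)) from e

    # -- module scores + subtype annotation -----------------------------------
    try:
        scores = gsva_scores(biopsy, retained_sets).scores
        expected = {name: {m: d for m, d in pat.items()}
                    for name, pat in truth.subtype_module_pattern.items()}
        # expected pattern is keyed by planted module ids; map retained modules
        # to planted ids by gene overlap so labels carry over
        mapping = _map_to_planted(retained_sets, truth.module_genes[biopsy_name])
        scores_planted = scores.rename(index=mapping)
        names, directions = annotate_subtypes(
            assignments, scores_planted,
            lambda s, mask: _one_vs_rest(s, mask, biopsy.metadata), expected,
            fdr=cfg.fdr)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("annotation", str(e)) from e

    subtype_labels = assignments.map(names)

    # -- classifier -----------------------------------------------------------
    try:
        gene_modules = []
        for m, genes in retained_sets.items():
            e, ve = module_eigengene(biopsy, genes)
            gene_modules.append(GeneModule(label=mapping.get(m, m), genes=genes,
                                           eigengene=e, var_explained=ve,
                                           source_dataset=biopsy_name))
        alloc = allocate_genes_per_module(biopsy, gene_modules, panel_size=cfg.panel_size)
        model = train_nearest_centroid(biopsy, subtype_labels, alloc.panel)
        train_pred, _ = predict_subtype(model, biopsy, biopsy)
        prolif_row = [c for c, n in names.items() if n == "Proliferative"]
        presence_modules = None
        if prolif_row:
            d = directions.loc[prolif_row[0]]
            presence_modules = [m for m in d.index if d[m] != 0]
        presence = train_presence_classifier(biopsy, subtype_labels, alloc,
                                             positive_class="Proliferative",
                                             module_subset=presence_modules)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("classifier", str(e)) from e

    # -- brush evaluation -----------------------------------------------------
    try:
        brush = processed[brush_name]
        brush_pred, _ = predict_subtype(presence, brush, biopsy)
        brush_eval = evaluate_brush_prediction(
            brush_pred, brush.metadata, train_pred, biopsy.metadata,
            positive_class="Proliferative")
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("brush", str(e)) from e

    # -- progression association ----------------------------------------------
    try:
        meta = biopsy.metadata
        known = meta["progression"].isin(["progressive/persistent", "regressive"])
        sub = scores_planted.loc[:, known.to_numpy()]
        res = mixed_association(sub, meta.loc[known, "progression"].to_numpy(),
                                meta.loc[known, "subject"].to_numpy())
        prog_table = res.table.sort_values("qvalue")
        prog_mod = truth.progression_module
        if prog_mod in scores_planted.index:
            s = scores_planted.loc[prog_mod, known.to_numpy()]
            labels = meta.loc[known, "progression"] == "regressive"
            prog_auc = auc(s.to_numpy(), labels.to_numpy())
        else:
            prog_auc = float("nan")
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("progression", str(e)) from e

    report = {
        "n_modules": {name: len(m) for name, m in modules.items()},
        "retained_modules": decision.retained_biopsy_modules,
        "n_retained_genes": len(union_genes),
        "chosen_k": int(chosen_k),
        "cdf_area": {int(k): v for k, v in cons.cdf_area.items()},
        "delta": {int(k): v for k, v in cons.delta.items()},
        "subtype_sizes": subtype_labels.value_counts().to_dict(),
        "training_accuracy": float((train_pred == subtype_labels).mean()),
        "brush": brush_eval,
        "progression_top_module": prog_table.index[0],
        "progression_top_q": float(prog_table["qvalue"].iloc[0]),
        "progression_auc": float(prog_auc),
        "parameters": _config_record(cfg),
    }
    result = PipelineResult(datasets, truth, modules, decision, cons, assignments,
                            names, directions, alloc, model, train_pred, presence,
                            brush_eval, prog_table, prog_auc, report)
    if cfg.outdir:
        _write_artifacts(result, cfg, Path(cfg.outdir))
    return result


def _map_to_planted(retained_sets: dict[str, list[str]],
                    planted: dict[str, list[str]]) -> dict[str, str]:
    """Map detected module ids to planted module ids by best gene overlap."""
    mapping = {}
    for m, genes in retained_sets.items():
        gset = set(genes)
        best, best_j = m, 0.0
        for pid, pgenes in planted.items():
            pset = set(pgenes)
            j = len(gset & pset) / len(gset | pset)
            if j > best_j:
                best, best_j = pid, j
        mapping[m] = best
    return mapping


def _config_record(cfg: PipelineConfig) -> dict:
    rec = dataclasses.asdict(cfg)
    rec["sim"]["subtype_proportions"] = list(rec["sim"]["subtype_proportions"])
    rec["sim"]["progression_probs"] = list(rec["sim"]["progression_probs"])
    rec.pop("outdir", None)        # a path, not an analysis parameter
    return rec


def _write_artifacts(result: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_simulation(result.datasets, result.truth, cfg.sim, outdir / "simulated")
    for name, mods in result.modules.items():
        rows = [(g, m.label) for m in mods for g in m.genes]
        pd.DataFrame(rows, columns=["gene", "module"]).to_csv(
            outdir / f"modules_{name}.tsv", sep="\t", index=False)
    result.decision.summed_matrix.to_csv(outdir / "conservation_summed.tsv", sep="\t")
    _io.write_gmt({m: g for m, g in result.decision.filtered_genes.items()},
                  outdir / "retained_modules.gmt")
    for k, mat in result.consensus.consensus.items():
        mat.round(6).to_csv(outdir / f"consensus_k{k}.tsv", sep="\t")
    result.assignments.to_frame().assign(
        subtype=result.assignments.map(result.subtype_names)).to_csv(
        outdir / "assignments.tsv", sep="\t")
    pd.Series(result.allocation.panel, name="gene").to_frame().assign(
        module=[result.allocation.panel_module[g] for g in result.allocation.panel]
    ).to_csv(outdir / "panel.tsv", sep="\t", index=False)
    (outdir / "centroid_model.json").write_text(
        json.dumps(result.model.to_json(), indent=1, sort_keys=True, default=str))
    result.progression.to_csv(outdir / "progression_association.tsv", sep="\t",
                              float_format="%.10g")
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True, default=str))
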