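"""Synthetic multi-dataset expression generator with planted structure.

The generator emulates the structure of a premalignant-lesion subtyping
study: four linked datasets (endobronchial biopsies, normal-appearing airway
brushes, a tumor compendium, and a mouse model) that share a set of gene
co-expression modules, with additional modules private to each dataset.
Biopsies carry four molecular subtypes driven by module activity, repeated
biopsies per subject with a shared subject effect, batch and RNA-quality
(TIN) covariates, and a progression label anti-correlated with one module's
latent factor.

The generative model is an additive latent-factor model on the log scale:

    x_gj = mu_g + sum_m L_gm f_mj + beta_TIN * (TIN_j - 75) + batch_j
           + subject_j + eps_gj,     eps ~ Normal(0, noise_sd^2)

where L_gm = loading_strength for genes in module m and 0 otherwise.  With
unit-variance factors the expected within-module gene-gene correlation is
L^2 / (L^2 + noise_sd^2); the defaults (L = 2, noise_sd = 1) plant r = 0.8.

Biopsy subtype labels shift the factor mean of each module up or down
according to a per-subtype direction pattern (default: the four-subtype
pattern over nine shared modules with a Proliferative analogue that is up
in modules 4, 5 and 7 and down in module 6).  One designated module's
factor is lowered in progressive/persistent biopsies, making its activity a
progression biomarker by construction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from . import io as _io


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


#: four-subtype module direction pattern over the nine shared modules
#: (+1 up, -1 down, 0 neutral); the Proliferative analogue is up in
#: modules 4, 5, 7 and down in 6.
DEFAULT_SUBTYPE_PATTERN: dict[str, dict[str, int]] = {
    "Proliferative": {"M4": 1, "M5": 1, "M7": 1, "M6": -1},
    "Inflammatory": {"M1": 1, "M2": 1, "M7": 1, "M8": 1, "M4": -1, "M5": -1, "M6": -1},
    "Secretory": {"M6": 1, "M8": 1, "M1": -1, "M2": -1, "M5": -1, "M7": -1},
    "Normal-like": {"M1": 1, "M6": 1, "M8": -1, "M9": -1},
}

#: observed subtype frequencies used as sampling probabilities
DEFAULT_SUBTYPE_PROPORTIONS = (0.274, 0.195, 0.321, 0.211)

Y_GENES = ("Y1", "Y2", "Y3", "Y4", "Y5", "Y6")


@dataclass
class SimulationConfig:
    """Parameters of the four-dataset factor-model simulation.

    Defaults mirror the study design: sample sizes 190/89/471/25
    (biopsy/brush/tumor/mouse), 29 subjects with 3 procedures each,
    9 shared modules, module loading giving within-module r = 0.8.
    """

    n_genes: int = 1000
    n_samples_per_dataset: dict[str, int] = field(default_factory=lambda: {
        "biopsy": 190, "brush": 89, "tumor": 471, "mouse": 25})
    n_shared_modules: int = 9
    n_private_modules_per_dataset: int = 2
    module_size: int = 40
    loading_strength: float = 2.0
    noise_sd: float = 1.0
    n_subtypes: int = 4
    subtype_shift: float = 2.0
    subtype_pattern: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBTYPE_PATTERN.items()})
    subtype_proportions: tuple[float, ...] = DEFAULT_SUBTYPE_PROPORTIONS
    n_subjects: int = 29
    n_timepoints: int = 3
    subject_effect_sd: float = 0.3
    n_batches: int = 4
    batch_shift_sd: float = 0.3
    tin_effect: float = 0.02
    progression_module_index: int = 9      # 1-based among shared modules
    progression_effect: float = 1.5
    progression_probs: tuple[float, float, float] = (0.23, 0.16, 0.61)  # prog, regr, unknown
    brush_attenuation: float = 0.4
    sex_shift: float = 3.0
    biopsy_dataset: str = "biopsy"
    brush_dataset: str = "brush"
    seed: int = 0

    def validate(self) -> None:
        counts = {"n_genes": self.n_genes, "n_shared_modules": self.n_shared_modules,
                  "module_size": self.module_size, "n_subjects": self.n_subjects,
                  "n_timepoints": self.n_timepoints, "n_batches": self.n_batches,
                  "n_subtypes": self.n_subtypes}
        for k, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{k} must be positive, got {v}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.loading_strength < 0:
            raise ConfigurationError("loading_strength must be >= 0")
        n_datasets = len(self.n_samples_per_dataset)
        needed = self.module_size * (self.n_shared_modules
                                     + self.n_private_modules_per_dataset * n_datasets)
        if needed + len(Y_GENES) > self.n_genes:
            raise ConfigurationError(
                f"module genes ({needed}) plus {len(Y_GENES)} sex-marker genes exceed "
                f"n_genes ({self.n_genes})")
        if not 1 <= self.progression_module_index <= self.n_shared_modules:
            raise ConfigurationError("progression_module_index out of range")
        if self.biopsy_dataset not in self.n_samples_per_dataset:
            raise ConfigurationError(f"biopsy dataset {self.biopsy_dataset!r} missing")
        if len(self.subtype_pattern) < self.n_subtypes:
            raise ConfigurationError("subtype_pattern must cover n_subtypes subtypes")

    @property
    def shared_module_ids(self) -> list[str]:
        return [f"M{i}" for i in range(1, self.n_shared_modules + 1)]

    @property
    def progression_module(self) -> str:
        return f"M{self.progression_module_index}"


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study, for recovery tests."""

    module_membership: dict[str, dict[str, str]]       # dataset -> gene -> module
    shared_module_ids: list[str]
    module_genes: dict[str, dict[str, list[str]]]      # dataset -> module -> genes
    subtype_labels: dict[str, str]                     # biopsy sample -> subtype
    subtype_module_pattern: dict[str, dict[str, int]]
    progression_labels: dict[str, str]                 # biopsy -> label
    factor_scores: dict[str, pd.DataFrame]             # dataset -> module x sample
    progression_module: str = "M9"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "shared_module_ids": self.shared_module_ids,
            "module_genes": self.module_genes,
            "subtype_labels": self.subtype_labels,
            "subtype_module_pattern": self.subtype_module_pattern,
            "progression_labels": self.progression_labels,
            "progression_module": self.progression_module,
            "factor_scores": {d: df.to_dict(orient="split") for d, df in self.factor_scores.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label random substream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def _assign_module_genes(config: SimulationConfig) -> tuple[list[str], dict[str, dict[str, list[str]]]]:
    """Lay out gene ids and per-dataset module gene blocks.

    Shared modules occupy the same gene block in every dataset; each private
    module occupies a block used by exactly one dataset.  The last six genes
    are sex-marker (Y) genes and never belong to a module.
    """
    width = len(str(config.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, config.n_genes - len(Y_GENES) + 1)]
    gene_ids += list(Y_GENES)
    ms = config.module_size
    module_genes: dict[str, dict[str, list[str]]] = {d: {} for d in config.n_samples_per_dataset}
    pos = 0
    shared: dict[str, list[str]] = {}
    for mid in config.shared_module_ids:
        shared[mid] = gene_ids[pos:pos + ms]
        pos += ms
    for d in config.n_samples_per_dataset:
        module_genes[d].update({m: list(g) for m, g in shared.items()})
        for p in range(1, config.n_private_modules_per_dataset + 1):
            module_genes[d][f"{d}_P{p}"] = gene_ids[pos:pos + ms]
            pos += ms
    return gene_ids, module_genes


def _biopsy_design(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Assign biopsies to subjects and procedures, and draw labels."""
    pairs = [(s, t) for s in range(config.n_subjects) for t in range(config.n_timepoints)]
    # every subject-timepoint sampled at least once, remainder spread at random
    reps = [pairs[i % len(pairs)] for i in range(n)] if n >= len(pairs) else \
        [pairs[i] for i in rng.choice(len(pairs), size=n, replace=False)]
    rng.shuffle(reps)
    subjects = np.array([f"S{s + 1:02d}" for s, _ in reps])
    timepoints = np.array([t + 1 for _, t in reps])
    subtype_names = list(config.subtype_pattern)[:config.n_subtypes]
    probs = np.asarray(config.subtype_proportions[:config.n_subtypes], dtype=float)
    probs = probs / probs.sum()
    subtypes = rng.choice(subtype_names, size=n, p=probs)
    prog = rng.choice(["progressive/persistent", "regressive", "unknown"],
                      size=n, p=np.asarray(config.progression_probs))
    return subjects, timepoints, subtypes, prog


def generate_multidataset(config: SimulationConfig) -> tuple[dict[str, ExpressionDataset], SimulationTruth]:
    """Generate the four linked datasets and the ground truth behind them."""
    config.validate()
    gene_ids, module_genes = _assign_module_genes(config)
    root = _substream(config.seed, "root")
    mu = pd.Series(root.normal(6.0, 1.5, size=len(gene_ids)), index=gene_ids)
    subject_sex = {f"S{s + 1:02d}": ("male" if root.random() < 0.5 else "female")
                   for s in range(config.n_subjects)}
    subject_effect = {f"S{s + 1:02d}": root.normal(0.0, config.subject_effect_sd)
                      for s in range(config.n_subjects)}

    biopsy_rng = _substream(config.seed, "design:" + config.biopsy_dataset)
    n_biopsy = config.n_samples_per_dataset[config.biopsy_dataset]
    b_subj, b_tp, b_subtype, b_prog = _biopsy_design(config, n_biopsy, biopsy_rng)
    biopsy_sample_ids = [f"{config.biopsy_dataset}_{i + 1:03d}" for i in range(n_biopsy)]

    datasets: dict[str, ExpressionDataset] = {}
    factor_scores: dict[str, pd.DataFrame] = {}
    membership: dict[str, dict[str, str]] = {}
    subtype_names = list(config.subtype_pattern)[:config.n_subtypes]
    pattern = {s: {m: config.subtype_pattern[s].get(m, 0) for m in config.shared_module_ids}
               for s in subtype_names}

    for dname, n in config.n_samples_per_dataset.items():
        rng = _substream(config.seed, "data:" + dname)
        mods = module_genes[dname]
        mod_ids = list(mods)
        sample_ids = (biopsy_sample_ids if dname == config.biopsy_dataset
                      else [f"{dname}_{i + 1:03d}" for i in range(n)])

        # latent factors (modules x samples)
        f = rng.normal(0.0, 1.0, size=(len(mod_ids), n))
        meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
        meta["tissue"] = dname if dname in (config.biopsy_dataset, config.brush_dataset) else "other"
        meta["cohort"] = dname
        meta["batch"] = [f"B{b + 1}" for b in rng.integers(0, config.n_batches, size=n)]
        meta["tin"] = rng.normal(75.0, 5.0, size=n)

        if dname == config.biopsy_dataset:
            meta["subject"] = b_subj
            meta["timepoint"] = b_tp
            meta["sex"] = [subject_sex[s] for s in b_subj]
            meta["subtype_truth"] = b_subtype
            meta["progression"] = b_prog
            for i, s in enumerate(b_subtype):
                for k, m in enumerate(config.shared_module_ids):
                    f[mod_ids.index(m), i] += config.subtype_shift * pattern[s][m]
            prog_row = mod_ids.index(config.progression_module)
            f[prog_row, b_prog == "progressive/persistent"] -= config.progression_effect
            subj_eff = np.array([subject_effect[s] for s in b_subj])
        elif dname == config.brush_dataset:
            # brushes are sampled at subject procedures; the airway field carries
            # an attenuated echo of the subtypes of the biopsies taken then
            pairs = sorted({(s, t) for s, t in zip(b_subj, b_tp)})
            chosen = [pairs[i % len(pairs)] for i in range(n)]
            meta["subject"] = [s for s, _ in chosen]
            meta["timepoint"] = [t for _, t in chosen]
            meta["sex"] = [subject_sex[s] for s in meta["subject"]]
            for i, (s, t) in enumerate(chosen):
                mask = (b_subj == s) & (b_tp == t)
                if mask.any():
                    mean_pat = np.mean([[pattern[st][m] for m in config.shared_module_ids]
                                        for st in b_subtype[mask]], axis=0)
                    for k, m in enumerate(config.shared_module_ids):
                        f[mod_ids.index(m), i] += (config.brush_attenuation
                                                   * config.subtype_shift * mean_pat[k])
            subj_eff = np.array([subject_effect[s] for s in meta["subject"]])
        else:
            meta["subject"] = sample_ids
            meta["sex"] = ["male" if v < 0.5 else "female" for v in rng.random(n)]
            subj_eff = np.zeros(n)

        # assemble gene-by-sample matrix
        x = np.tile(mu.to_numpy()[:, None], (1, n)).astype(float)
        gene_index = {g: i for i, g in enumerate(gene_ids)}
        for k, m in enumerate(mod_ids):
            rows = [gene_index[g] for g in mods[m]]
            x[rows, :] += config.loading_strength * f[k, :]
        batch_eff = {f"B{b + 1}": rng.normal(0.0, config.batch_shift_sd)
                     for b in range(config.n_batches)}
        x += np.array([batch_eff[b] for b in meta["batch"]])[None, :]
        x += config.tin_effect * (meta["tin"].to_numpy() - 75.0)[None, :]
        x += subj_eff[None, :]
        y_rows = [gene_index[g] for g in Y_GENES]
        male = (meta["sex"] == "male").to_numpy()
        x[np.ix_(y_rows, np.where(male)[0])] += config.sex_shift
        x += rng.normal(0.0, config.noise_sd, size=x.shape)

        values = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
        datasets[dname] = ExpressionDataset(values, meta, scale="log", name=dname)
        factor_scores[dname] = pd.DataFrame(f, index=mod_ids, columns=sample_ids)
        membership[dname] = {g: m for m, genes in mods.items() for g in genes}

    truth = SimulationTruth(
        module_membership=membership,
        shared_module_ids=config.shared_module_ids,
        module_genes=module_genes,
        subtype_labels=dict(zip(biopsy_sample_ids, b_subtype)),
        subtype_module_pattern=pattern,
        progression_labels=dict(zip(biopsy_sample_ids, b_prog)),
        factor_scores=factor_scores,
        progression_module=config.progression_module,
    )
    return datasets, truth


def generate_counts(dataset: ExpressionDataset, library_sizes: np.ndarray | list[float],
                    dispersion: float, seed: int = 0) -> ExpressionDataset:
    """Draw negative-binomial counts with mean proportional to exp(value) x library size.

    Counts for gene g in sample j are NB with mean
    ``lib_j * exp(x_gj) / sum_g exp(x_gj)`` and variance ``mu + dispersion * mu^2``
    (gamma-Poisson mixture).  ``dispersion`` below 1e-12 degenerates to Poisson.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    libs = np.asarray(library_sizes, dtype=float)
    if libs.ndim == 0:
        libs = np.full(dataset.n_samples, float(libs))
    if libs.shape[0] != dataset.n_samples or (libs <= 0).any():
        raise ValueError("library_sizes must be positive, one per sample")
    rng = _substream(seed, "counts:" + (dataset.name or "dataset"))
    x = dataset.matrix()
    w = np.exp(x - x.max(axis=0, keepdims=True))
    mu = libs[None, :] * w / w.sum(axis=0, keepdims=True)
    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    values = pd.DataFrame(counts.astype(np.int64), index=dataset.values.index,
                          columns=dataset.values.columns)
    return dataset.with_values(values, scale="counts")


def write_simulation(datasets: dict[str, ExpressionDataset], truth: SimulationTruth,
                     config: SimulationConfig, outdir: str | Path) -> None:
    """Write each dataset as TSV (values + metadata), the truth as JSON, config as YAML."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ds in datasets.items():
        _io.write_expression_tsv(ds, outdir / f"{name}_expression.tsv")
        _io.write_metadata_tsv(ds, outdir / f"{name}_metadata.tsv")
    truth.to_json(outdir / "truth.json")
    cfg = asdict(config)
    cfg["subtype_proportions"] = list(cfg["subtype_proportions"])
    cfg["progression_probs"] = list(cfg["progression_probs"])
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    cfg = SimulationConfig(**raw)
    cfg.subtype_proportions = tuple(cfg.subtype_proportions)
    cfg.progression_probs = tuple(cfg.progression_probs)
    cfg.validate()
    return cfg
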