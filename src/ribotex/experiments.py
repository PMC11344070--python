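"""Experiment orchestration: feature extraction -> dataset grid -> K-fold
training -> aggregation and family comparison tables.

Four canned protocols compare model families over the full dataset grid:

1. solo vs hybrid vs ensemble DL (SDL / HDL / EDL);
2. ensemble DL with vs without convolutional stages;
3. solo vs voting-ensemble ML (SML / EML);
4. voting-ensemble ML vs ensemble DL (EML / EDL).

The default scale is a "desk" profile (subset of models, few epochs,
small recurrent widths) suitable for a single CPU; the full roster is a
flag away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexity import COMPOSITE_NAMES, featurize_corpus
from .datasets import build_all_datasets
from .evaluation import (
    AggregateReport,
    MetricsRecord,
    aggregate,
    evaluate_model_cv,
    family_differences,
    records_to_frame,
)
from .model_zoo import (
    EDL_BRANCHES,
    EDL_WITH_CNN,
    EDL_WITHOUT_CNN,
    EML_CONSTITUENTS,
    HDL_CONSTITUENTS,
    ModelSpec,
    SDL_NAMES,
    SML_NAMES,
    TrainingConfig,
    make_edl,
    make_eml,
    make_hdl,
    make_sdl,
    make_sml,
)

EXPERIMENT_FAMILIES = {
    1: ("SDL", "HDL", "EDL"),
    2: ("EDL_woCNN", "EDL_wCNN"),
    3: ("SML", "EML"),
    4: ("EML", "EDL"),
}


@dataclass
class ExperimentConfig:
    experiment_id: int
    K: int = 10
    seed: int = 0
    desk_scale: bool = True
    epochs: int = 10
    models_per_family: int | None = 2   # desk profile: subset per family
    hyperparameters: dict = field(default_factory=lambda: {"units": 16, "conv_filters": 8})

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_FAMILIES:
            raise ValueError("experiment id must be 1..4")


def corpus_frame(records) -> pd.DataFrame:
    """Featurize a record list into the labeled composite-feature table."""
    ids, labels, mat = featurize_corpus(records)
    df = pd.DataFrame(mat, columns=list(COMPOSITE_NAMES))
    df.insert(0, "label", labels)
    df.insert(0, "id", ids)
    return df


def experiment_specs(cfg: ExperimentConfig) -> dict[str, list[ModelSpec]]:
    """Model specs per compared family, honoring the desk-profile subset."""
    hp = cfg.hyperparameters if cfg.desk_scale else {}
    top = cfg.models_per_family if cfg.desk_scale else None

    def cut(items):
        return items[:top] if top else items

    eid = cfg.experiment_id
    if eid == 1:
        return {
            "SDL": [make_sdl(n, cfg.seed, **hp) for n in cut(list(SDL_NAMES))],
            "HDL": [make_hdl(i, cfg.seed, **hp) for i in cut(list(HDL_CONSTITUENTS))],
            "EDL": [make_edl(i, cfg.seed, **hp) for i in cut(list(EDL_BRANCHES))],
        }
    if eid == 2:
        return {
            "EDL_woCNN": [make_edl(i, cfg.seed, **hp) for i in cut(list(EDL_WITHOUT_CNN))],
            "EDL_wCNN": [make_edl(i, cfg.seed, **hp) for i in cut(list(EDL_WITH_CNN))],
        }
    if eid == 3:
        return {
            "SML": [make_sml(n, cfg.seed) for n in cut(list(SML_NAMES))],
            "EML": [make_eml(i, cfg.seed) for i in cut(list(EML_CONSTITUENTS))],
        }
    return {
        "EML": [make_eml(i, cfg.seed) for i in cut(list(EML_CONSTITUENTS))],
        "EDL": [make_edl(i, cfg.seed, **hp) for i in cut(list(EDL_BRANCHES))],
    }


def run_experiment(cfg: ExperimentConfig, corpus: pd.DataFrame,
                   datasets=None) -> AggregateReport:
    """Full model x dataset x fold grid plus the family comparison table."""
    if datasets is None:
        datasets = build_all_datasets(corpus)
    specs_by_family = experiment_specs(cfg)
    tc = TrainingConfig(epochs=cfg.epochs, seed=cfg.seed)
    # feasibility check before any training
    for ds in datasets:
        _, counts = np.unique(ds.labels, return_counts=True)
        if counts.min() < cfg.K:
            raise ValueError(
                f"dataset {ds.name!r}: smallest class {counts.min()} < K={cfg.K}")
    records: list[MetricsRecord] = []
    families: dict[str, str] = {}
    for family, specs in specs_by_family.items():
        for spec in specs:
            families[spec.identifier] = family
            for ds in datasets:
                records.extend(evaluate_model_cv(
                    spec, ds, K=cfg.K, seed=cfg.seed, cfg=tc))
    return aggregate(records, model_families=families)


def comparison_rows(report: AggregateReport,
                    family_a: str, family_b: str) -> dict[str, float]:
    """Bottom-row family comparison: grand means and rounded differences."""
    table = report.table
    eta_a = table.loc["Mean", f"eta_{family_a}(%)"]
    eta_b = table.loc["Mean", f"eta_{family_b}(%)"]
    alpha_a = table.loc["Mean", f"alpha_{family_a}"]
    alpha_b = table.loc["Mean", f"alpha_{family_b}"]
    return {
        f"eta_{family_a}": round(float(eta_a), 2),
        f"eta_{family_b}": round(float(eta_b), 2),
        f"alpha_{family_a}": round(float(alpha_a), 4),
        f"alpha_{family_b}": round(float(alpha_b), 4),
        "eta_diff": family_differences([eta_a], [eta_b], "percent"),
        "alpha_diff": family_differences([alpha_a], [alpha_b], "auc"),
    }


def protocol_sweep(corpus: pd.DataFrame, specs: list[ModelSpec],
                   Ks=(2, 4, 5, 10), seed: int = 0,
                   epochs: int = 10, datasets=None) -> pd.DataFrame:
    """Mean metrics per K-fold protocol plus K10-minus-K{5,4,2} differences.

    Returns a table with one row per metric (accuracy/AUC/recall/precision/
    F1) and one column per protocol, followed by difference columns D1/D2/D3
    (K10 minus K5/K4/K2) when those protocols are present.
    """
    if datasets is None:
        datasets = build_all_datasets(corpus)
    tc = TrainingConfig(epochs=epochs, seed=seed)
    rows = {}
    for K in Ks:
        records = []
        for spec in specs:
            for ds in datasets:
                records.extend(evaluate_model_cv(spec, ds, K=K, seed=seed, cfg=tc))
        df = records_to_frame(records)
        rows[f"K{K}"] = {
            "Accuracy(%)": df["eta"].mean() * 100,
            "AUC": df["alpha"].mean(),
            "Recall(%)": df["R"].mean() * 100,
            "Precision(%)": df["P"].mean() * 100,
            "F1(%)": df["F"].mean() * 100,
        }
    out = pd.DataFrame(rows)
    for label, other in (("D1", "K5"), ("D2", "K4"), ("D3", "K2")):
        if "K10" in out.columns and other in out.columns:
            out[label] = (out["K10"].round(2) - out[other].round(2)).abs().round(2)
    return out
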