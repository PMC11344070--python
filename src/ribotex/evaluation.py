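"""Evaluation harness: confusion metrics, ROC/AUC, stratified K-fold
protocols, grid aggregation, reliability tests, and permutation feature
importance.

Metrics are binary throughout (the one-vs-all datasets are materialized
as binary problems).  Aggregation follows the mean-over-datasets /
mean-over-models / system-mean scheme, with family comparison tables
whose difference rows are computed on means rounded to the report
precision (2 decimals for percentages, 4 for AUC) -- the convention the
printed tables use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datasets import MinMaxScaler, SpeciesDataset, balance_adasyn
from .model_zoo import ModelSpec, TrainedModel, TrainingConfig, train

VALID_K = (2, 4, 5, 10)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsRecord:
    model: str
    dataset: str
    K: int
    fold: int
    eta: float     # accuracy
    R: float       # recall
    P: float       # precision
    F: float       # F1
    alpha: float   # AUC


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 counts with class 1 as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision, F1; zero denominators give 0 + warning."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    eta = (c.TP + c.TN) / c.total

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} denominator is zero; reporting 0")
            return 0.0
        return num / den

    r = _ratio(c.TP, c.TP + c.FN, "recall")
    p = _ratio(c.TP, c.TP + c.FP, "precision")
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return {"eta": eta, "R": r, "P": p, "F": f}


def auc(y_true, scores) -> float:
    """Area under the ROC curve of P(class 1) scores."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


def kfold_split(ds: SpeciesDataset, K: int, seed: int):
    """Stratified shuffled K-fold index pairs (train_idx, test_idx)."""
    if K not in VALID_K:
        raise ValueError(f"K must be one of {VALID_K}")
    _, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < K:
        raise ValueError(f"smallest class has {counts.min()} rows < K={K}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return list(skf.split(ds.features, ds.labels))


def evaluate_model_cv(
    spec: ModelSpec,
    ds: SpeciesDataset,
    K: int = 10,
    seed: int = 0,
    cfg: TrainingConfig | None = None,
    balance: bool = True,
    corpus_wide_prep: bool = False,
) -> list[MetricsRecord]:
    """Per-fold metrics of one model on one dataset.

    Default is the leakage-free route: scaler bounds and ADASYN synthesis
    derive from the training fold only.  ``corpus_wide_prep`` instead scales
    and balances the whole dataset before splitting (synthetic rows then
    appear in test folds).
    """
    from dataclasses import replace

    work = ds
    if corpus_wide_prep:
        scaler = MinMaxScaler().fit(work.features)
        work = replace(work, features=scaler.transform(work.features))
        if balance:
            work = balance_adasyn(work, seed=seed)
    records = []
    for fold, (tr, te) in enumerate(kfold_split(work, K, seed)):
        tr_ds = SpeciesDataset(
            name=work.name, features=work.features[tr], labels=work.labels[tr],
            task=work.task, class_names=work.class_names,
            provenance=work.provenance[tr],
        )
        X_te, y_te = work.features[te], work.labels[te]
        if not corpus_wide_prep:
            scaler = MinMaxScaler().fit(tr_ds.features)
            tr_ds = replace(tr_ds, features=scaler.transform(tr_ds.features))
            if balance:
                tr_ds = balance_adasyn(tr_ds, seed=seed)
            X_te = scaler.transform(X_te)
        model = train(spec, tr_ds, cfg)
        proba = model.predict_proba(X_te)
        pos_col = int(np.where(model.classes_ == 1)[0][0])
        y_pred = model.classes_[proba.argmax(axis=1)]
        m = metrics(confusion(y_te, y_pred))
        records.append(MetricsRecord(
            model=spec.identifier, dataset=work.name, K=K, fold=fold,
            alpha=auc(y_te, proba[:, pos_col]), **m,
        ))
    return records


# --------------------------------------------------------------------------
# aggregation

def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class AggregateReport:
    per_model: pd.DataFrame    # mean eta/alpha per model over datasets
    per_dataset: pd.DataFrame  # mean eta/alpha per dataset over models
    system: dict[str, float]   # grand means
    table: pd.DataFrame | None = None  # family comparison table, if built


def aggregate(records: list[MetricsRecord],
              model_families: dict[str, str] | None = None) -> AggregateReport:
    """Per-model, per-dataset and system means of accuracy and AUC.

    Requires a complete model x dataset grid; per-fold records are first
    averaged within each (model, dataset) cell.
    """
    df = records_to_frame(records)
    cell = df.groupby(["model", "dataset"])[["eta", "alpha"]].mean().reset_index()
    grid = cell.pivot(index="model", columns="dataset", values="eta")
    if grid.isna().any().any():
        missing = [(m, d) for m in grid.index for d in grid.columns
                   if pd.isna(grid.loc[m, d])]
        raise ValueError(f"incomplete model x dataset grid; missing cells: {missing}")
    per_model = cell.groupby("model")[["eta", "alpha"]].mean()
    per_dataset = cell.groupby("dataset")[["eta", "alpha"]].mean()
    system = {"eta": float(cell["eta"].mean()), "alpha": float(cell["alpha"].mean())}
    report = AggregateReport(per_model=per_model, per_dataset=per_dataset,
                             system=system)
    if model_families:
        cell["family"] = cell["model"].map(model_families)
        report.table = family_table(cell)
    return report


def family_table(cell: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset family means (accuracy %, AUC) plus a bottom mean row."""
    fam = (cell.groupby(["dataset", "family"])[["eta", "alpha"]].mean()
           .unstack("family"))
    out = pd.DataFrame(index=fam.index)
    for family in fam["eta"].columns:
        out[f"eta_{family}(%)"] = fam["eta"][family] * 100
        out[f"alpha_{family}"] = fam["alpha"][family]
    out.loc["Mean"] = out.mean(axis=0)
    return out


def family_differences(
    means_a: pd.Series | list[float],
    means_b: pd.Series | list[float],
    scale: str = "percent",
) -> float:
    """|mean(b) - mean(a)| computed on report-precision-rounded means.

    ``percent`` rounds both grand means to 2 decimals before differencing;
    ``auc`` rounds to 4 decimals and reports the difference x 100.  This
    reproduces printed comparison rows exactly.
    """
    a = round(float(np.mean(np.asarray(means_a, dtype=float))), 2 if scale == "percent" else 4)
    b = round(float(np.mean(np.asarray(means_b, dtype=float))), 2 if scale == "percent" else 4)
    diff = abs(b - a)
    if scale == "auc":
        diff *= 100
    return round(diff, 2)


# --------------------------------------------------------------------------
# reliability

def reliability_tests(per_fold_acc: dict[str, np.ndarray],
                      probabilities: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                      alpha_level: float = 0.01) -> dict:
    """One-way ANOVA across models' per-fold accuracies, per-model two-tailed
    Z against the pooled mean, and (optionally) adjusted R^2 of predicted
    positive-class probabilities against true labels.
    """
    if len(per_fold_acc) < 2:
        raise ValueError("need at least 2 models")
    groups = {m: np.asarray(v, dtype=float) for m, v in per_fold_acc.items()}
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("need at least 3 folds per model")
    fstat, pval = stats.f_oneway(*groups.values())
    if np.isnan(fstat):  # identical groups: zero between- and within-variance
        fstat, pval = 0.0, 1.0
    pooled = np.concatenate(list(groups.values()))
    pooled_mean, pooled_sd = pooled.mean(), pooled.std(ddof=1)
    z_scores, z_pvals = {}, {}
    for m, v in groups.items():
        diff = v.mean() - pooled_mean
        if pooled_sd < 1e-12 or abs(diff) < 1e-12:
            z = 0.0
        else:
            z = diff / (pooled_sd / np.sqrt(len(v)))
        z_scores[m] = float(z)
        z_pvals[m] = float(2 * stats.norm.sf(abs(z)))
    out = {
        "anova_F": float(fstat),
        "anova_p": float(pval),
        "anova_pass": bool(pval < alpha_level),
        "Z_two_tailed": z_scores,
        "Z_p": z_pvals,
    }
    if probabilities:
        adj = {}
        for m, (y, p) in probabilities.items():
            adj[m] = adjusted_r2(np.asarray(y, float), np.asarray(p, float))
        out["adjusted_R2"] = adj
    return out


def adjusted_r2(y_true: np.ndarray, y_score: np.ndarray, n_predictors: int = 1) -> float:
    """Adjusted R^2 of predicted probabilities against 0/1 labels."""
    n = len(y_true)
    ss_res = np.sum((y_true - y_score) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    r2 = 1 - ss_res / ss_tot
    return float(1 - (1 - r2) * (n - 1) / (n - n_predictors - 1))


# --------------------------------------------------------------------------
# feature importance

def permutation_importance(model: TrainedModel, X: np.ndarray, y: np.ndarray,
                           seed: int = 0, n_repeats: int = 5,
                           feature_names=None) -> pd.DataFrame:
    """Mean held-out accuracy drop when each column is shuffled, descending."""
    rng = np.random.default_rng(seed)
    base = float(np.mean(model.predict(X) == y))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        accs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            accs.append(float(np.mean(model.predict(Xp) == y)))
        drops[j] = base - float(np.mean(accs))
    names = (list(feature_names) if feature_names is not None
             else [f"x{j}" for j in range(X.shape[1])])
    df = pd.DataFrame({"feature": names, "importance": drops})
    return df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
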