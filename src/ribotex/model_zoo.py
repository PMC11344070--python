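"""The classifier roster: 10 solo ML, 5 voting ML ensembles, 6 solo DL,
12 hybrid DL and 6 ensemble DL configurations (38 total).

ML models are standard scikit-learn / xgboost / lightgbm estimators;
voting ensembles average constituent class probabilities (soft voting),
with the linear SVM contributing a min-max-normalized decision score so
it can participate in probability averaging and AUC computation.  DL
models are built on the package's numpy network engine: solo models are
a single recurrent block, hybrids stack two blocks (optionally ending in
a 1-D convolutional stage), and ensembles run two hybrid branches -- each
truncated at its dropout layer -- whose outputs are concatenated and fed
to a dense stage and a softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier
from lightgbm import LGBMClassifier

from .datasets import SpeciesDataset
from .nn import (
    Bidirectional,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GRU,
    LSTM,
    MaxPool1D,
    Network,
    NeuralNetClassifier,
    SimpleRNN,
)

SML_NAMES = ("LR", "SVM", "DT", "RF", "ET", "XGBoost", "KNN", "LDA", "LGBM", "NB")

EML_CONSTITUENTS = {
    "EML1": ("LR", "SVM"),
    "EML2": ("DT", "KNN"),
    "EML3": ("DT", "RF"),
    "EML4": ("RF", "DT", "ET"),
    "EML5": ("ET", "XGBoost", "LGBM"),
}

SDL_NAMES = ("GRU", "BiGRU", "RNN", "BiRNN", "LSTM", "BiLSTM")

HDL_CONSTITUENTS = {
    "HDL1": ("LSTM", "GRU"),
    "HDL2": ("BiLSTM", "BiGRU"),
    "HDL3": ("LSTM", "CNN"),
    "HDL4": ("BiLSTM", "CNN"),
    "HDL5": ("GRU", "CNN"),
    "HDL6": ("BiGRU", "CNN"),
    "HDL7": ("BiRNN", "CNN"),
    "HDL8": ("BiGRU", "GRU"),
    "HDL9": ("BiLSTM", "LSTM"),
    "HDL10": ("BiRNN", "RNN"),
    "HDL11": ("RNN", "CNN"),
    "HDL12": ("LSTM", "GRU-CNN"),  # three-block hybrid LSTM-GRU-CNN
}

EDL_BRANCHES = {
    "EDL1": ("BiLSTM-BiGRU", "LSTM-GRU"),
    "EDL2": ("BiLSTM-BiGRU", "BiRNN-RNN"),
    "EDL3": ("BiGRU-GRU", "LSTM-CNN"),
    "EDL4": ("BiRNN-CNN", "GRU-CNN"),
    "EDL5": ("BiLSTM-LSTM", "RNN-CNN"),
    "EDL6": ("BiLSTM-CNN", "BiGRU-CNN"),
}

#: EDL models whose branches contain convolutional stages
EDL_WITH_CNN = ("EDL3", "EDL4", "EDL5", "EDL6")
EDL_WITHOUT_CNN = ("EDL1", "EDL2")

DEFAULT_HYPERPARAMETERS = {
    "units": 64,        # recurrent layer width
    "conv_filters": 32,
    "conv_kernel": 3,
    "pool": 2,
    "dropout": 0.2,
    "dense_units": 64,  # post-concatenation dense stage (EDL)
}


@dataclass(frozen=True)
class ModelSpec:
    family: str                  # SML | EML | SDL | HDL | EDL
    identifier: str
    constituents: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    classes_: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


# --------------------------------------------------------------------------
# spec constructors

def make_sml(name: str, seed: int = 0, **overrides) -> ModelSpec:
    if name not in SML_NAMES:
        raise ValueError(f"unknown SML model {name!r}; valid: {SML_NAMES}")
    return ModelSpec("SML", name, (name,), dict(overrides), seed)


def make_eml(identifier: str, seed: int = 0, **overrides) -> ModelSpec:
    if identifier not in EML_CONSTITUENTS:
        raise ValueError(f"unknown EML model {identifier!r}; "
                         f"valid: {tuple(EML_CONSTITUENTS)}")
    return ModelSpec("EML", identifier, EML_CONSTITUENTS[identifier],
                     dict(overrides), seed)


def make_sdl(name: str, seed: int = 0, **overrides) -> ModelSpec:
    if name not in SDL_NAMES:
        raise ValueError(f"unknown SDL model {name!r}; valid: {SDL_NAMES}")
    hp = {**DEFAULT_HYPERPARAMETERS, **overrides}
    return ModelSpec("SDL", name, (name,), hp, seed)


def make_hdl(identifier: str, seed: int = 0, **overrides) -> ModelSpec:
    if identifier not in HDL_CONSTITUENTS:
        raise ValueError(f"unknown HDL model {identifier!r}; "
                         f"valid: {tuple(HDL_CONSTITUENTS)}")
    hp = {**DEFAULT_HYPERPARAMETERS, **overrides}
    return ModelSpec("HDL", identifier, HDL_CONSTITUENTS[identifier], hp, seed)


def make_edl(identifier: str, seed: int = 0, **overrides) -> ModelSpec:
    if identifier not in EDL_BRANCHES:
        raise ValueError(f"unknown EDL model {identifier!r}; "
                         f"valid: {tuple(EDL_BRANCHES)}")
    hp = {**DEFAULT_HYPERPARAMETERS, **overrides}
    return ModelSpec("EDL", identifier, EDL_BRANCHES[identifier], hp, seed)


def all_specs(seed: int = 0, **overrides) -> list[ModelSpec]:
    """The full 38-model roster."""
    specs = [make_sml(n, seed) for n in SML_NAMES]
    specs += [make_eml(i, seed) for i in EML_CONSTITUENTS]
    specs += [make_sdl(n, seed, **overrides) for n in SDL_NAMES]
    specs += [make_hdl(i, seed, **overrides) for i in HDL_CONSTITUENTS]
    specs += [make_edl(i, seed, **overrides) for i in EDL_BRANCHES]
    return specs


# --------------------------------------------------------------------------
# ML estimators

class LinearSVMProb(BaseEstimator, ClassifierMixin):
    """Linear SVM exposing pseudo-probabilities.

    The signed decision score is min-max normalized over the training
    scores to [0, 1] and used as P(class 1); scores outside the training
    range are clipped.  Keeps the margin-based ranking (hence AUC) intact
    while allowing soft voting.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        self.svc_ = LinearSVC(C=self.C, random_state=self.random_state)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        scores = self.svc_.decision_function(X)
        self.lo_, self.hi_ = float(scores.min()), float(scores.max())
        if self.hi_ == self.lo_:
            self.hi_ = self.lo_ + 1.0
        return self

    def predict_proba(self, X):
        s = np.clip((self.svc_.decision_function(X) - self.lo_)
                    / (self.hi_ - self.lo_), 0.0, 1.0)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        return self.svc_.predict(X)


class SoftVotingClassifier(BaseEstimator, ClassifierMixin):
    """Soft voting: class probabilities are the arithmetic mean of the
    constituents' probabilities."""

    def __init__(self, estimators: list):
        self.estimators = estimators

    def fit(self, X, y):
        self.fitted_ = [clone(est).fit(X, y) for est in self.estimators]
        self.classes_ = self.fitted_[0].classes_
        return self

    def predict_proba(self, X):
        return np.mean([est.predict_proba(X) for est in self.fitted_], axis=0)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _sml_estimator(name: str, seed: int, hp: dict):
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if name == "SVM":
        return LinearSVMProb(random_state=seed, **hp)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **hp)
    if name == "ET":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed, **hp)
    if name == "XGBoost":
        return XGBClassifier(n_estimators=100, random_state=seed,
                             eval_metric="logloss", verbosity=0, **hp)
    if name == "KNN":
        return KNeighborsClassifier(**hp)
    if name == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if name == "LGBM":
        return LGBMClassifier(n_estimators=100, random_state=seed,
                              verbose=-1, **hp)
    if name == "NB":
        return GaussianNB(**hp)
    raise ValueError(f"unknown SML model {name!r}")


# --------------------------------------------------------------------------
# DL blueprints

_RECURRENT_BLOCKS = {
    "RNN": (SimpleRNN, False),
    "GRU": (GRU, False),
    "LSTM": (LSTM, False),
    "BiRNN": (SimpleRNN, True),
    "BiGRU": (GRU, True),
    "BiLSTM": (LSTM, True),
}


def _recurrent(block: str, units: int, return_sequences: bool):
    cls, bidir = _RECURRENT_BLOCKS[block]
    if bidir:
        return Bidirectional(cls, units, return_sequences=return_sequences)
    return cls(units, return_sequences=return_sequences)


def build_branch(blocks: tuple[str, ...], hp: dict) -> list:
    """Layer list for a solo/hybrid blueprint, ending in its dropout layer."""
    blocks = tuple(b for name in blocks for b in name.split("-"))
    layers: list = []
    rec_blocks = [b for b in blocks if b != "CNN"]
    has_cnn = "CNN" in blocks
    for i, b in enumerate(rec_blocks):
        last_rec = i == len(rec_blocks) - 1
        return_sequences = has_cnn or not last_rec
        layers.append(_recurrent(b, hp["units"], return_sequences))
    if has_cnn:
        layers.append(Conv1D(hp["conv_filters"], hp["conv_kernel"]))
        layers.append(MaxPool1D(hp["pool"]))
        layers.append(Flatten())
    layers.append(Dropout(hp["dropout"]))
    return layers


def build_network_fn(spec: ModelSpec) -> Callable[[int], Network]:
    """Network factory (closed over the spec) called once TC is known."""
    hp = spec.hyperparameters

    def build(n_classes: int) -> Network:
        if spec.family in ("SDL", "HDL"):
            branch = build_branch(spec.constituents, hp)
            return Network(branches=[branch], head=[Dense(n_classes)])
        if spec.family == "EDL":
            branches = [build_branch(tuple(b.split("-")), hp)
                        for b in spec.constituents]
            head = [Dense(hp["dense_units"], activation="relu"),
                    Dense(n_classes)]
            return Network(branches=branches, head=head)
        raise ValueError(f"not a DL spec: {spec.identifier}")

    return build


def build_estimator(spec: ModelSpec, cfg: TrainingConfig | None = None):
    """Unfitted estimator (fit/predict/predict_proba) for any spec."""
    cfg = cfg or TrainingConfig(seed=spec.seed)
    if spec.family == "SML":
        return _sml_estimator(spec.identifier, spec.seed, spec.hyperparameters)
    if spec.family == "EML":
        members = [_sml_estimator(n, spec.seed, {}) for n in spec.constituents]
        return SoftVotingClassifier(members)
    if spec.family in ("SDL", "HDL", "EDL"):
        return NeuralNetClassifier(
            build_network_fn(spec),
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            seed=spec.seed,
        )
    raise ValueError(f"unknown family {spec.family!r}")


def train(spec: ModelSpec, ds: SpeciesDataset,
          cfg: TrainingConfig | None = None) -> TrainedModel:
    """Fit the spec's estimator on a dataset's feature matrix."""
    if ds.n_samples == 0:
        raise ValueError("empty dataset")
    if not np.all(np.isfinite(ds.features)):
        raise ValueError("features must be finite")
    if len(np.unique(ds.labels)) < 2:
        raise ValueError("dataset contains a single class")
    est = build_estimator(spec, cfg)
    est.fit(ds.features, ds.labels)
    return TrainedModel(spec=spec, estimator=est, classes_=est.classes_)
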