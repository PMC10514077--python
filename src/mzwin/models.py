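"""The supervised model zoo and cohort split protocols.

Ten learners are run on every feature subset: seven conventional
algorithms (RF, DT, SVM, KNN, LR, LightGBM, NB), two ensemble
frameworks (Bagging, AdaBoost) and one small neural network (MLP with a
single 32-unit hidden layer).  Hyperparameters are fixed, not tuned:

==========  =======================================
RF          n_estimators = 10
DT          library defaults (no penalty parameter exists)
SVM         RBF kernel, cache_size = 200
KNN         n_neighbors = 5
LR          L2 penalty
LightGBM    n_estimators = 100
NB          Gaussian (features are continuous intensities; the stated
            smoothing alpha applies only to count/binary NB variants and
            is ignored, like the DT entry above)
Bagging     n_estimators = 100
AdaBoost    n_estimators = 50
MLP         hidden_layer_sizes = (32,)
==========  =======================================

Splits come in three flavours: a stratified train:test *ratio* split
(e.g. 2:1 or 7:3), *fixed per-class counts* for the train side, and
*batch holdout* (one acquisition batch is the external test set).  In
every flavour a stratified validation partition is carved from the
train side so model/subset choice never touches the test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from lightgbm import LGBMClassifier

from .io import Cohort

#: canonical model order; ties in the subset search resolve to the earlier name
MODEL_ORDER = ["RF", "DT", "SVM", "KNN", "LR", "LightGBM", "NB", "Bagging",
               "AdaBoost", "MLP"]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    standardize: bool = False  # optional scaling for SVM/MLP/KNN practicality

    def __post_init__(self) -> None:
        if self.name not in MODEL_ORDER:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_ORDER}")


def default_specs(seed: int = 0, standardize: bool | None = None) -> list[ModelSpec]:
    """The full zoo in canonical order.

    By default no model scales its input except the MLP, whose
    gradient-based fit diverges on raw intensity scales (the usual
    practice of pipelining a standardizer with a neural network).  Pass
    ``standardize`` explicitly to force one behaviour for all models.
    """
    return [
        ModelSpec(name=n, seed=seed,
                  standardize=(n == "MLP") if standardize is None else standardize)
        for n in MODEL_ORDER
    ]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.name == "RF":
        return RandomForestClassifier(n_estimators=10, random_state=seed, **hp)
    if spec.name == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.name == "SVM":
        return SVC(kernel="rbf", cache_size=200, random_state=seed, **hp)
    if spec.name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, **hp)
    if spec.name == "LR":
        return LogisticRegression(penalty="l2", max_iter=2000, random_state=seed, **hp)
    if spec.name == "LightGBM":
        return LGBMClassifier(n_estimators=100, random_state=seed, verbose=-1,
                              min_child_samples=hp.pop("min_child_samples", 5), **hp)
    if spec.name == "NB":
        return GaussianNB(**hp)
    if spec.name == "Bagging":
        return BaggingClassifier(n_estimators=100, random_state=seed, **hp)
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(n_estimators=50, random_state=seed, **hp)
    if spec.name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000,
                             random_state=seed, **hp)
    raise ValueError(f"unknown model {spec.name!r}")


def train_predict(spec: ModelSpec, X_train, y_train, X_test):
    """Fit one model and return (predicted labels, positive-class scores).

    Scores come from ``predict_proba`` where available, otherwise from
    the decision function — the rank AUC only needs an ordering.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(set(y_train)) < 2:
        raise ValueError("training labels must contain both classes")
    if spec.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    est = _build_estimator(spec)
    est.fit(X_train, y_train)
    y_pred = est.predict(X_test).astype(int)
    if hasattr(est, "predict_proba"):
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        scores = est.predict_proba(X_test)[:, pos_col]
    else:
        scores = est.decision_function(X_test)
    return y_pred, np.asarray(scores, dtype=float)


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a cohort into train / validation / test.

    strategy:
        ``ratio``         — stratified train-side:test split, e.g. "2:1" or "7:3";
        ``fixed_counts``  — exact per-class train-side counts
                            (``train_pos``/``train_neg``), remainder is test;
        ``batch_holdout`` — the named batch is the whole test set.
    A stratified ``validation_fraction`` of the train side becomes the
    validation partition in every strategy.
    """

    strategy: str = "ratio"
    ratio: str = "2:1"
    train_pos: int | None = None
    train_neg: int | None = None
    holdout_batch: str | None = None
    validation_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("ratio", "fixed_counts", "batch_holdout"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")


def _ratio_test_fraction(ratio: str) -> float:
    try:
        a, b = (Fraction(part) for part in ratio.split(":"))
    except Exception as exc:
        raise ValueError(f"bad ratio {ratio!r}; expected 'train:test'") from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio parts must be positive, got {ratio!r}")
    return float(b / (a + b))


def make_splits(cohort: Cohort, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (train, validation, test) index arrays for the cohort."""
    y = cohort.y
    idx = np.arange(len(cohort))
    rng_seed = spec.seed

    if spec.strategy == "ratio":
        frac = _ratio_test_fraction(spec.ratio)
        train_side, test = train_test_split(
            idx, test_size=frac, stratify=y, random_state=rng_seed)
    elif spec.strategy == "fixed_counts":
        if spec.train_pos is None or spec.train_neg is None:
            raise ValueError("fixed_counts split needs train_pos and train_neg")
        pos, neg = idx[y == 1], idx[y == 0]
        if spec.train_pos > len(pos) or spec.train_neg > len(neg):
            raise ValueError(
                f"requested train counts ({spec.train_pos}P/{spec.train_neg}N) "
                f"exceed class sizes ({len(pos)}P/{len(neg)}N)")
        rng = np.random.default_rng(rng_seed)
        pos, neg = rng.permutation(pos), rng.permutation(neg)
        train_side = np.concatenate([pos[:spec.train_pos], neg[:spec.train_neg]])
        test = np.concatenate([pos[spec.train_pos:], neg[spec.train_neg:]])
    else:  # batch_holdout
        batches = cohort.batches
        if spec.holdout_batch is None:
            raise ValueError("batch_holdout split needs holdout_batch")
        if spec.holdout_batch not in set(batches):
            raise ValueError(f"unknown batch id {spec.holdout_batch!r}")
        mask = batches == spec.holdout_batch
        test, train_side = idx[mask], idx[~mask]

    train_side = np.sort(train_side)
    test = np.sort(test)
    if spec.validation_fraction > 0 and len(train_side) > 1:
        train, val = train_test_split(
            train_side, test_size=spec.validation_fraction,
            stratify=y[train_side], random_state=rng_seed)
    else:
        train, val = train_side, np.array([], dtype=int)
    return np.sort(train), np.sort(val), test
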