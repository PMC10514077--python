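"""Chi-square feature scoring and minimal non-redundant subset search.

Two scoring forms are provided.

The *contingency* form scores a window by the 2x2 table of
presence/absence against class:

    chi2(F, L) = (AD - CB)^2 / ((A+C)(B+D)(A+B)(C+D))

where A counts samples of class L carrying feature F (a non-missing
window), B samples outside L carrying F, C samples of L lacking F and D
samples of neither.  Note the formula deliberately omits the sample-size
factor N of the classical Pearson statistic; multiplying by N recovers
Pearson exactly, and since N is constant across features the ranking is
unaffected.  ``classical=True`` applies the factor for interoperability.

The *frequency* form (the default) weights by intensity rather than
presence: observed = per-class sum of the feature's values, expected =
class sample-proportion x total sum, statistic = sum (O-E)^2/E over the
two classes.  This matches the chi2 scorer of scikit-learn's feature
selection on non-negative data.

The subset search sweeps the top-k prefixes of the chi-square ranking
for k = 1..k_max, fits every model of the zoo on the training split and
scores validation accuracy; it returns the smallest k (ties to the
earliest model in canonical order) attaining the maximum validation
accuracy, then evaluates that single choice once on the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .construct import FeatureMatrix
from .metrics import MetricReport, full_report
from .models import ModelSpec, default_specs, train_predict

__all__ = [
    "ContingencyCounts", "FeatureScore", "SubsetResult",
    "chi2_contingency", "presence_counts", "chi2_frequency",
    "rank_features", "minimal_subset_search",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 presence-by-class table; A+B+C+D = cohort size."""

    a: int  # in class, has feature
    b: int  # out of class, has feature
    c: int  # in class, lacks feature
    d: int  # out of class, lacks feature

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True)
class FeatureScore:
    feature_index: int
    chi2: float
    degenerate: bool = False


@dataclass
class SubsetResult:
    k: int
    feature_indices: list[int]
    model_name: str
    peak_type: str
    validation: MetricReport
    test: MetricReport
    sweep: list[dict] = field(default_factory=list)  # (k, model, val accuracy)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "feature_indices": list(map(int, self.feature_indices)),
            "model": self.model_name,
            "peak_type": self.peak_type,
            "validation": self.validation.to_dict(),
            "test": self.test.to_dict(),
        }


def chi2_contingency(counts: ContingencyCounts, classical: bool = False) -> float:
    """Evaluate the 2x2 statistic; a zero marginal yields 0 (degenerate)."""
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    den = (a + c) * (b + d) * (a + b) * (c + d)
    if den == 0:
        return 0.0
    stat = (a * d - c * b) ** 2 / den
    if classical:
        stat *= a + b + c + d
    return stat


def presence_counts(feature_column, labels, missing_mask=None) -> ContingencyCounts:
    """Tally the 2x2 presence table; "has feature" = non-missing window.

    Without an explicit mask, presence falls back to "non-zero after
    fill", which coincides with non-missing for zero-filled matrices.
    """
    col = np.asarray(feature_column, dtype=float)
    y = np.asarray(labels, dtype=int)
    if col.shape != y.shape:
        raise ValueError("feature column and labels must have equal length")
    present = ~np.asarray(missing_mask, bool) if missing_mask is not None else col != 0
    a = int(np.sum(present & (y == 1)))
    b = int(np.sum(present & (y == 0)))
    c = int(np.sum(~present & (y == 1)))
    d = int(np.sum(~present & (y == 0)))
    return ContingencyCounts(a=a, b=b, c=c, d=d)


def chi2_frequency(feature_column, labels) -> float:
    """Intensity-weighted chi-square of one non-negative feature column."""
    col = np.asarray(feature_column, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any(col < 0):
        raise ValueError("frequency form needs non-negative values")
    total = col.sum()
    if total == 0:
        return 0.0  # constant-zero feature carries no signal
    stat = 0.0
    n = len(y)
    for cls in (1, 0):
        obs = col[y == cls].sum()
        exp = (np.sum(y == cls) / n) * total
        if exp > 0:
            stat += (obs - exp) ** 2 / exp
    return stat


def rank_features(matrix: FeatureMatrix, labels, method: str = "frequency") -> list[FeatureScore]:
    """Score every window and sort descending by chi2, ties by lower index."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("ranking needs both classes present")
    if method not in ("frequency", "contingency"):
        raise ValueError(f"unknown method {method!r}")
    scores = []
    for j in range(matrix.n_windows):
        col = matrix.values[:, j]
        if method == "frequency":
            stat = chi2_frequency(col, y)
            degen = col.sum() == 0
        else:
            counts = presence_counts(col, y, matrix.missing_mask[:, j])
            stat = chi2_contingency(counts)
            degen = stat == 0.0 and (
                (counts.a + counts.b == 0) or (counts.c + counts.d == 0))
        scores.append(FeatureScore(feature_index=j, chi2=float(stat), degenerate=degen))
    return sorted(scores, key=lambda s: (-s.chi2, s.feature_index))


def minimal_subset_search(
    matrix: FeatureMatrix,
    labels,
    train_idx,
    val_idx,
    test_idx,
    *,
    models: list[ModelSpec] | None = None,
    k_max: int = 20,
    method: str = "frequency",
) -> SubsetResult:
    """Find the smallest top-k chi-square prefix maximizing validation accuracy.

    For each k = 1..k_max and each model (canonical order) the model is
    fit on the training rows restricted to the top-k ranked windows and
    scored on the validation rows; the winner is re-fit on the training
    rows and evaluated once on the test rows.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, matrix.n_windows)
    y = np.asarray(labels, dtype=int)
    specs = models if models is not None else default_specs()
    ranking = rank_features(matrix, y, method=method)
    ranked_idx = [s.feature_index for s in ranking]

    best = None  # (val_accuracy, k, model_position)
    sweep = []
    for k in range(1, k_max + 1):
        cols = ranked_idx[:k]
        X_tr, X_val = matrix.values[np.ix_(train_idx, cols)], matrix.values[np.ix_(val_idx, cols)]
        for pos, spec in enumerate(specs):
            y_pred, _ = train_predict(spec, X_tr, y[train_idx], X_val)
            acc = float(np.mean(y_pred == y[val_idx]))
            sweep.append({"k": k, "model": spec.name, "val_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, k, pos)

    _, k_best, pos_best = best
    spec_best = specs[pos_best]
    cols = ranked_idx[:k_best]
    X_tr = matrix.values[np.ix_(train_idx, cols)]
    y_val_pred, val_scores = train_predict(
        spec_best, X_tr, y[train_idx], matrix.values[np.ix_(val_idx, cols)])
    val_rep = full_report(y[val_idx], y_val_pred, val_scores)
    y_te_pred, te_scores = train_predict(
        spec_best, X_tr, y[train_idx], matrix.values[np.ix_(test_idx, cols)])
    test_rep = full_report(y[test_idx], y_te_pred, te_scores)

    return SubsetResult(k=k_best, feature_indices=cols, model_name=spec_best.name,
                        peak_type=matrix.peak_type, validation=val_rep,
                        test=test_rep, sweep=sweep)
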