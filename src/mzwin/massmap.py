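"""Back-mapping constructed features to m/z intervals and marker nomination.

A selected window index i recovers its original mass region as

    low  = i * step + start,      high = low + step

so a discriminative feature localizes a biomarker to a step-wide m/z
interval.  Within such an interval, candidate marker masses are found by
traversing the masses shared across samples: peak m/z values are rounded
to a fixed number of decimals (substances with equal rounded mass are
treated as the same species; 3 decimals by default) and rounded masses
reaching a minimum support fraction across samples are ranked by how
strongly their support (or, on ties, mean intensity) differs between
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .construct import FeatureMatrix, WindowGrid
from .io import Cohort

__all__ = ["MassInterval", "MarkerCandidate", "back_map",
           "common_mass_traversal", "scatter_export"]


@dataclass(frozen=True)
class MassInterval:
    feature_index: int
    low: float   # Da; = feature_index * step + start
    high: float  # Da; = low + step


@dataclass(frozen=True)
class MarkerCandidate:
    mass: float        # Da, rounded
    support: float     # fraction of all samples carrying the rounded mass
    support_pos: float
    support_neg: float
    class_gap: float   # |support_pos - support_neg|, tie-broken by intensity


def back_map(feature_index: int, grid: WindowGrid) -> MassInterval:
    """Original m/z interval of a constructed feature (width = step)."""
    if not 0 <= feature_index < grid.n_windows:
        raise IndexError(
            f"feature index {feature_index} out of range [0, {grid.n_windows})")
    low = feature_index * grid.step + grid.start
    return MassInterval(feature_index=int(feature_index), low=float(low),
                        high=float(low + grid.step))


def common_mass_traversal(
    cohort: Cohort,
    interval: MassInterval,
    decimals: int = 3,
    min_support: float = 1.0,
) -> list[MarkerCandidate]:
    """Rank rounded masses inside an interval by between-class difference.

    The last window of a grid is right-closed, so the traversal includes
    peaks at exactly ``interval.high``.  An interval containing no peak
    returns an empty list.
    """
    y = cohort.y
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    n = len(cohort)

    # per (rounded mass): which samples carry it, and their intensities
    carriers: dict[float, set[int]] = {}
    intens_pos: dict[float, list[float]] = {}
    intens_neg: dict[float, list[float]] = {}
    for si, sample in enumerate(cohort):
        mz = sample.mz
        inside = (mz >= interval.low) & (mz <= interval.high)
        if not inside.any():
            continue
        heights = sample.intensity("height")[inside]
        for m, h in zip(np.round(mz[inside], decimals), heights):
            m = float(m)
            carriers.setdefault(m, set()).add(si)
            (intens_pos if y[si] == 1 else intens_neg).setdefault(m, []).append(h)

    candidates = []
    for m, who in carriers.items():
        support = len(who) / n
        if support < min_support:
            continue
        sp = sum(1 for si in who if y[si] == 1) / n_pos if n_pos else 0.0
        sn = sum(1 for si in who if y[si] == 0) / n_neg if n_neg else 0.0
        candidates.append((m, support, sp, sn))

    def intensity_gap(m: float) -> float:
        pos = np.asarray(intens_pos.get(m, []), dtype=float)
        neg = np.asarray(intens_neg.get(m, []), dtype=float)
        if len(pos) == 0 or len(neg) == 0:
            return 0.0
        pooled = np.concatenate([pos, neg]).std()
        if pooled == 0:
            return 0.0
        return abs(pos.mean() - neg.mean()) / pooled

    result = [
        MarkerCandidate(mass=m, support=s, support_pos=sp, support_neg=sn,
                        class_gap=abs(sp - sn))
        for m, s, sp, sn in candidates
    ]
    # rank: support gap desc, then standardized intensity gap desc, then mass asc
    result.sort(key=lambda c: (-c.class_gap, -intensity_gap(c.mass), c.mass))
    return result


def scatter_export(matrix: FeatureMatrix, index_pair: tuple[int, int],
                   labels) -> pd.DataFrame:
    """Coordinates of every sample in the plane of two selected features.

    Returns a (sample_id, x, y, label) table for external plotting; no
    figure is rendered.  A repeated index gives the degenerate diagonal.
    """
    i, j = index_pair
    for ix in (i, j):
        if not 0 <= ix < matrix.n_windows:
            raise IndexError(f"feature index {ix} out of range")
    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "x": matrix.values[:, i],
        "y": matrix.values[:, j],
        "label": np.asarray(labels),
    })
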