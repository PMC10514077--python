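"""Sliding-window feature construction over the m/z axis.

Peak lists from different samples have different lengths (sampling time
differs), so they cannot feed a classifier directly.  The construction
step scans the cohort for its global m/z range, lays a grid of
fixed-width windows over that range, and represents each sample by the
per-window arithmetic mean of peak height (or peak area).  Every sample
then shares the same vector length — the alignment guarantee — while
within-window averaging suppresses noise and redundancy.

Window conventions
------------------
``n_windows = floor((stop - start) / step)``, with window ``i`` covering
``[start + i*step, start + (i+1)*step)`` and the final window closed on
the right at ``stop`` so the maximum-m/z peak is never orphaned.  A
degenerate range (or a step wider than the range) yields one window.
Windows where a sample detected no peak are recorded in a missing mask
and filled with 0 — the natural mass-spectrometric reading of "no
signal detected".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort

__all__ = [
    "WindowGrid",
    "FeatureMatrix",
    "MissingStats",
    "scan_mz_range",
    "build_grid",
    "assign_windows",
    "construct_features",
    "missing_stats",
]


@dataclass(frozen=True)
class WindowGrid:
    """The m/z binning scheme: ``n_windows`` bins of width ``step`` from ``start``."""

    start: float
    stop: float
    step: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")

    @property
    def feature_names(self) -> list[str]:
        return [f"F_{i}" for i in range(self.n_windows)]

    def to_dict(self) -> dict:
        return {"start": self.start, "stop": self.stop, "step": self.step,
                "n_windows": self.n_windows}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowGrid":
        return cls(float(d["start"]), float(d["stop"]), float(d["step"]),
                   int(d["n_windows"]))


@dataclass
class FeatureMatrix:
    """Samples x windows table of per-window mean intensity plus missing mask."""

    peak_type: str
    values: np.ndarray          # (n_samples, n_windows), missing cells filled
    missing_mask: np.ndarray    # bool, True where the sample had no peak
    grid: WindowGrid
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return self.grid.feature_names

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.feature_names)
        df.index.name = "sample_id"
        return df


@dataclass(frozen=True)
class MissingStats:
    """Per-class mean count of missing windows per sample."""

    mean_missing_positive: float
    mean_missing_negative: float


def scan_mz_range(cohort: Cohort) -> tuple[float, float]:
    """Global (min, max) m/z over every peak of every sample."""
    if len(cohort) == 0:
        raise ValueError("cannot scan an empty cohort")
    lo = min(s.mz.min() for s in cohort)
    hi = max(s.mz.max() for s in cohort)
    return float(lo), float(hi)


def build_grid(min_mz: float, max_mz: float, step: float) -> WindowGrid:
    """Build the window grid; ``n_windows = floor(range / step)``, at least 1."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if max_mz < min_mz:
        raise ValueError("max_mz must be >= min_mz")
    n = int(np.floor((max_mz - min_mz) / step))
    n = max(n, 1)
    return WindowGrid(start=float(min_mz), stop=float(max_mz), step=float(step),
                      n_windows=n)


def assign_windows(mz: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Window index per peak: ``min(floor((mz - start)/step), n_windows - 1)``.

    Each in-range peak lands in exactly one window; the clamp closes the
    last window on the right at the grid stop.
    """
    idx = np.floor((np.asarray(mz, dtype=float) - grid.start) / grid.step)
    return np.minimum(idx, grid.n_windows - 1).astype(int)


def construct_features(cohort: Cohort, grid: WindowGrid, peak_type: str) -> FeatureMatrix:
    """Aggregate each sample's peaks into per-window mean height or area.

    Raises if any peak's m/z falls outside ``[grid.start, grid.stop]`` —
    the caller should rebuild the grid from a fresh range scan.
    """
    if peak_type not in ("height", "area"):
        raise ValueError(f"peak_type must be 'height' or 'area', got {peak_type!r}")
    n_s, n_w = len(cohort), grid.n_windows
    values = np.zeros((n_s, n_w))
    counts = np.zeros((n_s, n_w), dtype=int)
    for si, sample in enumerate(cohort):
        mz = sample.mz
        out = (mz < grid.start) | (mz > grid.stop)
        if out.any():
            bad = mz[out][0]
            raise ValueError(
                f"sample {sample.sample_id!r}: peak m/z {bad} outside grid "
                f"[{grid.start}, {grid.stop}]; rebuild the grid"
            )
        idx = assign_windows(mz, grid)
        np.add.at(values[si], idx, sample.intensity(peak_type))
        np.add.at(counts[si], idx, 1)
    missing = counts == 0
    with np.errstate(invalid="ignore"):
        values = np.where(missing, 0.0, values / np.maximum(counts, 1))
    return FeatureMatrix(peak_type=peak_type, values=values, missing_mask=missing,
                         grid=grid, sample_ids=list(cohort.sample_ids))


def missing_stats(matrix: FeatureMatrix, cohort: Cohort) -> MissingStats:
    """Mean missing-window count per sample, split by class."""
    if matrix.n_samples != len(cohort):
        raise ValueError("matrix rows do not align with cohort samples")
    per_sample = matrix.missing_mask.sum(axis=1)
    y = cohort.y
    pos = float(per_sample[y == 1].mean()) if (y == 1).any() else 0.0
    neg = float(per_sample[y == 0].mean()) if (y == 0).any() else 0.0
    return MissingStats(mean_missing_positive=pos, mean_missing_negative=neg)
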