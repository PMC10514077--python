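"""Reading peak-list exports and sample manifests; writing feature tables.

A *feature list* is the per-sample CSV table exported by peak-picking
software (one row per detected chromatographic-mass feature).  Only four
columns matter downstream — mass-to-charge ratio, retention time, peak
height and peak area — and the export typically carries many more; the
mapping from those four roles to actual column headers is configuration,
not auto-detection, because header names vary between software versions.

A *manifest* is a small CSV/TSV listing one feature-list file per sample
together with its class label and acquisition batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mzwin")

#: label normalization: anything on the left maps to the token on the right
POSITIVE_TOKENS = {"p", "pos", "positive", "disease", "diseased", "sick", "case", "1"}
NEGATIVE_TOKENS = {"n", "neg", "negative", "health", "healthy", "control", "0"}

POSITIVE = "positive"
NEGATIVE = "negative"

#: default column mapping for MZmine-style exports (role -> header)
DEFAULT_COLUMN_MAP = {
    "mz": "Mass",
    "rt": "retention-time",
    "height": "peak-height",
    "area": "peak-area",
}


class ConfigurationError(ValueError):
    """A mapped column or label token is missing or unrecognized."""


class EmptySampleError(ValueError):
    """A feature list yielded zero valid peaks."""


@dataclass(frozen=True)
class PeakRecord:
    """One detected feature: m/z (Da), RT (min), height and area (counts)."""

    mz: float
    rt: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mz) and self.mz > 0):
            raise ValueError(f"mz must be finite and > 0, got {self.mz}")
        for name in ("rt", "height", "area"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class SamplePeakList:
    """A labeled, batched peak list for one sample; lengths vary by sample."""

    sample_id: str
    label: str
    batch: str
    peaks: list[PeakRecord]

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be normalized, got {self.label!r}")
        if not self.peaks:
            raise EmptySampleError(f"sample {self.sample_id!r} has no peaks")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def intensity(self, peak_type: str) -> np.ndarray:
        if peak_type not in ("height", "area"):
            raise ValueError(f"peak_type must be 'height' or 'area', got {peak_type!r}")
        return np.array([getattr(p, peak_type) for p in self.peaks])


@dataclass
class Cohort:
    """A collection of samples with unique ids."""

    samples: list[SamplePeakList] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def batches(self) -> np.ndarray:
        return np.array([s.batch for s in self.samples])

    @property
    def y(self) -> np.ndarray:
        """Binary label vector, 1 = positive (disease), 0 = negative."""
        return (self.labels == POSITIVE).astype(int)

    def require_two_classes(self) -> None:
        if len(set(self.labels)) < 2:
            raise ValueError("cohort must contain both classes for supervised stages")


def normalize_label(token: str) -> str:
    t = str(token).strip().lower()
    if t in POSITIVE_TOKENS:
        return POSITIVE
    if t in NEGATIVE_TOKENS:
        return NEGATIVE
    raise ConfigurationError(f"unknown label token {token!r}")


def read_feature_list(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    label: str = POSITIVE,
    batch: str = "1",
    delimiter: str = ",",
) -> SamplePeakList:
    """Read one per-sample feature-list CSV into a :class:`SamplePeakList`.

    Rows whose mapped cells fail numeric parsing, or carry negative
    intensities or non-positive m/z, are dropped with a logged count
    rather than aborting the read (real exports carry sentinel rows).

    Parameters
    ----------
    path:
        CSV file exported by the peak picker.
    column_map:
        Mapping of the four roles ``mz``, ``rt``, ``height``, ``area`` to
        column headers.  Defaults to :data:`DEFAULT_COLUMN_MAP`.  Extra
        columns in the file are ignored.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for role in ("mz", "rt", "height", "area"):
        if role not in cmap:
            raise ConfigurationError(f"column_map lacks a column for role {role!r}")

    table = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    missing = [c for c in cmap.values() if c not in table.columns]
    if missing:
        roles = [r for r, c in cmap.items() if c in missing]
        raise ConfigurationError(
            f"{path.name}: mapped column(s) {missing} for role(s) {roles} not found"
        )

    raw = table[[cmap["mz"], cmap["rt"], cmap["height"], cmap["area"]]].copy()
    raw.columns = ["mz", "rt", "height", "area"]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    valid = (
        numeric.notna().all(axis=1)
        & (numeric["mz"] > 0)
        & (numeric[["rt", "height", "area"]] >= 0).all(axis=1)
        & np.isfinite(numeric).all(axis=1)
    )
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%s: dropped %d unparseable/invalid row(s)", path.name, n_bad)
    numeric = numeric[valid]
    if numeric.empty:
        raise EmptySampleError(f"{path}: no valid peak rows")

    peaks = [
        PeakRecord(mz=r.mz, rt=r.rt, height=r.height, area=r.area)
        for r in numeric.itertuples(index=False)
    ]
    return SamplePeakList(
        sample_id=sample_id or path.stem, label=label, batch=str(batch), peaks=peaks
    )


def read_manifest(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> Cohort:
    """Assemble a :class:`Cohort` from a manifest of (file, label, batch) rows.

    Relative file paths are resolved against the manifest's directory.
    Labels are normalized to positive/negative at read time.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ("\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    man = pd.read_csv(path, sep=sep)
    for col in ("file", "label", "batch"):
        if col not in man.columns:
            raise ConfigurationError(f"manifest lacks required column {col!r}")

    samples = []
    for row in man.itertuples(index=False):
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"manifest lists unreadable file: {fpath}")
        label = normalize_label(row.label)
        sid = getattr(row, "sample_id", None) or fpath.stem
        samples.append(
            read_feature_list(
                fpath, column_map, sample_id=str(sid), label=label, batch=str(row.batch)
            )
        )
    return Cohort(samples=samples)


def write_feature_list(sample: SamplePeakList, path: str | Path,
                       column_map: Mapping[str, str] | None = None) -> None:
    """Write a peak list back to the canonical CSV form (round-trippable)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.DataFrame(
        {
            cmap["mz"]: [p.mz for p in sample.peaks],
            cmap["rt"]: [p.rt for p in sample.peaks],
            cmap["height"]: [p.height for p in sample.peaks],
            cmap["area"]: [p.area for p in sample.peaks],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 manifest_name: str = "manifest.csv") -> Path:
    """Write one CSV per sample plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.sample_id}.csv"
        write_feature_list(s, out_dir / fname)
        rows.append({"file": fname, "label": s.label, "batch": s.batch,
                     "sample_id": s.sample_id})
    mpath = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


def write_matrix_csv(values: np.ndarray, sample_ids: Sequence[str],
                     feature_names: Sequence[str], path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(sample_ids),
                      columns=list(feature_names))
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
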