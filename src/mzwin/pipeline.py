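"""End-to-end pipeline: cohort -> grids -> selection -> reports.

A run is fully described by a :class:`RunConfig` (serializable, hashed
into every artifact) and produces, per window step and peak type, a
sub-directory containing the feature matrix with its grid sidecar, the
chi-square ranking, the chosen minimal subset with validation/test
metrics, the back-mapped mass intervals, marker candidates from the
common-mass traversal, and the two-feature scatter coordinates.  A
machine-readable ``summary.json`` at the top level compares steps by the
number of features their best model needed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .construct import build_grid, construct_features, missing_stats, scan_mz_range, WindowGrid
from .massmap import back_map, common_mass_traversal, scatter_export
from .models import SplitSpec, default_specs, make_splits
from .select import minimal_subset_search, rank_features
from .simulate import SynthConfig, default_config, generate_cohort

logger = logging.getLogger("mzwin")


@dataclass
class RunConfig:
    manifest: str | None = None        # read a real cohort ...
    simulate: dict = field(default_factory=dict)  # ... or generate one
    out_dir: str = "mzwin_run"
    steps: list[float] = field(default_factory=lambda: [1.0])
    peak_types: list[str] = field(default_factory=lambda: ["height", "area"])
    method: str = "frequency"          # chi-square form
    k_max: int = 20
    split: dict = field(default_factory=lambda: {"strategy": "ratio", "ratio": "2:1"})
    decimals: int = 3                  # mass rounding in the traversal
    min_support: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_cohort(config: RunConfig):
    if config.manifest:
        return mio.read_manifest(config.manifest)
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    return generate_cohort(default_config(**sim))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    mio.write_json({**stamp, "config": config.to_dict()}, out / "run_config.json")

    cohort = _load_cohort(config)
    cohort.require_two_classes()
    y = cohort.y
    lo, hi = scan_mz_range(cohort)
    logger.info("cohort: %d samples, global m/z range %.4f-%.4f", len(cohort), lo, hi)

    split_spec = SplitSpec(**config.split, seed=config.seed)
    train, val, test = make_splits(cohort, split_spec)

    summary: dict = {**stamp, "n_samples": len(cohort),
                     "mz_range": [lo, hi], "results": []}
    for step in config.steps:
        grid = build_grid(lo, hi, step)
        step_dir = out / f"step_{step:g}"
        step_dir.mkdir(exist_ok=True)
        mio.write_json({**stamp, **grid.to_dict()}, step_dir / "grid.json")
        for peak_type in config.peak_types:
            pt_dir = step_dir / peak_type
            pt_dir.mkdir(exist_ok=True)
            matrix = construct_features(cohort, grid, peak_type)
            mio.write_matrix_csv(matrix.values, matrix.sample_ids,
                                 matrix.feature_names, pt_dir / "features.csv")
            ms = missing_stats(matrix, cohort)
            mio.write_json({**stamp,
                            "mean_missing_positive": ms.mean_missing_positive,
                            "mean_missing_negative": ms.mean_missing_negative},
                           pt_dir / "missing_stats.json")

            ranking = rank_features(matrix, y, method=config.method)
            pd.DataFrame(
                [{"rank": r, "feature_index": s.feature_index, "chi2": s.chi2}
                 for r, s in enumerate(ranking)]
            ).to_csv(pt_dir / "chi2_ranking.csv", index=False)

            result = minimal_subset_search(
                matrix, y, train, val, test,
                models=default_specs(seed=config.seed),
                k_max=config.k_max, method=config.method)
            mio.write_json({**stamp, **result.to_dict()}, pt_dir / "subset.json")

            intervals = [back_map(i, grid) for i in result.feature_indices]
            pd.DataFrame(
                [{"feature_index": iv.feature_index, "low": iv.low, "high": iv.high}
                 for iv in intervals]
            ).to_csv(pt_dir / "mass_intervals.csv", index=False)

            cands = common_mass_traversal(
                cohort, intervals[0], decimals=config.decimals,
                min_support=config.min_support)
            pd.DataFrame([dataclasses.asdict(c) for c in cands]).to_csv(
                pt_dir / "marker_candidates.csv", index=False)

            pair = (result.feature_indices[0],
                    result.feature_indices[1 if result.k > 1 else 0])
            scatter_export(matrix, pair, cohort.labels).to_csv(
                pt_dir / "scatter.csv", index=False)

            summary["results"].append({
                "step": step, "peak_type": peak_type,
                "n_windows": grid.n_windows, "k": result.k,
                "model": result.model_name,
                "val_accuracy": result.validation.accuracy,
                "test_accuracy": result.test.accuracy,
                "feature_indices": list(map(int, result.feature_indices)),
            })

    # the preferred step uses the fewest features at the highest validation accuracy
    best = min(summary["results"],
               key=lambda r: (-r["val_accuracy"], r["k"], r["step"]))
    summary["best"] = {k: best[k] for k in ("step", "peak_type", "k", "model",
                                            "val_accuracy", "test_accuracy")}
    mio.write_json(summary, out / "summary.json")
    return summary
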