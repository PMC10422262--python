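"""Experiment orchestration: feature-set comparison, channel combinations,
threshold sweep.

These reproduce, on synthetic data, the three experiment designs of the
study this pipeline implements: (1) compare the seven feature-family
combinations, (2) compare 3-channel subsets against the full 4-channel
montage, (3) sweep the binarization threshold T and track accuracy and the
number of selected features.  Each run records its spec and seeds in a
manifest so results are reproducible byte for byte.  Wall times are
reported, never asserted — they depend on hardware.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FAMILY_ORDER, FeatureMatrix, FeatureParams, build_feature_matrix
from .optimizers import OptimizerConfig
from .selection import CVConfig, SelectionMask, evaluate_mask, select_features
from .synthetic import GeneratorConfig, generate_dataset

#: The seven family combinations compared in the feature-set experiment.
DEFAULT_FEATURE_SETS = (
    ("TD",),
    ("TD", "FD"),
    ("TD", "WE"),
    ("TD", "NLD"),
    ("TD", "FD", "WE"),
    ("TD", "FD", "NLD"),
    ("FD", "WE"),
)

DEFAULT_THRESHOLD_GRID = (0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6)


@dataclass
class ExperimentSpec:
    """What to run: dataset, conditions, optimizer budget, seeds, output."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    feature_sets: tuple = DEFAULT_FEATURE_SETS
    threshold_grid: tuple = DEFAULT_THRESHOLD_GRID
    algorithms: tuple = ("csa", "goa")
    seeds: tuple = (0,)
    transfer_name: str = "S1"
    threshold: float = 0.5
    pop_size: int = 20
    max_iter: int = 50
    cv_folds: int = 10
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed required")
        if any(not (0 < t < 1) for t in self.threshold_grid):
            raise ValueError("threshold grid must lie inside (0, 1)")


def _dataset_matrix(spec: ExperimentSpec, channels=None, families=FAMILY_ORDER) -> FeatureMatrix:
    segments = generate_dataset(spec.generator)
    return build_feature_matrix(
        segments, spec.generator.fs, channels=channels,
        families=families, params=spec.feature_params,
    )


def _write(df: pd.DataFrame, spec: ExperimentSpec, name: str) -> None:
    if spec.out_dir is None:
        return
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    df.to_json(out / f"{name}.json", orient="records", indent=2)
    manifest = {
        "experiment": name,
        "seeds": list(spec.seeds),
        "algorithms": list(spec.algorithms),
        "threshold": spec.threshold,
        "threshold_grid": list(spec.threshold_grid),
        "transfer": spec.transfer_name,
        "pop_size": spec.pop_size,
        "max_iter": spec.max_iter,
        "cv_folds": spec.cv_folds,
        "generator_seed": spec.generator.seed,
        "reps_per_class": spec.generator.reps_per_class,
    }
    with open(out / f"{name}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _run_selection(fm: FeatureMatrix, spec: ExperimentSpec, algorithm: str,
                   seed: int, T: float):
    cfg = OptimizerConfig(
        dim=fm.n_features, pop_size=spec.pop_size, max_iter=spec.max_iter, seed=seed
    )
    cv = CVConfig(n_folds=spec.cv_folds, seed=seed)
    return select_features(
        fm, algorithm=algorithm, T=T, tf_name=spec.transfer_name, opt_cfg=cfg, cv=cv
    )


def run_feature_set_comparison(spec: ExperimentSpec) -> pd.DataFrame:
    """Selection accuracy, selected count and wall time per feature set."""
    segments = generate_dataset(spec.generator)
    rows = []
    for families in spec.feature_sets:
        fm = build_feature_matrix(
            segments, spec.generator.fs, families=families, params=spec.feature_params
        )
        for algorithm, seed in itertools.product(spec.algorithms, spec.seeds):
            t0 = time.perf_counter()
            rep = _run_selection(fm, spec, algorithm, seed, spec.threshold)
            rows.append(
                {
                    "feature_set": "+".join(families),
                    "algorithm": algorithm,
                    "seed": seed,
                    "n_features": fm.n_features,
                    "mean_acc": rep.mean_acc,
                    "mean_R": rep.mean_R,
                    "wall_time_s": time.perf_counter() - t0,
                }
            )
    df = pd.DataFrame(rows)
    _write(df, spec, "feature_set_comparison")
    return df


def run_channel_combinations(spec: ExperimentSpec) -> pd.DataFrame:
    """Selection accuracy per channel subset: all 3-subsets plus the full set."""
    segments = generate_dataset(spec.generator)
    n_ch = spec.generator.n_channels
    subsets = [list(c) for c in itertools.combinations(range(n_ch), n_ch - 1)]
    subsets.append(list(range(n_ch)))
    rows = []
    for channels in subsets:
        fm = build_feature_matrix(
            segments, spec.generator.fs, channels=channels, params=spec.feature_params
        )
        for algorithm, seed in itertools.product(spec.algorithms, spec.seeds):
            rep = _run_selection(fm, spec, algorithm, seed, spec.threshold)
            rows.append(
                {
                    "channels": "+".join(str(c + 1) for c in channels),
                    "algorithm": algorithm,
                    "seed": seed,
                    "n_features": fm.n_features,
                    "mean_acc": rep.mean_acc,
                    "mean_R": rep.mean_R,
                }
            )
    df = pd.DataFrame(rows)
    _write(df, spec, "channel_combinations")
    return df


def run_threshold_sweep(
    spec: ExperimentSpec, fm: FeatureMatrix | None = None
) -> pd.DataFrame:
    """Accuracy, selected count and per-class rates across the T grid.

    Returns one row per (T, algorithm, seed); aggregation is left to the
    caller (``groupby(["T", "algorithm"])``).  Per-class recognition rates
    are included as columns ``rate_<class>``.  A precomputed feature matrix
    of the spec's dataset may be passed to skip re-extraction.
    """
    if fm is None:
        fm = _dataset_matrix(spec)
    rows = []
    for T, algorithm, seed in itertools.product(
        spec.threshold_grid, spec.algorithms, spec.seeds
    ):
        rep = _run_selection(fm, spec, algorithm, seed, T)
        row = {
            "T": T,
            "algorithm": algorithm,
            "seed": seed,
            "mean_acc": rep.mean_acc,
            "R": rep.mask.R,
        }
        for cls, rate in zip(rep.confusion.classes, rep.per_class_rates):
            row[f"rate_{cls}"] = rate
        rows.append(row)
    df = pd.DataFrame(rows)
    _write(df, spec, "threshold_sweep")
    return df


def full_feature_baseline(spec: ExperimentSpec, channels=None) -> float:
    """Cross-validated accuracy with every feature kept (selector bypassed)."""
    fm = _dataset_matrix(spec, channels=channels)
    mask = SelectionMask(bits=np.ones(fm.n_features, dtype=bool))
    cv = CVConfig(n_folds=spec.cv_folds, seed=spec.seeds[0])
    return evaluate_mask(mask, fm, cv).mean_acc
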