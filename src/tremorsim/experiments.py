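"""Classification studies: axis ablations and sensor-quality combinations.

``run_experiment`` trains and evaluates one train-sensor / test-sensor /
channel-subset configuration; ``run_matrix`` runs several configurations
against the *same* underlying trials — identical ideal trajectories,
tremor events and noise draws, with only the sensor model and channel
subset varying — so differences between reports isolate the metrological
variable.  The canonical quality matrix is

    best/best    train mmr,            test mmr
    best/worst   train mmr,            test mmr_8bit_noisy
    worst/best   train mmr_8bit,       test mmr
    worst/worst  train mmr_8bit_noisy, test mmr_8bit_noisy

Three seeds (data, split, tree) are kept separate so each variance source
can be frozen independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tremorsim.dataset import (CHANNEL_NAMES, DatasetConfig, LabeledWindowSet,
                               generate_windows_multi, split_indices)
from tremorsim.features import (extract_features_batch, feature_column_names,
                                zscore_normalize)
from tremorsim.classify import ClassificationReport, train_tree, evaluate

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "run_matrix", "QUALITY_MATRIX"]

#: (name, train_sensor, test_sensor) triples of the quality study.
QUALITY_MATRIX = [
    ("best_best", "mmr", "mmr"),
    ("best_worst", "mmr", "mmr_8bit_noisy"),
    ("worst_best", "mmr_8bit", "mmr"),
    ("worst_worst", "mmr_8bit_noisy", "mmr_8bit_noisy"),
]


@dataclass
class ExperimentConfig:
    """One train/test sensor pairing over a channel subset."""

    train_sensor: str = "mmr"
    test_sensor: str = "mmr"
    channels: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))
    n_trials_per_task: int = 200
    balance_target: int | None = 10_000
    train_frac: float = 0.7
    max_splits: int = 100
    seed_data: int = 0
    seed_split: int = 0
    seed_tree: int = 0
    dataset: DatasetConfig | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channel subset must be non-empty")

    def dataset_config(self) -> DatasetConfig:
        base = self.dataset or DatasetConfig()
        return replace(base, n_trials_per_task=self.n_trials_per_task,
                       balance_target=self.balance_target, seed=self.seed_data)


@dataclass
class ExperimentResult:
    name: str
    config: ExperimentConfig
    report: ClassificationReport
    n_train: int
    n_test: int

    @property
    def accuracy(self) -> float:
        return self.report.accuracy


def _features_for(ws: LabeledWindowSet) -> np.ndarray:
    return extract_features_batch(ws.windows, ws.fs)


def _column_subset(feature_names: list[str], channels: list[str]) -> list[int]:
    return [i for i, nm in enumerate(feature_names)
            if nm.split("__")[0] in channels]


def run_matrix(base: ExperimentConfig, combinations) -> tuple[dict[str, ExperimentResult], pd.DataFrame]:
    """Run several (name, train_sensor, test_sensor[, channels]) combinations
    on shared trials.

    Returns (results by name, summary table).  A failing combination is
    recorded in the summary with its error; completed results are kept.
    """
    combos = []
    for combo in combinations:
        if len(combo) == 3:
            name, tr, te = combo
            ch = list(base.channels)
        else:
            name, tr, te, ch = combo
            ch = list(ch)
        combos.append((name, tr, te, ch))
    if not combos:
        raise ValueError("need at least one combination")

    sensors = sorted({s for _, tr, te, _ in combos for s in (tr, te)})
    dcfg = base.dataset_config()
    sets = generate_windows_multi(dcfg, sensors)
    any_set = next(iter(sets.values()))
    labels = any_set.labels
    tr_idx, te_idx = split_indices(labels, base.train_frac, base.seed_split)
    all_names = feature_column_names(any_set.channel_names)
    feats = {name: _features_for(ws) for name, ws in sets.items()}

    results: dict[str, ExperimentResult] = {}
    rows = []
    for name, tr_sensor, te_sensor, channels in combos:
        try:
            cols = _column_subset(all_names, channels)
            if not cols:
                raise ValueError(f"no features for channel subset {channels}")
            x_tr = feats[tr_sensor][np.ix_(tr_idx, cols)]
            x_te = feats[te_sensor][np.ix_(te_idx, cols)]
            y_tr, y_te = labels[tr_idx], labels[te_idx]
            x_tr_z, x_te_z, _, _ = zscore_normalize(x_tr, x_te)
            model = train_tree(x_tr_z, y_tr, max_splits=base.max_splits,
                               seed=base.seed_tree)
            report = evaluate(model, x_te_z, y_te)
            cfg = replace(base, train_sensor=tr_sensor, test_sensor=te_sensor,
                          channels=channels)
            results[name] = ExperimentResult(name, cfg, report,
                                             len(tr_idx), len(te_idx))
            rows.append({"name": name, "train_sensor": tr_sensor,
                         "test_sensor": te_sensor,
                         "n_channels": len(channels),
                         "accuracy_pct": report.accuracy, "error": ""})
        except Exception as exc:  # keep completed runs on partial failure
            rows.append({"name": name, "train_sensor": tr_sensor,
                         "test_sensor": te_sensor, "n_channels": len(channels),
                         "accuracy_pct": np.nan,
                         "error": f"{type(exc).__name__}: {exc}"})
    summary = pd.DataFrame(rows).set_index("name")
    done = summary.dropna(subset=["accuracy_pct"])
    for a in done.index:
        for b in done.index:
            if a < b:
                summary.loc[a, f"delta_vs_{b}"] = (
                    done.loc[a, "accuracy_pct"] - done.loc[b, "accuracy_pct"])
    return results, summary


ACCEL_CHANNELS = ["accel_x", "accel_y", "accel_z"]

#: The full study: the four sensor-quality combinations plus the
#: accelerometer-only ablation of the matched-sensor run.
STUDY_COMBOS = [
    ("best_best", "mmr", "mmr"),
    ("accel_only", "mmr", "mmr", ACCEL_CHANNELS),
    ("worst_best", "mmr_8bit", "mmr"),
    ("best_worst", "mmr", "mmr_8bit_noisy"),
    ("worst_worst", "mmr_8bit_noisy", "mmr_8bit_noisy"),
]


def run_quality_study(n_trials_per_task: int = 200, seed: int = 0,
                      combos=None) -> tuple[dict[str, ExperimentResult], pd.DataFrame]:
    """Run the full sensor-quality study on one shared trial corpus.

    Data, split and tree seeds derive from ``seed`` (seed, seed+1, seed+2)
    so a single integer reproduces the whole study.
    """
    cfg = ExperimentConfig(n_trials_per_task=n_trials_per_task,
                           seed_data=seed, seed_split=seed + 1,
                           seed_tree=seed + 2)
    return run_matrix(cfg, combos or STUDY_COMBOS)


def run_experiment(cfg: ExperimentConfig, name: str = "run") -> ExperimentResult:
    """Generate data, train and evaluate a single configuration."""
    results, summary = run_matrix(
        cfg, [(name, cfg.train_sensor, cfg.test_sensor, cfg.channels)])
    if name not in results:
        raise RuntimeError(f"experiment failed: {summary.loc[name, 'error']}")
    return results[name]
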