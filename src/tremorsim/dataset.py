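"""Trial generation, windowing, labeling, balancing and splitting.

The trial protocol pairs each assessment task with the tremor class it
elicits clinically: postural hold -> postural tremor, finger-to-nose ->
kinetic tremor, rest -> rest tremor.  Every trial is 60 s and carries five
disjoint 2 s tremor bursts; windows of 2 s with 1 s overlap are labeled
with the tremor class when at least half the window lies inside a burst,
otherwise class 1 (no tremor).  Healthy (class-1) windows therefore come
from all three tasks.

Class numbering follows the reporting convention 1 = no tremor,
2 = postural, 3 = rest, 4 = kinetic (configurable).

The raw protocol yields roughly five class-1 windows per tremor window;
balancing down-samples every class to a common per-class target
(``balance_target / n_classes``, capped by the smallest class), giving the
default corpus of about 10,000 windows at the full 1000-trial protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

from tremorsim.sensor_model import InertialRecord, get_preset, apply_sensor_model
from tremorsim.trajectory import (TaskId, MotionParams, make_task_trajectory,
                                  trajectory_to_inertial)
from tremorsim.tremor import TremorSpec, TremorEvent, inject_tremor

__all__ = [
    "CHANNEL_NAMES", "DEFAULT_CLASS_MAP", "DEFAULT_TASK_TREMOR",
    "LabeledWindowSet", "DatasetConfig", "window_record", "label_windows",
    "generate_dataset", "generate_windows_multi", "train_test_split_windows",
]

CHANNEL_NAMES = ["accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z"]

#: class label per tremor class (1 is always "no tremor")
DEFAULT_CLASS_MAP = {"PT": 2, "RT": 3, "KT": 4}

#: which tremor class each task elicits
DEFAULT_TASK_TREMOR = {
    TaskId.postural_hold: "PT",
    TaskId.finger_to_nose: "KT",
    TaskId.rest: "RT",
}


@dataclass
class LabeledWindowSet:
    """Fixed-length windows with per-window labels and provenance.

    windows: (n_windows, n_channels, n_samples) float32
    labels:  (n_windows,) int in {1, 2, 3, 4}
    provenance: DataFrame with task, sensor, trial, start_s columns
    """

    windows: np.ndarray
    labels: np.ndarray
    fs: float
    window_s: float
    channel_names: list[str]
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.shape[0] != self.labels.shape[0]:
            raise ValueError("windows and labels must align")
        if len(self.provenance) != len(self.labels):
            raise ValueError("provenance and labels must align")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, indices) -> "LabeledWindowSet":
        indices = np.asarray(indices)
        return LabeledWindowSet(
            self.windows[indices], self.labels[indices], self.fs, self.window_s,
            list(self.channel_names),
            self.provenance.iloc[indices].reset_index(drop=True))

    def channel_indices(self, channels) -> list[int]:
        return [self.channel_names.index(c) for c in channels]

    def select_channels(self, channels) -> "LabeledWindowSet":
        idx = self.channel_indices(channels)
        return LabeledWindowSet(
            self.windows[:, idx, :], self.labels, self.fs, self.window_s,
            list(channels), self.provenance)


@dataclass
class DatasetConfig:
    """Everything needed to regenerate a window corpus deterministically."""

    sensor: str = "mmr"
    n_trials_per_task: int = 1000
    trial_duration: float = 60.0
    reference_rate: float = 1000.0       # ideal-trajectory synthesis rate
    window_s: float = 2.0
    overlap_s: float = 1.0
    min_overlap_frac: float = 0.5
    balance_target: int | None = 10_000
    seed: int = 0
    channels: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES))
    class_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    task_tremor: dict = field(default_factory=lambda: dict(DEFAULT_TASK_TREMOR))
    tremor_spec: TremorSpec | None = None    # template; class set per task
    motion_params: MotionParams | None = None

    def tremor_for(self, task: TaskId) -> TremorSpec:
        cls = self.task_tremor[TaskId(task)]
        base = self.tremor_spec or TremorSpec(tremor_class=cls)
        return replace(base, tremor_class=cls,
                       freq_band=None if base.tremor_class != cls else base.freq_band,
                       trial_duration=self.trial_duration)


def window_record(record: InertialRecord, window_s: float = 2.0,
                  overlap_s: float = 1.0,
                  channels: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Slice a record into overlapping windows.

    Returns (windows, start_times): windows has shape
    (n_windows, n_channels, window_s * fs); the hop is window_s - overlap_s
    and any trailing partial window is dropped.
    """
    if overlap_s >= window_s:
        raise ValueError("overlap must be smaller than the window")
    fs = record.sample_rate
    chans = channels or CHANNEL_NAMES
    data = np.vstack([record.accel, record.gyro, record.mag])
    all_names = CHANNEL_NAMES + ["mag_x", "mag_y", "mag_z"]
    data = data[[all_names.index(c) for c in chans]]
    wlen = int(round(window_s * fs))
    hop = int(round((window_s - overlap_s) * fs))
    n = data.shape[1]
    if n < wlen:
        return np.empty((0, len(chans), wlen), dtype=np.float32), np.empty(0)
    count = (n - wlen) // hop + 1
    windows = np.empty((count, len(chans), wlen), dtype=np.float32)
    starts = np.empty(count)
    for i in range(count):
        s = i * hop
        windows[i] = data[:, s:s + wlen]
        starts[i] = s / fs
    return windows, starts


def label_windows(window_starts: np.ndarray, window_s: float,
                  events: list[TremorEvent], tremor_label: int,
                  min_overlap_frac: float = 0.5) -> np.ndarray:
    """Label a window with the tremor class iff its temporal intersection
    with any event reaches ``min_overlap_frac * window_s``; else class 1."""
    starts = np.asarray(window_starts, dtype=float)
    labels = np.ones(len(starts), dtype=int)
    thresh = min_overlap_frac * window_s
    for ev in events:
        inter = (np.minimum(starts + window_s, ev.end)
                 - np.maximum(starts, ev.start))
        labels[inter >= thresh - 1e-12] = tremor_label
    return labels


def _balanced_indices(labels: np.ndarray, target_total: int | None,
                      rng: np.random.Generator) -> np.ndarray:
    classes, counts = np.unique(labels, return_counts=True)
    per_class = counts.min()
    if target_total is not None:
        per_class = min(per_class, target_total // len(classes))
    if per_class < 1:
        raise ValueError(f"infeasible balance target; class counts: "
                         f"{dict(zip(classes.tolist(), counts.tolist()))}")
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=per_class, replace=False))
    return np.sort(np.concatenate(keep))


def generate_windows_multi(config: DatasetConfig,
                           sensors: list[str]) -> dict[str, LabeledWindowSet]:
    """Generate the window corpus through several sensor models at once.

    All sensors see the identical ideal trajectories, tremor events and
    underlying noise draws — only the metrological model differs — so
    cross-sensor experiments isolate the sensor variable.  Balancing picks
    the same window indices for every sensor.
    """
    specs = {name: get_preset(name) for name in sensors}
    out_fs = {spec.sample_rate for spec in specs.values()}
    if len(out_fs) != 1:
        raise ValueError("all sensor presets must share an output rate")
    mp = config.motion_params or MotionParams()

    per_sensor: dict[str, list[np.ndarray]] = {name: [] for name in sensors}
    all_labels: list[np.ndarray] = []
    prov_rows: list[dict] = []
    tasks = list(config.task_tremor.keys())
    for ti, task in enumerate(tasks):
        spec_t = config.tremor_for(task)
        label = config.class_map[spec_t.tremor_class]
        for trial in range(config.n_trials_per_task):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(ti, trial))
            traj_ss, tremor_ss, sensor_ss = ss.spawn(3)
            traj = make_task_trajectory(task, config.trial_duration,
                                        config.reference_rate, mp,
                                        np.random.default_rng(traj_ss))
            ideal = trajectory_to_inertial(traj)
            path, events = inject_tremor(ideal, spec_t,
                                         np.random.default_rng(tremor_ss))
            labels = None
            for name, spec in specs.items():
                # a fresh generator from the same SeedSequence gives every
                # sensor model the identical underlying noise stream
                noisy = apply_sensor_model(path, spec,
                                           np.random.default_rng(sensor_ss))
                windows, starts = window_record(noisy, config.window_s,
                                                config.overlap_s, config.channels)
                per_sensor[name].append(windows)
                if labels is None:
                    labels = label_windows(starts, config.window_s, events,
                                           label, config.min_overlap_frac)
            all_labels.append(labels)
            prov_rows.extend(
                {"task": TaskId(task).value, "trial": trial, "start_s": s}
                for s in starts)

    labels = np.concatenate(all_labels)
    prov = pd.DataFrame(prov_rows)
    if config.balance_target is None:
        keep = np.arange(len(labels))
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,)))
        keep = _balanced_indices(labels, config.balance_target, rng)

    fs = out_fs.pop()
    result = {}
    for name in sensors:
        stack = np.concatenate(per_sensor[name], axis=0)
        p = prov.copy()
        p["sensor"] = name
        ws = LabeledWindowSet(stack, labels, fs, config.window_s,
                              list(config.channels), p)
        result[name] = ws.subset(keep)
    return result


def generate_dataset(config: DatasetConfig) -> LabeledWindowSet:
    """Generate the balanced, labeled window corpus for one sensor preset."""
    return generate_windows_multi(config, [config.sensor])[config.sensor]


def train_test_split_windows(ws: LabeledWindowSet, train_frac: float = 0.7,
                             seed: int = 0) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Stratified train/test split of a window set (disjoint, exhaustive)."""
    tr, te = split_indices(ws.labels, train_frac, seed)
    return ws.subset(tr), ws.subset(te)


def split_indices(labels: np.ndarray, train_frac: float = 0.7,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 windows to stratify")
    idx = np.arange(len(labels))
    tr, te = _sk_split(idx, train_size=train_frac, stratify=labels,
                       random_state=int(seed) % (2 ** 32))
    return np.sort(tr), np.sort(te)
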