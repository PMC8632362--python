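"""Containers and I/O for multi-subject event-locked MEG.

The central object is :class:`MultiSubjectDataset`: for each of N subjects a
tensor of shape ``n_events x n_sensors x n_time`` holding the stimulus-locked
response to the same event stream (every subject saw the identical stimuli at
identical times, so event axes are aligned across subjects).  Cross-subject
models operate on the flattened two-dimensional view produced by
:func:`flatten`: a matrix ``X_i`` of shape ``n_events x d`` where each column
is one (sensor, time-bin) pair of subject ``i``.

Time convention
---------------
Time bins are labelled by the *start* offset of the bin from event onset, in
milliseconds, and bins are half-open intervals ``[t, t + bin_ms)``.  A
300-500 ms analysis window at 25 ms resolution therefore covers the bins whose
labels are 300, 325, ..., 475.

Flattening convention
---------------------
Columns are ordered sensor-major: all time bins of the first selected sensor,
then all time bins of the second, and so on.  :func:`flatten` and
:func:`unflatten` are exact inverses for any subset choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("megdenoise")

FORMAT_VERSION = "1.0"

REGIONS = (
    "left-temporal",
    "right-temporal",
    "left-parietal",
    "right-parietal",
    "left-occipital",
    "right-occipital",
    "left-frontal",
    "right-frontal",
    "other",
)

SENSOR_KINDS = ("gradiometer", "magnetometer")


class SensorTable:
    """Per-sensor metadata: identifier, kind, region label, 2-D layout position.

    Region labels are supplied metadata (they come from the recording montage),
    not inferred from geometry.  Layout coordinates exist only to define
    spatial neighborhoods for locally constrained cross-subject models.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sensor", "kind", "region", "x", "y"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sensor table missing columns: {sorted(missing)}")
        if frame["sensor"].duplicated().any():
            raise ValueError("sensor identifiers must be unique")
        bad_kind = set(frame["kind"]) - set(SENSOR_KINDS)
        if bad_kind:
            raise ValueError(f"unknown sensor kinds: {sorted(bad_kind)}")
        bad_region = set(frame["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region labels: {sorted(bad_region)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SensorTable) and self.frame.equals(other.frame)

    def indices(self, kind: str | None = None, region: str | Sequence[str] | None = None) -> np.ndarray:
        """Sensor indices matching a kind and/or region filter."""
        mask = np.ones(len(self.frame), dtype=bool)
        if kind is not None:
            mask &= (self.frame["kind"] == kind).to_numpy()
        if region is not None:
            regions = [region] if isinstance(region, str) else list(region)
            mask &= self.frame["region"].isin(regions).to_numpy()
        return np.flatnonzero(mask)

    def nearest(self, sensor_index: int, k: int) -> np.ndarray:
        """Indices of the ``k`` nearest sensors in layout coordinates.

        The sensor itself is always included (distance zero).  Ties are broken
        by sensor index so neighborhoods are deterministic.
        """
        if not 0 <= sensor_index < len(self.frame):
            raise IndexError(f"sensor index {sensor_index} out of range")
        if k < 1:
            raise ValueError("neighborhood size must be >= 1")
        xy = self.frame[["x", "y"]].to_numpy(float)
        d = np.hypot(*(xy - xy[sensor_index]).T)
        order = np.lexsort((np.arange(len(d)), d))
        return np.sort(order[: min(k, len(d))])


class StimulusTable:
    """Per-event word annotations: token, length, log-frequency, surprisal,
    and an optional fixed-dimension embedding vector (columns ``emb_0..``)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"token", "length", "log_frequency", "surprisal"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"stimulus table missing columns: {sorted(missing)}")
        if (frame["length"] < 1).any():
            raise ValueError("word_length must be >= 1")
        self.frame = frame.reset_index(drop=True)
        emb_cols = [c for c in frame.columns if c.startswith("emb_")]
        emb_cols.sort(key=lambda c: int(c.split("_")[1]))
        self._emb_cols = emb_cols

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, StimulusTable) and self.frame.equals(other.frame)

    @property
    def word_length(self) -> np.ndarray:
        return self.frame["length"].to_numpy(int)

    @property
    def log_frequency(self) -> np.ndarray:
        return self.frame["log_frequency"].to_numpy(float)

    @property
    def surprisal(self) -> np.ndarray:
        return self.frame["surprisal"].to_numpy(float)

    @property
    def embeddings(self) -> np.ndarray | None:
        if not self._emb_cols:
            return None
        return self.frame[self._emb_cols].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StimulusTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class MultiSubjectDataset:
    """Aligned event-locked MEG tensors for N subjects.

    Parameters
    ----------
    subjects
        Subject identifiers, in a fixed order.
    data
        Mapping subject id -> array of shape ``(n_events, n_sensors, n_time)``.
        Events are stimulus-locked and identical across subjects.
    time_axis
        Bin-start offsets from event onset in ms; strictly increasing with a
        constant step.
    sensors
        Sensor metadata shared by all subjects (index alignment is assumed:
        sensor ``j`` is the same helmet position in every subject).
    runs
        Half-open ``(start_event, end_event)`` intervals partitioning the
        event axis into acquisition runs.
    """

    subjects: list[str]
    data: dict[str, np.ndarray]
    time_axis: np.ndarray
    sensors: SensorTable
    runs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.subjects) != set(self.data):
            raise ValueError("subjects list and data keys disagree")
        shapes = {s: self.data[s].shape for s in self.subjects}
        ref = shapes[self.subjects[0]]
        if any(len(sh) != 3 for sh in shapes.values()):
            raise ValueError("each subject tensor must be 3-D (events x sensors x time)")
        if any(sh != ref for sh in shapes.values()):
            raise ValueError(f"subject tensor shapes differ: {shapes}")
        if ref[1] != len(self.sensors):
            raise ValueError(
                f"tensor has {ref[1]} sensors but sensor table has {len(self.sensors)}"
            )
        self.time_axis = np.asarray(self.time_axis, float)
        if ref[2] != len(self.time_axis):
            raise ValueError("time_axis length does not match tensor time dimension")
        steps = np.diff(self.time_axis)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time_axis must be strictly increasing with constant bin width")
        self._check_runs(ref[0])

    def _check_runs(self, n_events: int) -> None:
        runs = sorted(self.runs)
        if not runs:
            raise ValueError("runs must be non-empty")
        if runs[0][0] != 0 or runs[-1][1] != n_events:
            raise ValueError(f"runs must cover [0, {n_events})")
        for (a0, a1), (b0, b1) in zip(runs, runs[1:]):
            if a1 != b0:
                raise ValueError("runs must be contiguous and disjoint")
        for a0, a1 in runs:
            if a1 <= a0:
                raise ValueError("empty run interval")
        self.runs = runs

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return self.data[self.subjects[0]].shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data[self.subjects[0]].shape[1]

    @property
    def n_time(self) -> int:
        return self.data[self.subjects[0]].shape[2]

    @property
    def bin_ms(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0]) if len(self.time_axis) > 1 else 0.0

    def time_window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Indices of bins whose half-open interval lies inside [start, stop) ms."""
        starts = self.time_axis
        return np.flatnonzero((starts >= start_ms) & (starts + self.bin_ms <= stop_ms))


@dataclass
class EventMatrix:
    """Flattened per-event view: rows are events, columns (sensor, time) pairs."""

    values: np.ndarray
    sensor_subset: np.ndarray
    time_subset: np.ndarray
    subject: str | None = None
    # column j maps to (sensor_subset[j // len(time_subset)],
    #                   time_subset[j % len(time_subset)])  -- sensor-major
    column_sensors: np.ndarray = field(init=False)
    column_times: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ns, nt = len(self.sensor_subset), len(self.time_subset)
        if self.values.ndim != 2 or self.values.shape[1] != ns * nt:
            raise ValueError("values shape inconsistent with subsets (expect d = |S| * |T|)")
        self.column_sensors = np.repeat(np.asarray(self.sensor_subset), nt)
        self.column_times = np.tile(np.asarray(self.time_subset), ns)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def flatten(
    dataset: MultiSubjectDataset,
    subject: str,
    sensor_subset: Sequence[int] | None = None,
    time_subset: Sequence[int] | None = None,
) -> EventMatrix:
    """Reshape one subject's tensor to an ``n_events x d`` matrix.

    ``d = |sensor_subset| * |time_subset|``; columns are sensor-major.  Omitted
    subsets default to all sensors / all time bins.
    """
    if subject not in dataset.data:
        raise KeyError(f"unknown subject {subject!r}")
    tensor = dataset.data[subject]
    sensor_subset = (
        np.arange(dataset.n_sensors) if sensor_subset is None else np.asarray(sensor_subset, int)
    )
    time_subset = (
        np.arange(dataset.n_time) if time_subset is None else np.asarray(time_subset, int)
    )
    for name, subset, bound in (
        ("sensor", sensor_subset, dataset.n_sensors),
        ("time", time_subset, dataset.n_time),
    ):
        if subset.size == 0:
            raise ValueError(f"empty {name} subset")
        if subset.min() < 0 or subset.max() >= bound:
            raise IndexError(f"{name} subset out of range [0, {bound})")
    sub = tensor[:, sensor_subset][:, :, time_subset]
    values = sub.reshape(tensor.shape[0], len(sensor_subset) * len(time_subset))
    return EventMatrix(values, sensor_subset, time_subset, subject=subject)


def unflatten(matrix: EventMatrix) -> np.ndarray:
    """Inverse of :func:`flatten`: recover the ``n_events x |S| x |T|`` sub-tensor."""
    ns, nt = len(matrix.sensor_subset), len(matrix.time_subset)
    return matrix.values.reshape(matrix.n_events, ns, nt)


def epoch_and_downsample(
    continuous: np.ndarray,
    onsets_ms: Sequence[float],
    window_ms: float,
    bin_ms: float,
    sample_ms: float = 1.0,
) -> np.ndarray:
    """Cut a continuous recording into event epochs and average into time bins.

    Parameters
    ----------
    continuous
        Array of shape ``(n_sensors, n_samples)`` sampled every ``sample_ms``.
    onsets_ms
        Event onset times in ms from recording start.
    window_ms, bin_ms
        Epoch duration and bin resolution; ``bin_ms`` must divide
        ``window_ms``.  Bin ``k`` of an event is the mean of the raw samples in
        ``[onset + k*bin_ms, onset + (k+1)*bin_ms)``.

    Returns
    -------
    Array of shape ``(n_events, n_sensors, window_ms / bin_ms)``.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError("continuous signal must be 2-D (sensors x samples)")
    n_bins_f = window_ms / bin_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin_ms={bin_ms} does not divide window_ms={window_ms}")
    per_bin_f = bin_ms / sample_ms
    per_bin = int(round(per_bin_f))
    if abs(per_bin_f - per_bin) > 1e-9 or per_bin < 1:
        raise ValueError(f"sample step {sample_ms} ms does not divide bin_ms={bin_ms}")
    n_sensors, n_samples = continuous.shape
    epochs = np.empty((len(onsets_ms), n_sensors, n_bins), dtype=continuous.dtype)
    for e, onset in enumerate(onsets_ms):
        start_f = onset / sample_ms
        start = int(round(start_f))
        if abs(start_f - start) > 1e-9:
            raise ValueError(f"event {e}: onset {onset} ms is not sample-aligned")
        stop = start + n_bins * per_bin
        if start < 0 or stop > n_samples:
            raise ValueError(
                f"event {e}: window [{onset}, {onset + window_ms}) ms falls outside the recording"
            )
        seg = continuous[:, start:stop].reshape(n_sensors, n_bins, per_bin)
        epochs[e] = seg.mean(axis=2)
    return epochs


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(dataset: MultiSubjectDataset, path) -> None:
    """Write the documented HDF5 layout.

    Layout: ``/subjects/<id>/data`` (events x sensors x time), ``/sensors``
    (one dataset per column), ``/runs`` (k x 2 int), ``/time_axis``; root
    attributes ``format_version``, ``bin_ms``, ``window_ms``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["bin_ms"] = dataset.bin_ms
        f.attrs["window_ms"] = dataset.bin_ms * dataset.n_time
        f.create_dataset("time_axis", data=dataset.time_axis)
        f.create_dataset("runs", data=np.asarray(dataset.runs, int))
        g = f.create_group("subjects")
        for s in dataset.subjects:
            g.create_group(s).create_dataset("data", data=dataset.data[s])
        f.attrs["subject_order"] = [s.encode() for s in dataset.subjects]
        sg = f.create_group("sensors")
        sf = dataset.sensors.frame
        sg.create_dataset("sensor", data=[str(v).encode() for v in sf["sensor"]])
        sg.create_dataset("kind", data=[str(v).encode() for v in sf["kind"]])
        sg.create_dataset("region", data=[str(v).encode() for v in sf["region"]])
        sg.create_dataset("x", data=sf["x"].to_numpy(float))
        sg.create_dataset("y", data=sf["y"].to_numpy(float))


def load_dataset(path) -> MultiSubjectDataset:
    """Read the HDF5 layout written by :func:`save_dataset`.

    Missing groups raise a descriptive error; a format-version mismatch is
    logged as a warning but the file is still read.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            logger.warning(
                "dataset %s has format_version %r, expected %r", path, version, FORMAT_VERSION
            )
        for group in ("subjects", "sensors", "time_axis", "runs"):
            if group not in f:
                raise KeyError(f"dataset file {path} lacks required group /{group}")
        time_axis = f["time_axis"][()]
        runs = [tuple(int(v) for v in row) for row in f["runs"][()]]
        def _dec(v):
            return v.decode() if isinstance(v, bytes) else str(v)

        if "subject_order" in f.attrs:
            subjects = [_dec(s) for s in f.attrs["subject_order"]]
        else:
            subjects = sorted(f["subjects"])
        data = {s: f[f"subjects/{s}/data"][()] for s in subjects}
        sg = f["sensors"]
        frame = pd.DataFrame(
            {
                "sensor": [_dec(v) for v in sg["sensor"][()]],
                "kind": [_dec(v) for v in sg["kind"][()]],
                "region": [_dec(v) for v in sg["region"][()]],
                "x": sg["x"][()],
                "y": sg["y"][()],
            }
        )
    return MultiSubjectDataset(subjects, data, time_axis, SensorTable(frame), runs)
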