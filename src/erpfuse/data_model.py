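"""Epoch container, epoching, baseline correction and file I/O.

The central object is :class:`EpochedRecording`: a ``(n_trials, n_channels,
n_samples)`` voltage tensor in microvolts, cut around stimulus-onset events
of a two-condition oddball experiment (``rare`` / ``frequent``), together
with the sampling rate and the epoch window in milliseconds relative to
onset.

Time-axis convention
--------------------
Sample ``k`` of an epoch sits at ``t = t_start + k * 1000 / srate`` ms and
the epoch includes both endpoints, so a [-1000, 2000] ms window at 150 Hz
has 451 samples.  The baseline window [-200, 0] ms likewise includes the
sample at t = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

logger = logging.getLogger(__name__)

CONDITIONS = ("rare", "frequent")
SCHEMA_VERSION = 1


class ErpfuseError(Exception):
    """Base class for all package errors."""


class SchemaError(ErpfuseError):
    """An HDF5 epoch container is missing or mangles a required field."""


class EDFFormatError(ErpfuseError):
    """An EDF file could not be parsed."""


def n_samples_for_window(window: tuple[float, float], srate: float) -> int:
    """Number of samples in an inclusive-endpoint epoch window (ms)."""
    t0, t1 = window
    return int(round((t1 - t0) / 1000.0 * srate)) + 1


def time_axis(window: tuple[float, float], srate: float) -> np.ndarray:
    """Per-sample times in ms for an inclusive-endpoint epoch window."""
    n = n_samples_for_window(window, srate)
    return window[0] + np.arange(n) * 1000.0 / srate


@dataclass
class EpochedRecording:
    """Epoched multi-channel EEG for one participant.

    Parameters
    ----------
    data
        Voltage in microvolts, shape ``(n_trials, n_channels, n_samples)``.
    srate
        Sampling rate in Hz.
    window
        ``(t_start, t_end)`` of the epoch in ms relative to event onset;
        ``t_start < 0 < t_end``.
    labels
        Per-trial condition tag, each ``"rare"`` or ``"frequent"``.
    channel_names
        Electrode labels, one per channel.
    participant_id
        Free-form identifier.
    """

    data: np.ndarray
    srate: float
    window: tuple[float, float]
    labels: list[str]
    channel_names: list[str] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voltage data contains non-finite values")
        t0, t1 = self.window
        if not (t0 < 0.0 < t1):
            raise ValueError("epoch window must span the event onset (t_start < 0 < t_end)")
        expected = n_samples_for_window(self.window, self.srate)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"n_samples {self.data.shape[2]} inconsistent with window {self.window} "
                f"at {self.srate} Hz (expected {expected})"
            )
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        bad = sorted({l for l in self.labels if l not in CONDITIONS})
        if bad:
            raise ValueError(f"unknown condition labels {bad}; expected {CONDITIONS}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("one channel name per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time in ms relative to event onset."""
        return time_axis(self.window, self.srate)

    def trial_indices(self, condition: str) -> np.ndarray:
        """Indices of trials carrying ``condition``."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return np.flatnonzero(np.array(self.labels) == condition)

    def crop(self, window: tuple[float, float]) -> "EpochedRecording":
        """Return a copy restricted to ``window`` (ms, inclusive)."""
        t = self.times
        mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
        if not mask.any():
            raise ValueError("crop window does not overlap the epoch")
        kept = t[mask]
        return replace(self, data=self.data[:, :, mask], window=(float(kept[0]), float(kept[-1])))


@dataclass
class EventTable:
    """Stimulus events on a continuous record: sample indices plus labels."""

    onsets: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.ndim != 1 or len(self.labels) != self.onsets.size:
            raise ValueError("onsets and labels must be parallel 1-D sequences")
        if self.onsets.size and self.onsets.min() < 0:
            raise ValueError("onset samples must be non-negative")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onset samples must be strictly increasing")
        bad = sorted({l for l in self.labels if l not in CONDITIONS})
        if bad:
            raise ValueError(f"unknown event labels {bad}; expected {CONDITIONS}")

    def __len__(self) -> int:
        return int(self.onsets.size)


def read_events_tsv(path) -> EventTable:
    """Read a tab-separated events file with header ``onset_sample<TAB>label``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("onset_sample", "label"):
        if col not in df.columns:
            raise SchemaError(f"events file {path} is missing column {col!r}")
    return EventTable(df["onset_sample"].to_numpy(), df["label"].astype(str).tolist())


def write_events_tsv(events: EventTable, path) -> None:
    import pandas as pd

    pd.DataFrame({"onset_sample": events.onsets, "label": events.labels}).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class BaselineSpec:
    """Pre-stimulus window (ms) whose mean is subtracted from every trace."""

    window: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        b0, b1 = self.window
        if not (b0 < b1 <= 0.0):
            raise ValueError("baseline window must satisfy b_start < b_end <= 0")

    def mask(self, times: np.ndarray) -> np.ndarray:
        b0, b1 = self.window
        m = (times >= b0 - 1e-9) & (times <= b1 + 1e-9)
        if not m.any():
            raise ValueError(f"baseline window {self.window} contains no samples")
        return m


def baseline_correct(x: np.ndarray, times: np.ndarray, spec: BaselineSpec) -> np.ndarray:
    """Subtract the per-index mean over the baseline window.

    ``x`` may have any number of leading axes; the trailing axis is time and
    must align with ``times`` (ms).  After correction the mean of every
    trace over the baseline samples is zero.
    """
    x = np.asarray(x)
    times = np.asarray(times)
    if x.shape[-1] != times.size:
        raise ValueError("trailing axis of x must match the time axis")
    m = spec.mask(times)
    return x - x[..., m].mean(axis=-1, keepdims=True)


def epoch_continuous(
    signal: np.ndarray,
    srate: float,
    events: EventTable,
    window: tuple[float, float],
    channel_names: list[str] | None = None,
    participant_id: str = "",
) -> EpochedRecording:
    """Cut inclusive-endpoint epochs around event onsets.

    Trial ``i`` contains samples ``onset_i + round(t_start/1000*srate)`` …
    ``onset_i + round(t_end/1000*srate)`` of the continuous record.  Events
    whose window does not fit inside the record are dropped with a logged
    warning; if no event survives, a ``ValueError`` is raised.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_total = signal.shape[1]
    k0 = int(round(window[0] / 1000.0 * srate))
    k1 = int(round(window[1] / 1000.0 * srate))
    epochs, labels = [], []
    for onset, label in zip(events.onsets, events.labels):
        lo, hi = int(onset) + k0, int(onset) + k1
        if lo < 0 or hi >= n_total:
            logger.warning(
                "dropping event at sample %d (%s): window [%d, %d] exceeds record of %d samples",
                onset, label, lo, hi, n_total,
            )
            continue
        epochs.append(signal[:, lo : hi + 1])
        labels.append(label)
    if not epochs:
        raise ValueError("no event window fits inside the continuous record")
    return EpochedRecording(
        data=np.stack(epochs, axis=0),
        srate=srate,
        window=window,
        labels=labels,
        channel_names=channel_names or [],
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# HDF5 epoch container


def write_container(rec: EpochedRecording, path) -> None:
    """Write an :class:`EpochedRecording` to the package's HDF5 container.

    Layout: datasets ``/data``, ``/labels``, ``/channel_names``; root
    attributes ``srate``, ``window``, ``participant_id``, ``schema_version``.
    Timestamp tracking is disabled so identical recordings produce identical
    files.
    """
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("data", data=rec.data, track_times=False)
        f.create_dataset("labels", data=np.array(rec.labels, dtype=str_dt), track_times=False)
        f.create_dataset(
            "channel_names", data=np.array(rec.channel_names, dtype=str_dt), track_times=False
        )
        f.attrs["srate"] = float(rec.srate)
        f.attrs["window"] = np.array(rec.window, dtype=np.float64)
        f.attrs["participant_id"] = rec.participant_id
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_container(path) -> EpochedRecording:
    """Read an epoch container written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "channel_names"):
            if name not in f:
                raise SchemaError(f"container {path} is missing dataset /{name}")
        for attr in ("srate", "window", "schema_version"):
            if attr not in f.attrs:
                raise SchemaError(f"container {path} is missing attribute {attr!r}")
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(f"container {path}: unsupported schema_version {version}")
        return EpochedRecording(
            data=f["data"][()],
            srate=float(f.attrs["srate"]),
            window=tuple(np.asarray(f.attrs["window"], dtype=float)),
            labels=[s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]],
            channel_names=[
                s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()]
            ],
            participant_id=str(f.attrs.get("participant_id", "")),
        )


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording.

    Returns ``(signal, srate, channel_names)`` with the signal in microvolts,
    shape ``(n_channels, n_samples)``.  EDF physical dimensions are converted
    from the SI volts that the reader reports.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of ValueError/OSError subtypes
        raise EDFFormatError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
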