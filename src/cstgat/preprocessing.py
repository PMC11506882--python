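"""Filtering, class-period extraction, and sliding-window segmentation.

Recordings are bandpass filtered (default fourth-order Butterworth,
0.5-150 Hz, applied zero-phase so seizure-onset timing is not shifted),
split into pre-seizure (class 0) and seizure (class 1) periods around each
annotated onset, and segmented into fixed-length overlapping windows.  The
pre-seizure period is the minority class, so its stride can be shrunk to
oversample it; :func:`balanced_class0_stride` picks a stride that brings the
class counts within a stated ratio.

All intervals are half-open ``[start, end)`` in seconds; window offsets are
0-based sample indices into the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from .synthetic import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSet",
    "bandpass_filter",
    "extract_class_periods",
    "segment_windows",
    "balanced_class0_stride",
    "write_window_set",
    "read_window_set",
]

DEFAULT_LOW_HZ = 0.5
DEFAULT_HIGH_HZ = 150.0
DEFAULT_ORDER = 4
DEFAULT_PRE_SEIZURE_MIN = 5.0
DEFAULT_SEIZURE_MIN = 30.0


@dataclass(frozen=True)
class WindowSet:
    """Fixed-length labelled windows cut from one recording.

    ``windows`` is (n, channels, window_len); ``labels`` holds class ids
    (0 = pre-seizure, 1 = seizure); ``source_offsets`` are the starting
    sample indices in the source recording.
    """

    windows: np.ndarray
    labels: np.ndarray
    window_len: int
    source_offsets: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        offsets = np.asarray(self.source_offsets, dtype=int)
        if w.ndim != 3 or w.shape[2] != self.window_len:
            raise ValueError("windows must be (n, channels, window_len)")
        if len(labels) != w.shape[0] or len(offsets) != w.shape[0]:
            raise ValueError("labels/offsets length mismatch")
        if len(labels) and not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be in {0, 1}")
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "source_offsets", offsets)

    def __len__(self) -> int:
        return self.windows.shape[0]


def design_bandpass_sos(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    """Butterworth band design in second-order sections.

    If ``high_hz`` reaches the Nyquist rate the band degenerates to a
    high-pass, matching how a 0.5-150 Hz spec behaves at low sampling rates.
    """
    nyq = fs / 2.0
    if not (0 < low_hz < nyq):
        raise ValueError(f"low_hz={low_hz} must lie in (0, fs/2={nyq})")
    if high_hz <= low_hz:
        raise ValueError(f"high_hz={high_hz} must exceed low_hz={low_hz}")
    if order < 1:
        raise ValueError("order must be >= 1")
    if high_hz >= nyq:
        logger.warning("high_hz=%.1f >= Nyquist %.1f; using high-pass at %.2f Hz", high_hz, nyq, low_hz)
        return sps.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    recording: Recording,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> Recording:
    """Zero-phase Butterworth bandpass, each channel filtered independently.

    Forward-backward application (``sosfiltfilt``) squares the magnitude
    response and cancels phase, so event timing is preserved.
    """
    sos = design_bandpass_sos(low_hz, high_hz, order, recording.fs)
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(
        signal=filtered,
        fs=recording.fs,
        channel_names=recording.channel_names,
        annotations=recording.annotations,
    )


def extract_class_periods(
    recording: Recording,
    pre_seizure_min: float = DEFAULT_PRE_SEIZURE_MIN,
    seizure_min: float = DEFAULT_SEIZURE_MIN,
) -> list[tuple[float, float, int]]:
    """Class-0/class-1 intervals around each annotated seizure onset.

    For an onset at t0 with annotated end t1: class 0 spans
    ``[t0 - pre_seizure_min*60, t0)`` clipped to the recording start and to
    the previous seizure's end; class 1 spans ``[t0, t0 + min(seizure_min*60,
    t1 - t0))``.  Periods from different seizures never overlap.
    """
    seizures = sorted((s, e) for s, e, _ in recording.annotations)
    if not seizures:
        raise ValueError("recording has no seizure annotations")
    periods: list[tuple[float, float, int]] = []
    prev_end = 0.0
    for t0, t1 in seizures:
        pre_start = t0 - pre_seizure_min * 60.0
        clipped = max(pre_start, prev_end, 0.0)
        if clipped > pre_start:
            logger.warning("pre-seizure interval for onset %.1f s clipped to start %.1f s", t0, clipped)
        if clipped < t0:
            periods.append((clipped, t0, 0))
        sz_end = t0 + min(seizure_min * 60.0, t1 - t0)
        sz_end = min(sz_end, recording.duration_s)
        if t0 < sz_end:
            periods.append((t0, sz_end, 1))
        prev_end = sz_end
    return periods


def segment_windows(
    recording: Recording,
    periods: list[tuple[float, float, int]],
    window_s: float,
    stride_class0_s: float,
    stride_class1_s: float,
) -> WindowSet:
    """Cut overlapping sliding windows from each class period.

    Within a period of length L, windows start at ``period_start + k*stride``
    while the full window fits, giving ``floor((L - window_s)/stride) + 1``
    windows.  Class 0 conventionally gets the smaller stride to oversample
    the pre-seizure minority class.
    """
    if stride_class0_s <= 0 or stride_class1_s <= 0:
        raise ValueError("strides must be positive")
    fs = recording.fs
    wlen = int(round(window_s * fs))
    windows, labels, offsets = [], [], []
    any_fits = False
    for start, end, cls in periods:
        stride = stride_class0_s if cls == 0 else stride_class1_s
        length = end - start
        if window_s > length + 1e-12:
            continue
        any_fits = True
        n_win = int(np.floor((length - window_s) / stride + 1e-9)) + 1
        for k in range(n_win):
            off = int(round((start + k * stride) * fs))
            if off + wlen > recording.n_samples:
                break
            windows.append(recording.signal[:, off : off + wlen])
            labels.append(cls)
            offsets.append(off)
    if not any_fits:
        raise ValueError(f"window_s={window_s} longer than every class period")
    return WindowSet(
        windows=np.asarray(windows),
        labels=np.asarray(labels, dtype=int),
        window_len=wlen,
        source_offsets=np.asarray(offsets, dtype=int),
    )


def balanced_class0_stride(
    periods: list[tuple[float, float, int]],
    window_s: float,
    stride_class1_s: float,
    tolerance: float = 0.10,
) -> float:
    """Pick a class-0 stride so class counts match within ``tolerance``.

    Searches decreasing strides (from the class-1 stride) until the class-0
    window count is within ``tolerance`` of the class-1 count, or the ratio
    crosses 1.  The chosen stride is logged.
    """

    def counts(stride0: float) -> tuple[int, int]:
        c = [0, 0]
        for start, end, cls in periods:
            stride = stride0 if cls == 0 else stride_class1_s
            length = end - start
            if window_s > length + 1e-12:
                continue
            c[cls] += int(np.floor((length - window_s) / stride + 1e-9)) + 1
        return c[0], c[1]

    _, n1 = counts(stride_class1_s)
    if n1 == 0:
        raise ValueError("no class-1 windows; cannot balance")
    stride0 = stride_class1_s
    best = stride0
    for _ in range(64):
        n0, _ = counts(stride0)
        if n0 >= n1 * (1 - tolerance):
            best = stride0
            break
        stride0 *= 0.75
        best = stride0
    n0, n1 = counts(best)
    logger.info("balanced class-0 stride %.4f s (counts %d vs %d)", best, n0, n1)
    return best


def write_window_set(ws: WindowSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows, dtype="float64")
        f.create_dataset("labels", data=ws.labels)
        f.create_dataset("offsets", data=ws.source_offsets)


def read_window_set(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as f:
        windows = f["windows"][()]
        labels = f["labels"][()]
        offsets = f["offsets"][()]
    return WindowSet(windows=windows, labels=labels, window_len=windows.shape[2], source_offsets=offsets)
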