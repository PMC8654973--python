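"""Baseline removal and fixed-window segmentation of raw accelerometry.

Each axis of each sensor is passed through a causal 4th-order Butterworth
high-pass filter (critical frequency 0.2 Hz) to remove the static gravity
offset and slow orientation drift, then segmented into non-overlapping 5-s
analysis windows (~50 samples at 10 Hz).  Filtering is a single causal pass
(IIR difference equation); a zero-phase forward-backward variant is exposed
as a switch.  Filter state is reset at every missing-data gap so transients
do not bleed across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

BASELINE_FC_HZ = 0.2
WINDOW_S = 5.0


class InvalidFilterError(ValueError):
    """Critical frequency incompatible with the sampling rate."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter definition (order, critical frequency, kind, rate)."""

    f_c: float
    fs: float
    kind: str = "high-pass"   # or "low-pass"
    order: int = 4

    def __post_init__(self):
        if self.order < 1:
            raise InvalidFilterError("order must be >= 1")
        if not 0 < self.f_c < self.fs / 2:
            raise InvalidFilterError(
                f"critical frequency {self.f_c} Hz must lie in (0, fs/2) for fs={self.fs}")
        if self.kind not in ("high-pass", "low-pass"):
            raise InvalidFilterError(f"unknown filter kind {self.kind!r}")

    def ba(self):
        btype = "highpass" if self.kind == "high-pass" else "lowpass"
        return signal.butter(self.order, self.f_c, btype=btype, fs=self.fs)


@dataclass
class AccelWindow:
    """One 5-s triaxial analysis window."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    start_time: float
    placement: str
    complete: bool

    @property
    def n(self) -> int:
        return len(self.x)


def _filter_segment(b, a, seg: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        padlen = min(3 * (max(len(a), len(b)) - 1), len(seg) - 1)
        if padlen < 1:
            return seg - seg  # too short to filter meaningfully
        return signal.filtfilt(b, a, seg, padlen=padlen)
    return signal.lfilter(b, a, seg)


def highpass_baseline(stream: pd.DataFrame, spec: FilterSpec,
                      zero_phase: bool = False) -> pd.DataFrame:
    """Filter each axis of a stream, resetting state at missing-data gaps.

    ``stream`` uses the cohort CSV dialect (``time_s, x_g, y_g, z_g,
    missing``).  Missing samples stay NaN; each contiguous observed run is
    filtered independently from zero initial state, so output length equals
    input length.
    """
    b, a = spec.ba()
    out = stream.copy()
    observed = ~stream["missing"].to_numpy().astype(bool)
    n = len(stream)
    if n == 0:
        return out
    # contiguous observed runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], observed.view(np.int8), [0]])))
    starts, stops = edges[0::2], edges[1::2]
    for col in ("x_g", "y_g", "z_g"):
        v = stream[col].to_numpy(dtype=float)
        f = np.full(n, np.nan)
        for s, e in zip(starts, stops):
            f[s:e] = _filter_segment(b, a, v[s:e], zero_phase)
        out[col] = f
    return out


def segment_windows(stream: pd.DataFrame, fs: float, placement: str = "",
                    window_s: float = WINDOW_S) -> list[AccelWindow]:
    """Tile a stream into non-overlapping windows anchored at the start.

    Windows overlapping any missing sample are emitted with
    ``complete=False``; the trailing partial window is dropped.
    """
    n_per = int(round(window_s * fs))
    n = len(stream)
    n_win = n // n_per
    x = stream["x_g"].to_numpy(dtype=float)
    y = stream["y_g"].to_numpy(dtype=float)
    z = stream["z_g"].to_numpy(dtype=float)
    t = stream["time_s"].to_numpy(dtype=float)
    missing = stream["missing"].to_numpy().astype(bool)
    windows = []
    for i in range(n_win):
        sl = slice(i * n_per, (i + 1) * n_per)
        complete = not missing[sl].any()
        windows.append(AccelWindow(
            x=x[sl], y=y[sl], z=z[sl], fs=fs,
            start_time=float(t[sl.start]), placement=placement, complete=complete))
    return windows


def windowed_arrays(stream: pd.DataFrame, fs: float, window_s: float = WINDOW_S):
    """Vectorized windowing: returns (xw, yw, zw, starts, complete).

    ``xw`` etc. have shape (n_windows, samples_per_window); ``complete`` is a
    boolean mask (no missing sample in the window).  Used by the batched
    feature extractor; :func:`segment_windows` is the per-window view.
    """
    n_per = int(round(window_s * fs))
    n_win = len(stream) // n_per
    upto = n_win * n_per
    def shape(col):
        return stream[col].to_numpy(dtype=float)[:upto].reshape(n_win, n_per)
    xw, yw, zw = shape("x_g"), shape("y_g"), shape("z_g")
    missing = stream["missing"].to_numpy().astype(bool)[:upto].reshape(n_win, n_per)
    starts = stream["time_s"].to_numpy(dtype=float)[:upto:n_per]
    return xw, yw, zw, starts, ~missing.any(axis=1)
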