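"""Motion features per 5-s window and bed-motion correction.

Eight feature types are extracted from each sensor.  Seven are computed
per non-overlapping 5-s window of the baseline-filtered signal and
root-sum-of-squares (RSS) levelled across the three axes:

* ``SMA``   signal magnitude area: trapezoidal mean absolute acceleration,
  ``(0.1/(2*5)) * sum_{n=1}^{N-1} (|x_{n+1}|+|y_{n+1}|+|z_{n+1}|+|x_n|+|y_n|+|z_n|)``.
* ``HLF_h`` / ``HLF_l``  RSS of per-axis medians of the window convolved
  with a 4th-order Butterworth high-/low-pass filter at 2.5 Hz.
* ``MFR``   RSS of per-axis median frequencies (smallest one-sided DFT bin
  frequency at which cumulative power reaches half the total).
* ``FDE``   RSS of per-axis spectral entropies of the DFT power
  distribution, scaled by 1/log2(N); bounded by sqrt(3).
* ``BPW``   RSS of per-axis band powers over 0.3-3.5 Hz (rectangle rule
  over DFT bins), scaled by 1/(3.2 Hz).
* ``WVL``   RSS of per-axis summed squared level-2..6 detail coefficients
  of the 5th-order Daubechies wavelet transform.

The eighth, ``PDA`` (proportion of dynamic activity), is the fraction of
5-s SMA values at or above 0.135 g within an observation window and is
computed at observation-matrix assembly time.

Gross external (bed) movements: where the bed-frame sensor's SMA exceeds
0.135 g and precedes a spike in an extremity's features, the bed values of
SMA, HLF and the energy features are subtracted from (and MFR/FDE added
to) the extremity values; corrections falling outside a feature's static
activity range are replaced by a uniform draw from that range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .preprocessing import (BASELINE_FC_HZ, WINDOW_S, FilterSpec,
                            highpass_baseline, windowed_arrays)

logger = logging.getLogger(__name__)

FEATURES = ("SMA", "HLF_h", "HLF_l", "MFR", "FDE", "BPW", "WVL")
FEATURE_TYPES = ("PDA",) + FEATURES          # the 8 types of the significance grid
DYNAMIC_SMA_G = 0.135                         # static/dynamic activity threshold (g)
BPW_BAND_HZ = (0.3, 3.5)
WVL_LEVELS = (2, 6)                           # inclusive detail-level range
_SUBTRACT = ("SMA", "HLF_h", "HLF_l", "BPW", "WVL")
_ADD = ("MFR", "FDE")


# ---------------------------------------------------------------------------
# Batched per-window features: inputs are (n_windows, N) arrays per axis.


def sma_batch(xw: np.ndarray, yw: np.ndarray, zw: np.ndarray,
              fs: float, window_s: float = WINDOW_S) -> np.ndarray:
    """Trapezoidal signal magnitude area per window (g)."""
    dt = 1.0 / fs
    out = np.zeros(xw.shape[0])
    for w in (xw, yw, zw):
        s = np.abs(w)
        out += (s[:, 1:] + s[:, :-1]).sum(axis=1)
    return dt / (2.0 * window_s) * out


def hlf_batch(xw, yw, zw, fs: float, f_c: float = 2.5, order: int = 4):
    """(HLF_h, HLF_l): RSS of per-axis medians of 2.5 Hz filtered windows."""
    from scipy.signal import lfilter
    bh, ah = FilterSpec(f_c=f_c, fs=fs, kind="high-pass", order=order).ba()
    bl, al = FilterSpec(f_c=f_c, fs=fs, kind="low-pass", order=order).ba()
    hi = np.zeros(xw.shape[0])
    lo = np.zeros(xw.shape[0])
    for w in (xw, yw, zw):
        hi += np.median(lfilter(bh, ah, w, axis=1), axis=1) ** 2
        lo += np.median(lfilter(bl, al, w, axis=1), axis=1) ** 2
    return np.sqrt(hi), np.sqrt(lo)


def _one_sided_power(w: np.ndarray, fs: float):
    """One-sided DFT power per window: (power[n_win, K], freqs[K])."""
    n = w.shape[1]
    spec = np.fft.rfft(w, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return power, freqs


def mfr_batch(xw, yw, zw, fs: float) -> np.ndarray:
    """RSS of per-axis half-total-power median frequencies (Hz).

    An all-zero axis contributes 0 by convention.
    """
    out = np.zeros(xw.shape[0])
    for w in (xw, yw, zw):
        power, freqs = _one_sided_power(w, fs)
        total = power.sum(axis=1)
        cum = np.cumsum(power, axis=1)
        reached = cum >= 0.5 * total[:, None]
        idx = reached.argmax(axis=1)
        mf = freqs[idx]
        mf = np.where(total > 0, mf, 0.0)
        out += mf ** 2
    return np.sqrt(out)


def fde_batch(xw, yw, zw, fs: float) -> np.ndarray:
    """Normalized frequency-domain entropy, RSS over axes; in [0, sqrt(3)].

    Entropy uses the full-length DFT power distribution of each axis; a
    zero axis contributes zero entropy.
    """
    n = xw.shape[1]
    out = np.zeros(xw.shape[0])
    for w in (xw, yw, zw):
        spec = np.fft.fft(w, axis=1)
        power = np.abs(spec) ** 2
        total = power.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, power / total, 0.0)
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        h = np.abs((p * logp).sum(axis=1))
        out += h ** 2
    return np.sqrt(out) / np.log2(n)


def bpw_batch(xw, yw, zw, fs: float,
              band: tuple = BPW_BAND_HZ) -> np.ndarray:
    """Band power over ``band`` Hz per axis (rectangle rule), RSS, / 3.2 Hz."""
    out = np.zeros(xw.shape[0])
    width = band[1] - band[0]
    for w in (xw, yw, zw):
        power, freqs = _one_sided_power(w, fs)
        df = fs / w.shape[1]
        sel = (freqs >= band[0]) & (freqs <= band[1])
        p = (power[:, sel] * df).sum(axis=1)
        out += p ** 2
    return np.sqrt(out) / width


def wvl_batch(xw, yw, zw, fs: float, wavelet: str = "db5",
              mode: str = "symmetric") -> np.ndarray:
    """RSS over axes of summed squared level-2..6 db5 detail energies.

    With 50-sample windows and a length-10 filter the deeper levels are
    dominated by boundary extension; they are computed anyway (levels 2-6)
    and a warning is logged once.
    """
    n = xw.shape[1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < WVL_LEVELS[1] and not getattr(wvl_batch, "_warned", False):
        logger.warning(
            "window length %d supports %d wavelet levels; levels up to %d are "
            "boundary-dominated", n, max_level, WVL_LEVELS[1])
        wvl_batch._warned = True
    out = np.zeros(xw.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for w in (xw, yw, zw):
            coeffs = pywt.wavedec(w, wavelet, mode=mode, level=WVL_LEVELS[1], axis=1)
            # coeffs = [cA6, cD6, cD5, cD4, cD3, cD2, cD1]
            energy = np.zeros(w.shape[0])
            for level, d in zip(range(WVL_LEVELS[1], 0, -1), coeffs[1:]):
                if WVL_LEVELS[0] <= level <= WVL_LEVELS[1]:
                    energy += (d ** 2).sum(axis=1)
            out += energy ** 2
    return np.sqrt(out)


def _spectral_batch(xw, yw, zw, fs: float, band: tuple = BPW_BAND_HZ):
    """MFR, FDE and BPW in one spectral pass per axis (shared FFT)."""
    n = xw.shape[1]
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    k_half = n // 2 + 1
    one_freqs = np.abs(freqs[:k_half].copy())
    if n % 2 == 0:
        one_freqs[-1] = fs / 2
    sel = (one_freqs >= band[0]) & (one_freqs <= band[1])
    df = fs / n
    mfr_sq = np.zeros(xw.shape[0])
    fde_sq = np.zeros(xw.shape[0])
    bpw_sq = np.zeros(xw.shape[0])
    for w in (xw, yw, zw):
        power_full = np.abs(np.fft.fft(w, axis=1)) ** 2
        total_full = power_full.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total_full > 0, power_full / total_full, 0.0)
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        h = np.abs((p * logp).sum(axis=1))
        fde_sq += h ** 2
        power = power_full[:, :k_half]
        total = power.sum(axis=1)
        cum = np.cumsum(power, axis=1)
        idx = (cum >= 0.5 * total[:, None]).argmax(axis=1)
        mf = np.where(total > 0, one_freqs[idx], 0.0)
        mfr_sq += mf ** 2
        bpw_sq += ((power[:, sel] * df).sum(axis=1)) ** 2
    return (np.sqrt(mfr_sq), np.sqrt(fde_sq) / np.log2(n),
            np.sqrt(bpw_sq) / (band[1] - band[0]))


# ---------------------------------------------------------------------------
# Scalar wrappers operating on AccelWindow (missing -> NaN marker).


def _scalar(fn, window, *args, **kwargs):
    if not window.complete:
        return np.nan
    res = fn(window.x[None, :], window.y[None, :], window.z[None, :],
             window.fs, *args, **kwargs)
    if isinstance(res, tuple):
        return tuple(float(r[0]) for r in res)
    return float(res[0])


def sma(window) -> float:
    """Signal magnitude area of one window; NaN if incomplete."""
    return _scalar(sma_batch, window)


def hlf(window) -> tuple:
    """(HLF_h, HLF_l) of one window; (NaN, NaN) if incomplete."""
    res = _scalar(hlf_batch, window)
    return (np.nan, np.nan) if np.isscalar(res) and np.isnan(res) else res


def mfr(window) -> float:
    return _scalar(mfr_batch, window)


def fde(window) -> float:
    return _scalar(fde_batch, window)


def bpw(window) -> float:
    return _scalar(bpw_batch, window)


def wvl(window) -> float:
    return _scalar(wvl_batch, window)


def pda(sma_series, threshold: float = DYNAMIC_SMA_G) -> float:
    """Proportion of observed SMA values at or above ``threshold``.

    NaN entries are ignored; an empty or all-missing series yields NaN.
    """
    v = np.asarray(sma_series, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan
    return float((v >= threshold).mean())


# ---------------------------------------------------------------------------
# Window feature series: one DataFrame per patient,
# index = window number, columns = MultiIndex (placement, feature).


@dataclass
class WindowFeatureSeries:
    """Per-patient 0.2 Hz feature series for all placements.

    ``frame`` holds one row per 5-s window with a (placement, feature)
    column MultiIndex; NaN marks missing features.  ``starts`` gives the
    window start times in seconds.
    """

    patient_id: str
    frame: pd.DataFrame
    starts: np.ndarray
    window_s: float = WINDOW_S

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.frame.isna()

    def placements(self):
        return list(dict.fromkeys(self.frame.columns.get_level_values(0)))


def extract_features(recording, baseline_spec: FilterSpec | None = None,
                     zero_phase: bool = False) -> WindowFeatureSeries:
    """Run the filter -> segment -> extract pipeline for one recording."""
    fs = recording.fs
    if baseline_spec is None:
        baseline_spec = FilterSpec(f_c=BASELINE_FC_HZ, fs=fs, kind="high-pass")
    cols = {}
    starts = None
    for placement, stream in recording.streams.items():
        filtered = highpass_baseline(stream, baseline_spec, zero_phase=zero_phase)
        xw, yw, zw, st, complete = windowed_arrays(filtered, fs)
        if starts is None:
            starts = st
        xs = np.where(complete[:, None], np.nan_to_num(xw), 0.0)
        ys = np.where(complete[:, None], np.nan_to_num(yw), 0.0)
        zs = np.where(complete[:, None], np.nan_to_num(zw), 0.0)
        hi, lo = hlf_batch(xs, ys, zs, fs)
        mfr_v, fde_v, bpw_v = _spectral_batch(xs, ys, zs, fs)
        vals = {
            "SMA": sma_batch(xs, ys, zs, fs),
            "HLF_h": hi,
            "HLF_l": lo,
            "MFR": mfr_v,
            "FDE": fde_v,
            "BPW": bpw_v,
            "WVL": wvl_batch(xs, ys, zs, fs),
        }
        for feat, v in vals.items():
            v = np.where(complete, v, np.nan)
            cols[(placement, feat)] = v
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["placement", "feature"])
    return WindowFeatureSeries(patient_id=recording.patient_id, frame=frame,
                               starts=np.asarray(starts))


# ---------------------------------------------------------------------------
# Static activity ranges and bed-motion correction.


@dataclass
class StaticRange:
    """Per-feature (low, high) bounds of static-activity values."""

    bounds: dict = field(default_factory=dict)   # feature -> (low, high)

    def __post_init__(self):
        for feat, (lo, hi) in self.bounds.items():
            if lo > hi or lo < 0:
                raise ValueError(f"invalid static range for {feat}: ({lo}, {hi})")

    def __getitem__(self, feat):
        return self.bounds[feat]

    def __contains__(self, feat):
        return feat in self.bounds


def estimate_static_ranges(series_list, percentile: float = 97.5) -> StaticRange:
    """Estimate static-activity ranges from windows with all extremities static.

    A window is static when every extremity sensor's SMA is below the
    0.135 g dynamic threshold; the range per feature is
    ``[0, percentile]`` of that feature's pooled static values across
    extremity sensors.  Estimated per fit, serialized with the model.
    """
    from .synthetic import EXTREMITIES
    pooled = {feat: [] for feat in FEATURES}
    for series in series_list:
        frame = series.frame
        ext = [p for p in EXTREMITIES if p in frame.columns.get_level_values(0)]
        sma_cols = frame.loc[:, [(p, "SMA") for p in ext]]
        static = (sma_cols < DYNAMIC_SMA_G).all(axis=1) & sma_cols.notna().all(axis=1)
        for feat in FEATURES:
            vals = frame.loc[static, [(p, feat) for p in ext]].to_numpy().ravel()
            pooled[feat].append(vals[~np.isnan(vals)])
    bounds = {}
    for feat in FEATURES:
        v = np.concatenate(pooled[feat]) if pooled[feat] else np.array([0.0])
        hi = float(np.percentile(v, percentile)) if v.size else 0.0
        bounds[feat] = (0.0, max(hi, 0.0))
    return StaticRange(bounds=bounds)


def detect_bed_events(bed_sma: np.ndarray, extremity_sma: np.ndarray,
                      threshold: float = DYNAMIC_SMA_G, k_windows: int = 2,
                      k_mad: float = 3.0, roll: int = 24) -> np.ndarray:
    """Flag windows where bed motion precedes an extremity spike.

    A window is flagged when bed SMA exceeds ``threshold`` and, within the
    following ``k_windows`` windows, the extremity SMA exceeds its trailing
    rolling median (length ``roll``) by ``k_mad`` rolling MADs.
    """
    bed_sma = np.asarray(bed_sma, dtype=float)
    ext = np.asarray(extremity_sma, dtype=float)
    n = len(bed_sma)
    s = pd.Series(ext)
    med = s.rolling(roll, min_periods=3).median().to_numpy()
    mad = (s - pd.Series(med)).abs().rolling(roll, min_periods=3).median().to_numpy()
    floor = np.nanmax(np.abs(ext[~np.isnan(ext)])) * 1e-3 if np.any(~np.isnan(ext)) else 0.0
    spike = ext > med + k_mad * np.maximum(mad, max(floor, 1e-12))
    spike = np.where(np.isnan(ext) | np.isnan(med) | np.isnan(mad), False, spike)
    mask = np.zeros(n, dtype=bool)
    exceed = np.nan_to_num(bed_sma) > threshold
    for i in np.flatnonzero(exceed):
        if spike[i + 1: i + 1 + k_windows].any():
            mask[i] = True
    return mask


def correct_features(extremity: dict, bed: dict, ranges: StaticRange,
                     rng: np.random.Generator) -> dict:
    """Correct one extremity feature vector for gross external movement.

    SMA, HLF_h, HLF_l, BPW and WVL have the bed values subtracted; MFR and
    FDE have them added.  A corrected value falling outside the feature's
    static-activity range is replaced by a uniform draw from that range.
    """
    for feat in FEATURES:
        if feat not in ranges:
            raise ValueError(f"static range missing for feature {feat}")
    out = dict(extremity)
    for feat in FEATURES:
        e, b = extremity.get(feat, np.nan), bed.get(feat, np.nan)
        if np.isnan(e) or np.isnan(b):
            continue
        v = e - b if feat in _SUBTRACT else e + b
        lo, hi = ranges[feat]
        if not (lo <= v <= hi):
            v = float(rng.uniform(lo, hi))
        out[feat] = v
    return out


def apply_bed_correction(series: WindowFeatureSeries, ranges: StaticRange,
                         rng: np.random.Generator,
                         threshold: float = DYNAMIC_SMA_G,
                         k_windows: int = 2, k_mad: float = 3.0,
                         roll: int = 24) -> WindowFeatureSeries:
    """Apply the external-movement correction to all extremity sensors.

    Runs on the feature series before imputation.  Returns a new series;
    the BED columns are left untouched.
    """
    from .synthetic import EXTREMITIES
    frame = series.frame.copy()
    if ("BED", "SMA") not in frame.columns:
        return WindowFeatureSeries(series.patient_id, frame, series.starts,
                                   series.window_s)
    bed_sma = frame[("BED", "SMA")].to_numpy()
    for placement in EXTREMITIES:
        if (placement, "SMA") not in frame.columns:
            continue
        ext_sma = frame[(placement, "SMA")].to_numpy()
        mask = detect_bed_events(bed_sma, ext_sma, threshold=threshold,
                                 k_windows=k_windows, k_mad=k_mad, roll=roll)
        for i in np.flatnonzero(mask):
            ext_vec = {f: frame.loc[i, (placement, f)] for f in FEATURES}
            bed_vec = {f: frame.loc[i, ("BED", f)] for f in FEATURES}
            corrected = correct_features(ext_vec, bed_vec, ranges, rng)
            for f in FEATURES:
                frame.loc[i, (placement, f)] = corrected[f]
    return WindowFeatureSeries(series.patient_id, frame, series.starts,
                               series.window_s)


def features_to_tidy(series: WindowFeatureSeries) -> pd.DataFrame:
    """Tidy CSV form: patient, placement, window_start_s, feature, value, missing."""
    rows = series.frame.stack(["placement", "feature"], future_stack=True)
    tidy = rows.rename("value").reset_index()
    tidy.columns = ["window", "placement", "feature", "value"]
    tidy["window_start_s"] = series.starts[tidy["window"].to_numpy()]
    tidy["missing"] = tidy["value"].isna()
    tidy.insert(0, "patient", series.patient_id)
    return tidy[["patient", "placement", "window_start_s", "feature", "value", "missing"]]
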