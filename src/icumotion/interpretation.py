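"""Feature-significance mapping and sliding-window state monitoring.

Significance of a sensor-feature combination in a fitted model is the mean
absolute LOL loading of the combination's columns weighted by the absolute
logistic coefficient of the corresponding component, summed over
components, then averaged across the cross-validation splits; bootstrap
resampling across splits yields 95% intervals for each of the
6 placements x 8 feature types cells.

The monitor replays a recording through two fitted detection bundles (a
short, reactive observation window such as 27 min and a long, stable one
such as 6 h), predicting every 10 minutes; uncertainty at each step is a
bootstrap over the per-imputation predictions.  Crossings of the 0.5
boundary (with a two-step debounce) are paired with the nearest clinical
GCSm transition to report lead or lag times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_TYPES
from .model import InsufficientHistoryError, ModelBundle, assemble_observation
from .synthetic import EXTREMITIES

logger = logging.getLogger(__name__)

MONITOR_STEP_S = 600.0


@dataclass
class SignificanceMatrix:
    """6 placements x 8 feature types grid of (mean, ci_low, ci_high)."""

    mean: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return int(self.mean.size)

    def top_features(self) -> list:
        """Feature types ranked by total significance, descending."""
        return list(self.mean.sum(axis=0).sort_values(ascending=False).index)


@dataclass
class MonitorTrace:
    """Per-step predicted probabilities with bootstrap intervals."""

    patient_id: str
    frame: pd.DataFrame     # time_s, prob_short, lo_short, hi_short, prob_long, ...
    gcsm_events: list

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _bundle_cell_scores(bundle: ModelBundle) -> pd.DataFrame:
    """Per-combination score for one bundle: sum_k mean|L_cols,k| * |beta_k|."""
    meta = bundle.schema.metadata()
    L = np.abs(bundle.lol.loadings)            # (p, d)
    beta = np.abs(bundle.beta[1:bundle.d + 1])  # component coefficients
    weighted = L[:, :len(beta)] * beta[None, :]
    per_col = weighted.sum(axis=1)             # sum over components
    df = pd.DataFrame({"placement": meta.placement, "feature": meta.feature,
                       "score": per_col})
    cell = df.groupby(["placement", "feature"], sort=False)["score"].mean()
    return cell.unstack("feature").reindex(index=list(EXTREMITIES),
                                           columns=list(FEATURE_TYPES))


def feature_significance(bundles, n_resamples: int = 1000,
                         seed: int = 0) -> SignificanceMatrix:
    """Loading-weighted significance across splits with bootstrap intervals.

    ``bundles`` is a sequence of fitted :class:`ModelBundle` objects (one
    per cross-validation split of the chosen configuration); they must
    share a column schema.
    """
    bundles = list(bundles)
    if not bundles:
        raise ValueError("at least one bundle required")
    schema0 = bundles[0].schema
    for b in bundles[1:]:
        if (b.schema.n_steps != schema0.n_steps
                or b.schema.placements != schema0.placements):
            raise ValueError("bundles do not share a column schema")
    per_split = np.stack([_bundle_cell_scores(b).to_numpy() for b in bundles])
    mean = per_split.mean(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence(seed & 0x7FFFFFFF))
    n = len(bundles)
    boots = np.empty((n_resamples,) + mean.shape)
    for i in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        boots[i] = per_split[idx].mean(axis=0)
    lo = np.quantile(boots, 0.025, axis=0)
    hi = np.quantile(boots, 0.975, axis=0)
    index = list(EXTREMITIES)
    cols = list(FEATURE_TYPES)
    return SignificanceMatrix(
        mean=pd.DataFrame(mean, index=index, columns=cols),
        ci_low=pd.DataFrame(lo, index=index, columns=cols),
        ci_high=pd.DataFrame(hi, index=index, columns=cols))


def sliding_monitor(imputed_series: list, bundle_short: ModelBundle,
                    bundle_long: ModelBundle, gcsm_events=None,
                    step_s: float = MONITOR_STEP_S, n_resamples: int = 10_000,
                    seed: int = 0, patient_id: str = "") -> MonitorTrace:
    """Predict both bundles over a sliding grid of times.

    ``imputed_series`` is the list of m completed feature series of one
    patient (one entry when nothing is missing).  At each step with
    sufficient history the observation row is assembled per imputation and
    per bundle; the trace reports the mean probability and a bootstrap 95%
    interval over the per-imputation predictions.  Steps lacking history
    for the long bundle are absent for the long model only.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed & 0x7FFFFFFF))
    m = len(imputed_series)
    series0 = imputed_series[0]
    total_s = len(series0.frame) * series0.window_s
    short_dur = bundle_short.duration_s
    long_dur = bundle_long.duration_s
    # grid anchored to multiples of the step from recording start
    t0 = np.ceil(short_dur / step_s) * step_s
    times = np.arange(t0, total_s + 1e-9, step_s)

    def boot_ci(preds):
        preds = np.asarray(preds, dtype=float)
        if np.ptp(preds) < 1e-15:
            return float(preds[0]), float(preds[0])
        means = rng.integers(0, len(preds), size=(n_resamples, len(preds)))
        sampled = preds[means].mean(axis=1)
        return float(np.quantile(sampled, 0.025)), float(np.quantile(sampled, 0.975))

    rows = []
    for t in times:
        row = {"time_s": float(t)}
        for tag, bundle, dur in (("short", bundle_short, short_dur),
                                 ("long", bundle_long, long_dur)):
            if t < dur:
                row[f"prob_{tag}"] = np.nan
                row[f"lo_{tag}"] = np.nan
                row[f"hi_{tag}"] = np.nan
                continue
            preds = []
            for series in imputed_series:
                try:
                    obs = assemble_observation(series, t, dur)
                except InsufficientHistoryError:
                    preds = []
                    break
                preds.append(float(bundle.predict(obs)[0]))
            if not preds:
                row[f"prob_{tag}"] = np.nan
                row[f"lo_{tag}"] = np.nan
                row[f"hi_{tag}"] = np.nan
                continue
            lo, hi = boot_ci(preds)
            row[f"prob_{tag}"] = float(np.mean(preds))
            row[f"lo_{tag}"] = lo
            row[f"hi_{tag}"] = hi
        rows.append(row)
    frame = pd.DataFrame(rows)
    return MonitorTrace(patient_id=patient_id or series0.patient_id,
                        frame=frame, gcsm_events=list(gcsm_events or []))


def _debounced_crossings(times: np.ndarray, values: np.ndarray,
                         threshold: float, debounce: int) -> list:
    """Crossings of ``threshold`` after suppressing runs shorter than ``debounce``.

    The boolean above/below series is cleaned by absorbing any run shorter
    than ``debounce`` steps into the preceding state, so single-step blips
    produce no crossing; each boundary of the cleaned series is a crossing.
    """
    valid = ~np.isnan(values)
    t = times[valid]
    v = values[valid]
    if len(v) == 0:
        return []
    above = v >= threshold
    # run-length encode
    runs = []            # (start_idx, state, length)
    start = 0
    for i in range(1, len(above) + 1):
        if i == len(above) or above[i] != above[start]:
            runs.append([start, bool(above[start]), i - start])
            start = i
    # absorb short runs into the previous state, merging neighbours
    cleaned = [runs[0]]
    for run in runs[1:]:
        if run[2] < debounce:
            cleaned[-1][2] += run[2]
        elif run[1] == cleaned[-1][1]:
            cleaned[-1][2] += run[2]
        else:
            cleaned.append(run)
    return [(float(t[run[0]]), "up" if run[1] else "down") for run in cleaned[1:]]


def transition_report(trace: MonitorTrace, threshold: float = 0.5,
                      debounce: int = 2, gcsm_boundary: int = 4,
                      which: str = "short") -> list:
    """Pair debounced probability crossings with clinical GCSm transitions.

    Each crossing of ``threshold`` sustained for ``debounce`` steps is
    matched to the nearest clinical crossing of the ``GCSm > gcsm_boundary``
    boundary; the signed lead time (positive = monitor leads the clinical
    evaluation) is reported.  Without clinical transitions the crossings
    are reported unpaired (lead = None).
    """
    frame = trace.frame
    values = frame[f"prob_{which}"].to_numpy(dtype=float)
    times = frame["time_s"].to_numpy(dtype=float)
    crossings = _debounced_crossings(times, values, threshold, debounce)

    clinical = []
    events = sorted(trace.gcsm_events)
    for (t0, s0), (t1, s1) in zip(events, events[1:]):
        above0, above1 = s0 > gcsm_boundary, s1 > gcsm_boundary
        if above0 != above1:
            clinical.append((t1, "up" if above1 else "down"))

    report = []
    for t, direction in crossings:
        if clinical:
            nearest = min(clinical, key=lambda c: abs(c[0] - t))
            lead = nearest[0] - t
        else:
            lead = None
        report.append({"time_s": t, "direction": direction, "lead_s": lead})
    return report
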