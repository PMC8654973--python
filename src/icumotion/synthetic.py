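"""Seeded synthetic ICU accelerometry cohorts.

No clinical accelerometry from severe-brain-injury (SBI) cohorts is openly
available, so every downstream stage of the pipeline is exercised on
synthetic recordings whose ground truth is known.  A patient is modelled as
a continuous-time latent trajectory over the six levels of the motor
component of the Glasgow Coma Scale (GCSm, 1 = no response .. 6 = obeys
commands).  Conditional on the current level, each extremity sensor emits

    gravity baseline (slowly drifting unit-norm orientation)
  + Poisson-scheduled movement bursts (exponentially damped sinusoids whose
    rate, amplitude and dominant frequency band increase with the level)
  + white measurement noise,

while the bed-frame sensor emits only patient-independent bed-movement
bursts.  Recordings are censored by missing-at-random contiguous gaps, the
clinical team scores GCSm at Poisson-scheduled evaluation times, and an
ordinal Glasgow Outcome Scale-Extended (GOSE, 1..8) outcome is drawn from a
proportional-odds model driven by the patient's latent movement activity.

All randomness is a pure function of ``(config, seed)``: every patient and
purpose gets its own ``numpy.random.Generator`` derived from the master
seed through ``SeedSequence`` spawn keys, so enlarging a cohort never
perturbs existing patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EXTREMITIES = ("RE", "LE", "RW", "LW", "RA", "LA")
PLACEMENTS = EXTREMITIES + ("BED",)

#: GCSm distribution at ICU admission (levels 1..6), used as the initial
#: state distribution of the latent trajectory.
GCSM_ADMISSION_P = np.array([0.0580, 0.0435, 0.0870, 0.0580, 0.2464, 0.5072])
GCSM_ADMISSION_P = GCSM_ADMISSION_P / GCSM_ADMISSION_P.sum()

#: Marginal GOSE distributions (scores 1..8) at hospital discharge and at
#: 12 months post discharge in the emulated cohort; the proportional-odds
#: cutpoints are calibrated so that a zero-strength activity link
#: reproduces these marginals.
GOSE_DISCHARGE_P = np.array([0.2319, 0.0580, 0.4348, 0.1594, 0.0870, 0.0145, 0.0145, 0.0])
GOSE_DISCHARGE_P = GOSE_DISCHARGE_P / GOSE_DISCHARGE_P.sum()
GOSE_12MO_P = np.array([0.4375, 0.0312, 0.2188, 0.1875, 0.0469, 0.0, 0.0469, 0.0312])
GOSE_12MO_P = GOSE_12MO_P / GOSE_12MO_P.sum()

_PURPOSES = {
    "trajectory": 1,
    "accel": 2,
    "bed": 3,
    "missing": 4,
    "events": 5,
    "orientation": 6,
}
_PLACEMENT_CODE = {p: i for i, p in enumerate(PLACEMENTS)}


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative conditions for one synthetic cohort.

    Rates are per-level sequences indexed by GCSm level 1..6 (element 0 is
    level 1).  Amplitudes are in g, frequencies in Hz, times in hours.
    """

    n_patients: int = 10
    recording_hours: float = 24.0
    fs: float = 10.0
    gcsm_eval_rate: float = 9.25            # evaluations / day
    state_dwell_mean: float = 3.0           # hours
    movement_rate_by_state: tuple = (5.0, 15.0, 40.0, 100.0, 250.0, 600.0)  # bursts/h
    movement_amp_by_state: tuple = (0.30, 0.34, 0.38, 0.42, 0.46, 0.50)     # g
    movement_freq_band_by_state: tuple = (
        (0.3, 0.8), (0.4, 1.0), (0.5, 1.5), (0.8, 2.2), (1.0, 3.0), (1.5, 4.0))
    wrist_hf_multiplier: float = 1.3        # extra high-frequency content, levels 5-6
    bed_event_rate: float = 2.0             # bursts / h
    bed_event_amp: float = 0.45             # g
    bed_coupling: float = 0.0               # fraction of bed burst leaked to extremities
    noise_sigma: float = 0.01               # g
    missing_fraction: float = 0.016
    missing_gap_mean_s: float = 300.0
    outcome_link_strength: float = 0.0      # log-odds per SD of latent activity
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.recording_hours <= 0:
            raise InvalidConfigError("recording duration must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise InvalidConfigError("missing_fraction must lie in [0, 1)")
        if self.state_dwell_mean <= 0:
            raise InvalidConfigError("state dwell mean must be positive")
        if self.gcsm_eval_rate < 0 or self.bed_event_rate < 0:
            raise InvalidConfigError("rates must be nonnegative")
        if any(r < 0 for r in self.movement_rate_by_state):
            raise InvalidConfigError("movement rates must be nonnegative")
        amps = np.asarray(self.movement_amp_by_state, dtype=float)
        if np.any(np.diff(amps) < 0):
            raise InvalidConfigError("movement amplitude must be non-decreasing with level")

    @property
    def n_samples(self) -> int:
        return int(round(self.recording_hours * 3600 * self.fs))


@dataclass(frozen=True)
class LatentTrajectory:
    """Ground-truth GCSm trajectory: contiguous (start_s, end_s, level) segments."""

    patient_id: str
    segments: tuple  # of (start_s, end_s, level)

    def level_at(self, t: float | np.ndarray) -> np.ndarray:
        """GCSm level at time(s) ``t`` seconds (right-open segments)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s[0] for s in self.segments])
        levels = np.array([s[2] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(levels) - 1)
        return levels[idx]

    @property
    def span(self) -> tuple:
        return self.segments[0][0], self.segments[-1][1]


@dataclass
class SensorRecording:
    """One patient's multichannel recording plus clinical annotations.

    ``streams`` maps placement -> DataFrame with columns
    ``time_s, x_g, y_g, z_g, missing`` (missing samples keep NaN axes).
    """

    patient_id: str
    fs: float
    streams: dict
    gcsm_events: list               # of (time_s, score)
    gose_discharge: int
    gose_12mo: int | None
    trajectory: LatentTrajectory | None = None

    def missing_fraction(self, placement: str) -> float:
        m = self.streams[placement]["missing"].to_numpy()
        return float(m.mean()) if len(m) else 0.0


@dataclass
class Cohort:
    config: CohortConfig
    recordings: list

    def __iter__(self):
        return iter(self.recordings)

    def __len__(self):
        return len(self.recordings)


def _rng(seed: int, patient_index: int, purpose: str, extra: int = 0) -> np.random.Generator:
    """Independent generator for one (patient, purpose) pair."""
    ss = np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF,
        spawn_key=(int(patient_index), _PURPOSES[purpose], int(extra)),
    )
    return np.random.Generator(np.random.PCG64(ss))


# ---------------------------------------------------------------------------
# Latent trajectory


def generate_trajectory(config: CohortConfig, patient_seed: int) -> LatentTrajectory:
    """Simulate the semi-Markov GCSm trajectory of one patient.

    Dwell times are exponential with mean ``config.state_dwell_mean`` hours;
    transitions move one level up or down with reflecting bounds at 1 and 6.
    The initial level is drawn from the admission GCSm distribution.
    """
    if config.state_dwell_mean <= 0:
        raise InvalidConfigError("state dwell mean must be positive")
    rng = _rng(config.seed, patient_seed, "trajectory")
    total_s = config.recording_hours * 3600.0
    level = int(rng.choice(np.arange(1, 7), p=GCSM_ADMISSION_P))
    t = 0.0
    segments = []
    while t < total_s:
        dwell = rng.exponential(config.state_dwell_mean * 3600.0)
        end = min(t + dwell, total_s)
        segments.append((t, end, level))
        t = end
        if level == 1:
            level = 2
        elif level == 6:
            level = 5
        else:
            level = level + 1 if rng.random() < 0.5 else level - 1
    return LatentTrajectory(patient_id=f"P{patient_seed:03d}", segments=tuple(segments))


# ---------------------------------------------------------------------------
# Accelerometry synthesis


def _drifting_gravity(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly drifting unit-norm orientation (gravity direction), (n, 3)."""
    knot_spacing_s = 600.0
    n_knots = max(int(np.ceil(n / fs / knot_spacing_s)) + 2, 2)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    knots = [v]
    for _ in range(n_knots - 1):
        w = knots[-1] + 0.15 * rng.normal(size=3)
        knots.append(w / np.linalg.norm(w))
    knots = np.array(knots)
    kt = np.arange(n_knots) * knot_spacing_s
    t = np.arange(n) / fs
    g = np.empty((n, 3))
    for a in range(3):
        g[:, a] = np.interp(t, kt, knots[:, a])
    g /= np.sqrt((g * g).sum(axis=1))[:, None]
    return g


def _add_bursts(sig: np.ndarray, fs: float, times: np.ndarray, amps: np.ndarray,
                freqs: np.ndarray, durs: np.ndarray, dirs: np.ndarray) -> None:
    """Superimpose damped-sinusoid bursts onto ``sig`` (n, 3), in place.

    Vectorized over events: every burst occupies a row of a (n_events,
    L_max) lattice which is scatter-added into the signal.
    """
    n = sig.shape[0]
    n_ev = len(times)
    if n_ev == 0:
        return
    times = np.asarray(times, dtype=float)
    durs = np.asarray(durs, dtype=float)
    i0 = (times * fs).astype(int)
    lengths = np.minimum((durs * fs).astype(int) + 1, n - i0)
    lmax = int(lengths.max()) if len(lengths) else 0
    if lmax <= 0:
        return
    steps = np.arange(lmax)
    tt = steps[None, :] / fs                                    # (n_ev, lmax)
    tau = (durs / 2.0)[:, None]
    wave = (np.asarray(amps)[:, None] * np.exp(-tt / tau)
            * np.sin(2 * np.pi * np.asarray(freqs)[:, None] * tt))
    idx = i0[:, None] + steps[None, :]
    valid = (steps[None, :] < lengths[:, None]) & (idx < n) & (i0[:, None] < n)
    contrib = wave[:, :, None] * np.asarray(dirs)[:, None, :]   # (n_ev, lmax, 3)
    np.add.at(sig, idx[valid], contrib[valid])


def _bed_bursts(config: CohortConfig, patient_seed: int):
    """Bed-movement burst parameters; independent of the patient trajectory."""
    rng = _rng(config.seed, patient_seed, "bed")
    total_s = config.recording_hours * 3600.0
    n_ev = rng.poisson(config.bed_event_rate * config.recording_hours)
    times = np.sort(rng.uniform(0, total_s, size=n_ev))
    amps = config.bed_event_amp * rng.uniform(0.6, 1.4, size=n_ev)
    freqs = rng.uniform(0.4, 1.5, size=n_ev)
    durs = rng.uniform(1.0, 4.0, size=n_ev)
    dirs = rng.normal(size=(n_ev, 3))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = np.where(norms > 0, dirs / norms, np.array([[1.0, 0, 0]]))
    return times, amps, freqs, durs, dirs


def synthesize_accelerometry(trajectory: LatentTrajectory, placement: str,
                             config: CohortConfig, patient_seed: int) -> pd.DataFrame:
    """Synthesize one placement's triaxial stream (time_s, x_g, y_g, z_g).

    Extremity placements combine a drifting gravity baseline, level-dependent
    movement bursts and white noise; wrist placements get extra
    high-frequency content at levels 5-6.  The BED placement contains only
    patient-independent bed bursts (plus noise) and does not depend on the
    trajectory.
    """
    if placement not in PLACEMENTS:
        raise ValueError(f"unknown placement {placement!r}")
    n = config.n_samples
    fs = config.fs
    t = np.arange(n) / fs
    code = _PLACEMENT_CODE[placement]

    if placement == "BED":
        rng = _rng(config.seed, patient_seed, "bed", extra=100)
        sig = np.zeros((n, 3))
        _add_bursts(sig, fs, *_bed_bursts(config, patient_seed))
        if config.noise_sigma > 0:
            sig += rng.normal(0.0, config.noise_sigma, size=(n, 3))
        np.clip(sig, -16.0, 16.0, out=sig)
        return pd.DataFrame({"time_s": t, "x_g": sig[:, 0], "y_g": sig[:, 1],
                             "z_g": sig[:, 2], "missing": False})

    rng = _rng(config.seed, patient_seed, "accel", extra=code)
    orient_rng = _rng(config.seed, patient_seed, "orientation", extra=code)
    sig = _drifting_gravity(n, fs, orient_rng)

    is_wrist = placement in ("RW", "LW")
    total_s = config.recording_hours * 3600.0
    for (seg_start, seg_end, level) in trajectory.segments:
        seg_end = min(seg_end, total_s)
        if seg_end <= seg_start:
            continue
        rate = config.movement_rate_by_state[level - 1] / 3600.0  # per second
        n_ev = rng.poisson(rate * (seg_end - seg_start))
        if n_ev == 0:
            continue
        times = np.sort(rng.uniform(seg_start, seg_end, size=n_ev))
        amp0 = config.movement_amp_by_state[level - 1]
        amps = amp0 * rng.uniform(0.7, 1.3, size=n_ev)
        lo, hi = config.movement_freq_band_by_state[level - 1]
        freqs = rng.uniform(lo, hi, size=n_ev)
        if is_wrist and level >= 5:
            freqs = freqs * config.wrist_hf_multiplier
        durs = rng.uniform(0.5, 3.0, size=n_ev)
        dirs = rng.normal(size=(n_ev, 3))
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = np.where(norms > 0, dirs / norms, np.array([[1.0, 0, 0]]))
        _add_bursts(sig, fs, times, amps, freqs, durs, dirs)

    if config.bed_coupling > 0:
        bt, ba, bf, bd, bdir = _bed_bursts(config, patient_seed)
        _add_bursts(sig, fs, bt, config.bed_coupling * ba, bf, bd, bdir)

    if config.noise_sigma > 0:
        sig += rng.normal(0.0, config.noise_sigma, size=(n, 3))
    np.clip(sig, -16.0, 16.0, out=sig)
    return pd.DataFrame({"time_s": t, "x_g": sig[:, 0], "y_g": sig[:, 1],
                         "z_g": sig[:, 2], "missing": False})


# ---------------------------------------------------------------------------
# Missingness


def apply_missingness(recording: SensorRecording, config: CohortConfig,
                      patient_seed: int) -> SensorRecording:
    """Censor contiguous gaps per sensor, independent of placement and time.

    Gap count is Poisson with mean chosen so the expected deleted fraction
    equals ``config.missing_fraction``; gap starts are uniform over the
    recording and lengths exponential with mean ``missing_gap_mean_s``.  The
    realized deleted fraction is capped at three times the target.  Censored
    samples have NaN axes and ``missing=True``.
    """
    if config.missing_fraction == 0:
        return recording
    total_s = config.recording_hours * 3600.0
    cap = 3.0 * config.missing_fraction * total_s
    streams = {}
    for placement, df in recording.streams.items():
        rng = _rng(config.seed, patient_seed, "missing",
                   extra=_PLACEMENT_CODE[placement])
        mean_gaps = config.missing_fraction * total_s / config.missing_gap_mean_s
        n_gaps = rng.poisson(mean_gaps)
        starts = rng.uniform(0, total_s, size=n_gaps)
        lengths = rng.exponential(config.missing_gap_mean_s, size=n_gaps)
        df = df.copy()
        mask = df["missing"].to_numpy().copy()
        tvec = df["time_s"].to_numpy()
        deleted = 0.0
        for s, length in zip(starts, lengths):
            if deleted >= cap:
                break
            length = min(length, cap - deleted)
            sel = (tvec >= s) & (tvec < s + length)
            mask |= sel
            deleted += length
        df.loc[mask, ["x_g", "y_g", "z_g"]] = np.nan
        df["missing"] = mask
        streams[placement] = df
    return dataclasses.replace(recording, streams=streams)


# ---------------------------------------------------------------------------
# Clinical events and outcomes


def _activity_z(trajectory: LatentTrajectory, config: CohortConfig) -> float:
    """Latent activity driver: time-weighted mean of rate*amplitude, standardized.

    The per-level score rate*amp mirrors the proportion-of-dynamic-activity
    signal that dominates the fitted models; standardization uses the
    across-level mean and SD of the score so the link strength is in
    log-odds per SD.
    """
    scores = np.asarray(config.movement_rate_by_state) * np.asarray(config.movement_amp_by_state)
    w = np.zeros(6)
    for s0, s1, level in trajectory.segments:
        w[level - 1] += s1 - s0
    w = w / w.sum()
    a = float(np.dot(w, scores))
    sd = float(np.std(scores))
    return (a - float(np.mean(scores))) / sd if sd > 0 else 0.0


def _draw_gose(p_marginal: np.ndarray, eta: float, rng: np.random.Generator) -> int:
    """Proportional-odds draw: cutpoints from the zero-link marginal."""
    cum = np.clip(np.cumsum(p_marginal)[:-1], 1e-12, 1 - 1e-12)
    c = np.log(cum / (1 - cum))            # logit cutpoints for scores 1..7
    # zero marginal mass above the last nonzero score keeps its cutpoint at +inf
    c = np.where(np.cumsum(p_marginal)[:-1] >= 1 - 1e-12, np.inf, c)
    p_le = 1.0 / (1.0 + np.exp(-(c - eta)))
    p_le = np.concatenate([p_le, [1.0]])
    u = rng.random()
    return int(np.searchsorted(p_le, u) + 1)


def schedule_gcsm_and_outcomes(trajectory: LatentTrajectory, config: CohortConfig,
                               patient_seed: int):
    """Poisson GCSm evaluation schedule plus proportional-odds GOSE outcomes.

    Evaluation times follow a homogeneous Poisson process at
    ``config.gcsm_eval_rate`` per day; each recorded score is the latent
    level at that instant.  GOSE at discharge and at 12 months are drawn
    from proportional-odds models whose linear predictor is
    ``outcome_link_strength`` times the standardized latent activity, with
    cutpoints calibrated so a zero link reproduces the cohort marginals.
    """
    if not trajectory.segments:
        raise ValueError("trajectory must be nonempty")
    rng = _rng(config.seed, patient_seed, "events")
    total_s = config.recording_hours * 3600.0
    rate_per_s = config.gcsm_eval_rate / 86400.0
    n_ev = rng.poisson(rate_per_s * total_s)
    times = np.sort(rng.uniform(0, total_s, size=n_ev))
    scores = trajectory.level_at(times)
    gcsm_events = [(float(t), int(s)) for t, s in zip(times, scores)]

    eta = config.outcome_link_strength * _activity_z(trajectory, config)
    gose_discharge = _draw_gose(GOSE_DISCHARGE_P, eta, rng)
    gose_12mo = _draw_gose(GOSE_12MO_P, eta, rng)
    return gcsm_events, gose_discharge, gose_12mo


# ---------------------------------------------------------------------------
# Cohort assembly and I/O


def generate_patient(config: CohortConfig, patient_index: int) -> SensorRecording:
    """Generate one complete patient recording (trajectory kept as ground truth)."""
    traj = generate_trajectory(config, patient_index)
    streams = {p: synthesize_accelerometry(traj, p, config, patient_index)
               for p in PLACEMENTS}
    gcsm_events, gose_d, gose_12 = schedule_gcsm_and_outcomes(traj, config, patient_index)
    rec = SensorRecording(
        patient_id=traj.patient_id, fs=config.fs, streams=streams,
        gcsm_events=gcsm_events, gose_discharge=gose_d, gose_12mo=gose_12,
        trajectory=traj,
    )
    return apply_missingness(rec, config, patient_index)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full seeded cohort."""
    return Cohort(config=config,
                  recordings=[generate_patient(config, i) for i in range(config.n_patients)])


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write long-format sensor CSVs, event CSVs and cohort metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": dataclasses.asdict(cohort.config), "patients": []}
    for rec in cohort.recordings:
        frames = []
        for placement, df in rec.streams.items():
            d = df.copy()
            d.insert(1, "placement", placement)
            frames.append(d)
        long = pd.concat(frames, ignore_index=True)
        long.to_csv(out / f"{rec.patient_id}_sensors.csv", index=False)
        ev = pd.DataFrame(rec.gcsm_events, columns=["time_s", "gcsm"])
        ev.to_csv(out / f"{rec.patient_id}_events.csv", index=False)
        meta["patients"].append({
            "patient_id": rec.patient_id,
            "gose_discharge": rec.gose_discharge,
            "gose_12mo": rec.gose_12mo,
        })
    with open(out / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    with open(src / "cohort.json") as fh:
        meta = json.load(fh)
    cfg_d = dict(meta["config"])
    for key in ("movement_rate_by_state", "movement_amp_by_state"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg_d["movement_freq_band_by_state"] = tuple(
        tuple(b) for b in cfg_d["movement_freq_band_by_state"])
    config = CohortConfig(**cfg_d)
    recordings = []
    for pat in meta["patients"]:
        pid = pat["patient_id"]
        long = pd.read_csv(src / f"{pid}_sensors.csv")
        streams = {}
        for placement, grp in long.groupby("placement", sort=False):
            streams[placement] = grp.drop(columns="placement").reset_index(drop=True)
        ev = pd.read_csv(src / f"{pid}_events.csv")
        events = [(float(r.time_s), int(r.gcsm)) for r in ev.itertuples()]
        recordings.append(SensorRecording(
            patient_id=pid, fs=config.fs, streams=streams, gcsm_events=events,
            gose_discharge=int(pat["gose_discharge"]),
            gose_12mo=None if pat["gose_12mo"] is None else int(pat["gose_12mo"]),
        ))
    return Cohort(config=config, recordings=recordings)
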