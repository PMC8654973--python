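"""Scaled synthetic-cohort studies exercising the pipeline end to end.

Each study generates its own seeded cohort, runs the relevant pipeline
stages and returns plain dictionaries of computed quantities.  Problem
sizes are scaled desk-top versions of the full protocol (rationale in
docs/methods.md): short recordings, a dense evaluation schedule, and a
3-window x 3-d grid instead of the full 19 x 19.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import evaluation as ev
from . import model as md
from .features import WindowFeatureSeries, extract_features
from .impute import ImputationConfig, impute_multiple
from .interpretation import feature_significance, sliding_monitor, transition_report
from .pipeline import gcsm_evaluations, prepare_cohort_features, run_grid
from .synthetic import (CohortConfig, LatentTrajectory, SensorRecording,
                        generate_cohort, generate_patient, PLACEMENTS,
                        synthesize_accelerometry)

logger = logging.getLogger(__name__)

#: Reference validation-set class-count pairs (negative, positive) of the
#: emulated clinical cohort, with their reported no-information rates;
#: used as worked-example inputs for the metric arithmetic.
CLASS_COUNT_PAIRS = {
    ("GCSm", 1): (15, 244, 0.94),
    ("GCSm", 2): (84, 480, 0.85),
    ("GCSm", 3): (175, 424, 0.71),
    ("GCSm", 4): (166, 322, 0.66),
    ("GCSm", 5): (344, 255, 0.57),
    ("GOSE_discharge", 1): (120, 368, 0.75),
    ("GOSE_discharge", 2): (89, 245, 0.73),
    ("GOSE_discharge", 3): (451, 198, 0.69),
    ("GOSE_discharge", 4): (567, 77, 0.88),
    ("GOSE_discharge", 5): (479, 9, 0.98),
    ("GOSE_12mo", 1): (270, 339, 0.56),
    ("GOSE_12mo", 2): (288, 329, 0.53),
    ("GOSE_12mo", 3): (390, 203, 0.66),
    ("GOSE_12mo", 4): (488, 105, 0.82),
    ("GOSE_12mo", 5): (538, 70, 0.88),
    ("GOSE_12mo", 6): (538, 70, 0.88),
    ("GOSE_12mo", 7): (591, 24, 0.96),
}


def null_calibration_study(n_replicates: int = 100, n_patients: int = 40,
                           seed: int = 0, n_resamples: int = 1000) -> dict:
    """BBC-CV interval coverage of AUC = 0.5 on null outcome cohorts.

    Each replicate draws a fresh cohort with ``outcome_link_strength = 0``
    (outcomes independent of activity), runs the 3-window x 3-d
    GOSE-discharge > 3 grid under repeated stratified CV and asks whether
    the 95% BBC-CV interval for AUC covers 0.5.
    """
    covered = 0
    used = 0
    means = []
    for rep in range(n_replicates):
        cfg = CohortConfig(n_patients=n_patients, recording_hours=0.5,
                           gcsm_eval_rate=192.0, missing_fraction=0.0,
                           outcome_link_strength=0.0,
                           seed=(seed * 100003 + rep) & 0x7FFFFFFF)
        cohort = generate_cohort(cfg)
        try:
            res = run_grid(cohort, windows_s=[180, 360, 540], d_grid=[2, 5, 8],
                           thresholds=[3], endpoint="GOSE_discharge",
                           seed=cfg.seed, repeats=2)
            est = res.bbc_cv_ci(3, n_resamples=n_resamples, seed=cfg.seed)
        except ValueError:
            # degenerate cohort (e.g. a fold without both classes everywhere)
            continue
        used += 1
        means.append(est.mean)
        if est.ci_low <= 0.5 <= est.ci_high:
            covered += 1
    return {"n_replicates": used, "n_covered": covered,
            "coverage": covered / used if used else np.nan,
            "mean_auc": float(np.mean(means)) if means else np.nan}


def signal_recovery_study(seed: int = 0, n_patients: int = 60,
                          n_resamples: int = 1000) -> dict:
    """GCSm > 4 detection on a cohort with a strong state-activity link.

    2-h recordings, dense evaluation schedule, 9/18/27-min windows,
    d in {2, 5, 8}; returns BBC-CV AUC estimates for GCSm > 4 and > 1 and
    the feature-significance ranking of the optimal configuration.
    """
    cfg = CohortConfig(n_patients=n_patients, recording_hours=2.0,
                       gcsm_eval_rate=96.0, missing_fraction=0.0,
                       seed=seed & 0x7FFFFFFF)
    cohort = generate_cohort(cfg)
    res = run_grid(cohort, windows_s=[540, 1080, 1620], d_grid=[2, 5, 8],
                   thresholds=[4, 1], endpoint="GCSm", seed=cfg.seed)
    est4 = res.bbc_cv_ci(4, n_resamples=n_resamples, seed=cfg.seed)
    est1 = res.bbc_cv_ci(1, n_resamples=n_resamples, seed=cfg.seed)

    # significance matrix of the optimally discriminating configuration
    w0, d0, _ = res.select_optimal(4)
    feats = prepare_cohort_features(cohort, m=1, seed=cfg.seed, bed_correction=False)
    evals, strata = gcsm_evaluations(cohort)
    series = {pid: c[0] for pid, c in feats.items()}
    obs = md.assemble_matrix(series, evals, w0, log_skipped=False)
    plan = ev.partition_repeated_cv(sorted(series), strata, m=1, seed=cfg.seed)
    bundles = []
    for train, _, _ in plan.splits:
        tr = obs.rows_for(train)
        sub = md.ObservationMatrix(obs.values[tr], obs.schema, obs.patients[tr],
                                   obs.eval_times[tr], obs.scores[tr])
        if np.unique(sub.labels(4)).size < 2:
            continue
        bundles.append(md.fit_bundles_multi_d(sub, 4, [int(d0)],
                                              endpoint="GCSm")[int(d0)])
    sig = feature_significance(bundles, n_resamples=200, seed=seed)
    ranking = sig.top_features()
    return {"auc_gt4": est4, "auc_gt1": est1, "optimal": (w0, int(d0)),
            "significance": sig, "feature_ranking": ranking}


def imputation_recovery_study(seed: int = 0, n_rows: int = 300,
                              n_cols: int = 49, rho: float = 0.8,
                              mask_fraction: float = 0.05, m: int = 9) -> dict:
    """Held-out recovery of masked entries on a correlated feature set.

    A positive, skewed, equicorrelated matrix is masked completely at
    random; the bootstrap-EM imputer (cross-sectional correlation only)
    is compared column-wise against marginal-mean imputation by RMSE on
    the held-out truth.
    """
    import pandas as pd
    from .features import FEATURES
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    shared = rng.normal(size=(n_rows, 1))
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=(n_rows, n_cols))
    vals = np.exp(0.5 * z)
    mask = rng.random(vals.shape) < mask_fraction
    cols = [(p, f) for p in PLACEMENTS for f in FEATURES][:n_cols]
    frame = pd.DataFrame(np.where(mask, np.nan, vals),
                         columns=pd.MultiIndex.from_tuples(
                             cols, names=["placement", "feature"]))
    series = WindowFeatureSeries(patient_id="SYN", frame=frame,
                                 starts=np.arange(n_rows) * 5.0)
    comps = impute_multiple(series, ImputationConfig(m=m, seed=seed,
                                                     n_lags=0, n_leads=0))
    stack = np.stack([c.frame.to_numpy() for c in comps])
    observed_altered = bool(np.any(stack[:, ~mask] != vals[~mask]))
    between_var = stack.var(axis=0)
    frac_masked_varying = float((between_var[mask] > 1e-20).mean())
    differ_only_at_masked = (not observed_altered) and frac_masked_varying > 0.99
    imputed = stack.mean(axis=0)
    col_means = np.nanmean(np.where(mask, np.nan, vals), axis=0)
    wins, total = 0, 0
    for j in range(n_cols):
        mj = mask[:, j]
        if mj.sum() < 3:
            continue
        rmse_imp = float(np.sqrt(np.mean((imputed[mj, j] - vals[mj, j]) ** 2)))
        rmse_mean = float(np.sqrt(np.mean((col_means[j] - vals[mj, j]) ** 2)))
        total += 1
        wins += rmse_imp < rmse_mean
    return {"n_columns": total, "n_wins": wins,
            "win_fraction": wins / total if total else np.nan,
            "observed_altered": observed_altered,
            "frac_masked_varying": frac_masked_varying,
            "differ_only_at_masked": differ_only_at_masked, "m": m}


def _transition_patient(cfg: CohortConfig, patient_seed: int,
                        transition_h: float) -> SensorRecording:
    """One patient pinned at level 6 then level 2 after ``transition_h``."""
    total_s = cfg.recording_hours * 3600.0
    traj = LatentTrajectory(f"CASE{patient_seed}", (
        (0.0, transition_h * 3600.0, 6),
        (transition_h * 3600.0, total_s, 2)))
    streams = {p: synthesize_accelerometry(traj, p, cfg, patient_seed)
               for p in PLACEMENTS}
    events = [(transition_h * 3600.0 + 600.0, 2)]
    return SensorRecording(traj.patient_id, cfg.fs, streams, events, 3, 3,
                           trajectory=traj)


def monitor_case_study(seed: int = 0, n_train: int = 12,
                       transition_h: float = 8.0,
                       recording_h: float = 14.0) -> dict:
    """Sliding monitor on a patient with a persistent level-6 -> level-2 drop.

    Two GCSm > 4 detection models (27-min and 6-h observation windows) are
    trained on a separate synthetic cohort and replayed over the case
    recording at 10-min steps; returns both traces and their debounced
    downward crossing times.
    """
    cfg = CohortConfig(n_patients=n_train, recording_hours=recording_h,
                       gcsm_eval_rate=24.0, missing_fraction=0.0,
                       seed=seed & 0x7FFFFFFF)
    cohort = generate_cohort(cfg)
    feats = prepare_cohort_features(cohort, m=1, seed=cfg.seed,
                                    bed_correction=False)
    evals, _ = gcsm_evaluations(cohort)
    series = {pid: c[0] for pid, c in feats.items()}
    bundles = {}
    for dur in (27 * 60.0, 6 * 3600.0):
        obs = md.assemble_matrix(series, evals, dur, log_skipped=False)
        bundles[dur] = md.fit_bundles_multi_d(obs, 4, [4], endpoint="GCSm")[4]

    case = _transition_patient(cfg, n_train + 1, transition_h)
    case_series = extract_features(case)
    trace = sliding_monitor([case_series], bundles[27 * 60.0],
                            bundles[6 * 3600.0], gcsm_events=case.gcsm_events,
                            n_resamples=100, seed=seed)
    report = {}
    for tag in ("short", "long"):
        crossings = transition_report(trace, which=tag, gcsm_boundary=4)
        downs = [c for c in crossings if c["direction"] == "down"]
        report[tag] = downs
    return {"trace": trace, "down_short": report["short"],
            "down_long": report["long"], "transition_s": transition_h * 3600.0}
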