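"""End-to-end cohort workflows: features -> correction -> imputation -> grid.

Convenience runners that chain the pipeline stages for a whole synthetic
cohort, used by the command line, the acceptance script and the scaled
end-to-end studies.
"""

from __future__ import annotations

import logging

import numpy as np

from . import evaluation as ev
from . import model as md
from .features import (apply_bed_correction, estimate_static_ranges,
                       extract_features)
from .impute import ImputationConfig, impute_multiple
from .synthetic import Cohort

logger = logging.getLogger(__name__)


def prepare_cohort_features(cohort: Cohort, m: int = 1, seed: int = 0,
                            bed_correction: bool = True) -> dict:
    """Extract, bed-correct and multiply impute features for every patient.

    Returns ``patient_id -> [m completed WindowFeatureSeries]``.  Static
    activity ranges for the correction are estimated cohort-wide from
    windows where every extremity sensor is below the dynamic threshold.
    """
    raw = {rec.patient_id: extract_features(rec) for rec in cohort}
    if bed_correction:
        ranges = estimate_static_ranges(list(raw.values()))
        rng = np.random.default_rng(np.random.SeedSequence((seed & 0x7FFFFFFF, 17)))
        raw = {pid: apply_bed_correction(series, ranges, rng)
               for pid, series in raw.items()}
    out = {}
    for i, (pid, series) in enumerate(sorted(raw.items())):
        cfg = ImputationConfig(m=m, seed=(seed + 7919 * i) & 0x7FFFFFFF)
        if series.frame.isna().to_numpy().any():
            out[pid] = impute_multiple(series, cfg)
        else:
            out[pid] = [series] * m
    return out


def gcsm_evaluations(cohort: Cohort):
    """(patient, time, GCSm score) rows plus median-GCSm strata."""
    evals, strata = [], {}
    for rec in cohort:
        strata[rec.patient_id] = ev.median_gcsm_stratum(rec.gcsm_events)
        for t, s in rec.gcsm_events:
            evals.append((rec.patient_id, t, s))
    return evals, strata


def gose_evaluations(cohort: Cohort, which: str = "discharge"):
    """(patient, time, GOSE score) rows (one per GCSm evaluation time).

    Observation rows are anchored at clinical evaluation times; the label
    is the patient-level outcome.  Patients lacking the outcome are
    dropped.  Strata are the GOSE scores themselves.
    """
    evals, strata = [], {}
    for rec in cohort:
        score = rec.gose_discharge if which == "discharge" else rec.gose_12mo
        if score is None:
            continue
        strata[rec.patient_id] = int(score)
        for t, _ in rec.gcsm_events:
            evals.append((rec.patient_id, t, int(score)))
    return evals, strata


def run_grid(cohort: Cohort, windows_s, d_grid, thresholds, endpoint: str = "GCSm",
             m: int = 1, seed: int = 0, repeats: int = 5, folds: int = 5,
             bed_correction: bool = False, keep_bundles: bool = False):
    """Full cross-validated grid for one endpoint on a synthetic cohort."""
    features = prepare_cohort_features(cohort, m=m, seed=seed,
                                       bed_correction=bed_correction)
    if endpoint == "GCSm":
        evals, strata = gcsm_evaluations(cohort)
    elif endpoint == "GOSE_discharge":
        evals, strata = gose_evaluations(cohort, "discharge")
    else:
        evals, strata = gose_evaluations(cohort, "12mo")
    evals = [e for e in evals if e[0] in features]
    mats = {}
    for w in windows_s:
        per_imp = []
        for i in range(m):
            series_i = {pid: comps[min(i, len(comps) - 1)]
                        for pid, comps in features.items()}
            per_imp.append(md.assemble_matrix(series_i, evals, w, log_skipped=False))
        mats[w] = per_imp
    plan = ev.partition_repeated_cv(sorted(features), strata, repeats=repeats,
                                    folds=folds, m=m, seed=seed)
    grid = ev.GridEvaluation(mats, plan, thresholds=thresholds, d_grid=d_grid,
                             endpoint=endpoint)
    return grid.run(keep_bundles=keep_bundles)
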