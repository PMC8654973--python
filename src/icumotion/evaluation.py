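"""Cross-validated grid evaluation with bias-corrected uncertainty.

The cohort is partitioned 25 times by repeated stratified k-fold
cross-validation (5 repeats of 5 folds; GCSm endpoints stratify patients
by their median observed score, outcome endpoints by GOSE), with one of
the m imputations drawn with replacement for each partition.  For every
(split, observation window, LOL dimensionality, threshold) the pipeline is
fitted on the training patients and produces out-of-fold probabilities for
the validation patients; pooled predictions feed discrimination (AUC,
Mann-Whitney with tie half-credit), classification metrics at the 0.5
boundary, precision-recall / average precision, and flexible-calibration
indices (ICI, E_max).

Because the reported configuration is itself selected by maximal AUC,
naive pooled metrics are optimistic.  Bootstrap bias-corrected
cross-validation (BBC-CV) removes that optimism: each of 1000 patient-level
bootstrap resamples selects the best configuration on in-bag patients'
pooled out-of-fold predictions and evaluates it on out-of-bag patients;
the mean and bias-corrected percentile interval over resamples estimate
the deployable performance.  Variation across the patient set, the m
imputations and the 25 partitions is inherited through the pooled store.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import (ObservationMatrix, ThresholdModel, fit_bundles_multi_d,
                    predict_proba, yeo_johnson_apply)

logger = logging.getLogger(__name__)

#: Fraction of points used by the local-linear calibration smoother
#: (plug-in constant on the logit scale; see docs/methods.md).
CALIBRATION_LOWESS_FRAC = 2.0 / 3.0


@dataclass
class PartitionPlan:
    """25 = repeats x folds splits of the patient set."""

    repeats: int
    folds: int
    splits: list          # of (train_ids, validation_ids, imputation_index)
    strata: dict          # patient -> stratum label

    def __len__(self):
        return len(self.splits)


@dataclass
class MetricEstimate:
    """BBC-CV summary of one metric."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    n_resamples: int
    n_dropped: int = 0
    selected: dict = field(default_factory=dict)   # modal selected configuration


def partition_repeated_cv(patients, stratum_labels: dict, repeats: int = 5,
                          folds: int = 5, m: int = 9, seed: int = 0) -> PartitionPlan:
    """Stratified repeated k-fold partition of the patient set.

    Within each repeat every stratum's patients are allocated to folds by
    largest remainder after a seeded shuffle, so fold sizes differ by at
    most one and the validation folds partition the cohort.  Each of the
    repeats*folds splits carries one imputation index drawn uniformly with
    replacement from 1..m.
    """
    patients = list(patients)
    if folds > len(patients):
        raise ValueError("more folds than patients")
    rng = np.random.default_rng(np.random.SeedSequence(seed & 0x7FFFFFFF))
    splits = []
    for _ in range(repeats):
        fold_members = [[] for _ in range(folds)]
        fold_counts = np.zeros(folds, dtype=int)
        strata = {}
        for pid in patients:
            strata.setdefault(stratum_labels[pid], []).append(pid)
        for label in sorted(strata, key=str):
            members = list(strata[label])
            rng.shuffle(members)
            # allocate counts by largest remainder, preferring emptier folds
            base, rem = divmod(len(members), folds)
            counts = np.full(folds, base)
            order = np.argsort(fold_counts + rng.random(folds) * 1e-9, kind="stable")
            for k in range(rem):
                counts[order[k]] += 1
            i = 0
            for f in range(folds):
                fold_members[f].extend(members[i:i + counts[f]])
                i += counts[f]
            fold_counts += counts
        for f in range(folds):
            val = sorted(fold_members[f])
            train = sorted(set(patients) - set(val))
            imp = int(rng.integers(1, m + 1))
            splits.append((train, val, imp))
    return PartitionPlan(repeats=repeats, folds=folds, splits=splits,
                         strata=dict(stratum_labels))


def median_gcsm_stratum(gcsm_events) -> int:
    """Patient stratum for GCSm endpoints: median observed score, halves up."""
    scores = np.array([s for _, s in gcsm_events], dtype=float)
    if scores.size == 0:
        return 0
    return int(np.ceil(np.median(scores)))


# ---------------------------------------------------------------------------
# Metrics


def roc_auc(probabilities, labels) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined with a single class")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def no_information_rate(n_neg: int, n_pos: int) -> float:
    """Accuracy of always predicting the majority class."""
    return max(n_neg, n_pos) / (n_neg + n_pos)


def classification_metrics(probabilities, labels, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a probability boundary (class 1 iff p >= 0.5).

    Precision is reported as 0 (flagged) when there are no positive
    predictions.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return {
        "accuracy": (tp + tn) / len(y),
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "F1": f1,
        "precision_defined": precision_defined,
        "nir": no_information_rate(tn + fp, tp + fn),
    }


def pr_curve_average_precision(probabilities, labels):
    """Precision-recall curve over descending thresholds and step-sum AP."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("PR curve undefined with a single class")
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate at distinct thresholds only (last index of each run)
    distinct = np.flatnonzero(np.diff(np.append(p[order], -np.inf)) != 0)
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / y.sum()
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_recall) * precision))
    return {"precision": precision, "recall": recall, "ap": ap}


def calibration(probabilities, labels, frac: float = CALIBRATION_LOWESS_FRAC) -> dict:
    """Flexible calibration curve with ICI and E_max.

    The curve is a local-linear (lowess) smooth of the binary outcomes on
    the predicted probabilities, evaluated at the observed predictions, so
    the mean absolute deviation from the identity (ICI) is weighted by the
    prediction density by construction; E_max is the maximal deviation.
    Requires >= 50 predictions spanning both classes; a degenerate
    probability spread falls back to the constant (mean outcome) curve.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(float)
    if len(p) < 50:
        raise ValueError("calibration requires at least 50 predictions")
    if y.min() == y.max():
        raise ValueError("calibration requires both classes")
    if np.ptp(p) < 1e-6:
        curve = np.full_like(p, y.mean())
        flagged = True
    else:
        sm = lowess(y, p, frac=frac, it=0, return_sorted=True)
        curve = np.interp(p, sm[:, 0], sm[:, 1])
        curve = np.clip(curve, 0.0, 1.0)
        flagged = False
    abs_dev = np.abs(curve - p)
    return {"curve_p": p, "curve": curve, "ICI": float(abs_dev.mean()),
            "E_max": float(abs_dev.max()), "degenerate": flagged}


# ---------------------------------------------------------------------------
# Grid evaluation


class GridEvaluation:
    """Fit the (window x d) grid across a partition plan for one endpoint.

    Parameters
    ----------
    matrices_by_window : dict
        ``duration_s -> [ObservationMatrix per imputation 1..m]`` (a single
        matrix is accepted where missingness is absent).
    plan : PartitionPlan
    thresholds : sequence of int
    d_grid : sequence of int
    endpoint : str
    """

    def __init__(self, matrices_by_window: dict, plan: PartitionPlan,
                 thresholds, d_grid, endpoint: str = "GCSm",
                 normalizer_mode: str = "mean_sd"):
        self.matrices_by_window = {
            dur: (mats if isinstance(mats, (list, tuple)) else [mats])
            for dur, mats in matrices_by_window.items()}
        self.plan = plan
        self.thresholds = tuple(thresholds)
        self.d_grid = tuple(d_grid)
        self.endpoint = endpoint
        self.normalizer_mode = normalizer_mode

    def run(self, keep_bundles: bool = False) -> "EvaluationResults":
        """Fit every (split, window, d, threshold); pool validation predictions."""
        records = []
        bundles = {}
        n_skipped = 0
        for duration_s, mats in self.matrices_by_window.items():
            for split_idx, (train_ids, val_ids, imp) in enumerate(self.plan.splits):
                obs = mats[(imp - 1) % len(mats)]
                tr = obs.rows_for(train_ids)
                va = obs.rows_for(val_ids)
                if tr.sum() == 0 or va.sum() == 0:
                    n_skipped += 1
                    continue
                train_obs = ObservationMatrix(values=obs.values[tr], schema=obs.schema,
                                              patients=obs.patients[tr],
                                              eval_times=obs.eval_times[tr],
                                              scores=obs.scores[tr])
                for threshold in self.thresholds:
                    y_tr = train_obs.labels(threshold)
                    if np.unique(y_tr).size < 2:
                        n_skipped += 1
                        continue
                    fitted = fit_bundles_multi_d(
                        train_obs, threshold, self.d_grid, endpoint=self.endpoint,
                        normalizer_mode=self.normalizer_mode)
                    # validation rows share the normalization/projection too
                    ref = fitted[max(self.d_grid)]
                    Xn_va = ref.normalizer.apply(obs.values[va], obs.schema)
                    Z_va = ref.lol.transform(Xn_va)
                    T_va = yeo_johnson_apply(Z_va, ref.yj)
                    for d in self.d_grid:
                        b = fitted[d]
                        probs = predict_proba(b.beta, T_va[:, :b.d])
                        for pid, t, score, pr in zip(obs.patients[va], obs.eval_times[va],
                                                     obs.scores[va], probs):
                            records.append((pid, t, threshold, duration_s, d,
                                            split_idx, float(pr), int(score > threshold)))
                        if keep_bundles:
                            bundles[(duration_s, d, threshold, split_idx)] = b
        if n_skipped:
            logger.info("skipped %d degenerate split/threshold configurations", n_skipped)
        store = pd.DataFrame(records, columns=[
            "patient", "eval_time", "threshold", "window", "d",
            "split", "probability", "label"])
        return EvaluationResults(store=store, plan=self.plan,
                                 endpoint=self.endpoint, bundles=bundles)


class EvaluationResults:
    """Pooled out-of-fold prediction store plus BBC-CV estimators."""

    def __init__(self, store: pd.DataFrame, plan: PartitionPlan,
                 endpoint: str, bundles: dict | None = None):
        self.store = store
        self.plan = plan
        self.endpoint = endpoint
        self.bundles = bundles or {}

    def config_metric(self, threshold: int, metric=roc_auc) -> pd.DataFrame:
        """Pooled metric per (window, d) configuration."""
        sub = self.store[self.store.threshold == threshold]
        rows = []
        for (w, d), grp in sub.groupby(["window", "d"]):
            try:
                val = metric(grp.probability.to_numpy(), grp.label.to_numpy())
            except ValueError:
                val = np.nan
            rows.append((w, d, val))
        return pd.DataFrame(rows, columns=["window", "d", "metric"])

    def select_optimal(self, threshold: int, metric=roc_auc):
        """(window, d) with maximal pooled metric; ties -> shorter window, smaller d."""
        table = self.config_metric(threshold, metric).dropna()
        if table.empty:
            raise ValueError("no evaluated configuration")
        table = table.sort_values(["window", "d"], kind="stable")
        best = table.loc[table.metric.idxmax()]
        top = table[np.isclose(table.metric, best.metric)]
        chosen = top.sort_values(["window", "d"], kind="stable").iloc[0]
        return float(chosen.window), int(chosen.d), float(chosen.metric)

    def bbc_cv_ci(self, threshold: int, metric=roc_auc, n_resamples: int = 1000,
                  seed: int = 0, alpha: float = 0.05) -> MetricEstimate:
        """Patient-level BBC-CV estimate with bias-corrected percentile CI.

        Per resample the configuration is selected by the maximal metric on
        in-bag patients' pooled predictions and scored on out-of-bag
        patients.  Resamples whose out-of-bag set lacks a class are redrawn
        up to 10 times, then dropped (counted).
        """
        sub = self.store[self.store.threshold == threshold]
        if sub.empty:
            raise ValueError(f"no predictions stored for threshold {threshold}")
        patients = np.array(sorted(sub.patient.unique(), key=str), dtype=object)
        pat_code = {p: i for i, p in enumerate(patients)}
        n_pat = len(patients)
        rng = np.random.default_rng(np.random.SeedSequence(seed & 0x7FFFFFFF))
        use_fast_auc = metric is roc_auc
        configs = []
        cfg_data = []
        for cfg, grp in sub.groupby(["window", "d"]):
            p = grp.probability.to_numpy()
            lb = grp.label.to_numpy().astype(float)
            pc = np.array([pat_code[x] for x in grp.patient], dtype=int)
            order = np.argsort(p, kind="stable")
            p, lb, pc = p[order], lb[order], pc[order]
            # tie-group boundaries of equal probabilities (ascending)
            starts = np.flatnonzero(np.concatenate([[True], np.diff(p) != 0]))
            configs.append(tuple(cfg))
            cfg_data.append((p, lb, pc, starts))

        def weighted_auc(data, w_pat):
            """Mann-Whitney AUC with per-row weights, half-credit ties."""
            p, lb, pc, starts = data
            w = w_pat[pc]
            wpos = w * lb
            wneg = w * (1 - lb)
            gpos = np.add.reduceat(wpos, starts)
            gneg = np.add.reduceat(wneg, starts)
            tot_pos, tot_neg = gpos.sum(), gneg.sum()
            if tot_pos <= 0 or tot_neg <= 0:
                return None
            cum_neg_before = np.concatenate([[0.0], np.cumsum(gneg)[:-1]])
            u = np.sum(gpos * (cum_neg_before + 0.5 * gneg))
            return float(u / (tot_pos * tot_neg))

        def generic_metric(data, w_pat):
            p, lb, pc, _ = data
            counts = w_pat[pc].astype(int)
            pr = np.repeat(p, counts)
            y = np.repeat(lb, counts).astype(int)
            if pr.size == 0 or y.min() == y.max():
                return None
            return metric(pr, y)

        eval_metric = weighted_auc if use_fast_auc else generic_metric
        values = []
        selections = []
        n_dropped = 0
        for _ in range(n_resamples):
            value = None
            for _attempt in range(10):
                idx = rng.integers(0, n_pat, size=n_pat)
                w_in = np.bincount(idx, minlength=n_pat).astype(float)
                w_oob = (w_in == 0).astype(float)
                if w_oob.sum() == 0:
                    continue
                best_cfg, best_val = None, -np.inf
                for cfg, data in zip(configs, cfg_data):
                    v = eval_metric(data, w_in)
                    if v is not None and v > best_val:
                        best_cfg, best_val = cfg, v
                if best_cfg is None:
                    continue
                value = eval_metric(cfg_data[configs.index(best_cfg)], w_oob)
                if value is None:
                    continue
                selections.append(best_cfg)
                break
            if value is None:
                n_dropped += 1
            else:
                values.append(value)
        values = np.asarray(values)
        if values.size == 0:
            raise ValueError("no valid BBC-CV resample")
        # reference estimate for the bias correction: metric of the
        # full-data-selected configuration on all pooled predictions
        w0, d0, _ = self.select_optimal(threshold, metric)
        full = sub[(sub.window == w0) & (sub.d == d0)]
        theta_hat = metric(full.probability.to_numpy(), full.label.to_numpy())
        frac_below = np.clip((values < theta_hat).mean(), 1.0 / (len(values) + 1),
                             1 - 1.0 / (len(values) + 1))
        z0 = norm.ppf(frac_below)
        lo_q = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
        hi_q = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
        ci_low, ci_high = np.quantile(values, [lo_q, hi_q])
        mean = float(values.mean())
        sel_mode = max(set(selections), key=selections.count) if selections else None
        return MetricEstimate(
            name=getattr(metric, "__name__", "metric"), mean=mean,
            ci_low=float(min(ci_low, mean)), ci_high=float(max(ci_high, mean)),
            n_resamples=n_resamples, n_dropped=n_dropped,
            selected={"window": sel_mode[0], "d": sel_mode[1]} if sel_mode else {})

    def summary(self, threshold: int, metric=roc_auc, n_resamples: int = 1000,
                seed: int = 0) -> str:
        est = self.bbc_cv_ci(threshold, metric=metric, n_resamples=n_resamples,
                             seed=seed)
        w0, d0, raw = self.select_optimal(threshold, metric)
        lines = [
            f"Endpoint {self.endpoint} > {threshold}",
            f"Optimal configuration: window {w0 / 60:.0f} min, d = {d0} "
            f"(pooled {est.name} = {raw:.3f})",
            f"BBC-CV {est.name}: {est.mean:.3f} "
            f"[{est.ci_low:.3f}-{est.ci_high:.3f}] "
            f"({est.n_resamples} resamples, {est.n_dropped} dropped)",
        ]
        return "\n".join(lines)


def select_optimal(estimates: dict):
    """Best (window, d) by mean AUC; ties toward shorter window then smaller d."""
    items = sorted(estimates.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    best_key, best_val = None, -np.inf
    for key, val in items:
        if val > best_val + 1e-12:
            best_key, best_val = key, val
    return best_key, best_val
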