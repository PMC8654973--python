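"""Missingness diagnostics and bootstrap-EM multiple imputation.

Missing 5-s feature values (sensor dropouts, interventions, transport) are
multiply imputed (m = 9 by default) under a multivariate-normal model of
the Box-Cox-standardized feature columns.  Spatial correlation enters
through the joint covariance of the 7 features x 7 sensors of one patient;
temporal correlation through lag/lead copies of every column appended to
the design (the standard time-series device of the Amelia family).  Each
completion is produced by the bootstrap-EM recipe: resample rows, run EM
for the mean and covariance under ignorable (MAR) missingness, then draw
missing entries from their conditional normal given the observed entries
of the same row.  Observed values are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for multiple imputation (defaults follow the pipeline)."""

    m: int = 9
    boxcox_shift: float = 1e-3
    jitter: float = 1e-7          # tie-breaking uniform jitter, removed on inversion
    n_lags: int = 1
    n_leads: int = 1
    em_max_iter: int = 100
    em_tol: float = 1e-4
    ridge: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be positive")


@dataclass
class TransformParams:
    """Per-column Box-Cox + standardization parameters."""

    lmbda: dict = field(default_factory=dict)
    shift: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    flagged: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Missingness diagnostics


def missingness_report(series) -> dict:
    """Per-placement and per-hour missing fractions with homogeneity tests.

    Returns a dict with ``by_placement`` and ``by_hour`` fraction Series and
    chi-squared statistics/p-values testing homogeneity of missing counts
    across placements and across hours of the day.  Degenerate tables (no
    missing values) are reported as not applicable (p = NaN).
    """
    mask = series.mask
    placements = series.placements()
    by_placement = {}
    counts_p = []
    for p in placements:
        m = mask[p].to_numpy().any(axis=1)      # a window is missing if any feature is
        by_placement[p] = float(m.mean())
        counts_p.append([int(m.sum()), int((~m).sum())])
    hours = (series.starts // 3600.0).astype(int) % 24
    by_hour = {}
    counts_h = []
    any_missing = mask.to_numpy().any(axis=1)
    for h in np.unique(hours):
        sel = hours == h
        by_hour[int(h)] = float(any_missing[sel].mean())
        counts_h.append([int(any_missing[sel].sum()), int((~any_missing[sel]).sum())])

    def _chi2(table):
        table = np.asarray(table)
        if table[:, 0].sum() == 0 or table.shape[0] < 2:
            return np.nan, np.nan
        try:
            res = stats.chi2_contingency(table[table.sum(axis=1) > 0])
            return float(res.statistic), float(res.pvalue)
        except ValueError:
            return np.nan, np.nan

    chi_p, p_p = _chi2(counts_p)
    chi_h, p_h = _chi2(counts_h)
    return {
        "by_placement": pd.Series(by_placement),
        "by_hour": pd.Series(by_hour),
        "placement_chi2": chi_p, "placement_p": p_p,
        "hour_chi2": chi_h, "hour_p": p_h,
    }


# ---------------------------------------------------------------------------
# Box-Cox normalization


def boxcox_fit_apply(columns: pd.DataFrame, shift: float = 1e-3):
    """Fit per-column Box-Cox (profile-ML lambda) and standardize.

    Columns must be nonnegative after the shift.  Zero-variance or fully
    missing columns get lambda = 1 and are flagged.  Returns the
    transformed frame (NaNs preserved) and the fitted parameters.
    """
    params = TransformParams()
    out = {}
    for col in columns.columns:
        v = columns[col].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        params.shift[col] = shift
        if obs.size < 3 or np.ptp(obs) < 1e-12:
            params.lmbda[col] = 1.0
            params.flagged.add(col)
            y = v + shift
        else:
            try:
                _, lam = stats.boxcox(obs + shift)
            except ValueError:
                lam = 1.0
                params.flagged.add(col)
            params.lmbda[col] = float(lam)
            y = special.boxcox(v + shift, params.lmbda[col])
        yobs = y[~np.isnan(y)]
        mu = float(yobs.mean()) if yobs.size else 0.0
        sd = float(yobs.std(ddof=0)) if yobs.size else 1.0
        if sd <= 1e-12:
            sd = 1.0
            params.flagged.add(col)
        params.mean[col], params.sd[col] = mu, sd
        out[col] = (y - mu) / sd
    frame = pd.DataFrame(out, index=columns.index)
    frame.columns = columns.columns
    return frame, params


def boxcox_invert(transformed: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Invert :func:`boxcox_fit_apply` (round-trip exact to ~1e-8)."""
    out = {}
    for col in transformed.columns:
        z = transformed[col].to_numpy(dtype=float)
        y = z * params.sd[col] + params.mean[col]
        x = special.inv_boxcox(y, params.lmbda[col]) - params.shift[col]
        out[col] = x
    frame = pd.DataFrame(out, index=transformed.index)
    frame.columns = transformed.columns
    return frame


# ---------------------------------------------------------------------------
# EM for the multivariate normal with missing data


def _em_mvn(X: np.ndarray, max_iter: int, tol: float, ridge: float):
    """EM estimates (mu, Sigma, converged) for MVN data with NaNs."""
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.where(np.isnan(np.nanmean(X, axis=0)), 0.0, np.nanmean(X, axis=0))
    var = np.nanvar(X, axis=0)
    var = np.where(np.isnan(var) | (var < 1e-8), 1.0, var)
    sigma = np.diag(var)
    patterns = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    converged = False
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            rows = np.asarray(rows)
            Xo = X[np.ix_(rows, np.flatnonzero(o))]
            if m.any() and o.any():
                Soo = sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
                Smo = sigma[np.ix_(m, o)]
                K = np.linalg.solve(Soo, Smo.T).T          # Σ_mo Σ_oo^{-1}
                cond_mean = mu[m][None, :] + (Xo - mu[o][None, :]) @ K.T
                cond_cov = sigma[np.ix_(m, m)] - K @ Smo.T
            elif m.any():
                cond_mean = np.tile(mu[m], (len(rows), 1))
                cond_cov = sigma[np.ix_(m, m)]
            else:
                cond_mean = np.zeros((len(rows), 0))
                cond_cov = np.zeros((0, 0))
            Xfull = np.empty((len(rows), p))
            Xfull[:, o] = Xo
            if m.any():
                Xfull[:, m] = cond_mean
            sum_x += Xfull.sum(axis=0)
            sum_xx += Xfull.T @ Xfull
            if m.any():
                idx_m = np.flatnonzero(m)
                sum_xx[np.ix_(idx_m, idx_m)] += len(rows) * cond_cov
        new_mu = sum_x / n
        new_sigma = sum_xx / n - np.outer(new_mu, new_mu)
        new_sigma = 0.5 * (new_sigma + new_sigma.T) + ridge * np.eye(p)
        delta = max(np.max(np.abs(new_mu - mu)), np.max(np.abs(new_sigma - sigma)))
        mu, sigma = new_mu, new_sigma
        if delta < tol:
            converged = True
            break
    return mu, sigma, converged


def _conditional_draw(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                      ridge: float, rng: np.random.Generator) -> np.ndarray:
    """Fill NaNs of X with draws from their conditional normal, rowwise."""
    out = X.copy()
    obs = ~np.isnan(X)
    patterns = {}
    for i in range(X.shape[0]):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        o = np.frombuffer(key, dtype=bool)
        m = ~o
        if not m.any():
            continue
        rows = np.asarray(rows)
        if o.any():
            Soo = sigma[np.ix_(o, o)] + ridge * np.eye(o.sum())
            Smo = sigma[np.ix_(m, o)]
            K = np.linalg.solve(Soo, Smo.T).T
            cond_mean = mu[m][None, :] + (X[np.ix_(rows, np.flatnonzero(o))]
                                          - mu[o][None, :]) @ K.T
            cond_cov = sigma[np.ix_(m, m)] - K @ Smo.T
        else:
            cond_mean = np.tile(mu[m], (len(rows), 1))
            cond_cov = sigma[np.ix_(m, m)]
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        w, V = np.linalg.eigh(cond_cov)
        root = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        noise = rng.standard_normal((len(rows), int(m.sum()))) @ root.T
        out[np.ix_(rows, np.flatnonzero(m))] = cond_mean + noise
    return out


def _augment(Z: np.ndarray, n_lags: int, n_leads: int) -> np.ndarray:
    """Append lag/lead copies of every column (NaN at the edges)."""
    blocks = [Z]
    for j in range(1, n_lags + 1):
        lag = np.full_like(Z, np.nan)
        lag[j:] = Z[:-j]
        blocks.append(lag)
    for j in range(1, n_leads + 1):
        lead = np.full_like(Z, np.nan)
        lead[:-j] = Z[j:]
        blocks.append(lead)
    return np.concatenate(blocks, axis=1)


def impute_multiple(series, config: ImputationConfig | None = None) -> list:
    """Produce ``config.m`` completed copies of a window feature series.

    Each completion bootstraps the window rows, runs EM on the Box-Cox
    standardized, lag/lead-augmented column matrix, and draws the missing
    entries conditionally.  Observed entries pass through unchanged;
    imputed values are clipped to the nonnegative feature domain.
    """
    from .features import WindowFeatureSeries
    if config is None:
        config = ImputationConfig()
    frame = series.frame
    values = frame.to_numpy(dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("cannot impute a series with no observed values")
    mask = np.isnan(values)
    if not mask.any():
        return [WindowFeatureSeries(series.patient_id, frame.copy(),
                                    series.starts, series.window_s)
                for _ in range(config.m)]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed & 0x7FFFFFFF))
    jittered = frame.copy()
    if config.jitter > 0:
        j = rng.uniform(0, config.jitter, size=values.shape)
        jittered = pd.DataFrame(np.where(mask, np.nan, values + j),
                                index=frame.index, columns=frame.columns)
    Zf, params = boxcox_fit_apply(jittered, shift=config.boxcox_shift)
    Z = Zf.to_numpy(dtype=float)
    n, p = Z.shape
    A = _augment(Z, config.n_lags, config.n_leads)

    completions = []
    for i in range(config.m):
        boot = rng.integers(0, n, size=n)
        mu, sigma, converged = _em_mvn(A[boot], config.em_max_iter,
                                       config.em_tol, config.ridge)
        ridge = config.ridge
        if not converged:
            ridge = 10 * config.ridge
            sigma = sigma + ridge * np.eye(sigma.shape[0])
            logger.warning("EM did not converge for draw %d of %s; "
                           "using ridge-regularized conditional draws",
                           i + 1, series.patient_id)
        filled_aug = _conditional_draw(A, mu, sigma, ridge, rng)
        Zfill = filled_aug[:, :p]
        back = boxcox_invert(pd.DataFrame(Zfill, index=frame.index,
                                          columns=frame.columns), params)
        bt = back.to_numpy(dtype=float)
        # draws outside the Box-Cox domain invert to NaN; map them to the floor
        bt = np.where(np.isfinite(bt), bt, 0.0)
        comp = np.where(mask, np.clip(bt, 0.0, None), values)
        comp_frame = pd.DataFrame(comp, index=frame.index, columns=frame.columns)
        completions.append(WindowFeatureSeries(series.patient_id, comp_frame,
                                               series.starts, series.window_s))
    return completions
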