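"""Observation-matrix assembly and the LOL -> Yeo-Johnson -> logistic model.

For every clinical evaluation, the feature history in the preceding
observation window is flattened into one design row: for each of the six
extremity sensors and each of the seven per-window feature types, the
consecutive 5-s values in ``[eval_time - duration, eval_time)`` in time
order, followed by one proportion-of-dynamic-activity (PDA) column per
sensor — ``6*7*T + 6`` columns for ``T`` timesteps.  Columns are normalized
with statistics pooled per placement-feature combination (48 of them),
projected to ``d`` dimensions (2..20) with linear optimal low-rank
projection (LOL: the class-mean difference direction followed by the top
principal directions of the class-centered data, orthonormalized), made
marginally Gaussian with element-wise Yeo-Johnson transforms, and fed to
an unpenalized logistic regression with a binary threshold endpoint.

The fitted state of one configuration lives in a :class:`ModelBundle`;
:class:`ThresholdModel` / :class:`ThresholdModelResults` present the same
pipeline as a model object fitted to data, with coefficient uncertainties
and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import DYNAMIC_SMA_G, FEATURES, StaticRange
from .preprocessing import WINDOW_S
from .synthetic import EXTREMITIES

logger = logging.getLogger(__name__)

#: Default ladder of the 19 tested observation windows (seconds):
#: 3, 6, 9, 12, 18, 27, 36, 48 min and 1, 1.5, 2, 3, 4, 6, 9, 12, 16, 20, 24 h.
DEFAULT_WINDOWS_S = tuple(
    [m * 60 for m in (3, 6, 9, 12, 18, 27, 36, 48)]
    + [int(h * 3600) for h in (1, 1.5, 2, 3, 4, 6, 9, 12, 16, 20, 24)]
)
D_GRID = tuple(range(2, 21))   # LOL target dimensionality hyperparameter

ENDPOINTS = {
    "GCSm": tuple(range(1, 6)),             # thresholds GCSm > 1 .. > 5
    "GOSE_discharge": tuple(range(1, 6)),   # GOSE > 1 .. > 5
    "GOSE_12mo": tuple(range(1, 8)),        # GOSE > 1 .. > 7
}


class InsufficientHistoryError(ValueError):
    """Raised when an evaluation lacks the required feature history."""


class SchemaMismatchError(ValueError):
    """Raised when a row does not match a bundle's column schema."""


@dataclass(frozen=True)
class ObservationConfig:
    """Grid definition: observation windows, endpoint and thresholds."""

    window_durations_s: tuple = DEFAULT_WINDOWS_S
    endpoint: str = "GCSm"
    thresholds: tuple | None = None

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.thresholds is None:
            object.__setattr__(self, "thresholds", ENDPOINTS[self.endpoint])
        bound = max(ENDPOINTS[self.endpoint]) + 1
        if any(not 1 <= t < bound + 1 for t in self.thresholds):
            raise ValueError("thresholds outside the scale bounds")


@dataclass(frozen=True)
class ColumnSchema:
    """Fixed column layout of an observation matrix."""

    n_steps: int
    window_s: float = WINDOW_S
    placements: tuple = EXTREMITIES
    features: tuple = FEATURES

    @property
    def n_columns(self) -> int:
        return len(self.placements) * len(self.features) * self.n_steps + len(self.placements)

    def metadata(self) -> pd.DataFrame:
        """One row per column: placement, feature ('PDA' rows last), timestep."""
        cached = self.__dict__.get("_metadata")
        if cached is not None:
            return cached
        rows = []
        for p in self.placements:
            for f in self.features:
                for t in range(self.n_steps):
                    rows.append((p, f, t))
        for p in self.placements:
            rows.append((p, "PDA", -1))
        meta = pd.DataFrame(rows, columns=["placement", "feature", "timestep"])
        object.__setattr__(self, "_metadata", meta)
        return meta

    def combo_columns(self) -> dict:
        """(placement, feature) -> column indices; the 48 combinations."""
        cached = self.__dict__.get("_combo_columns")
        if cached is not None:
            return cached
        T = self.n_steps
        nf = len(self.features)
        combos = {}
        for i, p in enumerate(self.placements):
            base = i * nf * T
            for j, f in enumerate(self.features):
                combos[(p, f)] = np.arange(base + j * T, base + (j + 1) * T)
            combos[(p, "PDA")] = np.array(
                [len(self.placements) * nf * T + i])
        object.__setattr__(self, "_combo_columns", combos)
        return combos


@dataclass
class ObservationMatrix:
    """Design rows for one (endpoint, window-duration) combination."""

    values: np.ndarray              # (n_rows, n_columns)
    schema: ColumnSchema
    patients: np.ndarray            # patient id per row
    eval_times: np.ndarray          # seconds
    scores: np.ndarray              # raw endpoint value per row (GCSm or GOSE)

    def labels(self, threshold: int) -> np.ndarray:
        return (self.scores > threshold).astype(int)

    def rows_for(self, patient_ids) -> np.ndarray:
        return np.isin(self.patients, np.asarray(list(patient_ids)))


def _series_array(series) -> np.ndarray:
    """Feature frame as (n_windows, 6 placements, 7 features) in schema order.

    Cached on the series object; repeated observation assembly (grids,
    sliding monitors) dominates runtime otherwise.
    """
    cached = getattr(series, "_schema_array", None)
    if cached is not None and len(cached) == len(series.frame):
        return cached
    cols = [(p, f) for p in EXTREMITIES for f in FEATURES]
    arr = series.frame.loc[:, cols].to_numpy(dtype=float)
    arr = arr.reshape(len(series.frame), len(EXTREMITIES), len(FEATURES))
    series._schema_array = arr
    return arr


def assemble_observation(series, eval_time: float, duration_s: float,
                         pda_threshold: float = DYNAMIC_SMA_G) -> np.ndarray:
    """Flatten one observation window into a design row.

    Requires a complete (imputed) series with at least ``duration_s`` of
    history strictly before ``eval_time``.
    """
    w = series.window_s
    n_steps = int(round(duration_s / w))
    k_end = int(np.floor(eval_time / w))
    k_start = k_end - n_steps
    if k_start < 0 or k_end > len(series.frame):
        raise InsufficientHistoryError(
            f"evaluation at {eval_time:.0f}s lacks {duration_s:.0f}s of history")
    arr = _series_array(series)[k_start:k_end]           # (T, 6, 7)
    if np.isnan(arr).any():
        raise InsufficientHistoryError(
            f"observation window at {eval_time:.0f}s contains missing features")
    flat = arr.transpose(1, 2, 0).ravel()                # placement -> feature -> time
    sma_idx = FEATURES.index("SMA")
    pda_vals = (arr[:, :, sma_idx] >= pda_threshold).mean(axis=0)
    return np.concatenate([flat, pda_vals])


def assemble_matrix(series_by_patient: dict, evaluations, duration_s: float,
                    log_skipped: bool = True) -> ObservationMatrix:
    """Assemble all rows for one window duration.

    ``evaluations`` is an iterable of ``(patient_id, eval_time_s, score)``.
    Evaluations without sufficient history are skipped (the per-window
    sample attrition of shorter recordings), optionally logged.
    """
    rows, pats, times, scores = [], [], [], []
    n_skipped = 0
    schema = None
    for pid, t, score in evaluations:
        series = series_by_patient[pid]
        if schema is None:
            schema = ColumnSchema(n_steps=int(round(duration_s / series.window_s)),
                                  window_s=series.window_s)
        try:
            rows.append(assemble_observation(series, t, duration_s))
        except InsufficientHistoryError:
            n_skipped += 1
            continue
        pats.append(pid)
        times.append(t)
        scores.append(score)
    if log_skipped and n_skipped:
        logger.info("skipped %d evaluations lacking %.0f s history",
                    n_skipped, duration_s)
    if schema is None:
        schema = ColumnSchema(n_steps=int(round(duration_s / WINDOW_S)))
    values = np.vstack(rows) if rows else np.empty((0, schema.n_columns))
    return ObservationMatrix(values=values, schema=schema,
                             patients=np.asarray(pats, dtype=object),
                             eval_times=np.asarray(times, dtype=float),
                             scores=np.asarray(scores, dtype=float))


# ---------------------------------------------------------------------------
# Column normalization (48 placement-feature combinations)


@dataclass
class ColumnNormalizer:
    """Pooled location/scale per placement-feature combination."""

    loc: dict                      # (placement, feature) -> float
    scale: dict
    mode: str = "mean_sd"
    flagged: set = field(default_factory=set)

    def apply(self, X: np.ndarray, schema: ColumnSchema) -> np.ndarray:
        cached = self.__dict__.get("_apply_cache")
        if cached is not None and cached[0] == schema.n_steps:
            loc, scale = cached[1], cached[2]
        else:
            loc = np.empty(schema.n_columns)
            scale = np.empty(schema.n_columns)
            for combo, cols in schema.combo_columns().items():
                loc[cols] = self.loc[combo]
                scale[cols] = self.scale[combo]
            self.__dict__["_apply_cache"] = (schema.n_steps, loc, scale)
        return (X - loc[None, :]) / scale[None, :]


def fit_column_normalizer(X: np.ndarray, schema: ColumnSchema,
                          mode: str = "mean_sd") -> ColumnNormalizer:
    """Estimate one location/scale pair per placement-feature combination.

    Values are pooled across all timestep columns of the combination and
    across training rows.  ``mean_sd`` (classical z-scoring) is the
    default; ``median_iqr`` is a robust switch, but on zero-inflated burst
    features its near-degenerate IQR amplifies outliers and destabilizes
    the projection.  Zero pooled spread sets the scale to 1 and flags the
    combination.
    """
    if mode not in ("median_iqr", "mean_sd"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    loc, scale, flagged = {}, {}, set()
    for combo, cols in schema.combo_columns().items():
        v = X[:, cols].ravel()
        v = v[~np.isnan(v)]
        if mode == "median_iqr":
            if v.size:
                q25, c, q75 = np.percentile(v, [25, 50, 75])
                c, s = float(c), float(q75 - q25)
            else:
                c, s = 0.0, 0.0
        else:
            c = float(v.mean()) if v.size else 0.0
            s = float(v.std(ddof=0)) if v.size else 0.0
        if s <= 1e-12:
            s = 1.0
            flagged.add(combo)
        loc[combo], scale[combo] = c, s
    return ColumnNormalizer(loc=loc, scale=scale, mode=mode, flagged=flagged)


# ---------------------------------------------------------------------------
# Linear optimal low-rank projection (LOL)


@dataclass
class LOLProjection:
    """Orthonormal loadings (columns x d); first direction = mean difference."""

    loadings: np.ndarray
    d: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return X @ self.loadings


def fit_lol(X: np.ndarray, y: np.ndarray, d: int) -> LOLProjection:
    """Supervised low-rank projection.

    Direction 1 is the difference of class means; directions 2..d are the
    leading right singular vectors of the class-mean-centered data.  The
    stacked directions are orthonormalized in order (Gram-Schmidt, mean
    difference first).  ``d`` above the achievable rank is reduced with a
    log message.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LOL requires both classes present")
    if not 1 <= d <= min(X.shape):
        if d > min(X.shape):
            logger.info("reducing LOL d from %d to %d (rank limit)", d, min(X.shape))
            d = min(X.shape)
    mu1 = X[y == classes[1]].mean(axis=0)
    mu0 = X[y == classes[0]].mean(axis=0)
    delta = mu1 - mu0
    Xc = X.copy()
    Xc[y == classes[0]] -= mu0
    Xc[y == classes[1]] -= mu1
    n_dir = min(d - 1 + 4, min(Xc.shape))
    if min(Xc.shape) > 64:
        # large design: truncated randomized SVD (deterministic state)
        from sklearn.utils.extmath import randomized_svd
        _, s, Vt = randomized_svd(Xc, n_components=n_dir, n_iter=4,
                                  random_state=0)
    else:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    directions = [delta] + [Vt[i] for i in range(min(n_dir, Vt.shape[0]))]
    # Gram-Schmidt in order, mean-difference direction first
    basis = []
    for v in directions:
        w = v.astype(float).copy()
        for b in basis:
            w -= (w @ b) * b
        nrm = np.linalg.norm(w)
        if nrm > 1e-10:
            basis.append(w / nrm)
        if len(basis) == d:
            break
    if len(basis) < d:
        logger.info("LOL rank %d below requested d=%d", len(basis), d)
    L = np.stack(basis, axis=1)
    return LOLProjection(loadings=L, d=L.shape[1])


# ---------------------------------------------------------------------------
# Yeo-Johnson component normalization


@dataclass
class YeoJohnsonParams:
    lmbdas: np.ndarray
    means: np.ndarray
    sds: np.ndarray


def _yj_forward(x: np.ndarray, lam: float) -> np.ndarray:
    pos = x >= 0
    out = np.empty_like(x, dtype=float)
    if abs(lam) > 1e-12:
        out[pos] = ((x[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -(((1.0 - x[~pos]) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def _yj_inverse(y: np.ndarray, lam: float) -> np.ndarray:
    pos = y >= 0
    out = np.empty_like(y, dtype=float)
    if abs(lam) > 1e-12:
        out[pos] = (lam * y[pos] + 1.0) ** (1.0 / lam) - 1.0
    else:
        out[pos] = np.expm1(y[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = 1.0 - (1.0 - (2.0 - lam) * y[~pos]) ** (1.0 / (2.0 - lam))
    else:
        out[~pos] = -np.expm1(-y[~pos])
    return out


def _yj_mle_lambda(x: np.ndarray, bounds: tuple = (-3.0, 5.0)) -> float:
    """Profile-ML lambda for the Yeo-Johnson family (vectorized likelihood)."""
    from scipy.optimize import minimize_scalar
    x = np.asarray(x, dtype=float)
    n = len(x)
    jac = np.sign(x) * np.log1p(np.abs(x))     # d/dx log-Jacobian term

    def neg_llf(lam):
        t = _yj_forward(x, lam)
        var = t.var()
        if not np.isfinite(var) or var <= 0:
            return np.inf
        return 0.5 * n * np.log(var) - (lam - 1.0) * jac.sum()

    res = minimize_scalar(neg_llf, bounds=bounds, method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def yeo_johnson_fit_apply(Z: np.ndarray):
    """Per-component Yeo-Johnson (profile-ML lambda) plus standardization."""
    Z = np.asarray(Z, dtype=float)
    d = Z.shape[1]
    lmbdas = np.empty(d)
    means = np.empty(d)
    sds = np.empty(d)
    out = np.empty_like(Z)
    for j in range(d):
        col = Z[:, j]
        if np.ptp(col) < 1e-12:
            lam = 1.0
        else:
            try:
                lam = _yj_mle_lambda(col)
            except Exception:
                lam = 1.0
        t = _yj_forward(col, lam)
        mu, sd = float(t.mean()), float(t.std(ddof=0))
        if sd <= 1e-12:
            sd = 1.0
        out[:, j] = (t - mu) / sd
        lmbdas[j], means[j], sds[j] = lam, mu, sd
    return out, YeoJohnsonParams(lmbdas=lmbdas, means=means, sds=sds)


def yeo_johnson_apply(Z: np.ndarray, params: YeoJohnsonParams) -> np.ndarray:
    out = np.empty_like(Z, dtype=float)
    for j in range(Z.shape[1]):
        out[:, j] = (_yj_forward(Z[:, j], params.lmbdas[j]) - params.means[j]) / params.sds[j]
    return out


def yeo_johnson_invert(T: np.ndarray, params: YeoJohnsonParams) -> np.ndarray:
    out = np.empty_like(T, dtype=float)
    for j in range(T.shape[1]):
        out[:, j] = _yj_inverse(T[:, j] * params.sds[j] + params.means[j],
                                params.lmbdas[j])
    return out


# ---------------------------------------------------------------------------
# Logistic regression (IRLS with ridge fallback)


def _irls(Xd: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          max_iter: int = 100, tol: float = 1e-10):
    """IRLS for logistic regression; optional ridge on the slopes."""
    n, p = Xd.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0                     # intercept unpenalized
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = Xd.T @ (Xd * w[:, None]) + np.diag(pen)
        b = Xd.T @ (w * z) + 0.0
        new = np.linalg.solve(A, b)
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            converged = True
            break
        beta = new
    eta = np.clip(Xd @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]) + np.diag(pen))
    return beta, cov, converged


def fit_logistic(Z: np.ndarray, y: np.ndarray, ridge_fallback: float = 1e-4):
    """Unpenalized ML logistic fit; ridge (1e-4) refit on separation.

    Returns ``(beta, cov, flagged)`` where ``beta[0]`` is the intercept.
    Separation is detected by non-convergence or runaway coefficients.
    """
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("logistic fit requires both classes present")
    Xd = np.column_stack([np.ones(len(y)), Z])
    try:
        beta, cov, converged = _irls(Xd, y, ridge=0.0)
    except np.linalg.LinAlgError:
        beta, converged = None, False
    flagged = False
    # components are standardized upstream, so runaway coefficients signal
    # separation rather than scale
    if beta is None or not converged or np.max(np.abs(beta)) > 10:
        beta, cov, _ = _irls(Xd, y, ridge=ridge_fallback)
        flagged = True
        logger.info("logistic separation/non-convergence: ridge fallback used")
    return beta, cov, flagged


def predict_proba(beta: np.ndarray, Z: np.ndarray) -> np.ndarray:
    eta = np.clip(np.column_stack([np.ones(len(Z)), Z]) @ beta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def classify(p: np.ndarray | float, threshold: float = 0.5) -> np.ndarray | int:
    """Class 1 iff probability >= 0.5 (boundary inclusive)."""
    arr = np.asarray(p)
    out = (arr >= threshold).astype(int)
    return int(out) if np.isscalar(p) else out


# ---------------------------------------------------------------------------
# Model bundle and the statsmodels-style model object


@dataclass
class ModelBundle:
    """Fitted state of one (endpoint, threshold, window, d) configuration."""

    schema: ColumnSchema
    normalizer: ColumnNormalizer
    lol: LOLProjection
    yj: YeoJohnsonParams
    beta: np.ndarray
    cov: np.ndarray
    static_ranges: StaticRange | None
    endpoint: str
    threshold: int
    duration_s: float
    d: int
    ridge_flagged: bool = False
    train_predictions: np.ndarray | None = None

    def predict(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows)
        if rows.shape[1] != self.schema.n_columns:
            raise SchemaMismatchError(
                f"row has {rows.shape[1]} columns, bundle expects "
                f"{self.schema.n_columns} (T={self.schema.n_steps})")
        Xn = self.normalizer.apply(rows, self.schema)
        Z = self.lol.transform(Xn)
        T = yeo_johnson_apply(Z, self.yj)
        return predict_proba(self.beta, T)

    def to_json(self) -> str:
        payload = {
            "schema": {"n_steps": self.schema.n_steps, "window_s": self.schema.window_s,
                       "placements": list(self.schema.placements),
                       "features": list(self.schema.features)},
            "normalizer": {"mode": self.normalizer.mode,
                           "loc": {f"{p}|{f}": v for (p, f), v in self.normalizer.loc.items()},
                           "scale": {f"{p}|{f}": v for (p, f), v in self.normalizer.scale.items()}},
            "loadings": self.lol.loadings.tolist(),
            "yj": {"lmbdas": self.yj.lmbdas.tolist(), "means": self.yj.means.tolist(),
                   "sds": self.yj.sds.tolist()},
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "static_ranges": (None if self.static_ranges is None
                              else {k: list(v) for k, v in self.static_ranges.bounds.items()}),
            "endpoint": self.endpoint, "threshold": self.threshold,
            "duration_s": self.duration_s, "d": self.d,
            "ridge_flagged": self.ridge_flagged,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelBundle":
        p = json.loads(text)
        schema = ColumnSchema(n_steps=p["schema"]["n_steps"],
                              window_s=p["schema"]["window_s"],
                              placements=tuple(p["schema"]["placements"]),
                              features=tuple(p["schema"]["features"]))
        loc = {tuple(k.split("|")): v for k, v in p["normalizer"]["loc"].items()}
        scale = {tuple(k.split("|")): v for k, v in p["normalizer"]["scale"].items()}
        return cls(
            schema=schema,
            normalizer=ColumnNormalizer(loc=loc, scale=scale, mode=p["normalizer"]["mode"]),
            lol=LOLProjection(loadings=np.asarray(p["loadings"]), d=p["d"]),
            yj=YeoJohnsonParams(lmbdas=np.asarray(p["yj"]["lmbdas"]),
                                means=np.asarray(p["yj"]["means"]),
                                sds=np.asarray(p["yj"]["sds"])),
            beta=np.asarray(p["beta"]), cov=np.asarray(p["cov"]),
            static_ranges=(None if p["static_ranges"] is None
                           else StaticRange({k: tuple(v) for k, v in p["static_ranges"].items()})),
            endpoint=p["endpoint"], threshold=p["threshold"],
            duration_s=p["duration_s"], d=p["d"],
            ridge_flagged=p["ridge_flagged"],
        )


def fit_bundles_multi_d(obs: ObservationMatrix, threshold: int, d_grid,
                        endpoint: str = "GCSm", normalizer_mode: str = "mean_sd",
                        static_ranges: StaticRange | None = None) -> dict:
    """Fit one configuration for every ``d`` sharing the expensive stages.

    The LOL directions for a smaller ``d`` are a prefix of those for the
    largest (mean difference first, then ordered principal directions), and
    the Yeo-Johnson transform is element-wise, so the normalizer, the
    projection and the component transforms are computed once at
    ``max(d_grid)`` and sliced; only the logistic fit is repeated per d.
    """
    y = obs.labels(threshold)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    normalizer = fit_column_normalizer(obs.values, obs.schema, mode=normalizer_mode)
    Xn = normalizer.apply(obs.values, obs.schema)
    d_max = max(d_grid)
    lol_full = fit_lol(Xn, y, d_max)
    Z = lol_full.transform(Xn)
    T, yj_full = yeo_johnson_fit_apply(Z)
    bundles = {}
    for d in sorted(d_grid):
        dd = min(d, lol_full.d)
        beta, cov, flagged = fit_logistic(T[:, :dd], y)
        bundle = ModelBundle(
            schema=obs.schema, normalizer=normalizer,
            lol=LOLProjection(loadings=lol_full.loadings[:, :dd], d=dd),
            yj=YeoJohnsonParams(lmbdas=yj_full.lmbdas[:dd],
                                means=yj_full.means[:dd], sds=yj_full.sds[:dd]),
            beta=beta, cov=cov, static_ranges=static_ranges,
            endpoint=endpoint, threshold=threshold,
            duration_s=obs.schema.n_steps * obs.schema.window_s, d=dd,
            ridge_flagged=flagged)
        bundles[d] = bundle
    return bundles


class ThresholdModel:
    """Threshold classifier on observation matrices (model/results pattern).

    Parameters
    ----------
    observations : ObservationMatrix
        Assembled design rows with raw endpoint scores.
    threshold : int
        Binary endpoint is ``score > threshold``.
    d : int
        LOL target dimensionality (2..20).
    normalizer_mode : str
        ``mean_sd`` (default) or ``median_iqr`` column normalization.
    """

    def __init__(self, observations: ObservationMatrix, threshold: int, d: int = 8,
                 endpoint: str = "GCSm", normalizer_mode: str = "mean_sd",
                 static_ranges: StaticRange | None = None):
        self.observations = observations
        self.threshold = int(threshold)
        self.d = int(d)
        self.endpoint = endpoint
        self.normalizer_mode = normalizer_mode
        self.static_ranges = static_ranges

    def fit(self) -> "ThresholdModelResults":
        obs = self.observations
        y = obs.labels(self.threshold)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        normalizer = fit_column_normalizer(obs.values, obs.schema,
                                           mode=self.normalizer_mode)
        Xn = normalizer.apply(obs.values, obs.schema)
        lol = fit_lol(Xn, y, self.d)
        Z = lol.transform(Xn)
        T, yj = yeo_johnson_fit_apply(Z)
        beta, cov, flagged = fit_logistic(T, y)
        bundle = ModelBundle(
            schema=obs.schema, normalizer=normalizer, lol=lol, yj=yj,
            beta=beta, cov=cov, static_ranges=self.static_ranges,
            endpoint=self.endpoint, threshold=self.threshold,
            duration_s=obs.schema.n_steps * obs.schema.window_s, d=lol.d,
            ridge_flagged=flagged,
        )
        bundle.train_predictions = bundle.predict(obs.values)
        return ThresholdModelResults(model=self, bundle=bundle)


class ThresholdModelResults:
    """Fit results: coefficients, uncertainties, predictions, summary."""

    def __init__(self, model: ThresholdModel, bundle: ModelBundle):
        self.model = model
        self.bundle = bundle
        self.params = bundle.beta
        self.bse = np.sqrt(np.diag(bundle.cov))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.bundle.train_predictions

    def predict(self, rows: np.ndarray) -> np.ndarray:
        return self.bundle.predict(rows)

    def summary(self) -> str:
        names = ["intercept"] + [f"LOL_{k + 1}" for k in range(self.bundle.d)]
        lines = [
            f"Threshold model: {self.bundle.endpoint} > {self.bundle.threshold}",
            f"Observation window: {self.bundle.duration_s / 60:.0f} min "
            f"({self.bundle.schema.n_steps} steps), d = {self.bundle.d}",
            f"Rows: {len(self.model.observations.values)}, "
            f"columns: {self.bundle.schema.n_columns}",
            f"Ridge fallback: {'yes' if self.bundle.ridge_flagged else 'no'}",
            "",
            f"{'term':<12}{'coef':>12}{'std err':>12}{'z':>10}",
        ]
        for name, b, se in zip(names, self.params, self.bse):
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:<12}{b:>12.4f}{se:>12.4f}{z:>10.2f}")
        return "\n".join(lines)
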