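"""Geographically weighted regression (GWR).

A stationarity check for the global linear models: at every site a
weighted least-squares fit is computed with Gaussian kernel weights

    w_ij = exp(-d_ij^2 / (2 b^2)),

d_ij the Euclidean distance in decimal degrees between sites i and j and
b the (fixed, not adaptive) bandwidth.  As b grows every local fit
converges to the global OLS fit; strong dispersion of the local
coefficients relative to the global standard errors signals spatial
non-stationarity / autocorrelation that the global model misses.

Bandwidth may be given in degrees or selected by leave-one-out
cross-validation over a log-spaced grid spanning the inter-site distance
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import _ParamsMixin, _as_frame, ols_fit


@dataclass
class GWRResult:
    """Local fits at every site plus a global comparison summary."""

    bandwidth: float
    sites: np.ndarray                 # (n, 2) lon/lat
    local_coef: pd.DataFrame          # one row per site, one column per predictor
    local_intercept: np.ndarray
    local_r2: np.ndarray
    valid: np.ndarray                 # False where the local fit was rank-deficient
    global_coef: dict[str, float]
    global_se: dict[str, float]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def nonstationarity_ratio(self) -> dict[str, float]:
        """SD of local coefficients over the global SE, per predictor.

        Ratios well above ~1-2 flag coefficients that drift over space.
        """
        out = {}
        for name in self.local_coef.columns:
            sd = float(self.local_coef.loc[self.valid, name].std(ddof=1))
            se = self.global_se[name]
            out[name] = sd / se if se > 0 else float("inf")
        return out


def _gaussian_weights(d: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-(d**2) / (2.0 * bandwidth**2))


def _wls(Xmat: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS via sqrt-weight scaling; returns (beta, ok, r2)."""
    sw = np.sqrt(w)
    Xw = Xmat * sw[:, None]
    yw = y * sw
    # effective support: weights that actually contribute
    if np.count_nonzero(w > 1e-12) < Xmat.shape[1] + 1:
        return None, False, np.nan
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < Xmat.shape[1]:
        return None, False, np.nan
    fitted = Xmat @ beta
    resid = y - fitted
    wmean = np.average(y, weights=w)
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return beta, True, r2


def _loo_cv_score(
    Xmat: np.ndarray, y: np.ndarray, dist: np.ndarray, bandwidth: float
) -> float:
    n = len(y)
    sse = 0.0
    for i in range(n):
        w = _gaussian_weights(dist[i], bandwidth)
        w[i] = 0.0
        beta, ok, _ = _wls(Xmat, y, w)
        if not ok:
            return np.inf
        sse += float((y[i] - Xmat[i] @ beta) ** 2)
    return sse


def gwr_fit(
    X,
    y,
    coords,
    *,
    bandwidth: float | str = "cv",
    n_bandwidths: int = 10,
) -> GWRResult:
    """Fit local Gaussian-kernel regressions at every site.

    Parameters
    ----------
    X, y : predictors and (already transformed) response
    coords : (n, 2) array of (lon, lat) in decimal degrees
    bandwidth : kernel bandwidth in degrees, or ``"cv"`` for
        leave-one-out CV over a log-spaced grid between the median
        nearest-neighbour distance and the extent diagonal.

    Sites whose local design is rank-deficient at the chosen bandwidth
    are flagged invalid and excluded from the summary.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, k = len(X), X.shape[1]
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n, 2) lon/lat")
    if n < k + 5:
        raise ValueError(f"GWR needs at least k+5={k + 5} sites, got {n}")

    Xmat = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    dist = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    )

    if bandwidth == "cv":
        pos = dist[dist > 0]
        if pos.size == 0:
            raise ValueError("bandwidth CV needs distinct coordinates")
        d_nn = np.median(
            np.min(np.where(dist > 0, dist, np.inf), axis=1)
        )
        d_max = float(dist.max())
        lo = max(d_nn, 1e-6)
        hi = max(d_max, lo * 10)
        grid = np.geomspace(lo, hi, n_bandwidths)
        scores = [_loo_cv_score(Xmat, y, dist, b) for b in grid]
        bandwidth = float(grid[int(np.argmin(scores))])
    bandwidth = float(bandwidth)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    local_beta = np.full((n, k + 1), np.nan)
    local_r2 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        w = _gaussian_weights(dist[i], bandwidth)
        beta, ok, r2 = _wls(Xmat, y, w)
        if ok:
            local_beta[i] = beta
            local_r2[i] = r2
            valid[i] = True

    glob = ols_fit(X, y)
    names = list(X.columns)
    coef_df = pd.DataFrame(local_beta[:, 1:], columns=names)
    result = GWRResult(
        bandwidth=bandwidth,
        sites=coords,
        local_coef=coef_df,
        local_intercept=local_beta[:, 0],
        local_r2=local_r2,
        valid=valid,
        global_coef=dict(glob.coef),
        global_se=dict(glob.se),
    )
    result.summary = {
        name: {
            "global": glob.coef[name],
            "global_se": glob.se[name],
            "local_sd": float(coef_df.loc[valid, name].std(ddof=1)),
            "local_min": float(coef_df.loc[valid, name].min()),
            "local_max": float(coef_df.loc[valid, name].max()),
        }
        for name in names
    }
    return result


class GWRRegressor(_ParamsMixin):
    """Estimator facade over :func:`gwr_fit`.

    ``fit(X, y, coords=...)`` stores a :class:`GWRResult` in
    ``result_``; ``predict(X, coords=...)`` evaluates each point with
    the local model refit at that point's location.
    """

    _param_names = ("bandwidth", "n_bandwidths")

    def __init__(self, bandwidth: float | str = "cv", n_bandwidths: int = 10):
        self.bandwidth = bandwidth
        self.n_bandwidths = n_bandwidths

    def fit(self, X, y, coords=None):
        if coords is None:
            raise ValueError("GWRRegressor.fit requires coords=(n,2) lon/lat")
        X = _as_frame(X)
        self.result_ = gwr_fit(
            X, y, coords, bandwidth=self.bandwidth, n_bandwidths=self.n_bandwidths
        )
        self._train_X = X.to_numpy(dtype=float)
        self._train_y = np.asarray(y, dtype=float)
        self._train_coords = np.asarray(coords, dtype=float)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, coords=None):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        if coords is None:
            raise ValueError("GWRRegressor.predict requires coords")
        X = _as_frame(X).to_numpy(dtype=float)
        coords = np.asarray(coords, dtype=float)
        n_train = len(self._train_y)
        Xmat_train = np.column_stack([np.ones(n_train), self._train_X])
        out = np.empty(len(X))
        b = self.result_.bandwidth
        for i, (xrow, c) in enumerate(zip(X, coords)):
            d = np.sqrt(((self._train_coords - c) ** 2).sum(axis=1))
            beta, ok, _ = _wls(Xmat_train, self._train_y, _gaussian_weights(d, b))
            out[i] = np.nan if not ok else float(np.r_[1.0, xrow] @ beta)
        return out
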