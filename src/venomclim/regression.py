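"""Transformation-gridded linear models with diagnostic gating.

The modelling procedure fits, for one enzyme activity y and the seven
bioclim predictors, ordinary least squares on each response transform
tau in {identity, ln, sqrt, inverse}, refines each fit by backward
stepwise elimination of non-significant predictors (t-test p > alpha,
stopping when a drop would lower the adjusted R^2), and gates every cell
with four diagnostics:

* N — residual normality, Shapiro-Wilk;
* H — homoscedasticity, studentized (Koenker) Breusch-Pagan,
  LM = n * R^2 of the auxiliary regression of squared residuals on X;
* L — linearity, Rainbow F test comparing the full-sample fit against
  the fit on the central 50% of observations ordered by fitted values;
* M — multicollinearity, variance inflation factors (VIF >= 10 fails).

The cell with the highest adjusted R^2 among those passing N, H and L is
downselected; multicollinearity is reported but does not veto, because
collinear bioclim predictors are expected and the selected model may
legitimately fail M.  AIC is reported on the Gaussian-likelihood
convention with constants (comparable only within a transform of the
same response; downselection never compares AIC across transforms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

TRANSFORMS = ("identity", "ln", "sqrt", "inverse")

__all__ = [
    "TRANSFORMS",
    "TransformDomainError",
    "FitResult",
    "DiagnosticsReport",
    "ModelCard",
    "apply_transform",
    "back_transform",
    "ols_fit",
    "backward_stepwise",
    "run_diagnostics",
    "build_model_grid",
    "TransformedLinearModel",
    "BackwardStepwise",
    "ModelGridSelector",
]


class TransformDomainError(ValueError):
    """Response values outside the domain of the requested transform."""


def apply_transform(y, transform: str) -> np.ndarray:
    """Elementwise response transform; domain violations raise, never shift."""
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y.copy()
    if transform == "ln":
        bad = np.flatnonzero(~(y > 0))
        if bad.size:
            raise TransformDomainError(
                f"ln requires positive activities; offending samples {bad.tolist()}"
            )
        return np.log(y)
    if transform == "sqrt":
        bad = np.flatnonzero(~(y >= 0))
        if bad.size:
            raise TransformDomainError(
                f"sqrt requires nonnegative activities; offending samples {bad.tolist()}"
            )
        return np.sqrt(y)
    if transform == "inverse":
        bad = np.flatnonzero(~(y > 0))
        if bad.size:
            raise TransformDomainError(
                f"inverse requires positive activities; offending samples {bad.tolist()}"
            )
        return 1.0 / y
    raise ValueError(f"unknown transform {transform!r}")


def back_transform(values, transform: str) -> np.ndarray:
    """Invert :func:`apply_transform` (naive, no retransformation bias fix).

    The reciprocal of zero is returned as NaN rather than infinity.
    """
    v = np.asarray(values, dtype=float)
    if transform == "identity":
        return v.copy()
    if transform == "ln":
        return np.exp(v)
    if transform == "sqrt":
        return np.square(v)
    if transform == "inverse":
        with np.errstate(divide="ignore"):
            out = np.where(v != 0, 1.0 / v, np.nan)
        return out
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class FitResult:
    """A fitted OLS model on the transformed response scale."""

    response: str
    transform: str
    predictors: list[str]
    intercept: float
    coef: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    intercept_se: float
    r2: float
    adj_r2: float
    f_pvalue: float
    aic: float
    n: int
    k: int
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    fittedvalues: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    flags: list[str] = field(default_factory=list)

    def predict_transformed(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor on the transformed scale."""
        out = np.full(len(X), self.intercept, dtype=float)
        for name in self.predictors:
            out += self.coef[name] * np.asarray(X[name], dtype=float)
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Prediction in response units (back-transformed)."""
        return back_transform(self.predict_transformed(X), self.transform)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Classical t confidence intervals for the slopes."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.n - self.k - 1)
        return {
            name: (
                self.coef[name] - tcrit * self.se[name],
                self.coef[name] + tcrit * self.se[name],
            )
            for name in self.predictors
        }

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d.pop("residuals")
        d.pop("fittedvalues")
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "FitResult":
        return cls(residuals=None, fittedvalues=None, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def ols_fit(
    X, y, *, response: str = "activity", transform: str = "identity"
) -> FitResult:
    """OLS with intercept; classical SEs, adjusted R^2, F-test p, AIC.

    ``y`` is taken to be already on the transformed scale; ``transform``
    is recorded for prediction-time back-transformation.  Rank-deficient
    design matrices are rejected with the collinear columns named.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, k = len(X), X.shape[1]
    if k < 1:
        raise ValueError("at least one predictor required")
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} predictors")
    Xmat = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        # identify offending columns by dependence on the preceding ones
        bad = []
        for j in range(1, Xmat.shape[1]):
            if np.linalg.matrix_rank(Xmat[:, : j + 1]) < j + 1:
                bad.append(X.columns[j - 1])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    res = sm.OLS(y, Xmat).fit()
    rss = float(res.ssr)
    # Gaussian log-likelihood AIC with k+2 parameters (slopes, intercept, sigma),
    # the convention of R's AIC(lm).
    if rss > 0:
        llf = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
        aic = -2.0 * llf + 2.0 * (k + 2)
    else:
        aic = float("-inf")
    names = list(X.columns)
    return FitResult(
        response=response,
        transform=transform,
        predictors=names,
        intercept=float(res.params[0]),
        coef={nm: float(b) for nm, b in zip(names, res.params[1:])},
        se={nm: float(s) for nm, s in zip(names, res.bse[1:])},
        tvalues={nm: float(t) for nm, t in zip(names, res.tvalues[1:])},
        pvalues={nm: float(p) for nm, p in zip(names, res.pvalues[1:])},
        intercept_se=float(res.bse[0]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_pvalue=float(res.f_pvalue) if k >= 1 else float("nan"),
        aic=float(aic),
        n=n,
        k=k,
        residuals=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
    )


def backward_stepwise(
    X, y, *, alpha: float = 0.05, response: str = "activity",
    transform: str = "identity", protect_adj_r2: bool = False,
) -> FitResult:
    """Backward elimination of non-significant predictors by t-statistics.

    At each step the predictor with the largest p-value above ``alpha``
    is dropped and the model refit, until every remaining predictor is
    significant.  Ties break by column order.  With
    ``protect_adj_r2=True`` elimination additionally stops as soon as a
    drop would decrease the adjusted R^2 (a predictor with |t| > 1 then
    blocks further pruning even when non-significant); the default
    eliminates on significance alone.  If every predictor is eliminated
    an intercept-only result is returned, flagged.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    current = list(X.columns)
    fit = ols_fit(X[current], y, response=response, transform=transform)
    while True:
        worst_name, worst_p = None, alpha
        for name in current:  # ordinal tie-break: first occurrence of the max
            p = fit.pvalues[name]
            if p > worst_p:
                worst_name, worst_p = name, p
        if worst_name is None:
            return fit
        remaining = [c for c in current if c != worst_name]
        if not remaining:
            ybar = y.mean()
            resid = y - ybar
            sst = float((resid**2).sum())
            n = len(y)
            llf = (
                -0.5 * n * (math.log(2 * math.pi) + math.log(sst / n) + 1.0)
                if sst > 0
                else float("inf")
            )
            return FitResult(
                response=response,
                transform=transform,
                predictors=[],
                intercept=float(ybar),
                coef={},
                se={},
                tvalues={},
                pvalues={},
                intercept_se=float(np.sqrt(sst / (n - 1) / n)) if n > 1 else float("nan"),
                r2=0.0,
                adj_r2=0.0,
                f_pvalue=float("nan"),
                aic=float(-2.0 * llf + 2.0 * 2) if sst > 0 else float("-inf"),
                n=n,
                k=0,
                residuals=resid,
                fittedvalues=np.full(n, ybar),
                flags=["intercept_only"],
            )
        candidate = ols_fit(X[remaining], y, response=response, transform=transform)
        if protect_adj_r2 and candidate.adj_r2 < fit.adj_r2 - 1e-12:
            return fit
        current, fit = remaining, candidate


@dataclass
class DiagnosticsReport:
    """Four regression diagnostics with alpha-level pass flags."""

    shapiro_w: float
    shapiro_p: float
    bp_stat: float
    bp_p: float
    rainbow_stat: float
    rainbow_p: float
    vif: dict[str, float]
    passed_normality: bool
    passed_homoscedasticity: bool
    passed_linearity: bool
    passed_multicollinearity: bool
    flags: list[str] = field(default_factory=list)

    @property
    def pass_flags(self) -> dict[str, bool]:
        return {
            "N": self.passed_normality,
            "H": self.passed_homoscedasticity,
            "L": self.passed_linearity,
            "M": self.passed_multicollinearity,
        }

    def to_json_dict(self) -> dict:
        return asdict(self)


def rainbow_test(
    X, y, *, frac: float = 0.5
) -> tuple[float, float]:
    """Rainbow linearity test, central fraction ordered by fitted values.

    The full-sample fit is compared with a fit on the central ``frac`` of
    observations (ordered by the full-model fitted values); under
    linearity the F statistic ~ F(n - n_sub, n_sub - k - 1).
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, k = len(X), X.shape[1]
    Xmat = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    full = sm.OLS(y, Xmat).fit()
    order = np.argsort(full.fittedvalues, kind="stable")
    n_sub = int(round(frac * n))
    lo = (n - n_sub) // 2
    idx = order[lo : lo + n_sub]
    sub = sm.OLS(y[idx], Xmat[idx]).fit()
    rss_full, rss_sub = float(full.ssr), float(sub.ssr)
    df_num = n - n_sub
    df_den = n_sub - k - 1
    if df_den <= 0:
        raise ValueError("central subset too small for the rainbow test")
    if rss_sub <= 0:
        return float("nan"), 1.0
    f = ((rss_full - rss_sub) / df_num) / (rss_sub / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p


def variance_inflation_factors(X) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j), predictor j regressed on the others."""
    X = _as_frame(X)
    names = list(X.columns)
    if len(names) == 1:
        return {names[0]: 1.0}
    out = {}
    for name in names:
        others = [c for c in names if c != name]
        Z = sm.add_constant(X[others].to_numpy(dtype=float), has_constant="add")
        r2 = sm.OLS(X[name].to_numpy(dtype=float), Z).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 else float(1.0 / (1.0 - r2))
    return out


def run_diagnostics(
    fit: FitResult,
    X,
    y=None,
    *,
    alpha: float = 0.05,
    vif_threshold: float = 10.0,
    bp_studentized: bool = True,
) -> DiagnosticsReport:
    """Gate a fitted model on normality/homoscedasticity/linearity/VIF.

    ``X`` must be the predictor frame the model was fitted on; ``y`` (the
    transformed response) is only needed to re-fit for the rainbow test
    and defaults to fitted + residuals.  A perfect fit (RSS = 0) makes
    the rainbow statistic undefined; it is reported as a pass, flagged.
    """
    X = _as_frame(X)
    if fit.residuals is None:
        raise ValueError("diagnostics need a fit with stored residuals")
    resid = np.asarray(fit.residuals, dtype=float)
    if resid.size < 8:
        raise ValueError("diagnostics need >= 8 residuals")
    if y is None:
        y = np.asarray(fit.fittedvalues) + resid
    flags: list[str] = []

    sw_w, sw_p = stats.shapiro(resid)

    Xmat = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.ptp(resid**2) <= 1e-14:
        # squared residuals constant: the auxiliary regression is degenerate
        # and explains nothing, so the LM statistic is 0 by definition
        bp_stat, bp_p = 0.0, 1.0
    else:
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, Xmat, robust=bp_studentized)

    if float((resid**2).sum()) <= 1e-14:
        rb_stat, rb_p = float("nan"), 1.0
        flags.append("rainbow_undefined_perfect_fit")
    else:
        rb_stat, rb_p = rainbow_test(X[fit.predictors], np.asarray(y, dtype=float))

    vif = variance_inflation_factors(X[fit.predictors])

    return DiagnosticsReport(
        shapiro_w=float(sw_w),
        shapiro_p=float(sw_p),
        bp_stat=float(bp_stat),
        bp_p=float(bp_p),
        rainbow_stat=rb_stat,
        rainbow_p=float(rb_p),
        vif=vif,
        passed_normality=bool(sw_p > alpha),
        passed_homoscedasticity=bool(bp_p > alpha),
        passed_linearity=bool(rb_p > alpha),
        passed_multicollinearity=bool(max(vif.values()) < vif_threshold),
        flags=flags,
    )


@dataclass
class GridCell:
    """One (transform) cell of a model card."""

    transform: str
    full_fit: FitResult | None
    stepwise_fit: FitResult | None
    diagnostics: DiagnosticsReport | None
    downselected: bool = False
    error: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "transform": self.transform,
            "full_fit": self.full_fit.to_json_dict() if self.full_fit else None,
            "stepwise_fit": (
                self.stepwise_fit.to_json_dict() if self.stepwise_fit else None
            ),
            "diagnostics": (
                self.diagnostics.to_json_dict() if self.diagnostics else None
            ),
            "downselected": self.downselected,
            "error": self.error,
        }


@dataclass
class ModelCard:
    """Pass/fail matrix over the transform grid for one response."""

    response: str
    candidates: list[str]
    cells: list[GridCell]

    @property
    def selected(self) -> GridCell | None:
        for cell in self.cells:
            if cell.downselected:
                return cell
        return None

    def to_json_dict(self) -> dict:
        return {
            "response": self.response,
            "candidates": self.candidates,
            "cells": [c.to_json_dict() for c in self.cells],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def build_model_grid(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    transforms: tuple[str, ...] = TRANSFORMS,
    alpha: float = 0.05,
    vif_threshold: float = 10.0,
    f_alpha: float = 0.05,
) -> ModelCard:
    """Fit the transform grid, refine by stepwise, gate, and downselect.

    For each transform: fit the full MLR, refine by backward stepwise,
    run the four diagnostics on the refined model.  The downselected
    cell maximises adjusted R^2 among cells that pass normality,
    homoscedasticity and linearity, keep at least one predictor, and are
    significant by the overall F-test.  Multicollinearity is reported
    but never vetoes.  If no cell qualifies the card carries no
    selection.
    """
    cells: list[GridCell] = []
    y_raw = np.asarray(data[response], dtype=float)
    X = data[list(candidates)]
    for transform in transforms:
        try:
            y_t = apply_transform(y_raw, transform)
            full = ols_fit(X, y_t, response=response, transform=transform)
            step = backward_stepwise(
                X, y_t, alpha=alpha, response=response, transform=transform
            )
            diag = (
                run_diagnostics(
                    step, X[step.predictors], y_t,
                    alpha=alpha, vif_threshold=vif_threshold,
                )
                if step.k >= 1
                else None
            )
            cells.append(GridCell(transform, full, step, diag))
        except (TransformDomainError, np.linalg.LinAlgError, ValueError) as exc:
            cells.append(GridCell(transform, None, None, None, error=str(exc)))

    best, best_adj = None, -np.inf
    for cell in cells:
        fit, diag = cell.stepwise_fit, cell.diagnostics
        if fit is None or diag is None or fit.k < 1:
            continue
        if not (np.isfinite(fit.f_pvalue) and fit.f_pvalue < f_alpha):
            continue
        if not (
            diag.passed_normality
            and diag.passed_homoscedasticity
            and diag.passed_linearity
        ):
            continue
        if fit.adj_r2 > best_adj:
            best, best_adj = cell, fit.adj_r2
    if best is not None:
        best.downselected = True
    return ModelCard(response=response, candidates=list(candidates), cells=cells)


# ---------------------------------------------------------------------------
# sklearn-style estimator facade


class _ParamsMixin:
    _param_names: tuple[str, ...] = ()

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self


class TransformedLinearModel(_ParamsMixin):
    """OLS of tau(y) on X with back-transformed predictions.

    Parameters
    ----------
    transform : {"identity", "ln", "sqrt", "inverse"}
        Response transform applied before fitting.  Predictions are
        returned in response units by naive inversion.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : slopes and intercept on the transformed scale
    result_ : the underlying :class:`FitResult`
    feature_names_in_, n_features_in_
    """

    _param_names = ("transform", "response")

    def __init__(self, transform: str = "identity", response: str = "activity"):
        self.transform = transform
        self.response = response

    def fit(self, X, y):
        X = _as_frame(X)
        y_t = apply_transform(y, self.transform)
        self.result_ = ols_fit(
            X, y_t, response=self.response, transform=self.transform
        )
        self.feature_names_in_ = np.asarray(self.result_.predictors, dtype=object)
        self.n_features_in_ = self.result_.k
        self.coef_ = np.array([self.result_.coef[c] for c in self.result_.predictors])
        self.intercept_ = self.result_.intercept
        return self

    def predict(self, X):
        self._check_fitted()
        return self.result_.predict(_as_frame(X))

    def score(self, X=None, y=None):
        """Adjusted R^2 on the transformed scale of the training fit."""
        self._check_fitted()
        return self.result_.adj_r2

    def diagnostics(self, X, y=None, **kwargs) -> DiagnosticsReport:
        self._check_fitted()
        X = _as_frame(X)
        y_t = None if y is None else apply_transform(y, self.transform)
        return run_diagnostics(self.result_, X, y_t, **kwargs)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class BackwardStepwise(_ParamsMixin):
    """Backward stepwise refinement of a transformed OLS model.

    Fitted attributes: ``support_`` (retained predictor names),
    ``result_`` (:class:`FitResult` of the refined model).
    """

    _param_names = ("transform", "alpha", "response", "protect_adj_r2")

    def __init__(
        self, transform: str = "identity", alpha: float = 0.05,
        response: str = "activity", protect_adj_r2: bool = False,
    ):
        self.transform = transform
        self.alpha = alpha
        self.response = response
        self.protect_adj_r2 = protect_adj_r2

    def fit(self, X, y):
        X = _as_frame(X)
        y_t = apply_transform(y, self.transform)
        self.result_ = backward_stepwise(
            X, y_t, alpha=self.alpha, response=self.response,
            transform=self.transform, protect_adj_r2=self.protect_adj_r2,
        )
        self.support_ = list(self.result_.predictors)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        return self.result_.predict(_as_frame(X))


class ModelGridSelector(_ParamsMixin):
    """Grid search over response transforms with diagnostic gating.

    Analogous to a model-selection meta-estimator: fits the full
    transform grid via :func:`build_model_grid` and exposes the
    downselected cell.  Fitted attributes: ``card_`` (the full
    :class:`ModelCard`), ``best_result_`` (FitResult of the selected
    cell or None), ``best_transform_``.
    """

    _param_names = ("transforms", "alpha", "vif_threshold", "f_alpha", "response")

    def __init__(
        self,
        transforms: tuple[str, ...] = TRANSFORMS,
        alpha: float = 0.05,
        vif_threshold: float = 10.0,
        f_alpha: float = 0.05,
        response: str = "activity",
    ):
        self.transforms = transforms
        self.alpha = alpha
        self.vif_threshold = vif_threshold
        self.f_alpha = f_alpha
        self.response = response

    def fit(self, X, y):
        X = _as_frame(X)
        data = X.copy()
        data[self.response] = np.asarray(y, dtype=float)
        self.card_ = build_model_grid(
            data,
            self.response,
            list(X.columns),
            transforms=tuple(self.transforms),
            alpha=self.alpha,
            vif_threshold=self.vif_threshold,
            f_alpha=self.f_alpha,
        )
        sel = self.card_.selected
        self.best_result_ = sel.stepwise_fit if sel else None
        self.best_transform_ = sel.transform if sel else None
        return self

    def predict(self, X):
        if not hasattr(self, "card_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        if self.best_result_ is None:
            raise RuntimeError("no model was downselected; nothing to predict with")
        return self.best_result_.predict(_as_frame(X))
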