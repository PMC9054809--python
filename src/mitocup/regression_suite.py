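"""Linear, polynomial and additive regressions of divergence rates on
codon-usage indices, with the train/test protocol and residual diagnostics.

Workflow: response outliers are removed (beyond ``outlier_k`` x IQR from the
quartiles), the remainder is split 75/25 with a seeded shuffle, each model
class is fitted on the training rows, and every fit reports R^2, adjusted
R^2, AIC, test RMSE, plus Breusch-Pagan (heteroscedasticity) and
Shapiro-Wilk (residual normality) p-values.

* LM: ordinary least squares, E(Y) = b0 + b1 X.
* PM: polynomial least squares with the degree chosen by minimizing AIC or
  BIC over 1..max_degree (default 20).  Fitting uses a Legendre basis on the
  predictor rescaled to [-1, 1] for numerical stability; forced degree 1
  reproduces the LM fit.
* AM: penalized B-spline additive smoother (Gaussian family, identity
  link), with the penalty weight chosen by the fitter's generalized
  cross-validation-style criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial import legendre
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = ["RegressionFit", "split_data", "fit_lm", "fit_poly",
           "fit_additive", "diagnostics", "log_transform_responses"]

DEFAULT_SEED = 12345
MAX_DEGREE = 20


@dataclass
class RegressionFit:
    model: str                  # LM | PM | AM
    response: str
    predictor: str
    coefficients: np.ndarray | None
    degree: int | None
    edf: float
    r2: float
    adj_r2: float
    aic: float
    rmse_test: float
    fitted: np.ndarray
    residuals: np.ndarray
    predict: object = field(repr=False, default=None)   # callable x -> yhat


def _iqr_mask(y: pd.Series, k: float) -> pd.Series:
    q1, q3 = y.quantile(0.25), y.quantile(0.75)
    iqr = q3 - q1
    return (y >= q1 - k * iqr) & (y <= q3 + k * iqr)


def split_data(rows: pd.DataFrame, response: str,
               train_fraction: float = 0.75, seed: int = DEFAULT_SEED,
               outlier_k: float | None = 3.0):
    """Outlier-filtered, seeded train/test split.

    Rows whose response lies beyond ``outlier_k`` x IQR from the quartiles
    are dropped first (``outlier_k=None`` disables the rule).  Returns
    ``(train, test, n_removed)``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    data = rows.dropna(subset=[response])
    if outlier_k is not None:
        kept = _iqr_mask(data[response], outlier_k)
        n_removed = int((~kept).sum()) + (len(rows) - len(data))
        data = data[kept]
    else:
        n_removed = len(rows) - len(data)
    if len(data) < 8:
        raise ValueError("too few rows after outlier filtering")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    n_train = int(round(train_fraction * len(data)))
    train = data.iloc[idx[:n_train]]
    test = data.iloc[idx[n_train:]]
    return train, test, n_removed


def _finite_xy(train: pd.DataFrame, response: str, predictor: str):
    sub = train[[predictor, response]].replace([np.inf, -np.inf], np.nan).dropna()
    n_dropped = len(train) - len(sub)
    return sub[predictor].to_numpy(float), sub[response].to_numpy(float), n_dropped


def _metrics(y, fitted):
    resid = y - fitted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return resid, r2


def _test_rmse(predict, test, response, predictor) -> float:
    if test is None or len(test) == 0:
        return math.nan
    x, y, _ = _finite_xy(test, response, predictor)
    if len(x) == 0:
        return math.nan
    return float(np.sqrt(np.mean((y - predict(x)) ** 2)))


def fit_lm(train: pd.DataFrame, response: str, predictor: str,
           test: pd.DataFrame | None = None) -> RegressionFit:
    x, y, _ = _finite_xy(train, response, predictor)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    predict = lambda xs: res.params[0] + res.params[1] * np.asarray(xs, float)
    fitted = predict(x)
    resid, r2 = _metrics(y, fitted)
    return RegressionFit(
        "LM", response, predictor, res.params, 1, 2.0, r2,
        float(res.rsquared_adj) if np.isfinite(res.rsquared_adj) else r2,
        float(res.aic), _test_rmse(predict, test, response, predictor),
        fitted, resid, predict,
    )


def _poly_design(x: np.ndarray, degree: int, lo: float, hi: float) -> np.ndarray:
    span = hi - lo if hi > lo else 1.0
    z = 2.0 * (np.asarray(x, float) - lo) / span - 1.0
    return legendre.legvander(z, degree)


def fit_poly(train: pd.DataFrame, response: str, predictor: str,
             test: pd.DataFrame | None = None, degree: int | None = None,
             criterion: str = "aic", max_degree: int = MAX_DEGREE) -> RegressionFit:
    """Polynomial fit; ``degree=None`` selects the degree by AIC or BIC."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    x, y, _ = _finite_xy(train, response, predictor)
    lo, hi = float(x.min()), float(x.max())
    degrees = [degree] if degree is not None else list(range(1, max_degree + 1))
    best = None
    for d in degrees:
        if len(x) < d + 2:
            break
        design = _poly_design(x, d, lo, hi)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            if degree is not None:
                raise np.linalg.LinAlgError(
                    f"rank-deficient polynomial design at degree {d}")
            continue
        res = sm.OLS(y, design).fit()
        score = res.aic if criterion == "aic" else res.bic
        if best is None or score < best[0]:
            best = (score, d, res)
    if best is None:
        raise ValueError("no polynomial degree could be fitted")
    _, d, res = best
    coefs = res.params.copy()
    predict = lambda xs: _poly_design(np.asarray(xs, float), d, lo, hi) @ coefs
    fitted = predict(x)
    resid, r2 = _metrics(y, fitted)
    return RegressionFit(
        "PM", response, predictor, coefs, d, float(d + 1), r2,
        float(res.rsquared_adj) if np.isfinite(res.rsquared_adj) else r2,
        float(res.aic), _test_rmse(predict, test, response, predictor),
        fitted, resid, predict,
    )


def fit_additive(train: pd.DataFrame, response: str, predictor: str,
                 test: pd.DataFrame | None = None, df: int = 10,
                 spline_degree: int = 3) -> RegressionFit:
    """Penalized-spline additive model (Gaussian, identity link)."""
    x, y, _ = _finite_xy(train, response, predictor)
    xdf = pd.DataFrame({predictor: x})
    basis_df = min(df, max(4, len(x) // 3))
    splines = BSplines(xdf, df=[basis_df], degree=[spline_degree])
    model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=splines)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            alpha = model.select_penweight()[0]
        except Exception:
            alpha = [1.0]
        model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=splines,
                       alpha=alpha)
        res = model.fit()
    edf = float(np.sum(res.edf)) if hasattr(res, "edf") else math.nan

    def predict(xs):
        xs = np.asarray(xs, float)
        clipped = np.clip(xs, x.min(), x.max())
        ex = splines.transform(clipped.reshape(-1, 1))
        return res.params[0] + ex @ res.params[1:]

    fitted = np.asarray(res.fittedvalues)
    resid, r2 = _metrics(y, fitted)
    n = len(y)
    sigma2 = float(np.sum(resid ** 2)) / n
    aic = n * math.log(sigma2) + n * (1 + math.log(2 * math.pi)) + 2 * (edf + 1)
    adj = 1 - (1 - r2) * (n - 1) / max(n - edf - 1, 1)
    return RegressionFit(
        "AM", response, predictor, None, None, edf, r2, adj, aic,
        _test_rmse(predict, test, response, predictor), fitted, resid, predict,
    )


@dataclass
class DiagnosticReport:
    bp_p: float
    sw_p: float
    fitted: np.ndarray
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_ordered: np.ndarray


def diagnostics(fit: RegressionFit) -> DiagnosticReport:
    """Breusch-Pagan and Shapiro-Wilk p-values plus plot-ready vectors."""
    resid = np.asarray(fit.residuals, float)
    if len(resid) < 3:
        raise ValueError("diagnostics need at least 3 residuals")
    exog = sm.add_constant(np.asarray(fit.fitted, float))
    bp_p = float(het_breuschpagan(resid, exog)[1])
    sw_p = float(stats.shapiro(resid).pvalue)
    order = np.sort(resid)
    n = len(resid)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    theo = resid.mean() + resid.std(ddof=1) * theo
    return DiagnosticReport(bp_p, sw_p, np.asarray(fit.fitted), resid,
                            theo, order)


def log_transform_responses(rows: pd.DataFrame,
                            responses=("adS", "adN", "omega")):
    """Append natural-log response columns; non-positive rows are dropped.

    Returns ``(table, n_dropped)``.
    """
    present = [r for r in responses if r in rows.columns]
    if not present:
        raise ValueError("no response columns found")
    mask = pd.Series(True, index=rows.index)
    for r in present:
        mask &= rows[r] > 0
    if not mask.any():
        raise ValueError("all rows non-positive under log transform")
    out = rows[mask].copy()
    for r in present:
        out[f"log_{r}"] = np.log(out[r])
    return out, int((~mask).sum())
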