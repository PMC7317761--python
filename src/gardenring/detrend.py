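"""Two-step standardization of ring-trait series.

Step 1 removes non-climatic trends (cambial age, tree size, competition)
with a penalized additive spline model; step 2 removes serial
autocorrelation per tree with an AR(p) fit chosen by AIC, leaving
innovations ("prewhitened" residuals) that feed the dendroclimatic
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# Step 1: additive trend removal


@dataclass
class TrendFit:
    """Fitted additive trend: per-observation fit, residuals, diagnostics."""

    fitted: np.ndarray
    residuals: np.ndarray
    edf: float
    alpha: list
    covariates: tuple


def fit_trend(data: pd.DataFrame, response: str,
              covariates=("age", "size", "comp"),
              spline_df: int = 8, alpha_search: bool = True,
              max_alpha_n: int = 4000, seed: int = 0) -> TrendFit:
    """Remove age/size/competition trends with penalized B-spline smooths.

    One cubic penalized spline per covariate; the smoothing parameters are
    chosen by generalized cross-validation (on a subsample when the table
    is large, for speed). Residuals are response-scale: observed - fitted.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    covariates = tuple(c for c in covariates if c in data.columns)
    if not covariates:
        raise ValueError("no trend covariates present in data")
    if len(data) < 30:
        raise ValueError("need >= 30 observations to fit trend smooths")
    for c in covariates:
        if data[c].nunique() < spline_df:
            raise ValueError(
                f"covariate {c!r} is rank-deficient for a {spline_df}-df smooth"
            )
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return TrendFit(fitted=y.copy(), residuals=np.zeros_like(y),
                        edf=1.0, alpha=[np.inf] * len(covariates),
                        covariates=covariates)
    X = data[list(covariates)]
    k = len(covariates)
    bs = BSplines(X, df=[spline_df] * k, degree=[3] * k)
    const = np.ones((len(y), 1))
    alpha = [1.0] * k
    if alpha_search:
        if len(data) > max_alpha_n:
            # GCV search on a subsample; alpha rescaled ~n for the full fit
            idx = np.random.default_rng(seed).choice(
                len(data), size=max_alpha_n, replace=False
            )
            sub = data.iloc[np.sort(idx)]
            ys = sub[response].to_numpy(dtype=float)
            bs_sub = BSplines(sub[list(covariates)], df=[spline_df] * k,
                              degree=[3] * k)
            gam_sub = GLMGam(ys, exog=np.ones((len(ys), 1)),
                             smoother=bs_sub, alpha=alpha)
            gam_sub.fit()
            a, _, _ = gam_sub.select_penweight(criterion="gcv", method="nm",
                                               disp=False)
            alpha = list(np.asarray(a) * len(data) / len(sub))
        else:
            gam0 = GLMGam(y, exog=const, smoother=bs, alpha=alpha)
            gam0.fit()
            a, _, _ = gam0.select_penweight(criterion="gcv", method="nm",
                                            disp=False)
            alpha = list(a)
    gam = GLMGam(y, exog=const, smoother=bs, alpha=alpha)
    res = gam.fit()
    fitted = np.asarray(res.fittedvalues)
    try:
        edf = float(np.sum(res.edf))
    except Exception:  # pragma: no cover - older statsmodels layouts
        edf = float("nan")
    return TrendFit(fitted=fitted, residuals=y - fitted, edf=edf,
                    alpha=alpha, covariates=covariates)


# ---------------------------------------------------------------------------
# Competition index (Hegyi-type distance-weighted size ratio)


def competition_index(design, sizes: pd.Series, radius: float = 3.6) -> pd.Series:
    """Hegyi-type competition index per tree.

    CI_i = sum over neighbours j within `radius` metres of
    (size_j / size_i) / d_ij.  Trees with no neighbour get 0.
    Requires planting coordinates x, y (metres) in the design table.
    """
    df = design.data
    for c in ("x", "y"):
        if c not in df.columns:
            raise ValueError("design table lacks planting coordinates x/y")
    trees = df["tree"].to_numpy()
    sizes = sizes.reindex(trees)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()][:5])
        raise ValueError(f"missing sizes for trees {missing}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    s = sizes.to_numpy(dtype=float)
    tree_kd = cKDTree(xy)
    pairs = tree_kd.query_pairs(r=radius, output_type="ndarray")
    ci = np.zeros(len(trees))
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(xy[i] - xy[j], axis=1)
        keep = d > 0
        i, j, d = i[keep], j[keep], d[keep]
        np.add.at(ci, i, (s[j] / s[i]) / d)
        np.add.at(ci, j, (s[i] / s[j]) / d)
    return pd.Series(ci, index=trees, name="competition")


# ---------------------------------------------------------------------------
# Step 2: autoregressive prewhitening


def _aic_ar(x: np.ndarray, p: int, hold_back: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional-likelihood AR(p) fit on a common sample.

    Returns (AIC, coefficients incl. intercept, residuals for t >= p).
    All orders are compared on the sample t >= hold_back so AICs are
    comparable.
    """
    n = len(x)
    rows = []
    for t in range(hold_back, n):
        rows.append([1.0] + [x[t - k] for k in range(1, p + 1)])
    A = np.asarray(rows)
    yv = x[hold_back:]
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid_fit = yv - A @ beta
    m = len(yv)
    sigma2 = max(float(resid_fit @ resid_fit) / m, 1e-300)
    aic = m * np.log(sigma2) + 2.0 * (p + 2)
    # residuals over the full usable range t >= p with the fitted coefs
    rows_full = []
    for t in range(p, n):
        rows_full.append([1.0] + [x[t - k] for k in range(1, p + 1)])
    Af = np.asarray(rows_full)
    resid = x[p:] - Af @ beta
    return aic, beta, resid


def _is_stationary(beta: np.ndarray) -> bool:
    """Check AR coefficients (beta[1:]) define a stationary process."""
    phi = beta[1:]
    if len(phi) == 0:
        return True
    roots = np.roots(np.concatenate([[1.0], -phi]))
    return bool(np.all(np.abs(roots) < 1.0))


def ar_innovations(x: np.ndarray, p_max: int = 3, rescale: bool = True,
                   fill: str = "nan") -> tuple[np.ndarray, int]:
    """Prewhiten one series with an AR(p) model, p chosen by AIC over 0..p_max.

    Returns a full-length array of innovations (first p slots NaN, or the
    centered raw values when ``fill="center"``) and the selected order.
    Innovations are mean-centred and, if `rescale`, scaled back to the
    input series' variance so chronologies keep comparable amplitude.
    Non-stationary fits fall back to order p-1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p_max + 5:
        raise ValueError(f"series too short ({n}) for AR selection up to {p_max}")
    if np.ptp(x) == 0:
        return np.zeros(n), 0
    hold_back = p_max
    fits = {p: _aic_ar(x, p, hold_back) for p in range(p_max + 1)}
    order = sorted(fits, key=lambda p: fits[p][0])
    p = order[0]
    while p > 0 and not _is_stationary(fits[p][1]):
        p -= 1
    _, beta, resid = fits[p]
    resid = resid - resid.mean()
    if rescale and resid.std() > 0:
        resid = resid * (x.std() / resid.std())
    out = np.full(n, np.nan)
    out[p:] = resid
    if fill == "center" and p > 0:
        head = x[:p] - x.mean()
        if rescale and x.std() > 0:
            pass  # head already on the input scale
        out[:p] = head
    return out, p


def prewhiten(residuals: pd.DataFrame, value_col: str = "residual1",
              p_max: int = 3, min_years: int = 15) -> pd.DataFrame:
    """Apply AR prewhitening tree by tree.

    Input: long frame tree, year, `value_col` (step-1 residuals).
    Output adds columns ``p`` (selected AR order), ``residual2``
    (innovations; NaN for the first p years) and ``flagged`` for
    degenerate or too-short series.
    """
    out = []
    for tree, grp in residuals.groupby("tree", sort=False):
        grp = grp.sort_values("year").copy()
        x = grp[value_col].to_numpy(dtype=float)
        if len(x) < min_years or np.ptp(x) == 0:
            grp["p"] = 0
            grp["residual2"] = 0.0 if np.ptp(x) == 0 else np.nan
            grp["flagged"] = True
            out.append(grp)
            continue
        res, p = ar_innovations(x, p_max=p_max)
        grp["p"] = p
        grp["residual2"] = res
        grp["flagged"] = False
        out.append(grp)
    return pd.concat(out, ignore_index=True)
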