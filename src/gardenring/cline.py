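"""Clinal climate-of-origin analysis with hinge-basis adaptive splines.

Provenance-mean traits (growth, resilience, climate-sensitivity
correlations) are regressed on climate normals at seed origin (MAT, MAP,
ADD, Summer_SMI) with an adaptive piecewise-linear basis: a forward pass
greedily adds mirrored hinge pairs max(0, x-k) / max(0, k-x) (optionally
times an existing basis term, up to pairwise interactions), and a
backward pass prunes terms by generalized cross-validation.  Predictors
are standardized internally, so the fit is invariant to affine rescaling
of the inputs; knots are reported in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HingeFactor:
    var: str
    knot: float  # original units
    sign: int    # +1: max(0, x-knot); -1: max(0, knot-x)


@dataclass
class BasisTerm:
    factors: tuple = ()  # empty tuple = intercept

    @property
    def degree(self) -> int:
        return len(self.factors)

    def involves(self, var: str) -> bool:
        return any(f.var == var for f in self.factors)

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(X))
        for f in self.factors:
            x = X[f.var].to_numpy(dtype=float)
            out = out * np.maximum(0.0, f.sign * (x - f.knot))
        return out

    def label(self) -> str:
        if not self.factors:
            return "1"
        parts = [
            f"max(0, {f.var} - {f.knot:.4g})" if f.sign > 0
            else f"max(0, {f.knot:.4g} - {f.var})"
            for f in self.factors
        ]
        return " * ".join(parts)


def _gcv(rss: float, n: int, n_terms: int, penalty: float) -> float:
    c = n_terms + penalty * (n_terms - 1) / 2.0
    if c >= n:
        return np.inf
    return (rss / n) / (1.0 - c / n) ** 2


class MarsRegression:
    """Adaptive regression-spline model of provenance means on origin climate.

    Parameters
    ----------
    data
        Frame holding the response and predictor columns.
    response, predictors
        Column names; predictors are standardized internally.
    max_degree
        1 for additive, 2 allows pairwise hinge products.
    max_terms
        Forward-pass cap on basis terms including the intercept.
    penalty
        GCV cost per knot; defaults to 3 when interactions are enabled,
        2 otherwise.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 predictors=("origin_MAT", "origin_MAP", "origin_ADD",
                             "origin_summer_smi"),
                 max_degree: int = 2, max_terms: int = 21,
                 penalty: float | None = None):
        predictors = [p for p in predictors if p in data.columns]
        if not predictors:
            raise ValueError("no predictor columns found")
        df = data.dropna(subset=[response, *predictors])
        if len(df) < 10:
            raise ValueError("need >= 10 provenances for the clinal fit")
        self.y = df[response].to_numpy(dtype=float)
        self.X = df[predictors].astype(float).reset_index(drop=True)
        self.response = response
        self.predictors = list(predictors)
        self.max_degree = max_degree
        self.max_terms = max_terms
        self.penalty = penalty if penalty is not None else (
            3.0 if max_degree > 1 else 2.0
        )
        self._mu = self.X.mean()
        self._sd = self.X.std().replace(0.0, 1.0)

    # ------------------------------------------------------------------

    def _design(self, terms, X=None) -> np.ndarray:
        X = self.X if X is None else X
        return np.column_stack([t.evaluate(X) for t in terms])

    @staticmethod
    def _rss(B: np.ndarray, y: np.ndarray):
        coef, res, rank, _ = np.linalg.lstsq(B, y, rcond=None)
        if rank < B.shape[1]:
            return np.inf, coef
        rss = float(np.sum((y - B @ coef) ** 2))
        return rss, coef

    def _forward(self):
        y = self.y
        n = len(y)
        terms = [BasisTerm()]
        B = self._design(terms)
        rss, _ = self._rss(B, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return terms
        while len(terms) + 2 <= self.max_terms:
            best = None
            for parent in terms:
                if parent.degree >= self.max_degree:
                    continue
                parent_col = parent.evaluate(self.X)
                active = parent_col > 0
                if active.sum() < 4:
                    continue
                for var in self.predictors:
                    if parent.involves(var):
                        continue
                    xv = self.X[var].to_numpy(dtype=float)
                    knots = np.unique(xv[active])
                    if len(knots) > 2:
                        knots = knots[1:-1]  # endpoint hinges are degenerate
                    for k in knots:
                        t_pos = BasisTerm(parent.factors + (HingeFactor(var, float(k), +1),))
                        t_neg = BasisTerm(parent.factors + (HingeFactor(var, float(k), -1),))
                        Bc = np.column_stack(
                            [B, t_pos.evaluate(self.X), t_neg.evaluate(self.X)]
                        )
                        rss_c, _ = self._rss(Bc, y)
                        if np.isfinite(rss_c) and (best is None or rss_c < best[0]):
                            best = (rss_c, t_pos, t_neg)
            if best is None or best[0] >= rss * (1.0 - 1e-10):
                break
            rss = best[0]
            terms += [best[1], best[2]]
            B = self._design(terms)
            if rss <= 1e-12 * tss:
                break
        return terms

    def _backward(self, terms):
        y = self.y
        n = len(y)
        B = self._design(terms)
        rss, _ = self._rss(B, y)
        best_terms = list(terms)
        best_gcv = _gcv(rss, n, len(terms), self.penalty)
        forward_gcv = best_gcv
        current = list(terms)
        while len(current) > 1:
            candidates = []
            for i in range(1, len(current)):  # never drop the intercept
                sub = current[:i] + current[i + 1:]
                rss_s, _ = self._rss(self._design(sub), y)
                candidates.append((_gcv(rss_s, n, len(sub), self.penalty), sub))
            g, sub = min(candidates, key=lambda t: t[0])
            current = sub
            if g < best_gcv:
                best_gcv, best_terms = g, list(sub)
        return best_terms, best_gcv, forward_gcv

    def fit(self) -> "MarsResults":
        # work on standardized predictors; map knots back afterwards
        Xs = (self.X - self._mu) / self._sd
        orig_X = self.X
        self.X = Xs
        try:
            fwd = self._forward()
            terms, gcv_sel, gcv_fwd = self._backward(fwd)
            B = self._design(terms)
            rss, coef = self._rss(B, self.y)
            rss_fwd, _ = self._rss(self._design(fwd), self.y)
        finally:
            self.X = orig_X
        # translate knots to original units
        def to_orig(t: BasisTerm) -> BasisTerm:
            facs = tuple(
                HingeFactor(
                    f.var,
                    float(f.knot * self._sd[f.var] + self._mu[f.var]),
                    f.sign,
                )
                for f in t.factors
            )
            return BasisTerm(facs)

        terms_o = [to_orig(t) for t in terms]
        # rescale coefficients so predictions on original units match
        scale = np.array([
            np.prod([1.0 / self._sd[f.var] for f in t.factors]) if t.factors else 1.0
            for t in terms
        ])
        coef_o = coef * scale
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        r2_fwd = 1.0 - rss_fwd / tss if tss > 0 else 0.0
        return MarsResults(
            model=self, terms=terms_o, coef=np.asarray(coef_o),
            rss=rss, r2=r2, gcv=gcv_sel, gcv_forward=gcv_fwd,
            r2_forward=r2_fwd,
        )


@dataclass
class MarsResults:
    """Selected hinge-basis model with GCV bookkeeping."""

    model: MarsRegression
    terms: list
    coef: np.ndarray
    rss: float
    r2: float
    gcv: float
    gcv_forward: float
    r2_forward: float

    @property
    def knots(self) -> list[tuple[str, float]]:
        return [
            (f.var, f.knot) for t in self.terms for f in t.factors
        ]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        B = np.column_stack([t.evaluate(X) for t in self.terms])
        return B @ self.coef

    @property
    def fitted(self) -> np.ndarray:
        return self.predict(self.model.X)

    def summary(self) -> dict:
        return {
            "response": self.model.response,
            "n": len(self.model.y),
            "terms": [t.label() for t in self.terms],
            "coefficients": self.coef.tolist(),
            "knots": self.knots,
            "r2": self.r2,
            "gcv": self.gcv,
            "gcv_forward": self.gcv_forward,
        }

    def response_surface(self, var1: str, var2: str, n_grid: int = 25,
                         others: str = "mean",
                         limits: dict | None = None) -> pd.DataFrame:
        """Predictions on a var1 x var2 grid (others fixed at their mean).

        `limits` optionally overrides the grid range per variable as
        (lo, hi); by default the observed range is used.  Grid cells
        outside the convex hull of the observed (var1, var2) points are
        flagged as extrapolation; a grid fully outside the data raises.
        """
        from scipy.spatial import Delaunay

        X = self.model.X
        limits = limits or {}
        lo1, hi1 = limits.get(var1, (X[var1].min(), X[var1].max()))
        lo2, hi2 = limits.get(var2, (X[var2].min(), X[var2].max()))
        g1 = np.linspace(lo1, hi1, n_grid)
        g2 = np.linspace(lo2, hi2, n_grid)
        G1, G2 = np.meshgrid(g1, g2)
        grid = pd.DataFrame({var1: G1.ravel(), var2: G2.ravel()})
        for c in self.model.predictors:
            if c not in (var1, var2):
                grid[c] = X[c].mean() if others == "mean" else X[c].median()
        pts = X[[var1, var2]].to_numpy()
        try:
            hull = Delaunay(pts)
            inside = hull.find_simplex(grid[[var1, var2]].to_numpy()) >= 0
        except Exception:  # degenerate (collinear) point sets
            inside = np.ones(len(grid), dtype=bool)
        if not inside.any():
            raise ValueError("grid lies entirely outside the observed data")
        grid["prediction"] = self.predict(grid)
        grid["extrapolated"] = ~inside
        return grid


def mars_fit(data: pd.DataFrame, response: str, **kwargs) -> MarsResults:
    """Convenience wrapper around :class:`MarsRegression`."""
    return MarsRegression(data, response, **kwargs).fit()
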