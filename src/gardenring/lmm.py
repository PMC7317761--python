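"""REML estimation of hierarchical mixed models for provenance trials.

The models fitted here have the half-sib common-garden structure: fixed
block / year / tree-size effects, random provenance, family-within-
provenance, their interactions with year, and the plot (family-by-block)
error term, with a residual that may be independent, AR(1) or
heterogeneous AR(1) (ARH1: year-specific variances, correlation
rho^|lag|) across the repeated annual measurements within a tree.

Estimation maximizes the restricted likelihood through the sparse
mixed-model-equations identity

    -2 l_R = (n - p) log 2pi + log|R| + log|G| + log|C| + y' P y

where C is the MME coefficient matrix.  Variances are optimized on the
log scale (rho through atanh), which keeps every iterate inside the
parameter space; the asymptotic covariance of the variance estimates is
the inverse observed information, obtained by finite differences at the
optimum.

The public surface is statsmodels-like: build a
:class:`ProvenanceTrialLMM` from a dataframe and a :class:`ModelSpec`,
call :meth:`~ProvenanceTrialLMM.fit`, and read estimates, standard
errors and the summary table off the returned :class:`LMMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import chi2

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    fixed/random terms are column names, with ``a:b`` denoting the
    combined factor of two (or more) columns.  Float columns enter the
    fixed part as linear covariates; everything else is categorical.
    ``residual`` is one of ``iid``, ``ar1``, ``arh1``; the latter two
    need ``subject`` (tree) and ``time`` (year) columns with contiguous
    years per tree.  ``het_random`` maps a random term to a column whose
    levels get separate variances (e.g. the plot term nested in year).
    """

    response: str
    fixed: list = field(default_factory=list)
    random: list = field(default_factory=list)
    residual: str = "iid"
    subject: str | None = None
    time: str | None = None
    het_random: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.residual not in ("iid", "ar1", "arh1"):
            raise ValueError(f"unknown residual structure {self.residual!r}")
        if self.residual in ("ar1", "arh1") and not (self.subject and self.time):
            raise ValueError("ar1/arh1 residuals need subject and time columns")


def _combined_factor(data: pd.DataFrame, term: str) -> pd.Series:
    cols = term.split(":")
    for c in cols:
        if c not in data.columns:
            raise ValueError(f"term {term!r}: column {c!r} not in data")
    if len(cols) == 1:
        return data[cols[0]].astype(str)
    out = data[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + "/" + data[c].astype(str)
    return out


def _is_numeric_covariate(data: pd.DataFrame, term: str) -> bool:
    return (
        ":" not in term
        and term in data.columns
        and pd.api.types.is_float_dtype(data[term])
    )


def build_fixed_matrix(data: pd.DataFrame, fixed: list) -> tuple[np.ndarray, list]:
    """Intercept + covariates + treatment-coded factors, pruned to full rank."""
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in fixed:
        if _is_numeric_covariate(data, term):
            cols.append(data[term].to_numpy(dtype=float))
            names.append(term)
        else:
            fac = _combined_factor(data, term)
            dummies = pd.get_dummies(fac, prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
    X = np.column_stack(cols)
    # prune linearly dependent columns (e.g. year main effect inside
    # block-nested-in-year dummies)
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


def _random_design(data: pd.DataFrame, term: str) -> tuple[sp.csr_matrix, list]:
    fac = _combined_factor(data, term)
    levels, codes = np.unique(fac, return_inverse=True)
    Z = sp.csr_matrix(
        (np.ones(len(fac)), (np.arange(len(fac)), codes)),
        shape=(len(fac), len(levels)),
    )
    return Z, list(levels)


class ProvenanceTrialLMM:
    """Gaussian linear mixed model for a common-garden provenance trial."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        used = {spec.response}
        for t in list(spec.fixed) + list(spec.random):
            used |= set(t.split(":"))
        if spec.subject:
            used.add(spec.subject)
        if spec.time:
            used.add(spec.time)
        missing = used - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns {sorted(missing)}")
        data = data.dropna(subset=sorted(used)).copy()
        if spec.subject and spec.time:
            data = data.sort_values([spec.subject, spec.time])
            for subj, grp in data.groupby(spec.subject, sort=False):
                t = grp[spec.time].to_numpy()
                if len(t) != len(set(t)):
                    raise ValueError(f"subject {subj!r} has duplicate times")
                if spec.residual in ("ar1", "arh1") and np.any(np.diff(t) != 1):
                    raise ValueError(
                        f"subject {subj!r} has non-contiguous years; "
                        "exclude gapped series before fitting"
                    )
        self.data = data.reset_index(drop=True)
        self._build()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **spec_kwargs):
        return cls(data, ModelSpec(**spec_kwargs))

    # ------------------------------------------------------------------

    def _build(self):
        spec, data = self.spec, self.data
        self.y = data[spec.response].to_numpy(dtype=float)
        self.n = len(self.y)
        self.X, self.fixed_names = build_fixed_matrix(data, spec.fixed)
        self.p = self.X.shape[1]

        self.Z_blocks, self.term_levels = [], {}
        self.term_slices = {}
        offset = 0
        for term in spec.random:
            Z, levels = _random_design(data, term)
            self.Z_blocks.append(Z)
            self.term_levels[term] = levels
            self.term_slices[term] = slice(offset, offset + len(levels))
            offset += len(levels)
        self.q = offset

        # variance-parameter layout: one sigma^2 per random term, or per
        # het group for terms in het_random; then residual parameters
        self.vparam_names: list[str] = []
        self._level_group = np.zeros(self.q, dtype=int)
        gidx = 0
        for term in spec.random:
            sl = self.term_slices[term]
            if term in spec.het_random:
                bycol = spec.het_random[term]
                cols = term.split(":")
                if bycol not in cols:
                    raise ValueError(
                        f"het_random column {bycol!r} must be part of term {term!r}"
                    )
                pos = cols.index(bycol)
                groups = [lev.split("/")[pos] for lev in self.term_levels[term]]
                uniq = list(dict.fromkeys(sorted(set(groups))))
                for g in uniq:
                    self.vparam_names.append(f"sigma2_{term}[{bycol}={g}]")
                gmap = {g: gidx + i for i, g in enumerate(uniq)}
                self._level_group[sl] = [gmap[g] for g in groups]
                gidx += len(uniq)
            else:
                self.vparam_names.append(f"sigma2_{term}")
                self._level_group[sl] = gidx
                gidx += 1
        self.n_g_params = gidx

        if spec.residual == "arh1":
            self._res_years = np.sort(data[spec.time].unique())
            self.vparam_names += [f"sigma2_e[{y}]" for y in self._res_years]
            self.vparam_names.append("rho")
        elif spec.residual == "ar1":
            self.vparam_names += ["sigma2_e", "rho"]
        else:
            self.vparam_names.append("sigma2_e")

        self._precompute_grams()

    def _row_classes(self):
        """interior/singleton flags and within-subject adjacency pairs."""
        n = self.n
        interior = np.zeros(n, dtype=bool)
        singleton = np.ones(n, dtype=bool)
        pair_a: list[int] = []
        if self.spec.subject and self.spec.time:
            subj = self.data[self.spec.subject].to_numpy()
            starts = np.r_[0, np.nonzero(subj[1:] != subj[:-1])[0] + 1, n]
            for s, e in zip(starts[:-1], starts[1:]):
                m = e - s
                if m > 1:
                    singleton[s:e] = False
                    interior[s + 1 : e - 1] = True
                    pair_a.extend(range(s, e - 1))
        return interior, singleton, np.asarray(pair_a, dtype=int)

    def _precompute_grams(self):
        """Gram matrices of W = [X | Z | y] under the AR(1)-inverse pieces.

        The tridiagonal inverse correlation of a contiguous AR(1) block is
        T/(1-rho^2) with T = I + rho^2*Interior - rho^2*Singleton
        - rho*Adjacency, so W'R^{-1}W is a cheap weighted sum of fixed
        sparse Grams at each optimizer step.  For ARH1 the Grams are kept
        split by year so the per-year scalings can be applied.
        """
        W = sp.hstack(
            [sp.csr_matrix(self.X)] + self.Z_blocks
            + [sp.csr_matrix(self.y[:, None])]
        ).tocsr()
        self._W = W
        interior, singleton, pair_a = self._row_classes()
        split_years = self.spec.residual == "arh1"
        year = (
            self.data[self.spec.time].to_numpy()
            if self.spec.time
            else np.zeros(self.n, dtype=int)
        )

        def gram(mask):
            Wm = W[mask]
            return (Wm.T @ Wm).tocsr()

        if split_years:
            self._g_all, self._g_int, self._g_sing = {}, {}, {}
            self._n_year = {}
            for yv in self._res_years:
                mask = year == yv
                self._n_year[yv] = int(mask.sum())
                self._g_all[yv] = gram(mask)
                self._g_int[yv] = gram(mask & interior)
                self._g_sing[yv] = gram(mask & singleton)
            self._g_adj = {}
            if pair_a.size:
                ya = year[pair_a]
                for yv in np.unique(ya):
                    sel = pair_a[ya == yv]
                    A, B = W[sel], W[sel + 1]
                    M = (A.T @ B).tocsr()
                    self._g_adj[(yv, yv + 1)] = (M + M.T).tocsr()
        else:
            self._g_all = gram(np.ones(self.n, dtype=bool))
            self._g_int = gram(interior)
            self._g_sing = gram(singleton)
            if pair_a.size:
                A, B = W[pair_a], W[pair_a + 1]
                M = (A.T @ B).tocsr()
                self._g_adj = (M + M.T).tocsr()
            else:
                self._g_adj = sp.csr_matrix(self._g_all.shape)
        n_subj = (
            self.data[self.spec.subject].nunique() if self.spec.subject else self.n
        )
        self._n_blocks = n_subj
        self._year_counts = {
            yv: int((year == yv).sum()) for yv in np.unique(year)
        }

    # ------------------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        k = self.n_g_params
        g_sigma2 = np.exp(theta[:k])
        rest = theta[k:]
        if self.spec.residual == "arh1":
            ny = len(self._res_years)
            res_sigma2 = np.exp(rest[:ny])
            rho = np.tanh(rest[ny])
        elif self.spec.residual == "ar1":
            res_sigma2 = np.exp(rest[0])
            rho = np.tanh(rest[1])
        else:
            res_sigma2 = np.exp(rest[0])
            rho = 0.0
        return g_sigma2, res_sigma2, rho

    def _whole_gram_and_logdetR(self, res_sigma2, rho):
        spec = self.spec
        if spec.residual == "iid":
            S = self._g_all / res_sigma2
            logdetR = self.n * np.log(res_sigma2)
        elif spec.residual == "ar1":
            T = (
                self._g_all
                + rho**2 * self._g_int
                - rho**2 * self._g_sing
                - rho * self._g_adj
            )
            S = T / (res_sigma2 * (1.0 - rho**2))
            logdetR = self.n * np.log(res_sigma2) + (
                self.n - self._n_blocks
            ) * np.log(1.0 - rho**2)
        else:  # arh1
            inv_s = {
                yv: 1.0 / res_sigma2[i] for i, yv in enumerate(self._res_years)
            }
            S = None
            for yv in self._res_years:
                part = (
                    self._g_all[yv]
                    + rho**2 * self._g_int[yv]
                    - rho**2 * self._g_sing[yv]
                ) * inv_s[yv]
                S = part if S is None else S + part
            for (y1, y2), M in self._g_adj.items():
                S = S - rho * np.sqrt(inv_s[y1] * inv_s[y2]) * M
            S = S / (1.0 - rho**2)
            logdetR = sum(
                self._n_year[yv] * np.log(res_sigma2[i])
                for i, yv in enumerate(self._res_years)
            ) + (self.n - self._n_blocks) * np.log(1.0 - rho**2)
        return S, logdetR

    def neg2_reml(self, theta: np.ndarray) -> float:
        g_sigma2, res_sigma2, rho = self._unpack(theta)
        S, logdetR = self._whole_gram_and_logdetR(res_sigma2, rho)
        S = S.tocsc()
        pq = self.p + self.q
        Spq = S[:pq, :pq]
        r = np.asarray(S[:pq, pq].todense()).ravel()
        yRy = S[pq, pq]
        ginv_diag = np.zeros(pq)
        if self.q:
            ginv_diag[self.p :] = 1.0 / g_sigma2[self._level_group]
        C = (Spq + sp.diags(ginv_diag)).tocsc()
        try:
            lu = splu(C)
        except RuntimeError:
            return np.inf
        Udiag = lu.U.diagonal()
        if np.any(Udiag == 0):
            return np.inf
        logdetC = float(np.sum(np.log(np.abs(Udiag))))
        sol = lu.solve(r)
        yPy = float(yRy - r @ sol)
        logdetG = float(
            np.sum(np.log(g_sigma2[self._level_group])) if self.q else 0.0
        )
        return (
            (self.n - self.p) * _LOG2PI + logdetR + logdetG + logdetC + yPy
        )

    # ------------------------------------------------------------------

    def _start_values(self) -> list[np.ndarray]:
        vy = float(np.var(self.y))
        if vy <= 0:
            vy = 1.0
        k_var = len(self.vparam_names) - (
            1 if self.spec.residual in ("ar1", "arh1") else 0
        )
        base = np.log(np.full(k_var, vy / (self.n_g_params + 2.0)))
        starts = []
        for rho0, scale in ((0.3, 1.0), (0.0, 0.25), (0.6, 2.0)):
            th = np.log(np.exp(base) * scale)
            if self.spec.residual in ("ar1", "arh1"):
                th = np.r_[th, np.arctanh(rho0)]
            starts.append(th)
        return starts

    def fit(self, maxiter: int = 400, starts: list | None = None,
            tol: float = 1e-8) -> "LMMResults":
        """Maximize the restricted likelihood (L-BFGS-B on transformed scale).

        Runs from several documented start values and keeps the best
        optimum; raises if none of the runs converges.
        """
        vy = float(np.var(self.y)) or 1.0
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e4)
        bounds = []
        for name in self.vparam_names:
            if name == "rho":
                bounds.append((np.arctanh(-0.98), np.arctanh(0.98)))
            else:
                bounds.append((lo, hi))
        best = None
        n_ok = 0
        for th0 in (starts or self._start_values()):
            th0 = np.clip(th0, [b[0] for b in bounds], [b[1] for b in bounds])
            opt = scipy.optimize.minimize(
                self.neg2_reml, th0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol},
            )
            if np.isfinite(opt.fun):
                n_ok += 1
                if best is None or opt.fun < best.fun - 1e-9:
                    best = opt
        if best is None or n_ok == 0:
            raise RuntimeError("REML optimization failed from every start")
        boundary = [
            self.vparam_names[i]
            for i, (b, v) in enumerate(zip(bounds, best.x))
            if v <= b[0] + 1e-6 and self.vparam_names[i] != "rho"
        ]
        if boundary:
            warnings.warn(
                f"variance estimate(s) at boundary: {boundary}", stacklevel=2
            )
        return LMMResults(self, best.x, -0.5 * float(best.fun),
                          converged=bool(best.success or best.fun < np.inf),
                          boundary_terms=boundary, optimizer=best)

    # exposed for the results object ------------------------------------

    def _solve_effects(self, theta):
        g_sigma2, res_sigma2, rho = self._unpack(theta)
        S, _ = self._whole_gram_and_logdetR(res_sigma2, rho)
        S = S.tocsc()
        pq = self.p + self.q
        Spq = S[:pq, :pq]
        r = np.asarray(S[:pq, pq].todense()).ravel()
        ginv_diag = np.zeros(pq)
        if self.q:
            ginv_diag[self.p :] = 1.0 / g_sigma2[self._level_group]
        C = (Spq + sp.diags(ginv_diag)).tocsc()
        lu = splu(C)
        sol = lu.solve(r)
        eye = np.zeros((pq, self.p))
        eye[: self.p, :] = np.eye(self.p)
        Cinv_p = lu.solve(eye)
        cov_beta = Cinv_p[: self.p, :]
        return sol[: self.p], sol[self.p :], cov_beta


class LMMResults:
    """REML fit: variance components, fixed effects, diagnostics."""

    def __init__(self, model: ProvenanceTrialLMM, theta: np.ndarray,
                 loglik: float, converged: bool, boundary_terms: list,
                 optimizer=None):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.loglik = float(loglik)
        self.converged = converged
        self.boundary_terms = boundary_terms
        self.optimizer = optimizer
        g_sigma2, res_sigma2, rho = model._unpack(self.theta)
        self._natural = self._pack_natural(g_sigma2, res_sigma2, rho)
        beta, u, cov_beta = model._solve_effects(self.theta)
        self.fe_params = pd.Series(beta, index=model.fixed_names)
        self.fe_cov = pd.DataFrame(cov_beta, index=model.fixed_names,
                                   columns=model.fixed_names)
        self.random_effects = u
        self._vc_cov = None

    def _pack_natural(self, g_sigma2, res_sigma2, rho):
        vals = list(g_sigma2)
        if self.model.spec.residual == "arh1":
            vals += list(res_sigma2) + [rho]
        elif self.model.spec.residual == "ar1":
            vals += [res_sigma2, rho]
        else:
            vals += [res_sigma2]
        return pd.Series(vals, index=self.model.vparam_names)

    @property
    def varcomp(self) -> pd.Series:
        """Named variance components (and rho) on the natural scale."""
        return self._natural.copy()

    @property
    def rho(self) -> float:
        return float(self._natural.get("rho", 0.0))

    def residual_sigma2(self, average_years: bool = True) -> float:
        """Residual variance; ARH1 year-specific values averaged if asked."""
        if self.model.spec.residual == "arh1":
            vals = [
                v for k, v in self._natural.items() if k.startswith("sigma2_e[")
            ]
            return float(np.mean(vals)) if average_years else vals
        return float(self._natural["sigma2_e"])

    def term_sigma2(self, term: str, average_groups: bool = True):
        """Variance of one random term; het groups averaged if asked."""
        exact = f"sigma2_{term}"
        if exact in self._natural.index:
            return float(self._natural[exact])
        vals = [
            v for k, v in self._natural.items()
            if k.startswith(f"sigma2_{term}[")
        ]
        if not vals:
            raise KeyError(f"no variance component for term {term!r}")
        return float(np.mean(vals)) if average_groups else vals

    # ------------------------------------------------------------------

    def vc_cov(self, rel_step: float = 1e-3) -> pd.DataFrame:
        """Asymptotic covariance of the variance parameters (natural scale).

        Observed information: numerical Hessian of the negative restricted
        log-likelihood with respect to the natural-scale parameters,
        inverted at the optimum.  Cached after the first call.
        """
        if self._vc_cov is not None:
            return self._vc_cov
        names = self.model.vparam_names
        phi0 = self._natural.to_numpy().copy()

        def f(phi):
            theta = []
            k = self.model.n_g_params
            theta.extend(np.log(np.maximum(phi[:k], 1e-300)))
            if self.model.spec.residual == "arh1":
                ny = len(self.model._res_years)
                theta.extend(np.log(np.maximum(phi[k : k + ny], 1e-300)))
                theta.append(np.arctanh(np.clip(phi[k + ny], -0.99, 0.99)))
            elif self.model.spec.residual == "ar1":
                theta.append(np.log(max(phi[k], 1e-300)))
                theta.append(np.arctanh(np.clip(phi[k + 1], -0.99, 0.99)))
            else:
                theta.append(np.log(max(phi[k], 1e-300)))
            return 0.5 * self.model.neg2_reml(np.asarray(theta))

        d = len(phi0)
        h = np.maximum(np.abs(phi0) * rel_step, 1e-10)
        H = np.zeros((d, d))
        f0 = f(phi0)
        fp = np.zeros(d)
        fm = np.zeros(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h[i]
            fp[i] = f(phi0 + e)
            fm[i] = f(phi0 - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = f(phi0 + ei + ej)
                fmm = f(phi0 - ei - ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        self._vc_cov = pd.DataFrame(cov, index=names, columns=names)
        return self._vc_cov

    # ------------------------------------------------------------------

    def lrt_against(self, reduced: "LMMResults") -> tuple[float, float]:
        """Boundary-corrected REML likelihood-ratio test for one variance.

        The reduced model must drop exactly one random term (same fixed
        part).  p-value from the 0.5*chi2_0 + 0.5*chi2_1 mixture.
        """
        if set(reduced.model.fixed_names) != set(self.model.fixed_names):
            raise ValueError("LRT requires identical fixed effects")
        diff = set(self.model.spec.random) - set(reduced.model.spec.random)
        if len(diff) != 1 or set(reduced.model.spec.random) - set(
            self.model.spec.random
        ):
            raise ValueError("models must differ by exactly one random term")
        lr = 2.0 * (self.loglik - reduced.loglik)
        if lr <= 0:
            return max(lr, 0.0), 1.0
        return lr, 0.5 * float(chi2.sf(lr, df=1))

    def summary(self) -> str:
        lines = [
            "Provenance-trial mixed model (REML)",
            f"  observations: {self.model.n}   fixed params: {self.model.p}"
            f"   random levels: {self.model.q}",
            f"  residual structure: {self.model.spec.residual}",
            f"  REML log-likelihood: {self.loglik:.4f}"
            f"   converged: {self.converged}",
            "",
            "Variance components:",
        ]
        for k, v in self._natural.items():
            flag = "  (boundary)" if k in self.boundary_terms else ""
            lines.append(f"  {k:<34s} {v:>12.6g}{flag}")
        lines.append("")
        lines.append("Fixed effects (first 12):")
        se = np.sqrt(np.diag(self.fe_cov))
        for name, b, s in list(zip(self.fe_params.index, self.fe_params, se))[:12]:
            lines.append(f"  {name:<28s} {b:>12.5g}  (SE {s:.3g})")
        return "\n".join(lines)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, **fit_kwargs) -> LMMResults:
    """Convenience wrapper: build the model and fit it."""
    return ProvenanceTrialLMM(data, spec).fit(**fit_kwargs)


def lrt_random(data: pd.DataFrame, spec: ModelSpec, term: str,
               **fit_kwargs) -> dict:
    """Significance of one random term by boundary-mixture REML LRT."""
    if term not in spec.random:
        raise ValueError(f"{term!r} is not a random term of the model")
    full = fit_lmm(data, spec, **fit_kwargs)
    reduced_spec = ModelSpec(
        response=spec.response, fixed=list(spec.fixed),
        random=[t for t in spec.random if t != term],
        residual=spec.residual, subject=spec.subject, time=spec.time,
        het_random={k: v for k, v in spec.het_random.items() if k != term},
    )
    reduced = fit_lmm(data, reduced_spec, **fit_kwargs)
    lr, p = full.lrt_against(reduced)
    return {"term": term, "lr": lr, "p": p,
            "loglik_full": full.loglik, "loglik_reduced": reduced.loglik}
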