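"""Quantitative-genetic estimators: heritability, Q_ST, G-matrix, F_ST.

Heritability and Q_ST are ratio estimators on REML variance components
from the half-sib provenance-trial models.  With within-family
relatedness r, the additive variance is sigma2_A = sigma2_fam / r, so

    h2   = (1/r) * sigma2_fam / sigma2_p
    Q_ST = sigma2_pop / (sigma2_pop + 2 * sigma2_fam / r)

where sigma2_p = sigma2_fam + sigma2_fam:year + sigma2_plot + sigma2_e
(year-specific plot and residual variances averaged across years).
Standard errors come from the delta method on the component covariance;
95% CIs are estimate +/- 1.96*SE.

The marker side provides the VanRaden genomic relationship matrix (used
to estimate realized within-family relatedness r) and Weir–Cockerham /
Nei estimators of among-provenance differentiation F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .lmm import LMMResults, ModelSpec


@dataclass
class RatioEstimate:
    """Point estimate with delta-method SE and symmetric 95% CI."""

    estimate: float
    se: float | None = None

    @property
    def ci(self) -> tuple[float, float] | None:
        if self.se is None or not np.isfinite(self.se):
            return None
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    def __repr__(self) -> str:
        if self.ci is None:
            return f"{self.estimate:.4g}"
        lo, hi = self.ci
        return f"{self.estimate:.4g} (95% CI {lo:.4g}, {hi:.4g})"


# ---------------------------------------------------------------------------
# h2 and Q_ST from named components


def heritability_from_components(sigma2_fam: float, sigma2_p: float,
                                 r: float) -> float:
    """Individual narrow-sense h2 = (1/r) * sigma2_fam / sigma2_p."""
    if not (0 < r <= 0.5):
        raise ValueError("relatedness r must be in (0, 0.5]")
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return (sigma2_fam / r) / sigma2_p


def qst_from_components(sigma2_pop: float, sigma2_fam: float,
                        r: float) -> float:
    """Q_ST = sigma2_pop / (sigma2_pop + 2 * sigma2_fam / r).

    The additive variance enters as sigma2_A = sigma2_fam / r so that a
    purely neutral trait with sigma2_pop = 2*sigma2_A gives Q_ST = 0.5.
    """
    if r <= 0:
        raise ValueError("relatedness r must be positive")
    denom = sigma2_pop + 2.0 * sigma2_fam / r
    if denom == 0:
        raise ValueError("Q_ST undefined: both components are zero")
    return sigma2_pop / denom


def _delta_se(grad: np.ndarray, cov: np.ndarray) -> float:
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritability(res: LMMResults, r: float,
                 fam_term: str = "family",
                 pheno_terms: tuple = ("family", "family:year"),
                 plot_term: str | None = None,
                 with_se: bool = True) -> RatioEstimate:
    """h2 from a fitted model's components (delta-method SE).

    ``pheno_terms`` lists the random terms entering sigma2_p besides the
    plot term and the residual; year-specific variances are averaged.
    """
    vc = res.varcomp
    names = list(res.model.vparam_names)

    def term_weights(term):
        """weight vector over vparams realizing the (possibly averaged) term"""
        w = np.zeros(len(names))
        exact = f"sigma2_{term}"
        if exact in names:
            w[names.index(exact)] = 1.0
            return w
        idxs = [i for i, k in enumerate(names) if k.startswith(f"sigma2_{term}[")]
        if not idxs:
            return None
        for i in idxs:
            w[i] = 1.0 / len(idxs)
        return w

    w_fam = term_weights(fam_term)
    if w_fam is None:
        raise KeyError(f"model has no random term {fam_term!r}")
    w_p = np.zeros(len(names))
    for t in pheno_terms:
        wt = term_weights(t)
        if wt is not None:
            w_p += wt
    if plot_term:
        wt = term_weights(plot_term)
        if wt is None:
            raise KeyError(f"model has no random term {plot_term!r}")
        w_p += wt
    # residual (averaged over years for ARH1)
    e_idx = [i for i, k in enumerate(names)
             if k == "sigma2_e" or k.startswith("sigma2_e[")]
    for i in e_idx:
        w_p[i] += 1.0 / len(e_idx)

    phi = vc.to_numpy()
    s_fam = float(w_fam @ phi)
    s_p = float(w_p @ phi)
    h2 = heritability_from_components(s_fam, s_p, r)
    se = None
    if with_se:
        cov = res.vc_cov().to_numpy()
        # d h2 / d phi = (1/r) * (w_fam * s_p - s_fam * w_p) / s_p^2
        grad = (w_fam * s_p - s_fam * w_p) / (r * s_p**2)
        se = _delta_se(grad, cov)
    return RatioEstimate(h2, se)


def qst(res: LMMResults, r: float, pop_term: str = "provenance",
        fam_term: str = "family", with_se: bool = True) -> RatioEstimate:
    """Q_ST from a fitted model's components (delta-method SE)."""
    vc = res.varcomp
    names = list(res.model.vparam_names)
    try:
        i_pop = names.index(f"sigma2_{pop_term}")
        i_fam = names.index(f"sigma2_{fam_term}")
    except ValueError as exc:
        raise KeyError(f"model lacks term: {exc}") from None
    s_pop, s_fam = float(vc.iloc[i_pop]), float(vc.iloc[i_fam])
    q = qst_from_components(s_pop, s_fam, r)
    se = None
    if with_se:
        cov = res.vc_cov().to_numpy()
        denom = s_pop + 2.0 * s_fam / r
        grad = np.zeros(len(names))
        grad[i_pop] = (denom - s_pop) / denom**2
        grad[i_fam] = -s_pop * (2.0 / r) / denom**2
        se = _delta_se(grad, cov)
    return RatioEstimate(q, se)


# ---------------------------------------------------------------------------
# Canonical model specifications


def drought_model_spec(response: str,
                       tree_size: str = "tree_size") -> ModelSpec:
    """Single-year model for drought-resilience traits.

    Fixed block + tree size; random provenance, family(provenance),
    family-by-block plot term; independent residual.
    """
    return ModelSpec(
        response=response,
        fixed=["block", tree_size],
        random=["provenance", "family", "family:block"],
        residual="iid",
    )


def repeated_model_spec(response: str, residual: str = "arh1",
                        plot_term: bool = True,
                        het_plot: bool = False) -> ModelSpec:
    """Repeated-measures model for annual ring traits.

    Fixed year and block-nested-in-year; random provenance,
    family(provenance), their year interactions and (optionally) the
    plot-by-year term; AR1/ARH1 residual across years within tree.
    """
    random = ["provenance", "family", "provenance:year", "family:year"]
    het = {}
    if plot_term:
        random.append("family:block:year")
        if het_plot:
            het["family:block:year"] = "year"
    return ModelSpec(
        response=response,
        fixed=["year", "block:year"],
        random=random,
        residual=residual,
        subject="tree",
        time="year",
        het_random=het,
    )


# ---------------------------------------------------------------------------
# Genomic relationship matrix (VanRaden method 1)


def gmatrix(gm: GenotypeMatrix, min_maf: float = 0.0) -> pd.DataFrame:
    """Realized genomic relationship matrix, VanRaden method 1.

    G = W W' / (2 * sum_k p_k (1 - p_k)) with W = M - 2p and missing
    genotypes mean-imputed per SNP.  Monomorphic SNPs carry no
    information and are dropped; an all-monomorphic panel raises.
    """
    if gm.n_snps < 100:
        raise ValueError("need >= 100 SNPs for a stable G-matrix")
    M = gm.counts.copy()
    p = np.nanmean(M, axis=0) / 2.0
    poly = (p > min_maf) & (p < 1 - min_maf) & (p * (1 - p) > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; G-matrix undefined")
    M = M[:, poly]
    p = p[poly]
    inds = np.where(np.isnan(M))
    M[inds] = (2.0 * p)[inds[1]]
    W = M - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    return pd.DataFrame(G, index=gm.trees, columns=gm.trees)


def avg_within_family(G: pd.DataFrame, family: pd.Series) -> float:
    """Mean off-diagonal relationship over within-family pairs (r-hat)."""
    fam = family.reindex(G.index)
    vals = []
    for f, idx in fam.groupby(fam).groups.items():
        ids = list(idx)
        if len(ids) < 2:
            continue
        sub = G.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        vals.append(sub[iu])
    if not vals:
        raise ValueError("no family with >= 2 genotyped trees")
    return float(np.concatenate(vals).mean())


# ---------------------------------------------------------------------------
# F_ST


def fst_weir_cockerham(gm: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Weir–Cockerham theta per SNP and the overall ratio-of-sums estimate.

    Diploid two-level estimator (individuals within provenances); SNPs
    monomorphic overall get NaN and are excluded from the overall sums.
    """
    if gm.provenance is None:
        raise ValueError("genotypes carry no provenance labels")
    pops = pd.Series(np.asarray(gm.provenance), index=gm.trees)
    labels = pops.unique()
    if len(labels) < 2:
        raise ValueError("need >= 2 provenances")
    counts = gm.counts
    a_l, b_l, c_l = [], [], []
    for lab in labels:
        rows = counts[(pops == lab).to_numpy()]
        n_i = np.sum(~np.isnan(rows), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nanmean(rows, axis=0) / 2.0
            h_i = np.nanmean(rows == 1, axis=0)
        a_l.append((n_i, p_i, h_i))
    n_mat = np.vstack([x[0] for x in a_l])
    p_mat = np.vstack([x[1] for x in a_l])
    h_mat = np.vstack([x[2] for x in a_l])
    valid = n_mat >= 2
    r_eff = valid.sum(axis=0).astype(float)
    n_mat = np.where(valid, n_mat, 0.0)
    p_mat = np.where(valid, p_mat, 0.0)
    h_mat = np.where(valid, h_mat, 0.0)
    nsum = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r_eff
        nc = (nsum - (n_mat**2).sum(axis=0) / nsum) / (r_eff - 1.0)
        pbar = (n_mat * p_mat).sum(axis=0) / nsum
        s2 = (n_mat * (p_mat - pbar) ** 2).sum(axis=0) / ((r_eff - 1.0) * nbar)
        hbar = (n_mat * h_mat).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r_eff - 1.0) / r_eff) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    mono = (pbar <= 0) | (pbar >= 1)
    theta = np.where(mono, np.nan, theta)
    per_snp = pd.Series(theta, index=gm.snps, name="theta_wc")
    keep = ~mono & np.isfinite(a + b + c)
    overall = float(np.sum(a[keep]) / np.sum((a + b + c)[keep]))
    return per_snp, overall


def fst_nei(gm: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Nei-style G_ST per SNP ((H_T - H_S)/H_T, unweighted provenance means)."""
    if gm.provenance is None:
        raise ValueError("genotypes carry no provenance labels")
    pops = pd.Series(np.asarray(gm.provenance), index=gm.trees)
    p_mat = np.vstack([
        np.nanmean(gm.counts[(pops == lab).to_numpy()], axis=0) / 2.0
        for lab in pops.unique()
    ])
    hs = np.mean(2.0 * p_mat * (1.0 - p_mat), axis=0)
    pbar = p_mat.mean(axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = (ht - hs) / ht
    mono = ht <= 0
    gst = np.where(mono, np.nan, gst)
    keep = ~mono
    overall = float(np.sum((ht - hs)[keep]) / np.sum(ht[keep]))
    return pd.Series(gst, index=gm.snps, name="gst_nei"), overall
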