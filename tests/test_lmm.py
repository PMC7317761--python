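"""REML engine: oracle equivalence, structure identities, LRT behaviour."""

import numpy as np
import pandas as pd
import pytest

from gardenring.lmm import ModelSpec, ProvenanceTrialLMM, fit_lmm, lrt_random

from conftest import balanced_oneway


def _tiny_repeated(seed=0, n_prov=3, n_fam=2, n_blocks=2, ny=4):
    rng = np.random.default_rng(seed)
    rows, tid = [], 0
    for p in range(n_prov):
        for f in range(n_fam):
            for b in range(n_blocks):
                tid += 1
                for t in range(ny):
                    rows.append((f"T{tid}", f"P{p}", f"F{p}{f}", b,
                                 2000 + t, rng.normal()))
    return pd.DataFrame(rows, columns=["tree", "provenance", "family",
                                       "block", "year", "y"])


class TestRemlOracles:
    def test_balanced_oneway_matches_anova(self):
        df, s_a, s_e = balanced_oneway(seed=1)
        res = fit_lmm(df, ModelSpec(response="y", random=["g"]))
        assert res.varcomp["sigma2_g"] == pytest.approx(s_a, abs=1e-4)
        assert res.varcomp["sigma2_e"] == pytest.approx(s_e, abs=1e-4)

    @pytest.mark.parametrize("residual", ["iid", "ar1", "arh1"])
    def test_sparse_likelihood_equals_dense_gls(self, residual):
        """The sparse MME identity must reproduce the brute-force REML
        log-likelihood computed from the dense marginal covariance."""
        df = _tiny_repeated(seed=0)
        spec = ModelSpec(response="y", fixed=["year"],
                         random=["provenance", "family"],
                         residual=residual, subject="tree", time="year")
        m = ProvenanceTrialLMM(df, spec)
        rng = np.random.default_rng(42)
        theta = rng.normal(-0.3, 0.3, size=len(m.vparam_names))
        if residual != "iid":
            theta[-1] = np.arctanh(0.4)
        g_s2, r_s2, rho = m._unpack(theta)

        n, y, X = m.n, m.y, m.X
        Z = np.hstack([z.toarray() for z in m.Z_blocks])
        Gd = np.diag(g_s2[m._level_group])
        years = m.data["year"].to_numpy()
        subj = m.data["tree"].to_numpy()
        yr_list = np.sort(df["year"].unique())
        R = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if subj[i] != subj[j]:
                    continue
                lag = abs(years[i] - years[j])
                if residual == "iid":
                    R[i, j] = r_s2 if i == j else 0.0
                elif residual == "ar1":
                    R[i, j] = r_s2 * rho**lag
                else:
                    si = np.sqrt(r_s2[np.flatnonzero(yr_list == years[i])[0]])
                    sj = np.sqrt(r_s2[np.flatnonzero(yr_list == years[j])[0]])
                    R[i, j] = si * sj * rho**lag
        V = R + Z @ Gd @ Z.T
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        _, ld_V = np.linalg.slogdet(V)
        _, ld_X = np.linalg.slogdet(XtViX)
        dense = ((n - X.shape[1]) * np.log(2 * np.pi) + ld_V + ld_X
                 + resid @ Vi @ resid)
        assert m.neg2_reml(theta) == pytest.approx(dense, rel=1e-10)

    def test_all_zero_response_gives_zero_variances(self):
        df, _, _ = balanced_oneway(seed=2, k=10, n=5)
        df["y"] = 0.0
        res = fit_lmm(df, ModelSpec(response="y", random=["g"]))
        assert res.varcomp["sigma2_g"] < 1e-6
        assert res.varcomp["sigma2_e"] < 1e-6

    def test_rescaling_response_scales_variances(self):
        df, _, _ = balanced_oneway(seed=3, k=20, n=6)
        spec = ModelSpec(response="y", random=["g"])
        r1 = fit_lmm(df, spec)
        r2 = fit_lmm(df.assign(y=df["y"] * 10), spec)
        assert r2.varcomp["sigma2_g"] == pytest.approx(
            100 * r1.varcomp["sigma2_g"], rel=1e-3)
        assert r2.varcomp["sigma2_e"] == pytest.approx(
            100 * r1.varcomp["sigma2_e"], rel=1e-3)


class TestStructure:
    def test_noncontiguous_years_rejected(self):
        df = _tiny_repeated()
        df = df[~((df.tree == "T1") & (df.year == 2001))]
        spec = ModelSpec(response="y", fixed=["year"], random=["provenance"],
                         residual="ar1", subject="tree", time="year")
        with pytest.raises(ValueError, match="non-contiguous"):
            ProvenanceTrialLMM(df, spec)

    def test_duplicate_times_rejected(self):
        df = _tiny_repeated()
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        spec = ModelSpec(response="y", fixed=["year"], random=["provenance"],
                         residual="ar1", subject="tree", time="year")
        with pytest.raises(ValueError, match="duplicate times"):
            ProvenanceTrialLMM(df, spec)

    def test_collinear_fixed_terms_pruned(self):
        df = _tiny_repeated()
        spec = ModelSpec(response="y", fixed=["year", "block:year"],
                         random=["provenance"], residual="ar1",
                         subject="tree", time="year")
        m = ProvenanceTrialLMM(df, spec)
        X = m.X
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_het_random_term_per_year_variances(self):
        df = _tiny_repeated(seed=5)
        spec = ModelSpec(response="y", fixed=["year"],
                         random=["provenance", "family:block:year"],
                         residual="iid", subject="tree", time="year",
                         het_random={"family:block:year": "year"})
        m = ProvenanceTrialLMM(df, spec)
        per_year = [n for n in m.vparam_names
                    if n.startswith("sigma2_family:block:year[")]
        assert len(per_year) == 4

    def test_summary_mentions_structure(self):
        df, _, _ = balanced_oneway(seed=4, k=10, n=4)
        res = fit_lmm(df, ModelSpec(response="y", random=["g"]))
        s = res.summary()
        assert "REML" in s and "sigma2_g" in s


class TestLrt:
    def test_null_term_type_i_error_controlled(self):
        reject = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed + 1000)
            g = np.repeat([f"g{i}" for i in range(10)], 12)
            h = np.tile([f"h{i}" for i in range(12)], 10)
            y = r.normal(size=120) + r.normal(0, 1.0, 10)[
                np.repeat(np.arange(10), 12)]
            df = pd.DataFrame({"y": y, "g": g, "h": h})
            out = lrt_random(df, ModelSpec(response="y", random=["g", "h"]),
                             "h")
            reject += out["p"] < 0.05
        assert reject / n_seeds <= 0.075

    def test_large_variance_detected(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df, _, _ = balanced_oneway(seed=seed, k=30, n=8,
                                       sigma_a2=2.0, sigma_e2=1.0)
            out = lrt_random(df, ModelSpec(response="y", random=["g"]), "g")
            hits += out["p"] < 0.001
        assert hits >= 0.95 * n_seeds

    def test_negligible_statistic_gives_p_near_one(self):
        df, _, _ = balanced_oneway(seed=9, k=10, n=4)
        df["h"] = np.tile([f"h{i}" for i in range(8)], 5)
        out = lrt_random(df, ModelSpec(response="y", random=["g", "h"]), "h")
        assert 0.0 <= out["p"] <= 1.0
        if out["lr"] <= 1e-8:
            assert out["p"] == pytest.approx(1.0, abs=1e-3)

    def test_non_nested_comparison_rejected(self):
        df, _, _ = balanced_oneway(seed=11, k=10, n=4)
        df["h"] = np.tile([f"h{i}" for i in range(8)], 5)
        a = fit_lmm(df, ModelSpec(response="y", random=["g"]))
        b = fit_lmm(df, ModelSpec(response="y", random=["h"]))
        with pytest.raises(ValueError, match="one random term"):
            a.lrt_against(b)
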