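"""Heritability/Q_ST estimators, G-matrix, and F_ST estimators."""

import numpy as np
import pandas as pd
import pytest

from gardenring import quantgen as qg
from gardenring.datatypes import DesignTable, GenotypeMatrix
from gardenring.lmm import ModelSpec, fit_lmm
from gardenring.simulate import gen_genotypes

from conftest import balanced_oneway

R_PAPER = 0.2573


class TestRatioEstimators:
    def test_wood_density_row(self):
        h2 = qg.heritability_from_components(144.723, 1689.941, R_PAPER)
        q = qg.qst_from_components(110.689, 144.723, R_PAPER)
        assert round(h2, 3) == 0.333
        assert round(q, 3) == 0.090

    def test_lumen_diameter_row(self):
        h2 = qg.heritability_from_components(0.204, 2.95, R_PAPER)
        q = qg.qst_from_components(0.123, 0.204, R_PAPER)
        assert round(h2, 3) == 0.269
        assert round(q, 3) == 0.072

    def test_qst_half_when_pop_equals_twice_additive(self):
        r = 0.25
        s_fam = 0.8
        s_pop = 2 * s_fam / r
        assert qg.qst_from_components(s_pop, s_fam, r) == pytest.approx(0.5)

    def test_degenerate_inputs_rejected(self):
        assert qg.heritability_from_components(0.0, 1.0, 0.25) == 0.0
        assert qg.qst_from_components(0.0, 1.0, 0.25) == 0.0
        with pytest.raises(ValueError):
            qg.heritability_from_components(1.0, 0.0, 0.25)
        with pytest.raises(ValueError):
            qg.heritability_from_components(1.0, 1.0, 0.7)
        with pytest.raises(ValueError):
            qg.qst_from_components(0.0, 0.0, 0.25)

    def test_scale_invariance_of_ratios(self):
        for c in (0.1, 1.0, 250.0):
            h2 = qg.heritability_from_components(0.204 * c, 2.95 * c, R_PAPER)
            assert round(h2, 6) == round(
                qg.heritability_from_components(0.204, 2.95, R_PAPER), 6)


class TestDeltaMethod:
    @staticmethod
    def _fit_structured(seed, k_prov, k_fam_per):
        rng = np.random.default_rng(seed)
        rows = []
        u_pop = rng.normal(0, 1.0, k_prov)
        tid = 0
        for p in range(k_prov):
            for f in range(k_fam_per):
                uf = rng.normal(0, 0.7)
                for b in range(4):
                    for _ in range(2):
                        tid += 1
                        rows.append((f"T{tid}", f"P{p}", f"F{p}_{f}", b,
                                     u_pop[p] + uf + rng.normal()))
        df = pd.DataFrame(rows, columns=["tree", "provenance", "family",
                                         "block", "y"])
        spec = ModelSpec(response="y", fixed=["block"],
                         random=["provenance", "family"])
        return fit_lmm(df, spec)

    def test_ci_symmetric_and_shrinks_with_design_size(self):
        small = self._fit_structured(0, 8, 2)
        large = self._fit_structured(0, 32, 3)
        h_small = qg.heritability(small, 0.25, pheno_terms=("family",))
        h_large = qg.heritability(large, 0.25, pheno_terms=("family",))
        lo, hi = h_small.ci
        assert hi - h_small.estimate == pytest.approx(h_small.estimate - lo)
        assert h_large.se < h_small.se
        q_small = qg.qst(small, 0.25)
        q_large = qg.qst(large, 0.25)
        assert q_large.se < q_small.se


def _unrelated_design(n_prov, n_per):
    rows = [{"tree": f"T{p}_{i}", "family": f"F{p}_{i}",
             "provenance": f"P{p}", "block": 1}
            for p in range(n_prov) for i in range(n_per)]
    return DesignTable(pd.DataFrame(rows))


def _family_design(n_prov, n_fam, fam_size):
    rows = [{"tree": f"T{p}_{f}_{i}", "family": f"F{p}_{f}",
             "provenance": f"P{p}", "block": 1}
            for p in range(n_prov) for f in range(n_fam)
            for i in range(fam_size)]
    return DesignTable(pd.DataFrame(rows))


class TestGmatrix:
    def test_all_heterozygous_gives_zero_relationships(self):
        counts = np.ones((6, 120))
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(6)])
        G = qg.gmatrix(gm)
        assert np.allclose(G.to_numpy(), 0.0)

    def test_halfsib_relatedness_near_pedigree(self):
        d = _family_design(20, 5, 6)
        gm = gen_genotypes(d, 5000, fst=0.0, seed=1)
        G = qg.gmatrix(gm)
        r_hat = qg.avg_within_family(G, gm.family)
        assert 0.2 <= r_hat <= 0.3
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_panel_rejected(self):
        counts = np.zeros((5, 150))
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="polymorphic"):
            qg.gmatrix(gm)

    def test_missing_genotypes_mean_imputed(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(30, 200)).astype(float)
        miss = rng.random(counts.shape) < 0.1
        counts[miss] = np.nan
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(30)])
        G = qg.gmatrix(gm)
        assert np.isfinite(G.to_numpy()).all()


class TestFst:
    def test_fixed_alternate_alleles_theta_one(self):
        counts = np.vstack([np.zeros((5, 300)), np.full((5, 300), 2.0)])
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(10)],
                            provenance=pd.Series(["A"] * 5 + ["B"] * 5))
        per_snp, overall = qg.fst_weir_cockerham(gm)
        assert overall == pytest.approx(1.0)
        assert np.allclose(per_snp, 1.0)

    def test_panmictic_theta_near_zero(self):
        d = _unrelated_design(20, 25)
        gm = gen_genotypes(d, 5000, fst=0.0, seed=2)
        _, overall = qg.fst_weir_cockerham(gm)
        assert abs(overall) <= 0.005

    def test_monomorphic_snp_excluded(self):
        counts = np.ones((8, 150))
        counts[:, 0] = 0.0  # monomorphic ref
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(8)],
                            provenance=pd.Series(["A"] * 4 + ["B"] * 4))
        per_snp, overall = qg.fst_weir_cockerham(gm)
        assert np.isnan(per_snp.iloc[0])
        assert np.isfinite(overall)

    def test_nei_gst_tracks_differentiation(self):
        d = _unrelated_design(15, 30)
        lo = gen_genotypes(d, 2000, fst=0.01, seed=3)
        hi = gen_genotypes(d, 2000, fst=0.15, seed=3)
        _, g_lo = qg.fst_nei(lo)
        _, g_hi = qg.fst_nei(hi)
        assert g_hi > g_lo

    def test_single_provenance_rejected(self):
        counts = np.ones((4, 150))
        gm = GenotypeMatrix(counts, trees=[f"t{i}" for i in range(4)],
                            provenance=pd.Series(["A"] * 4))
        with pytest.raises(ValueError, match=">= 2 provenances"):
            qg.fst_weir_cockerham(gm)
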