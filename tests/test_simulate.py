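"""Synthetic-data generator: moments, design combinatorics, ground truth."""

import numpy as np
import pandas as pd
import pytest

from gardenring import climate as clim
from gardenring.simulate import (
    SimParams,
    WeatherParams,
    gen_design,
    gen_genotypes,
    gen_rings,
    gen_weather,
    simulate_dataset,
)


class TestWeather:
    def test_summer_precip_matches_stationary_mean(self):
        wp = WeatherParams()
        daily = gen_weather(range(1900, 2100), seed=1, params=wp)
        daily["year"] = daily["date"].dt.year
        daily["month"] = daily["date"].dt.month
        jja = daily[daily.month.isin([6, 7, 8])]
        totals = jja.groupby("year")["prec"].sum()
        se = totals.std() / np.sqrt(len(totals))
        assert abs(totals.mean() - wp.expected_summer_precip()) <= 3 * se

    def test_drought_year_below_tenth_percentile(self):
        wp = WeatherParams()
        base = gen_weather(range(1950, 2050), seed=0, params=wp)
        base["year"] = base["date"].dt.year
        base["month"] = base["date"].dt.month
        q10 = (base[base.month.isin([6, 7, 8])]
               .groupby("year")["prec"].sum().quantile(0.10))
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            d = gen_weather([2000, 2001], seed=seed,
                            drought_years={2001: 0.3}, params=wp)
            d["year"] = d["date"].dt.year
            d["month"] = d["date"].dt.month
            tot = d[(d.year == 2001) & d.month.isin([6, 7, 8])]["prec"].sum()
            hits += tot < q10
        assert hits >= 0.95 * n_seeds

    def test_temperature_ordering_and_vpd(self):
        d = gen_weather(range(2000, 2003), seed=5)
        assert (d.tmin <= d.tmean).all()
        assert (d.tmean <= d.tmax).all()
        assert (d.vpd >= 0).all()

    def test_reproducible(self):
        a = gen_weather(range(2000, 2002), seed=9)
        b = gen_weather(range(2000, 2002), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestDesign:
    def test_paper_scale_slots(self):
        d = gen_design(SimParams(), seed=1)
        assert len(d) == 197 * 6 * 5
        counts = d.data.groupby("provenance")["family"].nunique()
        assert counts.between(1, 5).all()
        assert counts.sum() == 197

    def test_minimal_design(self):
        p = SimParams(n_prov=1, families_total=1, fam_min=1, fam_max=1,
                      n_blocks=1, trees_per_plot=5)
        d = gen_design(p, seed=0)
        assert len(d) == 5
        assert d.data["plot"].nunique() == 1

    def test_randomized_layouts_differ_but_counts_match(self):
        p = SimParams(n_prov=5, families_total=12, n_blocks=2, trees_per_plot=2)
        d1, d2 = gen_design(p, seed=1), gen_design(p, seed=2)
        assert not d1.data[["x", "y", "family"]].equals(d2.data[["x", "y", "family"]])
        c1 = d1.data.groupby("family").size().sort_index()
        c2 = d2.data.groupby("family").size().sort_index()
        pd.testing.assert_series_equal(c1, c2)

    def test_origin_gradient_spans_and_ranks(self):
        d = gen_design(SimParams(), seed=3)
        origin = d.origin_climate()
        smi = origin["origin_summer_smi"]
        assert smi.min() == pytest.approx(40.0)
        assert smi.max() == pytest.approx(90.0)
        # ranking of origins by Summer_SMI is strict (gradient preserved)
        assert smi.nunique() == len(smi)


class TestGenotypes:
    def test_target_fst_recovered(self):
        rows = [{"tree": f"T{p}_{i}", "family": f"F{p}_{i}",
                 "provenance": f"P{p}", "block": 1}
                for p in range(43) for i in range(30)]
        from gardenring.datatypes import DesignTable
        from gardenring.quantgen import fst_weir_cockerham

        d = DesignTable(pd.DataFrame(rows))
        gm = gen_genotypes(d, 5000, fst=0.043, seed=2)
        _, theta = fst_weir_cockerham(gm)
        assert abs(theta - 0.043) <= 0.01

    def test_genotypes_reproducible_and_valid(self, small_sim):
        gm = small_sim["genotypes"]
        assert set(np.unique(gm.counts)) <= {0.0, 1.0, 2.0}
        assert gm.n_snps == 400


class TestRings:
    def test_zero_variance_flat_climate_identical_trees(self):
        p = SimParams(n_prov=2, families_total=4, fam_min=2, fam_max=2,
                      n_blocks=2, trees_per_plot=1, ring_years=(1990, 2000),
                      sigma2_pop=0, sigma2_fam=0, sigma2_plot=0,
                      sigma2_pop_year=0, sigma2_fam_year=0, sigma2_e=0,
                      rho=0.0, sens_noise_sd=0, resil_noise_sd=0,
                      resil_fam_sd=0, drought_years={})
        smi = pd.Series(60.0, index=range(1990, 2001))
        rings, _ = gen_rings(gen_design(p, seed=1), smi, p, seed=1)
        wide = rings.wide("RW")
        assert np.allclose(wide.sub(wide.iloc[:, 0], axis=0), 0.0)

    def test_drought_year_depresses_mean_bai(self, trial_sim):
        from gardenring.rings import rw_to_bai

        bai = rw_to_bai(trial_sim["rings"])
        yearly = bai.groupby("year")["BAI"].mean()
        assert yearly[1997] < yearly[1996]
        assert yearly[1997] < yearly[1998]
        assert yearly[2002] < yearly[2000]
        assert yearly[2002] < yearly[2003]

    def test_missing_smi_years_rejected(self):
        p = SimParams(n_prov=1, families_total=1, fam_min=1, fam_max=1,
                      n_blocks=1, trees_per_plot=1, ring_years=(1990, 2000))
        smi = pd.Series(60.0, index=range(1995, 2001))
        with pytest.raises(ValueError, match="does not cover"):
            gen_rings(gen_design(p, seed=0), smi, p, seed=0)

    def test_tracheid_traits_satisfy_invariants(self, small_sim):
        df = small_sim["rings"].data
        assert (df["CWT"] < df[["TDr", "TDt"]].min(axis=1)).all()
        assert (df["RW"] > 0).all()

    def test_dataset_reproducible_from_seed(self):
        p = SimParams(n_prov=3, families_total=6, fam_min=2, fam_max=2,
                      n_blocks=2, trees_per_plot=1, n_sampled_trees=12,
                      n_snps=50, ring_years=(1990, 2000))
        a = simulate_dataset(p, seed=4)
        b = simulate_dataset(p, seed=4)
        pd.testing.assert_frame_equal(a["rings"].data, b["rings"].data)
        assert np.array_equal(a["genotypes"].counts, b["genotypes"].counts)
        pd.testing.assert_frame_equal(a["daily"], b["daily"])


class TestParameterRecovery:
    def test_true_qst_recovered_through_quantgen(self):
        """Generate log ring series with a known Q_ST and recover it with
        the repeated-measures REML model (mean over seeds within 0.03)."""
        from gardenring.lmm import ModelSpec, ProvenanceTrialLMM
        from gardenring.quantgen import qst

        r = 0.2573
        s_fam = 0.005
        target = 0.09
        s_pop = target / (1 - target) * 2 * s_fam / r
        ests = []
        for seed in range(10):
            p = SimParams(n_prov=43, families_total=197, fam_min=1, fam_max=5,
                          n_blocks=6, trees_per_plot=1, n_sampled_trees=10**6,
                          ring_years=(1994, 2004),
                          sigma2_pop=s_pop, sigma2_fam=s_fam, sigma2_plot=0.0,
                          # clinal links off: the experiment controls
                          # provenance variance through sigma2_pop alone
                          beta_smi=0.0, beta_mat=0.0, sens_noise_sd=0.0,
                          beta_resil=0.0, resil_mat=0.0, resil_noise_sd=0.0,
                          resil_fam_sd=0.0, seed=seed)
            sim = simulate_dataset(p, seed=seed, with_genotypes=False)
            df = sim["rings"].data.copy()
            df["logRW"] = np.log(df["RW"])
            d = sim["design"].data.set_index("tree")
            df["provenance"] = df["tree"].map(d["provenance"])
            df["family"] = df["tree"].map(d["family"])
            df["block"] = df["tree"].map(d["block"])
            spec = ModelSpec(
                response="logRW", fixed=["year", "block:year"],
                random=["provenance", "family", "provenance:year",
                        "family:year"],
                residual="ar1", subject="tree", time="year",
            )
            m = ProvenanceTrialLMM(df, spec)
            res = m.fit(starts=[m._start_values()[0]])
            ests.append(qst(res, r, with_se=False).estimate)
        assert abs(np.mean(ests) - target) <= 0.03
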