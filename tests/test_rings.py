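"""BAI conversion, tracheid derivations, chronologies/EPS, dating screen."""

import numpy as np
import pandas as pd
import pytest

from gardenring import rings as rg
from gardenring.datatypes import RingSeriesSet


def _set(rows):
    return RingSeriesSet(pd.DataFrame(rows))


class TestBai:
    def test_hand_example(self):
        rr = _set({"tree": "A", "year": [2000, 2001, 2002], "RW": [1.0, 1.0, 1.0]})
        bai = rg.rw_to_bai(rr)["BAI"].to_numpy()
        assert np.allclose(bai, [np.pi, 3 * np.pi, 5 * np.pi])

    def test_single_ring(self):
        rr = _set({"tree": "A", "year": [2000], "RW": [2.5]})
        assert rg.rw_to_bai(rr)["BAI"].iloc[0] == pytest.approx(np.pi * 2.5**2)

    def test_telescoping_total_basal_area(self, rng):
        rw = rng.uniform(0.2, 3.0, 25)
        rr = _set({"tree": "A", "year": np.arange(1980, 2005), "RW": rw})
        bai = rg.rw_to_bai(rr)["BAI"]
        assert bai.sum() == pytest.approx(np.pi * rw.sum() ** 2)
        assert (bai > 0).all()

    def test_invertible_to_rw(self, rng):
        rw = rng.uniform(0.2, 3.0, 20)
        rr = _set({"tree": "A", "year": np.arange(1980, 2000), "RW": rw})
        bai = rg.rw_to_bai(rr)["BAI"].to_numpy()
        r = np.sqrt(np.cumsum(bai) / np.pi)
        assert np.allclose(np.diff(np.concatenate([[0.0], r])), rw)

    def test_nonpositive_rw_rejected(self):
        rr = pd.DataFrame({"tree": "A", "year": [2000, 2001], "RW": [1.0, 1.0]})
        rs = RingSeriesSet(rr)
        rs.data.loc[1, "RW"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            rg.rw_to_bai(rs)


class TestTracheid:
    def test_formula_arithmetic(self):
        df = pd.DataFrame({"tree": "A", "year": [2000], "TDr": [30.0],
                           "TDt": [30.0], "CWT": [2.0]})
        out = rg.derive_tracheid(df)
        assert out["LD"].iloc[0] == 28.0
        assert out["CWRr"].iloc[0] == pytest.approx((4.0 / 28.0) ** 2)

    def test_cwr_vanishes_with_wall(self):
        df = pd.DataFrame({"tree": "A", "year": [2000], "TDr": [30.0],
                           "TDt": [28.0], "CWT": [1e-9]})
        assert rg.derive_tracheid(df)["CWR"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_cwr_dimensionless(self):
        df = pd.DataFrame({"tree": "A", "year": [2000], "TDr": [30.0],
                           "TDt": [26.0], "CWT": [2.0]})
        out1 = rg.derive_tracheid(df)
        out2 = rg.derive_tracheid(df.assign(TDr=60.0, TDt=52.0, CWT=4.0))
        assert out1["CWR"].iloc[0] == pytest.approx(out2["CWR"].iloc[0])

    def test_wall_thicker_than_tracheid_rejected(self):
        df = pd.DataFrame({"tree": "A", "year": [2000], "TDr": [3.0],
                           "TDt": [30.0], "CWT": [5.0]})
        with pytest.raises(ValueError, match="tree 'A'"):
            rg.derive_tracheid(df)

    def test_single_wall_convention(self):
        df = pd.DataFrame({"tree": "A", "year": [2000], "TDr": [30.0],
                           "TDt": [30.0], "CWT": [2.0]})
        d2 = rg.derive_tracheid(df, wall="double")["CWRr"].iloc[0]
        d1 = rg.derive_tracheid(df, wall="single")["CWRr"].iloc[0]
        assert d2 == pytest.approx(4.0 * d1)


class TestChronology:
    def test_eps_closed_form(self):
        assert rg.eps(10, 0.3) == pytest.approx(3.0 / 3.7)

    def test_identical_series_full_signal(self):
        years = np.arange(1990, 2010)
        sig = np.sin(years / 2.0)
        df = pd.concat([
            pd.DataFrame({"tree": f"T{i}", "year": years, "value": sig})
            for i in range(5)
        ])
        chron, stats = rg.build_chronology(
            df, pd.Series("G", index=[f"T{i}" for i in range(5)])
        )
        assert stats["rbar"].iloc[0] == pytest.approx(1.0)
        assert stats["EPS"].iloc[0] == pytest.approx(1.0)
        assert (chron["depth"] == 5).all()

    def test_eps_monotone_in_n_and_rbar(self):
        assert rg.eps(20, 0.3) > rg.eps(10, 0.3)
        assert rg.eps(10, 0.5) > rg.eps(10, 0.3)

    def test_single_tree_group_flagged(self):
        df = pd.DataFrame({"tree": "T0", "year": np.arange(1990, 2000),
                           "value": np.arange(10.0)})
        _, stats = rg.build_chronology(df, pd.Series({"T0": "G"}))
        assert stats["flagged"].iloc[0]
        assert np.isnan(stats["EPS"].iloc[0])

    def test_white_noise_has_low_eps(self):
        years = np.arange(1940, 2000)
        low = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = pd.concat([
                pd.DataFrame({"tree": f"T{i}", "year": years,
                              "value": r.normal(size=60)})
                for i in range(20)
            ])
            _, stats = rg.build_chronology(
                df, pd.Series("G", index=[f"T{i}" for i in range(20)])
            )
            low += stats["EPS"].iloc[0] < 0.5
        assert low >= 0.95 * n_seeds


class TestCrossdate:
    @staticmethod
    def _coherent_set(seed=0, n=12, shift=None, noise_tree=None):
        r = np.random.default_rng(seed)
        years = np.arange(1980, 2008)
        signal = r.normal(size=len(years))
        frames = []
        for i in range(n):
            vals = 1.5 + 0.5 * signal + 0.2 * r.normal(size=len(years))
            yrs = years.copy()
            if shift is not None and i == 0:
                yrs = years + shift
            if noise_tree is not None and i in noise_tree:
                vals = 1.5 + 0.55 * r.normal(size=len(years))
            frames.append(pd.DataFrame({"tree": f"T{i}", "year": yrs,
                                        "RW": np.exp(vals)}))
        return RingSeriesSet(pd.concat(frames, ignore_index=True))

    def test_series_equal_to_master(self):
        years = np.arange(1980, 2008)
        sig = np.exp(np.random.default_rng(1).normal(size=len(years)))
        frames = [pd.DataFrame({"tree": f"T{i}", "year": years, "RW": sig})
                  for i in range(3)]
        rep = rg.crossdate_check(RingSeriesSet(pd.concat(frames)))
        assert np.allclose(rep["r0"], 1.0, atol=1e-8)
        assert (rep["best_lag"] == 0).all()

    def test_shifted_series_detected(self):
        rep = rg.crossdate_check(self._coherent_set(seed=3, shift=+1))
        row = rep[rep.tree == "T0"].iloc[0]
        assert row["best_lag"] == -1

    def test_noise_series_flagged(self):
        rep = rg.crossdate_check(self._coherent_set(seed=5, noise_tree={0, 1, 2}))
        flagged = rep.set_index("tree")["flagged"]
        assert flagged[["T0", "T1", "T2"]].all()
        assert not flagged[[f"T{i}" for i in range(3, 12)]].any()

    def test_insufficient_overlap_flagged_not_failed(self):
        frames = [pd.DataFrame({"tree": "short", "year": [2000, 2001, 2002],
                                "RW": [1.0, 1.1, 0.9]})]
        frames += [pd.DataFrame({"tree": f"T{i}",
                                 "year": np.arange(1980, 2008),
                                 "RW": np.random.default_rng(i).uniform(0.5, 2, 28)})
                   for i in range(3)]
        rep = rg.crossdate_check(RingSeriesSet(pd.concat(frames)))
        row = rep[rep.tree == "short"].iloc[0]
        assert row["flagged"] and row["reason"] == "insufficient overlap"
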