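"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gardenring.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete linked dataset (12 provenances, 120 cored trees)."""
    params = SimParams(
        n_prov=12, families_total=30, fam_min=1, fam_max=5, n_blocks=3,
        trees_per_plot=2, n_sampled_trees=120, n_snps=400,
        ring_years=(1985, 2007),
    )
    return simulate_dataset(params, seed=7)


@pytest.fixture(scope="session")
def trial_sim():
    """Trial-scale dataset (43 provenances, 1481 cored trees, no SNPs)."""
    return simulate_dataset(SimParams(), seed=3, with_genotypes=False)


@pytest.fixture(scope="session")
def small_bai(small_sim):
    from gardenring.rings import rw_to_bai

    return rw_to_bai(small_sim["rings"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def balanced_oneway(seed=1, k=50, n=10, sigma_a2=2.0, sigma_e2=1.0):
    """Balanced one-way random-effects data plus its ANOVA estimators."""
    r = np.random.default_rng(seed)
    g = np.repeat(np.arange(k), n)
    a = r.normal(0, np.sqrt(sigma_a2), k)
    y = 1.0 + a[g] + r.normal(0, np.sqrt(sigma_e2), k * n)
    df = pd.DataFrame({"y": y, "g": g.astype(str)})
    gm = df.groupby("g")["y"].mean()
    msb = n * ((gm - y.mean()) ** 2).sum() / (k - 1)
    msw = ((y - gm[df["g"]].to_numpy()) ** 2).sum() / (k * (n - 1))
    return df, (msb - msw) / n, msw
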