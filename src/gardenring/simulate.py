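"""Synthetic common-garden data with known ground truth.

Generates everything the pipeline consumes: daily weather for the trial
site (seasonal sinusoid temperatures with AR(1) anomalies, Markov-chain
precipitation occurrence with gamma amounts, RH/VPD consistent with
temperature, and multiplicative precipitation reductions in imposed
drought years), the randomized-complete-block half-sib field design with
planting coordinates and a clinal gradient of provenance-origin climate,
Balding–Nichols SNP genotypes with explicit maternal alleles (so
half-sib families have realized genomic relatedness near 0.25), and
climate-driven multi-trait ring series whose variance structure mirrors
the repeated-measures analysis model (provenance, family, plot, year
interactions, AR(1) tree-level residual on the log scale).

Defaults reproduce the study conditions: 43 provenances, 197 half-sib
families (one to five per provenance), 6 blocks, five-tree row plots,
1481 sampled trees, ring years 1979-2007 with droughts in 1997,
2001-2002 and 2005, and 6386 SNPs at F_ST 0.043.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import DesignTable, GenotypeMatrix, RingSeriesSet, TruthRecord


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class WeatherParams:
    """Daily weather generator settings for the trial site."""

    tmean_annual: float = 4.0       # deg C, annual mean
    tamp: float = 16.0              # deg C, seasonal half-amplitude
    t_ar_phi: float = 0.7           # AR(1) of daily temperature anomaly
    t_ar_sd: float = 3.0            # innovation SD (deg C)
    t_range: float = 5.0            # Tmax - Tmean and Tmean - Tmin offset
    p_wd: float = 0.30              # P(wet | dry yesterday)
    p_ww: float = 0.60              # P(wet | wet yesterday)
    gamma_shape: float = 0.7
    gamma_mean: float = 6.4         # mm per wet day
    rh_base: float = 85.0           # %
    rh_t_slope: float = 0.8         # % decrease per deg C anomaly
    rh_sd: float = 4.0
    drought_t_bump: float = 2.0     # deg C per unit (1 - severity)
    drought_rh_drop: float = 10.0   # % per unit (1 - severity)

    @property
    def wet_fraction(self) -> float:
        """Stationary wet-day probability of the occurrence chain."""
        return self.p_wd / (1.0 + self.p_wd - self.p_ww)

    def expected_summer_precip(self) -> float:
        """Stationary June-August precipitation total (mm), no drought."""
        return 92.0 * self.wet_fraction * self.gamma_mean


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic common garden."""

    n_prov: int = 43
    families_total: int = 197
    fam_min: int = 1
    fam_max: int = 5
    n_blocks: int = 6
    trees_per_plot: int = 5
    n_sampled_trees: int = 1481
    ring_years: tuple = (1979, 2007)
    drought_years: dict = field(
        default_factory=lambda: {1997: 0.5, 2001: 0.5, 2002: 0.45, 2005: 0.55}
    )  # year -> precipitation severity multiplier (1 = no drought)
    # variance components of log ring width (trait units^2)
    sigma2_pop: float = 0.008
    sigma2_fam: float = 0.005
    sigma2_plot: float = 0.05
    sigma2_pop_year: float = 0.01
    sigma2_fam_year: float = 0.02
    sigma2_e: float = 0.23
    rho: float = 0.5
    # climate response: sensitivity of log growth to the summer-SMI z-score
    gamma0: float = 0.12
    beta_smi: float = 0.004     # per Summer_SMI %; >0: wetter origin = more sensitive
    beta_mat: float = 0.010     # per deg C of origin MAT
    sens_noise_sd: float = 0.01
    drought_extra: float = 2.0  # extra z-units of stress per (1 - severity)
    # post-drought recovery (clinal link): log-BAI boost in the 1-2 years
    # after a drought, higher for drier/cooler origins, heritable within
    # provenances through a family-level deviation
    beta_resil: float = 0.02    # per Summer_SMI %; >0: drier origin recovers better
    resil_mat: float = 0.03     # per deg C of origin MAT (warm origins recover worse)
    resil_noise_sd: float = 0.02
    resil_fam_sd: float = 0.05
    recovery_decay: tuple = (1.0, 0.5)  # lag-1, lag-2 weights, scaled by (1-severity)
    # age trend of log ring width (mm): a + b*log(age) - c*age
    trend_a: float = 0.4
    trend_b: float = 0.6
    trend_c: float = 0.09
    # genotypes
    n_snps: int = 6386
    fst: float = 0.043
    af_low: float = 0.1
    af_high: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma2_pop", "sigma2_fam", "sigma2_plot",
                     "sigma2_pop_year", "sigma2_fam_year", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if not 1 <= self.fam_min <= self.fam_max:
            raise ValueError("family counts per provenance must satisfy 1 <= min <= max")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")


# ---------------------------------------------------------------------------
# Weather


def _saturation_vp(t):
    """Saturation vapour pressure (kPa), Tetens form."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def gen_weather(years, seed: int = 0, drought_years: dict | None = None,
                params: WeatherParams | None = None) -> pd.DataFrame:
    """Generate a daily weather table for the given calendar years.

    `drought_years` maps year -> severity multiplier s in (0, 1]; in
    those years June-September precipitation amounts are multiplied by s,
    temperatures get a bump and RH a drop proportional to (1 - s).
    """
    years = sorted(int(y) for y in years)
    if len(years) < 2:
        raise ValueError("generate at least 2 years of weather")
    wp = params or WeatherParams()
    drought_years = drought_years or {}
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    n = len(dates)
    doy = dates.day_of_year.to_numpy()
    year = dates.year.to_numpy()
    month = dates.month.to_numpy()

    # temperature: seasonal sinusoid + AR(1) anomaly
    seasonal = wp.tmean_annual - wp.tamp * np.cos(2 * np.pi * (doy - 15) / 365.25)
    anom = np.zeros(n)
    innov = rng.normal(0.0, wp.t_ar_sd, size=n)
    anom[0] = innov[0] / np.sqrt(1 - wp.t_ar_phi**2)
    for i in range(1, n):
        anom[i] = wp.t_ar_phi * anom[i - 1] + innov[i]
    tmean = seasonal + anom

    # precipitation occurrence chain started at its stationary law
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < wp.wet_fraction
    for i in range(1, n):
        p = wp.p_ww if wet[i - 1] else wp.p_wd
        wet[i] = u[i] < p
    amounts = rng.gamma(wp.gamma_shape,
                        wp.gamma_mean / wp.gamma_shape, size=n)
    prec = np.where(wet, amounts, 0.0)

    # drought modifications (June-September)
    sev = np.ones(n)
    for y, s in drought_years.items():
        mask = (year == y) & (month >= 6) & (month <= 9)
        sev[mask] = s
    prec = prec * sev
    tmean = tmean + wp.drought_t_bump * (1.0 - sev)

    rh = (wp.rh_base - wp.rh_t_slope * anom
          - wp.drought_rh_drop * (1.0 - sev)
          + rng.normal(0, wp.rh_sd, size=n))
    rh = np.clip(rh, 15.0, 100.0)
    vpd = np.maximum(_saturation_vp(tmean) * (1.0 - rh / 100.0), 0.0)

    off = np.abs(rng.normal(wp.t_range, 1.0, size=(2, n)))
    return pd.DataFrame({
        "date": dates,
        "tmin": tmean - off[0],
        "tmax": tmean + off[1],
        "tmean": tmean,
        "prec": prec,
        "rh": rh,
        "vpd": vpd,
    })


# ---------------------------------------------------------------------------
# Field design


def _family_counts(params: SimParams, rng) -> np.ndarray:
    """Families per provenance, each in [fam_min, fam_max], fixed total."""
    lo, hi, k, total = params.fam_min, params.fam_max, params.n_prov, params.families_total
    if not lo * k <= total <= hi * k:
        raise ValueError("families_total incompatible with per-provenance bounds")
    counts = np.full(k, lo)
    excess = total - lo * k
    while excess > 0:
        room = np.nonzero(counts < hi)[0]
        pick = rng.choice(room, size=min(excess, len(room)), replace=False)
        counts[pick] += 1
        excess -= len(pick)
    return counts


def gen_design(params: SimParams, seed: int | None = None) -> DesignTable:
    """Randomized complete block design with row plots and origin climate.

    Every family appears once per block as a `trees_per_plot`-tree row
    plot; plot order within each block is randomized.  Planting uses
    1.2 m spacing within rows and 2.4 m between rows.  Provenance-origin
    climate normals follow a Summer_SMI gradient with correlated MAT,
    MAP and ADD.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    counts = _family_counts(params, rng)
    provs = [f"POP_{i + 1:02d}" for i in range(params.n_prov)]
    fams, fam_prov = [], {}
    fid = 0
    for p, c in zip(provs, counts):
        for _ in range(c):
            fid += 1
            name = f"FAM_{fid:03d}"
            fams.append(name)
            fam_prov[name] = p

    # provenance-origin climate gradient
    smi_grid = np.linspace(40.0, 90.0, params.n_prov)
    perm = rng.permutation(params.n_prov)
    origin = {}
    for i, p in enumerate(provs):
        smi = smi_grid[perm[i]]
        mat = 2.2 - 0.03 * (smi - 65.0) + rng.normal(0, 1.4)
        mapn = 841.0 + (smi - 40.0) / 50.0 * (1359.0 - 841.0) + rng.normal(0, 30.0)
        add = 230.0 - (mapn - 1100.0) / 10.0 + rng.normal(0, 5.0)
        origin[p] = (mat, mapn, add, smi)

    rows = []
    tree_id = 0
    block_width = params.trees_per_plot * 1.2 + 3.6
    for b in range(1, params.n_blocks + 1):
        order = rng.permutation(len(fams))
        for plot_idx, fi in enumerate(order):
            fam = fams[fi]
            prov = fam_prov[fam]
            mat, mapn, add, smi = origin[prov]
            for k in range(params.trees_per_plot):
                tree_id += 1
                rows.append({
                    "tree": f"T{tree_id:04d}",
                    "family": fam,
                    "provenance": prov,
                    "block": b,
                    "plot": f"B{b}_{fam}",
                    "x": (b - 1) * block_width + k * 1.2,
                    "y": plot_idx * 2.4,
                    "origin_MAT": mat,
                    "origin_MAP": mapn,
                    "origin_ADD": add,
                    "origin_summer_smi": smi,
                })
    return DesignTable(pd.DataFrame(rows))


def sample_trees(design: DesignTable, n: int, seed: int = 0) -> list:
    """Random subset of trees standing in for the cored subsample."""
    rng = np.random.default_rng(seed)
    trees = np.asarray(design.trees)
    if n >= len(trees):
        return list(trees)
    return list(trees[np.sort(rng.choice(len(trees), size=n, replace=False))])


# ---------------------------------------------------------------------------
# Genotypes


def gen_genotypes(design: DesignTable, n_snps: int, fst: float,
                  seed: int = 0, trees=None,
                  af_range=(0.1, 0.9)) -> GenotypeMatrix:
    """Balding–Nichols SNPs with explicit half-sib maternal alleles.

    Ancestral frequencies are uniform on `af_range`; provenance-specific
    frequencies follow Beta(p(1-F)/F, (1-p)(1-F)/F).  Within a family
    every tree draws one allele from the common mother (two maternal
    alleles drawn once per family) and one from the provenance pool,
    giving expected within-family genomic relatedness 0.25.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = design.data if trees is None else (
        design.data[design.data["tree"].isin(set(trees))]
    )
    d = d.reset_index(drop=True)
    provs = list(dict.fromkeys(d["provenance"]))
    fams = list(dict.fromkeys(d["family"]))
    prov_idx = {p: i for i, p in enumerate(provs)}
    fam_idx = {f: i for i, f in enumerate(fams)}
    fam_prov = (
        d.drop_duplicates("family").set_index("family")["provenance"].map(prov_idx)
    )
    tree_fam = d["family"].map(fam_idx).to_numpy()
    tree_prov = d["provenance"].map(prov_idx).to_numpy()

    p_anc = rng.uniform(af_range[0], af_range[1], size=n_snps)
    if fst > 0:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_pop = rng.beta(a, b, size=(len(provs), n_snps))
        p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)
    else:
        p_pop = np.tile(p_anc, (len(provs), 1))

    fam_pop = fam_prov.reindex(fams).to_numpy()
    # two maternal alleles per family x SNP
    mother = rng.random((2, len(fams), n_snps)) < p_pop[fam_pop][None, :, :]
    n_trees = len(d)
    pick = rng.integers(0, 2, size=(n_trees, n_snps))
    maternal = np.where(pick == 0, mother[0][tree_fam], mother[1][tree_fam])
    paternal = rng.random((n_trees, n_snps)) < p_pop[tree_prov]
    counts = (maternal.astype(np.int8) + paternal.astype(np.int8)).astype(float)
    return GenotypeMatrix(
        counts, list(d["tree"]),
        snps=[f"snp{j + 1}" for j in range(n_snps)],
        provenance=d["provenance"], family=d["family"],
    )


# ---------------------------------------------------------------------------
# Ring series


def gen_rings(design: DesignTable, summer_smi: pd.Series, params: SimParams,
              seed: int | None = None,
              trees=None) -> tuple[RingSeriesSet, TruthRecord]:
    """Climate-driven multi-trait ring series with known effect structure.

    log RW = age trend + sens_i * z_t + u_pop + u_fam + u_plot
             + u_pop:year + u_fam:year + AR(rho) residual,

    where z_t is the summer-SMI z-score (with extra imposed stress in
    drought years) and the provenance climate sensitivity sens_i follows
    the clinal link against origin Summer_SMI and MAT.  Tracheid traits
    share the genetic structure through a latent lumen factor with a
    negative wood-density/lumen coupling.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    y0, y1 = params.ring_years
    years = np.arange(y0, y1 + 1)
    missing = [int(y) for y in years if y not in summer_smi.index]
    if missing:
        raise ValueError(f"summer SMI does not cover ring years {missing}")
    smi = summer_smi.loc[years].to_numpy(dtype=float)
    z = (smi - smi.mean()) / (smi.std() if smi.std() > 0 else 1.0)
    for y, s in params.drought_years.items():
        if y0 <= y <= y1:
            z[years == y] -= params.drought_extra * (1.0 - s)

    d = design.data if trees is None else (
        design.data[design.data["tree"].isin(set(trees))]
    )
    d = d.reset_index(drop=True)
    provs = list(dict.fromkeys(d["provenance"]))
    fams = list(dict.fromkeys(d["family"]))
    plots = list(dict.fromkeys(d["plot"])) if "plot" in d.columns else []

    origin = design.origin_climate()
    smi_o = origin["origin_summer_smi"]
    mat_o = origin["origin_MAT"]
    sens = {
        p: (params.gamma0
            + params.beta_smi * (smi_o[p] - smi_o.mean())
            + params.beta_mat * (mat_o[p] - mat_o.mean())
            + rng.normal(0, params.sens_noise_sd))
        for p in provs
    }
    # clinal recovery effect: drier and cooler origins rebound better
    resil_prov = {
        p: (-params.beta_resil * (smi_o[p] - smi_o.mean())
            - params.resil_mat * (mat_o[p] - mat_o.mean())
            + rng.normal(0, params.resil_noise_sd))
        for p in provs
    }
    fam_prov_map = d.drop_duplicates("family").set_index("family")["provenance"]
    resil_fam = {
        f: resil_prov[fam_prov_map[f]] + rng.normal(0, params.resil_fam_sd)
        for f in fams
    }
    # per-year recovery weight: sum of lagged (1 - severity) pulses
    w_rec = np.zeros(ny := len(years))
    for dy, s in params.drought_years.items():
        for lag, dec in enumerate(params.recovery_decay, start=1):
            t = dy + lag
            if y0 <= t <= y1:
                w_rec[years == t] += dec * (1.0 - s)

    ny = len(years)
    u_pop = {p: rng.normal(0, np.sqrt(params.sigma2_pop)) for p in provs}
    u_fam = {f: rng.normal(0, np.sqrt(params.sigma2_fam)) for f in fams}
    u_plot = {pl: rng.normal(0, np.sqrt(params.sigma2_plot)) for pl in plots}
    u_pop_year = {p: rng.normal(0, np.sqrt(params.sigma2_pop_year), ny) for p in provs}
    u_fam_year = {f: rng.normal(0, np.sqrt(params.sigma2_fam_year), ny) for f in fams}
    # latent lumen genetic factor per family/provenance (shares the
    # half-sib structure; drives the WD-LD trade-off)
    l_pop = {p: rng.normal(0, 1.0) for p in provs}
    l_fam = {f: rng.normal(0, 0.7) for f in fams}

    age = np.arange(1, ny + 1, dtype=float)
    trend = params.trend_a + params.trend_b * np.log(age) - params.trend_c * age

    n_trees = len(d)
    eps = rng.normal(0, 1.0, size=(n_trees, ny))
    ar = np.zeros_like(eps)
    rho = params.rho
    ar[:, 0] = eps[:, 0]
    for t in range(1, ny):
        ar[:, t] = rho * ar[:, t - 1] + np.sqrt(1 - rho**2) * eps[:, t]
    ar *= np.sqrt(params.sigma2_e)

    records = []
    for i, rec in d.iterrows():
        p, f = rec["provenance"], rec["family"]
        pl = rec.get("plot")
        base = (trend
                + sens[p] * z
                + resil_fam[f] * w_rec
                + u_pop[p] + u_fam[f]
                + (u_plot.get(pl, 0.0))
                + u_pop_year[p] + u_fam_year[f]
                + ar[i])
        rw = np.exp(base)
        l_tree = l_pop[p] + l_fam[f] + rng.normal(0, 0.5)
        ld = 25.0 + 2.0 * l_tree + 0.8 * z + rng.normal(0, 1.0, ny)
        ld = np.maximum(ld, 8.0)
        cwt = np.maximum(2.5 - 0.25 * l_tree - 0.2 * z + rng.normal(0, 0.15, ny), 0.8)
        wd = 420.0 - 8.0 * (ld - 25.0) - 15.0 * z + 25.0 * (cwt - 2.5) \
            + rng.normal(0, 12.0, ny)
        records.append(pd.DataFrame({
            "tree": rec["tree"],
            "year": years,
            "RW": rw,
            "WD": wd,
            "CWT": cwt,
            "TDr": ld + 1.0 + cwt,
            "TDt": ld - 1.0 + cwt,
        }))
    rings = RingSeriesSet(pd.concat(records, ignore_index=True))
    truth = TruthRecord(
        params=asdict(params),
        effects={
            "u_pop": u_pop, "u_fam": u_fam, "sens": sens,
            "resil_prov": resil_prov, "resil_fam": resil_fam,
            "z": dict(zip((int(y) for y in years), z)),
            "summer_smi": dict(zip((int(y) for y in years), smi)),
        },
    )
    return rings, truth


# ---------------------------------------------------------------------------
# One-call dataset


def simulate_dataset(params: SimParams | None = None, seed: int | None = None,
                     with_genotypes: bool = True) -> dict:
    """Generate a complete linked dataset (weather, design, rings, SNPs).

    Returns a dict with keys daily, monthly, smi, design, sampled_trees,
    rings, truth and (optionally) genotypes.  Everything derives from
    (params, seed) only.
    """
    from . import climate as clim

    params = params or SimParams()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s_weather, s_design, s_geno, s_rings, s_sample = rng.integers(
        0, 2**31 - 1, size=5
    )
    y0, y1 = params.ring_years
    daily = gen_weather(range(y0 - 1, y1 + 1), seed=int(s_weather),
                        drought_years=params.drought_years)
    monthly = clim.aggregate_monthly(daily)
    smi = clim.compute_smi(monthly)
    summer = (
        smi[smi["month"].isin(clim.SUMMER_MONTHS)]
        .groupby("year")["SMI"].mean()
    )
    design = gen_design(params, seed=int(s_design))
    sampled = sample_trees(design, params.n_sampled_trees, seed=int(s_sample))
    rings, truth = gen_rings(design, summer, params, seed=int(s_rings),
                             trees=sampled)
    out = {
        "daily": daily, "monthly": monthly, "smi": smi,
        "summer_smi": summer, "design": design,
        "sampled_trees": sampled, "rings": rings, "truth": truth,
    }
    if with_genotypes:
        out["genotypes"] = gen_genotypes(
            design, params.n_snps, params.fst, seed=int(s_geno), trees=sampled
        )
    return out
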