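"""Monthly climate aggregation, soil-moisture water balance, and drought detection.

The soil moisture index (SMI) follows a monthly bucket model: the soil
store W (mm, bounded by ``w_max``) gains precipitation and loses actual
evapotranspiration AET = PET * g(W), where potential evapotranspiration
PET comes from a simplified Penman–Monteith expression driven by mean
temperature and vapour-pressure deficit, and the drawdown function g is
quadratic in W below the critical store ``w_crit`` and saturates at 1
above it ("quadratic + linear" formulation).  With the default
parameterization (w_max = 300 mm < w_crit = 400 mm) the store never
leaves the quadratic regime.  SMI is reported as a percentage of w_max.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

#: Threshold (mm) below which a day counts as dry for the ADD statistic.
DRY_DAY_MM = 0.2

#: Summer months used for Summer_SMI and for summer anomaly ratios.
SUMMER_MONTHS = (6, 7, 8)


def aggregate_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate daily records to monthly values.

    Temperatures, RH and VPD are averaged; precipitation is summed;
    ``dry_days`` counts days with precipitation below 0.2 mm.  Months with
    missing days raise an error listing the dates.
    """
    df = daily.copy()
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    # completeness check
    for (y, m), grp in df.groupby(["year", "month"]):
        ndays = calendar.monthrange(y, m)[1]
        if len(grp) != ndays:
            have = set(grp["date"].dt.day)
            miss = sorted(set(range(1, ndays + 1)) - have)
            raise ValueError(f"month {y}-{m:02d} missing days {miss}")
    agg = {
        "tmin": ("tmin", "mean"),
        "tmax": ("tmax", "mean"),
        "tmean": ("tmean", "mean"),
        "prec": ("prec", "sum"),
    }
    if "rh" in df.columns:
        agg["rh"] = ("rh", "mean")
    if "vpd" in df.columns:
        agg["vpd"] = ("vpd", "mean")
    out = df.groupby(["year", "month"]).agg(**agg)
    out["dry_days"] = df.groupby(["year", "month"])["prec"].apply(
        lambda p: int((p < DRY_DAY_MM).sum())
    )
    return out.reset_index()


def potential_evapotranspiration(tmean, vpd) -> np.ndarray:
    """Monthly PET (mm) from a simplified Penman–Monteith expression.

    PET = 93 * VPD * exp(tmean / 23.88), zero for frozen months
    (tmean < 0).  VPD in kPa, tmean in deg C; the canopy and aerodynamic
    terms are folded into the fixed constants.
    """
    tmean = np.asarray(tmean, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    pet = 93.0 * np.maximum(vpd, 0.0) * np.exp(tmean / 23.88)
    return np.where(tmean < 0.0, 0.0, pet)


def drawdown_fraction(w_prev, w_crit) -> float:
    """AET/PET fraction g(W): quadratic below w_crit, 1 above.

    g(W) = (W / w_crit) * (2 - W / w_crit) for W < w_crit, else 1.
    """
    x = np.minimum(np.asarray(w_prev, dtype=float) / float(w_crit), 1.0)
    return x * (2.0 - x)


def compute_smi(
    monthly: pd.DataFrame,
    w_max: float = 300.0,
    w_crit: float = 400.0,
    w_init: float | None = None,
    snow: bool = True,
) -> pd.DataFrame:
    """Run the monthly bucket water balance and return the SMI series.

    Parameters
    ----------
    monthly
        Output of :func:`aggregate_monthly`; must carry ``vpd``.
    w_max, w_crit
        Maximum and critical plant-available soil water (mm).
    w_init
        Initial store; defaults to a full bucket (w_max).
    snow
        If True, precipitation of frozen months (tmean < 0) accumulates in
        a snowpack released at the first month with tmean > 0.

    Returns a frame with year, month, P_eff, PET, AET, W, overflow, SMI.
    """
    if w_max <= 0 or w_crit <= 0:
        raise ValueError("w_max and w_crit must be positive")
    m = monthly.sort_values(["year", "month"]).reset_index(drop=True)
    if "vpd" not in m.columns:
        raise ValueError("monthly table must include vpd for PET")
    w = float(w_max if w_init is None else w_init)
    pack = 0.0
    rows = []
    pet_all = potential_evapotranspiration(m["tmean"], m["vpd"])
    for i, rec in m.iterrows():
        p = float(rec["prec"])
        pet = float(pet_all[i])
        if snow and rec["tmean"] < 0.0:
            pack += p
            p_eff = 0.0
        else:
            p_eff = p
            if snow and pack > 0.0 and rec["tmean"] > 0.0:
                p_eff += pack
                pack = 0.0
        aet = pet * drawdown_fraction(w, w_crit)
        aet = min(aet, w + p_eff)  # cannot evaporate more water than exists
        w_new = w + p_eff - aet
        overflow = max(0.0, w_new - w_max)
        w_new = min(max(w_new, 0.0), w_max)
        rows.append(
            {
                "year": int(rec["year"]),
                "month": int(rec["month"]),
                "P_eff": p_eff,
                "PET": pet,
                "AET": aet,
                "W": w_new,
                "overflow": overflow,
                "SMI": 100.0 * w_new / w_max,
            }
        )
        w = w_new
    return pd.DataFrame(rows)


def annual_normals(monthly: pd.DataFrame, smi: pd.DataFrame,
                   period: tuple[int, int]) -> dict:
    """Long-term climate normals: MAT, MAP, ADD, Summer_SMI.

    MAT is the mean of monthly mean temperatures, MAP the mean annual
    precipitation total, ADD the mean annual count of dry days, and
    Summer_SMI the June–August mean of the soil moisture index, all over
    ``period`` (inclusive year range).
    """
    y0, y1 = period
    if y1 < y0:
        raise ValueError("empty normals period")
    msel = monthly[(monthly["year"] >= y0) & (monthly["year"] <= y1)]
    ssel = smi[(smi["year"] >= y0) & (smi["year"] <= y1)]
    if msel.empty or ssel.empty:
        raise ValueError(f"period {period} outside data range")
    return {
        "MAT": float(msel["tmean"].mean()),
        "MAP": float(msel.groupby("year")["prec"].sum().mean()),
        "ADD": float(msel.groupby("year")["dry_days"].sum().mean()),
        "Summer_SMI": float(
            ssel[ssel["month"].isin(SUMMER_MONTHS)]["SMI"].mean()
        ),
    }


def summer_anomaly(series: pd.DataFrame, value_col: str,
                   baseline: tuple[int, int],
                   months=SUMMER_MONTHS) -> pd.Series:
    """Per-year ratio of summer mean to the baseline-period summer mean.

    A ratio of 1 means a normal summer; values below 1 indicate drier /
    lower-than-normal conditions for the chosen variable.
    """
    sel = series[series["month"].isin(months)]
    yearly = sel.groupby("year")[value_col].mean()
    base = yearly.loc[baseline[0]: baseline[1]]
    if base.empty:
        raise ValueError(f"baseline {baseline} outside data range")
    ref = base.mean()
    if ref == 0:
        raise ValueError("baseline summer mean is zero")
    return yearly / ref


def detect_droughts(anomalies: pd.Series, quantile: float = 0.15,
                    max_ratio: float = 0.9) -> list[int]:
    """Flag drought years from summer anomaly ratios.

    A year is flagged when its ratio falls below the given quantile of
    all years *and* below `max_ratio` (a drought must be absolutely
    anomalous, not merely the driest of an unremarkable run). Consecutive
    flagged years merge into one event dated at its final year (a
    two-year drought spanning Y-1/Y is reported as Y).  Returns an empty
    list when no year stands out (e.g. flat climate).
    """
    if len(anomalies) < 5:
        raise ValueError("need at least 5 years of anomalies")
    vals = anomalies.sort_index()
    thresh = min(vals.quantile(quantile), max_ratio)
    flagged = sorted(vals.index[vals < thresh])
    events: list[int] = []
    for y in flagged:
        if events and y == events[-1] + 1:
            events[-1] = y  # extend the run; keep its final year
        else:
            events.append(y)
    return events
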