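"""Dendroclimatic correlation analysis.

Correlates residual chronologies against monthly climate over an 18-slot
window running from May of the previous year to October of the current
year, with significance from a stationary bootstrap over years (and a
parametric t-test flag alongside).  The per-provenance correlation with a
chosen variable/month ("climate sensitivity trait", e.g. COR_BAI-Jul(t))
feeds the clinal analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: (label, year offset, month) for the 18-slot window prev-May .. curr-Oct.
WINDOW_SLOTS = (
    [(f"prev-{m:02d}", -1, m) for m in range(5, 13)]
    + [(f"curr-{m:02d}", 0, m) for m in range(1, 11)]
)


def climate_slot_matrix(monthly: pd.DataFrame, variable: str,
                        years) -> pd.DataFrame:
    """Years x 18-slot matrix of a monthly climate variable.

    Row year t holds the variable at (t-1, May..Dec) and (t, Jan..Oct).
    """
    lut = monthly.set_index(["year", "month"])[variable]
    rows = {}
    for t in years:
        vals = {}
        for label, off, m in WINDOW_SLOTS:
            key = (t + off, m)
            vals[label] = lut.get(key, np.nan)
        rows[t] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


def stationary_bootstrap_indices(n: int, n_boot: int, rng,
                                 mean_block: float = 4.0) -> np.ndarray:
    """Index matrix (n_boot x n) for the stationary bootstrap.

    Blocks start at uniform positions and have geometric lengths with
    mean `mean_block`; series wrap around, preserving short-range serial
    dependence in the resampled year sequences.
    """
    p = 1.0 / mean_block
    starts = rng.integers(0, n, size=(n_boot, n))
    restart = rng.random(size=(n_boot, n)) < p
    restart[:, 0] = True
    idx = np.zeros((n_boot, n), dtype=int)
    for b in range(n_boot):
        cur = 0
        for t in range(n):
            if restart[b, t]:
                cur = starts[b, t]
            else:
                cur = (cur + 1) % n
            idx[b, t] = cur
    return idx


def monthly_correlations(chronology: pd.Series, monthly: pd.DataFrame,
                         variable: str, years: tuple[int, int],
                         n_boot: int = 1000, seed: int = 0,
                         mean_block: float = 4.0,
                         min_years: int = 15) -> pd.DataFrame:
    """Correlate one chronology against each slot of the monthly window.

    Returns a frame indexed by slot label with Pearson r, bootstrap 95%
    percentile CI, a bootstrap significance flag (CI excludes 0) and a
    parametric p-value flag (p < 0.05).
    """
    yrs = [y for y in range(years[0], years[1] + 1) if y in chronology.index]
    if len(yrs) < min_years:
        raise ValueError(
            f"only {len(yrs)} overlapping years; need >= {min_years}"
        )
    slots = climate_slot_matrix(monthly, variable, yrs)
    y = chronology.loc[yrs].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = stationary_bootstrap_indices(len(yrs), n_boot, rng, mean_block)
    rows = []
    for label in slots.columns:
        x = slots[label].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_years or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append({"slot": label, "r": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "sig_boot": False,
                         "p_param": np.nan, "sig_param": False,
                         "flagged": True})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        xs, ys = x[ok], y[ok]
        sub = idx[:, : len(xs)] % len(xs)
        xb, yb = xs[sub], ys[sub]
        xm = xb - xb.mean(axis=1, keepdims=True)
        ym = yb - yb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (xm * ym).sum(axis=1) / denom
        rb = rb[np.isfinite(rb)]
        lo, hi = np.percentile(rb, [2.5, 97.5])
        rows.append({
            "slot": label, "r": float(r), "ci_lo": float(lo),
            "ci_hi": float(hi), "sig_boot": bool(lo > 0 or hi < 0),
            "p_param": float(p), "sig_param": bool(p < 0.05),
            "flagged": False,
        })
    return pd.DataFrame(rows).set_index("slot")


def climate_sensitivity(chronologies: dict, monthly: pd.DataFrame,
                        variable: str, slot: str,
                        years: tuple[int, int],
                        min_years: int = 15) -> pd.Series:
    """Per-provenance correlation with one climate variable/month slot.

    `chronologies` maps provenance -> Series (year -> mean residual).
    The result is itself a trait vector (one r per provenance) for the
    clinal climate-of-origin analysis.  Constant chronologies yield NaN.
    """
    labels = [lab for lab, _, _ in WINDOW_SLOTS]
    if slot not in labels:
        raise ValueError(f"unknown slot {slot!r}; use one of {labels}")
    out = {}
    for prov, chron in chronologies.items():
        yrs = [y for y in range(years[0], years[1] + 1) if y in chron.index]
        if len(yrs) < min_years:
            raise ValueError(
                f"provenance {prov!r}: only {len(yrs)} years of overlap"
            )
        x = climate_slot_matrix(monthly, variable, yrs)[slot].to_numpy(float)
        y = chron.loc[yrs].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_years or np.ptp(y[ok]) == 0 or np.ptp(x[ok]) == 0:
            out[prov] = np.nan
            continue
        out[prov] = float(stats.pearsonr(x[ok], y[ok])[0])
    return pd.Series(out, name=f"COR_{variable}-{slot}")
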