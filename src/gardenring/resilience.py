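"""Lloret drought-resilience indices computed from basal area increments.

For a drought event year E with pre/post windows of `pre_n`/`post_n`
years (the event year itself excluded from both windows):

* resistance          Rs = Dr / PreDr
* recovery            Rc = PostDr / Dr
* resilience          Rl = PostDr / PreDr
* relative resilience Rr = Rl - Rs

where PreDr / Dr / PostDr are the mean pre-event BAI, the event-year BAI
and the mean post-event BAI.  Indices are computed per tree and averaged
across events for long-term means; all are unitless ratios, invariant to
rescaling the whole BAI series.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

INDEX_COLUMNS = ("Rs", "Rc", "Rl", "Rr")


def lloret_indices(bai: pd.DataFrame, event_year: int,
                   pre_n: int = 2, post_n: int = 2) -> pd.DataFrame:
    """Compute per-tree resilience indices for one drought event.

    `bai` is a long frame (tree, year, BAI).  Trees missing any year of
    the window [event-pre_n, event+post_n] are skipped with a reason
    recorded; a zero event-year BAI raises (the ratios are undefined).
    """
    if pre_n < 1 or post_n < 1:
        raise ValueError("window lengths must be >= 1 year")
    rows, skipped = [], []
    for tree, grp in bai.groupby("tree", sort=False):
        s = grp.set_index("year")["BAI"]
        window = range(event_year - pre_n, event_year + post_n + 1)
        if any(y not in s.index or not np.isfinite(s[y]) for y in window):
            skipped.append({"tree": tree, "event": event_year,
                            "reason": "incomplete window"})
            continue
        pre = float(s.loc[event_year - pre_n: event_year - 1].mean())
        dr = float(s[event_year])
        post = float(s.loc[event_year + 1: event_year + post_n].mean())
        if dr == 0:
            raise ValueError(f"zero event-year BAI for tree {tree!r} in {event_year}")
        rs = dr / pre
        rc = post / dr
        rl = post / pre
        rows.append({
            "tree": tree, "event": event_year,
            "PreDr": pre, "Dr": dr, "PostDr": post,
            "Rs": rs, "Rc": rc, "Rl": rl, "Rr": rl - rs,
            "pre_n": pre_n, "post_n": post_n,
        })
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped  # list of {tree, event, reason}
    return out


def resilience_for_events(bai: pd.DataFrame, events: list[int],
                          pre_n: int = 2, post_n: int = 2) -> pd.DataFrame:
    """Indices for a list of events; warns when windows of consecutive
    events overlap (they are still computed on the overlapping windows)."""
    events = sorted(events)
    for a, b in zip(events, events[1:]):
        if b - a < pre_n + post_n:
            warnings.warn(
                f"pre/post windows of events {a} and {b} overlap "
                f"(gap {b - a} < {pre_n + post_n} yr)", stacklevel=2,
            )
    parts = [lloret_indices(bai, e, pre_n, post_n) for e in events]
    parts = [p for p in parts if len(p)]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def mean_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Average each index across events per tree (long-term resilience).

    Returns one row per tree with Rs_MEAN..Rr_MEAN and the number of
    events contributing.
    """
    if records.empty:
        raise ValueError("no resilience records to average")
    agg = records.groupby("tree").agg(
        **{f"{c}_MEAN": (c, "mean") for c in INDEX_COLUMNS},
        n_events=("event", "nunique"),
    )
    return agg.reset_index()


def group_summary(records: pd.DataFrame, grouping: pd.Series,
                  columns=INDEX_COLUMNS) -> pd.DataFrame:
    """Mean and SD of indices per group (family or provenance)."""
    df = records.copy()
    df["group"] = df["tree"].map(grouping)
    return df.groupby("group")[list(columns)].agg(["mean", "std", "count"])
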