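"""Readers and writers for the interchange formats used by the pipeline.

Supported formats: Tucson/decadal RWL for ring widths, long-format CSV for
multi-trait ring tables, CSV design tables, CSV genotype matrices (rows =
trees, columns = SNPs, entries 0/1/2), and optionally VCF via cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import TRAIT_COLUMNS, DesignTable, GenotypeMatrix, RingSeriesSet

#: Tucson stop markers and the unit divisor each one implies.
_STOP_UNITS = {999: 100.0, -9999: 1000.0}


class RwlParseError(ValueError):
    pass


def read_rwl(path) -> RingSeriesSet:
    """Read a Tucson/decadal ring-width file into a :class:`RingSeriesSet`.

    Values are rescaled to millimetres: the conventional divisor is 100
    (0.01 mm precision) unless the series terminates with -9999, which
    declares 0.001 mm units. The stop marker is consumed, not stored.
    """
    series: dict[str, dict[int, float]] = {}
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    closed: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise RwlParseError(f"{path}:{lineno}: malformed decade line")
            sid = parts[0]
            try:
                decade_year = int(parts[1])
                values = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise RwlParseError(
                    f"{path}:{lineno}: malformed decade line ({exc})"
                ) from None
            if sid in closed:
                raise RwlParseError(
                    f"{path}:{lineno}: duplicate series id {sid!r}"
                )
            raw.setdefault(sid, []).append((decade_year, values))
            if values and values[-1] in _STOP_UNITS:
                closed.add(sid)

    for sid, chunks in raw.items():
        divisor = 100.0
        vals: dict[int, float] = {}
        stopped = False
        for decade_year, values in chunks:
            year = decade_year
            for v in values:
                if v in _STOP_UNITS:
                    divisor = _STOP_UNITS[v]
                    stopped = True
                    break
                vals[year] = v
                year += 1
            if stopped:
                break
        if not vals:
            raise RwlParseError(f"series {sid!r} is empty")
        series[sid] = {y: w / divisor for y, w in vals.items()}

    rows = [
        {"tree": sid, "year": y, "RW": w}
        for sid, d in series.items()
        for y, w in sorted(d.items())
    ]
    return RingSeriesSet(pd.DataFrame(rows))


def write_rwl(rings: RingSeriesSet, path, precision: float = 0.01) -> None:
    """Write ring widths in Tucson decadal layout.

    `precision` 0.01 mm uses the 999 stop marker; 0.001 mm uses -9999.
    """
    if precision == 0.01:
        divisor, stop = 100, 999
    elif precision == 0.001:
        divisor, stop = 1000, -9999
    else:
        raise ValueError("precision must be 0.01 or 0.001 mm")
    with open(path, "w") as fh:
        for tree, grp in rings.data.groupby("tree", sort=False):
            years = grp["year"].to_numpy()
            vals = np.rint(grp["RW"].to_numpy() * divisor).astype(int)
            tokens = list(zip(years, vals)) + [(years[-1] + 1, stop)]
            i = 0
            while i < len(tokens):
                y0 = tokens[i][0]
                decade_end = (y0 // 10 + 1) * 10
                row = []
                while i < len(tokens) and tokens[i][0] < decade_end:
                    row.append(tokens[i][1])
                    i += 1
                fh.write(
                    f"{str(tree)[:8]:<8}{y0:>4} "
                    + " ".join(f"{v:>5d}" for v in row)
                    + "\n"
                )


def read_long_csv(path) -> RingSeriesSet:
    """Read a long-format ring-trait CSV (tree, year, RW[, WD, CWT, TDr, TDt])."""
    df = pd.read_csv(path)
    missing = {"tree", "year", "RW"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    keep = ["tree", "year"] + [c for c in TRAIT_COLUMNS if c in df.columns]
    return RingSeriesSet(df[keep])


def write_long_csv(rings: RingSeriesSet, path) -> None:
    rings.data.to_csv(path, index=False)


def read_design(path) -> DesignTable:
    """Read the field-design CSV (tree, family, provenance, block, ...)."""
    return DesignTable(pd.read_csv(path))


def write_design(design: DesignTable, path) -> None:
    design.data.to_csv(path, index=False)


def read_genotypes(path, design: DesignTable | None = None) -> GenotypeMatrix:
    """Read a genotype CSV: first column tree id, remaining columns SNPs.

    Entries must be 0/1/2 or empty (missing). Raises on any other coding.
    """
    df = pd.read_csv(path)
    tree_col = df.columns[0]
    trees = list(df[tree_col])
    counts = df.drop(columns=[tree_col]).to_numpy(dtype=float)
    gm = GenotypeMatrix(counts, trees, snps=list(df.columns[1:]))
    if design is not None:
        gm.attach_design(design)
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.counts, columns=gm.snps)
    # keep 0/1/2 as integers where not missing
    df.insert(0, "tree", gm.trees)
    df.to_csv(path, index=False, float_format="%.0f")


def read_vcf(path, design: DesignTable | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into 0/1/2 alt-allele counts.

    Requires cyvcf2; multi-allelic records are rejected.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    trees = list(vcf.samples)
    snps, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        snps.append(var.ID or f"{var.CHROM}:{var.POS}")
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 2] = np.nan
        gt[gt == 3] = 2.0
        rows.append(gt)
    counts = np.column_stack(rows) if rows else np.empty((len(trees), 0))
    gm = GenotypeMatrix(counts, trees, snps=snps)
    if design is not None:
        gm.attach_design(design)
    return gm


def read_daily_climate(path) -> pd.DataFrame:
    """Read a daily climate CSV with columns date, tmin, tmax, tmean, prec, rh, vpd."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "tmin", "tmax", "tmean", "prec"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.sort_values("date").reset_index(drop=True)
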