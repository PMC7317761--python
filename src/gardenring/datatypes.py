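"""Core data containers for common-garden tree-ring analysis.

The package keeps three tabular containers, all thin validating wrappers
around :class:`pandas.DataFrame` / :class:`numpy.ndarray`:

* :class:`RingSeriesSet` — per-tree annual multi-trait ring series,
* :class:`DesignTable`  — tree → family → provenance → block mapping with
  planting coordinates and provenance-origin climate normals,
* :class:`GenotypeMatrix` — trees × SNP minor-allele counts (0/1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ring-level trait columns understood throughout the package.
#: RW ring width (mm), WD wood density (kg m^-3), CWT cell-wall thickness
#: (um), TDr/TDt radial/tangential tracheid diameters (um).
TRAIT_COLUMNS = ("RW", "WD", "CWT", "TDr", "TDt")


class RingSeriesSet:
    """Per-tree annual ring series in long format.

    Parameters
    ----------
    data
        Long-format frame with columns ``tree``, ``year``, ``RW`` and
        optionally further trait columns from :data:`TRAIT_COLUMNS`.
        Years must be contiguous within each tree (rings are counted from
        the pith; a missing calendar year means a dating problem, not a
        zero-width ring).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"tree", "year", "RW"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"ring table missing columns: {sorted(missing)}")
        data = data.copy()
        data["year"] = data["year"].astype(int)
        data = data.sort_values(["tree", "year"]).reset_index(drop=True)
        dup = data.duplicated(["tree", "year"])
        if dup.any():
            t, y = data.loc[dup.idxmax(), ["tree", "year"]]
            raise ValueError(f"duplicate record for tree {t!r} year {y}")
        for tree, grp in data.groupby("tree", sort=False):
            yrs = grp["year"].to_numpy()
            gaps = np.nonzero(np.diff(yrs) != 1)[0]
            if gaps.size:
                raise ValueError(
                    f"series {tree!r} has a gap after year {yrs[gaps[0]]}"
                )
        self.data = data

    # -- basic accessors -------------------------------------------------

    @property
    def trees(self) -> list:
        return list(dict.fromkeys(self.data["tree"]))

    @property
    def traits(self) -> list[str]:
        return [c for c in TRAIT_COLUMNS if c in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RingSeriesSet({len(self.trees)} trees, "
            f"{self.data['year'].min()}-{self.data['year'].max()}, "
            f"traits={self.traits})"
        )

    def first_year(self) -> pd.Series:
        """First ring year per tree (pith year of the measured sequence)."""
        return self.data.groupby("tree")["year"].min()

    def with_cambial_age(self) -> pd.DataFrame:
        """Return the long table with a 1-based ``age`` column appended."""
        out = self.data.copy()
        first = out.groupby("tree")["year"].transform("min")
        out["age"] = out["year"] - first + 1
        return out

    def wide(self, trait: str = "RW") -> pd.DataFrame:
        """Years x trees matrix for one trait (NaN outside a tree's span)."""
        if trait not in self.data.columns:
            raise KeyError(f"trait {trait!r} not present")
        return self.data.pivot(index="year", columns="tree", values=trait)


class DesignTable:
    """Common-garden field design: tree → family → provenance → block.

    Optional columns: planting coordinates ``x``/``y`` (metres), row-plot
    identifiers, and provenance-origin climate normals (``origin_MAT``,
    ``origin_MAP``, ``origin_ADD``, ``origin_summer_smi``).
    """

    REQUIRED = ("tree", "family", "provenance", "block")
    ORIGIN_COLUMNS = ("origin_MAT", "origin_MAP", "origin_ADD", "origin_summer_smi")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        data = data.copy().reset_index(drop=True)
        if data["tree"].duplicated().any():
            dups = data.loc[data["tree"].duplicated(), "tree"].unique()[:5]
            raise ValueError(f"duplicate tree ids in design: {list(dups)}")
        self.data = data

    @property
    def trees(self) -> list:
        return list(self.data["tree"])

    @property
    def provenances(self) -> list:
        return list(dict.fromkeys(self.data["provenance"]))

    @property
    def families(self) -> list:
        return list(dict.fromkeys(self.data["family"]))

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DesignTable({len(self)} trees, {len(self.provenances)} provenances, "
            f"{len(self.families)} families, "
            f"{self.data['block'].nunique()} blocks)"
        )

    def origin_climate(self) -> pd.DataFrame:
        """Provenance-origin climate normals, one row per provenance."""
        cols = [c for c in self.ORIGIN_COLUMNS if c in self.data.columns]
        if not cols:
            raise ValueError("design table carries no origin climate columns")
        out = self.data.groupby("provenance")[cols].first()
        return out

    def check_trees(self, trees) -> None:
        """Raise if any of `trees` is absent from the design."""
        missing = sorted(set(trees) - set(self.data["tree"]))
        if missing:
            raise ValueError(
                f"{len(missing)} tree(s) absent from design table: {missing[:10]}"
            )


class GenotypeMatrix:
    """Trees x SNPs biallelic minor-allele counts with provenance labels.

    `counts` is float with NaN for missing genotypes; valid entries are
    {0, 1, 2}.
    """

    def __init__(self, counts: np.ndarray, trees, snps=None,
                 provenance: pd.Series | None = None,
                 family: pd.Series | None = None):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("genotype counts must be 2-D (trees x SNPs)")
        bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-biallelic genotype coding {counts[i, j]!r} "
                f"at tree index {i}, SNP index {j}"
            )
        if np.isnan(counts).all(axis=0).any():
            raise ValueError("SNP with 100% missingness present")
        if len(trees) != counts.shape[0]:
            raise ValueError("tree id count does not match genotype rows")
        self.counts = counts
        self.trees = list(trees)
        self.snps = list(snps) if snps is not None else [
            f"snp{j}" for j in range(counts.shape[1])
        ]
        if len(self.snps) != counts.shape[1]:
            raise ValueError("SNP id count does not match genotype columns")
        self.provenance = None if provenance is None else pd.Series(
            np.asarray(provenance), index=self.trees
        )
        self.family = None if family is None else pd.Series(
            np.asarray(family), index=self.trees
        )

    @property
    def n_trees(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_trees} trees x {self.n_snps} SNPs)"

    def attach_design(self, design: DesignTable) -> "GenotypeMatrix":
        """Fill provenance/family labels from a design table (by tree id)."""
        design.check_trees(self.trees)
        d = design.data.set_index("tree")
        self.provenance = d.loc[self.trees, "provenance"]
        self.family = d.loc[self.trees, "family"]
        return self


@dataclass
class TruthRecord:
    """Ground truth stored alongside every simulated dataset.

    Keeps the generating parameter values and the realized random effects
    so parameter-recovery tests can compare estimates against the truth.
    """

    params: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        return {"params": conv(self.params), "effects": conv(self.effects)}
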