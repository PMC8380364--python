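"""OTU abundance tables: container, TSV round-trip, normalization, filters.

The table is oriented rows = samples, columns = taxa throughout the package.
Counts and relative-abundance tables share one container distinguished by a
``kind`` flag; operations that require one kind check it explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "to_relative",
    "filter_otus",
    "aggregate_by_rank",
    "read_taxonomy",
    "write_taxonomy",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Malformed tabular input (ragged, duplicated ids, negative values...)."""


@dataclass
class OtuTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with taxon-id columns. Counts are
        integers, relative abundances floats with rows summing to 1.
    kind
        ``"counts"`` or ``"relative"``.
    """

    data: pd.DataFrame
    kind: Literal["counts", "relative"] = "counts"
    # column subsets of a relative table (e.g. after filtering) keep
    # kind="relative" but legitimately sum to < 1 per row
    check_sums: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        vals = self.data.to_numpy()
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative value at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.kind == "relative" and self.check_sums and len(self.data):
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-6
            if bad.any():
                raise FormatError(
                    "rows do not sum to 1 for samples "
                    f"{self.data.index[bad].tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.kind == other.kind and self.data.equals(other.data)


@dataclass
class TaxonomyMap:
    """taxon_id -> lineage mapping; missing ranks read as 'unclassified'."""

    lineages: pd.DataFrame  # indexed by taxon id, columns a subset of RANKS

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise FormatError("duplicate taxon ids in taxonomy")

    def rank_of(self, taxon_id: str, rank: str) -> str:
        if rank not in self.lineages.columns:
            raise KeyError(f"unknown rank {rank!r}")
        if taxon_id not in self.lineages.index:
            return "unclassified"
        val = self.lineages.loc[taxon_id, rank]
        if pd.isna(val) or val == "":
            return "unclassified"
        return str(val)


def _check_orientation(df: pd.DataFrame) -> None:
    # Reject a table that looks transposed (taxon-like row ids, sample-like
    # column ids) rather than silently flipping it.
    rows_otu = sum(str(r).lower().startswith("otu") for r in df.index)
    cols_otu = sum(str(c).lower().startswith("otu") for c in df.columns)
    if len(df) and rows_otu > len(df.index) / 2 and cols_otu <= len(df.columns) / 2:
        raise FormatError(
            "table looks transposed (row ids look like OTU ids); expected "
            "rows = samples, columns = taxa — transpose the input explicitly"
        )


def read_otu_table(path: str | Path, kind: Literal["counts", "relative"] = "counts") -> OtuTable:
    """Read a TSV with a header row of taxon ids and first column of sample ids.

    Lines starting with '#' are ignored. Counts are parsed as integers,
    relative abundances as floats.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing/ragged value in row {r!r} of {path}")
    _check_orientation(df)
    if kind == "counts":
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"non-integer counts in {path}")
        df = df.astype(np.int64)
    else:
        df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df, kind=kind)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    taxonomy.lineages.to_csv(path, sep="\t", index_label="taxon_id")


def to_relative(table: OtuTable) -> OtuTable:
    """Row-normalize a counts table to relative abundances."""
    if table.kind != "counts":
        raise ValueError("to_relative expects a counts table")
    vals = table.values.astype(float)
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise ValueError(
            f"all-zero sample rows: {table.data.index[zero].tolist()}"
        )
    rel = vals / sums[:, None]
    return OtuTable(pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
                    kind="relative")


def filter_otus(
    table: OtuTable,
    min_mean_abundance: float,
    min_prevalence: float,
    *,
    inclusive: bool = False,
) -> OtuTable:
    """Apply the abundance/prevalence inclusion filter.

    Keeps taxa whose mean relative abundance exceeds ``min_mean_abundance``
    AND that are nonzero in more than ``min_prevalence`` of samples. Strict
    ``>`` comparisons by default; ``inclusive=True`` switches to ``>=``.
    Typical settings: 0.0005 / 0.01 for the association scan, 0.001 for
    co-abundance-group construction.
    """
    if table.kind != "relative":
        raise ValueError("filter_otus expects a relative-abundance table")
    for name, thr in (("min_mean_abundance", min_mean_abundance),
                      ("min_prevalence", min_prevalence)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    vals = table.values
    mean_ab = vals.mean(axis=0)
    prev = (vals > 0).mean(axis=0)
    if inclusive:
        keep = (mean_ab >= min_mean_abundance) & (prev >= min_prevalence)
    else:
        keep = (mean_ab > min_mean_abundance) & (prev > min_prevalence)
    return OtuTable(table.data.loc[:, keep], kind=table.kind, check_sums=False)


def aggregate_by_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum taxon columns that share a lineage value at ``rank``.

    Taxa without a mapping collapse into an ``unclassified`` bucket. Row
    sums are preserved exactly (pure column regrouping).
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}; one of {RANKS}")
    if rank not in taxonomy.lineages.columns:
        raise KeyError(f"taxonomy has no {rank!r} column")
    groups = [taxonomy.rank_of(t, rank) for t in table.taxon_ids]
    agg = table.data.T.groupby(pd.Index(groups, name=rank)).sum().T
    agg = agg.sort_index(axis=1)
    return OtuTable(agg, kind=table.kind)
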