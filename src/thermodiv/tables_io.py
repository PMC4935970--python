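"""OTU tables and sample metadata: reading, writing, site pooling, rarefaction.

An OTU table is an integer count matrix with OTUs as rows and samples as
columns.  Site-level analyses sum counts over each site's replicate samples;
richness comparisons across samples of unequal sequencing depth go through
rarefaction (random subsampling without replacement to a common depth).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "RAREFACTION_DEPTHS",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "pool_by_site",
    "rarefy",
]

#: Rarefaction depths used for the three marker genes (reads per sample):
#: the global minimum sample depth for each gene's sample set.
RAREFACTION_DEPTHS = {"16S": 25_901, "ITS": 13_688, "nifH": 16_000}

#: Metadata columns that are properties of a site, not of a single sample.
SITE_LEVEL_VARIABLES = ("temperature_c", "precipitation_mm", "plant_richness")


class TableValidationError(ValueError):
    """Raised when an OTU table violates its structural invariants."""


@dataclass
class OtuTable:
    """Integer OTU-by-sample count matrix with an optional sample->site map.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer matrix; index = OTU ids, columns = sample ids.
    site_of : dict, optional
        Maps each sample id to a site id.  Required for site-level
        operations (pooling, site alpha profiles).
    """

    counts: pd.DataFrame
    site_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise TableValidationError("counts must be integral")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise TableValidationError("counts must be nonnegative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sites(self) -> dict[str, list[str]]:
        """Group sample ids by site, preserving column order."""
        if self.site_of is None:
            raise TableValidationError("no sample->site mapping attached")
        missing = [s for s in self.sample_ids if s not in self.site_of]
        if missing:
            raise TableValidationError(f"samples lack a site assignment: {missing}")
        groups: dict[str, list[str]] = {}
        for s in self.sample_ids:
            groups.setdefault(self.site_of[s], []).append(s)
        return groups


@dataclass
class SampleMetadata:
    """Per-sample environmental metadata with a site column.

    Holds one row per sample.  Site-level variables (mean annual temperature,
    precipitation, plant richness) repeat across a site's samples; per-sample
    soil variables (pH, moisture, total C, total N, ...) are averaged to the
    site mean when a site-level view is requested.
    """

    table: pd.DataFrame  # index = sample_id, must include a 'site_id' column

    def __post_init__(self) -> None:
        if "site_id" not in self.table.columns:
            raise TableValidationError("metadata needs a 'site_id' column")
        if self.table.index.has_duplicates:
            raise TableValidationError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def site_of(self) -> dict[str, str]:
        return self.table["site_id"].to_dict()

    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c != "site_id"]

    def site_table(self) -> pd.DataFrame:
        """One row per site: arithmetic mean of each numeric variable.

        Site-level variables are constant within a site, so their mean is
        just the site value.
        """
        num = self.table.select_dtypes("number").columns
        return self.table.groupby(self.table["site_id"])[list(num)].mean()

    def frame(self, level: str = "sample") -> pd.DataFrame:
        if level == "sample":
            return self.table.drop(columns="site_id")
        if level == "site":
            return self.site_table()
        raise ValueError(f"level must be 'sample' or 'site', got {level!r}")


def read_otu_table(path, metadata: SampleMetadata | None = None) -> OtuTable:
    """Read a tab-separated OTU table (first row sample ids, first column OTU ids).

    The top-left header cell is ignored.  Every data cell must parse as a
    nonnegative integer; the offending row/column is named otherwise.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableValidationError(f"{path}: empty OTU table") from exc
    if df.shape[1] == 0:
        raise TableValidationError(f"{path}: no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0))) | (vals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableValidationError(
                f"{path}: cell at OTU {row!r}, sample {col!r} is not a "
                f"nonnegative integer: {df.loc[row, col]!r}"
            )
        parsed[col] = vals.astype(np.int64)
    site_of = metadata.site_of if metadata is not None else None
    return OtuTable(parsed, site_of=site_of)


def write_otu_table(t: OtuTable, path) -> None:
    t.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path) -> SampleMetadata:
    """Read a metadata TSV with columns sample_id, site_id, <variables...>."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    if "sample_id" not in df.columns:
        raise TableValidationError(f"{path}: metadata needs a 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def pool_by_site(t: OtuTable) -> OtuTable:
    """Sum each OTU's counts over all samples of a site.

    Output columns are site ids in order of first appearance; the grand
    total of counts is conserved.
    """
    groups = t.sites()
    pooled = pd.DataFrame(
        {site: t.counts[cols].sum(axis=1) for site, cols in groups.items()}
    )
    return OtuTable(pooled, site_of={s: s for s in pooled.columns})


def _column_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Substream keyed on the sample label (not its position) so that
    # reordering columns does not change any sample's subsample.
    digest = hashlib.sha256(sample_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def rarefy(t: OtuTable, depth: int, seed: int, on_small: str = "error") -> OtuTable:
    """Subsample every column to exactly ``depth`` reads without replacement.

    Each column's retained counts follow a multivariate hypergeometric draw
    from its read multiset.  Deterministic given ``seed``; each sample gets
    an independent substream keyed on its id.

    Parameters
    ----------
    depth : int
        Target reads per sample; must not exceed any retained column total.
    on_small : {"error", "drop"}
        What to do with samples whose total is below ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    if on_small not in {"error", "drop"}:
        raise ValueError("on_small must be 'error' or 'drop'")
    totals = t.counts.sum(axis=0)
    small = list(totals.index[totals < depth])
    if small:
        if on_small == "error":
            raise ValueError(
                f"depth {depth} exceeds the total of sample(s) {small}; "
                "pass on_small='drop' to discard them"
            )
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d sample(s) below depth %d: %s", len(small), depth, small
        )
    keep = [s for s in t.sample_ids if s not in small]
    if not keep:
        raise ValueError("no samples at or above the requested depth")
    out = {}
    for s in keep:
        col = t.counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col.copy()
        else:
            rng = _column_rng(seed, s)
            out[s] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=t.counts.index, columns=keep)
    site_of = None
    if t.site_of is not None:
        site_of = {s: t.site_of[s] for s in keep if s in t.site_of}
    return OtuTable(rarefied, site_of=site_of)
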