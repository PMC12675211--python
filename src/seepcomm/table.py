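"""Community feature tables: reading, writing, rarefaction, relative abundance.

The central container is :class:`CommunityTable`, a thin validated wrapper
around a pandas DataFrame oriented taxa x samples. Counts are non-negative;
a table flagged ``is_relative`` holds per-sample proportions summing to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "rarefy",
    "relative_abundance",
]


@dataclass
class CommunityTable:
    """Taxa x samples abundance matrix with identifier bookkeeping.

    Parameters
    ----------
    data:
        DataFrame with taxon ids as the index and sample ids as columns.
    is_relative:
        True when each sample column holds proportions summing to 1.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size == 0:
            raise ValueError("no data rows")
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric values in feature table")
        if np.any(~np.isfinite(values)):
            raise ValueError("non-finite values in feature table")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at taxon {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = cols[np.abs(sums - 1.0) > 1e-9].tolist()
                raise ValueError(f"relative columns do not sum to 1: {bad}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Matrix view (taxa x samples)."""
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "CommunityTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CommunityTable(self.data[list(sample_ids)].copy(), self.is_relative)

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.data.sum(axis=1) > 0
        return CommunityTable(self.data.loc[keep].copy(), self.is_relative)


def read_feature_table(path, orientation: str = "taxa_rows") -> CommunityTable:
    """Read a TSV feature table (header row, identifier first column).

    ``orientation`` is either ``taxa_rows`` (QIIME-export convention, the
    default) or ``samples_rows``; the returned table is always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell at row {bad[0]!r}, column {col!r}"
            )
        if coerced.isna().any():
            raise ValueError(f"missing value in column {col!r}")
        df[col] = coerced
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    return CommunityTable(df)


def write_feature_table(table: CommunityTable, path, orientation: str = "taxa_rows") -> None:
    df = table.data if orientation == "taxa_rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (sample id first column).

    Geochemical columns are coerced to float; empty cells stay NaN and are
    reported, never silently zeroed.
    """
    md = pd.read_csv(path, sep="\t", index_col=0)
    if md.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    md.index = md.index.astype(str)
    numeric = md.select_dtypes(include=[np.number])
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        logger.warning("metadata contains %d missing numeric values", n_missing)
    return md


def rarefy(
    table: CommunityTable,
    depth: int | None = None,
    seed: int = 0,
    strict: bool = False,
) -> CommunityTable:
    """Rarefy each sample to ``depth`` reads by subsampling without replacement.

    ``depth`` defaults to the minimum sample total. Samples whose total is
    below ``depth`` are dropped with a warning (or raise when ``strict``).
    The draw is a multivariate hypergeometric per sample, so no rarefied
    count can exceed its original count and every kept column sums exactly
    to ``depth``. Deterministic given ``seed``.
    """
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        if strict:
            raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below rarefaction depth {depth}: {shallow}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = {}
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            continue
        if totals[j] == depth:
            out[sid] = counts[:, j]
        else:
            out[sid] = rng.multivariate_hypergeometric(counts[:, j], depth)
    if not out:
        raise ValueError("no samples at or above rarefaction depth")
    df = pd.DataFrame(out, index=table.data.index)
    return CommunityTable(df)


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Convert counts to per-sample proportions."""
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    return CommunityTable(table.data / sums, is_relative=True)
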