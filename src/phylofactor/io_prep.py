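"""Reading and preprocessing of taxon count tables.

Sequence-count tables carry only relative information: the total count per
sample is an artifact of sequencing depth, so all downstream analysis works
on compositions (strictly positive columns summing to one).  This module
covers the standard preprocessing chain for such data:

    read counts -> prevalence / mean-count filters -> zero replacement
    (pseudo-counts on zero cells only) -> closure -> log-ratio transforms.

Tables are taxa x samples throughout.  Natural logarithms are used in every
log-ratio quantity so that fold-ratio back-conversion is consistent across
the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "CompositionTable",
    "read_count_table",
    "read_metadata",
    "read_taxonomy",
    "filter_by_prevalence",
    "filter_by_mean_count",
    "replace_zeros",
    "close_to_composition",
    "clr_transform",
    "align_samples",
]

#: Default pseudo-count added to zero cells before closure.
DEFAULT_PSEUDOCOUNT = 0.65


@dataclass
class CountTable:
    """A non-negative taxa x samples count matrix with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample id.
    taxonomy
        Optional map from taxon id to a semicolon-delimited lineage string
        (Greengenes style, ranks ordered root to tip).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        if idx.duplicated().any():
            raise ValueError(f"duplicate taxon ids: {sorted(set(idx[idx.duplicated()]))}")
        if cols.duplicated().any():
            raise ValueError(f"duplicate sample ids: {sorted(set(cols[cols.duplicated()]))}")
        if self.counts.size == 0:
            raise ValueError("empty count table")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(idx)
            if unknown:
                raise ValueError(f"taxonomy keys not in table: {sorted(unknown)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class CompositionTable:
    """Strictly positive relative abundances; every sample column sums to 1."""

    relabund: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.relabund.to_numpy(dtype=float)
        if (values <= 0).any():
            raise ValueError("composition entries must be strictly positive")
        colsums = values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise ValueError("composition columns must sum to 1 (run close_to_composition)")
        if self.relabund.index.duplicated().any() or self.relabund.columns.duplicated().any():
            raise ValueError("duplicate taxon or sample ids")

    @property
    def taxa(self) -> list[str]:
        return list(self.relabund.index)

    @property
    def samples(self) -> list[str]:
        return list(self.relabund.columns)

    @property
    def values(self) -> np.ndarray:
        return self.relabund.to_numpy(dtype=float)


def read_count_table(path, orientation: str = "taxa-rows") -> CountTable:
    """Read a delimited count table (TSV or CSV, sniffed from the header).

    ``orientation`` states whether rows are taxa (``"taxa-rows"``) or samples
    (``"samples-rows"``); the returned table is always taxa x samples.
    """
    df = _read_delimited(path)
    if orientation == "samples-rows":
        df = df.T
    elif orientation != "taxa-rows":
        raise ValueError(f"orientation must be 'taxa-rows' or 'samples-rows', got {orientation!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        cell = bad[bad].index[0]
        raise ValueError(f"non-numeric cell at {cell}")
    return CountTable(numeric)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata keyed by sample id (first column)."""
    df = _read_delimited(path)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df


def read_taxonomy(path) -> dict[str, str]:
    """Read a two-column (taxon id, lineage string) table into a dict."""
    df = _read_delimited(path)
    return {str(k): str(v) for k, v in df.iloc[:, 0].items()}


def _read_delimited(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def filter_by_prevalence(table: CountTable, min_samples: int) -> CountTable:
    """Keep taxa with nonzero counts in at least ``min_samples`` samples."""
    n = len(table.samples)
    if not 0 <= min_samples <= n:
        raise ValueError(f"min_samples must be in [0, {n}], got {min_samples}")
    prevalence = (table.counts.to_numpy() > 0).sum(axis=1)
    keep = prevalence >= min_samples
    if not keep.any():
        raise ValueError("prevalence filter removed all taxa")
    return _subset_taxa(table, keep)


def filter_by_mean_count(table: CountTable, min_mean: float) -> CountTable:
    """Keep taxa whose arithmetic mean count across all samples >= ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = table.counts.to_numpy().mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("mean-count filter removed all taxa")
    return _subset_taxa(table, keep)


def _subset_taxa(table: CountTable, keep: np.ndarray) -> CountTable:
    counts = table.counts.loc[keep]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {t: s for t, s in table.taxonomy.items() if t in set(counts.index)}
    return CountTable(counts, taxonomy)


def replace_zeros(table: CountTable | pd.DataFrame, pseudo: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Replace zero cells with ``pseudo``; nonzero cells are left untouched.

    This is zeros-only replacement (a pseudo-count added to the zero entries),
    not a global shift of the whole table.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    df = table.counts if isinstance(table, CountTable) else table
    out = df.astype(float).copy()
    out[out == 0] = pseudo
    return out


def close_to_composition(table: pd.DataFrame) -> CompositionTable:
    """Divide each sample column by its sum (closure onto the simplex)."""
    if isinstance(table, CompositionTable):
        table = table.relabund
    values = table.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("closure requires strictly positive entries; run replace_zeros first")
    closed = values / values.sum(axis=0, keepdims=True)
    return CompositionTable(pd.DataFrame(closed, index=table.index, columns=table.columns))


def clr_transform(comp: CompositionTable) -> pd.DataFrame:
    """Centered log-ratio transform: ln y_i minus the per-sample mean of ln y.

    Output columns sum to zero; rows are taxa on a log scale relative to the
    sample's geometric mean.
    """
    logs = np.log(comp.values)
    centered = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=comp.relabund.index, columns=comp.relabund.columns)


def align_samples(
    table: CountTable,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Restrict table and metadata to shared samples with complete covariates.

    Samples missing from the metadata, or with missing values in any requested
    covariate, are dropped with a warning; the sample order of the table is
    preserved.
    """
    if covariates:
        missing_cols = [c for c in covariates if c not in metadata.columns]
        if missing_cols:
            raise ValueError(f"covariates not in metadata: {missing_cols}")
    shared = [s for s in table.samples if s in metadata.index]
    meta = metadata.loc[shared]
    if covariates:
        complete = meta[covariates].notna().all(axis=1)
        meta = meta.loc[complete]
    dropped = [s for s in table.samples if s not in set(meta.index)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) without complete metadata: {dropped[:10]}"
            + ("..." if len(dropped) > 10 else ""),
            stacklevel=2,
        )
    if len(meta) == 0:
        raise ValueError("no samples remain after metadata alignment")
    counts = table.counts[list(meta.index)]
    return CountTable(counts, table.taxonomy), meta
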