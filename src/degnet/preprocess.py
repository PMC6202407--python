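"""Expression-matrix I/O, quantile normalization, and probe-to-gene collapse.

Expression matrices are plain pandas DataFrames: rows are probes or genes
(unique labels in the index), columns are arrays/samples, values are log2
intensities. TSV is the on-disk format (first column = row id, header row =
sample ids).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ParseError

logger = logging.getLogger(__name__)


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression table (first column row ids, header samples).

    Raises :class:`ParseError` with row/column coordinates for any cell that
    is not a finite number, and :class:`FormatError` for duplicate row or
    sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    return numeric.astype(float)


def write_expression(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Write an expression matrix as TSV (full float precision, round-trips)."""
    matrix.to_csv(path, sep="\t", index_label=index_label)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array onto the common distribution of per-rank column means.

    After normalization each column's sorted value vector equals the mean of
    the input columns' sorted vectors; within-column ranks are preserved.
    Ties within a column receive the mean of the reference quantiles they
    span, which makes the map idempotent and permutation-equivariant.
    """
    if matrix.size == 0:
        raise DomainError("cannot quantile-normalize an empty matrix")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("expression matrix contains non-finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # runs of tied values share the mean of the reference slots they span
        starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_col)) + 1))
        counts = np.diff(np.concatenate((starts, [n])))
        run_means = np.add.reduceat(reference, starts) / counts
        out[order, j] = np.repeat(run_means, counts)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def read_probe_map(path) -> pd.Series:
    """Read a two-column probe_id/gene_symbol TSV into a probe->gene Series.

    Each probe must map to exactly one gene; a probe listed twice with
    conflicting genes is a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise FormatError(f"probe map {path} needs 2 columns (probe, gene)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    mapping = pd.Series(genes.to_numpy(), index=probes.to_numpy(), name="gene")
    conflicts = mapping.groupby(level=0).nunique()
    if (conflicts > 1).any():
        bad = conflicts.index[conflicts > 1].tolist()
        raise FormatError(f"probes mapped to multiple genes: {bad[:5]}")
    return mapping[~mapping.index.duplicated()]


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the highest mean intensity across samples is
    kept verbatim (ties broken by input order). Probes absent from the map
    are dropped with a logged count.
    """
    mapped = matrix.index.intersection(probe_map.index)
    n_dropped = len(matrix.index) - len(mapped)
    if len(mapped) == 0:
        raise DomainError("no probe in the matrix is present in the probe map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = matrix.loc[mapped]
    genes = probe_map.loc[mapped]
    means = sub.mean(axis=1)
    # idxmax returns the first maximum, so ties resolve to input order
    best = means.groupby(genes.to_numpy()).idxmax()
    best = best.sort_index()
    out = sub.loc[best.to_numpy()]
    out.index = pd.Index(best.index, name="gene")
    return out
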