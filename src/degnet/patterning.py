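"""Sign-pattern clustering of DEGs across contrasts and G1-G6 grouping.

Each DEG receives a sign vector over the three contrasts (one entry per
contrast: +1 up, -1 down, 0 not significant). Nonzero sign vectors define
clusters — at most 3^3 - 1 = 26 of them — labeled canonically as e.g.
"+.+.0" in contrast order. Projecting the vector onto the two reprogrammed
populations (iMSC-like and sorted-iMSC-like contrasts, i.e. the last two
entries) defines six disjoint groups:

=========  ==================  =================================
group      (s_iMSC, s_sort)    meaning
=========  ==================  =================================
G1         (+1, 0)             up in iMSC only
G2         (+1, +1)            up in both
G3         (0, +1)             up in sort-iMSC only
G4         (-1, 0)             down in iMSC only
G5         (-1, -1)            down in both
G6         (0, -1)             down in sort-iMSC only
=========  ==================  =================================

Sign-discordant patterns ((+1,-1) or (-1,+1)) and (0,0) belong to no group.
Genes are ordered for heatmap display by agglomerative clustering of their
log2 fold changes (Euclidean distance, complete linkage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import DomainError, ParameterError

logger = logging.getLogger(__name__)

_SIGN_CHAR = {1: "+", 0: "0", -1: "-"}
_GROUP_OF = {(1, 0): "G1", (1, 1): "G2", (0, 1): "G3",
             (-1, 0): "G4", (-1, -1): "G5", (0, -1): "G6"}
GROUPS = tuple(f"G{i}" for i in range(1, 7))


def cluster_label(signs) -> str:
    """Canonical label of a sign vector, e.g. (+1, -1, 0) -> '+.-.0'."""
    try:
        return ".".join(_SIGN_CHAR[int(s)] for s in signs)
    except KeyError as exc:
        raise ParameterError(f"invalid sign entry {exc.args[0]!r}") from exc


def assign_group(signs) -> str:
    """Group id (G1..G6 or 'none') from a sign vector.

    Only the last two entries — the iMSC-like and sorted-fraction contrasts —
    determine the group; the first (MDSC-like) entry is ignored. Vectors with
    fewer than two entries cannot be grouped.
    """
    s = tuple(int(x) for x in signs)
    if any(x not in (-1, 0, 1) for x in s):
        raise ParameterError(f"invalid sign vector {signs!r}")
    if len(s) < 2:
        raise ParameterError("sign vector needs at least two contrasts")
    return _GROUP_OF.get(s[-2:], "none")


def assign_patterns(stats_by_contrast: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sign vectors, cluster labels and groups for all DEGs.

    ``stats_by_contrast`` maps contrast name (test condition) to a statistics
    table with a ``call`` column, all over the same gene universe. Genes
    significant in no contrast are excluded. Returns a DataFrame indexed by
    gene with one ``s_<contrast>`` column per contrast plus ``cluster`` and
    ``group``.
    """
    if not stats_by_contrast:
        raise ParameterError("need at least one contrast table")
    names = list(stats_by_contrast)
    universe = stats_by_contrast[names[0]].index
    for name, table in stats_by_contrast.items():
        if not table.index.equals(universe):
            raise DomainError(
                f"contrast {name!r} covers a different gene universe"
            )
    sign_of = {"up": 1, "down": -1, "ns": 0}
    signs = pd.DataFrame(
        {f"s_{name}": stats_by_contrast[name]["call"].map(sign_of)
         for name in names},
        index=universe,
    ).astype(int)
    de = signs[(signs != 0).any(axis=1)]
    arr = de.to_numpy()
    out = de.copy()
    out["cluster"] = [cluster_label(row) for row in arr]
    out["group"] = [assign_group(row) for row in arr]
    logger.info("assign_patterns: %d DEGs in %d clusters",
                len(out), out["cluster"].nunique())
    return out


def group_sizes(patterns: pd.DataFrame) -> dict[str, int]:
    """Gene counts of G1..G6 (zero-filled for empty groups)."""
    counts = patterns["group"].value_counts()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def hierarchical_order(lfc: pd.DataFrame) -> np.ndarray:
    """Leaf ordering of DEG rows for heatmap display.

    Agglomerative clustering with Euclidean distance and complete linkage;
    single-row input returns the identity ordering. The ordering is
    deterministic for a fixed input row order (scipy's linkage breaks ties
    by merge order).
    """
    values = lfc.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("log2fc matrix contains non-finite values")
    if len(values) < 2:
        return np.arange(len(values))
    tree = linkage(values, method="complete", metric="euclidean")
    return np.asarray(leaves_list(tree))


def hierarchical_linkage(lfc: pd.DataFrame) -> np.ndarray:
    """Complete-linkage Euclidean linkage matrix (for dendrogram rendering)."""
    values = lfc.to_numpy(dtype=float)
    if len(values) < 2:
        raise DomainError("need at least two rows to build a dendrogram")
    return linkage(values, method="complete", metric="euclidean")


def plot_heatmap(lfc: pd.DataFrame, path, *, order: np.ndarray | None = None,
                 vmax: float = 3.0) -> None:
    """Render the DEG log2-fold-change heatmap (green-black-red) to a file.

    Rows are ordered by ``order`` (default: :func:`hierarchical_order`);
    the palette follows the microarray convention of red for up- and green
    for downregulation, saturating at ``+-vmax`` log2 units.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if order is None:
        order = hierarchical_order(lfc)
    data = lfc.to_numpy(dtype=float)[order]
    cmap = LinearSegmentedColormap.from_list(
        "microarray", ["#00a000", "#000000", "#e00000"]
    )
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * lfc.shape[1], 6), constrained_layout=True
    )
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
                   interpolation="nearest")
    ax.set_xticks(range(lfc.shape[1]), lfc.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{lfc.shape[0]} DEGs")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_patterns(patterns: pd.DataFrame, path) -> None:
    """Write the pattern table as TSV (gene, per-contrast signs, cluster, group)."""
    patterns.to_csv(path, sep="\t", index_label="gene")
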