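"""EASE-score gene-set enrichment against user-supplied GO-BP collections.

The EASE score is the conservative variant of the one-tailed Fisher /
hypergeometric overrepresentation test used by DAVID: the overlap count k is
decremented by one before computing the upper tail, i.e.

    p_EASE = P[X >= max(k - 1, 0)],   X ~ Hypergeom(N, K, n)

with N the background size, K the term's members inside the background and n
the query-list size inside the background. A single-gene overlap (k = 1)
therefore never scores better than p = 1, which damps spurious hits from tiny
lists. Terms are flagged enriched at p < 0.05 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_ENRICH_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (GO-BP term): id, free-text description, members."""

    term_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.term_id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of gene sets with unique term ids."""

    sets: tuple[GeneSet, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate term ids: {dup[:5]}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)

    @property
    def term_ids(self) -> list[str]:
        return [s.term_id for s in self.sets]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term, description, members...) with case-normalized
    (upper-cased) gene symbols. Lines with fewer than 3 fields are format
    errors reported with their line number."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term, desc, *genes = fields
            members = frozenset(g.strip().upper() for g in genes if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} is empty")
            sets.append(GeneSet(term, desc, members))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.description, *sorted(s.genes)]))
            fh.write("\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term x query enrichment outcome (2x2 table counts + EASE p)."""

    term_id: str
    description: str
    N: int  # background size
    K: int  # term members in background
    n: int  # query genes in background
    k: int  # overlap
    ease_p: float
    enriched: bool


def ease_test(query, term: GeneSet, background,
              alpha: float = DEFAULT_ENRICH_ALPHA) -> EnrichmentResult:
    """EASE-score overrepresentation test of ``query`` against one term.

    Gene symbols are matched case-insensitively; the term is intersected
    with the background, and query genes outside the background are dropped
    with a logged count.
    """
    bg = {str(g).upper() for g in background}
    if not bg:
        raise DomainError("background gene list is empty")
    q = {str(g).upper() for g in query}
    unmatched = len(q - bg)
    if unmatched:
        logger.info("ease_test(%s): %d query genes outside the background",
                    term.term_id, unmatched)
    q &= bg
    members = {g.upper() for g in term.genes} & bg
    k = len(q & members)
    # EASE: remove one overlapping gene before taking the hypergeometric tail
    k_pen = max(k - 1, 0)
    p = float(hypergeom.sf(k_pen - 1, len(bg), len(members), len(q)))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        term_id=term.term_id, description=term.description,
        N=len(bg), K=len(members), n=len(q), k=k,
        ease_p=p, enriched=p < alpha,
    )


def enrich_query(query, collection: GeneSetCollection, background,
                 alpha: float = DEFAULT_ENRICH_ALPHA) -> pd.DataFrame:
    """EASE results for one gene list against every term in the collection."""
    rows = [ease_test(query, term, background, alpha) for term in collection]
    return pd.DataFrame([r.__dict__ for r in rows])


def enrich_groups(patterns: pd.DataFrame, collection: GeneSetCollection,
                  background, alpha: float = DEFAULT_ENRICH_ALPHA,
                  ) -> pd.DataFrame:
    """Per-group EASE enrichment table (group x term).

    ``patterns`` is the sign-pattern table with a ``group`` column; genes with
    group 'none' are ignored and empty groups are skipped with a log entry.
    Output columns: group, term_id, description, k, n, K, N, ease_p, enriched.
    """
    frames = []
    for group in sorted(g for g in patterns["group"].unique() if g != "none"):
        genes = patterns.index[patterns["group"] == group]
        if len(genes) == 0:
            logger.info("enrich_groups: group %s is empty, skipped", group)
            continue
        table = enrich_query(genes, collection, background, alpha)
        table.insert(0, "group", group)
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["group", "term_id", "description",
                     "N", "K", "n", "k", "ease_p", "enriched"]
        )
    return pd.concat(frames, ignore_index=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
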