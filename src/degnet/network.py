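"""Reconstruction of the DEG signaling network.

DEGs belonging to selected biological processes (e.g. cell-cycle- and
differentiation-related GO-BP terms) and to a list of signaling pathways
(default: Calcium, Jak-STAT, MAPK, Notch, TGF-beta, VEGF, Wnt and regulation
of the actin cytoskeleton) are connected by typed interactions read from
user-supplied KEGG/PPI tables. Directed edge types are activation, repression
and indirect activation; PPIs are undirected and deduplicated regardless of
orientation. Nodes carry both contrasts' log2 fold changes and a pathway lane
attribute for display.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

DIRECTED_TYPES = ("activation", "repression", "indirect_activation")
INTERACTION_TYPES = DIRECTED_TYPES + ("ppi",)

#: Signaling pathways used to restrict the network's gene universe.
DEFAULT_PATHWAYS = (
    "Calcium signaling pathway",
    "Jak-STAT signaling pathway",
    "MAPK signaling pathway",
    "Notch signaling pathway",
    "TGF-beta signaling pathway",
    "VEGF signaling pathway",
    "Wnt signaling pathway",
    "Regulation of actin cytoskeleton",
)

#: Minimal structural schema of the JSON export (validated by
#: :func:`validate_network_json`).
NETWORK_JSON_SCHEMA = {
    "type": "object",
    "required": ["nodes", "edges"],
    "node": {"required": ["id"], "optional": ["pathway", "log2fc"]},
    "edge": {"required": ["source", "target", "interaction"],
             "interaction": list(INTERACTION_TYPES)},
}


@dataclass(frozen=True)
class InteractionRecord:
    """One typed molecular interaction; PPIs are stored endpoint-sorted."""

    source: str
    target: str
    interaction: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.interaction not in INTERACTION_TYPES:
            raise FormatError(
                f"unknown interaction type {self.interaction!r}; "
                f"expected one of {INTERACTION_TYPES}"
            )

    @property
    def directed(self) -> bool:
        return self.interaction != "ppi"

    def canonical(self) -> "InteractionRecord":
        """Orientation-independent form (sorts endpoints of undirected edges)."""
        if self.directed or self.source <= self.target:
            return self
        return InteractionRecord(self.target, self.source,
                                 self.interaction, self.provenance)


def read_interactions(path) -> list[InteractionRecord]:
    """Parse a SIF / TSV interaction table into deduplicated records.

    Each non-empty line is ``source  type  target`` (tab- or
    whitespace-separated) with an optional fourth provenance column. Unknown
    type tokens and short lines are format errors reported with their line
    number. PPI edges are canonicalized (endpoints sorted) so that
    ``A ppi B`` and ``B ppi A`` collapse to a single record.
    """
    records: list[InteractionRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: need source, type, target "
                    f"(got {len(fields)} fields)"
                )
            source, itype, target = (f.strip() for f in fields[:3])
            provenance = fields[3].strip() if len(fields) > 3 else ""
            try:
                rec = InteractionRecord(source, target, itype,
                                        provenance).canonical()
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            key = (rec.source, rec.target, rec.interaction)
            if key in seen:
                continue
            seen.add(key)
            records.append(rec)
    return records


def select_process_degs(patterns: pd.DataFrame,
                        enrichment: pd.DataFrame,
                        collection,
                        process_terms: list[str],
                        pathway_membership: pd.DataFrame,
                        pathways: tuple[str, ...] = DEFAULT_PATHWAYS,
                        ) -> list[str]:
    """DEGs that belong to >= 1 selected process and >= 1 listed pathway.

    ``process_terms`` must appear in the enrichment table (they are the
    cell-cycle / differentiation processes represented by the DEG groups);
    term membership comes from ``collection`` (a GeneSetCollection).
    ``pathway_membership`` is a two-column gene/pathway table. Matching is
    case-insensitive on gene symbols. Returns a sorted gene list (original
    casing from the pattern table).
    """
    known_terms = set(enrichment["term_id"]) if len(enrichment) else set()
    missing = [t for t in process_terms if t not in known_terms]
    if missing:
        raise DomainError(
            f"process terms not present in the enrichment results: {missing}"
        )
    process_genes: set[str] = set()
    for t in process_terms:
        process_genes |= set(collection[t].genes)  # already upper-cased

    pw = pathway_membership.iloc[:, :2].copy()
    pw.columns = ["gene", "pathway"]
    wanted = {p.lower() for p in pathways}
    pathway_genes = {
        str(g).upper()
        for g, p in zip(pw["gene"], pw["pathway"])
        if str(p).lower() in wanted
    }

    selected = [
        g for g in patterns.index
        if str(g).upper() in process_genes and str(g).upper() in pathway_genes
    ]
    if not selected:
        logger.warning("select_process_degs: empty selection; the network "
                       "will have no nodes")
    return sorted(selected)


@dataclass
class NetworkModel:
    """Typed interaction network over a DEG list.

    ``graph`` is a :class:`networkx.MultiDiGraph`; undirected PPI edges are
    stored once in canonical (sorted-endpoint) orientation with attribute
    ``directed = False``. Nodes carry per-contrast ``log2fc_<contrast>``
    attributes and an optional ``pathway`` lane.
    """

    graph: nx.MultiDiGraph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, k) for u, v, k in self.graph.edges(keys=True)]

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(dict(self.graph.nodes(data=True)),
                                      orient="index")


def build_network(genes,
                  interactions: list[InteractionRecord],
                  stats_by_contrast: dict[str, pd.DataFrame] | None = None,
                  pathway_of: dict[str, str] | None = None,
                  ) -> NetworkModel:
    """Induced subgraph of the interaction set on ``genes``.

    Every gene becomes a node (isolated nodes are retained — they still
    occupy a pathway lane in the display); only interactions with both
    endpoints in the gene list become edges. Node attributes record each
    contrast's log2 fold change (0.0 when the gene is missing from a table)
    and the pathway lane. Nodes and edges are inserted in sorted order so
    exports are deterministic.
    """
    genes = sorted(dict.fromkeys(genes))
    if not genes:
        raise DomainError("gene list is empty")
    gene_set = set(genes)
    g = nx.MultiDiGraph()
    for gene in genes:
        attrs: dict = {}
        if stats_by_contrast:
            for cname, table in stats_by_contrast.items():
                lfc = table["log2fc"].get(gene, 0.0)
                attrs[f"log2fc_{cname}"] = float(lfc)
        if pathway_of is not None:
            attrs["pathway"] = pathway_of.get(gene, "")
        g.add_node(gene, **attrs)
    kept = [r.canonical() for r in interactions
            if r.source in gene_set and r.target in gene_set]
    kept = sorted(set(kept), key=lambda r: (r.source, r.target, r.interaction))
    for rec in kept:
        g.add_edge(rec.source, rec.target, key=rec.interaction,
                   interaction=rec.interaction, directed=rec.directed,
                   provenance=rec.provenance)
    return NetworkModel(g)


def export_network(net: NetworkModel, path, fmt: str | None = None) -> None:
    """Write the network as SIF, GraphML or JSON.

    ``fmt`` defaults to the file extension. SIF keeps only the edge list
    (annotations are dropped by design); GraphML and JSON round-trip nodes,
    edges and attributes losslessly.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, k in net.graph.edges(keys=True):
                fh.write(f"{u}\t{k}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(network_to_json(net), fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise FormatError(f"unknown export format {fmt!r} "
                          "(expected sif, graphml or json)")


def import_graphml(path) -> NetworkModel:
    g = nx.read_graphml(path, force_multigraph=True)
    return NetworkModel(nx.MultiDiGraph(g))


def network_to_json(net: NetworkModel) -> dict:
    nodes = [{"id": n, **{k: v for k, v in d.items()}}
             for n, d in net.graph.nodes(data=True)]
    edges = [{"source": u, "target": v, "interaction": d["interaction"],
              "directed": bool(d.get("directed", True)),
              "provenance": d.get("provenance", "")}
             for u, v, d in net.graph.edges(data=True)]
    return {"nodes": nodes, "edges": edges}


def network_from_json(obj: dict) -> NetworkModel:
    validate_network_json(obj)
    g = nx.MultiDiGraph()
    for node in obj["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "id"}
        g.add_node(node["id"], **attrs)
    for e in obj["edges"]:
        g.add_edge(e["source"], e["target"], key=e["interaction"],
                   interaction=e["interaction"],
                   directed=bool(e.get("directed", True)),
                   provenance=e.get("provenance", ""))
    return NetworkModel(g)


def validate_network_json(obj: dict) -> None:
    """Structural validation against :data:`NETWORK_JSON_SCHEMA`."""
    if not isinstance(obj, dict) or not {"nodes", "edges"} <= set(obj):
        raise FormatError("network JSON must have 'nodes' and 'edges'")
    ids = set()
    for node in obj["nodes"]:
        if not isinstance(node, dict) or "id" not in node:
            raise FormatError(f"node without id: {node!r}")
        ids.add(node["id"])
    for e in obj["edges"]:
        missing = {"source", "target", "interaction"} - set(e)
        if missing:
            raise FormatError(f"edge missing fields {sorted(missing)}: {e!r}")
        if e["interaction"] not in INTERACTION_TYPES:
            raise FormatError(f"unknown interaction {e['interaction']!r}")
        if e["source"] not in ids or e["target"] not in ids:
            raise FormatError(f"edge endpoint outside node set: {e!r}")


def read_pathway_membership(path) -> pd.DataFrame:
    """Read a two-column gene/pathway TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"pathway membership {path} needs 2 columns")
    return df
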