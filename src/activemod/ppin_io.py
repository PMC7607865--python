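"""Input/output for interaction networks, p-value tables, and detected modules.

Networks are held as :class:`networkx.Graph` objects: undirected, simple
(no self-loops, no parallel edges), with string node identifiers. Metadata
(source description, organism) lives in ``G.graph``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .module_detection import SteinerModule

logger = logging.getLogger(__name__)

#: Default floor for p = 0: smallest positive normal double. Keeps log(p)
#: finite while staying far below any p-value a rank test can produce.
P_FLOOR = float(np.finfo(np.float64).tiny)

# Column names used by the two BioGRID tab-delimited dialects.
_TAB3_ORG_A = "Organism ID Interactor A"
_TAB3_ORG_B = "Organism ID Interactor B"
_TAB2_ORG_A = "Organism Interactor A"
_TAB2_ORG_B = "Organism Interactor B"
_ENTREZ_A = "Entrez Gene Interactor A"
_ENTREZ_B = "Entrez Gene Interactor B"
_EXP_TYPE = "Experimental System Type"


@dataclass
class PValueTable:
    """Per-gene p-values of differential expression for one cell cluster.

    Parameters
    ----------
    entries
        Mapping from gene identifier to p-value in (0, 1]. Identifiers are
        unique; a p-value of exactly zero is clamped upstream.
    cluster_label
        Free-text label of the cell cluster the table belongs to.
    """

    entries: dict[str, float]
    cluster_label: str = ""

    def __post_init__(self) -> None:
        bad = {g: p for g, p in self.entries.items() if not (0.0 <= p <= 1.0)}
        if bad:
            raise ValidationError(f"p-values outside [0, 1]: {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def pvalues(self) -> np.ndarray:
        """P-values in deterministic (sorted-gene) order."""
        return np.array([self.entries[g] for g in sorted(self.entries)])


def _finish_graph(G: nx.Graph, source: str, organism: str = "") -> nx.Graph:
    """Drop self-loops, attach metadata, and reject empty networks."""
    loops = list(nx.selfloop_edges(G))
    if loops:
        logger.info("dropped %d self-loop(s)", len(loops))
        G.remove_edges_from(loops)
    G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_edges() == 0:
        raise EmptyNetworkError(f"no interactions left after reading {source}")
    G.graph["source"] = source
    G.graph["organism"] = organism
    return G


def read_biogrid(
    path: str | Path,
    organism_id: int | str,
    physical_only: bool = False,
) -> nx.Graph:
    """Read a BioGRID tab-delimited export (TAB2 or TAB3) into a simple graph.

    Only rows where *both* interactors belong to ``organism_id`` (an NCBI
    taxonomy identifier, e.g. 9606 for human) are kept. Nodes are Entrez
    GeneIDs rendered as strings. Duplicate rows and self-interactions are
    collapsed. With ``physical_only`` rows whose experimental system type is
    not ``physical`` (i.e. genetic interactions) are discarded.

    Raises
    ------
    FormatError
        If the file has no recognisable BioGRID header.
    EmptyNetworkError
        If no interaction survives the organism filter.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, low_memory=False)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"cannot parse {path} as tab-delimited text: {exc}") from exc

    if _TAB3_ORG_A in df.columns:
        org_a, org_b = _TAB3_ORG_A, _TAB3_ORG_B
    elif _TAB2_ORG_A in df.columns:
        org_a, org_b = _TAB2_ORG_A, _TAB2_ORG_B
    else:
        raise FormatError(
            f"{path} lacks BioGRID organism columns (neither TAB2 nor TAB3 header)"
        )
    for col in (_ENTREZ_A, _ENTREZ_B):
        if col not in df.columns:
            raise FormatError(f"{path} lacks required column {col!r}")

    org = str(organism_id)
    df = df[(df[org_a] == org) & (df[org_b] == org)]
    if physical_only and _EXP_TYPE in df.columns:
        df = df[df[_EXP_TYPE].str.lower() == "physical"]
    if df.empty:
        raise EmptyNetworkError(
            f"no interactions in {path} with both interactors in organism {org}"
        )

    G = nx.Graph()
    G.add_edges_from(zip(df[_ENTREZ_A], df[_ENTREZ_B]))
    return _finish_graph(G, source=f"BioGRID:{path.name}", organism=org)


def read_edge_list(path: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Read a generic two-column edge list into a simple undirected graph.

    Each non-empty, non-``#`` line holds exactly two identifiers separated by
    ``delimiter`` (default: any whitespace). Duplicate edges and self-loops
    are dropped with a logged count.
    """
    path = Path(path)
    G = nx.Graph()
    n_loops = n_dupes = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, found {len(parts)}"
                )
            u, v = parts
            if u == v:
                n_loops += 1
                continue
            if G.has_edge(u, v):
                n_dupes += 1
                continue
            G.add_edge(u, v)
    if n_loops or n_dupes:
        logger.info("dropped %d self-loop(s) and %d duplicate edge(s)", n_loops, n_dupes)
    if G.number_of_edges() == 0:
        raise EmptyNetworkError(f"{path} contains no usable edges")
    return _finish_graph(G, source=str(path.name))


def read_pvalues(
    path: str | Path,
    gene_col: str = "gene",
    p_col: str = "pvalue",
    sep: str | None = None,
    cluster_label: str = "",
    p_floor: float = P_FLOOR,
    dedupe: str = "error",
) -> PValueTable:
    """Read a delimited gene/p-value table.

    Parameters
    ----------
    gene_col, p_col
        Column names holding the gene identifier and the p-value.
    sep
        Field separator; ``None`` sniffs comma vs tab from the header line.
    p_floor
        Replacement for p = 0 (the scorer takes logarithms). Defaults to the
        smallest positive normal double.
    dedupe
        ``"error"`` (default) rejects duplicated gene identifiers;
        ``"min"`` keeps the smallest p-value per gene.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in (gene_col, p_col):
        if col not in df.columns:
            raise FormatError(
                f"{path} lacks column {col!r}; available: {list(df.columns)}"
            )

    df[gene_col] = df[gene_col].astype(str)
    dup = df[gene_col][df[gene_col].duplicated()].unique()
    if len(dup):
        if dedupe == "min":
            df = df.sort_values(p_col).drop_duplicates(gene_col, keep="first")
            logger.warning("merged %d duplicated gene(s), keeping min p", len(dup))
        else:
            raise ValidationError(f"duplicated gene identifiers: {sorted(dup)[:10]}")

    pv = pd.to_numeric(df[p_col], errors="coerce")
    if pv.isna().any():
        raise ValidationError(f"non-numeric p-values in {path}")
    if ((pv < 0) | (pv > 1)).any():
        bad = df.loc[(pv < 0) | (pv > 1), gene_col].tolist()
        raise ValidationError(f"p-values outside [0, 1] for genes {bad[:10]}")
    n_zero = int((pv == 0).sum())
    if n_zero:
        logger.warning("clamped %d zero p-value(s) to %.3g", n_zero, p_floor)
        pv = pv.clip(lower=p_floor)

    return PValueTable(
        entries=dict(zip(df[gene_col], pv.astype(float))),
        cluster_label=cluster_label or path.stem,
    )


# ---------------------------------------------------------------------------
# Module serialisation


def _module_record(module: "SteinerModule") -> dict:
    nodes = sorted(module.nodes)
    return {
        "objective": module.objective,
        "fdr": module.fdr,
        "tau": module.tau,
        "exact": module.exact,
        "backend": module.backend,
        "nodes": [
            {
                "id": v,
                "pvalue": module.pvalues.get(v),
                "weight": module.weights[v],
                "connector": v in module.connectors,
            }
            for v in nodes
        ],
        "tree_edges": sorted(tuple(sorted(e)) for e in module.tree_edges),
    }


def write_module(module: "SteinerModule", path: str | Path, format: str = "json") -> None:
    """Serialise a detected module.

    ``json`` and ``graphml`` round-trip exactly through :func:`read_module`;
    ``tsv`` is a flat per-node table (columns: node, pvalue, weight,
    connector) with the scalar metadata in ``#``-prefixed header lines.
    Connector nodes are members with negative weight (p >= tau) kept only to
    join the significant nodes.
    """
    path = Path(path)
    rec = _module_record(module)
    if format == "json":
        path.write_text(json.dumps(rec, indent=1, sort_keys=True) + "\n")
    elif format == "graphml":
        G = nx.Graph()
        # set via G.graph: nx.Graph(**attrs) reserves the "backend" keyword
        G.graph.update(
            objective=module.objective,
            fdr=module.fdr,
            tau=module.tau,
            exact=module.exact,
            backend=module.backend,
        )
        for nd in rec["nodes"]:
            G.add_node(
                nd["id"],
                pvalue=float("nan") if nd["pvalue"] is None else nd["pvalue"],
                weight=nd["weight"],
                connector=nd["connector"],
            )
        G.add_edges_from(rec["tree_edges"])
        nx.write_graphml(G, path)
    elif format == "tsv":
        lines = [
            f"# objective\t{module.objective!r}",
            f"# fdr\t{module.fdr!r}",
            f"# tau\t{module.tau!r}",
            f"# exact\t{module.exact}",
            "node\tpvalue\tweight\tconnector",
        ]
        for nd in rec["nodes"]:
            p = "" if nd["pvalue"] is None else repr(nd["pvalue"])
            lines.append(f"{nd['id']}\t{p}\t{nd['weight']!r}\t{int(nd['connector'])}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown module format {format!r}")


def read_module(path: str | Path, format: str = "json") -> "SteinerModule":
    """Re-read a module written by :func:`write_module` (json or graphml)."""
    from .module_detection import SteinerModule

    path = Path(path)
    if format == "json":
        rec = json.loads(path.read_text())
        nodes = {nd["id"] for nd in rec["nodes"]}
        return SteinerModule(
            nodes=nodes,
            tree_edges=[tuple(e) for e in rec["tree_edges"]],
            weights={nd["id"]: nd["weight"] for nd in rec["nodes"]},
            pvalues={
                nd["id"]: nd["pvalue"] for nd in rec["nodes"] if nd["pvalue"] is not None
            },
            objective=rec["objective"],
            fdr=rec["fdr"],
            tau=rec["tau"],
            exact=rec["exact"],
            backend=rec["backend"],
        )
    if format == "graphml":
        G = nx.read_graphml(path)
        return SteinerModule(
            nodes=set(G.nodes),
            tree_edges=[tuple(e) for e in G.edges],
            weights={v: G.nodes[v]["weight"] for v in G.nodes},
            pvalues={
                v: G.nodes[v]["pvalue"]
                for v in G.nodes
                if not math.isnan(G.nodes[v].get("pvalue", float("nan")))
            },
            objective=G.graph["objective"],
            fdr=G.graph["fdr"],
            tau=G.graph["tau"],
            exact=G.graph["exact"],
            backend=G.graph["backend"],
        )
    raise ValidationError(f"unknown module format {format!r}")


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Write a graph as a two-column tab-separated edge list."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u}\t{v}\n")


def write_pvalues(table: PValueTable, path: str | Path) -> None:
    """Write a p-value table as CSV (columns: gene, pvalue)."""
    pd.DataFrame(
        {"gene": sorted(table.entries), "pvalue": [table.entries[g] for g in sorted(table.entries)]}
    ).to_csv(path, index=False)
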