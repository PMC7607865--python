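"""Maximum-weight connected subgraph (MWCS) detection on node-weighted PPINs.

The pipeline assembled here: score every measured gene with the BUM-derived
weight W(p), restrict the interaction network to scored nodes (or penalise
unmeasured ones), shift weights into a prize-collecting Steiner tree (PCST)
instance, and solve exactly for the connected subgraph of maximum total
weight — the *active module*. The weight shift is exact: for any tree T,

    sum of prizes over T - (|T| - 1) * edge_cost
        = sum of weights over T - w_floor,

with ``w_floor = min(0, min weight)`` and ``edge_cost = -w_floor``, so PCST
and MWCS optima coincide.

The default solver is an exact mixed-integer program (HiGHS via
``scipy.optimize.milp``): binary node-selection variables with a
single-commodity flow from one chosen root certify connectivity. A
brute-force enumerator over all connected induced subgraphs serves as an
independent oracle for small instances, and a greedy backend is available
for graphs beyond the exact-size bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .bum_model import BumFit, ScoringScheme, fit_bum, node_score, scoring_scheme
from .errors import NoSignalError, SolverError, ValidationError
from .ppin_io import PValueTable

logger = logging.getLogger(__name__)

#: Largest post-preprocessing component the exact backend accepts by default.
EXACT_SIZE_BOUND = 2000

#: Hard cap for the brute-force enumerator (2**n subsets).
BRUTE_FORCE_MAX = 15


@dataclass
class NodeWeightedGraph:
    """A PPIN restricted to scored nodes, each carrying a signed weight."""

    graph: nx.Graph
    weights: dict[str, float]
    scheme: ScoringScheme
    pvalues: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    missing_policy: str = "drop"

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.weights)
        if missing:
            raise ValidationError(f"nodes without weights: {sorted(missing)[:10]}")


@dataclass
class PCSTInstance:
    """Prize-collecting Steiner tree instance equivalent to an MWCS instance.

    ``offset`` is ``w_floor``; subtracting it from every node weight makes
    all prizes non-negative, and charging ``-w_floor`` per tree edge repays
    the shift for every node beyond the first.
    """

    graph: nx.Graph
    prizes: dict[str, float]
    edge_cost: float
    offset: float

    def tree_objective(self, tree_nodes) -> float:
        """PCST objective of a candidate tree on ``tree_nodes``."""
        k = len(tree_nodes)
        return sum(self.prizes[v] for v in tree_nodes) - (k - 1) * self.edge_cost


@dataclass
class SteinerModule:
    """A detected active module.

    ``connectors`` are members with negative weight (p >= tau): genes that
    are not themselves significant but are kept because they join the
    significant ones into one connected subnetwork.
    """

    nodes: set[str]
    tree_edges: list[tuple[str, str]]
    weights: dict[str, float]
    objective: float
    pvalues: dict[str, float] = field(default_factory=dict)
    fdr: float | None = None
    tau: float | None = None
    exact: bool = True
    backend: str = "exact"

    @property
    def connectors(self) -> set[str]:
        return {v for v in self.nodes if self.weights[v] < 0}

    @property
    def n_significant(self) -> int:
        return sum(1 for v in self.nodes if self.weights[v] > 0)

    def size(self) -> int:
        return len(self.nodes)

    def recomputed_objective(self) -> float:
        return sum(self.weights[v] for v in self.nodes)


# ---------------------------------------------------------------------------
# Construction


def build_weighted_network(
    ppin: nx.Graph,
    table: PValueTable,
    fdr: float,
    missing_policy: str = "drop",
    scheme: ScoringScheme | None = None,
) -> NodeWeightedGraph:
    """Attach BUM scores to the PPIN nodes that carry p-values.

    With ``missing_policy="drop"`` (the default) nodes without expression
    data are removed; with ``"penalty"`` they are retained at a fixed
    negative weight equal to the minimum observed score, so they can still
    act as connectors but never improve the objective on their own. Genes in
    the table but absent from the network are counted and ignored.

    If ``scheme`` is given it is used as-is (the sweep fits the mixture once
    and reuses it); otherwise the BUM model is fitted to the table here.
    """
    if missing_policy not in ("drop", "penalty"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    if scheme is None:
        fit = fit_bum(table.pvalues())
        scheme = scoring_scheme(fit, fdr)

    measured = set(ppin.nodes) & table.genes
    if not measured:
        raise ValidationError("no overlap between network nodes and p-value table")
    n_ignored = len(table.genes - set(ppin.nodes))
    if n_ignored:
        logger.info("%d gene(s) with p-values absent from the network", n_ignored)

    pvals = {v: table.entries[v] for v in measured}
    weights = {v: float(node_score(p, scheme)) for v, p in pvals.items()}

    if missing_policy == "drop":
        sub = ppin.subgraph(measured).copy()
        dropped = sorted(set(ppin.nodes) - measured)
    else:
        sub = ppin.copy()
        penalty = min(weights.values())
        for v in set(ppin.nodes) - measured:
            weights[v] = penalty
        dropped = []
    # isolated measured nodes stay: a lone node can be the optimal module
    weights = {v: weights[v] for v in sub.nodes}
    pvals = {v: p for v, p in pvals.items() if v in weights}
    return NodeWeightedGraph(
        graph=sub,
        weights=weights,
        scheme=scheme,
        pvalues=pvals,
        dropped=dropped,
        missing_policy=missing_policy,
    )


def mwcs_to_pcst(nwg: NodeWeightedGraph) -> PCSTInstance:
    """Shift node weights into non-negative prizes and a uniform edge cost."""
    w_floor = min(0.0, min(nwg.weights.values()))
    prizes = {v: w - w_floor for v, w in nwg.weights.items()}
    return PCSTInstance(
        graph=nwg.graph, prizes=prizes, edge_cost=-w_floor, offset=w_floor
    )


# ---------------------------------------------------------------------------
# Exact solver


def _spanning_tree_edges(G: nx.Graph, nodes: set[str]) -> list[tuple[str, str]]:
    """Deterministic BFS spanning tree of the induced subgraph."""
    if len(nodes) <= 1:
        return []
    sub = G.subgraph(nodes)
    root = min(nodes)
    edges = []
    seen = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(sub.neighbors(u)):
                if v not in seen:
                    seen.add(v)
                    edges.append((u, v))
                    nxt.append(v)
        frontier = nxt
    if len(seen) != len(nodes):
        raise SolverError("module node set is not connected")
    return edges


def _prune_negative_leaves(G: nx.Graph, weights: dict[str, float]) -> set[str]:
    """Iteratively strip degree-1 nodes with non-positive weight.

    Such a leaf can never help an optimal solution that contains any other
    node, so removing it preserves every optimum of size >= 2; single-node
    optima are covered separately by the best-single-node candidate.
    """
    keep = set(G.nodes)
    deg = {v: G.degree(v) for v in keep}
    stack = [v for v in keep if deg[v] <= 1 and weights[v] <= 0]
    while stack:
        v = stack.pop()
        if v not in keep or deg[v] > 1 or weights[v] > 0:
            continue
        keep.discard(v)
        for u in G.neighbors(v):
            if u in keep:
                deg[u] -= 1
                if deg[u] <= 1 and weights[u] <= 0:
                    stack.append(u)
    return keep


def _contract_positive(
    G: nx.Graph, weights: dict[str, float]
) -> tuple[nx.Graph, dict[str, float], dict[str, set[str]]]:
    """Contract each connected component of positive-weight nodes into one
    supernode.

    Valid for MWCS: an optimal solution touching a positive component can
    always absorb the whole component at no cost, so searching over
    contracted instances loses nothing. Returns the contracted graph, its
    weights, and the supernode -> original-node expansion map.
    """
    pos = {v for v in G.nodes if weights[v] > 0}
    label: dict[str, str] = {}
    expansion: dict[str, set[str]] = {}
    for comp in nx.connected_components(G.subgraph(pos)):
        name = min(comp)
        expansion[name] = set(comp)
        for v in comp:
            label[v] = name
    for v in G.nodes:
        if v not in label:
            label[v] = v
            expansion[v] = {v}
    H = nx.Graph()
    H.add_nodes_from(expansion)
    for u, v in G.edges:
        lu, lv = label[u], label[v]
        if lu != lv:
            H.add_edge(lu, lv)
    hw = {name: sum(weights[v] for v in members) for name, members in expansion.items()}
    return H, hw, expansion


def _solve_milp(
    c: np.ndarray, A: csr_matrix, lo: list[float], hi: list[float]
) -> np.ndarray:
    res = milp(
        c,
        constraints=LinearConstraint(A, lo, hi),
        integrality=np.ones_like(c),
        bounds=Bounds(np.zeros_like(c), np.ones_like(c)),
    )
    if not res.success:
        raise SolverError(f"MILP backend failed: {res.message}")
    return res.x


def _solve_component_milp(
    G: nx.Graph, weights: dict[str, float], max_rounds: int = 10000
) -> set[str]:
    """Exact MWCS on one connected graph by MILP with separator cuts.

    One binary per node; connectivity is enforced lazily. Each round solves
    ``max sum(w_v * y_v)`` under the cuts collected so far. If the selected
    set induces a connected subgraph it is optimal (the MILP value is an
    upper bound on the MWCS optimum). Otherwise, for every connected
    component ``C`` of the selection, any connected set containing a node of
    ``C`` and a selected node outside ``C``'s neighbourhood must cross the
    separator ``N(C)``, giving the valid cut

        y_u + y_v <= 1 + sum(y_s for s in N(C)),

    which the current (disconnected) selection violates. Components of each
    iterate double as feasible incumbents, so the loop can also stop early
    when the bound matches the best incumbent.
    """
    nodes = sorted(G.nodes)
    n = len(nodes)
    if n == 1:
        return {nodes[0]}
    idx = {v: i for i, v in enumerate(nodes)}
    c = np.array([-weights[v] for v in nodes])  # HiGHS minimises

    rows: list[int] = [0] * n
    cols: list[int] = list(range(n))
    vals: list[float] = [1.0] * n
    lo: list[float] = [1.0]  # nonempty module
    hi: list[float] = [np.inf]

    best_set: set[str] | None = None
    best_obj = -np.inf
    for _ in range(max_rounds):
        A = csr_matrix((vals, (rows, cols)), shape=(len(lo), n))
        x = _solve_milp(c, A, lo, hi)
        sel = {nodes[i] for i in range(n) if x[i] > 0.5}
        bound = sum(weights[v] for v in sel)
        comps = list(nx.connected_components(G.subgraph(sel)))
        for comp in comps:
            obj = sum(weights[v] for v in comp)
            if obj > best_obj:
                best_obj, best_set = obj, set(comp)
        if len(comps) == 1:
            return sel
        if bound <= best_obj + 1e-12:
            return best_set
        reps = [max(comp, key=lambda v: (weights[v], v)) for comp in comps]
        for comp, rep in zip(comps, reps):
            border = {s for v in comp for s in G.neighbors(v)} - comp
            border_cols = [idx[s] for s in border]
            u = idx[rep]
            for other in reps:
                if other in comp:
                    continue
                r = len(lo)
                rows.extend([r, r] + [r] * len(border_cols))
                cols.extend([u, idx[other]] + border_cols)
                vals.extend([1.0, 1.0] + [-1.0] * len(border_cols))
                lo.append(-np.inf)
                hi.append(1.0)
    raise SolverError("separator cut loop failed to converge")


def _greedy_component(G: nx.Graph, weights: dict[str, float]) -> set[str]:
    """Greedy MWCS heuristic: grow from the best node, adding the neighbour
    with the largest weight while the running objective does not decrease
    below its best value; finally prune negative leaves of the chosen set."""
    start = max(sorted(G.nodes), key=lambda v: weights[v])
    current = {start}
    best_set, best_obj = set(current), weights[start]
    obj = best_obj
    frontier = set(G.neighbors(start))
    while frontier:
        v = max(sorted(frontier), key=lambda u: weights[u])
        frontier.discard(v)
        current.add(v)
        obj += weights[v]
        frontier |= set(G.neighbors(v)) - current
        if obj > best_obj:
            # keep only nodes needed to connect the positives accumulated so far
            best_obj, best_set = obj, set(current)
    # prune: drop trailing negative-weight leaves of the spanning tree
    sub = G.subgraph(best_set).copy()
    changed = True
    while changed:
        changed = False
        for v in sorted(sub.nodes):
            if weights[v] < 0 and sub.degree(v) <= 1 and sub.number_of_nodes() > 1:
                sub.remove_node(v)
                changed = True
    comp = max(nx.connected_components(sub), key=lambda s: (sum(weights[v] for v in s), sorted(s)))
    return set(comp)


def solve_pcst(
    instance: PCSTInstance,
    backend: str = "exact",
    size_bound: int = EXACT_SIZE_BOUND,
    scheme: ScoringScheme | None = None,
    pvalues: dict[str, float] | None = None,
) -> SteinerModule:
    """Solve the PCST instance and report the module in MWCS terms.

    Each connected component is solved separately and the best-scoring
    module overall is returned (ties broken by lexicographically smallest
    sorted node sequence across components). Component shortcuts: an
    all-non-negative component is taken whole; a component whose nodes are
    all non-positive after preprocessing contributes its best single node.

    ``backend="exact"`` (MILP) certifies optimality up to ``size_bound``
    nodes per component after preprocessing and raises
    :class:`~activemod.errors.SolverError` beyond it; ``backend="greedy"``
    is a heuristic for larger instances and marks the result inexact.
    """
    if backend not in ("exact", "greedy"):
        raise SolverError(f"unknown backend {backend!r}")
    G = instance.graph
    weights = {v: instance.prizes[v] - instance.edge_cost for v in G.nodes}
    if not G.number_of_nodes():
        raise ValidationError("empty instance")

    best: tuple[float, list[str]] | None = None
    exact = True
    for comp in nx.connected_components(G):
        cand, cand_exact = _solve_component(G.subgraph(comp), weights, backend, size_bound)
        exact = exact and cand_exact
        obj = sum(weights[v] for v in cand)
        key = (obj, [v for v in sorted(cand)])
        if best is None or obj > best[0] + 1e-12 or (
            abs(obj - best[0]) <= 1e-12 and key[1] < best[1]
        ):
            best = key
    nodes = set(best[1])
    module = SteinerModule(
        nodes=nodes,
        tree_edges=_spanning_tree_edges(G, nodes),
        weights={v: weights[v] for v in nodes},
        objective=best[0],
        pvalues={v: pvalues[v] for v in nodes if pvalues and v in pvalues},
        fdr=scheme.fdr if scheme else None,
        tau=scheme.tau if scheme else None,
        exact=exact,
        backend=backend,
    )
    return module


def _solve_component(
    G: nx.Graph, weights: dict[str, float], backend: str, size_bound: int
) -> tuple[set[str], bool]:
    nodes = set(G.nodes)
    # best single node: covers the all-negative optimum and guards pruning
    single = min(sorted(nodes), key=lambda v: (-weights[v], v))
    if all(weights[v] <= 0 for v in nodes):
        return {single}, True
    if all(weights[v] >= 0 for v in nodes):
        return nodes, True

    keep = _prune_negative_leaves(G, weights)
    core = G.subgraph(keep)
    best_set: set[str] | None = None
    exact = True
    for comp in nx.connected_components(core):
        sub = core.subgraph(comp)
        if all(weights[v] >= 0 for v in comp):
            cand = set(comp)
        elif backend == "exact":
            H, hw, expansion = _contract_positive(sub, weights)
            if H.number_of_nodes() > size_bound:
                raise SolverError(
                    f"component with {H.number_of_nodes()} nodes after "
                    f"preprocessing exceeds the exact-size bound {size_bound}; "
                    "rerun with the greedy backend"
                )
            chosen = _solve_component_milp(H, hw)
            cand = {v for name in chosen for v in expansion[name]}
        else:
            cand = _greedy_component(sub, weights)
            exact = False
        if best_set is None or sum(weights[v] for v in cand) > sum(
            weights[v] for v in best_set
        ):
            best_set = cand
    if best_set is None or sum(weights[v] for v in best_set) < weights[single]:
        best_set = {single}
    return best_set, exact


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_mwcs(nwg: NodeWeightedGraph, max_nodes: int = BRUTE_FORCE_MAX) -> SteinerModule:
    """Exhaustive MWCS over all connected induced subgraphs (test oracle).

    Enumerates every non-empty node subset as a bitmask, keeps connected
    ones, and returns the maximum-weight subset; ties are broken by the
    lexicographically smallest sorted node sequence. Only feasible for tiny
    graphs, hence the hard size bound.
    """
    nodes = sorted(nwg.graph.nodes)
    n = len(nodes)
    if n > max_nodes:
        raise ValidationError(f"brute force limited to {max_nodes} nodes, got {n}")
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in nwg.graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    w = [nwg.weights[v] for v in nodes]

    best_obj = -np.inf
    best_mask = 0
    for mask in range(1, 1 << n):
        seen = mask & (-mask)
        frontier = seen
        while frontier:
            nxt = 0
            f = frontier
            while f:
                b = f & (-f)
                f ^= b
                nxt |= adj[b.bit_length() - 1]
            frontier = nxt & mask & ~seen
            seen |= frontier
        if seen != mask:
            continue
        obj = sum(w[i] for i in range(n) if mask >> i & 1)
        if obj > best_obj + 1e-12:
            best_obj, best_mask = obj, mask
        elif abs(obj - best_obj) <= 1e-12:
            cand = [nodes[i] for i in range(n) if mask >> i & 1]
            cur = [nodes[i] for i in range(n) if best_mask >> i & 1]
            if cand < cur:
                best_mask = mask
    sel = {nodes[i] for i in range(n) if best_mask >> i & 1}
    return SteinerModule(
        nodes=sel,
        tree_edges=_spanning_tree_edges(nwg.graph, sel),
        weights={v: nwg.weights[v] for v in sel},
        objective=float(best_obj),
        pvalues={v: nwg.pvalues[v] for v in sel if v in nwg.pvalues},
        fdr=nwg.scheme.fdr if nwg.scheme else None,
        tau=nwg.scheme.tau if nwg.scheme else None,
        exact=True,
        backend="brute-force",
    )


# ---------------------------------------------------------------------------
# Pipeline entry points


def detect_module(
    ppin: nx.Graph,
    table: PValueTable,
    fdr: float,
    missing_policy: str = "drop",
    backend: str = "exact",
    size_bound: int = EXACT_SIZE_BOUND,
    force: bool = False,
    scheme: ScoringScheme | None = None,
) -> SteinerModule:
    """Full detection pipeline: fit BUM -> threshold -> weights -> solve.

    Refuses to run when the mixture fit degenerates to pure uniform noise
    (no enrichment of small p-values) unless ``force`` is set.
    """
    if scheme is None:
        fit = fit_bum(table.pvalues())
        if fit.no_signal and not force:
            raise NoSignalError(
                "BUM fit found no signal component (lambda at its upper bound); "
                "pass force=True to score anyway"
            )
        scheme = scoring_scheme(fit, fdr)
    nwg = build_weighted_network(ppin, table, fdr, missing_policy, scheme=scheme)
    instance = mwcs_to_pcst(nwg)
    return solve_pcst(
        instance, backend=backend, size_bound=size_bound, scheme=scheme, pvalues=nwg.pvalues
    )


def fdr_sweep(
    ppin: nx.Graph,
    table: PValueTable,
    fdr_grid,
    missing_policy: str = "drop",
    backend: str = "exact",
    size_bound: int = EXACT_SIZE_BOUND,
    force: bool = False,
) -> list[tuple[float, SteinerModule]]:
    """Detect one module per FDR on a strictly increasing grid.

    The mixture model is fitted once and reused; only tau changes between
    grid points, which shifts every node weight by the same positive
    constant, so module sizes along the curve are non-decreasing (module
    *membership* need not be nested).
    """
    grid = [float(f) for f in fdr_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("fdr grid must be strictly increasing")
    fit = fit_bum(table.pvalues())
    if fit.no_signal and not force:
        raise NoSignalError(
            "BUM fit found no signal component; pass force=True to sweep anyway"
        )
    out = []
    for f in grid:
        scheme = scoring_scheme(fit, f)
        out.append(
            (
                f,
                detect_module(
                    ppin,
                    table,
                    f,
                    missing_policy=missing_policy,
                    backend=backend,
                    size_bound=size_bound,
                    scheme=scheme,
                ),
            )
        )
    return out


def sweep_table(sweep: list[tuple[float, SteinerModule]]):
    """Summarise a sweep as a DataFrame (one row per FDR grid point)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "fdr": [f for f, _ in sweep],
            "tau": [m.tau for _, m in sweep],
            "module_size": [m.size() for _, m in sweep],
            "n_significant": [m.n_significant for _, m in sweep],
            "n_connectors": [len(m.connectors) for _, m in sweep],
            "objective": [m.objective for _, m in sweep],
        }
    )
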