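"""Discrete Bayesian-network structure learning on fold-change profiles.

The stage mirrors a causal-inference readout on per-animal log2 fold
changes: values are discretized into a fixed number of intervals (equal
width or equal frequency), a directed acyclic graph is learned by greedy
hill climbing over add/remove/reverse moves scored with the BDeu marginal
likelihood (Bayesian Dirichlet equivalent, uniform prior), the parent count
is bounded, and a subnetwork is extracted by thresholding edge weights and
keeping the incoming neighbors of the retained nodes.

The BDeu score for node :math:`i` with arity :math:`r_i` and :math:`q_i`
parent configurations is

.. math::

    \\sum_j \\Big[\\ln\\Gamma(\\alpha_{ij}) - \\ln\\Gamma(\\alpha_{ij}+N_{ij})\\Big]
    + \\sum_{jk} \\Big[\\ln\\Gamma(\\alpha_{ijk}+N_{ijk}) - \\ln\\Gamma(\\alpha_{ijk})\\Big]

with :math:`\\alpha_{ijk} = \\mathrm{ess}/(r_i q_i)` and
:math:`\\alpha_{ij} = \\mathrm{ess}/q_i`; it is decomposable over nodes and
score-equivalent across Markov-equivalent DAGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class Dag:
    """A directed acyclic graph with per-edge weights.

    ``edges`` holds ``(source, target, weight)`` triples; ``edge_deltas``
    keeps the raw BDeu score improvement recorded when each edge was last
    added (or created by a reversal) during hill climbing, before min-max
    normalization to the ``weight`` scale.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    score: float | None = None
    ess: float | None = None
    edge_deltas: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge list contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w, delta=self.edge_deltas.get((u, v)))
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v, _ in self.edges if v == node)

    def parent_sets(self) -> dict[str, frozenset]:
        out = {n: set() for n in self.nodes}
        for u, v, _ in self.edges:
            out[v].add(u)
        return {n: frozenset(s) for n, s in out.items()}

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges}

    def skeleton(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v, _ in self.edges}

    # ------------------------------------------------------------ export

    def to_sif(self, path) -> None:
        """Write a simple-interaction-format file (source, relation, target)."""
        with open(path, "w") as fh:
            linked = set()
            for u, v, _ in self.edges:
                fh.write(f"{u}\tcauses\t{v}\n")
                linked.update((u, v))
            for n in self.nodes:
                if n not in linked:
                    fh.write(f"{n}\n")

    def to_graphml(self, path) -> None:
        g = self.to_networkx()
        for u, v, d in g.edges(data=True):
            if d.get("delta") is None:
                d.pop("delta", None)
        nx.write_graphml(g, Path(path))


@dataclass
class DiscreteDataset:
    """Interval-index matrix with the edges that produced it."""

    data: pd.DataFrame  # samples x variables, integer interval indices
    interval_edges: dict[str, np.ndarray]
    mode: str
    n_intervals: int

    @property
    def arities(self) -> dict[str, int]:
        return {v: self.n_intervals for v in self.data.columns}


def discretize(matrix: pd.DataFrame, mode: str = "equal_width", n_intervals: int = 20) -> DiscreteDataset:
    """Discretize each variable into ``n_intervals`` interval indices.

    ``equal_width`` partitions ``[min, max]`` of each variable into bins of
    equal length, with the maximum assigned to the last bin; ``equal_frequency``
    places bin edges at empirical quantiles. Default 20 intervals.
    """
    if mode not in ("equal_width", "equal_frequency"):
        raise ValueError(f"unknown discretization mode {mode!r}")
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if matrix.isna().any().any():
        raise ValueError("discretize requires a complete matrix; impute missing values first")
    n = len(matrix)
    if n < n_intervals:
        warnings.warn(
            f"{n} samples over {n_intervals} intervals: most bins will be empty or singletons; "
            "consider fewer intervals",
            stacklevel=2,
        )
    out = {}
    edges_out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"variable {col!r} is constant and cannot be discretized")
        if mode == "equal_width":
            edges = np.linspace(x.min(), x.max(), n_intervals + 1)
            width = x.max() - x.min()
            idx = np.minimum(((x - x.min()) / width * n_intervals).astype(int), n_intervals - 1)
        else:
            qs = np.quantile(x, np.linspace(0, 1, n_intervals + 1))
            edges = qs
            # interior edges define the bins; right-closed so ties share a bin
            idx = np.searchsorted(qs[1:-1], x, side="right")
        out[col] = idx
        edges_out[col] = edges
    return DiscreteDataset(
        data=pd.DataFrame(out, index=matrix.index),
        interval_edges=edges_out,
        mode=mode,
        n_intervals=n_intervals,
    )


# --------------------------------------------------------------------- BDeu


def _as_matrix(data, arities=None) -> tuple[pd.DataFrame, dict[str, int]]:
    if isinstance(data, DiscreteDataset):
        return data.data, dict(data.arities) if arities is None else dict(arities)
    df = pd.DataFrame(data)
    if arities is None:
        # inferred from the data; declare arities explicitly when some
        # states may be unobserved
        arities = {c: int(df[c].max()) + 1 for c in df.columns}
    return df, dict(arities)


def family_score(
    child: np.ndarray, parents: np.ndarray | None, r: int, parent_arities: list[int], ess: float
) -> float:
    """BDeu log marginal likelihood of one node given its parent columns.

    Parent configurations never observed in the data contribute zero, so
    only observed configurations are enumerated — this keeps 20-interval
    discretizations with few samples tractable.
    """
    if np.any(child >= r) or np.any(child < 0):
        raise ValueError("state index outside the declared arity")
    q = int(np.prod(parent_arities)) if parent_arities else 1
    a_jk = ess / (r * q)
    a_j = ess / q
    if parents is None or parents.size == 0:
        j_idx = np.zeros(child.shape[0], dtype=np.int64)
    else:
        for col, ar in zip(parents.T, parent_arities):
            if np.any(col >= ar) or np.any(col < 0):
                raise ValueError("state index outside the declared arity")
        strides = np.cumprod([1] + parent_arities[:-1])
        j_idx = parents @ np.asarray(strides, dtype=np.int64)
    combined = j_idx * r + child
    uniq, counts = np.unique(combined, return_counts=True)
    score = float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    j_uniq, j_counts = np.unique(j_idx, return_counts=True)
    score += float(np.sum(gammaln(a_j) - gammaln(a_j + j_counts)))
    return score


def bde_score(
    data, dag: Dag, ess: float = 1.0, arities: dict | None = None
) -> tuple[float, dict[str, float]]:
    """Total BDeu log score of ``dag`` on ``data``, with per-node local scores.

    ``data`` may be a :class:`DiscreteDataset` or an integer DataFrame. When
    a plain DataFrame is given without ``arities``, each variable's arity is
    inferred as max state + 1 — pass ``arities`` explicitly if some states
    may be unobserved.
    """
    if ess <= 0:
        raise ValueError("ess must be > 0")
    df, arities = _as_matrix(data, arities)
    missing = set(dag.nodes) - set(df.columns)
    if missing:
        raise ValueError(f"dag nodes absent from data: {sorted(missing)}")
    parent_sets = dag.parent_sets()
    local = {}
    for node in dag.nodes:
        pars = sorted(parent_sets[node])
        pmat = df[pars].to_numpy(dtype=np.int64) if pars else None
        local[node] = family_score(
            df[node].to_numpy(dtype=np.int64), pmat, arities[node], [arities[p] for p in pars], ess
        )
    return float(sum(local.values())), local


# -------------------------------------------------------------- hill climb


class _Climber:
    def __init__(self, df: pd.DataFrame, arities: dict[str, int], ess: float, max_parents: int):
        self.df = df
        self.cols = {c: df[c].to_numpy(dtype=np.int64) for c in df.columns}
        self.arities = arities
        self.ess = ess
        self.max_parents = max_parents
        self.nodes = list(df.columns)
        self.parents: dict[str, frozenset] = {n: frozenset() for n in self.nodes}
        self._cache: dict[tuple[str, frozenset], float] = {}

    def local(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key not in self._cache:
            pars = sorted(parents)
            pmat = (
                np.column_stack([self.cols[p] for p in pars]) if pars else None
            )
            self._cache[key] = family_score(
                self.cols[node], pmat, self.arities[node],
                [self.arities[p] for p in pars], self.ess,
            )
        return self._cache[key]

    def _reachable(self, src: str, dst: str, skip_edge=None) -> bool:
        """Directed reachability src -> dst over current parent sets."""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for v, pars in self.parents.items():
            for u in pars:
                if skip_edge and (u, v) == skip_edge:
                    continue
                children[u].append(v)
        stack, seen = [src], set()
        while stack:
            n = stack.pop()
            if n == dst:
                return True
            if n in seen:
                continue
            seen.add(n)
            stack.extend(children[n])
        return False

    def legal_moves(self, allow_reverse: bool):
        for u in self.nodes:
            for v in self.nodes:
                if u == v:
                    continue
                pv = self.parents[v]
                if u in pv:
                    base_v = self.local(v, pv)
                    d_rm = self.local(v, pv - {u}) - base_v
                    yield ("remove", u, v, d_rm)
                    if allow_reverse and len(self.parents[u]) < self.max_parents:
                        # v -> u must not close a cycle once u -> v is gone
                        if not self._reachable(u, v, skip_edge=(u, v)):
                            d_add = self.local(u, self.parents[u] | {v}) - self.local(u, self.parents[u])
                            yield ("reverse", u, v, d_rm + d_add)
                else:
                    if len(pv) >= self.max_parents:
                        continue
                    if self._reachable(v, u):
                        continue  # adding u -> v would close a cycle
                    yield ("add", u, v, self.local(v, pv | {u}) - self.local(v, pv))


def hill_climb(
    data,
    max_parents: int = 3,
    ess: float = 1.0,
    allow_reverse: bool = True,
    seed: int = 0,
    tol: float = 1e-9,
    arities: dict | None = None,
) -> Dag:
    """Greedy BDeu hill climbing from the empty graph.

    At each step every legal add/remove/reverse move (acyclicity and the
    ``max_parents`` bound preserved) is scored and the single best
    improvement is applied; the search stops when no move improves the score
    by more than ``tol``. Ties break lexicographically on
    ``(move type, source, target)``, making the search deterministic; the
    ``seed`` argument is accepted for interface symmetry but unused.

    Edge weights are the raw score improvement recorded at each edge's final
    add (or reverse) move, min-max normalized to [0, 1] across the returned
    edges; the raw deltas are kept in ``Dag.edge_deltas``.
    """
    del seed
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    df, arities = _as_matrix(data, arities)
    hc = _Climber(df, arities, ess, max_parents)
    deltas: dict[tuple[str, str], float] = {}
    while True:
        best = None
        for move in hc.legal_moves(allow_reverse):
            if move[3] <= tol:
                continue
            if best is None or move[3] > best[3] + 1e-12 or (
                abs(move[3] - best[3]) <= 1e-12 and move[:3] < best[:3]
            ):
                best = move
        if best is None:
            break
        kind, u, v, d = best
        if kind == "add":
            hc.parents[v] = hc.parents[v] | {u}
            deltas[(u, v)] = d
        elif kind == "remove":
            hc.parents[v] = hc.parents[v] - {u}
            deltas.pop((u, v), None)
        else:  # reverse u -> v  becomes  v -> u
            hc.parents[v] = hc.parents[v] - {u}
            hc.parents[u] = hc.parents[u] | {v}
            deltas.pop((u, v), None)
            deltas[(v, u)] = d
    raw = list(deltas.values())
    if raw:
        lo, hi = min(raw), max(raw)
        span = hi - lo
    edges = []
    for (u, v), d in sorted(deltas.items()):
        w = 1.0 if not raw or span <= 0 else (d - lo) / span
        edges.append((u, v, w))
    total = sum(hc.local(n, hc.parents[n]) for n in hc.nodes)
    return Dag(nodes=hc.nodes, edges=edges, score=float(total), ess=ess, edge_deltas=deltas)


def extract_subnetwork(dag: Dag, weight_threshold: float, use: str = "weight") -> Dag:
    """Subnetwork of edges above a weight threshold plus incoming neighbors.

    Keeps every edge whose weight (normalized ``"weight"`` or raw
    ``"delta"``) exceeds ``weight_threshold``, the nodes those edges touch,
    each kept node's incoming neighbors (parents in the full graph), and the
    parent edges that justify including them.
    """
    if use not in ("weight", "delta"):
        raise ValueError("use must be 'weight' or 'delta'")
    value = {(u, v): (w if use == "weight" else dag.edge_deltas.get((u, v), w))
             for u, v, w in dag.edges}
    core_edges = [(u, v, w) for u, v, w in dag.edges if value[(u, v)] > weight_threshold]
    core_nodes = {n for u, v, _ in core_edges for n in (u, v)}
    keep_edges = {(u, v): w for u, v, w in core_edges}
    nodes = set(core_nodes)
    for u, v, w in dag.edges:
        if v in core_nodes:
            nodes.add(u)
            keep_edges.setdefault((u, v), w)
    return Dag(
        nodes=sorted(nodes),
        edges=[(u, v, w) for (u, v), w in sorted(keep_edges.items())],
        score=dag.score,
        ess=dag.ess,
        edge_deltas={e: dag.edge_deltas[e] for e in keep_edges if e in dag.edge_deltas},
    )
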