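"""Mixed-graph data model for gene regulatory networks.

A regulatory network is stored as a single square adjacency matrix over an
ordered node list.  Entry ``(i, j)`` describes the ordered pair
*(target i, source j)*:

* ``+1`` — directed edge: gene *j* regulates gene *i*;
* ``-1`` — undirected edge: *i* and *j* interact but the direction is
  unknown (stored symmetrically, so one undirected edge occupies two cells);
* ``0``  — evidenced non-interaction (a "non-interaction", distinct from
  missing knowledge);
* ``NaN`` — unknown: no statement is made about the pair.

This four-state encoding lets knowledge-driven networks distinguish "we know
there is no edge" from "we do not know", which matters when models are scored
only on the pairs about which they make predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DIRECTED = 1.0
UNDIRECTED = -1.0
ABSENT = 0.0
UNKNOWN = math.nan

#: Modules (gene groupings) used throughout: the canonical labels for the
#: embryonic C-lineage system plus a catch-all "other".
MODULE_LABELS = ("initiation", "ectoderm", "mesoderm", "mixed", "other")

_TOKENS = {"1": DIRECTED, "-1": UNDIRECTED, "0": ABSENT, "-": UNKNOWN}


def is_unknown(value: float) -> bool:
    """True when an adjacency entry carries no information."""
    return isinstance(value, float) and math.isnan(value)


class GraphValueError(ValueError):
    """Raised for structurally invalid networks or conflicting entries."""


class ProbeMap:
    """Many-to-one mapping from microarray probes to genes.

    Preserves insertion order: gene order is the order of first appearance
    of a gene among the probes, which keeps collapsed networks deterministic.
    """

    def __init__(self, probe_to_gene: Mapping[str, str]):
        if not probe_to_gene:
            raise GraphValueError("probe map is empty")
        self._probe_to_gene = dict(probe_to_gene)
        self._gene_to_probes: dict[str, list[str]] = {}
        for probe, gene in self._probe_to_gene.items():
            self._gene_to_probes.setdefault(gene, []).append(probe)

    @classmethod
    def identity(cls, genes: Sequence[str]) -> "ProbeMap":
        """One probe per gene, probe id equal to the gene id."""
        return cls({g: g for g in genes})

    @property
    def probes(self) -> list[str]:
        return list(self._probe_to_gene)

    @property
    def genes(self) -> list[str]:
        return list(self._gene_to_probes)

    def gene_of(self, probe: str) -> str:
        try:
            return self._probe_to_gene[probe]
        except KeyError:
            raise GraphValueError(f"probe {probe!r} not in probe map") from None

    def probes_of(self, gene: str) -> list[str]:
        try:
            return list(self._gene_to_probes[gene])
        except KeyError:
            raise GraphValueError(f"gene {gene!r} not in probe map") from None

    def as_dict(self) -> dict[str, str]:
        return dict(self._probe_to_gene)

    def __len__(self) -> int:
        return len(self._probe_to_gene)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeMap) and self._probe_to_gene == other._probe_to_gene


class GeneNetwork:
    """A mixed graph over named nodes, backed by a float adjacency matrix.

    Parameters
    ----------
    nodes:
        Ordered, unique node identifiers.
    adjacency:
        Square float matrix; entries in {+1, -1, 0, NaN}.  ``adjacency[i, j]``
        refers to the ordered pair (target ``nodes[i]``, source ``nodes[j]``).
    module_map:
        Optional node -> module label mapping (labels are free-form but the
        canonical ones are in :data:`MODULE_LABELS`).
    """

    def __init__(
        self,
        nodes: Sequence[str],
        adjacency: np.ndarray,
        module_map: Mapping[str, str] | None = None,
        validate: bool = True,
    ):
        self.nodes = list(nodes)
        self.adjacency = np.asarray(adjacency, dtype=float)
        self.module_map = dict(module_map) if module_map else None
        self._index = {name: k for k, name in enumerate(self.nodes)}
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.nodes)
        if len(self._index) != n:
            raise GraphValueError("node identifiers are not unique")
        if self.adjacency.shape != (n, n):
            raise GraphValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} nodes"
            )
        finite = self.adjacency[~np.isnan(self.adjacency)]
        if not np.isin(finite, [DIRECTED, UNDIRECTED, ABSENT]).all():
            bad = sorted(set(finite) - {DIRECTED, UNDIRECTED, ABSENT})
            raise GraphValueError(f"invalid adjacency values {bad}")
        undirected = self.adjacency == UNDIRECTED
        if not (undirected == undirected.T).all():
            i, j = np.argwhere(undirected != undirected.T)[0]
            raise GraphValueError(
                f"undirected entry not symmetric for pair ({self.nodes[i]}, {self.nodes[j]})"
            )

    # -- basic access -----------------------------------------------------

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise GraphValueError(f"unknown node {node!r}") from None

    def entry(self, target: str, source: str) -> float:
        return float(self.adjacency[self.index(target), self.index(source)])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def module_of(self, node: str) -> str | None:
        if self.module_map is None:
            return None
        return self.module_map.get(node)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            self.nodes, self.adjacency.copy(), self.module_map, validate=False
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneNetwork)
            and self.nodes == other.nodes
            and np.array_equal(self.adjacency, other.adjacency, equal_nan=True)
            and self.module_map == other.module_map
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneNetwork(n={self.n_nodes}, directed={len(self.directed_edges())}, undirected={len(self.undirected_edges())})"

    # -- edge views -------------------------------------------------------

    def directed_edges(self) -> list[tuple[str, str]]:
        """(source, target) pairs with a +1 entry, excluding self-loops unless present."""
        out = []
        for i, j in np.argwhere(self.adjacency == DIRECTED):
            out.append((self.nodes[j], self.nodes[i]))
        return out

    def undirected_edges(self) -> list[tuple[str, str]]:
        """Unordered -1 pairs, each reported once with endpoints sorted by index."""
        out = []
        for i, j in np.argwhere(self.adjacency == UNDIRECTED):
            if i <= j:
                out.append((self.nodes[i], self.nodes[j]))
        return out

    def to_digraph(self, undirected: str = "both") -> nx.DiGraph:
        """Project onto a :class:`networkx.DiGraph`.

        ``undirected="both"`` expands each undirected edge into the two
        directed arcs (the default for path statistics); ``"skip"`` keeps
        directed edges only.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for src, tgt in self.directed_edges():
            g.add_edge(src, tgt)
        if undirected == "both":
            for a, b in self.undirected_edges():
                if a != b:
                    g.add_edge(a, b)
                    g.add_edge(b, a)
        elif undirected != "skip":
            raise GraphValueError(f"unknown undirected policy {undirected!r}")
        return g


# -- construction ----------------------------------------------------------


def make_network(
    nodes: Sequence[str],
    entries: Iterable[tuple[str, str, float]] = (),
    module_map: Mapping[str, str] | None = None,
    default: float = UNKNOWN,
) -> GeneNetwork:
    """Build a network from sparse ``(target, source, value)`` entries.

    Unspecified pairs take ``default`` (unknown unless overridden).
    Undirected (-1) entries are symmetrized automatically.  Conflicting
    values for the same ordered pair are rejected.
    """
    n = len(nodes)
    index = {name: k for k, name in enumerate(nodes)}
    if len(index) != n:
        raise GraphValueError("node identifiers are not unique")
    adj = np.full((n, n), default, dtype=float)
    seen: dict[tuple[int, int], float] = {}

    def _set(i: int, j: int, value: float) -> None:
        if (i, j) in seen:
            prev = seen[(i, j)]
            same = (is_unknown(prev) and is_unknown(value)) or prev == value
            if not same:
                raise GraphValueError(
                    f"conflicting entries for pair ({nodes[i]}, {nodes[j]}): "
                    f"{prev} vs {value}"
                )
            return
        seen[(i, j)] = value
        adj[i, j] = value

    for target, source, value in entries:
        for name in (target, source):
            if name not in index:
                raise GraphValueError(f"unknown node {name!r} in entries")
        value = float(value)
        if not (is_unknown(value) or value in (DIRECTED, UNDIRECTED, ABSENT)):
            raise GraphValueError(f"invalid entry value {value}")
        i, j = index[target], index[source]
        _set(i, j, value)
        if value == UNDIRECTED and i != j:
            _set(j, i, UNDIRECTED)
    return GeneNetwork(nodes, adj, module_map)


def collapse_probes(probe_net: GeneNetwork, probe_map: ProbeMap) -> GeneNetwork:
    """Collapse a probe-level network to the gene level by unanimity.

    The gene-pair entry is +1 (resp. -1) only if *every* probe-pair entry
    between the two probe sets is +1 (resp. -1); any disagreement, absence
    or unknown yields 0.  The diagonal is forced to 0: self-regulation is
    not representable at the gene level here.
    """
    for probe in probe_net.nodes:
        probe_map.gene_of(probe)  # raises for unmapped probes
    genes = [g for g in probe_map.genes if any(p in probe_net._index for p in probe_map.probes_of(g))]
    n = len(genes)
    adj = np.zeros((n, n), dtype=float)
    probe_idx = {
        g: [probe_net.index(p) for p in probe_map.probes_of(g) if p in probe_net._index]
        for g in genes
    }
    for a, ga in enumerate(genes):
        for b, gb in enumerate(genes):
            if a == b:
                continue
            block = probe_net.adjacency[np.ix_(probe_idx[ga], probe_idx[gb])]
            if np.all(block == DIRECTED):
                adj[a, b] = DIRECTED
            elif np.all(block == UNDIRECTED):
                adj[a, b] = UNDIRECTED
            else:
                adj[a, b] = ABSENT
    module_map = None
    if probe_net.module_map is not None:
        module_map = {}
        for g in genes:
            mods = {probe_net.module_map.get(p) for p in probe_map.probes_of(g) if p in probe_net._index}
            mods.discard(None)
            if len(mods) > 1:
                raise GraphValueError(f"probes of gene {g!r} carry conflicting modules {sorted(mods)}")
            module_map[g] = mods.pop() if mods else None
    return GeneNetwork(genes, adj, module_map)


# -- statistics ------------------------------------------------------------


def average_path_length(
    net: GeneNetwork,
    undirected: str = "both",
    unreachable: str = "exclude",
) -> float:
    """Mean shortest-path length over ordered pairs of distinct nodes.

    Undirected edges are traversable in both directions by default.  With
    ``unreachable="exclude"`` (default) pairs with no path are dropped from
    the mean; with ``unreachable="n"`` they contribute ``|nodes|``.
    """
    if net.n_nodes == 0:
        raise GraphValueError("empty network")
    g = net.to_digraph(undirected=undirected)
    g.remove_edges_from(nx.selfloop_edges(g))
    lengths = []
    n = net.n_nodes
    reach = dict(nx.all_pairs_shortest_path_length(g))
    for u in net.nodes:
        for v in net.nodes:
            if u == v:
                continue
            d = reach.get(u, {}).get(v)
            if d is not None:
                lengths.append(d)
            elif unreachable == "n":
                lengths.append(n)
            elif unreachable != "exclude":
                raise GraphValueError(f"unknown unreachable policy {unreachable!r}")
    if not lengths:
        raise GraphValueError("no reachable ordered pair: average path length undefined")
    return float(np.mean(lengths))


@dataclass
class DegreeReport:
    """Per-node directed degrees plus aggregates.

    Undirected edges are not counted toward in/out-degree (the notion of an
    "outgoing" edge is only defined for directed edges); their per-node
    counts are reported separately in ``undirected_degree``.
    """

    in_degree: dict[str, int]
    out_degree: dict[str, int]
    undirected_degree: dict[str, int]
    average_in_degree: float
    average_out_degree: float
    hubs: list[str]
    in_degree_range: tuple[int, int]
    include_undirected: bool = False


def degree_statistics(net: GeneNetwork, include_undirected: bool = False) -> DegreeReport:
    """Directed degree statistics; hubs have out-degree > |nodes| / 2.

    ``include_undirected=True`` additionally counts each undirected edge
    toward both the in- and out-degree of both endpoints.
    """
    adj = net.adjacency.copy()
    np.fill_diagonal(adj, ABSENT)
    directed = adj == DIRECTED
    undirected = adj == UNDIRECTED
    counted = directed | undirected if include_undirected else directed
    in_deg = {node: int(counted[i, :].sum()) for i, node in enumerate(net.nodes)}
    out_deg = {node: int(counted[:, j].sum()) for j, node in enumerate(net.nodes)}
    und_deg = {node: int(undirected[i, :].sum()) for i, node in enumerate(net.nodes)}
    n = net.n_nodes
    hubs = [node for node in net.nodes if out_deg[node] > n / 2]
    in_values = list(in_deg.values())
    return DegreeReport(
        in_degree=in_deg,
        out_degree=out_deg,
        undirected_degree=und_deg,
        average_in_degree=float(np.mean(in_values)) if n else 0.0,
        average_out_degree=float(np.mean(list(out_deg.values()))) if n else 0.0,
        hubs=hubs,
        in_degree_range=(min(in_values), max(in_values)) if n else (0, 0),
        include_undirected=include_undirected,
    )


@dataclass
class MotifReport:
    """Small regulatory motifs over the directed part of the graph."""

    two_cycles: list[tuple[str, str]]
    feedforward_loops: list[tuple[str, str, str]]
    feedback_loops: list[tuple[str, str, str]]


def find_motifs(net: GeneNetwork) -> MotifReport:
    """Enumerate 2-cycles, feedforward loops and 3-node feedback loops.

    Only directed edges participate.  A feedforward loop a->b->c with the
    shortcut a->c is reported as the ordered triple (a, b, c); a feedback
    loop a->b->c->a is reported once, rotated to start at its smallest node
    by network order.  Self-loops are ignored.
    """
    adj = net.adjacency.copy()
    np.fill_diagonal(adj, ABSENT)
    has = adj == DIRECTED  # has[i, j]: j -> i

    def arc(src: int, tgt: int) -> bool:
        return bool(has[tgt, src])

    n = net.n_nodes
    two_cycles = [
        (net.nodes[a], net.nodes[b])
        for a in range(n)
        for b in range(a + 1, n)
        if arc(a, b) and arc(b, a)
    ]
    ffl: list[tuple[str, str, str]] = []
    fbl: list[tuple[str, str, str]] = []
    for a in range(n):
        for b in range(n):
            if a == b or not arc(a, b):
                continue
            for c in range(n):
                if c in (a, b) or not arc(b, c):
                    continue
                if arc(a, c):
                    ffl.append((net.nodes[a], net.nodes[b], net.nodes[c]))
                if arc(c, a) and a == min(a, b, c):
                    fbl.append((net.nodes[a], net.nodes[b], net.nodes[c]))
    return MotifReport(two_cycles=two_cycles, feedforward_loops=ffl, feedback_loops=fbl)


# -- I/O -------------------------------------------------------------------


def _format_cell(value: float) -> str:
    if is_unknown(value):
        return "-"
    return str(int(value))


def write_adjacency_csv(net: GeneNetwork, path: str | Path) -> None:
    """Canonical on-disk form: header row/column of node names, cells in
    {1, -1, 0, -} where "-" marks an unknown pair."""
    rows = []
    for i, target in enumerate(net.nodes):
        rows.append([_format_cell(v) for v in net.adjacency[i]])
    df = pd.DataFrame(rows, index=net.nodes, columns=net.nodes)
    df.to_csv(path, index_label="")


def read_adjacency_csv(path: str | Path, module_map: Mapping[str, str] | None = None) -> GeneNetwork:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    nodes = [str(c) for c in df.columns]
    row_names = [str(r) for r in df.index]
    if row_names != nodes:
        if sorted(row_names) != sorted(nodes):
            raise GraphValueError(
                f"non-square or mismatched adjacency in {path}: rows {row_names} vs columns {nodes}"
            )
        df = df.loc[nodes]
    if len(set(nodes)) != len(nodes):
        raise GraphValueError(f"duplicate node names in {path}")
    n = len(nodes)
    adj = np.full((n, n), UNKNOWN)
    for i in range(n):
        for j in range(n):
            token = str(df.iat[i, j]).strip()
            if token not in _TOKENS:
                raise GraphValueError(
                    f"invalid cell token {token!r} at row {nodes[i]!r}, column {nodes[j]!r} in {path}"
                )
            adj[i, j] = _TOKENS[token]
    return GeneNetwork(nodes, adj, module_map)


def write_edgelist_tsv(net: GeneNetwork, path: str | Path) -> None:
    """Sparse form: one row per known ordered pair (target, source, value)."""
    records = []
    for i, target in enumerate(net.nodes):
        for j, source in enumerate(net.nodes):
            v = net.adjacency[i, j]
            if not is_unknown(v):
                records.append((target, source, int(v)))
    pd.DataFrame(records, columns=["target", "source", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist_tsv(path: str | Path, nodes: Sequence[str] | None = None) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"target": str, "source": str})
    for col in ("target", "source", "value"):
        if col not in df.columns:
            raise GraphValueError(f"edge list {path} missing column {col!r}")
    if nodes is None:
        seen: dict[str, None] = {}
        for name in pd.concat([df["target"], df["source"]]):
            seen.setdefault(str(name))
        nodes = list(seen)
    entries = [(str(r.target), str(r.source), float(r.value)) for r in df.itertuples()]
    return make_network(nodes, entries)


def write_sif(net: GeneNetwork, path: str | Path) -> None:
    """Cytoscape SIF export.  SIF cannot express unknown or explicit-absent
    pairs, so those are dropped; undirected edges get their own relation."""
    lines = []
    for src, tgt in net.directed_edges():
        lines.append(f"{src}\tregulates\t{tgt}")
    for a, b in net.undirected_edges():
        lines.append(f"{a}\tinteracts\t{b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    g = nx.DiGraph()
    for node in net.nodes:
        attrs = {}
        if net.module_map and node in net.module_map and net.module_map[node]:
            attrs["module"] = net.module_map[node]
        g.add_node(node, **attrs)
    for src, tgt in net.directed_edges():
        g.add_edge(src, tgt, kind="directed")
    for a, b in net.undirected_edges():
        g.add_edge(a, b, kind="undirected")
    nx.write_graphml(g, path)


def write_dot(net: GeneNetwork, path: str | Path) -> None:
    lines = ["digraph grn {"]
    for node in net.nodes:
        lines.append(f'  "{node}";')
    for src, tgt in net.directed_edges():
        lines.append(f'  "{src}" -> "{tgt}";')
    for a, b in net.undirected_edges():
        lines.append(f'  "{a}" -> "{b}" [dir=none, style=dashed];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


_WRITERS = {
    "adjacency-csv": write_adjacency_csv,
    "edgelist-tsv": write_edgelist_tsv,
    "sif": write_sif,
    "graphml": write_graphml,
    "dot": write_dot,
}


def write_network(net: GeneNetwork, path: str | Path, format: str = "adjacency-csv") -> None:
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise GraphValueError(f"unknown network format {format!r}") from None
    writer(net, path)


def read_network(path: str | Path, format: str = "adjacency-csv", **kwargs) -> GeneNetwork:
    if format == "adjacency-csv":
        return read_adjacency_csv(path, **kwargs)
    if format == "edgelist-tsv":
        return read_edgelist_tsv(path, **kwargs)
    raise GraphValueError(f"no reader for network format {format!r}")
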