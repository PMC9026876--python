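"""Multi-layer protein interaction network and proximity queries.

The map is a set of protein nodes (UniProt accessions) joined by
layer-tagged undirected interactions (physical, signaling, metabolic,
regulation).  All distance and random-walk computations run on the
*collapsed* simple graph: an interacting pair counts once for topology no
matter how many layers report it.  Direction (e.g. TF -> target in the
regulation layer) is kept only as metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

LAYERS = ("physical", "signaling", "metabolic", "regulation")


class _Unreachable:
    """Sentinel for node pairs in different components."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()


def normalize_accession(acc: str) -> str:
    """Canonicalize a UniProt accession: trim, uppercase, drop isoform suffix.

    ``"P07996-2 "`` -> ``"P07996"``.  Raises ``ValueError`` on empty input.
    """
    acc = acc.strip().upper()
    if "-" in acc:
        acc = acc.split("-", 1)[0]
    if not acc:
        raise ValueError("empty protein accession")
    return acc


@dataclass
class LoadReport:
    """Bookkeeping from one edge-list read."""

    lines: int = 0
    unique_edges: int = 0
    dropped_self_loops: int = 0
    dropped_duplicates: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


class KnowledgeGraph:
    """Undirected multi-layer interaction network over protein accessions.

    Thin wrapper around :class:`networkx.Graph`; the per-pair ``layers``
    edge attribute records every (layer, provenance) pair that reported the
    interaction, while topology queries see a single edge.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        self.load_report: LoadReport | None = None
        self._diameter_cap: int | None = None

    # -- construction -------------------------------------------------

    def add_node(self, acc: str, gene_name: str | None = None,
                 layer: str | None = None) -> str:
        acc = normalize_accession(acc)
        if acc not in self._g:
            self._g.add_node(acc, gene_name=gene_name, layers=set())
        if gene_name is not None:
            self._g.nodes[acc]["gene_name"] = gene_name
        if layer is not None:
            self._g.nodes[acc]["layers"].add(layer)
        return acc

    def add_edge(self, a: str, b: str, layer: str = "physical",
                 provenance: str = "") -> bool:
        """Add one layer-tagged interaction; returns False for a self-loop.

        Re-adding a pair in a new layer appends a layer record without
        changing topology.
        """
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        a = self.add_node(a, layer=layer)
        b = self.add_node(b, layer=layer)
        if a == b:
            return False
        if not self._g.has_edge(a, b):
            self._g.add_edge(a, b, layers={})
        self._g.edges[a, b]["layers"].setdefault(layer, []).append(provenance)
        self._diameter_cap = None
        return True

    def remove_edge(self, a: str, b: str) -> None:
        self._g.remove_edge(a, b)
        self._diameter_cap = None

    @classmethod
    def read_edge_list(cls, path: str | Path, layer: str = "physical") -> "KnowledgeGraph":
        """Read a TSV (``source<TAB>target[<TAB>provenance]``) or SIF file.

        ``.sif`` files are whitespace-delimited ``source relation target``.
        ``#`` lines are comments.  Self-loops are dropped (and counted in
        ``load_report``); duplicate pairs within the layer are deduplicated.
        """
        path = Path(path)
        sif = path.suffix.lower() == ".sif"
        g = cls()
        rep = LoadReport()
        seen: set[frozenset] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                if sif:
                    fields = line.split()
                    if len(fields) != 3:
                        raise ValueError(
                            f"{path}:{lineno}: malformed SIF line (expected "
                            f"'source relation target', got {len(fields)} fields)")
                    src, prov, dst = fields
                else:
                    fields = line.split("\t")
                    if len(fields) < 2:
                        raise ValueError(
                            f"{path}:{lineno}: malformed line (expected >=2 "
                            f"tab-separated columns, got {len(fields)})")
                    src, dst = fields[0], fields[1]
                    prov = fields[2] if len(fields) > 2 else ""
                if not src.strip() or not dst.strip():
                    raise ValueError(f"{path}:{lineno}: empty protein ID field")
                rep.lines += 1
                src, dst = normalize_accession(src), normalize_accession(dst)
                if src == dst:
                    rep.dropped_self_loops += 1
                    continue
                key = frozenset((src, dst))
                if key in seen:
                    rep.dropped_duplicates += 1
                    g._g.edges[src, dst]["layers"][layer].append(prov)
                    continue
                seen.add(key)
                g.add_edge(src, dst, layer=layer, provenance=prov)
        rep.unique_edges = len(seen)
        g.load_report = rep
        return g

    # -- accessors -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Edges in the collapsed simple graph (layer-agnostic)."""
        return self._g.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> Iterable[tuple[str, str]]:
        return self._g.edges()

    def has_node(self, acc: str) -> bool:
        return acc in self._g

    def neighbors(self, acc: str) -> set[str]:
        self._require(acc)
        return set(self._g.neighbors(acc))

    def degree(self, acc: str) -> int:
        self._require(acc)
        return self._g.degree[acc]

    def degree_sequence(self) -> dict[str, int]:
        """Degree of every node in the collapsed simple graph."""
        return dict(self._g.degree())

    def gene_name(self, acc: str) -> str | None:
        self._require(acc)
        return self._g.nodes[acc].get("gene_name")

    def layer_records(self, a: str, b: str) -> dict[str, list[str]]:
        return dict(self._g.edges[a, b]["layers"])

    def _require(self, acc: str) -> None:
        if acc not in self._g:
            raise KeyError(f"protein {acc!r} is not in the graph")

    # -- proximity -----------------------------------------------------

    def shortest_path_length(self, a: str, b: str):
        """Hop distance on the collapsed graph; ``UNREACHABLE`` across components."""
        self._require(a)
        self._require(b)
        try:
            return nx.shortest_path_length(self._g, a, b)
        except nx.NetworkXNoPath:
            return UNREACHABLE

    def single_source_distances(self, source: str) -> dict[str, int]:
        """BFS hop distances from ``source`` to every reachable node."""
        self._require(source)
        return dict(nx.single_source_shortest_path_length(self._g, source))

    def multi_source_distances(self, sources: Iterable[str]) -> dict[str, int]:
        """Hop distance from the nearest of ``sources`` to every reachable node."""
        sources = list(sources)
        for s in sources:
            self._require(s)
        return dict(nx.multi_source_dijkstra_path_length(self._g, sources, weight=None))

    def diameter_cap(self) -> int:
        """Diameter of the largest connected component, plus one.

        Used as the finite stand-in for ``UNREACHABLE`` when distances must
        enter a feature vector.  Cached; invalidated on edge insertion.
        """
        if self._diameter_cap is None:
            if self.n_nodes == 0:
                self._diameter_cap = 1
            else:
                comp = max(nx.connected_components(self._g), key=len)
                sub = self._g.subgraph(comp)
                d = nx.diameter(sub) if len(comp) > 1 else 0
                self._diameter_cap = d + 1
        return self._diameter_cap

    def rwr_proximity(self, seeds: Iterable[str], restart: float = 0.3,
                      tol: float = 1e-10) -> dict[str, float]:
        """Random walk with restart seeded uniformly on ``seeds``.

        Stationary distribution of the walk that, at each step, restarts to
        a uniform seed with probability ``restart`` and otherwise moves to a
        uniform neighbor; walkers on degree-0 nodes restart.  Solved exactly
        as a sparse linear system; the result sums to 1 within ``tol``.
        """
        seeds = sorted({normalize_accession(s) for s in seeds})
        if not seeds:
            raise ValueError("seed set is empty")
        for s in seeds:
            if s not in self._g:
                raise KeyError(f"seed protein {s!r} is not in the graph")
        if not 0.0 < restart < 1.0:
            raise ValueError(f"restart probability must be in (0,1), got {restart}")
        nodes = list(self._g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        e = np.zeros(n)
        e[[idx[s] for s in seeds]] = 1.0 / len(seeds)
        deg = np.array([self._g.degree[v] for v in nodes], dtype=float)
        # Column-stochastic transition; dangling columns restart to the seeds.
        rows, cols, vals = [], [], []
        for u, v in self._g.edges():
            iu, iv = idx[u], idx[v]
            rows.append(iv); cols.append(iu); vals.append(1.0 / deg[iu])
            rows.append(iu); cols.append(iv); vals.append(1.0 / deg[iv])
        dangling = deg == 0
        for j in np.flatnonzero(dangling):
            for i in np.flatnonzero(e):
                rows.append(int(i)); cols.append(int(j)); vals.append(float(e[i]))
        W = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        A = sp.eye(n, format="csc") - (1.0 - restart) * W
        p = spla.spsolve(A, restart * e)
        p = np.asarray(p).ravel()
        total = p.sum()
        if not math.isclose(total, 1.0, abs_tol=max(tol, 1e-8) * n):
            p = p / total
        return {nodes[i]: float(p[i]) for i in range(n)}

    # -- misc ----------------------------------------------------------

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        g._g = self._g.copy()
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (set(self._g.nodes) == set(other._g.nodes)
                and {frozenset(e) for e in self._g.edges}
                == {frozenset(e) for e in other._g.edges})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"KnowledgeGraph(nodes={self.n_nodes}, edges={self.n_edges})"


def merge_graphs(graphs: list[KnowledgeGraph]) -> KnowledgeGraph:
    """Union of node sets and layer records; topology is the collapsed union.

    A pair reported in k layers carries k layer records but one topological
    edge.  Merging an empty list yields an empty graph; merging a graph with
    itself is a topological no-op.
    """
    out = KnowledgeGraph()
    for g in graphs:
        for acc in g.nodes():
            out.add_node(acc, gene_name=g.gene_name(acc))
        for a, b in g.edges():
            for layer, provs in g.layer_records(a, b).items():
                for prov in provs:
                    out.add_edge(a, b, layer=layer, provenance=prov)
    return out


def write_edge_list(graph: KnowledgeGraph, path: str | Path) -> None:
    """Serialize the collapsed graph as a sorted TSV edge list."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tprovenance\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            recs = graph.layer_records(a, b)
            prov = ";".join(f"{layer}" for layer in sorted(recs))
            fh.write(f"{a}\t{b}\t{prov}\n")
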