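"""Synthetic studies with known ground truth.

The generator emulates the statistical structure the scoring method
assumes: a scale-free-like interaction network in which each disease
process is a densely wired module of effector proteins, and candidate
proteins sit either proximal to a module (related) or far from all of them
(unrelated).  Every stage of the pipeline can then be tested against the
planted labels without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np

from .disease import (CandidateEntry, CandidateList, CausalLevel, DiseaseMap,
                      Motive, save_candidates, save_disease_map)
from .graph import UNREACHABLE, KnowledgeGraph, write_edge_list
from .scoring import TruthTable, build_truth_table

_LEVEL_CYCLE = (CausalLevel.causative, CausalLevel.symptomatic, CausalLevel.both)


def generate_graph(n_nodes: int, edges_per_node: int, seed: int = 0) -> KnowledgeGraph:
    """Preferential-attachment network.

    Starts from a single edge; each subsequent node attaches
    ``min(edges_per_node, #existing)`` edges to distinct targets chosen with
    probability proportional to degree.  Connected by construction, with the
    heavy-tailed degree distribution typical of interaction networks.  Edge
    count is ``1 + sum_i min(m, i-1)`` over nodes ``i = 3..n``.
    """
    if n_nodes < 2:
        raise ValueError(f"need n_nodes >= 2, got {n_nodes}")
    if not 1 <= edges_per_node < n_nodes:
        raise ValueError(f"need 1 <= edges_per_node < n_nodes, got {edges_per_node}")
    rng = np.random.default_rng(seed)
    g = KnowledgeGraph()
    names = [f"SYN{i:05d}" for i in range(1, n_nodes + 1)]
    g.add_edge(names[0], names[1], provenance="generated")
    # repeated-node list: each entry one unit of degree
    pool = [names[0], names[1]]
    for i in range(2, n_nodes):
        k = min(edges_per_node, i)
        targets: set[str] = set()
        while len(targets) < k:
            targets.add(pool[int(rng.integers(0, len(pool)))])
        for t in sorted(targets):
            g.add_edge(names[i], t, provenance="generated")
            pool.append(t)
        pool.extend([names[i]] * k)
    return g


def _internal_edges(graph: KnowledgeGraph, module: set[str]) -> list[tuple[str, str]]:
    return [(a, b) for a, b in combinations(sorted(module), 2)
            if b in graph.neighbors(a)]


def _module_density(graph: KnowledgeGraph, module: set[str]) -> float:
    n = len(module)
    if n < 2:
        return 1.0
    return len(_internal_edges(graph, module)) / (n * (n - 1) / 2)


def plant_motives(graph: KnowledgeGraph, k_motives: int,
                  size_range: tuple[int, int], rewire_fraction: float = 0.1,
                  seed: int = 0, density_floor: float = 0.3) -> DiseaseMap:
    """Select k disjoint connected node sets as motive modules and densify.

    Modules are grown breadth-first from random roots over still-unused
    nodes; internal edges are added until each module's internal density
    reaches ``density_floor``, then ``rewire_fraction`` of the internal
    edges are swapped for random missing internal pairs (connectivity
    preserved) to decorrelate local structure.  Causal levels are assigned
    round-robin.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad size range {size_range}")
    if k_motives * hi > graph.n_nodes / 2:
        raise ValueError(
            f"{k_motives} modules of up to {hi} nodes exceed half the "
            f"{graph.n_nodes}-node graph")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    motives: list[Motive] = []
    all_nodes = sorted(graph.nodes())
    for mi in range(k_motives):
        size = int(rng.integers(lo, hi + 1))
        module: set[str] | None = None
        roots = [n for n in all_nodes if n not in used]
        rng.shuffle(roots)
        for root in roots:
            picked = {root}
            frontier = [root]
            while frontier and len(picked) < size:
                nxt = []
                for node in frontier:
                    for nb in sorted(graph.neighbors(node)):
                        if nb not in used and nb not in picked:
                            picked.add(nb)
                            nxt.append(nb)
                            if len(picked) == size:
                                break
                    if len(picked) == size:
                        break
                frontier = nxt
            if len(picked) == size:
                module = picked
                break
        if module is None:
            raise ValueError(
                f"cannot place {k_motives} disjoint modules of size "
                f"{size_range} in a {graph.n_nodes}-node graph")
        used |= module
        # densify to the floor
        missing = [(a, b) for a, b in combinations(sorted(module), 2)
                   if b not in graph.neighbors(a)]
        rng.shuffle(missing)
        while _module_density(graph, module) < density_floor and missing:
            a, b = missing.pop()
            graph.add_edge(a, b, provenance="planted")
        # rewire a fraction of internal edges (degree-free swap, keep density)
        internal = _internal_edges(graph, module)
        n_swap = int(rewire_fraction * len(internal))
        for _ in range(n_swap):
            internal = _internal_edges(graph, module)
            absent = [(a, b) for a, b in combinations(sorted(module), 2)
                      if b not in graph.neighbors(a)]
            if not absent:
                break
            old = internal[int(rng.integers(0, len(internal)))]
            new = absent[int(rng.integers(0, len(absent)))]
            graph.remove_edge(*old)
            graph.add_edge(*new, provenance="planted")
            if not _is_connected_subset(graph, module):
                graph.remove_edge(*new)
                graph.add_edge(*old, provenance="planted")
        motives.append(Motive(
            motive_id=f"motive_{mi + 1}",
            name=f"Planted module {mi + 1}",
            level=_LEVEL_CYCLE[mi % len(_LEVEL_CYCLE)],
            effectors=frozenset(module)))
    return DiseaseMap(motives=motives, general_effectors=frozenset())


def _is_connected_subset(graph: KnowledgeGraph, module: set[str]) -> bool:
    module = set(module)
    start = next(iter(sorted(module)))
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in graph.neighbors(node):
            if nb in module and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == module


@dataclass
class PlantedCandidates:
    """Candidate list plus ground truth: related motive id or None."""

    candidates: CandidateList
    labels: dict[str, str | None]


def plant_candidates(graph: KnowledgeGraph, dmap: DiseaseMap,
                     n_related_per_motive: int, n_unrelated: int,
                     attach_edges: int = 3, unrelated_min_distance: int = 2,
                     seed: int = 0) -> PlantedCandidates:
    """Plant labelled candidates.

    Related candidates are *new* nodes wired with ``attach_edges`` edges
    into one module (hop distance 1 by construction); unrelated candidates
    are *existing* nodes at distance >= ``unrelated_min_distance`` from
    every module, so their degrees are realistic for degree-matched nulls.
    """
    rng = np.random.default_rng(seed)
    module_nodes = sorted(set().union(*(m.effectors for m in dmap.motives)))
    dmin = graph.multi_source_distances(module_nodes)
    pool = [n for n in sorted(graph.nodes())
            if dmin.get(n, np.inf) >= unrelated_min_distance]
    if len(pool) < n_unrelated:
        raise ValueError(
            f"only {len(pool)} nodes lie at distance >= "
            f"{unrelated_min_distance} from all modules (need {n_unrelated}); "
            f"try a smaller unrelated_min_distance")
    unrelated = [str(x) for x in rng.choice(pool, size=n_unrelated, replace=False)]
    entries: list[CandidateEntry] = []
    labels: dict[str, str | None] = {}
    idx = 1
    for m in dmap.motives:
        members = sorted(m.effectors)
        k = min(attach_edges, len(members))
        for _ in range(n_related_per_motive):
            cand = f"CANDR{idx:04d}"
            idx += 1
            targets = rng.choice(members, size=k, replace=False)
            for t in sorted(str(x) for x in targets):
                graph.add_edge(cand, t, provenance="planted-candidate")
            entries.append(CandidateEntry(cand, f"planted related ({m.motive_id})"))
            labels[cand] = m.motive_id
    for u in unrelated:
        entries.append(CandidateEntry(u, "background protein"))
        labels[u] = None
    return PlantedCandidates(candidates=CandidateList(entries=entries),
                             labels=labels)


@dataclass
class StudyParams:
    """Default synthetic study conditions."""

    n_nodes: int = 500
    edges_per_node: int = 3
    k_motives: int = 4
    motive_size_range: tuple[int, int] = (8, 15)
    rewire_fraction: float = 0.1
    n_related_per_motive: int = 5
    n_unrelated: int = 20
    attach_edges: int = 3
    related_max_distance: int = 1
    unrelated_min_distance: int = 2
    neg_per_pos: int = 1
    min_neg_distance: int = 2


@dataclass
class SyntheticStudy:
    graph: KnowledgeGraph
    dmap: DiseaseMap
    candidates: CandidateList
    labels: dict[str, str | None]
    truth_table: TruthTable
    params: StudyParams
    seed: int

    def check_invariants(self) -> None:
        """Verify the planted distance contracts for every candidate."""
        for uid, motive_id in self.labels.items():
            if motive_id is not None:
                effs = self.dmap.effectors_of(motive_id)
                d = min(self.graph.shortest_path_length(uid, e) for e in effs)
                if d is UNREACHABLE or d > self.params.related_max_distance:
                    raise AssertionError(
                        f"related candidate {uid} at distance {d} from "
                        f"{motive_id} (max {self.params.related_max_distance})")
            else:
                for m in self.dmap.motives:
                    ds = [self.graph.shortest_path_length(uid, e)
                          for e in m.effectors]
                    ds = [d for d in ds if d is not UNREACHABLE]
                    if ds and min(ds) < self.params.unrelated_min_distance:
                        raise AssertionError(
                            f"unrelated candidate {uid} at distance {min(ds)} "
                            f"from {m.motive_id}")

    def write(self, outdir: str | Path) -> list[Path]:
        """Serialize the bundle; byte-identical for identical seeds."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []
        p = outdir / "edges.tsv"
        write_edge_list(self.graph, p)
        files.append(p)
        p = outdir / "disease_map.yaml"
        save_disease_map(self.dmap, p)
        files.append(p)
        p = outdir / "candidates.tsv"
        save_candidates(self.candidates, p)
        files.append(p)
        p = outdir / "truth_labels.tsv"
        with open(p, "w") as fh:
            fh.write("uniprot_id\trelated_motive\n")
            for e in self.candidates.entries:
                fh.write(f"{e.uniprot_id}\t{self.labels[e.uniprot_id] or 'none'}\n")
        files.append(p)
        p = outdir / "params.json"
        doc = asdict(self.params)
        doc["seed"] = self.seed
        p.write_text(json.dumps(doc, indent=2, sort_keys=True))
        files.append(p)
        return files


def simulate_study(params: StudyParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Compose graph, modules, candidates, and truth table into one bundle.

    Stage seeds are derived from ``seed`` by fixed offsets, so two runs with
    the same seed produce byte-identical serialized bundles.
    """
    params = params or StudyParams()
    graph = generate_graph(params.n_nodes, params.edges_per_node, seed=seed + 1)
    dmap = plant_motives(graph, params.k_motives, params.motive_size_range,
                         rewire_fraction=params.rewire_fraction, seed=seed + 2)
    planted = plant_candidates(
        graph, dmap, params.n_related_per_motive, params.n_unrelated,
        attach_edges=params.attach_edges,
        unrelated_min_distance=params.unrelated_min_distance, seed=seed + 3)
    table = build_truth_table(dmap, graph, neg_per_pos=params.neg_per_pos,
                              min_neg_distance=params.min_neg_distance,
                              seed=seed + 4)
    return SyntheticStudy(graph=graph, dmap=dmap,
                          candidates=planted.candidates,
                          labels=planted.labels, truth_table=table,
                          params=params, seed=seed)
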