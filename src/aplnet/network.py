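"""Minimal connected network (MCN) analysis over a protein interactome.

Seed genes (the recurrently mutated set plus known disease genes) are
mapped onto an undirected interactome.  The MCN keeps every direct
seed-seed interaction and admits a non-seed *intermediate* node when it is
adjacent to at least two seeds whose pair lacks a direct edge — i.e. one
intermediate is allowed on length-2 paths between seeds.  An optional
pruning step reduces the intermediate set to a minimum-cardinality subset
that preserves the seed-component partition (exact subset search up to a
size limit, greedy beyond it; ties broken lexicographically so the result
is deterministic).

Connectivity of the observed seed set is scored against random seed sets
of the same size (uniform over interactome nodes, or degree-matched), with
add-one empirical p-values: p = (1 + #{null >= observed}) / (M + 1) for
greater-is-connected statistics, reversed for the component count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment import EnrichmentResult

STATISTICS = ("connected_seed_count", "components", "mean_seed_degree")


class Interactome:
    """Undirected simple graph over gene symbols (no self-loops, no duplicates)."""

    def __init__(self, graph: nx.Graph) -> None:
        graph = nx.Graph(graph)
        graph.remove_edges_from(nx.selfloop_edges(graph))
        self.graph = graph
        self._adj: dict[str, frozenset[str]] = {
            node: frozenset(graph.neighbors(node)) for node in graph.nodes
        }

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def adjacency(self) -> Mapping[str, frozenset[str]]:
        return self._adj

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Interactome":
        graph = nx.Graph()
        graph.add_edges_from(edges)
        return cls(graph)

    @classmethod
    def from_sif(cls, path: str | Path) -> "Interactome":
        """Read a SIF ('A pp B', whitespace-delimited) or two-column edge list."""
        graph = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) == 3:
                    u, _, v = fields
                elif len(fields) == 2:
                    u, v = fields
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 or 3 fields, got {len(fields)}"
                    )
                if u != v:
                    graph.add_edge(u, v)
        return cls(graph)

    def to_sif(self, path: str | Path, relation: str = "pp") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{relation}\t{v}\n")


@dataclass
class MCNResult:
    """Minimal connected network with node roles and seed connectivity."""

    seeds: list[str]
    missing: list[str]
    intermediates: list[str]
    edges: list[tuple[str, str]]
    seed_components: list[list[str]]

    @property
    def roles(self) -> dict[str, str]:
        roles = {s: "seed" for s in self.seeds}
        roles.update({v: "intermediate" for v in self.intermediates})
        return roles

    @property
    def components(self) -> int:
        """Connected components among seeds (isolated seeds included)."""
        return len(self.seed_components)

    @property
    def connected_seed_count(self) -> int:
        """Seeds lying in a component of size >= 2."""
        return sum(len(c) for c in self.seed_components if len(c) >= 2)

    def connected_seeds(self) -> set[str]:
        return {s for c in self.seed_components if len(c) >= 2 for s in c}

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        for node in sorted(self.seeds) + sorted(self.intermediates):
            graph.add_node(node, role=self.roles[node])
        for u, v in sorted(self.edges):
            graph.add_edge(u, v)
        return graph


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry

    def partition(self) -> frozenset[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return frozenset(frozenset(g) for g in groups.values())


def _seed_partition(
    adj: Mapping[str, frozenset[str]],
    seeds: frozenset[str],
    intermediates: Iterable[str],
) -> frozenset[frozenset[str]]:
    uf = _UnionFind(seeds)
    for s in seeds:
        for t in adj[s] & seeds:
            uf.union(s, t)
    for v in intermediates:
        nb = sorted(adj[v] & seeds)
        for t in nb[1:]:
            uf.union(nb[0], t)
    return uf.partition()


def _candidate_intermediates(
    adj: Mapping[str, frozenset[str]], seeds: frozenset[str]
) -> list[str]:
    out = []
    for v in adj:
        if v in seeds:
            continue
        nb = adj[v] & seeds
        if len(nb) < 2:
            continue
        nbl = sorted(nb)
        if any(
            nbl[j] not in adj[nbl[i]]
            for i in range(len(nbl))
            for j in range(i + 1, len(nbl))
        ):
            out.append(v)
    return sorted(out)


def _prune_intermediates(
    adj: Mapping[str, frozenset[str]],
    seeds: frozenset[str],
    candidates: list[str],
    target: frozenset[frozenset[str]],
    exact_limit: int,
) -> list[str]:
    """Minimum subset of candidates preserving the seed-component partition.

    Exact search (increasing subset size, lexicographic order) when the
    candidate count allows; otherwise greedy removal of the most redundant
    intermediate (fewest seed neighbors, lexicographic ties) until no
    single removal preserves the partition.
    """
    if _seed_partition(adj, seeds, ()) == target:
        return []
    if len(candidates) <= exact_limit:
        for size in range(1, len(candidates) + 1):
            for subset in combinations(candidates, size):
                if _seed_partition(adj, seeds, subset) == target:
                    return list(subset)
        return list(candidates)
    kept = list(candidates)
    while True:
        removable = [
            v for v in kept if _seed_partition(adj, seeds, [u for u in kept if u != v]) == target
        ]
        if not removable:
            return kept
        victim = min(removable, key=lambda v: (len(adj[v] & seeds), v))
        kept.remove(victim)


def build_mcn(
    seeds: Iterable[str],
    net: Interactome,
    prune: bool = True,
    exact_prune_limit: int = 16,
) -> MCNResult:
    """Build the minimal connected network of a seed gene set.

    Seeds absent from the interactome are reported in ``missing`` (not an
    error unless *no* seed maps).  Deterministic and invariant to input
    order.
    """
    seed_list = sorted(set(seeds))
    adj = net.adjacency
    present = frozenset(s for s in seed_list if s in adj)
    missing = sorted(set(seed_list) - present)
    if not present:
        raise ValueError(f"no seed maps to the interactome; unmatched: {missing}")

    candidates = _candidate_intermediates(adj, present)
    target = _seed_partition(adj, present, candidates)
    if prune:
        intermediates = _prune_intermediates(
            adj, present, candidates, target, exact_prune_limit
        )
    else:
        intermediates = candidates

    edges: set[tuple[str, str]] = set()
    for s in present:
        for t in adj[s] & present:
            edges.add(tuple(sorted((s, t))))
    for v in intermediates:
        for s in adj[v] & present:
            edges.add(tuple(sorted((v, s))))

    partition = _seed_partition(adj, present, intermediates)
    seed_components = sorted((sorted(c) for c in partition), key=lambda c: (-len(c), c))
    return MCNResult(
        seeds=sorted(present),
        missing=missing,
        intermediates=sorted(intermediates),
        edges=sorted(edges),
        seed_components=seed_components,
    )


def mcn_statistics(result: MCNResult) -> dict[str, float]:
    """Connectivity statistics: connected seed count, component count,
    mean seed degree within the MCN."""
    degree = {s: 0 for s in result.seeds}
    for u, v in result.edges:
        if u in degree:
            degree[u] += 1
        if v in degree:
            degree[v] += 1
    mean_degree = sum(degree.values()) / len(result.seeds) if result.seeds else 0.0
    return {
        "connected_seed_count": float(result.connected_seed_count),
        "components": float(result.components),
        "mean_seed_degree": mean_degree,
    }


# ---------------------------------------------------------------------------
# Resampling null
# ---------------------------------------------------------------------------


@dataclass
class NullSummary:
    """Observed connectivity statistic against M random seed-set draws."""

    statistic: str
    observed: float
    M: int
    null_values: list[float]
    p_value: float
    rng_seed: int
    mode: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "statistic": self.statistic,
                    "observed": self.observed,
                    "M": self.M,
                    "p_value": self.p_value,
                    "rng_seed": self.rng_seed,
                    "mode": self.mode,
                    "null_values": self.null_values,
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def null_pvalue(observed: float, null_values: Sequence[float], statistic: str) -> float:
    """Add-one empirical p-value; component counts are smaller-is-connected."""
    null_arr = np.asarray(null_values, dtype=float)
    if statistic == "components":
        exceed = int(np.sum(null_arr <= observed))
    else:
        exceed = int(np.sum(null_arr >= observed))
    return (1 + exceed) / (len(null_arr) + 1)


def _degree_bins(net: Interactome) -> dict[int, list[str]]:
    bins: dict[int, list[str]] = {}
    for node in net.nodes:
        bins.setdefault(int(np.log2(net.degree(node) + 1)), []).append(node)
    return bins


def sample_null(
    net: Interactome,
    seed_size: int,
    M: int,
    mode: str = "uniform",
    rng_seed: int = 0,
    observed_seeds: Sequence[str] | None = None,
    prune: bool = False,
) -> list[dict[str, float]]:
    """Draw M random seed sets and score each through the MCN statistics.

    ``uniform``: node sets drawn without replacement from the interactome.
    ``degree_matched``: each draw matches the observed seeds' log2-degree
    bin profile (requires ``observed_seeds``); infeasible bins raise with
    the offending bins listed.  Reproducible given ``rng_seed``.  Pruning
    is off by default: the partition statistics are pruning-invariant and
    the mean seed degree is then measured on the unpruned MCN, observed
    and null alike.
    """
    nodes = net.nodes
    if seed_size > len(nodes):
        raise ValueError(f"seed_size {seed_size} exceeds node count {len(nodes)}")
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if mode == "uniform":
        draws = [
            [str(x) for x in rng.choice(nodes, size=seed_size, replace=False)]
            for _ in range(M)
        ]
    elif mode == "degree_matched":
        if observed_seeds is None:
            raise ValueError("degree_matched mode requires observed_seeds")
        bins = _degree_bins(net)
        need: dict[int, int] = {}
        for s in observed_seeds:
            need[int(np.log2(net.degree(s) + 1))] = (
                need.get(int(np.log2(net.degree(s) + 1)), 0) + 1
            )
        short = {b: k for b, k in need.items() if k > len(bins.get(b, []))}
        if short:
            raise ValueError(f"degree bins too small for matched sampling: {short}")
        draws = []
        for _ in range(M):
            draw: list[str] = []
            for b, k in sorted(need.items()):
                draw.extend(str(x) for x in rng.choice(bins[b], size=k, replace=False))
            draws.append(draw)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return [
        mcn_statistics(build_mcn(draw, net, prune=prune)) for draw in draws
    ]


def mcn_significance(
    seeds: Iterable[str],
    net: Interactome,
    statistic: str = "connected_seed_count",
    M: int = 999,
    mode: str = "uniform",
    rng_seed: int = 0,
    prune: bool = False,
) -> NullSummary:
    """Score the observed seed set's connectivity against the resampling null."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    observed_result = build_mcn(seeds, net, prune=prune)
    observed = mcn_statistics(observed_result)[statistic]
    null_stats = sample_null(
        net,
        seed_size=len(observed_result.seeds),
        M=M,
        mode=mode,
        rng_seed=rng_seed,
        observed_seeds=observed_result.seeds,
        prune=prune,
    )
    null_values = [s[statistic] for s in null_stats]
    return NullSummary(
        statistic=statistic,
        observed=observed,
        M=M,
        null_values=null_values,
        p_value=null_pvalue(observed, null_values, statistic),
        rng_seed=rng_seed,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """A prioritized gene: network-connected and recurrence-enriched."""

    gene: str
    enrichment_p: float
    k: int
    n: int
    cooccurrence_degree: int = 0


@dataclass
class PrioritizationResult:
    candidates: list[Candidate]
    not_in_network: list[str]  # enrichment-significant genes outside the interactome/MCN


def prioritize_candidates(
    null_summary: NullSummary,
    mcn: MCNResult,
    enrichment: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    cooccurrence_degree: Mapping[str, int] | None = None,
) -> PrioritizationResult:
    """Intersect network connectivity with recurrence enrichment.

    Candidates are seeds that (a) lie in a seed component of size >= 2 of
    an MCN whose null p-value is at most ``alpha`` and (b) are
    enrichment-significant; sorted by enrichment p-value then symbol, each
    annotated with its co-occurrence significant-degree when supplied.
    """
    significant = {r.gene: r for r in enrichment if r.p_value <= alpha}
    connected = mcn.connected_seeds() if null_summary.p_value <= alpha else set()
    candidates = [
        Candidate(
            gene=g,
            enrichment_p=significant[g].p_value,
            k=significant[g].k,
            n=significant[g].n,
            cooccurrence_degree=(cooccurrence_degree or {}).get(g, 0),
        )
        for g in sorted(connected & set(significant))
    ]
    candidates.sort(key=lambda c: (c.enrichment_p, c.gene))
    not_in_network = sorted(set(significant) - set(mcn.seeds))
    return PrioritizationResult(candidates=candidates, not_in_network=not_in_network)


def write_mcn_sif(result: MCNResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(result.edges):
            fh.write(f"{u}\tpp\t{v}\n")


def write_mcn_graphml(result: MCNResult, path: str | Path) -> None:
    nx.write_graphml(result.to_graph(), str(path))
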