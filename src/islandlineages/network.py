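"""Median-joining networks of Y-STR haplotypes (Bandelt et al. 1999 style).

A minimum-spanning network (MSN) at tolerance ``epsilon`` connects every
pair of haplotypes whose direct distance does not exceed the single-linkage
merge level of their clusters by more than ``epsilon``; at ``epsilon = 0``
this is exactly the union of all minimum spanning trees.  Median vectors
(per-locus medians of connected triplets) are then added whenever they
shorten the network, to a fixpoint, and obsolete medians are pruned.

Haplotypes are repeat-count vectors over the single-copy Yfiler loci; the
duplicated DYS385 locus is excluded by default because the per-locus
median of an unordered pair is ill-defined.  All tie-breaks (edge
insertion order, median candidate order) are deterministic — the
published algorithm leaves them open, and reproducibility requires fixing
them — so the output is invariant to input ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .core_io import IslandLineagesError, StrProfile, YFILER_SINGLE_COPY_LOCI

__all__ = [
    "HaplotypeNetwork",
    "IterationLimitError",
    "str_distance",
    "minimum_spanning_network",
    "median_joining",
]


class IterationLimitError(IslandLineagesError, RuntimeError):
    """Median insertion failed to converge within the round limit."""


def str_distance(a: StrProfile, b: StrProfile) -> int:
    """Single-step distance: sum of |repeat difference| over the 16 loci,
    with the unordered DYS385 pair matched under the cheaper assignment."""
    if set(a.repeats) != set(b.repeats):
        raise IslandLineagesError(
            f"locus sets differ between {a.sample_id} and {b.sample_id}"
        )
    d = sum(abs(a.repeats[l] - b.repeats[l]) for l in a.repeats)
    (a1, a2), (b1, b2) = a.dys385, b.dys385
    return d + min(abs(a1 - b1) + abs(a2 - b2), abs(a1 - b2) + abs(a2 - b1))


def _vector_distance(u: tuple[int, ...], v: tuple[int, ...]) -> int:
    return int(sum(abs(x - y) for x, y in zip(u, v)))


@dataclass
class HaplotypeNetwork:
    """A haplotype graph: observed vectors plus inferred median vectors.

    Nodes are repeat-count tuples; node attributes carry ``observed``,
    ``frequency``, ``samples`` and ``populations``.
    """

    graph: nx.Graph
    loci: tuple[str, ...]
    epsilon: int = 0

    @property
    def observed_nodes(self) -> list[tuple[int, ...]]:
        return [n for n, obs in self.graph.nodes(data="observed") if obs]

    @property
    def median_nodes(self) -> list[tuple[int, ...]]:
        return [n for n, obs in self.graph.nodes(data="observed") if not obs]

    def total_length(self) -> float:
        return float(sum(w for _, _, w in self.graph.edges(data="weight")))

    def edge_list(self) -> list[tuple[tuple, tuple, int]]:
        return sorted((min(u, v), max(u, v), w) for u, v, w in self.graph.edges(data="weight"))

    def to_gml(self, path) -> None:
        g = nx.relabel_nodes(
            self.graph, {n: "-".join(map(str, n)) for n in self.graph.nodes}, copy=True
        )
        for _, attrs in g.nodes(data=True):
            attrs["samples"] = ",".join(attrs.get("samples", ()))
            attrs["populations"] = ",".join(attrs.get("populations", ()))
        nx.write_gml(g, path)


def _single_linkage_levels(nodes: Sequence[tuple], dist: np.ndarray) -> dict[frozenset, int]:
    """Cophenetic (single-linkage merge) level for every node pair."""
    comp = {n: i for i, n in enumerate(nodes)}
    members: dict[int, list] = {i: [n] for i, n in enumerate(nodes)}
    levels: dict[frozenset, int] = {}
    order = sorted(
        (int(dist[i, j]), nodes[i], nodes[j])
        for i, j in itertools.combinations(range(len(nodes)), 2)
    )
    for d, u, v in order:
        cu, cv = comp[u], comp[v]
        if cu == cv:
            continue
        for a in members[cu]:
            for b in members[cv]:
                levels[frozenset((a, b))] = d
        for b in members[cv]:
            comp[b] = cu
        members[cu].extend(members.pop(cv))
    return levels


def minimum_spanning_network(
    nodes: Sequence[tuple[int, ...]], epsilon: int = 0
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over haplotype vectors.

    An edge (u, v) is included iff ``d(u, v) <= merge_level(u, v) + epsilon``;
    at ``epsilon = 0`` the result contains every minimum spanning tree.
    """
    nodes = sorted(set(nodes))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) < 2:
        return g
    idx = {n: i for i, n in enumerate(nodes)}
    dist = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u, v in itertools.combinations(nodes, 2):
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = _vector_distance(u, v)
    levels = _single_linkage_levels(nodes, dist)
    for u, v in itertools.combinations(nodes, 2):
        d = int(dist[idx[u], idx[v]])
        if d <= levels[frozenset((u, v))] + epsilon:
            g.add_edge(u, v, weight=d)
    return g


def _msn_length(nodes: Sequence[tuple], epsilon: int) -> float:
    g = minimum_spanning_network(nodes, epsilon)
    return float(sum(w for _, _, w in g.edges(data="weight")))


def _median_vector(u: tuple, v: tuple, w: tuple) -> tuple[int, ...]:
    return tuple(int(np.median([a, b, c])) for a, b, c in zip(u, v, w))


def median_joining(
    profiles: Sequence[StrProfile],
    epsilon: int = 0,
    max_median_rounds: int = 100,
    loci: Sequence[str] = YFILER_SINGLE_COPY_LOCI,
) -> HaplotypeNetwork:
    """Median-joining network of Y-STR haplotypes.

    Iterates: build the MSN at tolerance ``epsilon``; for every connected
    triplet (at least two of the three pairwise links present) whose
    per-locus median is new, add the median if it shortens the network;
    repeat to a fixpoint, then prune medians whose removal does not
    lengthen the network.
    """
    if not profiles:
        raise IslandLineagesError("median_joining needs at least one profile")
    loci = tuple(loci)
    observed: dict[tuple, dict] = {}
    for p in profiles:
        vec = p.vector(loci)
        attrs = observed.setdefault(
            vec, {"frequency": 0, "samples": [], "populations": set()}
        )
        attrs["frequency"] += 1
        attrs["samples"].append(p.sample_id)
        if p.population:
            attrs["populations"].add(p.population)
    if len(observed) < 2:
        g = nx.Graph()
        for vec, attrs in observed.items():
            g.add_node(vec, observed=True, **_freeze(attrs))
        return HaplotypeNetwork(g, loci, epsilon)

    nodes: list[tuple] = sorted(observed)
    for round_no in range(max_median_rounds + 1):
        g = minimum_spanning_network(nodes, epsilon)
        length = float(sum(w for _, _, w in g.edges(data="weight")))
        candidates = set()
        for u in g.nodes:
            nbrs = sorted(g.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                m = _median_vector(u, v, w)
                if m not in g.nodes:
                    candidates.add(m)
        improved = False
        for m in sorted(candidates):
            if _msn_length(nodes + [m], epsilon) < length - 1e-9:
                nodes = sorted(nodes + [m])
                improved = True
                break
        if not improved:
            break
        if round_no == max_median_rounds:
            raise IterationLimitError(
                f"median insertion still improving after {max_median_rounds} rounds"
            )

    # Prune medians that no longer shorten the network.
    changed = True
    while changed:
        changed = False
        length = _msn_length(nodes, epsilon)
        for m in sorted(n for n in nodes if n not in observed):
            remaining = [n for n in nodes if n != m]
            if _msn_length(remaining, epsilon) <= length + 1e-9:
                nodes = remaining
                changed = True
                break

    g = minimum_spanning_network(nodes, epsilon)
    for n in g.nodes:
        if n in observed:
            g.nodes[n].update(observed=True, **_freeze(observed[n]))
        else:
            g.nodes[n].update(observed=False, frequency=0, samples=(), populations=())
    return HaplotypeNetwork(g, loci, epsilon)


def _freeze(attrs: Mapping) -> dict:
    return {
        "frequency": attrs["frequency"],
        "samples": tuple(sorted(attrs["samples"])),
        "populations": tuple(sorted(attrs["populations"])),
    }
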