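"""Paired-end clustering: variant graph, maximal-clique heuristic, PE calls.

Discordant pairs of one signature class are nodes of an undirected weighted
graph; an edge joins two pairs whose left and right ends both lie within
the expected insert-size range, weighted by the difference of the SV sizes
they predict.  Each connected component contributes one cluster: a maximal
clique grown greedily from the smallest-weight edge.  Cluster coordinates
come from the innermost member coordinates on each breakpoint side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .libio import DiscordantPair, LibraryProfile


@dataclass
class VariantGraph:
    """Adjacency view over one signature class of discordant pairs."""

    nodes: list[int]
    adj: dict[int, dict[int, float]] = field(default_factory=dict)

    def add_edge(self, u: int, v: int, w: float) -> None:
        self.adj.setdefault(u, {})[v] = w
        self.adj.setdefault(v, {})[u] = w

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.adj.get(u, {})

    def edges(self):
        for u, nbrs in self.adj.items():
            for v, w in nbrs.items():
                if u < v:
                    yield u, v, w

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())


@dataclass
class PECall:
    """Imprecise paired-end SV call (interval estimate from a clique)."""

    id: str
    sv_type: str  # DEL / DUP / INV / TRA
    chrom: str
    start: int
    end: int
    pe_support: int
    mapq_mean: float
    member_ids: list[int]
    orientation: str  # original signature: DEL/DUP/INV_LEFT/INV_RIGHT/TRA_1..4
    chrom2: str | None = None  # TRA partner chromosome
    pos2: int | None = None  # TRA partner breakpoint
    precise: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start


def _predicted_size(p: DiscordantPair, profiles: dict[str, LibraryProfile]) -> float:
    """Library-adjusted SV size proxy: outer span minus the library median."""
    return (p.b_end - p.a_start) - profiles[p.library_id].median_insert


def build_variant_graph(pairs: list[DiscordantPair],
                        profiles: dict[str, LibraryProfile]) -> VariantGraph:
    """Line sweep over position-sorted pairs of one signature class.

    Edge condition: left starts and right ends each within the expected
    insert-size range (the larger ``insert_max`` of the two libraries).
    Intrachromosomal edge weight is the absolute difference of predicted SV
    sizes; for translocations it is the sum of absolute differences of the
    left-most alignment positions on both chromosomes.  The sweep abandons
    the inner scan at the first partner whose left-gap exceeds the range.
    """
    graph = VariantGraph(nodes=[p.pair_id for p in pairs])
    if not pairs:
        return graph
    interchrom = pairs[0].chrom_a != pairs[0].chrom_b
    imax = {lib: prof.insert_max for lib, prof in profiles.items()}
    max_range = max(imax.values())
    sizes = None if interchrom else [_predicted_size(p, profiles) for p in pairs]
    for i, pi in enumerate(pairs):
        for j in range(i + 1, len(pairs)):
            pj = pairs[j]
            if pj.a_start - pi.a_start > max_range:
                break
            rng = max(imax[pi.library_id], imax[pj.library_id])
            if pj.a_start - pi.a_start > rng:
                continue
            if interchrom:
                if abs(pi.b_start - pj.b_start) > rng:
                    continue
                w = abs(pi.a_start - pj.a_start) + abs(pi.b_start - pj.b_start)
            else:
                if abs(pi.b_end - pj.b_end) > rng:
                    continue
                w = abs(sizes[i] - sizes[j])
            graph.add_edge(pi.pair_id, pj.pair_id, float(w))
    return graph


def connected_components(graph: VariantGraph) -> list[list[int]]:
    """Node partition by reachability; singletons retained (dropped later)."""
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in graph.nodes:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph.adj.get(u, {}):
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def extract_clique(component: list[int], graph: VariantGraph) -> list[int]:
    """Greedy maximal clique seeded at the component's smallest-weight edge.

    The clique grows by repeatedly adding the node reachable through the
    smallest-weight edge incident to the clique whose addition keeps it a
    clique; equal weights break toward the smaller node id.  Singleton
    components yield no clique.
    """
    comp_set = set(component)
    edges = sorted(
        ((w, u, v) for u, v, w in graph.edges()
         if u in comp_set and v in comp_set),
        key=lambda t: (t[0], t[1], t[2]))
    if not edges:
        return []
    _, u0, v0 = edges[0]
    clique = {u0, v0}
    while True:
        best = None
        for w, u, v in edges:
            for inside, outside in ((u, v), (v, u)):
                if inside in clique and outside not in clique:
                    if all(graph.has_edge(outside, m) for m in clique):
                        cand = (w, outside)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            return sorted(clique)
        clique.add(best[1])


def clique_to_call(members: list[DiscordantPair], signature: str,
                   call_id: str) -> PECall | None:
    """Coordinate estimate from the innermost member coordinates.

    Deletions: [max upstream-read end, min downstream-read start).  The
    other types mirror the rule per breakpoint side, according to which
    side the supporting reads approach each breakpoint from.  Degenerate
    intrachromosomal estimates (start >= end) are discarded.
    """
    if len(members) < 2:
        return None
    a_start = min(p.a_start for p in members)
    a_end = max(p.a_end for p in members)
    b_start = min(p.b_start for p in members)
    b_end = max(p.b_end for p in members)
    mapq_mean = float(np.mean([p.mapq for p in members]))
    chrom = members[0].chrom_a
    chrom2 = members[0].chrom_b
    common = dict(pe_support=len(members), mapq_mean=mapq_mean,
                  member_ids=sorted(p.pair_id for p in members),
                  orientation=signature)
    if signature == "DEL":
        start, end = a_end, b_start
        sv_type = "DEL"
    elif signature == "DUP":
        start, end = a_start, b_end
        sv_type = "DUP"
    elif signature == "INV_LEFT":
        start, end = a_end, b_end
        sv_type = "INV"
    elif signature == "INV_RIGHT":
        start, end = a_start, b_start
        sv_type = "INV"
    elif signature.startswith("TRA"):
        # per-side innermost coordinate, by the strand reads approach with
        pos_a = a_end if members[0].strand_a == "+" else a_start
        pos_b = b_end if members[0].strand_b == "+" else b_start
        return PECall(call_id, "TRA", chrom, pos_a, pos_a + 1,
                      chrom2=chrom2, pos2=pos_b, **common)
    else:  # pragma: no cover
        raise ValueError(f"unknown signature {signature}")
    if start >= end:
        return None
    return PECall(call_id, sv_type, chrom, start, end, **common)


def call_paired_end(bins: dict[tuple, list[DiscordantPair]],
                    profiles: dict[str, LibraryProfile],
                    min_pairs: int = 2) -> list[PECall]:
    """Graph -> components -> cliques -> calls, per signature and chromosome bin.

    Different SV types are analyzed separately, so calls of different types
    may overlap or nest.  Only one clique is reported per component.
    """
    calls: list[PECall] = []
    counter = itertools.count(1)
    for key in sorted(bins):
        pairs = bins[key]
        by_id = {p.pair_id: p for p in pairs}
        graph = build_variant_graph(pairs, profiles)
        for comp in connected_components(graph):
            clique = extract_clique(comp, graph)
            if len(clique) < min_pairs:
                continue
            call = clique_to_call([by_id[i] for i in clique], key[0],
                                  f"pe{next(counter):05d}")
            if call is not None:
                calls.append(call)
    return calls
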