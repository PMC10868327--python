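"""Transcript path extraction from simplified cloud subgraphs.

After simplification a cloud's subgraph is usually a handful of simple
paths, one per captured mRNA molecule (barcodes are overwhelmingly likely
to tag molecules from distinct genes, so each connected component is
treated as one transcript).  Where branches survive — shared exons between
two captured genes, or short repeats inside one isoform — extension is
arbitrated by read linkage: a candidate edge is supported by read pairs
whose two mates straddle the junction at a separation compatible with the
library insert size (mean +- 3 SD, estimated per cloud set from pairs that
co-locate on a single edge), plus single reads whose alignment walks across
the junction.  Extension takes the winner only when its support clears an
absolute floor and a margin over the runner-up; otherwise the path stops —
conservative fragmentation is preferred over chimerism.

Repeated traversal of an edge is allowed when pair links demand it (short
repeats inside an isoform), capped at two visits per edge per path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import CloudSubgraph, GraphAlignment
from .graph import AssemblyGraph
from .io import ReadCloud
from .simplify import induced_in, induced_out, maximal_chains


@dataclass(frozen=True)
class TranscriptPath:
    """An ordered edge chain with terminal offsets, spellable as DNA."""

    barcode: str
    edges: tuple[str, ...]
    start_offset: int
    end_offset: int

    def spelled_length(self, graph: AssemblyGraph) -> int:
        k = graph.k
        total = sum(graph.edge_length(e) for e in self.edges)
        total -= (len(self.edges) - 1) * (k - 1)
        return total - self.start_offset - \
            (graph.edge_length(self.edges[-1]) - self.end_offset)


@dataclass(frozen=True)
class PathConfig:
    """Extension scoring tunables."""

    min_support: int = 2
    margin: float = 2.0
    lookahead_edges: int = 2
    max_edge_multiplicity: int = 2
    insert_prior_mean: float = 300.0
    insert_prior_sd: float = 50.0
    min_insert_samples: int = 5


def mirror_alignment(al: GraphAlignment, graph: AssemblyGraph
                     ) -> GraphAlignment:
    """The same placement expressed on the reverse-complement strand."""
    path = tuple(graph.twin(e) for e in reversed(al.edge_path))
    last_len = graph.edge_length(al.edge_path[-1])
    first_len = graph.edge_length(al.edge_path[0])
    return GraphAlignment(al.read_id, path,
                          last_len - al.end_offset,
                          first_len - al.start_offset,
                          al.strand, al.mismatches)


def pair_best_alignments(cloud: ReadCloud,
                         alignments: Mapping[str, Sequence[GraphAlignment]]
                         ) -> list[tuple[GraphAlignment | None,
                                         GraphAlignment | None]]:
    """Best alignment per mate for every pair of the cloud."""
    out = []
    for name, _r1, r2 in cloud.read_pairs:
        a1s = alignments.get(name + "/1")
        a2s = alignments.get(name + "/2") if r2 is not None else None
        out.append((a1s[0] if a1s else None, a2s[0] if a2s else None))
    return out


def estimate_insert_stats(pairs: Sequence[tuple[GraphAlignment | None,
                                                GraphAlignment | None]],
                          graph: AssemblyGraph,
                          config: PathConfig | None = None
                          ) -> tuple[float, float]:
    """Insert mean/SD from pairs whose mates co-locate on one edge.

    Falls back to the configured prior when too few unambiguous pairs are
    available (tiny clouds)."""
    config = config or PathConfig()
    samples = []
    for a1, a2 in pairs:
        if a1 is None or a2 is None:
            continue
        if len(a1.edge_path) != 1 or len(a2.edge_path) != 1:
            continue
        if graph.double_stranded:
            a2 = mirror_alignment(a2, graph)
        if a2.edge_path[0] != a1.edge_path[0]:
            continue
        lo = min(a1.start_offset, a2.start_offset)
        hi = max(a1.end_offset, a2.end_offset)
        samples.append(hi - lo)
    if len(samples) < config.min_insert_samples:
        return config.insert_prior_mean, config.insert_prior_sd
    arr = np.asarray(samples, dtype=float)
    return float(arr.mean()), max(float(arr.std()), 10.0)


@dataclass(frozen=True)
class _Link:
    up_edge: str
    up_end_off: int
    up_len: int
    down_edge: str
    down_start_off: int
    down_len: int


class PairLinkIndex:
    """Directional read-pair links and single-read junction spans.

    Every pair yields two directed hypotheses (molecule on either strand);
    support queries are therefore orientation-neutral.
    """

    def __init__(self, cloud: ReadCloud,
                 alignments: Mapping[str, Sequence[GraphAlignment]],
                 graph: AssemblyGraph, config: PathConfig | None = None):
        config = config or PathConfig()
        self.graph = graph
        self.config = config
        pairs = pair_best_alignments(cloud, alignments)
        self.insert_mean, self.insert_sd = \
            estimate_insert_stats(pairs, graph, config)
        self.window = self.insert_mean + 3 * self.insert_sd
        self.by_down: dict[str, list[_Link]] = defaultdict(list)
        self.by_up: dict[str, list[_Link]] = defaultdict(list)
        self.span: dict[tuple[str, str], int] = defaultdict(int)

        def add_link(up: GraphAlignment, down: GraphAlignment) -> None:
            link = _Link(up.edge_path[-1], up.end_offset,
                         up.aligned_length(graph),
                         down.edge_path[0], down.start_offset,
                         down.aligned_length(graph))
            self.by_down[link.down_edge].append(link)
            self.by_up[link.up_edge].append(link)

        for a1, a2 in pairs:
            if a1 is None or a2 is None:
                continue
            if graph.double_stranded:
                add_link(a1, mirror_alignment(a2, graph))
                add_link(a2, mirror_alignment(a1, graph))
            else:
                add_link(a1, a2)
                add_link(a2, a1)
        for als in alignments.values():
            al = als[0]
            reps = [al]
            if graph.double_stranded:
                reps.append(mirror_alignment(al, graph))
            for rep in reps:
                for a, b in zip(rep.edge_path, rep.edge_path[1:]):
                    self.span[(a, b)] += 1

    # -- support queries --------------------------------------------------

    def _insert_ok(self, implied: float) -> bool:
        return abs(implied - self.insert_mean) <= 3 * self.insert_sd

    def support_right(self, sub: CloudSubgraph, path: Sequence[str],
                      pos: Sequence[int], candidate: str) -> int:
        graph = self.graph
        k = graph.k
        junction = pos[-1] + graph.edge_length(path[-1]) - (k - 1)
        total = self.span.get((path[-1], candidate), 0)
        # candidate edge plus short lookahead beyond it, with positions
        targets: list[tuple[str, int]] = []
        frontier = [(candidate, junction)]
        for _ in range(self.config.lookahead_edges):
            targets.extend(frontier)
            nxt = []
            for eid, p in frontier:
                np_ = p + graph.edge_length(eid) - (k - 1)
                for succ in induced_out(sub, graph, graph.edges[eid].target):
                    nxt.append((succ, np_))
            frontier = nxt
        # path occurrences still within the insert window of the junction
        recent: list[tuple[str, int]] = []
        for i in range(len(path) - 1, -1, -1):
            end_pos = pos[i] + graph.edge_length(path[i])
            if junction - end_pos > self.window:
                break
            recent.append((path[i], pos[i]))
        for te, tpos in targets:
            for link in self.by_down.get(te, ()):
                for occ_edge, occ_pos in recent:
                    if occ_edge != link.up_edge:
                        continue
                    up_end = occ_pos + link.up_end_off
                    if up_end > junction + (k - 1):
                        continue
                    up_start = up_end - link.up_len
                    implied = (tpos + link.down_start_off + link.down_len) \
                        - up_start
                    if self._insert_ok(implied):
                        total += 1
                        break
        return total

    def support_left(self, sub: CloudSubgraph, path: Sequence[str],
                     pos: Sequence[int], candidate: str) -> int:
        graph = self.graph
        k = graph.k
        total = self.span.get((candidate, path[0]), 0)
        cand_pos = pos[0] - (graph.edge_length(candidate) - (k - 1))
        targets: list[tuple[str, int]] = []
        frontier = [(candidate, cand_pos)]
        for _ in range(self.config.lookahead_edges):
            targets.extend(frontier)
            nxt = []
            for eid, p in frontier:
                for pred in induced_in(sub, graph, graph.edges[eid].source):
                    nxt.append((pred,
                                p - (graph.edge_length(pred) - (k - 1))))
            frontier = nxt
        junction = pos[0]
        recent: list[tuple[str, int]] = []
        for i in range(len(path)):
            if pos[i] - junction > self.window:
                break
            recent.append((path[i], pos[i]))
        for te, tpos in targets:
            for link in self.by_up.get(te, ()):
                for occ_edge, occ_pos in recent:
                    if occ_edge != link.down_edge:
                        continue
                    down_start = occ_pos + link.down_start_off
                    if down_start < junction - (k - 1):
                        continue
                    up_start = tpos + link.up_end_off - link.up_len
                    implied = (down_start + link.down_len) - up_start
                    if self._insert_ok(implied):
                        total += 1
                        break
        return total


def _components(sub: CloudSubgraph, graph: AssemblyGraph
                ) -> list[frozenset[str]]:
    """Connected components (undirected) of the induced subgraph."""
    parent: dict[str, str] = {e: e for e in sub.edge_set}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_vertex: dict[str, list[str]] = defaultdict(list)
    for e in sub.edge_set:
        by_vertex[graph.edges[e].source].append(e)
        by_vertex[graph.edges[e].target].append(e)
    for edges in by_vertex.values():
        for other in edges[1:]:
            union(edges[0], other)
    groups: dict[str, set[str]] = defaultdict(set)
    for e in sub.edge_set:
        groups[find(e)].add(e)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def extract_paths(sub: CloudSubgraph, cloud: ReadCloud,
                  alignments: Mapping[str, Sequence[GraphAlignment]],
                  graph: AssemblyGraph,
                  config: PathConfig | None = None) -> list[TranscriptPath]:
    """Emit one transcript path per molecule captured by the cloud.

    Seeds one path per unvisited maximal chain, longest first, and extends
    it in both directions through branch vertices under the pair-link
    support rule.  On a double-stranded graph only the canonical
    orientation of each component is traversed.  Terminal offsets come from
    the extreme alignment positions of the terminal edges.
    """
    if sub.empty:
        return []
    config = config or PathConfig()
    links = PairLinkIndex(cloud, alignments, graph, config)
    k = graph.k
    max_len = 2 * len(sub.edge_set) + 4
    paths: list[TranscriptPath] = []
    all_chains = maximal_chains(sub, graph)
    for comp in _components(sub, graph):
        if graph.double_stranded:
            twin_comp = frozenset(graph.twin(e) for e in comp)
            if min(twin_comp) < min(comp):
                continue  # the mirror component is traversed instead
        chains = [c for c in all_chains if c[0] in comp]
        chains.sort(key=lambda c: (-sum(graph.edge_length(e) for e in c),
                                   tuple(c)))
        visited: set[str] = set()
        for chain in chains:
            if all(e in visited for e in chain):
                continue
            p = list(chain)
            pos = [0]
            for e in p[1:]:
                pos.append(pos[-1] + graph.edge_length(p[len(pos) - 1])
                           - (k - 1))

            def choose(cands: list[str], score) -> str | None:
                cands = [c for c in cands
                         if p.count(c) < config.max_edge_multiplicity]
                if not cands:
                    return None
                if len(cands) == 1:
                    c = cands[0]
                    if c not in p:
                        return c
                    return c if score(c) >= config.min_support else None
                scored = sorted(((score(c), c) for c in cands),
                                key=lambda t: (-t[0], t[1]))
                s1, winner = scored[0]
                s2 = scored[1][0]
                if s1 >= config.min_support and s1 >= config.margin * s2:
                    return winner
                # a repeat competes with its own context: when the
                # ambiguity involves an already-visited candidate, prefer
                # the best unvisited one if it scores at least as high —
                # the visited evidence is (or will be) explained by the
                # existing occurrence
                visited = [(s, c) for s, c in scored if c in p]
                fresh = [(s, c) for s, c in scored if c not in p]
                if visited and fresh:
                    s1, winner = fresh[0]
                    if s1 >= config.min_support and \
                            s1 >= max(s for s, _ in visited):
                        return winner
                return None

            while len(p) < max_len:
                cands = sorted(induced_out(sub, graph,
                                           graph.edges[p[-1]].target))
                c = choose(cands,
                           lambda c: links.support_right(sub, p, pos, c))
                if c is None:
                    break
                pos.append(pos[-1] + graph.edge_length(p[-1]) - (k - 1))
                p.append(c)
            while len(p) < max_len:
                cands = sorted(induced_in(sub, graph,
                                          graph.edges[p[0]].source))
                c = choose(cands,
                           lambda c: links.support_left(sub, p, pos, c))
                if c is None:
                    break
                pos.insert(0, pos[0] - (graph.edge_length(c) - (k - 1)))
                p.insert(0, c)
            visited.update(p)
            start = sub.extremes.get(p[0], (0, graph.edge_length(p[0])))[0]
            end = sub.extremes.get(p[-1],
                                   (0, graph.edge_length(p[-1])))[1]
            paths.append(TranscriptPath(cloud.barcode, tuple(p), start, end))
    return paths


def path_sequence(path: TranscriptPath, graph: AssemblyGraph) -> str:
    """Spell a transcript path as DNA, collapsing the k-1 overlaps and
    trimming to the terminal offsets."""
    k = graph.k
    if not path.edges:
        raise ValueError("empty path")
    for a, b in zip(path.edges, path.edges[1:]):
        if graph.edges[a].target != graph.edges[b].source:
            raise ValueError(f"edges {a} and {b} are not adjacent")
    parts = [graph.edges[path.edges[0]].seq]
    for e in path.edges[1:]:
        parts.append(graph.edges[e].seq[k - 1:])
    full = "".join(parts)
    last_len = graph.edge_length(path.edges[-1])
    if not (0 <= path.start_offset < graph.edge_length(path.edges[0])):
        raise ValueError("start offset out of range")
    if not (0 < path.end_offset <= last_len):
        raise ValueError("end offset out of range")
    out = full[path.start_offset: len(full) - (last_len - path.end_offset)]
    if not out:
        raise ValueError("path spells an empty sequence")
    return out
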