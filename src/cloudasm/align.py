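"""Alignment of cloud reads to the global graph and subgraph derivation.

Reads are aligned by seed-and-extend: exact k-mer seeds anchor the read on
an edge, and the placement is completed by walking adjacent edges in both
directions under a Hamming-distance budget (barcoded short reads are
substitution-dominated, and the graph was built from these same reads, so
indel-free extension is sufficient).  A read aligning equally well to
several loci contributes to every best-scoring locus for subgraph
membership and coverage; no fractional splitting is attempted, because the
per-cloud bulge-removal pass arbitrates later.

The cloud subgraph is the set of global edges touched by at least one
alignment of the cloud, annotated with barcode-specific coverage (aligned
bases per edge base) and the extreme (leftmost/rightmost) alignment
positions per edge, which later define transcript termini.  Deriving a
subgraph never mutates the global graph.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .graph import AssemblyGraph
from .io import ReadCloud
from .seq import revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphAlignment:
    """A read placed on a walk of graph edges.

    ``start_offset`` is 0-based on the first edge; ``end_offset`` is
    exclusive on the last edge.  ``strand`` is '+' when the read sequence
    itself was placed and '-' when its reverse complement was (only
    relevant for single-stranded graphs; a double-stranded graph contains
    both orientations, so reads are always placed as-is).
    """

    read_id: str
    edge_path: tuple[str, ...]
    start_offset: int
    end_offset: int
    strand: str
    mismatches: int

    def aligned_length(self, graph: AssemblyGraph) -> int:
        k = graph.k
        total = sum(graph.edge_length(e) for e in self.edge_path)
        total -= (len(self.edge_path) - 1) * (k - 1)
        return total - self.start_offset - \
            (graph.edge_length(self.edge_path[-1]) - self.end_offset)


class KmerIndex:
    """Exact k-mer -> (edge, offset) lookup over all graph edges."""

    def __init__(self, graph: AssemblyGraph, max_hits_per_kmer: int = 32):
        self.graph = graph
        self.max_hits = max_hits_per_kmer
        k = graph.k
        self.lookup: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for eid in sorted(graph.edges):
            seq = graph.edges[eid].seq
            for i in range(len(seq) - k + 1):
                self.lookup[seq[i:i + k]].append((eid, i))

    def get(self, kmer: str) -> list[tuple[str, int]]:
        hits = self.lookup.get(kmer, [])
        return hits[: self.max_hits]


def _extend_right(graph: AssemblyGraph, seq: str, i0: int, eid: str,
                  off0: int, budget: int) -> list[tuple[int, list[str], int]]:
    """Match ``seq[i0:]`` starting at position ``off0`` on edge ``eid``.

    Returns (mismatches, edge path, end offset) for all full-length
    completions within the budget, pruned against the best found so far.
    """
    results: list[tuple[int, list[str], int]] = []
    best = [budget + 1]
    k = graph.k

    def go(i: int, eid: str, off: int, mm: int, path: list[str]) -> None:
        s = graph.edges[eid].seq
        L = len(s)
        n = len(seq)
        while i < n and off < L:
            if seq[i] != s[off]:
                mm += 1
                if mm > budget or mm > best[0]:
                    return
            i += 1
            off += 1
        path = path + [eid]
        if i == n:
            if mm < best[0]:
                best[0] = mm
            results.append((mm, path, off))
            return
        for nxt in sorted(graph.out_edges(graph.edges[eid].target)):
            go(i, nxt, k - 1, mm, path)

    go(i0, eid, off0, 0, [])
    return results


def _extend_left(graph: AssemblyGraph, seq: str, i0: int, eid: str, off0: int,
                 budget: int) -> list[tuple[int, list[str], int]]:
    """Match ``seq[:i0]`` leftward, ending just before position ``off0`` on
    edge ``eid``.  Returns (mismatches, edge path preceding the anchor edge
    in left-to-right order, start offset on the first path edge — or on the
    anchor edge when the path is empty)."""
    results: list[tuple[int, list[str], int]] = []
    best = [budget + 1]
    k = graph.k

    def go(i: int, eid: str, off: int, mm: int, path: list[str]) -> None:
        # off: exclusive upper bound on this edge still to be matched
        s = graph.edges[eid].seq
        while i > 0 and off > 0:
            if seq[i - 1] != s[off - 1]:
                mm += 1
                if mm > budget or mm > best[0]:
                    return
            i -= 1
            off -= 1
        if i == 0:
            if mm < best[0]:
                best[0] = mm
            results.append((mm, list(reversed(path)), off))
            return
        for prv in sorted(graph.in_edges(graph.edges[eid].source)):
            pl = graph.edge_length(prv)
            go(i, prv, pl - (k - 1), mm, path + [prv])

    go(i0, eid, off0, 0, [])
    return results


def _align_oriented(seq: str, graph: AssemblyGraph, index: KmerIndex,
                    budget: int, max_anchors: int = 3
                    ) -> list[tuple[int, tuple[str, ...], int, int]]:
    """All co-best placements of ``seq`` (one orientation) on the graph."""
    k = graph.k
    n = len(seq)
    if n < k:
        return []
    hit_positions = [p for p in range(n - k + 1)
                     if seq[p:p + k] in index.lookup]
    if not hit_positions:
        return []
    anchors = {hit_positions[0], hit_positions[-1],
               hit_positions[len(hit_positions) // 2]}
    placements: list[tuple[int, tuple[str, ...], int, int]] = []
    seen: set[tuple[str, int]] = set()
    for p in sorted(anchors)[:max_anchors]:
        for eid, off in index.get(seq[p:p + k]):
            key = (eid, off - p)
            if key in seen:
                continue
            seen.add(key)
            lefts = _extend_left(graph, seq, p, eid, off, budget)
            if not lefts:
                continue
            lefts.sort(key=lambda r: (r[0], tuple(r[1])))
            for mml, lpath, start in lefts[:4]:
                rights = _extend_right(graph, seq, p, eid, off,
                                       budget - mml)
                for mmr, rpath, end in rights:
                    path = tuple(lpath) + tuple(rpath)
                    placements.append((mml + mmr, path, start, end))
    if not placements:
        return []
    best = min(p[0] for p in placements)
    out = sorted({p for p in placements if p[0] == best},
                 key=lambda p: (p[1], p[2]))
    return out


def align_read(read: str, graph: AssemblyGraph, index: KmerIndex | None = None,
               read_id: str = "", max_mismatch_frac: float = 0.05,
               all_best: bool = False
               ) -> GraphAlignment | list[GraphAlignment] | None:
    """Seed-and-extend alignment of one read.

    Returns the best alignment (fewest mismatches, deterministic
    tie-break), or the full co-best list when ``all_best`` is set, or
    ``None``/``[]`` when no seed k-mer is present in the graph or no
    placement fits the mismatch budget.
    """
    if index is None:
        index = KmerIndex(graph)
    if len(read) < graph.k:
        log.warning("read %s shorter than k; skipped", read_id or "<anon>")
        return [] if all_best else None
    budget = max(2, int(round(max_mismatch_frac * len(read))))
    read = read.upper()
    candidates = [(mm, path, s, e, "+")
                  for mm, path, s, e in _align_oriented(read, graph, index,
                                                        budget)]
    if not graph.double_stranded:
        # a double-stranded graph already contains both orientations
        candidates += [(mm, path, s, e, "-")
                       for mm, path, s, e in _align_oriented(
                           revcomp(read), graph, index, budget)]
    if not candidates:
        return [] if all_best else None
    best = min(c[0] for c in candidates)
    co_best = [GraphAlignment(read_id, path, s, e, strand, mm)
               for mm, path, s, e, strand in candidates if mm == best]
    co_best.sort(key=lambda a: (a.strand, a.edge_path, a.start_offset))
    if all_best:
        return co_best
    return co_best[0]


# -- subgraphs -------------------------------------------------------------


@dataclass
class CloudSubgraph:
    """Per-barcode view of the global graph.

    Mutable by the three subgraph simplifiers; the global graph itself is
    never touched.  ``coverage`` maps edge id to barcode-specific mean
    per-base depth; ``extremes`` maps edge id to the (leftmost, rightmost)
    alignment positions on that edge.
    """

    barcode: str
    edge_set: set[str] = field(default_factory=set)
    coverage: dict[str, float] = field(default_factory=dict)
    extremes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        assert set(self.coverage) <= self.edge_set
        assert set(self.extremes) <= self.edge_set

    @property
    def empty(self) -> bool:
        return not self.edge_set

    def copy(self) -> "CloudSubgraph":
        return CloudSubgraph(self.barcode, set(self.edge_set),
                             dict(self.coverage), dict(self.extremes))

    def remove_edge(self, eid: str) -> None:
        self.edge_set.discard(eid)
        self.coverage.pop(eid, None)
        self.extremes.pop(eid, None)

    def add_edge(self, eid: str, coverage: float,
                 extremes: tuple[int, int]) -> None:
        self.edge_set.add(eid)
        self.coverage[eid] = coverage
        self.extremes[eid] = extremes


def _alignment_intervals(al: GraphAlignment, graph: AssemblyGraph
                         ) -> list[tuple[str, int, int]]:
    """Covered (edge, start, end) intervals of one alignment."""
    path = al.edge_path
    if len(path) == 1:
        return [(path[0], al.start_offset, al.end_offset)]
    out = [(path[0], al.start_offset, graph.edge_length(path[0]))]
    for eid in path[1:-1]:
        out.append((eid, 0, graph.edge_length(eid)))
    out.append((path[-1], 0, al.end_offset))
    return out


def align_cloud(cloud: ReadCloud, graph: AssemblyGraph,
                index: KmerIndex | None = None,
                max_mismatch_frac: float = 0.05
                ) -> dict[str, list[GraphAlignment]]:
    """Best alignments (co-best list) for every read of a cloud."""
    if index is None:
        index = KmerIndex(graph)
    out: dict[str, list[GraphAlignment]] = {}
    for rid, seq in cloud.reads:
        als = align_read(seq, graph, index, read_id=rid,
                         max_mismatch_frac=max_mismatch_frac, all_best=True)
        if als:
            out[rid] = als
    return out


def derive_subgraph(cloud: ReadCloud, graph: AssemblyGraph,
                    alignments: Mapping[str, Sequence[GraphAlignment]]
                    | None = None,
                    index: KmerIndex | None = None) -> CloudSubgraph:
    """Edge subset touched by the cloud's alignments, with barcode-specific
    coverage and extreme positions.  On a double-stranded graph every
    contribution is mirrored onto the twin edge so the subgraph stays
    strand-symmetric."""
    if alignments is None:
        alignments = align_cloud(cloud, graph, index)
    bases: dict[str, int] = defaultdict(int)
    ext: dict[str, list[int]] = {}

    def add(eid: str, s: int, e: int) -> None:
        bases[eid] += e - s
        cur = ext.get(eid)
        if cur is None:
            ext[eid] = [s, e]
        else:
            cur[0] = min(cur[0], s)
            cur[1] = max(cur[1], e)

    for als in alignments.values():
        for al in als:
            for eid, s, e in _alignment_intervals(al, graph):
                add(eid, s, e)
                if graph.double_stranded:
                    tid = graph.twin(eid)
                    L = graph.edge_length(eid)
                    add(tid, L - e, L - s)
    sub = CloudSubgraph(cloud.barcode)
    if not bases and len(cloud) > 0:
        log.debug("cloud %s has no aligned reads; empty subgraph",
                  cloud.barcode)
    for eid in sorted(bases):
        cov = bases[eid] / graph.edge_length(eid)
        sub.add_edge(eid, cov, (ext[eid][0], ext[eid][1]))
    return sub
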