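"""Compacted de Bruijn graph construction and light global simplification.

All reads of a barcoded RNA-seq library are co-assembled into a single
compacted de Bruijn graph: vertices are (k-1)-mers, edges are maximal
unbranched sequences carrying the mean multiplicity of their constituent
k-mers as coverage.  The global graph is deliberately simplified only very
lightly (edges of extremely low coverage), because an edge that looks
erroneous globally may be the only witness of a rare isoform inside one
read cloud; all aggressive cleaning happens later on per-barcode subgraphs.

By default the graph is double-stranded: every edge has a reverse-complement
twin and the twin map is an involution.  A single-stranded mode is provided
for unit tests where strandedness is just noise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .seq import revcomp


@dataclass(frozen=True)
class Edge:
    """One compacted edge: an unbranched sequence with mean k-mer coverage."""

    eid: str
    seq: str
    source: str  # (k-1)-mer at the 5' end
    target: str  # (k-1)-mer at the 3' end
    coverage: float

    def __len__(self) -> int:
        return len(self.seq)


class AssemblyGraph:
    """Compacted de Bruijn graph over (k-1)-mer vertices.

    Immutable in practice: operations that change the edge set
    (:func:`prune_low_coverage`) return a new graph.  Edge identifiers are
    assigned deterministically (sorted by sequence), so two graphs built
    from the same input are identical object-for-object.
    """

    def __init__(self, k: int, edge_records: Iterable[tuple[str, float]],
                 double_stranded: bool = True):
        if k < 3 or k % 2 == 0:
            raise ValueError("k must be an odd integer >= 3")
        self.k = k
        self.double_stranded = double_stranded
        records = sorted(edge_records)
        self.edges: dict[str, Edge] = {}
        self._out: dict[str, list[str]] = defaultdict(list)
        self._in: dict[str, list[str]] = defaultdict(list)
        seq2id: dict[str, str] = {}
        width = max(1, len(str(max(len(records) - 1, 1))))
        for i, (seq, cov) in enumerate(records):
            if len(seq) < k:
                raise ValueError("edge sequence shorter than k")
            eid = f"E{i:0{width}d}"
            edge = Edge(eid, seq, seq[: k - 1], seq[-(k - 1):], float(cov))
            self.edges[eid] = edge
            self._out[edge.source].append(eid)
            self._in[edge.target].append(eid)
            seq2id[seq] = eid
        self._twin: dict[str, str] = {}
        if double_stranded:
            for eid, edge in self.edges.items():
                rc = revcomp(edge.seq)
                try:
                    self._twin[eid] = seq2id[rc]
                except KeyError:
                    raise ValueError(
                        "double-stranded graph is missing the reverse "
                        f"complement of edge {eid}") from None

    # -- topology ---------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        verts = set()
        for e in self.edges.values():
            verts.add(e.source)
            verts.add(e.target)
        return verts

    def out_edges(self, vertex: str) -> list[str]:
        return self._out.get(vertex, [])

    def in_edges(self, vertex: str) -> list[str]:
        return self._in.get(vertex, [])

    def out_degree(self, vertex: str) -> int:
        return len(self._out.get(vertex, ()))

    def in_degree(self, vertex: str) -> int:
        return len(self._in.get(vertex, ()))

    def twin(self, eid: str) -> str:
        if not self.double_stranded:
            raise ValueError("single-stranded graph has no twin edges")
        return self._twin[eid]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_length(self, eid: str) -> int:
        return len(self.edges[eid].seq)

    # -- invariants -------------------------------------------------------

    def assert_valid(self) -> None:
        """Check the structural invariants (used heavily in tests)."""
        k = self.k
        for e in self.edges.values():
            assert len(e.seq) >= k
            assert e.seq[: k - 1] == e.source
            assert e.seq[-(k - 1):] == e.target
        # compaction: no vertex with in-degree 1 / out-degree 1 joining two
        # distinct edges
        for v in self.vertices:
            if self.in_degree(v) == 1 and self.out_degree(v) == 1:
                a, b = self.in_edges(v)[0], self.out_edges(v)[0]
                assert a == b, f"vertex {v} is compressible ({a} -> {b})"
        if self.double_stranded:
            for eid, tid in self._twin.items():
                assert self._twin[tid] == eid, "twin map is not an involution"
                assert revcomp(self.edges[eid].seq) == self.edges[tid].seq

    # -- GFA1 -------------------------------------------------------------

    def to_gfa(self, path) -> None:
        """Write the graph as GFA1 (S lines with dp:f: coverage, L lines
        with k-1 overlaps)."""
        k = self.k
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for eid in sorted(self.edges):
                e = self.edges[eid]
                fh.write(f"S\t{eid}\t{e.seq}\tdp:f:{e.coverage:.4f}\n")
            for v in sorted(self.vertices):
                for a in sorted(self.in_edges(v)):
                    for b in sorted(self.out_edges(v)):
                        fh.write(f"L\t{a}\t+\t{b}\t+\t{k - 1}M\n")

    @classmethod
    def from_gfa(cls, path, k: int, double_stranded: bool = True
                 ) -> "AssemblyGraph":
        records = []
        links = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "S":
                    cov = 0.0
                    for tag in fields[3:]:
                        if tag.startswith("dp:f:"):
                            cov = float(tag[5:])
                    records.append((fields[2], cov))
                elif fields[0] == "L":
                    if fields[5] != f"{k - 1}M":
                        raise ValueError(
                            f"unexpected GFA overlap {fields[5]!r}")
                    links.append((fields[1], fields[3]))
        graph = cls(k, records, double_stranded=double_stranded)
        # adjacency is implied by shared (k-1)-mers; L lines only validated
        for a, b in links:
            if graph.edges[a].target != graph.edges[b].source:
                raise ValueError(f"GFA link {a}->{b} breaks the k-1 overlap")
        return graph


# -- construction ----------------------------------------------------------


def _count_kmers(reads: Iterable[str], k: int, double_stranded: bool
                 ) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    any_read = False
    for read in reads:
        any_read = True
        seqs = (read, revcomp(read)) if double_stranded else (read,)
        for s in seqs:
            s = s.upper()
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if "N" not in km:
                    counts[km] += 1
    if any_read and not counts:
        raise ValueError("no k-mers extracted")
    return dict(counts)


def _compact_kmers(counts: Mapping[str, int], k: int
                   ) -> list[tuple[str, float]]:
    """Collapse a k-mer multiset into maximal unbranched sequences."""
    out_by_vertex: dict[str, list[str]] = defaultdict(list)
    in_by_vertex: dict[str, list[str]] = defaultdict(list)
    for km in counts:
        out_by_vertex[km[:-1]].append(km)
        in_by_vertex[km[1:]].append(km)

    def branching(v: str) -> bool:
        return len(in_by_vertex.get(v, ())) != 1 or \
            len(out_by_vertex.get(v, ())) != 1

    edges: list[tuple[str, float]] = []
    visited: set[str] = set()

    def walk(start: str) -> None:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            v = cur[1:]
            if branching(v):
                break
            nxt = out_by_vertex[v][0]
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = chain[0] + "".join(c[-1] for c in chain[1:])
        cov = sum(counts[c] for c in chain) / len(chain)
        edges.append((seq, cov))

    for km in sorted(counts):
        if km not in visited and branching(km[:-1]):
            walk(km)
    # isolated cycles with no branching vertex
    for km in sorted(counts):
        if km not in visited:
            walk(km)
    return edges


def build_graph(reads: Iterable[str], k: int, double_stranded: bool = True
                ) -> AssemblyGraph:
    """Build the compacted de Bruijn graph of all reads combined.

    k-mers containing ``N`` are skipped.  An empty input yields an empty
    graph; a non-empty input in which no read reaches length ``k`` raises
    ``ValueError("no k-mers extracted")``.  Edge coverage is the mean count
    of the edge's constituent k-mers.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")
    counts = _count_kmers(reads, k, double_stranded)
    return AssemblyGraph(k, _compact_kmers(counts, k),
                         double_stranded=double_stranded)


# -- global simplification -------------------------------------------------


@dataclass(frozen=True)
class GlobalSimplifyConfig:
    """Thresholds for the light global cleanup of the co-assembly graph.

    cov_cutoff
        Absolute coverage floor: an edge below it is "extremely low" no
        matter the context.
    adaptive_frac
        The effective absolute floor is max(cov_cutoff, adaptive_frac x
        weighted-median edge coverage): errors recur in proportion to
        depth, so on deep data a fixed floor under-prunes.  Inert on
        shallow data.
    rel_cov
        Relative criterion: a tip or bulge branch is also extremely low
        when its coverage is under this fraction of its alternative's.
        Sequencing errors recur in proportion to depth, so a purely
        absolute cutoff cannot scale with deeply covered loci.
    max_tip_len
        Tips shorter than this are removal candidates; ``None`` means
        max(100, 2k) — error tips merge up to read scale, so the classic
        2k bound stalls the removal cascade for small k.
    bulge_span
        Bulges (two parallel simple paths between the same vertices, of
        similar length) are searched up to this spelled length and
        ``bulge_max_edges`` edges.  The length-similarity requirement
        (|dL| < max(50 bp, 10%)) is what separates error branches — exactly
        parallel to a same-length true segment — from genuine
        exon-skipping junctions, whose alternative differs by an exon.
    """

    cov_cutoff: float = 2.0
    adaptive_frac: float = 0.02
    rel_cov: float = 0.05
    max_tip_len: int | None = None
    bulge_span: int | None = None  # None -> max(150, 3k)
    bulge_max_edges: int = 4
    bulge_len_tol_abs: int = 50
    bulge_len_tol_frac: float = 0.10
    max_rounds: int = 100


def _recompact(graph: AssemblyGraph, keep: set[str]) -> list[tuple[str, float]]:
    """Re-compact the surviving edges (k-1 overlap merge of linear chains)."""
    k = graph.k
    out_by_vertex: dict[str, list[str]] = defaultdict(list)
    in_by_vertex: dict[str, list[str]] = defaultdict(list)
    for eid in keep:
        e = graph.edges[eid]
        out_by_vertex[e.source].append(eid)
        in_by_vertex[e.target].append(eid)

    def branching(v: str) -> bool:
        return len(in_by_vertex.get(v, ())) != 1 or \
            len(out_by_vertex.get(v, ())) != 1

    merged: list[tuple[str, float]] = []
    visited: set[str] = set()

    def walk(start: str) -> None:
        chain = [start]
        visited.add(start)
        cur = graph.edges[start]
        while True:
            v = cur.target
            if branching(v):
                break
            nxt = out_by_vertex[v][0]
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = graph.edges[nxt]
        seq = graph.edges[chain[0]].seq
        weight = len(seq) - k + 1
        cov = graph.edges[chain[0]].coverage * weight
        for eid in chain[1:]:
            e = graph.edges[eid]
            seq += e.seq[k - 1:]
            w = len(e.seq) - k + 1
            cov += e.coverage * w
            weight += w
        merged.append((seq, cov / weight))

    for eid in sorted(keep):
        if eid not in visited and branching(graph.edges[eid].source):
            walk(eid)
    for eid in sorted(keep):
        if eid not in visited:
            walk(eid)
    return merged


def _path_cov(graph: AssemblyGraph, path) -> float:
    num = den = 0.0
    for eid in path:
        w = len(graph.edges[eid].seq) - graph.k + 1
        num += graph.edges[eid].coverage * w
        den += w
    return num / den


def _find_bulge_removals(graph: AssemblyGraph, config: GlobalSimplifyConfig,
                         extreme, span: int) -> set[str]:
    """Edges with a similar-length, much better covered alternative path.

    Candidates are processed weakest-first; the alternative search is a
    spelled-length-bounded Dijkstra between the candidate's endpoints that
    avoids the candidate and everything already marked for removal, so a
    branch is never removed when its only detour has itself been removed
    this round.
    """
    k = graph.k
    remove: set[str] = set()
    candidates = sorted(
        (e for e in graph.edges.values() if len(e.seq) <= span),
        key=lambda e: (e.coverage, e.eid))
    for e in candidates:
        if e.eid in remove:
            continue
        tol = max(config.bulge_len_tol_abs,
                  config.bulge_len_tol_frac * len(e.seq))
        bound = len(e.seq) + tol
        # Dijkstra over spelled length from e.source towards e.target
        import heapq
        dist: dict[str, int] = {e.source: k - 1}
        parent: dict[str, tuple[str, str]] = {}
        heap = [(k - 1, e.source)]
        best = None
        while heap:
            d, v = heapq.heappop(heap)
            if d > dist.get(v, 1 << 30) or d > bound:
                continue
            if v == e.target and v in parent:
                best = d
                break
            for nxt in graph.out_edges(v):
                if nxt == e.eid or nxt in remove:
                    continue
                ne = graph.edges[nxt]
                nd = d + len(ne.seq) - (k - 1)
                if nd <= bound and nd < dist.get(ne.target, 1 << 30):
                    dist[ne.target] = nd
                    parent[ne.target] = (v, nxt)
                    heapq.heappush(heap, (nd, ne.target))
        if best is None or abs(best - len(e.seq)) >= tol:
            continue
        alt_path = []
        v = e.target
        while v in parent and (v != e.source or not alt_path):
            v, eid = parent[v]
            alt_path.append(eid)
            if v == e.source:
                break
        if not alt_path:
            continue
        alt_cov = _path_cov(graph, alt_path)
        if e.coverage < alt_cov and extreme(e.coverage, alt_cov):
            remove.add(e.eid)
    return remove


def _weighted_median_coverage(graph: AssemblyGraph) -> float:
    """Median coverage experienced by a sequenced base.

    Weighting by coverage x k-mers puts the median on the sequence that
    carries the read mass; error branches are numerous but carry almost
    none of it."""
    items = sorted((e.coverage, e.coverage * (len(e.seq) - graph.k + 1))
                   for e in graph.edges.values())
    total = sum(w for _, w in items)
    if not total:
        return 0.0
    acc = 0
    for cov, w in items:
        acc += w
        if acc * 2 >= total:
            return cov
    return items[-1][0]


def prune_low_coverage(graph: AssemblyGraph,
                       config: GlobalSimplifyConfig | None = None
                       ) -> AssemblyGraph:
    """Remove extremely low-covered tips and bulge branches, re-compact,
    and iterate until stable (so the operation is idempotent).

    A tip is removed when it is short and extremely low-covered relative
    to the route it hangs off; a bulge branch when it runs parallel to a
    similar-length alternative of much higher coverage.  "Extremely low"
    means below the absolute cutoff or below ``rel_cov`` times the
    alternative's coverage.
    """
    config = config or GlobalSimplifyConfig()
    max_tip_len = config.max_tip_len if config.max_tip_len is not None \
        else max(100, 2 * graph.k)
    span = config.bulge_span if config.bulge_span is not None \
        else max(150, 3 * graph.k)

    for _ in range(config.max_rounds):
        cutoff = max(config.cov_cutoff,
                     config.adaptive_frac *
                     _weighted_median_coverage(graph))

        def extreme(cov: float, alt: float) -> bool:
            return cov < cutoff or cov < config.rel_cov * alt

        remove: set[str] = set()
        for eid, e in graph.edges.items():
            dead = graph.in_degree(e.source) == 0 or \
                graph.out_degree(e.target) == 0
            if not dead or len(e.seq) >= max_tip_len:
                continue
            sibs = set(graph.out_edges(e.source) +
                       graph.in_edges(e.source) +
                       graph.out_edges(e.target) +
                       graph.in_edges(e.target)) - {eid}
            alt = max((graph.edges[s].coverage for s in sibs), default=0.0)
            if extreme(e.coverage, alt):
                remove.add(eid)
        remove |= _find_bulge_removals(graph, config, extreme, span)
        # error branches that merge into other error branches have no
        # parallel alternative; they are caught by the absolute cutoff
        # alone, protected so the strongest route at a vertex never goes
        for eid, e in graph.edges.items():
            if eid in remove or e.coverage >= cutoff or \
                    len(e.seq) >= max_tip_len:
                continue
            out_sibs = [s for s in graph.out_edges(e.source) if s != eid]
            in_sibs = [s for s in graph.in_edges(e.target) if s != eid]
            if not out_sibs or not in_sibs:
                continue
            rank = (e.coverage, eid)
            if rank < max((graph.edges[s].coverage, s) for s in out_sibs) \
                    and rank < max((graph.edges[s].coverage, s)
                                   for s in in_sibs):
                remove.add(eid)
        if graph.double_stranded:
            remove |= {graph.twin(eid) for eid in remove}
        if not remove:
            break
        keep = set(graph.edges) - remove
        graph = AssemblyGraph(graph.k, _recompact(graph, keep),
                              double_stranded=graph.double_stranded)
    return graph
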