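"""Subgraph-level correction passes: tip clipping, bulge removal, gap closing.

Because an edge that is erroneous for one barcode can be the true isoform
of another, nothing here ever modifies the global assembly graph; the three
passes only edit a cloud's own edge subset.  All of them work on *chains* —
sequences of global-graph edges that are unbranched inside the induced
subgraph — since a tip or bulge branch in the subgraph is typically a chain
of several global edges, and they use barcode-specific coverage rather than
global coverage.

The composition is applied in the order tips -> bulges -> gaps and iterated
to a fixpoint.  Tip clipping and bulge removal only shrink the edge set;
gap closing only grows it (re-inserting short global edges that a cloud's
coverage gap dropped, so that two fragments of one transcript merge back
into a single path).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass
from typing import Iterable

from .align import CloudSubgraph
from .graph import AssemblyGraph


@dataclass(frozen=True)
class CloudSimplifyConfig:
    """Tunables for the per-cloud passes (all in bp where applicable)."""

    max_tip_len: int = 100
    tip_rel_cov: float = 0.5
    bulge_len_tol_abs: int = 50
    bulge_len_tol_frac: float = 0.10
    check_bulge_lengths: bool = True
    max_gap_edge_len: int = 100
    max_gap_edges: int = 3
    max_rounds: int = 10


# -- induced-subgraph topology helpers -------------------------------------


def induced_out(sub: CloudSubgraph, graph: AssemblyGraph, v: str) -> list[str]:
    return [e for e in graph.out_edges(v) if e in sub.edge_set]


def induced_in(sub: CloudSubgraph, graph: AssemblyGraph, v: str) -> list[str]:
    return [e for e in graph.in_edges(v) if e in sub.edge_set]


def induced_degree(sub: CloudSubgraph, graph: AssemblyGraph, v: str) -> int:
    """Total degree of a vertex counting only subgraph edges."""
    return len(induced_out(sub, graph, v)) + len(induced_in(sub, graph, v))


def chain_length(chain: Iterable[str], graph: AssemblyGraph) -> int:
    chain = list(chain)
    total = sum(graph.edge_length(e) for e in chain)
    return total - (len(chain) - 1) * (graph.k - 1)


def chain_coverage(chain: Iterable[str], sub: CloudSubgraph,
                   graph: AssemblyGraph) -> float:
    """Length-weighted mean barcode coverage of a chain."""
    num = den = 0.0
    for e in chain:
        L = graph.edge_length(e)
        num += sub.coverage.get(e, 0.0) * L
        den += L
    return num / den if den else 0.0


def maximal_chains(sub: CloudSubgraph, graph: AssemblyGraph
                   ) -> list[list[str]]:
    """Maximal unbranched edge chains of the induced subgraph.

    A chain extends through vertices whose induced in- and out-degree are
    both exactly one; it breaks at any other vertex.  Deterministic order.
    """
    def through(v: str) -> bool:
        return len(induced_in(sub, graph, v)) == 1 and \
            len(induced_out(sub, graph, v)) == 1

    chains: list[list[str]] = []
    visited: set[str] = set()

    def walk(start: str) -> None:
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            v = graph.edges[cur].target
            if not through(v):
                break
            nxt = induced_out(sub, graph, v)[0]
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        chains.append(chain)

    for eid in sorted(sub.edge_set):
        if eid not in visited and not through(graph.edges[eid].source):
            walk(eid)
    for eid in sorted(sub.edge_set):  # cycles
        if eid not in visited:
            walk(eid)
    return chains


def _remove_chain(sub: CloudSubgraph, graph: AssemblyGraph,
                  chain: Iterable[str]) -> None:
    for e in list(chain):
        sub.remove_edge(e)
        if graph.double_stranded:
            sub.remove_edge(graph.twin(e))


# -- tip clipping ----------------------------------------------------------


def clip_tips(sub: CloudSubgraph, graph: AssemblyGraph,
              max_tip_len: int = 100, rel_cov: float = 0.5) -> CloudSubgraph:
    """Remove dead-end / dead-start chains that are short or low-covered.

    A tip is a maximal chain whose far vertex has induced degree one and
    whose anchor vertex has induced degree greater than two (internal
    vertices have degree two by construction).  It is clipped when its
    spelled length is at most ``max_tip_len`` OR its mean barcode coverage
    is below ``rel_cov`` times the coverage of the through-path at the
    anchor vertex.  Applied iteratively to a fixpoint.
    """
    sub = sub.copy()
    changed = True
    guard = 0
    while changed and guard < 100:
        guard += 1
        changed = False
        for chain in maximal_chains(sub, graph):
            if not all(e in sub.edge_set for e in chain):
                continue
            first_v = graph.edges[chain[0]].source
            last_v = graph.edges[chain[-1]].target
            d_first = induced_degree(sub, graph, first_v)
            d_last = induced_degree(sub, graph, last_v)
            if d_last == 1 and d_first > 2:
                anchor, tip_edge = first_v, chain[0]
            elif d_first == 1 and d_last > 2:
                anchor, tip_edge = last_v, chain[-1]
            else:
                continue
            through = [e for e in
                       induced_out(sub, graph, anchor) +
                       induced_in(sub, graph, anchor)
                       if e != tip_edge]
            through_cov = max((sub.coverage.get(e, 0.0) for e in through),
                              default=0.0)
            short = chain_length(chain, graph) <= max_tip_len
            weak = chain_coverage(chain, sub, graph) < rel_cov * through_cov
            if short or weak:
                _remove_chain(sub, graph, chain)
                changed = True
    return sub


# -- bulge removal ---------------------------------------------------------


def remove_bulges(sub: CloudSubgraph, graph: AssemblyGraph,
                  config: CloudSimplifyConfig | None = None) -> CloudSubgraph:
    """Collapse pairs of parallel chains, keeping the better-covered one.

    Two maximal chains sharing start and end vertices (interiors disjoint
    by construction) form a bulge; the one with lower length-weighted mean
    barcode coverage is removed.  Ties keep the lexicographically smaller
    edge-id chain.  By default the two branches must also be of similar
    length (|dL| < max(50 bp, 10%)), the classical bulge criterion.
    """
    config = config or CloudSimplifyConfig()
    sub = sub.copy()
    changed = True
    guard = 0
    while changed and guard < 100:
        guard += 1
        changed = False
        groups: dict[tuple[str, str], list[list[str]]] = defaultdict(list)
        for chain in maximal_chains(sub, graph):
            s = graph.edges[chain[0]].source
            t = graph.edges[chain[-1]].target
            if s != t:
                groups[(s, t)].append(chain)
        for chains in groups.values():
            if len(chains) < 2:
                continue
            chains = sorted(chains,
                            key=lambda c: (-chain_coverage(c, sub, graph),
                                           tuple(c)))
            keep = chains[0]
            keep_len = chain_length(keep, graph)
            for other in chains[1:]:
                if config.check_bulge_lengths:
                    ol = chain_length(other, graph)
                    tol = max(config.bulge_len_tol_abs,
                              config.bulge_len_tol_frac * max(keep_len, ol))
                    if abs(ol - keep_len) >= tol:
                        continue
                _remove_chain(sub, graph, other)
                changed = True
            if changed:
                break  # chains are stale; recompute
    return sub


# -- gap closing -----------------------------------------------------------


def _gap_walks(sub: CloudSubgraph, graph: AssemblyGraph, start_v: str,
               targets: set[str], max_edge_len: int, max_edges: int
               ) -> dict[str, tuple[int, int, tuple[str, ...]]]:
    """Best walk (total bp, edge count, ids) over short non-subgraph edges
    from ``start_v`` to each reachable target vertex."""
    best: dict[str, tuple[int, int, tuple[str, ...]]] = {}
    queue: deque[tuple[str, int, tuple[str, ...]]] = deque()
    queue.append((start_v, 0, ()))
    while queue:
        v, bp, walk = queue.popleft()
        if len(walk) >= max_edges:
            continue
        for eid in sorted(graph.out_edges(v)):
            if eid in sub.edge_set or eid in walk:
                continue
            L = graph.edge_length(eid)
            if L > max_edge_len:
                continue
            nv = graph.edges[eid].target
            nwalk = walk + (eid,)
            nbp = bp + L
            if nv in targets:
                cand = (nbp, len(nwalk), nwalk)
                if nv not in best or cand < best[nv]:
                    best[nv] = cand
            queue.append((nv, nbp, nwalk))
    return best


def close_gaps(sub: CloudSubgraph, graph: AssemblyGraph,
               max_gap_edge_len: int = 100, max_gap_edges: int = 3
               ) -> CloudSubgraph:
    """Re-insert short global edges that merge two subgraph paths into one.

    For each ordered pair of maximal chains (P, Q) where P dead-ends and Q
    dead-starts, the best walk of global edges (each at most
    ``max_gap_edge_len`` bp, at most ``max_gap_edges`` of them, intermediate
    vertices untouched by the subgraph) from the end of P to the start of Q
    is added.  Added edges get the mean barcode coverage of the two flanking
    edges (so they are not immediately re-clipped) and whole-edge extreme
    positions.  Greedy, shortest-first, iterated to a fixpoint.
    """
    sub = sub.copy()
    guard = 0
    while guard < 100:
        guard += 1
        chains = maximal_chains(sub, graph)
        tails = []  # chains whose last vertex has no subgraph continuation
        heads = {}  # start vertex -> chain whose first vertex has no inflow
        for chain in chains:
            tv = graph.edges[chain[-1]].target
            if not induced_out(sub, graph, tv) and \
                    len(induced_in(sub, graph, tv)) == 1:
                tails.append(chain)
            v = graph.edges[chain[0]].source
            if not induced_in(sub, graph, v) and \
                    len(induced_out(sub, graph, v)) == 1:
                heads[v] = chain
        candidates = []
        for p in tails:
            start_v = graph.edges[p[-1]].target
            targets = set(heads)
            walks = _gap_walks(sub, graph, start_v, targets,
                               max_gap_edge_len, max_gap_edges)
            for tv, (bp, ne, walk) in walks.items():
                q = heads[tv]
                if q is p:
                    continue
                if graph.double_stranded and \
                        tuple(q) == tuple(reversed([graph.twin(e)
                                                    for e in p])):
                    continue  # would fold a chain onto its own twin
                # intermediate vertices must be untouched by the subgraph
                ok = True
                for eid in walk[:-1]:
                    if induced_degree(sub, graph, graph.edges[eid].target):
                        ok = False
                        break
                if ok:
                    candidates.append((bp, ne, walk, p, q))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        bp, ne, walk, p, q = candidates[0]
        cov = 0.5 * (sub.coverage.get(p[-1], 0.0) +
                     sub.coverage.get(q[0], 0.0))
        for eid in walk:
            sub.add_edge(eid, cov, (0, graph.edge_length(eid)))
            if graph.double_stranded:
                tid = graph.twin(eid)
                sub.add_edge(tid, cov, (0, graph.edge_length(tid)))
    return sub


# -- composition -----------------------------------------------------------


def simplify_subgraph(sub: CloudSubgraph, graph: AssemblyGraph,
                      config: CloudSimplifyConfig | None = None
                      ) -> CloudSubgraph:
    """Tips -> bulges -> gaps, iterated until the edge set is stable (or
    ``max_rounds`` is hit).  The identity on a clean single-transcript
    cloud."""
    config = config or CloudSimplifyConfig()
    for _ in range(config.max_rounds):
        before = frozenset(sub.edge_set)
        sub = clip_tips(sub, graph, config.max_tip_len, config.tip_rel_cov)
        sub = remove_bulges(sub, graph, config)
        sub = close_gaps(sub, graph, config.max_gap_edge_len,
                         config.max_gap_edges)
        if frozenset(sub.edge_set) == before:
            break
    return sub
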