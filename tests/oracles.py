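"""Independent brute-force oracles used by the test suite.

These deliberately take the slow, obvious route (uncompacted k-mer graph,
per-base depth arrays, exhaustive walk enumeration) so they stay
independent of the implementation they check.
"""

from __future__ import annotations

from collections import defaultdict

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def bruteforce_unbranched_sequences(reads, k, double_stranded=False):
    """Multiset (sorted list) of maximal unbranched path sequences of the
    uncompacted k-mer graph."""
    kmers = set()
    for read in reads:
        seqs = (read, rc(read)) if double_stranded else (read,)
        for s in seqs:
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if "N" not in km:
                    kmers.add(km)
    succ = defaultdict(list)
    pred = defaultdict(list)
    for km in kmers:
        succ[km[:-1]].append(km)
        pred[km[1:]].append(km)

    def node_branches(v):
        return len(succ.get(v, ())) != 1 or len(pred.get(v, ())) != 1

    paths = set()
    for km in kmers:
        # walk left from km to the start of its unbranched run
        cur = km
        seen = {km}
        while True:
            v = cur[:-1]
            if node_branches(v):
                break
            prv = pred[v][0]
            if prv in seen:
                break
            seen.add(prv)
            cur = prv
        # walk right collecting the run
        chain = [cur]
        seen = {cur}
        while True:
            v = chain[-1][1:]
            if node_branches(v):
                break
            nxt = succ[v][0]
            if nxt in seen:
                break
            chain.append(nxt)
            seen.add(nxt)
        paths.add(tuple(chain))
    out = []
    for chain in paths:
        out.append(chain[0] + "".join(c[-1] for c in chain[1:]))
    return sorted(out)


def depth_array_coverage(reads_with_pos, edge_len):
    """Mean per-base depth of an edge from (start, end) read intervals."""
    depth = [0] * edge_len
    for s, e in reads_with_pos:
        for i in range(s, e):
            depth[i] += 1
    return sum(depth) / edge_len


def enumerate_walks(graph, max_edges, edge_multiplicity=2):
    """All edge walks of a graph with bounded length and multiplicity."""
    walks = []

    def go(walk):
        walks.append(tuple(walk))
        if len(walk) >= max_edges:
            return
        v = graph.edges[walk[-1]].target
        for nxt in sorted(graph.out_edges(v)):
            if walk.count(nxt) < edge_multiplicity:
                go(walk + [nxt])

    for eid in sorted(graph.edges):
        go([eid])
    return walks


def spell_walk(graph, walk):
    k = graph.k
    seq = graph.edges[walk[0]].seq
    for e in walk[1:]:
        seq += graph.edges[e].seq[k - 1:]
    return seq
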