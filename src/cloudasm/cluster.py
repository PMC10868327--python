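"""Cross-barcode clustering of transcript paths and output filters.

Paths from different clouds that traverse the same edge chain and start /
end within a small window (default < 30 bp at each endpoint, strict) are
the same isoform and are pooled into one cluster.  The endpoint window is
what separates isoforms that differ only in their initial or final regions
(alternative transcription start / polyadenylation).  Each cluster keeps
the multiset of contributing barcodes: the number of *distinct* barcodes is
the abundance estimate of the isoform, and is also the handle for output
filtering (real transcripts recur across clouds, assembly noise does not).

On a double-stranded graph a path and its reverse complement are the same
molecule; chains are canonicalised before keying.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .graph import AssemblyGraph
from .paths import TranscriptPath, path_sequence


@dataclass
class Cluster:
    cluster_id: int
    chain: tuple[str, ...]
    leftmost: int       # representative start offset (founding path)
    rightmost: int      # representative end offset (founding path)
    barcodes: Counter = field(default_factory=Counter)
    sequence: str = ""

    @property
    def n_barcodes(self) -> int:
        """Abundance: number of distinct supporting barcodes."""
        return len(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.sequence)


class PathClusterStore:
    """Greedy first-match clustering keyed by edge chain + endpoint window.

    Deterministic under a fixed insertion order; the partition is not
    guaranteed to be insertion-order independent (documented behaviour of
    the greedy rule).
    """

    def __init__(self, endpoint_tol: int = 30):
        self.endpoint_tol = endpoint_tol
        self.clusters: dict[int, Cluster] = {}
        self.index: dict[tuple[str, ...], list[int]] = {}
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_paths(self) -> int:
        return sum(sum(c.barcodes.values()) for c in self.clusters.values())

    def _canonical(self, path: TranscriptPath, graph: AssemblyGraph
                   ) -> TranscriptPath:
        if not graph.double_stranded:
            return path
        rc_chain = tuple(graph.twin(e) for e in reversed(path.edges))
        if rc_chain < path.edges:
            last_len = graph.edge_length(path.edges[-1])
            first_len = graph.edge_length(path.edges[0])
            return TranscriptPath(path.barcode, rc_chain,
                                  last_len - path.end_offset,
                                  first_len - path.start_offset)
        return path

    def insert_path(self, path: TranscriptPath, graph: AssemblyGraph) -> int:
        """Insert one path; returns the cluster id it joined or founded."""
        path = self._canonical(path, graph)
        tol = self.endpoint_tol
        for cid in self.index.get(path.edges, ()):
            cl = self.clusters[cid]
            if abs(cl.leftmost - path.start_offset) < tol and \
                    abs(cl.rightmost - path.end_offset) < tol:
                cl.barcodes[path.barcode] += 1
                return cid
        cid = self._next_id
        self._next_id += 1
        cl = Cluster(cid, path.edges, path.start_offset, path.end_offset,
                     Counter([path.barcode]),
                     path_sequence(path, graph))
        self.clusters[cid] = cl
        self.index.setdefault(path.edges, []).append(cid)
        return cid


def insert_path(store: PathClusterStore, path: TranscriptPath,
                graph: AssemblyGraph) -> int:
    """Functional alias for :meth:`PathClusterStore.insert_path`."""
    return store.insert_path(path, graph)


def filter_clusters(store: PathClusterStore, min_length: int = 300,
                    min_barcodes: int = 1) -> list[Cluster]:
    """Clusters with sequence length strictly greater than ``min_length``
    and at least ``min_barcodes`` distinct barcodes, sorted by abundance
    then length (both descending)."""
    out = [c for c in store.clusters.values()
           if c.length > min_length and c.n_barcodes >= min_barcodes]
    out.sort(key=lambda c: (-c.n_barcodes, -c.length, c.cluster_id))
    return out


def write_clusters_fasta(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            edges = ",".join(c.chain)
            fh.write(f">cluster_{c.cluster_id} barcodes={c.n_barcodes} "
                     f"length={c.length} edges={edges}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i:i + 80] + "\n")


def clusters_table(clusters: list[Cluster]) -> pd.DataFrame:
    """One row per (cluster, barcode): cluster id, barcode, path length,
    edge chain."""
    rows = []
    for c in clusters:
        for bc in sorted(c.barcodes):
            rows.append({"cluster_id": c.cluster_id, "barcode": bc,
                         "length": c.length, "edges": ",".join(c.chain)})
    return pd.DataFrame(rows, columns=["cluster_id", "barcode", "length",
                                       "edges"])


def write_clusters_tsv(clusters: list[Cluster], path) -> None:
    clusters_table(clusters).to_csv(path, sep="\t", index=False)
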