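import numpy as np
import pytest

from cloudasm.graph import AssemblyGraph
from cloudasm.io import ReadCloud
from cloudasm.seq import random_dna


def clouds_from_pairs(pairs):
    """Group simulator output into ReadCloud objects, sorted by barcode."""
    clouds = {}
    for p in pairs:
        cloud = clouds.setdefault(p.barcode, ReadCloud(p.barcode))
        cloud.read_pairs.append((p.name, p.read1, p.read2))
    return [clouds[b] for b in sorted(clouds)]


def toy_graph(topology, k=5, lengths=None, seed=0):
    """Single-stranded graph from an explicit edge topology.

    ``topology`` is a list of (edge label, source label, target label);
    vertex labels get unique random (k-1)-mers, edge interiors are random.
    Returns (graph, {label: edge id}).
    """
    rng = np.random.default_rng(seed)
    lengths = lengths or {}
    verts = {}
    for _, s, t in topology:
        for lab in (s, t):
            if lab not in verts:
                while True:
                    v = random_dna(rng, k - 1)
                    if v not in verts.values():
                        verts[lab] = v
                        break
    records = []
    seqs = {}
    for lab, s, t in topology:
        n = lengths.get(lab, 30)
        mid = random_dna(rng, max(0, n - 2 * (k - 1)))
        seq = verts[s] + mid + verts[t]
        records.append((seq, 1.0))
        seqs[lab] = seq
    graph = AssemblyGraph(k, records, double_stranded=False)
    seq2id = {e.seq: eid for eid, e in graph.edges.items()}
    return graph, {lab: seq2id[s] for lab, s in seqs.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
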