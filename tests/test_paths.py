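"""Transcript path extraction and spelling."""

import numpy as np
import pytest

from cloudasm.align import KmerIndex, align_cloud, derive_subgraph
from cloudasm.graph import build_graph
from cloudasm.io import ReadCloud
from cloudasm.paths import (PathConfig, TranscriptPath, extract_paths,
                            path_sequence)
from cloudasm.seq import random_dna, revcomp

from conftest import toy_graph
from oracles import enumerate_walks, spell_walk


def make_sub_from(graph, ids, labels, extremes=None):
    from cloudasm.align import CloudSubgraph
    sub = CloudSubgraph("B1")
    for lab in labels:
        eid = ids[lab]
        ext = (extremes or {}).get(lab, (0, graph.edge_length(eid)))
        sub.add_edge(eid, 1.0, ext)
    return sub


class TestExtract:
    def test_three_edge_simple_path(self):
        g, ids = toy_graph([("A", "v0", "v1"), ("B", "v1", "v2"),
                            ("C", "v2", "v3")])
        sub = make_sub_from(g, ids, "ABC",
                            extremes={"A": (7, 30), "C": (0, 22)})
        cloud = ReadCloud("B1", [])
        paths = extract_paths(sub, cloud, {}, g)
        assert len(paths) == 1
        p = paths[0]
        assert set(p.edges) == {ids[x] for x in "ABC"}
        assert p.start_offset == 7 and p.end_offset == 22

    def test_two_components_two_paths(self):
        g, ids = toy_graph([("A", "v0", "v1"), ("B", "v1", "v2"),
                            ("C", "v3", "v4"), ("D", "v4", "v5")])
        sub = make_sub_from(g, ids, "ABCD")
        paths = extract_paths(sub, ReadCloud("B1", []), {}, g)
        assert len(paths) == 2
        comps = {frozenset(p.edges) for p in paths}
        assert comps == {frozenset({ids["A"], ids["B"]}),
                         frozenset({ids["C"], ids["D"]})}

    def test_determinism(self):
        g, ids = toy_graph([("A", "v0", "v1"), ("B", "v1", "v2"),
                            ("C", "v3", "v4")])
        sub = make_sub_from(g, ids, "ABC")
        p1 = extract_paths(sub, ReadCloud("B1", []), {}, g)
        p2 = extract_paths(sub.copy(), ReadCloud("B1", []), {}, g)
        assert p1 == p2


class TestRepeatResolution:
    def make_repeat_case(self):
        """Transcript X-R-Y-R-Z with a short internal repeat R.

        Read pairs tile the transcript at high coverage with inserts
        shorter than X/Y/Z but longer than R, so X->Y and Y->Z linkage is
        unambiguous while R alone is not.
        """
        rng = np.random.default_rng(42)
        X = random_dna(rng, 300)
        R = random_dna(rng, 50)
        Y = random_dna(rng, 300)
        Z = random_dna(rng, 300)
        t = X + R + Y + R + Z
        read_len, insert = 100, 250
        pairs = []
        for s in range(0, len(t) - insert + 1, 25):
            frag = t[s:s + insert]
            pairs.append((frag[:read_len], revcomp(frag[-read_len:])))
        reads = [r for p in pairs for r in p]
        graph = build_graph(reads, 21)
        cloud = ReadCloud("B1", [(f"p{i}", r1, r2)
                                 for i, (r1, r2) in enumerate(pairs)])
        return graph, cloud, t

    def test_repeat_traversed_twice_matches_walk_oracle(self):
        graph, cloud, t = self.make_repeat_case()
        idx = KmerIndex(graph)
        als = align_cloud(cloud, graph, idx)
        sub = derive_subgraph(cloud, graph, als)
        paths = extract_paths(sub, cloud, als, graph, PathConfig())
        assert len(paths) == 1
        seq = path_sequence(paths[0], graph)
        assert seq == t or revcomp(seq) == t
        # one edge (the repeat) is visited twice
        assert len(paths[0].edges) == len(set(paths[0].edges)) + 1

        # oracle: among all bounded walks of the graph, exactly one (per
        # strand) spells a sequence consistent with every read pair at a
        # plausible insert separation
        consistent = []
        for walk in enumerate_walks(graph, 7):
            spelled = spell_walk(graph, walk)
            if len(spelled) != len(t):
                continue
            ok = True
            for _name, r1, r2 in cloud.read_pairs:
                placed = False
                for fwd, rev in ((r1, revcomp(r2)), (r2, revcomp(r1))):
                    p1 = spelled.find(fwd)
                    if p1 < 0:
                        continue
                    p2 = spelled.find(rev, p1)
                    if p2 >= 0 and 150 <= p2 + len(rev) - p1 <= 350:
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if ok:
                consistent.append(spelled)
        assert sorted(set(consistent)) == sorted({t, revcomp(t)})


class TestPathSequence:
    def test_single_edge_full_span_is_verbatim(self):
        g, ids = toy_graph([("A", "v0", "v1")], lengths={"A": 60})
        p = TranscriptPath("B1", (ids["A"],), 0, 60)
        assert path_sequence(p, g) == g.edges[ids["A"]].seq

    def test_junction_spelling_collapses_overlap(self):
        g, ids = toy_graph([("A", "v0", "v1"), ("B", "v1", "v2")])
        p = TranscriptPath("B1", (ids["A"], ids["B"]), 0,
                           g.edge_length(ids["B"]))
        seq = path_sequence(p, g)
        a, b = g.edges[ids["A"]].seq, g.edges[ids["B"]].seq
        assert seq == a + b[4:]  # k - 1 == 4
        assert len(seq) == p.spelled_length(g)

    def test_empty_spell_rejected(self):
        g, ids = toy_graph([("A", "v0", "v1")], lengths={"A": 60})
        with pytest.raises(ValueError):
            path_sequence(TranscriptPath("B1", (ids["A"],), 10, 10), g)

    def test_non_adjacent_edges_rejected(self):
        g, ids = toy_graph([("A", "v0", "v1"), ("B", "v2", "v3")])
        with pytest.raises(ValueError):
            path_sequence(TranscriptPath("B1", (ids["A"], ids["B"]), 0,
                                         g.edge_length(ids["B"])), g)


def test_perfect_data_recovery_on_linear_neighborhood():
    """A noiseless >=2x cloud from one transcript in a linear graph region
    yields exactly one path spelling the transcript."""
    from cloudasm.simulate import make_gene, simulate_clouds
    from conftest import clouds_from_pairs
    gene = make_gene("G0", 5, 1, rng_seed=9)
    pairs, truths = simulate_clouds([gene], n_barcodes=3,
                                    cloud_size_model=("coverage", 2.5),
                                    read_len=100, insert_mean=180,
                                    insert_sd=20, error_rate=0.0, rng_seed=8)
    clouds = clouds_from_pairs(pairs)
    graph = build_graph([s for c in clouds for _, s in c.reads], 21)
    idx = KmerIndex(graph)
    truth = gene.transcript(gene.isoform_ids[0])
    for cloud in clouds:
        als = align_cloud(cloud, graph, idx)
        sub = derive_subgraph(cloud, graph, als)
        paths = extract_paths(sub, cloud, als, graph)
        assert len(paths) == 1
        seq = path_sequence(paths[0], graph)
        assert seq == truth or revcomp(seq) == truth
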