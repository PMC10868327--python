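"""End-to-end assembly driver: reads in, isoform clusters out.

One global graph is built from all reads combined; every cloud is then
aligned to it, its subgraph simplified, its transcript paths extracted, and
all paths pooled into the cross-barcode cluster store.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .align import KmerIndex, align_cloud, derive_subgraph
from .cluster import PathClusterStore
from .graph import AssemblyGraph, GlobalSimplifyConfig, build_graph, \
    prune_low_coverage
from .io import ReadCloud
from .paths import PathConfig, TranscriptPath, extract_paths, path_sequence
from .simplify import CloudSimplifyConfig, simplify_subgraph

log = logging.getLogger(__name__)


@dataclass
class AssemblyResult:
    graph: AssemblyGraph
    paths: list[TranscriptPath]
    store: PathClusterStore
    contigs: dict[str, list[str]] = field(default_factory=dict)
    # barcode -> spelled contig sequences, in path order


def assemble_clouds(clouds: Sequence[ReadCloud], k: int = 55,
                    global_config: GlobalSimplifyConfig | None = None,
                    cloud_config: CloudSimplifyConfig | None = None,
                    path_config: PathConfig | None = None,
                    endpoint_tol: int = 30,
                    double_stranded: bool = True,
                    max_mismatch_frac: float = 0.05) -> AssemblyResult:
    """Assemble transcript isoforms for every read cloud.

    Default k is 55 (real-scale data); small simulations typically use 21.
    """
    reads = [seq for cloud in clouds for _rid, seq in cloud.reads]
    graph = build_graph(reads, k, double_stranded=double_stranded)
    graph = prune_low_coverage(graph, global_config)
    index = KmerIndex(graph)
    store = PathClusterStore(endpoint_tol=endpoint_tol)
    all_paths: list[TranscriptPath] = []
    contigs: dict[str, list[str]] = {}
    for cloud in clouds:
        alignments = align_cloud(cloud, graph, index,
                                 max_mismatch_frac=max_mismatch_frac)
        sub = derive_subgraph(cloud, graph, alignments)
        if sub.empty:
            log.debug("cloud %s: no aligned reads, skipped", cloud.barcode)
            continue
        sub = simplify_subgraph(sub, graph, cloud_config)
        paths = extract_paths(sub, cloud, alignments, graph, path_config)
        seqs = []
        for path in paths:
            store.insert_path(path, graph)
            seqs.append(path_sequence(path, graph))
        contigs[cloud.barcode] = seqs
        all_paths.extend(paths)
    return AssemblyResult(graph, all_paths, store, contigs)


def write_contigs_fasta(contigs: dict[str, list[str]], path) -> None:
    """Per-barcode contig FASTA (headers carry ``barcode=`` tokens, the
    format the evaluation command consumes)."""
    with open(path, "w") as fh:
        for bc in sorted(contigs):
            for i, seq in enumerate(contigs[bc]):
                fh.write(f">{bc}_{i} barcode={bc} length={len(seq)}\n")
                for j in range(0, len(seq), 80):
                    fh.write(seq[j:j + 80] + "\n")
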