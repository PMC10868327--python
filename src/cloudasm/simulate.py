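"""Synthetic multi-isoform genes and barcoded read-cloud simulation.

The generator emulates sparse linked-read RNA-seq (SPIso-seq / Loop-Seq /
Tell-Seq style) libraries: each barcode tags one (or a few, from distinct
genes) full-length mRNA molecule; the molecule is fragmented into
consecutive fragments that tile it end to end; a subset of fragments is
sequenced as paired reads with substitution errors.  Cloud sizes — read
pairs per barcode — follow a configurable distribution whose default is a
zero-truncated negative binomial with mean 8 pairs and dispersion r=2,
giving many 1–3-pair clouds and per-molecule coverage down to ~1x, the
regime this assembler targets.

Ground truth (which isoform each barcode came from, how many reads it got)
is returned alongside the reads so every downstream module is testable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .seq import DNA, random_dna, revcomp


@dataclass(frozen=True)
class GeneModel:
    """A synthetic gene: genomic sequence, exons, and isoform exon chains.

    Exons are 0-based half-open intervals, non-overlapping and sorted;
    every isoform's chain is a strictly increasing list of exon indices
    that always contains the first and last exon (constitutive termini).
    """

    gene_id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    isoforms: tuple[tuple[str, tuple[int, ...]], ...]

    def transcript(self, isoform_id: str) -> str:
        chain = dict(self.isoforms)[isoform_id]
        return "".join(self.sequence[s:e]
                       for s, e in (self.exons[i] for i in chain))

    @property
    def isoform_ids(self) -> list[str]:
        return [iso for iso, _ in self.isoforms]

    def junctions(self, isoform_id: str) -> list[int]:
        """Splice junction positions in transcript coordinates."""
        chain = dict(self.isoforms)[isoform_id]
        out, pos = [], 0
        for i in chain[:-1]:
            pos += self.exons[i][1] - self.exons[i][0]
            out.append(pos)
        return out


@dataclass
class CloudTruth:
    """Per-barcode ground truth written by the simulator."""

    barcode: str
    molecules: list[tuple[str, str]]  # (gene id, isoform id)
    reads_emitted: int
    coverage: float  # sequenced bases / summed transcript length


def make_gene(gene_id: str, n_exons: int, n_isoforms: int,
              exon_len_range: tuple[int, int] = (120, 300),
              intron_len_range: tuple[int, int] = (60, 200),
              rng_seed: int | np.random.Generator = 0) -> GeneModel:
    """Random gene with ``n_isoforms`` distinct exon chains.

    The first and last exon are constitutive, so at most 2^(n_exons - 2)
    distinct isoforms exist; asking for more raises ``ValueError``.  Every
    transcript is at least 200 bp (terminal exon lengths are re-drawn if
    needed).  Deterministic under the seed.
    """
    if n_exons < 2:
        raise ValueError("a gene needs at least 2 exons")
    max_iso = 2 ** (n_exons - 2)
    if n_isoforms < 1 or n_isoforms > max_iso:
        raise ValueError(
            f"cannot draw {n_isoforms} distinct isoforms from {n_exons} "
            f"exons (max {max_iso})")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    lo, hi = exon_len_range
    for _ in range(100):
        exon_lens = rng.integers(lo, hi + 1, size=n_exons)
        if exon_lens[0] + exon_lens[-1] >= 200:
            break
    else:
        raise ValueError("exon length range cannot satisfy the 200 bp "
                         "minimum transcript length")
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                               size=n_exons - 1)
    exons, pos = [], 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    sequence = random_dna(rng, pos)
    middle = list(range(1, n_exons - 1))
    if max_iso <= 4096:
        all_subsets = []
        for r in range(len(middle) + 1):
            all_subsets.extend(combinations(middle, r))
        idx = rng.choice(len(all_subsets), size=n_isoforms, replace=False)
        subsets = [all_subsets[i] for i in sorted(idx)]
    else:
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < n_isoforms:
            mask = rng.random(len(middle)) < 0.5
            chosen.add(tuple(m for m, keep in zip(middle, mask) if keep))
        subsets = sorted(chosen)
    isoforms = []
    for j, subset in enumerate(subsets):
        chain = (0, *subset, n_exons - 1)
        isoforms.append((f"{gene_id}.i{j:02d}", chain))
    return GeneModel(gene_id, sequence, tuple(exons), tuple(isoforms))


@dataclass
class SimulatedPair:
    name: str
    barcode: str
    read1: str
    read2: str


def _fragment_tiling(length: int, read_len: int, insert_mean: float,
                     insert_sd: float, rng: np.random.Generator
                     ) -> list[tuple[int, int]]:
    """Consecutive fragments covering [0, length) end to end.

    The first fragment's length is drawn uniformly up to one insert so the
    boundary phase differs between tilings — shearing has no preferred
    register, and a fixed phase would leave the same inter-read windows
    unsequenced in every cloud.
    """
    frags = []
    pos = 0
    first = True
    while pos < length:
        fl = int(round(rng.normal(insert_mean, insert_sd)))
        fl = max(fl, read_len)
        if first:
            fl = int(rng.integers(read_len, max(fl, read_len) + 1))
            first = False
        end = min(pos + fl, length)
        start = pos if end - pos >= read_len else max(0, end - read_len)
        frags.append((start, end))
        pos += fl
    return frags


def _cloud_size(model, rng: np.random.Generator) -> int | None:
    """Draw a cloud size; ``None`` means 'all fragments' (coverage mode)."""
    kind = model[0]
    if kind == "nb":
        _, mean, r = model
        p = r / (r + mean)
        for _ in range(1000):
            n = int(rng.negative_binomial(r, p))
            if n > 0:
                return n
        return 1
    if kind == "lognormal":
        _, mu, sigma = model
        return max(1, int(round(rng.lognormal(mu, sigma))))
    if kind == "empirical":
        _, table = model
        return max(1, int(rng.choice(table)))
    if kind == "coverage":
        return None
    raise ValueError(f"unknown cloud size model {model!r}")


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        choices = [b for b in DNA if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_clouds(genes: Sequence[GeneModel],
                    n_barcodes: int,
                    isoform_weights: dict[tuple[str, str], float]
                    | None = None,
                    cloud_size_model: tuple = ("nb", 8.0, 2.0),
                    molecules_per_barcode: int = 1,
                    read_len: int = 100,
                    insert_mean: float = 300.0,
                    insert_sd: float = 30.0,
                    error_rate: float = 0.005,
                    fragmentation: str = "tiling",
                    rng_seed: int = 0
                    ) -> tuple[list[SimulatedPair], list[CloudTruth]]:
    """Simulate barcoded read clouds from the given genes.

    Each barcode draws ``molecules_per_barcode`` molecules from distinct
    genes (isoform chosen by ``isoform_weights``, uniform by default); the
    cloud size model sets how many read pairs each molecule yields.  With
    ``fragmentation="tiling"`` (default) fragments are sampled from
    end-to-end fragmentations of the molecule, so at high coverage the
    extreme read positions reach the true transcript termini; the
    ``"uniform"`` mode draws independent fragment start positions instead.
    Fully deterministic under ``rng_seed``.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be within [0, 0.1]")
    if molecules_per_barcode > len(genes):
        raise ValueError("molecules per barcode exceeds the number of genes")
    shortest = min(len(g.transcript(i)) for g in genes
                   for i in g.isoform_ids)
    if read_len > shortest:
        raise ValueError(
            f"read length {read_len} exceeds the shortest transcript "
            f"({shortest} bp)")
    rng = np.random.default_rng(rng_seed)
    choices = [(g.gene_id, iso) for g in genes for iso in g.isoform_ids]
    weights = np.array([1.0 if isoform_weights is None
                        else isoform_weights.get(c, 0.0) for c in choices])
    if weights.sum() <= 0:
        raise ValueError("isoform weights sum to zero")
    weights = weights / weights.sum()
    by_gene = {g.gene_id: g for g in genes}

    barcodes: set[str] = set()
    pairs: list[SimulatedPair] = []
    truths: list[CloudTruth] = []
    for _ in range(n_barcodes):
        while True:
            bc = random_dna(rng, 16)
            if bc not in barcodes:
                barcodes.add(bc)
                break
        mol_idx = []
        used_genes: set[str] = set()
        for _ in range(molecules_per_barcode):
            for _ in range(1000):
                i = int(rng.choice(len(choices), p=weights))
                if choices[i][0] not in used_genes:
                    used_genes.add(choices[i][0])
                    mol_idx.append(i)
                    break
        reads_emitted = 0
        seq_bases = 0
        total_len = 0
        molecules = []
        for i in mol_idx:
            gene_id, iso = choices[i]
            tseq = by_gene[gene_id].transcript(iso)
            molecules.append((gene_id, iso))
            L = len(tseq)
            total_len += L
            n = _cloud_size(cloud_size_model, rng)
            if fragmentation == "tiling" or n is None:
                pool: list[tuple[int, int]] = []
                if n is None:  # coverage mode: whole tilings
                    target = cloud_size_model[1] * L
                    while sum(min(e - s, 2 * read_len)
                              for s, e in pool) < target:
                        pool.extend(_fragment_tiling(
                            L, read_len, insert_mean, insert_sd, rng))
                    frags = pool
                else:
                    while len(pool) < n:
                        pool.extend(_fragment_tiling(
                            L, read_len, insert_mean, insert_sd, rng))
                    idx = rng.choice(len(pool), size=n, replace=False)
                    frags = [pool[j] for j in sorted(idx)]
            elif fragmentation == "uniform":
                frags = []
                for _ in range(n):
                    fl = max(read_len,
                             int(round(rng.normal(insert_mean, insert_sd))))
                    fl = min(fl, L)
                    s = int(rng.integers(0, L - fl + 1))
                    frags.append((s, s + fl))
            else:
                raise ValueError(f"unknown fragmentation {fragmentation!r}")
            for s, e in frags:
                r1 = tseq[s:s + read_len]
                r2 = revcomp(tseq[max(s, e - read_len):e])
                r1 = _mutate(r1, error_rate, rng)
                r2 = _mutate(r2, error_rate, rng)
                name = f"{bc}:{reads_emitted:05d}"
                pairs.append(SimulatedPair(name, bc, r1, r2))
                reads_emitted += 1
                seq_bases += len(r1) + len(r2)
        truths.append(CloudTruth(bc, molecules, reads_emitted,
                                 seq_bases / total_len if total_len else 0.0))
    return pairs, truths


# -- file output -----------------------------------------------------------


def write_fastq(pairs: Iterable[SimulatedPair], r1_path, r2_path,
                quality: int = 35) -> None:
    """Paired FASTQ with ``BX:Z:`` barcode comments and constant quality."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name} BX:Z:{p.barcode}\n{p.read1}\n+\n"
                     f"{chr(33 + quality) * len(p.read1)}\n")
            f2.write(f"@{p.name} BX:Z:{p.barcode}\n{p.read2}\n+\n"
                     f"{chr(33 + quality) * len(p.read2)}\n")


def write_truth_tsv(truths: Iterable[CloudTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tgene\tisoform\tn_reads\tcoverage\n")
        for t in truths:
            for gene, iso in t.molecules:
                fh.write(f"{t.barcode}\t{gene}\t{iso}\t{t.reads_emitted}\t"
                         f"{t.coverage:.3f}\n")


def write_transcripts_fasta(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for iso in g.isoform_ids:
                seq = g.transcript(iso)
                fh.write(f">{iso} gene={g.gene_id} length={len(seq)}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def write_genome_fasta(genes: Iterable[GeneModel], path) -> None:
    """Genomic (exon+intron) sequence of each synthetic gene."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i:i + 80] + "\n")


def load_gene_models(gtf_path, genome_fasta_path) -> list[GeneModel]:
    """Rebuild GeneModel objects from the simulator's GTF + genome FASTA."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(genome_fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    exons_by_iso: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(gtf_path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (a.strip() for a in fields[8].split(";")) if kv)
            key = (fields[0], attrs["transcript_id"])
            exons_by_iso.setdefault(key, []).append(
                (int(fields[3]) - 1, int(fields[4])))
    genes: dict[str, dict] = {}
    for (gene_id, iso), exons in sorted(exons_by_iso.items()):
        g = genes.setdefault(gene_id, {"exons": [], "isos": []})
        chain = []
        for ex in sorted(exons):
            if ex not in g["exons"]:
                g["exons"].append(ex)
            chain.append(ex)
        g["isos"].append((iso, chain))
    out = []
    for gene_id, g in sorted(genes.items()):
        exons = sorted(g["exons"])
        index = {ex: i for i, ex in enumerate(exons)}
        isoforms = tuple((iso, tuple(index[ex] for ex in chain))
                         for iso, chain in g["isos"])
        out.append(GeneModel(gene_id, seqs[gene_id], tuple(exons), isoforms))
    return out


def write_gene_models_gtf(genes: Iterable[GeneModel], path) -> None:
    """Minimal GTF-like annotation of the synthetic genes."""
    with open(path, "w") as fh:
        for g in genes:
            end = len(g.sequence)
            fh.write(f'{g.gene_id}\tcloudasm_sim\tgene\t1\t{end}\t.\t+\t.\t'
                     f'gene_id "{g.gene_id}";\n')
            for iso, chain in g.isoforms:
                for i in chain:
                    s, e = g.exons[i]
                    fh.write(f'{g.gene_id}\tcloudasm_sim\texon\t{s + 1}\t{e}'
                             f'\t.\t+\t.\tgene_id "{g.gene_id}"; '
                             f'transcript_id "{iso}";\n')
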