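"""FASTQ input, barcode parsing and read-cloud grouping.

A *read cloud* is the set of reads sharing one barcode.  Barcodes can be
carried three ways (exactly one mode is active per run):

``bx``
    SAM-style ``BX:Z:<barcode>`` tag in the FASTQ comment field.
``suffix``
    Read-name suffix after a delimiter (default ``#``), e.g.
    ``read17#ACGT...``.
``tenx``
    10x-style: the first N bases of read 1 are the barcode and are trimmed
    off the sequence.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)


@dataclass
class PairRecord:
    """One (possibly single-ended) read pair with its parsed barcode."""

    name: str
    seq1: str
    seq2: str | None
    barcode: str | None


@dataclass
class ReadCloud:
    """All read pairs sharing one barcode."""

    barcode: str
    read_pairs: list[tuple[str, str, str | None]] = field(default_factory=list)
    # tuples of (read name, read1, read2-or-None)

    def __len__(self) -> int:
        return len(self.read_pairs)

    @property
    def reads(self) -> list[tuple[str, str]]:
        """Flat list of (read id, sequence) including both mates."""
        out = []
        for name, r1, r2 in self.read_pairs:
            out.append((name + "/1", r1))
            if r2 is not None:
                out.append((name + "/2", r2))
        return out


def _open(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def _barcode_from_record(rec, mode: str, delimiter: str, bx_len: int,
                         is_read1: bool) -> tuple[str | None, str]:
    """Return (barcode or None, possibly trimmed sequence)."""
    seq = str(rec.seq)
    if mode == "bx":
        for token in rec.description.split()[1:]:
            if token.startswith("BX:Z:"):
                return token[5:], seq
        return None, seq
    if mode == "suffix":
        name = _strip_mate(rec.id)
        if delimiter in name:
            return name.rsplit(delimiter, 1)[1] or None, seq
        return None, seq
    if mode == "tenx":
        if is_read1:
            if len(seq) <= bx_len:
                return None, seq
            return seq[:bx_len], seq[bx_len:]
        return "", seq  # read 2 inherits the mate's barcode
    raise ValueError(f"unknown barcode mode {mode!r}")


def read_paired_fastq(r1_path, r2_path=None, barcode_mode: str = "bx",
                      delimiter: str = "#", bx_len: int = 16
                      ) -> Iterator[PairRecord]:
    """Stream read pairs from one or two FASTQ files (optionally gzipped).

    With two files the streams are walked in lockstep and names must match
    after stripping ``/1``/``/2``.  With one file, reads are single-ended.
    """
    with _open(r1_path) as fh1:
        it1 = SeqIO.parse(fh1, "fastq")
        if r2_path is None:
            for rec in it1:
                bc, seq = _barcode_from_record(rec, barcode_mode, delimiter,
                                               bx_len, True)
                yield PairRecord(_strip_mate(rec.id), seq, None, bc)
            return
        with _open(r2_path) as fh2:
            it2 = SeqIO.parse(fh2, "fastq")
            for rec1 in it1:
                try:
                    rec2 = next(it2)
                except StopIteration:
                    log.warning("read %s has no mate; treated as single",
                                rec1.id)
                    bc, seq = _barcode_from_record(
                        rec1, barcode_mode, delimiter, bx_len, True)
                    yield PairRecord(_strip_mate(rec1.id), seq, None, bc)
                    continue
                n1, n2 = _strip_mate(rec1.id), _strip_mate(rec2.id)
                if n1 != n2:
                    raise ValueError(
                        f"unsynchronised mates: {rec1.id} vs {rec2.id}")
                bc, seq1 = _barcode_from_record(rec1, barcode_mode, delimiter,
                                                bx_len, True)
                _, seq2 = _barcode_from_record(rec2, barcode_mode, delimiter,
                                               bx_len, False)
                yield PairRecord(n1, seq1, seq2, bc)


def group_by_barcode(records: Iterable[PairRecord]
                     ) -> tuple[list[ReadCloud], list[PairRecord]]:
    """Group read pairs into one ReadCloud per distinct barcode.

    Records without a parseable barcode go to the returned reject bin;
    clouds come back sorted by barcode for determinism.
    """
    clouds: dict[str, ReadCloud] = {}
    rejected: list[PairRecord] = []
    for rec in records:
        if not rec.barcode:
            rejected.append(rec)
            continue
        cloud = clouds.get(rec.barcode)
        if cloud is None:
            cloud = clouds[rec.barcode] = ReadCloud(rec.barcode)
        cloud.read_pairs.append((rec.name, rec.seq1, rec.seq2))
    if rejected:
        log.warning("%d records without a barcode were routed to the "
                    "reject bin", len(rejected))
    return [clouds[b] for b in sorted(clouds)], rejected
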