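"""Contig-to-isoform assignment and per-barcode precision / recall.

Assembled contigs are assigned to reference isoforms by sequence: a contig
is aligned (edit distance, infix mode) against every reference transcript,
and the set of isoforms it matches within a small edit budget stands in
for junction-chain comparison — for spliced transcripts over the same gene
two isoforms agree on a region exactly where their junction chains do.
Categories follow the usual isoform-assignment vocabulary:

``unique``             full-length match (both endpoints within 30 bp) to
                       exactly one isoform;
``unique_minor``       as above with endpoint slack up to 100 bp;
``ambiguous``          the matched region is compatible with two or more
                       isoforms;
``inconsistent``       overlaps a gene but matches no isoform at full
                       length (chimeras, truncations beyond the slack);
``non_informative``    aligned span under 300 bp, or junction-free inside a
                       multi-isoform gene;
``intergenic``         no reference alignment at all.

The barcode-based "fixed" filter drops contigs from clouds that produced
more than one assignment (either per gene, or in total): such clouds were
either split by coverage gaps or carried two molecules, and both situations
poison per-barcode isoform calls.  Fixed recall is recall recomputed after
this filter with the dropped barcodes removed from the denominator as well.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import edlib
import pandas as pd

from .seq import revcomp
from .simulate import CloudTruth, GeneModel

CATEGORIES = ("unique", "unique_minor", "ambiguous", "inconsistent",
              "non_informative", "intergenic")


@dataclass(frozen=True)
class Assignment:
    contig_id: str
    barcode: str
    gene_id: str | None
    isoform_id: str | None
    category: str


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    fixed_recall: float
    category_counts: dict[str, int]
    n_denominator: int
    n_fixed_denominator: int


class ReferenceSet:
    """Reference transcripts of a set of gene models, indexed for
    assignment."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, tuple[str, str]] = {}
        for g in genes:
            for iso in g.isoform_ids:
                self.transcripts[iso] = (g.gene_id, g.transcript(iso))

    def gene_of(self, isoform_id: str) -> str:
        return self.transcripts[isoform_id][0]


@dataclass(frozen=True)
class AssignConfig:
    max_edit_frac: float = 0.02     # contig-to-transcript edit budget
    loose_edit_frac: float = 0.20   # gene-overlap detection for chimeras
    endpoint_tol: int = 30          # full-length window -> unique
    minor_tol: int = 100            # relaxed window -> unique_minor
    min_span: int = 300             # shorter aligned spans are uninformative


def _best_infix(contig: str, target: str) -> tuple[int, int, int]:
    """(edit distance, target start, target end) over both orientations."""
    best = None
    for q in (contig, revcomp(contig)):
        res = edlib.align(q, target, mode="HW", task="locations")
        ed = res["editDistance"]
        if ed < 0:
            continue
        s, e = res["locations"][0]
        cand = (ed, s, e + 1)
        if best is None or cand < best:
            best = cand
    return best if best is not None else (len(contig) + len(target), 0, 0)


def assign_contig(contig: str, barcode: str, reference: ReferenceSet,
                  contig_id: str = "", config: AssignConfig | None = None
                  ) -> Assignment:
    """Assign one contig to a reference isoform (or a failure category)."""
    if not contig:
        raise ValueError("empty contig")
    config = config or AssignConfig()
    budget = max(2, int(config.max_edit_frac * len(contig)))
    hits = []   # (ed, iso, ts, te, transcript length)
    loose = []  # gene-overlap evidence for otherwise unmatched contigs
    for iso, (gene, tseq) in sorted(reference.transcripts.items()):
        ed, ts, te = _best_infix(contig, tseq)
        if ed <= budget:
            hits.append((ed, iso, ts, te, len(tseq)))
        elif ed <= config.loose_edit_frac * len(contig):
            loose.append((ed, iso))
    if not hits:
        if loose:
            gene = reference.gene_of(min(loose)[1])
            return Assignment(contig_id, barcode, gene, None, "inconsistent")
        return Assignment(contig_id, barcode, None, None, "intergenic")
    hits.sort()
    ed0, iso0, ts0, te0, tl0 = hits[0]
    gene0 = reference.gene_of(iso0)
    if te0 - ts0 < config.min_span:
        return Assignment(contig_id, barcode, None, None, "non_informative")
    junctions = reference.genes[gene0].junctions(iso0)
    has_junction = any(ts0 < j < te0 for j in junctions)
    multi_iso = len(reference.genes[gene0].isoforms) > 1
    if not has_junction and multi_iso:
        return Assignment(contig_id, barcode, None, None, "non_informative")
    full30 = [h for h in hits
              if h[2] <= config.endpoint_tol
              and h[4] - h[3] <= config.endpoint_tol]
    if len(full30) == 1:
        return Assignment(contig_id, barcode,
                          reference.gene_of(full30[0][1]), full30[0][1],
                          "unique")
    if len(full30) > 1:
        return Assignment(contig_id, barcode, gene0, None, "ambiguous")
    full100 = [h for h in hits
               if h[2] <= config.minor_tol and h[4] - h[3] <= config.minor_tol]
    if len(full100) == 1:
        return Assignment(contig_id, barcode,
                          reference.gene_of(full100[0][1]), full100[0][1],
                          "unique_minor")
    if len(full100) > 1:
        return Assignment(contig_id, barcode, gene0, None, "ambiguous")
    if len({h[1] for h in hits}) >= 2:
        return Assignment(contig_id, barcode, gene0, None, "ambiguous")
    return Assignment(contig_id, barcode, gene0, None, "inconsistent")


FixedMode = Literal["per_gene", "per_barcode"]


def fixed_filter(assignments: Sequence[Assignment],
                 mode: FixedMode = "per_gene") -> list[Assignment]:
    """Drop assignments from clouds that were assigned more than once.

    ``per_gene``: remove every assignment whose (barcode, gene) pair occurs
    on more than one contig.  ``per_barcode``: remove every assignment
    whose barcode carries more than one gene-level assignment in total.
    Unassigned categories (no gene) are never counted and never removed.
    """
    counted = [a for a in assignments if a.gene_id is not None]
    if mode == "per_gene":
        mult = Counter((a.barcode, a.gene_id) for a in counted)

        def drop(a: Assignment) -> bool:
            return a.gene_id is not None and \
                mult[(a.barcode, a.gene_id)] > 1
    elif mode == "per_barcode":
        mult = Counter(a.barcode for a in counted)

        def drop(a: Assignment) -> bool:
            return a.gene_id is not None and mult[a.barcode] > 1
    else:
        raise ValueError(f"unknown fixed-filter mode {mode!r}")
    return [a for a in assignments if not drop(a)]


def _recovered_barcodes(assignments: Iterable[Assignment],
                        truth_by_bc: dict[str, set[str]]) -> set[str]:
    got: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        if a.category in ("unique", "unique_minor") and a.isoform_id:
            got[a.barcode].add(a.isoform_id)
    return {bc for bc, isos in truth_by_bc.items()
            if isos and isos <= got.get(bc, set())}


def score_assembly(assignments: Sequence[Assignment],
                   truth: Sequence[CloudTruth],
                   denominator: str | tuple[str, int] = "all",
                   fixed_mode: FixedMode = "per_barcode") -> EvalMetrics:
    """Per-barcode precision, recall and fixed recall.

    precision: among unique / unique-minor assignments, the fraction whose
    isoform equals a truth isoform of that barcode.  recall: fraction of
    denominator barcodes whose every truth isoform was uniquely and
    correctly recovered; the denominator is all truth barcodes, or
    ``("min_reads", n)`` for barcodes with at least n read pairs.  Fixed
    recall repeats the recall after :func:`fixed_filter`, with the filtered
    barcodes removed from the denominator as well.
    """
    truth_by_bc = {t.barcode: {iso for _, iso in t.molecules}
                   for t in truth}
    if denominator == "all":
        denom = set(truth_by_bc)
    else:
        kind, n = denominator
        if kind != "min_reads":
            raise ValueError(f"unknown denominator {denominator!r}")
        denom = {t.barcode for t in truth if t.reads_emitted >= n}
    if not denom:
        raise ValueError("empty recall denominator")

    assigned = [a for a in assignments
                if a.category in ("unique", "unique_minor")]
    correct = [a for a in assigned
               if a.isoform_id in truth_by_bc.get(a.barcode, set())]
    precision = len(correct) / len(assigned) if assigned else 0.0

    recovered = _recovered_barcodes(assignments, truth_by_bc)
    recall = len(recovered & denom) / len(denom)

    kept = fixed_filter(assignments, mode=fixed_mode)
    kept_ids = {id(a) for a in kept}
    removed_bcs = {a.barcode for a in assignments if id(a) not in kept_ids}
    fixed_denom = denom - removed_bcs
    if fixed_denom:
        fixed_rec = _recovered_barcodes(kept, truth_by_bc)
        fixed_recall = len(fixed_rec & fixed_denom) / len(fixed_denom)
    else:
        fixed_recall = 0.0

    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return EvalMetrics(precision, recall, fixed_recall, counts,
                       len(denom), len(fixed_denom))


def assignments_table(assignments: Sequence[Assignment],
                      truth: Sequence[CloudTruth] | None = None
                      ) -> pd.DataFrame:
    truth_by_bc = {}
    if truth:
        truth_by_bc = {t.barcode: {iso for _, iso in t.molecules}
                       for t in truth}
    rows = []
    for a in assignments:
        tiso = sorted(truth_by_bc.get(a.barcode, set()))
        rows.append({
            "contig_id": a.contig_id, "barcode": a.barcode,
            "category": a.category, "gene": a.gene_id or "",
            "isoform": a.isoform_id or "",
            "truth_isoform": ",".join(tiso),
            "correct": bool(a.isoform_id and a.isoform_id in
                            truth_by_bc.get(a.barcode, set())),
        })
    return pd.DataFrame(rows, columns=["contig_id", "barcode", "category",
                                       "gene", "isoform", "truth_isoform",
                                       "correct"])
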