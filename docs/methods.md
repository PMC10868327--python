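# Methods

## Model and assumptions

cloudasm assumes reads are barcoded so that one barcode tags reads from one
or a few mRNA molecules, usually from distinct genes. Under that
assumption, the reads of one cloud aligned to a shared assembly graph
should trace a set of vertex-disjoint simple paths, one per molecule; the
whole pipeline is organised around restoring that ideal picture when
sequencing errors and coverage gaps break it. Two isoforms of the same
gene under one barcode are treated as out of model (each connected
component of a cloud's subgraph is assumed to be one transcript); when it
does happen the cloud produces multiple contigs, which the downstream
"fixed" filter is designed to flag.

The graph is double-stranded: every edge has a reverse-complement twin and
the twin map is an involution. Cloud subgraphs mirror every alignment onto
the twin so they stay strand-symmetric; path extraction traverses only the
canonical orientation of each component, and clustering canonicalises a
path against its reverse complement. A single-stranded mode exists for
unit tests where strand bookkeeping is noise.

## Global graph and its simplification

The compacted de Bruijn graph is built from all reads combined; k-mers
containing N are skipped and edge coverage is the mean count of the edge's
k-mers. Default k is 55 for real-size libraries (SPAdes-family practice);
the bundled simulations use k = 21, appropriate for their kb-scale genes.

Global cleanup is deliberately light — an edge that is noise for one cloud
may be the only witness of another cloud's isoform — but it must actually
remove what sequencing errors create, and errors at a deeply covered locus
recur in proportion to depth (expected branch coverage ≈ depth ×
error-rate / 3). Three removal classes, iterated with re-compaction to a
fixpoint (the operation is idempotent):

* **Tips**: dead-start/dead-end edges shorter than `max_tip_len`
  (default max(100, 2k); error tips merge up to read scale, so the classic
  2k bound stalls for small k) whose coverage is extremely low relative to
  the route they hang off.
* **Bulge branches**: for each short edge, a spelled-length-bounded
  Dijkstra searches for an alternative path between its endpoints. The
  edge is removed only when the alternative has *similar length*
  (|ΔL| < max(50 bp, 10%)) and much higher coverage. Length similarity is
  the discriminator that matters: an error branch is exactly parallel to a
  same-length true segment, while an exon-skipping junction's alternative
  differs by the length of the skipped exon. Candidates are processed
  weakest-first and an alternative never routes through edges already
  marked for removal in the round.
* **Orphan error branches**: error branches that merge into *other* error
  branches have no parallel alternative; edges below the absolute floor
  with strictly stronger siblings on both ends are removed (the strongest
  route at a vertex is always protected, so removal never strands a
  vertex).

"Extremely low" means below the absolute floor **or** below 5% of the
alternative's coverage. The absolute floor itself scales with depth:
max(2.0, 0.02 × mass-weighted median coverage), where the median is
weighted by coverage × k-mers so it reflects the depth a sequenced base
experiences rather than the (numerous, near-massless) error edges. On
shallow or noiseless data the adaptive term is inert. The cost of the
relative rules is that isoform-specific sequence carrying less than ~2% of
its locus's expression can be lost — the same trade a conventional
assembler makes, and per-cloud gap closing cannot resurrect sequence
missing from the global graph.

## Alignment and subgraphs

Reads align by exact k-mer seeding (up to three anchor positions, all
occurrences) and bidirectional Hamming extension across edges under a
budget of max(2, 5% of read length) mismatches; indels are not modelled
because the graph was built from these same reads and the data are
substitution-dominated. A read aligning equally well to several loci
contributes membership and coverage to every co-best locus; no fractional
splitting is attempted, since per-cloud bulge removal arbitrates later.
Reads shorter than k are skipped with a warning. Barcode-specific coverage
of an edge is aligned bases divided by edge length; extreme positions are
the leftmost/rightmost aligned coordinates per edge. Subgraph derivation
never mutates the global graph.

## Per-cloud correction

All three passes work on *chains* — runs of global edges unbranched inside
the induced subgraph — because a tip or bulge of the subgraph is typically
a chain of several global edges, and all coverage comparisons use
barcode-specific coverage. Order: tips → bulges → gaps, iterated to a
fixpoint with at most 10 rounds. Tips and bulges only shrink the edge set;
gap closing only grows it.

* Tip predicate: the degree condition (internal vertices of induced degree
  2, far end degree 1, anchor degree > 2) and removal when spelled length
  ≤ 100 bp **or** mean coverage < 0.5 × the through-route's coverage.
* Bulges require the two parallel chains to be length-similar
  (|ΔL| < max(50 bp, 10%)); ties keep the lexicographically smaller edge
  chain, making the pass deterministic.
* Gap closing inserts the best walk (fewest bp, then fewest edges, then
  lexicographic) of global edges each ≤ 100 bp, at most 3 per gap, between
  a dangling path end and a dangling path start, with intermediate
  vertices untouched by the subgraph, and only where the insertion merges
  two simple paths into one. Inserted edges take the mean coverage of the
  flanking edges (so they are not immediately re-clipped) and whole-edge
  extreme positions.

All three length/coverage knobs are exposed on the CLI; the defaults above
were chosen once as values that separate error artefacts (k-mer-scale)
from exons (≥ tens of bp) at these read lengths.

## Path extraction

Paths seed from maximal chains, longest first, and extend in both
directions. At a branch the support of a candidate edge is the number of
read pairs whose two mates straddle the junction at an implied separation
within mean ± 3 SD of the library insert (estimated per cloud from pairs
co-locating on one edge; prior 300 ± 50 when a cloud has fewer than five
such pairs), plus single reads whose alignment walks the junction.
Extension takes the winner only if its support is ≥ 2 and ≥ 2× the
runner-up — conservative fragmentation is preferred to chimerism. One
refinement handles short repeats: when the runner-up is an edge already on
the path (a repeat competing with its own context), the best unvisited
candidate wins if it scores at least as high, because the visited evidence
is explained by the existing occurrence. Re-entering an already visited
edge requires positive pair demand, and an edge may occur at most twice in
one path, which bounds traversal. Terminal offsets come from the extreme
positions of the terminal edges, so contig ends are where the cloud's
outermost reads ended.

## Clustering, abundance, output filters

Paths are keyed by canonical edge chain; within a chain, a path joins the
first existing cluster whose representative endpoints both differ by
strictly less than 30 bp, else founds a new cluster. The window separates
isoforms differing only at their termini. The representative sequence is
the founding path's (no consensus step); abundance is the number of
distinct barcodes, with the full multiset kept for diagnostics. The greedy
first-match rule makes the partition deterministic for a fixed insertion
order but not insertion-order invariant. Output filtering keeps clusters
with length strictly greater than 300 bp and at least a minimal number of
barcodes; the per-barcode "fixed" filter additionally drops every
assignment from barcodes carrying more than one (gene-level) assignment,
in either a per-(barcode, gene) or a per-barcode mode.

## Simulator

The simulator emulates sparse linked-read RNA-seq: random multi-exon genes
with constitutive terminal exons and distinct exon-subset isoforms
(transcripts ≥ 200 bp); one molecule per barcode by default (optionally
several, from distinct genes); cloud sizes from a zero-truncated negative
binomial with mean 8 pairs and dispersion r = 2 (many 1–3-pair clouds,
per-molecule coverage down to ~1×), a log-normal, an empirical table, or a
fixed per-molecule coverage; 2×100 bp pairs from ~300 ± 30 bp fragments;
uniform substitution errors at 0.5% by default; unique random 16-nt
barcodes. Fragments are sampled from end-to-end *tilings* of the molecule
(consecutive fragments with a uniformly random phase for the first one),
which reflects the physics of shearing a full-length molecule: at high
sampling depth the outermost reads reach the true transcript termini, and
at low depth gaps appear anywhere — both properties the assembler's
extreme-position and gap-closing machinery depends on. A uniform
independent-fragment mode is available for comparison.

What the simulator does not model: PCR duplicates, barcode sequencing
errors or collisions, 3′ coverage bias (a knob exists for fragment start
bias but default is uniform), indels, quality-score structure, intronic or
intergenic background, and expression-level skew across isoforms (weights
are configurable but default uniform). Passing tests on these simulations
therefore demonstrate the graph/cloud algorithms, not robustness to every
artefact of real libraries.

## Evaluation surrogate

Contigs are assigned to reference isoforms by sequence: edlib infix
alignment of the contig (both orientations) against every reference
transcript, with a hit budget of max(2, 2% of contig length) edits. For
spliced transcripts of one gene, two isoforms agree on a region exactly
where their junction chains do, so the hit set stands in for junction-chain
comparison. Categories: `unique` (full-length match, both endpoints within
30 bp, to exactly one isoform), `unique_minor` (one isoform within 100 bp
endpoint slack), `ambiguous` (region compatible with ≥ 2 isoforms),
`inconsistent` (overlaps a gene — including hits only at a loose 20%
threshold, i.e. chimeras — but matches no isoform at full length),
`non_informative` (aligned span < 300 bp, or junction-free inside a
multi-isoform gene), `intergenic` (no alignment). A truncated contig
matching exactly one isoform beyond the minor slack is deliberately
`inconsistent` rather than `unique`: full-length status is part of the
claim being scored.

Precision is the fraction of unique/unique-minor assignments whose isoform
matches the barcode's truth; recall is the fraction of truth barcodes
whose every molecule was uniquely and correctly recovered (denominator:
all truth barcodes, or barcodes with ≥ n read pairs); fixed recall repeats
recall after the per-barcode fixed filter with the dropped barcodes
removed from the denominator as well — the only reading under which
removing split clouds can raise recall.

## Problem sizes and numerical choices

The bundled simulations use k = 21, kb-scale genes, hundreds to ~1700
clouds per gene, and 2×100 bp reads; the acceptance script's three
scenarios mirror the complexity (5/16/15 isoforms) and cloud counts
(539/1702/1399) of the human genes GYPC, MAPT and BIN1. All randomness is
driven by numpy Generators under explicit seeds; every tie-break in graph
construction, simplification, extraction and clustering is lexicographic
on deterministic edge identifiers, so identical inputs give identical
outputs. Degenerate inputs are defined: empty read sets give empty graphs,
clouds with no aligned reads are skipped with a log message, an empty
recall denominator is an error, and an empty spelled path is an error.

## Known limitations

* Sequence carrying under ~2% of its locus's coverage can be pruned
  globally and is then unrecoverable per cloud.
* Two same-gene isoforms under one barcode are not deconvolved; the cloud
  yields multiple contigs and is sacrificed by the fixed filter.
* The aligner has no indel mode by default, so indel-rich data would need
  the edit-distance extension or upstream correction.
* Abundances are raw barcode counts; no length or depth normalisation.
* Assignment is transcript-sequence based; it does not use genome
  coordinates and will not place contigs from genes absent from the
  reference set.
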