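# Methods

`sinekit` annotates short interspersed nuclear elements (SINEs) — 80–500 bp
nonautonomous retrotransposons mobilised by a partner LINE's reverse
transcriptase — in genomic sequence. This note records the models,
conventions and numerical choices behind each stage, and what the synthetic
validation does and does not demonstrate.

## Sequence model and alignment conventions

All sequences are uppercase IUPAC DNA. Pairwise alignment is
Needleman–Wunsch (global) or Smith–Waterman (local) with affine gap
penalties, executed by Biopython's `PairwiseAligner` over a substitution
matrix in which only identical unambiguous bases match; `N` and the other
ambiguity codes never match anything, including themselves, so unknown bases
count against identity rather than for it.

Default scoring is match +1, mismatch −1, gap open −2, gap extend −0.5.
**Percent identity** is matches divided by aligned columns, where terminal
gap overhangs are excluded from the denominator and internal gap columns
count as mismatches. Free-end-gap ("overhang-tolerant") global alignment is
used wherever a fragment is compared against a full-length consensus —
truncation calls, identity profiles — because a 5′-truncated copy should not
be penalised for sequence it never had.

Two comparison tasks deliberately use sterner gap costs (open −4, extend
−2): local segment matching between families and head-versus-reference
classification. With cheap gap extension, an optimal alignment of two
*unrelated* sequences degenerates into a longest-common-subsequence harvest
(~65% of positions on random DNA), which would inflate shared-segment
extents and make any identity threshold meaningless. Head classification
additionally divides matches by the length of the shorter sequence rather
than by aligned core columns: under free end gaps the "core" of an unrelated
pair collapses to a short perfect island, and anchoring the denominator to
the shorter sequence is what keeps the empirical null low (measured: 200/200
random 70-mers classify as `unknown`, maximum score 0.37, while a reference
mutated at 20% still scores ≈0.79).

Local alignments are post-processed to the shortest co-optimal form:
leading/trailing alignment segments with cumulative score ≤ 0 are trimmed,
so reported segments never end on score-neutral mismatch runs. This is also
what makes hit boundaries deterministic.

## Homology scanning

The scanner is a seed-and-extend search: exact k-mers (default word size 11)
shared between query and contig are chained along diagonals (drift ≤ 50 bp),
and each chain is resolved by one Smith–Waterman extension of the query
against the spanned window, on both strands. Hits below 80 bp or 70%
identity are dropped — the defaults bracket the SINE size class. Hit
identity is recomputed by a free-end global alignment of the extracted
genomic segment against the query, so the reported value is exactly
reproducible from the coordinates. Coordinates are 1-based inclusive with
`start > end` encoding the minus strand (the convention of the published
copy tables); BED export converts to 0-based half-open at a single point.

### Boundary handling around tandem tails

Per-copy tail lengths vary (a (TGA)n tail of 3–10 units against a consensus
carrying 5), which makes naive alignment boundaries unreliable at the 3′
end. Three measures keep boundaries exact:

1. **Query tail trimming** (`trim_query_tail`): the scan query's terminal
   tandem run is reduced to two complete units, so the alignment always ends
   on an in-phase unit boundary inside the element's tail instead of letting
   surplus query units creep base-by-base into the downstream target site
   duplication.
2. **Whole-unit 3′ extension** (`refine_tail_boundary`): the boundary is
   pushed outward only in complete units (period detected at the element
   end, units of ≥2 bp). Single-base stepping would walk into any TSD that
   begins with the same base as the tail (a 1-in-4 event); full-unit
   stepping requires the TSD to begin with the entire unit (≈1.5% for a
   trinucleotide at 36% GC), which we accept as residual noise.
3. **5′ claim-back**: when the local alignment leaves a short (≤5 bp)
   unaligned query prefix, the copy's first bases are mutated rather than
   absent, and the element start is extended to claim them; otherwise the
   left flank would begin inside the element and TSD detection would see a
   shifted window.

A TSD-quality-arbitrated retraction of the final tail unit was evaluated and
rejected: retracting a *correct* boundary exposes a tail unit at the start
of the right flank, and flanking bases then extend the candidate repeat
often enough (~30% of copies) that the arbitration misfires more than it
repairs.

## Target site duplications

TSD search enumerates substring pairs between the final 30 bp of the left
flank and the first 30 bp of the right flank, with each copy required to lie
within 10 bp of its element boundary — duplications are created at the
integration boundaries, so the offset allowance covers boundary-call slop,
not repeats loose in the flanks. Lengths 5–19 bp and ≤1 edit (mismatch or
indel, via edlib) are considered. Candidates are ranked by
`length − 3 × edits`, then longer, then fewer edits, then closer to the
boundaries.

The edit penalty deserves a note. A pure longest-first rule is unusable:
for any true perfect L-bp duplication, the pair (one flank base + the
duplication) versus (the duplication alone) has length L+1 at one edit and
would always win, so the detector would systematically over-report by one
base. Penalising each edit by 3 means an imperfect longer repeat must earn
its extra length three times over; the published examples — a 16 bp perfect
TSD and the 14 bp single-insertion TSD written `atcctcta(g)cagtc` — are
still preferred over their shorter perfect sub-repeats. Absence of a TSD is
a legal annotation (some genuine copies have none).

## Promoter boxes, heads, tails, truncation

RNA polymerase III internal promoters are scanned as IUPAC motifs with a
per-box mismatch allowance (default 1): the tRNA-type (type 2) layout is box
A (`TRGCNNARYNNG`) before box B (`GTTCRANNC`) separated by 20–80 bp; the
5S-type (type 1) layout is boxes A/IE/C in order, with defaults laid out on
the canonical +50…+97 internal-control-region geometry. The type-1 motif
strings are loose heuristics — real analyses should supply curated patterns
through the config; everything here (motifs, spacings, allowances) is a
parameter, not a constant. The best chain minimises total mismatches, then
leftmost positions, and equals an exhaustive sliding-window match by
construction (property-tested against one).

Head classification aligns the first 90 bp of the element against a
user-supplied reference RNA library (tRNAs, 5S rRNA); the class is read from
the best reference's annotation, with a 0.50 identity floor below which the
head is `unknown`. A covariance-model tRNA scan is out of scope; an
identity-plus-motif classification is what the data here can support.

Tails are the best tandem repeat (unit 1–6 bp) whose run ends within 60 bp
of the 3′ terminus, grown greedily in both directions while purity stays
≥0.8 and stopping after two consecutive off-period bases. Ranking maximises
copies × purity; exact product ties (common with small integers — a 6-bp
impure homopolymer ties a 15-bp perfect trinucleotide run) break to the run
with more matched positions, then the smaller unit, then 3′ proximity.
Minimum 3 copies. The purine-rich `ATAAAAA` motif near the 3′ end is
reported separately as an exact IUPAC match within the final 60 bp.

A copy is 5′-truncated when a free-end alignment to the family consensus
leaves ≥25% of the consensus 5′ end uncovered; the uncovered length is
reported. Truncated copies skip promoter/head calls (their head region is
gone).

## Consensus and identity profiles

Family consensi are built by star alignment: each member is aligned to the
longest member with free end gaps, and the pairwise alignments are projected
onto common coordinates by merging inserted gap columns (ungapping any row
recovers its input exactly — a tested invariant). Per column, the plurality
base is emitted when it reaches 50% of non-gap characters (ties break
alphabetically), `N` otherwise; columns that are majority-gap are dropped.
Ambiguous positions are emitted as `N` rather than two-base codes to keep
downstream matching simple. An externally computed MSA (aligned FASTA or
Clustal) can be supplied instead.

The identity profile aligns each copy to the consensus (free end gaps) and
reports min / median / max, with the median defined as the mean of the two
central order statistics for even n. Simulated families at fixed divergence
d profile at median 1−d within ±0.02 (tested at d = 0.10 over 20
replicates).

## Family comparison and LINE partnership

Shared domains between families are the best local segment under the
gap-averse scoring, reported with coordinates from which the identity is
recomputable. A chimera call splits a consensus into head (first 90 bp) and
body+tail (the rest), sources each part independently (head against the RNA
library and other families' heads; body+tail against other family
consensi), and reports a mosaic when both parts confidently (identity ≥0.7,
segment ≥40 bp) match *different* sources — the architecture of a 5S-headed
element carrying another family's body and tail. SINE–LINE partnership
compares the final 60 bp of both sequences; reverse-transcriptase identity
translates the LINE's longest ORF (≥100 aa) and scores plain amino-acid
identity with free terminal gaps, since that is the statistic usually
quoted.

## Phylogenetics

Distances are p-distances over mutually ungapped columns (pairs with no
comparable columns raise; bootstrap replicates substitute a fixed 0.75
ceiling so a replicate cannot crash on a sparse pair). Tree construction is
Saitou–Nei neighbor joining with deterministic tie-breaking (lowest index
pair on Q ties); it reconstructs additive matrices exactly (path error
≤1e-9, tested) and agrees topologically with scikit-bio's independent NJ on
random metrics. Negative branch lengths are clamped to zero with a warning,
the standard practice. No substitution-model correction (K2P/GTR) is
offered: the distance model behind the original figures is unstated, so the
package exposes the one model it can defend. Bootstrap resamples alignment
columns with replacement; replicate r draws from a generator seeded by
(seed, r), so supports are reproducible and independent of evaluation
order. Support is the percentage of replicates containing each internal
bipartition of the full-data tree; Newick output can hide supports below
50, the usual display convention.

## Synthetic genomes

The generator emulates the observed copy architecture: i.i.d. background at
36.1% GC (the GC of the sequenced genome fraction the study conditions
mirror); a family consensus of 386 bp with a tRNA-like head carrying exact
promoter-box instances, a random body, and a (TGA)₅ tail; copies mutated
per-site (substitutions at a per-copy rate drawn from 3–23% by default,
matching the identity spread of the published family, plus 1% short indels);
5′ truncation with probability 0.5 to surviving lengths of 75–356 bp;
per-copy tails of 3–10 units; TSDs of 5–19 bp *sampled from the insertion
site* (the target-site model) and duplicated on both sides, with an optional
single edit on the right copy (default probability 0.05 — about the rate of
imperfect TSDs in the published tables); uniform placement on both strands
with ≥100 bp spacing and no nesting (an explicit choice: nested insertions
exist in real data but would complicate truth-based scoring). Ground truth
records coordinates in the final genome, the TSD string, truncation and
realized divergence per copy; truth TSDs are verbatim present at the
recorded positions (tested by direct string extraction), and fixed seeds
give byte-identical FASTA and truth tables.

What passing the synthetic suite shows: the scanner, boundary refinement,
TSD/promoter/tail detectors and consensus builder are correct against known
truth under realistic divergence, composition and strand mixtures. What it
does not show: performance on real genomes with repeat landscapes, nested
or fragmented elements, segmental duplications, or sequencing error — the
background here is i.i.d. and copies never overlap.

Recovery under the validation conditions (divergence ≤10%, TSDs planted
exactly, 360 full-length copies across 24 genomes): ≥99% of copies
recovered with ≤5 bp boundary error, 93–97% with the exact planted TSD
string (seeds 1 and 2). The residual TSD misses are understood: TSDs whose
first bases continue the tail period (the boundary genuinely cannot be
placed from sequence alone), AT-rich background producing a near-tandem
repeat adjacent to the site that outranks a short true TSD, and single-base
coincidences at a mutated element start.

## Copy-number extrapolation and tables

Genome-wide copy numbers scale the observed count linearly by genome size
over sampled size (defaults 400 Mb and 1.963 Mb — the published BAC sample)
and round to two significant figures, half-up, matching how such estimates
are quoted. The sampled fraction is reported as a percentage to one
decimal. The packaged copy tables transcribe the published full-length and
5′-truncated element inventories verbatim; the validator recomputes every
length from its coordinates and flags the one row whose printed length
disagrees (HaSE1.11-1: coordinates give 367, the table prints 361) and the
coordinate-duplicate pair (HaSE1.30/HaSE1.34). Counts feeding the
extrapolation are BAC-resident rows (FP-prefixed accessions): 32 full-length
plus 22 truncated HaSE1 rows (54), and the 6 HaSE2 rows at ≥90% consensus
identity — the one deeply degenerate copy (66%) is not counted toward the
active family, which is the assumption required to reproduce the published
figure.

## Known limitations

- The scanner has no E-value model; thresholds are identity/length based.
- Tail-aware boundary refinement assumes tails of unit ≥2 bp; pure poly(A)
  tails get no whole-unit extension and may sit a few bases short.
- Type-1 promoter motif defaults are heuristic placeholders.
- Chimera detection uses fixed head/body boundaries (90 bp / final 60 bp);
  elements with unusual architecture need the boundaries reconfigured.
- NJ with p-distances underestimates distances at high divergence; the tree
  is a similarity summary, not a dated phylogeny.
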