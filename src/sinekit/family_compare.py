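"""Segment-level comparison between SINE families and candidate partner LINEs.

Three relationships matter for SINE biology and are detected here:

* shared domains — a high-identity local segment between two family
  consensi (e.g. a conserved central domain shared by two tRNA-derived
  families);
* chimeric architecture — head and body/tail descending from different
  sources (e.g. a 5S rRNA-derived head spliced onto another family's body
  and tail by template switching during reverse transcription);
* SINE-LINE partnership — a shared 3' tail through which the partner
  LINE's reverse transcriptase recognises the SINE transcript, plus the
  amino-acid identity of LINE RT domains.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from . import seqcore, structure_annot
from .seqcore import NucSequence, SequenceError


@dataclass(frozen=True)
class SegmentMatch:
    a_interval: tuple[int, int]  # 1-based inclusive in sequence A
    b_interval: tuple[int, int]
    length: int  # alignment columns
    identity: float


@dataclass
class ChimeraReport:
    family_id: str
    head_source: str | None  # "tRNA" | "5S" | other family id
    head_identity: float
    head_segment: SegmentMatch | None
    body_tail_source: str | None
    body_tail_segment: SegmentMatch | None
    is_chimera: bool


@dataclass(frozen=True)
class PartnerMatch:
    sine_id: str
    line_id: str
    tail_segment: SegmentMatch | None
    passes: bool


# Local segment comparison uses gap-averse scoring: with cheap gap extension
# a Smith-Waterman path can harvest a longest-common-subsequence from the
# unrelated sequence around a true shared segment, inflating its extent and
# deflating its identity. Stern gaps keep reported segments tight.
LOCAL_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -4.0, "gap_extend": -2.0}


def best_local_match(
    a: NucSequence | str,
    b: NucSequence | str,
    min_length: int = 20,
    scoring: dict | None = None,
) -> SegmentMatch | None:
    """Highest-scoring Smith-Waterman segment of >= min_length columns."""
    res = seqcore.local_align(a, b, scoring or LOCAL_SCORING)
    if res is None:
        return None
    aln, ai, bi = res
    if len(aln.gapped_a) < min_length:
        return None
    return SegmentMatch(ai, bi, len(aln.gapped_a), aln.identity)


def detect_chimera(
    family_consensus: NucSequence,
    head_refs: list[NucSequence],
    other_family_consensi: list[NucSequence],
    head_len: int = 90,
    tail_window: int = 60,
    min_identity: float = 0.7,
    min_length: int = 40,
    head_min_identity: float = 0.50,
) -> ChimeraReport:
    """Call a mosaic architecture: head source vs body+tail source.

    The head (first *head_len* bp) is classified against the RNA reference
    library and against other families' head regions; the body+tail (the
    remainder) is matched locally against each other family consensus. The
    element is chimeric when both regions confidently match different
    sources.
    """
    if not head_refs or not other_family_consensi:
        raise SequenceError("head references and family consensi must be non-empty")
    cons = str(family_consensus)
    head = cons[:head_len]
    body_tail = cons[head_len:]

    # head: best of RNA references and other families' heads
    head_cls, head_ident, _ref = structure_annot.classify_head(
        head, head_refs, min_identity=0.0
    )
    head_source: str | None = head_cls if head_ident >= head_min_identity else None
    for fam in other_family_consensi:
        if fam.id == family_consensus.id:
            continue
        seg = best_local_match(head, str(fam)[:head_len], min_length=min(min_length, len(head)))
        if seg and seg.identity > head_ident and seg.identity >= min_identity:
            head_ident = seg.identity
            head_source = fam.id

    body_source: str | None = None
    body_seg: SegmentMatch | None = None
    best_key = (0.0, 0)
    for fam in other_family_consensi:
        if fam.id == family_consensus.id:
            continue
        seg = best_local_match(body_tail, str(fam), min_length=min_length)
        if seg and seg.identity >= min_identity and (seg.identity, seg.length) > best_key:
            best_key = (seg.identity, seg.length)
            body_source = fam.id
            body_seg = seg

    is_chimera = (
        head_source is not None
        and body_source is not None
        and head_ident >= min_identity
        and head_source != body_source
    )
    return ChimeraReport(
        family_id=family_consensus.id,
        head_source=head_source,
        head_identity=head_ident,
        head_segment=None,
        body_tail_source=body_source,
        body_tail_segment=body_seg,
        is_chimera=is_chimera,
    )


def match_line_partner(
    sine_consensus: NucSequence,
    line_candidates: list[NucSequence],
    tail_window: int = 60,
    min_identity: float = 0.7,
    min_length: int = 20,
) -> list[PartnerMatch]:
    """Compare the final *tail_window* bp of the SINE against each LINE 3' end.

    A candidate passes when the best local segment between the two tails
    reaches min_identity over min_length columns. Sorted best-first.
    """
    s = str(sine_consensus)
    if tail_window > len(s):
        raise SequenceError("tail_window longer than the SINE consensus")
    sine_tail = s[-tail_window:]
    out: list[PartnerMatch] = []
    for line in line_candidates:
        l = str(line)
        if tail_window > len(l):
            raise SequenceError(f"tail_window longer than LINE {line.id}")
        seg = best_local_match(sine_tail, l[-tail_window:], min_length=min(min_length, tail_window))
        passes = bool(seg and seg.identity >= min_identity and seg.length >= min_length)
        out.append(PartnerMatch(sine_consensus.id, line.id, seg, passes))
    out.sort(key=lambda p: -(p.tail_segment.identity if p.tail_segment else -1.0))
    return out


def rt_protein_identity(line_a: NucSequence, line_b_protein: str, min_aa: int = 100) -> float:
    """Amino-acid identity between a LINE's longest ORF and a reference RT.

    The longest ORF of >= min_aa codons is translated and globally aligned
    (identity scoring, free terminal gaps) to the reference protein.
    """
    orfs = [o for o in seqcore.six_frame_orfs(line_a, min_aa=min_aa) if len(o.protein) >= min_aa]
    if not orfs:
        raise SequenceError(f"no ORF of >= {min_aa} aa in {line_a.id}")
    protein = max(orfs, key=lambda o: len(o.protein)).protein
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0
    aln = aligner.align(protein, line_b_protein)[0]
    ga, gb = str(aln[0]), str(aln[1])
    n = len(ga)
    lo = 0
    while lo < n and (ga[lo] == "-" or gb[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (ga[hi - 1] == "-" or gb[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        raise SequenceError("protein alignment has zero counted columns")
    match = sum(1 for i in range(lo, hi) if ga[i] == gb[i] and ga[i] != "-")
    return match / (hi - lo)


def format_comparison(report: ChimeraReport) -> str:
    """Human-readable text block for one family's mosaic-architecture call."""
    lines = [f"family {report.family_id}:"]
    lines.append(
        f"  head   -> {report.head_source or 'no confident source'}"
        f" (identity {report.head_identity:.2f})"
    )
    if report.body_tail_segment:
        seg = report.body_tail_segment
        lines.append(
            f"  body+tail -> {report.body_tail_source} "
            f"(identity {seg.identity:.2f} over {seg.length} columns, "
            f"segment {seg.a_interval[0]}-{seg.a_interval[1]})"
        )
    else:
        lines.append("  body+tail -> no confident source")
    lines.append(f"  chimera: {'yes' if report.is_chimera else 'no'}")
    return "\n".join(lines)
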