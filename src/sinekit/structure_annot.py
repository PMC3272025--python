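"""Structural hallmark annotation for candidate SINE copies.

A SINE copy is called on the evidence of (i) a target site duplication (TSD)
flanking both ends, (ii) an internal RNA polymerase III promoter — the
bipartite box A / box B layout of tRNA-derived heads (type 2) or the
box A / IE / C layout of 5S rRNA-derived heads (type 1), (iii) an RNA-derived
head classifiable against a reference RNA library, (iv) a short tandem-repeat
tail near the 3' terminus (e.g. (TGA)n or poly(A)), and (v) full-length vs
5'-truncated status relative to the family consensus.

All motifs, windows and allowances live in :class:`AnnotConfig`; the defaults
target the 80-500 bp tRNA/5S SINE architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from . import seqcore
from .homology_scan import GenomicLocation
from .seqcore import NucSequence

# IUPAC code -> allowed bases, for motif scanning
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class AnnotConfig:
    """Tunable parameters for hallmark annotation (all lengths in bp)."""

    # TSD search
    tsd_min_len: int = 5
    tsd_max_len: int = 19
    tsd_max_edits: int = 1
    tsd_window: int = 30
    tsd_max_offset: int = 10
    tsd_edit_penalty: int = 3
    # promoters
    box_a: str = "TRGCNNARYNNG"
    box_b: str = "GTTCRANNC"
    box_ab_spacing: tuple[int, int] = (20, 80)
    box_mismatch_allowance: int = 1
    # type-1 (5S) boxes laid out on the canonical +50..+97 internal control
    # region geometry; the motifs themselves are loose heuristics
    box1_a: str = "TRGCNNARYNNG"
    box1_ie: str = "RGNTRR"
    box1_c: str = "RGGNNNRYNNNNNRGNNR"
    box1_spacings: tuple[tuple[int, int], tuple[int, int]] = ((0, 30), (0, 30))
    # head / tail / truncation
    head_len: int = 90
    head_min_identity: float = 0.50
    tail_window: int = 60
    tail_max_unit: int = 6
    tail_min_copies: float = 3.0
    tail_min_purity: float = 0.8
    purine_motif: str = "ATAAAAA"
    purine_window: int = 60
    truncation_head_fraction: float = 0.25


@dataclass(frozen=True)
class TsdHit:
    left_seq: str
    right_seq: str
    length: int  # max of the two copy lengths
    edits: int  # mismatches + indels between the two copies
    left_end_offset: int  # bp between left copy end and the element 5' boundary
    right_start_offset: int  # bp between the element 3' boundary and right copy start


@dataclass(frozen=True)
class BoxHit:
    name: str
    start: int  # 1-based within the head
    end: int
    mismatches: int


@dataclass(frozen=True)
class PromoterAnnotation:
    promoter_type: str  # "type2_AB" | "type1_AIEC" | "none"
    boxes: tuple[BoxHit, ...] = ()
    spacing_ok: bool = False


@dataclass(frozen=True)
class TailRepeat:
    unit: str
    copies: float
    purity: float
    start: int  # 1-based within the element
    end: int
    distance_from_3prime: int


@dataclass
class SineAnnotation:
    copy_id: str
    location: GenomicLocation | None
    tsd: TsdHit | None
    promoter: PromoterAnnotation
    head_class: str  # "tRNA" | "5S" | "unknown"
    head_identity: float
    head_reference: str | None
    tail: TailRepeat | None
    purine_motif: tuple[int, str] | None
    truncation: str  # "full_length" | "five_prime_truncated"
    missing_5prime_bp: int = 0


# ---------------------------------------------------------------------------
# TSD detection


def tsd_rank_key(hit: TsdHit | None, edit_penalty: int = 3) -> tuple:
    """Ranking key for comparing candidate TSD calls (larger is better)."""
    if hit is None:
        return (float("-inf"),)
    return (
        hit.length - edit_penalty * hit.edits,
        hit.length,
        -hit.edits,
        -(hit.left_end_offset + hit.right_start_offset),
    )


def find_tsd(
    left_flank: NucSequence | str,
    right_flank: NucSequence | str,
    min_len: int = 5,
    max_len: int = 19,
    max_edits: int = 1,
    window: int = 30,
    max_offset: int = 10,
    edit_penalty: int = 3,
) -> TsdHit | None:
    """Best direct-repeat pair between the end of the left flank and the
    start of the right flank.

    Candidates are substring pairs within the final/first *window* bp of
    the flanks whose edit distance is <= max_edits, with each copy at most
    *max_offset* bp from its element boundary — target site duplications
    are created at the integration boundaries, so the offset allowance
    covers boundary-call slop, not repeats loose in the flanks. Ranking
    maximises ``length - edit_penalty * edits`` (an imperfect longer repeat
    must earn its extra length several times over), then longer, then fewer
    edits, then proximity to the boundaries. Returns None when nothing
    qualifies — absence of a TSD is a legal annotation.
    """
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    lf, rf = str(left_flank), str(right_flank)
    lwin = lf[-window:]
    rwin = rf[:window]
    if len(lwin) < min_len or len(rwin) < min_len:
        return None
    best: tuple[tuple, TsdHit] | None = None
    for llen in range(min(max_len, len(lwin)), min_len - 1, -1):
        # left copy must end within max_offset of the element 5' boundary
        for lstart in range(max(0, len(lwin) - llen - max_offset), len(lwin) - llen + 1):
            lsub = lwin[lstart : lstart + llen]
            for rlen in range(max(min_len, llen - max_edits), min(max_len, len(rwin), llen + max_edits) + 1):
                for rstart in range(min(max_offset, len(rwin) - rlen) + 1):
                    rsub = rwin[rstart : rstart + rlen]
                    ed = edlib.align(lsub, rsub, task="distance", k=max_edits)["editDistance"]
                    if ed < 0 or ed > max_edits:
                        continue
                    length = max(llen, rlen)
                    left_off = len(lwin) - (lstart + llen)
                    hit = TsdHit(lsub, rsub, length, ed, left_off, rstart)
                    key = tsd_rank_key(hit, edit_penalty)
                    if best is None or key > best[0]:
                        best = (key, hit)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Pol III promoter scanning


def _iupac_mismatches(pattern: str, text: str, start: int) -> int:
    mm = 0
    for i, p in enumerate(pattern):
        if text[start + i] not in _IUPAC_SETS[p]:
            mm += 1
    return mm


def scan_motif(head: str, pattern: str, max_mismatches: int) -> list[BoxHit]:
    """All sliding-window IUPAC matches with <= max_mismatches, left to right."""
    out = []
    plen = len(pattern)
    for start in range(len(head) - plen + 1):
        mm = _iupac_mismatches(pattern, head, start)
        if mm <= max_mismatches:
            out.append(BoxHit("", start + 1, start + plen, mm))
    return out


def _best_ordered_boxes(
    head: str,
    patterns: list[tuple[str, str]],
    spacings: list[tuple[int, int]],
    allowance: int,
) -> tuple[BoxHit, ...] | None:
    """Best chain of ordered box matches subject to inter-box spacing bounds.

    Minimises total mismatches, then leftmost positions. Spacing is the gap
    in bp between the end of one box and the start of the next.
    """
    candidates = []
    for name, pat in patterns:
        hits = [replace(h, name=name) for h in scan_motif(head, pat, allowance)]
        if not hits:
            return None
        candidates.append(hits)

    best: tuple[tuple[int, tuple[int, ...]], tuple[BoxHit, ...]] | None = None

    def rec(i: int, chain: tuple[BoxHit, ...], mm: int) -> None:
        nonlocal best
        if i == len(candidates):
            key = (mm, tuple(h.start for h in chain))
            if best is None or key < best[0]:
                best = (key, chain)
            return
        for h in candidates[i]:
            if chain:
                gap = h.start - chain[-1].end - 1
                lo, hi = spacings[i - 1]
                if gap < lo or gap > hi:
                    continue
            rec(i + 1, chain + (h,), mm + h.mismatches)

    rec(0, (), 0)
    return best[1] if best else None


def scan_type2_promoter(
    head: NucSequence | str,
    motif_a: str = AnnotConfig.box_a,
    motif_b: str = AnnotConfig.box_b,
    spacing: tuple[int, int] = AnnotConfig.box_ab_spacing,
    max_mismatches: int = AnnotConfig.box_mismatch_allowance,
) -> PromoterAnnotation:
    """tRNA-type internal promoter: box A before box B with bounded spacing."""
    h = str(head)
    chain = _best_ordered_boxes(h, [("A", motif_a), ("B", motif_b)], [spacing], max_mismatches)
    if chain is None:
        return PromoterAnnotation("none")
    return PromoterAnnotation("type2_AB", chain, True)


def scan_type1_promoter(
    head: NucSequence | str,
    motif_a: str = AnnotConfig.box1_a,
    motif_ie: str = AnnotConfig.box1_ie,
    motif_c: str = AnnotConfig.box1_c,
    spacings: tuple[tuple[int, int], tuple[int, int]] = AnnotConfig.box1_spacings,
    max_mismatches: int = AnnotConfig.box_mismatch_allowance,
) -> PromoterAnnotation:
    """5S-type internal promoter: ordered boxes A < IE < C."""
    h = str(head)
    chain = _best_ordered_boxes(
        h, [("A", motif_a), ("IE", motif_ie), ("C", motif_c)], list(spacings), max_mismatches
    )
    if chain is None:
        return PromoterAnnotation("none")
    return PromoterAnnotation("type1_AIEC", chain, True)


# ---------------------------------------------------------------------------
# Head classification


# scoring for head-vs-reference comparison: gaps cost enough that the
# aligner cannot harvest a longest-common-subsequence from unrelated
# sequences (with cheap gap extension, two random 70-mers share ~65% of
# positions as an LCS, which would swamp any identity threshold)
_CLASSIFY_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -4.0, "gap_extend": -2.0}


def head_reference_identity(head: NucSequence | str, ref: NucSequence | str) -> float:
    """Coverage-aware identity between a head region and a reference RNA.

    Matches from a free-end-gap global alignment under gap-averse scoring,
    divided by the shorter sequence length. Dividing by aligned core columns
    alone would let a random pair score high over a tiny perfect core;
    anchoring the denominator to the shorter sequence keeps unrelated pairs
    far below any sensible classification threshold while an embedded true
    copy still reaches 1.0.
    """
    try:
        aln = seqcore.global_align(head, ref, scoring=_CLASSIFY_SCORING, free_end_gaps=True)
    except seqcore.SequenceError:
        # unrelated pair: the optimum is pure side-by-side overhang (score 0)
        return 0.0
    return aln.n_match / min(len(str(head)), len(str(ref)))


def classify_head(
    head: NucSequence | str,
    references: list[NucSequence],
    min_identity: float = 0.50,
) -> tuple[str, float, str | None]:
    """Align the head to each reference RNA (global, free terminal gaps) and
    return (class, identity, best reference id).

    A reference's class is read from its id/description: anything containing
    "5S" (case-insensitive) is 5S rRNA, everything else is treated as tRNA.
    Below *min_identity* the head is "unknown".
    """
    if not references:
        raise seqcore.SequenceError("empty reference library")
    best_id, best_ref = -1.0, None
    for ref in references:
        ident = head_reference_identity(head, ref)
        if ident > best_id:
            best_id, best_ref = ident, ref
    if best_id < min_identity or best_ref is None:
        return "unknown", best_id, None
    label = f"{best_ref.id} {best_ref.description or ''}".upper()
    cls = "5S" if "5S" in label else "tRNA"
    return cls, best_id, best_ref.id


# ---------------------------------------------------------------------------
# Tail repeats and 3' motifs


def find_tail_repeat(
    element: NucSequence | str,
    max_unit: int = 6,
    tail_window: int = 60,
    min_copies: float = 3.0,
    min_purity: float = 0.8,
) -> TailRepeat | None:
    """Best tandem repeat ending within *tail_window* bp of the 3' terminus.

    For every candidate unit (each substring of length 1..max_unit inside the
    window) the repeat run is grown greedily in both directions while overall
    purity (fraction of positions matching the periodic expectation) stays
    >= min_purity. Ranking maximises copies x purity; exact product ties
    (common with small integer counts) prefer the run with more matched
    positions, then the smaller unit, then the run closest to the 3' end.
    """
    if not 1 <= max_unit <= 6:
        raise ValueError("max_unit must be in [1, 6]")
    s = str(element)
    if tail_window > len(s):
        tail_window = len(s)
    win_start = len(s) - tail_window  # 0-based offset of window in element
    window = s[win_start:]
    best: tuple[tuple[float, int, int], TailRepeat] | None = None
    for u in range(1, max_unit + 1):
        for i in range(len(window) - u + 1):
            run = _grow_run(window, i, u, min_purity)
            if run is None:
                continue
            rs, re, matches = run
            copies = (re - rs) / u
            purity = matches / (re - rs)
            if copies < min_copies or purity < min_purity:
                continue
            dist3 = len(window) - re
            tr = TailRepeat(
                unit=window[rs : rs + u],
                copies=copies,
                purity=purity,
                start=win_start + rs + 1,
                end=win_start + re,
                distance_from_3prime=dist3,
            )
            key = (copies * purity, matches, -u, -dist3)
            if best is None or key > best[0]:
                best = (key, tr)
    return best[1] if best else None


def _grow_run(window: str, i: int, u: int, min_purity: float) -> tuple[int, int, int] | None:
    """Greedy periodic extension of the anchor unit window[i:i+u].

    Extends right then left, stopping after two consecutive off-period
    positions; the run always starts and ends on an in-period match and its
    overall purity stays >= min_purity. Returns (start, end, matches) as
    0-based half-open offsets within the window.
    """
    unit = window[i : i + u]
    if len(unit) < u:
        return None

    def fits(j: int) -> bool:
        return window[j] == unit[(j - i) % u]

    n = len(window)
    best_e, cur, streak = i + u, u, 0
    j = i + u
    while j < n and streak < 2:
        if fits(j):
            cur += 1
            streak = 0
            if cur / (j + 1 - i) >= min_purity:
                best_e = j + 1
        else:
            streak += 1
        j += 1
    matches = sum(1 for k in range(i, best_e) if fits(k))
    best_s, cur, streak = i, matches, 0
    j = i
    while j > 0 and streak < 2:
        j -= 1
        if fits(j):
            cur += 1
            streak = 0
            if cur / (best_e - j) >= min_purity:
                best_s = j
        else:
            streak += 1
    matches = sum(1 for k in range(best_s, best_e) if fits(k))
    return best_s, best_e, matches


def find_motif_near_3prime(
    element: NucSequence | str, motif: str = "ATAAAAA", window: int = 60
) -> tuple[int, str] | None:
    """Leftmost exact IUPAC match of *motif* within the final *window* bases.

    Returns (1-based position within the element, matched string) or None.
    """
    s = str(element)
    if window > len(s):
        window = len(s)
    off = len(s) - window
    for start in range(off, len(s) - len(motif) + 1):
        if _iupac_mismatches(motif, s, start) == 0:
            return start + 1, s[start : start + len(motif)]
    return None


# ---------------------------------------------------------------------------
# Truncation and composite annotation


def classify_truncation(
    copy: NucSequence | str,
    consensus: NucSequence | str,
    head_fraction: float = 0.25,
) -> tuple[str, int]:
    """(status, missing 5' bp) from a free-end-gap alignment to the consensus.

    The copy is 5'-truncated when at least *head_fraction* of the consensus
    5' end is left uncovered by the alignment.
    """
    if not str(consensus):
        raise seqcore.SequenceError("empty consensus")
    aln = seqcore.global_align(copy, consensus, free_end_gaps=True)
    ga, gb = aln.gapped_a, aln.gapped_b
    # uncovered consensus 5' bases = consensus chars in the leading copy-gap overhang
    i = 0
    while i < len(ga) and ga[i] == "-":
        i += 1
    missing = sum(1 for c in gb[:i] if c != "-")
    status = (
        "five_prime_truncated"
        if missing >= head_fraction * len(str(consensus))
        else "full_length"
    )
    return status, missing


def annotate_element(
    element: NucSequence,
    left_flank: NucSequence,
    right_flank: NucSequence,
    consensus: NucSequence,
    references: list[NucSequence],
    config: AnnotConfig | None = None,
    location: GenomicLocation | None = None,
) -> SineAnnotation:
    """Compose every hallmark scan into one structural record for a copy."""
    cfg = config or AnnotConfig()
    if not str(element):
        raise seqcore.SequenceError("empty element")
    tsd = find_tsd(
        left_flank, right_flank,
        min_len=cfg.tsd_min_len, max_len=cfg.tsd_max_len,
        max_edits=cfg.tsd_max_edits, window=cfg.tsd_window,
        max_offset=cfg.tsd_max_offset, edit_penalty=cfg.tsd_edit_penalty,
    )
    truncation, missing = classify_truncation(element, consensus, cfg.truncation_head_fraction)
    head = str(element)[: cfg.head_len]
    promoter = PromoterAnnotation("none")
    head_class, head_identity, head_ref = "unknown", 0.0, None
    if truncation == "full_length" and len(head) >= 40:
        p2 = scan_type2_promoter(head, cfg.box_a, cfg.box_b, cfg.box_ab_spacing,
                                 cfg.box_mismatch_allowance)
        if p2.promoter_type != "none":
            promoter = p2
        else:
            p1 = scan_type1_promoter(head, cfg.box1_a, cfg.box1_ie, cfg.box1_c,
                                     cfg.box1_spacings, cfg.box_mismatch_allowance)
            if p1.promoter_type != "none":
                promoter = p1
        head_class, head_identity, head_ref = classify_head(head, references, cfg.head_min_identity)
    tail = find_tail_repeat(element, cfg.tail_max_unit, cfg.tail_window,
                            cfg.tail_min_copies, cfg.tail_min_purity)
    purine = find_motif_near_3prime(element, cfg.purine_motif, cfg.purine_window)
    return SineAnnotation(
        copy_id=element.id,
        location=location,
        tsd=tsd,
        promoter=promoter,
        head_class=head_class,
        head_identity=head_identity,
        head_reference=head_ref,
        tail=tail,
        purine_motif=purine,
        truncation=truncation,
        missing_5prime_bp=missing,
    )


# ---------------------------------------------------------------------------
# Report writers

_TSV_HEADER = (
    "copy_id\tcontig\tstart\tend\tstrand\ttsd_seq\ttsd_len\tpromoter_type\t"
    "head_class\thead_identity\ttail_unit\ttail_copies\ttruncation\n"
)


def write_annotations_tsv(annotations: list[SineAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for a in annotations:
            loc = a.location
            fh.write(
                "\t".join(
                    [
                        a.copy_id,
                        loc.contig if loc else ".",
                        str(loc.start) if loc else ".",
                        str(loc.end) if loc else ".",
                        loc.strand if loc else ".",
                        a.tsd.left_seq if a.tsd else ".",
                        str(a.tsd.length) if a.tsd else "0",
                        a.promoter.promoter_type,
                        a.head_class,
                        f"{a.head_identity:.3f}",
                        a.tail.unit if a.tail else ".",
                        f"{a.tail.copies:.1f}" if a.tail else "0",
                        a.truncation,
                    ]
                )
                + "\n"
            )


def write_annotations_gff3(annotations: list[SineAnnotation], path, source: str = "sinekit") -> None:
    """GFF3 with one dispersed_repeat per copy and child features for boxes,
    TSD copies and the tail repeat (element-relative children are emitted only
    when the genomic location is known)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            if a.location is None:
                continue
            loc = a.location
            strand = loc.strand
            attrs = [f"ID={a.copy_id}", f"truncation={a.truncation}", f"head_class={a.head_class}"]
            fh.write(
                f"{loc.contig}\t{source}\tdispersed_repeat\t{loc.lo}\t{loc.hi}\t.\t{strand}\t.\t"
                + ";".join(attrs) + "\n"
            )

            def child(ftype: int | str, s: int, e: int, extra: str) -> None:
                fh.write(
                    f"{loc.contig}\t{source}\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"Parent={a.copy_id};{extra}\n"
                )

            def elem2genomic(p: int) -> int:
                # 1-based element coordinate -> forward-strand genomic coordinate
                return loc.lo + p - 1 if strand == "+" else loc.hi - p + 1

            for box in a.promoter.boxes:
                g1, g2 = sorted((elem2genomic(box.start), elem2genomic(box.end)))
                child("TF_binding_site", g1, g2, f"Name=box_{box.name}")
            if a.tail:
                g1, g2 = sorted((elem2genomic(a.tail.start), elem2genomic(a.tail.end)))
                child("tandem_repeat", g1, g2, f"Name=tail_{a.tail.unit}")
            if a.tsd:
                llen, rlen = len(a.tsd.left_seq), len(a.tsd.right_seq)
                if strand == "+":
                    l2 = loc.lo - 1 - a.tsd.left_end_offset
                    child("target_site_duplication", l2 - llen + 1, l2, "Name=TSD_left")
                    r1 = loc.hi + 1 + a.tsd.right_start_offset
                    child("target_site_duplication", r1, r1 + rlen - 1, "Name=TSD_right")
                else:
                    l1 = loc.hi + 1 + a.tsd.left_end_offset
                    child("target_site_duplication", l1, l1 + llen - 1, "Name=TSD_left")
                    r2 = loc.lo - 1 - a.tsd.right_start_offset
                    child("target_site_duplication", r2 - rlen + 1, r2, "Name=TSD_right")
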