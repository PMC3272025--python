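"""Sequence primitives shared by every pipeline stage.

Nucleotide sequences are plain uppercase IUPAC strings wrapped in
:class:`NucSequence`. Pairwise alignment is Needleman–Wunsch / Smith–Waterman
with affine gap penalties (match +1, mismatch -1, gap open -2, gap extend
-0.5 by default), executed by Biopython's :class:`Bio.Align.PairwiseAligner`
over a custom substitution matrix in which only identical unambiguous bases
match — ``N`` and the other ambiguity codes never match anything, including
themselves.

Percent identity follows one convention throughout the package: matched
columns divided by aligned columns, where terminal gap overhangs are
excluded from the denominator and internal gap columns count as mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align, AlignIO, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = "ACGTRYSWKMBDHVN"
_IUPAC_RE = re.compile(f"[^{IUPAC_DNA}]")

DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -0.5}


class SequenceError(ValueError):
    """Raised for invalid residues, empty sequences, or undefined statistics."""


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over the IUPAC alphabet (stored uppercase)."""

    id: str
    residues: str
    description: str | None = None

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("U", "T")
        bad = _IUPAC_RE.search(res)
        if bad:
            raise SequenceError(
                f"{self.id}: non-IUPAC character {res[bad.start()]!r} at position {bad.start() + 1}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def slice(self, start: int, end: int, sid: str | None = None) -> "NucSequence":
        """Subsequence by 1-based inclusive coordinates."""
        return NucSequence(sid or f"{self.id}:{start}-{end}", self.residues[start - 1 : end])


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment plus the identity bookkeeping used everywhere."""

    gapped_a: str
    gapped_b: str
    score: float
    n_match: int = field(init=False)
    n_columns_counted: int = field(init=False)
    identity: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise SequenceError("gapped rows differ in length")
        self.n_match, self.n_columns_counted = _count_core(self.gapped_a, self.gapped_b)
        if self.n_columns_counted == 0:
            raise SequenceError("alignment has zero counted columns")
        self.identity = self.n_match / self.n_columns_counted


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: NucSequence | str) -> NucSequence | str:
    """Watson–Crick reverse complement; ambiguity codes map to their complements."""
    if isinstance(seq, str):
        return NucSequence("x", seq).residues.translate(_COMPLEMENT)[::-1]
    return NucSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1], seq.description)


def _count_core(ga: str, gb: str) -> tuple[int, int]:
    """(matches, counted columns): terminal overhangs excluded, internal gaps counted."""
    n = len(ga)
    lo = 0
    while lo < n and (ga[lo] == "-" or gb[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (ga[hi - 1] == "-" or gb[hi - 1] == "-"):
        hi -= 1
    match = 0
    for i in range(lo, hi):
        a, b = ga[i], gb[i]
        if a == b and a in "ACGT":
            match += 1
    return match, hi - lo


_MATRIX_CACHE: dict[tuple[float, float], substitution_matrices.Array] = {}


def _matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    key = (match, mismatch)
    if key not in _MATRIX_CACHE:
        m = substitution_matrices.Array(alphabet=IUPAC_DNA, dims=2)
        for a in IUPAC_DNA:
            for b in IUPAC_DNA:
                m[a, b] = match if (a == b and a in "ACGT") else mismatch
        _MATRIX_CACHE[key] = m
    return _MATRIX_CACHE[key]


def make_aligner(
    scoring: dict | None = None, mode: str = "global", free_end_gaps: bool = False
) -> Align.PairwiseAligner:
    s = {**DEFAULT_SCORING, **(scoring or {})}
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix(s["match"], s["mismatch"])
    aligner.mode = mode
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    if free_end_gaps and mode == "global":
        aligner.end_gap_score = 0.0
    return aligner


def global_align(
    a: NucSequence | str,
    b: NucSequence | str,
    scoring: dict | None = None,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    With ``free_end_gaps`` terminal gaps are unpenalised, which is the mode
    used for comparing possibly-truncated copies against a full consensus.
    """
    sa, sb = str(a), str(b)
    if not sa or not sb:
        raise SequenceError("cannot align an empty sequence")
    aligner = make_aligner(scoring, "global", free_end_gaps)
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def local_align(
    a: NucSequence | str, b: NucSequence | str, scoring: dict | None = None
) -> tuple[PairwiseAlignment, tuple[int, int], tuple[int, int]] | None:
    """Best Smith–Waterman local alignment.

    Returns (alignment, a_interval, b_interval) with 1-based inclusive
    intervals, or None when the best local score is not positive. Among
    co-optimal alignments the shortest is returned: trailing and leading
    alignment segments whose cumulative score is <= 0 are trimmed, so the
    result never ends on a score-neutral mismatch run.
    """
    sa, sb = str(a), str(b)
    if not sa or not sb:
        raise SequenceError("cannot align an empty sequence")
    aligner = make_aligner(scoring, "local")
    alns = aligner.align(sa, sb)
    try:
        aln = alns[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    ga, gb = str(aln[0]), str(aln[1])
    (ast, aen), (bst, ben) = _local_span(aln)
    ga, gb, ast, aen, bst, ben = _trim_neutral_ends(ga, gb, ast, aen, bst, ben, scoring)
    if not ga:
        return None
    pa = PairwiseAlignment(ga, gb, float(aln.score))
    return pa, (ast + 1, aen), (bst + 1, ben)


def _local_span(aln) -> tuple[tuple[int, int], tuple[int, int]]:
    ta, qa = aln.aligned
    return (int(ta[0][0]), int(ta[-1][1])), (int(qa[0][0]), int(qa[-1][1]))


def _trim_neutral_ends(ga, gb, ast, aen, bst, ben, scoring):
    """Drop end columns of a local alignment whose cumulative score <= 0."""
    s = {**DEFAULT_SCORING, **(scoring or {})}

    def colscore(i, opened):
        a, b = ga[i], gb[i]
        if a == "-" or b == "-":
            return (s["gap_extend"] if opened else s["gap_open"]), True
        return (s["match"] if (a == b and a in "ACGT") else s["mismatch"]), False

    # trailing trim
    total, cut = 0.0, len(ga)
    opened = False
    best = 0.0
    for i in range(len(ga) - 1, -1, -1):
        sc, opened = colscore(i, opened)
        total += sc
        if total <= 0:
            cut = i
            best = total
    if cut < len(ga):
        for i in range(cut, len(ga)):
            if ga[i] != "-":
                aen -= 1
            if gb[i] != "-":
                ben -= 1
        ga, gb = ga[:cut], gb[:cut]
    # leading trim
    total, cut = 0.0, 0
    opened = False
    for i in range(len(ga)):
        sc, opened = colscore(i, opened)
        total += sc
        if total <= 0:
            cut = i + 1
    if cut > 0:
        for i in range(cut):
            if ga[i] != "-":
                ast += 1
            if gb[i] != "-":
                bst += 1
        ga, gb = ga[cut:], gb[cut:]
    return ga, gb, ast, aen, bst, ben


def percent_identity(aln: PairwiseAlignment) -> float:
    """Matches / counted columns (terminal overhangs excluded)."""
    return aln.identity


def identity(a: NucSequence | str, b: NucSequence | str, free_end_gaps: bool = True) -> float:
    """Convenience: global-align two sequences and return their identity."""
    return global_align(a, b, free_end_gaps=free_end_gaps).identity


def gc_fraction(seq: NucSequence | str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes and N are excluded entirely."""
    s = str(seq).upper()
    if not s:
        raise SequenceError("empty sequence has no GC fraction")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise SequenceError("GC fraction undefined: no unambiguous bases")
    return gc / (gc + at)


@dataclass(frozen=True)
class Orf:
    frame: int  # +1..+3 forward, -1..-3 reverse
    start: int  # 1-based forward-strand coordinates, start <= end
    end: int
    protein: str


def six_frame_orfs(seq: NucSequence | str, min_aa: int = 10) -> list[Orf]:
    """Maximal ATG-to-stop ORFs of >= min_aa codons on both strands.

    Coordinates are 1-based on the forward strand and include the stop codon.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    s = str(seq)
    n = len(s)
    out: list[Orf] = []
    for strand, work in ((1, s), (-1, reverse_complement(s))):
        for off in range(3):
            i = off
            orf_start = None
            while i + 3 <= len(work):
                codon = work[i : i + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if orf_start is not None:
                        aa_len = (i - orf_start) // 3
                        if aa_len >= min_aa:
                            prot = str(Seq(work[orf_start:i]).translate())
                            w0, w1 = orf_start, i + 3  # 0-based half open on `work`
                            if strand == 1:
                                start, end = w0 + 1, w1
                            else:
                                start, end = n - w1 + 1, n - w0
                            out.append(Orf(strand * (off + 1), start, end, prot))
                        orf_start = None
                elif codon == "ATG" and orf_start is None:
                    orf_start = i
                i += 3
    out.sort(key=lambda o: (o.start, o.end, o.frame))
    return out


# ---------------------------------------------------------------------------
# FASTA / alignment I/O


def read_fasta(path) -> list[NucSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    return [NucSequence(r.id, str(r.seq), r.description or None) for r in records]


def write_fasta(seqs: Iterable[NucSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_alignment(path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an externally produced MSA (aligned FASTA or Clustal).

    Returns (id, gapped row) pairs; rows keep their gap characters.
    """
    msa = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq).upper()) for rec in msa]


def write_alignment(rows: Sequence[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(g), id=name, description="") for name, g in rows]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
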