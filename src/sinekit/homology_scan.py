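"""Local homology search: find copies of a query in genome FASTA.

A stand-in for a web blastn round-trip: exact k-mer seeds are collected per
contig and strand, chained along diagonals, and each chain is resolved by a
Smith–Waterman extension of the query against the spanned genomic window.
Hit identity is then recomputed by a free-end-gap global alignment of the
extracted genomic segment against the query, so the reported number always
agrees with :func:`sinekit.seqcore.percent_identity` on the same pair.

Coordinates follow the 1-based inclusive convention used in the copy tables:
``start > end`` encodes a minus-strand element (e.g. "1082-759").
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from . import seqcore
from .seqcore import NucSequence, SequenceError

DEFAULT_WORD_SIZE = 11
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_LENGTH = 80  # SINEs are ~80-500 bp
DIAG_DRIFT = 50  # max diagonal drift when chaining co-linear seeds


@dataclass(frozen=True)
class GenomicLocation:
    """1-based inclusive location; start > end means minus strand."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"non-positive coordinate in {self}")

    @property
    def strand(self) -> str:
        return "-" if self.start > self.end else "+"

    @property
    def lo(self) -> int:
        return min(self.start, self.end)

    @property
    def hi(self) -> int:
        return max(self.start, self.end)

    @property
    def length(self) -> int:
        return self.hi - self.lo + 1

    def to_bed(self) -> tuple[str, int, int, str]:
        """(chrom, 0-based start, half-open end, strand) — the BED convention."""
        return self.contig, self.lo - 1, self.hi, self.strand


@dataclass(frozen=True)
class ScanHit:
    query_id: str
    location: GenomicLocation
    identity: float
    aligned_length: int
    score: float


def _as_genome(genome) -> dict[str, str]:
    if isinstance(genome, NucSequence):
        genome = [genome]
    if isinstance(genome, dict):
        return {k: str(v) for k, v in genome.items()}
    return {g.id: str(g) for g in genome}


def scan_genome(
    query: NucSequence,
    genome,
    word_size: int = DEFAULT_WORD_SIZE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    scoring: dict | None = None,
) -> list[ScanHit]:
    """Seeded scan of both strands of every contig for copies of *query*."""
    if not 8 <= word_size <= 16:
        raise ValueError("word_size must be in [8, 16]")
    q = str(query)
    if len(q) < word_size:
        raise SequenceError("query shorter than word_size")
    contigs = _as_genome(genome)
    hits: list[ScanHit] = []
    for contig_id, cseq in contigs.items():
        index = _kmer_index(cseq, word_size)
        for strand, qseq in ((+1, q), (-1, str(seqcore.reverse_complement(q)))):
            seeds = _find_seeds(qseq, index, word_size)
            for gstart, gend in _chain_windows(seeds, word_size, len(qseq), len(cseq)):
                hit = _extend(
                    query.id, qseq, cseq, contig_id, strand, gstart, gend,
                    min_identity, min_length, scoring,
                )
                if hit is not None:
                    hits.append(hit)
    hits = _dedup(hits)
    hits.sort(key=lambda h: (h.location.contig, h.location.lo, h.location.hi))
    return hits


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _find_seeds(qseq: str, index, k: int) -> list[tuple[int, int]]:
    seeds = []
    for qpos in range(len(qseq) - k + 1):
        for gpos in index.get(qseq[qpos : qpos + k], ()):
            seeds.append((qpos, gpos))
    return seeds


def _chain_windows(seeds, k: int, qlen: int, clen: int) -> list[tuple[int, int]]:
    """Cluster co-linear seeds into candidate genomic windows (0-based half-open)."""
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    chains: list[list[tuple[int, int]]] = []
    cur = [by_diag[0]]
    for s in by_diag[1:]:
        pd = cur[-1][1] - cur[-1][0]
        d = s[1] - s[0]
        if abs(d - pd) <= DIAG_DRIFT and s[1] - cur[-1][1] <= qlen:
            cur.append(s)
        else:
            chains.append(cur)
            cur = [s]
    chains.append(cur)
    windows = []
    for ch in chains:
        qmin = min(s[0] for s in ch)
        gmin = min(s[1] for s in ch)
        gmax = max(s[1] for s in ch) + k
        # allow the extension to reach the full query extent plus slack
        lo = max(0, gmin - qmin - 30)
        hi = min(clen, gmax + (qlen - max(s[0] for s in ch) - k) + 30)
        windows.append((lo, hi))
    # merge overlapping windows so one locus is extended once
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _extend(
    query_id, qseq, cseq, contig_id, strand, wlo, whi, min_identity, min_length, scoring
) -> ScanHit | None:
    window = cseq[wlo:whi]
    res = seqcore.local_align(qseq, window, scoring)
    if res is None:
        return None
    aln, (qst, qen), (bst, ben) = res
    glo, ghi = wlo + bst, wlo + ben  # 1-based inclusive on forward strand
    # a short unaligned query prefix on the element's 5' side means the
    # copy's first bases are mutated, not absent: claim them for the element
    # so the upstream flank (and any TSD in it) starts at the true boundary
    if strand > 0:
        head_missing = qst - 1
        if 1 <= head_missing <= 5:
            glo = max(1, glo - head_missing)
    else:
        head_missing = len(qseq) - qen
        if 1 <= head_missing <= 5:
            ghi = min(len(cseq), ghi + head_missing)
    if ghi - glo + 1 < min_length:
        return None
    segment = cseq[glo - 1 : ghi]
    if strand < 0:
        segment = str(seqcore.reverse_complement(segment))
        loc = GenomicLocation(contig_id, ghi, glo)
    else:
        loc = GenomicLocation(contig_id, glo, ghi)
    ident = seqcore.identity(segment, qseq if strand > 0 else str(seqcore.reverse_complement(qseq)))
    if ident < min_identity:
        return None
    return ScanHit(query_id, loc, ident, len(aln.gapped_a), aln.score)


def _dedup(hits: list[ScanHit]) -> list[ScanHit]:
    """Report one hit per locus: drop hits mostly contained in a better hit."""
    kept: list[ScanHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        ov = False
        for k in kept:
            if k.location.contig != h.location.contig:
                continue
            if k.location.strand != h.location.strand:
                continue
            inter = min(k.location.hi, h.location.hi) - max(k.location.lo, h.location.lo) + 1
            if inter > 0.5 * h.location.length:
                ov = True
                break
        if not ov:
            kept.append(h)
    return kept


def merge_hits(hits: list[ScanHit], max_gap: int) -> list[ScanHit]:
    """Merge same-contig, same-strand hits whose genomic gap is <= max_gap.

    The merged locus spans both hits; identity is length-weighted.
    """
    groups: dict[tuple[str, str, str], list[ScanHit]] = defaultdict(list)
    for h in hits:
        groups[(h.query_id, h.location.contig, h.location.strand)].append(h)
    out: list[ScanHit] = []
    for (qid, contig, strand), hs in groups.items():
        hs.sort(key=lambda h: h.location.lo)
        cur = hs[0]
        for h in hs[1:]:
            gap = h.location.lo - cur.location.hi - 1
            if gap <= max_gap:
                lo = min(cur.location.lo, h.location.lo)
                hi = max(cur.location.hi, h.location.hi)
                w1, w2 = cur.location.length, h.location.length
                ident = (cur.identity * w1 + h.identity * w2) / (w1 + w2)
                loc = GenomicLocation(contig, hi, lo) if strand == "-" else GenomicLocation(contig, lo, hi)
                cur = ScanHit(qid, loc, ident, cur.aligned_length + h.aligned_length,
                              cur.score + h.score)
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    out.sort(key=lambda h: (h.location.contig, h.location.lo, h.location.hi))
    return out


def extract_with_flanks(
    genome, loc: GenomicLocation, flank: int = 200
) -> tuple[NucSequence, NucSequence, NucSequence]:
    """(left_flank, element, right_flank), all in the element's 5'->3' orientation.

    Flanks are clipped at contig edges, never padded. For minus-strand
    locations everything is reverse-complemented, so "left" is the element's
    5' side in its own reading direction.
    """
    contigs = _as_genome(genome)
    if loc.contig not in contigs:
        raise SequenceError(f"contig {loc.contig!r} not in genome")
    cseq = contigs[loc.contig]
    if loc.hi > len(cseq):
        raise SequenceError(f"{loc} outside contig of length {len(cseq)}")
    elem_fwd = cseq[loc.lo - 1 : loc.hi]
    up = cseq[max(0, loc.lo - 1 - flank) : loc.lo - 1]  # forward-strand upstream
    down = cseq[loc.hi : loc.hi + flank]
    name = f"{loc.contig}:{loc.start}-{loc.end}"
    if loc.strand == "+":
        left, elem, right = up, elem_fwd, down
    else:
        left = str(seqcore.reverse_complement(down))
        elem = str(seqcore.reverse_complement(elem_fwd))
        right = str(seqcore.reverse_complement(up))
    return (
        NucSequence(name + ":L", left) if left else NucSequence(name + ":L", "N"),
        NucSequence(name, elem),
        NucSequence(name + ":R", right) if right else NucSequence(name + ":R", "N"),
    )


def refine_tail_boundary(genome, hit: ScanHit, unit: str | None = None) -> ScanHit:
    """Extend a hit's 3' end through whole-unit continuations of a tandem tail.

    Per-copy tail lengths vary around the consensus tail, so the aligned 3'
    boundary can stop mid-run; the element boundary is pushed outward while
    the next full period exactly repeats the current end. Extension steps by
    whole units of length >= 2 only — single-base stepping would routinely
    walk one or two bases into a downstream target site duplication that
    happens to start with the same base as the tail.

    Pair this with :func:`trim_query_tail` on the scan query: with the query
    tail reduced to two complete units the aligned 3' boundary always sits on
    an in-phase unit boundary inside the element's tail, and the whole-unit
    extension then stops exactly at the tail's end rather than walking into
    a downstream target site duplication.

    When *unit* is None the terminal repeat period is detected from the
    element's final bases; hits that do not end in a tandem run are returned
    unchanged.
    """
    contigs = _as_genome(genome)
    cseq = contigs[hit.location.contig]
    loc = hit.location
    if unit is None:
        _, elem, _ = extract_with_flanks(contigs, loc, flank=0)
        u = _terminal_period(str(elem))
        if u is None:
            return hit
    else:
        u = len(unit)
    if u < 2:
        return hit
    if loc.strand == "+":
        end = loc.hi  # 1-based
        while end + u <= len(cseq) and end - u >= 0 and cseq[end : end + u] == cseq[end - u : end]:
            end += u
    else:
        end = loc.lo  # element 3' end is the forward-strand low coordinate
        while (
            end - 1 - u >= 0
            and end - 1 + u <= len(cseq)
            and cseq[end - 1 - u : end - 1] == cseq[end - 1 : end - 1 + u]
        ):
            end -= u
    loc = (
        GenomicLocation(loc.contig, loc.lo, end)
        if loc.strand == "+"
        else GenomicLocation(loc.contig, loc.hi, end)
    )
    if loc != hit.location:
        return replace(hit, location=loc)
    return hit


def _terminal_run(s: str, u: int) -> int:
    """Length of the period-u tandem run covering the 3' end of s."""
    k = 0
    while k + u < len(s) and s[len(s) - 1 - k] == s[len(s) - 1 - k - u]:
        k += 1
    return k + u


def _terminal_period(s: str, max_unit: int = 6, min_units: int = 2) -> int | None:
    """Smallest period 2..max_unit whose tandem run covers the element's 3' end
    with at least min_units complete units; None when the end is not repetitive."""
    for u in range(2, max_unit + 1):
        if _terminal_run(s, u) >= min_units * u:
            return u
    return None


def trim_query_tail(query: NucSequence, max_units: int = 2) -> NucSequence:
    """Trim a scan query's terminal tandem run down to *max_units* whole units.

    Per-copy tail lengths vary, so aligning a full-tail query against a
    short-tailed copy lets trailing query units creep base-by-base into the
    downstream TSD. Scanning with a short in-phase tail and recovering the
    full extent with :func:`refine_tail_boundary` keeps 3' boundaries exact.
    """
    s = str(query)
    u = _terminal_period(s)
    if u is None:
        return query
    run = _terminal_run(s, u)
    n_remove = max(0, run // u - max_units)
    if n_remove == 0:
        return query
    return NucSequence(query.id, s[: len(s) - n_remove * u], query.description)


def write_hits_tsv(hits: list[ScanHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcontig\tstart\tend\tstrand\tidentity\taligned_length\tscore\n")
        for h in hits:
            l = h.location
            fh.write(
                f"{h.query_id}\t{l.contig}\t{l.start}\t{l.end}\t{l.strand}\t"
                f"{h.identity:.4f}\t{h.aligned_length}\t{h.score:g}\n"
            )


def write_hits_bed(hits: list[ScanHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            chrom, start, end, strand = h.location.to_bed()
            fh.write(f"{chrom}\t{start}\t{end}\t{h.query_id}\t{int(round(1000 * h.identity))}\t{strand}\n")
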