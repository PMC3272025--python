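"""Genome-scale statistics around annotated copies.

Covers the coordinate arithmetic of the copy tables (1-based inclusive,
start > end on the minus strand), flanking GC content in a configurable
window (2 kb by default), linear extrapolation of genome-wide copy number
from a sampled fraction of the genome, and genomic-context labelling of
insertions against a GFF3 annotation (exonic / intronic / near a
transposable element / intergenic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import gffutils
from intervaltree import IntervalTree

from . import seqcore
from .homology_scan import GenomicLocation, extract_with_flanks
from .seqcore import SequenceError

# the study-scale defaults: 1.963 Mb of BAC sequence out of a 400 Mb genome
DEFAULT_SAMPLED_MB = 1.963
DEFAULT_GENOME_MB = 400.0
DEFAULT_GC_WINDOW = 2000

_TE_TYPES = {
    "transposable_element",
    "mobile_genetic_element",
    "repeat_region",
    "dispersed_repeat",
    "transposable_element_gene",
}


@dataclass(frozen=True)
class CopyNumberEstimate:
    observed_count: int
    sampled_mb: float
    genome_mb: float
    raw_estimate: float
    rounded_estimate: int
    sampled_fraction_pct: float


@dataclass(frozen=True)
class FlankGC:
    gc_5prime: float | None
    gc_3prime: float | None
    window: int
    truncated_5: bool
    truncated_3: bool


def location_length(loc: GenomicLocation | tuple[int, int]) -> int:
    """|end - start| + 1 — the printed length of a 1-based inclusive span."""
    if isinstance(loc, tuple):
        start, end = loc
        if start < 1 or end < 1:
            raise ValueError("coordinates must be positive")
        return abs(end - start) + 1
    return loc.length


def flank_gc(genome, loc: GenomicLocation, window: int = DEFAULT_GC_WINDOW) -> FlankGC:
    """GC of the *window* bases on the element's 5' and 3' sides.

    Windows are clipped at contig edges and flagged; a side with no
    available flank at all yields None for that side.
    """
    left, _elem, right = extract_with_flanks(genome, loc, flank=window)
    lres, rres = str(left), str(right)
    lres = "" if lres == "N" else lres
    rres = "" if rres == "N" else rres

    def side(s: str) -> tuple[float | None, bool]:
        if not s:
            return None, True
        return seqcore.gc_fraction(s), len(s) < window

    gc5, t5 = side(lres)
    gc3, t3 = side(rres)
    return FlankGC(gc5, gc3, window, t5, t3)


def round_sig(x: float, sig: int = 2) -> int:
    """Round to *sig* significant figures, half-up on the last kept digit."""
    if x == 0:
        return 0
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return int(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def estimate_copy_number(
    observed_count: int,
    sampled_mb: float = DEFAULT_SAMPLED_MB,
    genome_mb: float = DEFAULT_GENOME_MB,
    sig_figs: int = 2,
) -> CopyNumberEstimate:
    """Linear extrapolation of genome-wide copy number from a sampled slice.

    raw = observed x genome_mb / sampled_mb, reported rounded to *sig_figs*
    significant figures, alongside the sampled fraction as a percentage to
    one decimal.
    """
    if sampled_mb <= 0:
        raise ValueError("sampled_mb must be positive")
    if genome_mb < sampled_mb:
        raise ValueError("genome_mb must be >= sampled_mb")
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    raw = observed_count * genome_mb / sampled_mb
    return CopyNumberEstimate(
        observed_count=observed_count,
        sampled_mb=sampled_mb,
        genome_mb=genome_mb,
        raw_estimate=raw,
        rounded_estimate=round_sig(raw, sig_figs),
        sampled_fraction_pct=round(100.0 * sampled_mb / genome_mb, 1),
    )


class GenomeAnnotation:
    """Interval lookup over a GFF3 file's genes, exons and TE features."""

    def __init__(self, gff3_path) -> None:
        self.genes: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        self.tes: dict[str, IntervalTree] = {}
        try:
            features = list(gffutils.iterators.DataIterator(str(gff3_path)))
        except Exception as exc:  # gffutils reports the offending line text
            raise SequenceError(f"malformed GFF3 {gff3_path}: {exc}") from exc
        for n, feat in enumerate(features, start=1):
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise SequenceError(f"malformed GFF3 feature at record {n}: {feat}")
            tree = None
            if feat.featuretype == "gene":
                tree = self.genes
            elif feat.featuretype in ("exon", "CDS"):
                tree = self.exons
            elif feat.featuretype in _TE_TYPES:
                tree = self.tes
            if tree is not None:
                name = feat.attributes.get("ID", [feat.featuretype])[0]
                tree.setdefault(feat.seqid, IntervalTree()).addi(
                    feat.start, feat.end + 1, (name, feat.featuretype)
                )

    @staticmethod
    def _query(trees, contig: str, lo: int, hi: int):
        tree = trees.get(contig)
        return sorted(tree.overlap(lo, hi + 1)) if tree else []


def genomic_context(
    loc: GenomicLocation,
    annotation: GenomeAnnotation,
    te_distance: int = 1000,
) -> tuple[str, str | None]:
    """(label, nearest feature name) for one insertion.

    Precedence: exonic > intronic > near_TE > intergenic. Intronic means
    fully inside a gene while overlapping no exon; near_TE means within
    *te_distance* bp of a transposable-element feature.
    """
    contig, lo, hi = loc.contig, loc.lo, loc.hi
    exons = annotation._query(annotation.exons, contig, lo, hi)
    if exons:
        return "exonic", exons[0].data[0]
    genes = [iv for iv in annotation._query(annotation.genes, contig, lo, hi)
             if iv.begin <= lo and iv.end - 1 >= hi]
    if genes:
        return "intronic", genes[0].data[0]
    tes = annotation._query(annotation.tes, contig, max(1, lo - te_distance), hi + te_distance)
    if tes:
        return "near_TE", tes[0].data[0]
    return "intergenic", None


def context_summary(labels: list[str]) -> dict[str, int]:
    """Counts per context label; the values always sum to len(labels)."""
    out = {"exonic": 0, "intronic": 0, "near_TE": 0, "intergenic": 0}
    for lab in labels:
        out[lab] += 1
    return out
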