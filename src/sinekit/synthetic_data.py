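"""Synthetic genomes with planted SINE families and full ground truth.

The generator emulates the copy architecture observed in real insect SINE
families: a family consensus with an RNA-derived head carrying Pol III
promoter boxes, a unique body, and a short tandem-repeat tail; copies
planted on both strands at per-copy divergence (substitutions + short
indels), with optional 5' truncation, per-copy tail-length variation, and
perfect or near-perfect target site duplications of 5-19 bp drawn from the
insertion site itself (the target-site model). Background sequence is i.i.d.
with configurable GC, defaulting to the 36.1% GC of the sequenced fraction
of the cotton bollworm genome that the study conditions mirror.

Ground truth records, per planted copy: final-genome coordinates, strand,
the TSD string, truncation status and realized divergence — everything the
recovery tests need to score the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import seqcore
from .homology_scan import GenomicLocation
from .seqcore import NucSequence

DEFAULT_GC = 0.361

# an arbitrary but fixed tRNA-like head used when no reference is supplied:
# carries exact instances of the default box A (TRGCNNARYNNG) and box B
# (GTTCRANNC) motifs at tRNA-typical positions (boxes at ~+8 and ~+52)
DEFAULT_HEAD = (
    "GGTCCCATAGCTCAGTTGGTAGAGCATCAGACTTTTAATCTGAGGGTCCAGGGTTCAAGTCCCTGTTGGGACG"
)


@dataclass
class FamilySpec:
    """Generation parameters for one planted family."""

    name: str = "simSE1"
    consensus: NucSequence | None = None  # auto-generated when None
    consensus_len: int = 386
    head_template: str = DEFAULT_HEAD
    tail_unit: str = "TGA"
    tail_copies_range: tuple[int, int] = (3, 10)
    consensus_tail_copies: int = 5
    divergence: tuple[float, float] = (0.03, 0.23)  # per-copy uniform draw
    indel_rate: float = 0.01
    truncation_prob: float = 0.5
    truncation_range: tuple[int, int] = (75, 356)  # surviving copy lengths, bp
    tsd_len_range: tuple[int, int] = (5, 19)
    tsd_edit_prob: float = 0.05
    n_copies: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.divergence[0] <= self.divergence[1] <= 0.5:
            raise ValueError("divergence bounds must lie in [0, 0.5]")
        if not (4 <= self.tsd_len_range[0] <= self.tsd_len_range[1] <= 25):
            raise ValueError("tsd_len_range must lie within [4, 25]")
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")


@dataclass
class PlantedTruth:
    copy_id: str
    family: str
    location: GenomicLocation
    tsd_seq: str  # plus-strand genomic sequence of the duplicated site
    tsd_len: int
    truncated: bool
    missing_5prime_bp: int
    realized_divergence: float
    strand: str


def generate_background(length: int, gc: float = DEFAULT_GC, seed: int = 0) -> NucSequence:
    """i.i.d. background: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        np.array(["A", "C", "G", "T"]),
        size=length,
        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
    )
    return NucSequence(f"background_seed{seed}", "".join(bases))


def make_consensus(spec: FamilySpec, seed: int = 0) -> NucSequence:
    """Family consensus = head template + random body + canonical tail."""
    if spec.consensus is not None:
        return spec.consensus
    rng = np.random.default_rng([seed, 977])
    tail = spec.tail_unit * spec.consensus_tail_copies
    body_len = max(0, spec.consensus_len - len(spec.head_template) - len(tail))
    body = "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=body_len))
    return NucSequence(f"{spec.name}_consensus", spec.head_template + body + tail)


def mutate_copy(
    consensus: NucSequence | str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, float]:
    """Mutate a consensus copy: per-site substitutions and 1-3 bp indels.

    Returns (copy, realized divergence), the latter as edit events per
    consensus length.
    """
    if divergence + indel_rate >= 0.5:
        raise ValueError("divergence + indel_rate must be < 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = str(consensus)
    out: list[str] = []
    events = 0
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for ch in s:
        u = rng.random()
        if u < indel_rate:
            events += 1
            ln = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before this site
                ins = "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=ln))
                out.append(ins + ch)
            else:  # deletion of this site (ln collapses to 1 for simplicity)
                continue
        elif u < indel_rate + divergence and ch in others:
            events += 1
            out.append(others[ch][int(rng.integers(0, 3))])
        else:
            out.append(ch)
    return "".join(out), events / len(s)


def plant_family(
    genome: NucSequence,
    spec: FamilySpec,
    seed: int = 0,
    min_spacing: int = 100,
) -> tuple[NucSequence, list[PlantedTruth]]:
    """Insert n_copies mutated copies with TSDs into the background.

    Insertion sites are uniform with >= min_spacing bp between planted
    elements; the TSD is read from the target site and duplicated on both
    sides (optionally with one edit on the right copy). All truth
    coordinates refer to the final, post-insertion genome.
    """
    rng = np.random.default_rng([seed, 31337])
    consensus = make_consensus(spec, seed)
    cons = str(consensus)
    cons_tail_len = len(spec.tail_unit) * spec.consensus_tail_copies
    core = cons[: len(cons) - cons_tail_len]
    background = str(genome)
    n = spec.n_copies
    if n == 0:
        return genome, []
    # choose non-overlapping anchor points in the original background
    need = n * (min_spacing + spec.tsd_len_range[1])
    if len(background) < need + 2 * min_spacing:
        raise ValueError("genome too short for non-overlapping placement")
    while True:
        anchors = np.sort(rng.integers(min_spacing, len(background) - min_spacing, size=n))
        if n == 1 or np.all(np.diff(anchors) >= min_spacing + spec.tsd_len_range[1]):
            break

    pieces: list[str] = []
    truths: list[PlantedTruth] = []
    prev = 0
    offset = 0  # cumulative inserted length so far
    for k, anchor in enumerate(anchors):
        div = rng.uniform(*spec.divergence)
        copy, realized = mutate_copy(core, div, spec.indel_rate, rng)
        truncated = False
        missing = 0
        if rng.random() < spec.truncation_prob:
            lo, hi = spec.truncation_range
            hi = min(hi, len(copy) - 1)
            if hi > lo:
                keep = int(rng.integers(lo, hi + 1))
                missing = len(copy) - keep
                copy = copy[-keep:]
                truncated = True
        tail_copies = int(rng.integers(spec.tail_copies_range[0], spec.tail_copies_range[1] + 1))
        element = copy + spec.tail_unit * tail_copies
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = element if strand == "+" else str(seqcore.reverse_complement(element))

        tsd_len = int(rng.integers(spec.tsd_len_range[0], spec.tsd_len_range[1] + 1))
        site = background[anchor : anchor + tsd_len]
        right_copy = site
        if rng.random() < spec.tsd_edit_prob:
            pos = int(rng.integers(0, tsd_len))
            alt = "ACGT"[int(rng.integers(0, 4))]
            right_copy = site[:pos] + alt + site[pos + 1 :]

        pieces.append(background[prev : anchor + tsd_len])
        pieces.append(inserted)
        pieces.append(right_copy)
        prev = anchor + tsd_len

        elem_start = offset + anchor + tsd_len + 1  # 1-based in final genome
        elem_end = elem_start + len(inserted) - 1
        offset += len(inserted) + len(right_copy)

        if strand == "+":
            loc = GenomicLocation(genome.id, elem_start, elem_end)
        else:
            loc = GenomicLocation(genome.id, elem_end, elem_start)
        truths.append(
            PlantedTruth(
                copy_id=f"{spec.name}.{k + 1}",
                family=spec.name,
                location=loc,
                tsd_seq=site,
                tsd_len=tsd_len,
                truncated=truncated,
                missing_5prime_bp=missing,
                realized_divergence=realized,
                strand=strand,
            )
        )
    pieces.append(background[prev:])
    new_genome = NucSequence(genome.id, "".join(pieces), genome.description)
    return new_genome, truths


def write_truth_tsv(truths: list[PlantedTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "copy_id\tfamily\tcontig\tstart\tend\tstrand\ttsd_seq\ttsd_len\t"
            "truncated\tmissing_5prime_bp\trealized_divergence\n"
        )
        for t in truths:
            l = t.location
            fh.write(
                f"{t.copy_id}\t{t.family}\t{l.contig}\t{l.start}\t{l.end}\t{t.strand}\t"
                f"{t.tsd_seq}\t{t.tsd_len}\t{int(t.truncated)}\t{t.missing_5prime_bp}\t"
                f"{t.realized_divergence:.4f}\n"
            )


def write_truth_bed(truths: list[PlantedTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            chrom, start, end, strand = t.location.to_bed()
            fh.write(f"{chrom}\t{start}\t{end}\t{t.copy_id}\t0\t{strand}\n")


def write_spec_json(spec: FamilySpec, seed: int, path) -> None:
    payload = asdict(spec)
    if spec.consensus is not None:
        payload["consensus"] = {"id": spec.consensus.id, "residues": str(spec.consensus)}
    payload["seed"] = seed
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
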