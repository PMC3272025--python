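"""Family consensus construction and identity profiles.

A family consensus approximates the ancestral active element. It is built by
a star alignment: every member is globally aligned (free terminal gaps) to a
seed copy — by default the longest member — and the pairwise alignments are
projected onto common coordinates by merging the gap columns they insert
into the seed. Per column the majority base is emitted when its frequency
among non-gap characters reaches ``min_fraction``; mostly-gap columns are
dropped.

The identity profile (min / median / max identity of each member to the
consensus) is the family-level statistic reported per family, e.g. a family
whose copies range from 77% to 97% identity with a median of 89%.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass

from . import seqcore
from .seqcore import NucSequence, SequenceError


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows, one per copy; ungapping recovers the input."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("an alignment needs at least 2 rows")
        width = len(self.rows[0][1])
        if any(len(g) != width for _, g in self.rows):
            raise SequenceError("alignment rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def ungapped(self, i: int) -> str:
        return self.rows[i][1].replace("-", "")

    def column(self, j: int) -> list[str]:
        return [g[j] for _, g in self.rows]


@dataclass
class ConsensusProfile:
    consensus: NucSequence
    per_copy_identity: dict[str, float]
    min_identity: float
    median_identity: float
    max_identity: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "consensus_id": self.consensus.id,
                "n": len(self.per_copy_identity),
                "min": self.min_identity,
                "median": self.median_identity,
                "max": self.max_identity,
            },
            indent=2,
        )


def star_msa(copies: list[NucSequence], seed_id: str | None = None) -> MultipleAlignment:
    """Star alignment of *copies* around a seed (default: the longest copy).

    Deterministic for a fixed input order; ungapping any row recovers the
    corresponding input sequence exactly.
    """
    if len(copies) < 2:
        raise SequenceError("need at least 2 copies for an alignment")
    if seed_id is None:
        seed = max(copies, key=lambda c: (len(c), ))  # first-longest wins ties
    else:
        matches = [c for c in copies if c.id == seed_id]
        if not matches:
            raise SequenceError(f"seed {seed_id!r} not among copies")
        seed = matches[0]
    sres = str(seed)
    slen = len(sres)

    # per copy: aligned char at each seed position (or '-') and insertions
    # keyed by the seed position they precede (slot slen = trailing)
    aligned_chars: list[list[str]] = []
    insertions: list[list[str]] = []
    for copy in copies:
        if copy is seed:
            aligned_chars.append(list(sres))
            insertions.append([""] * (slen + 1))
            continue
        aln = seqcore.global_align(seed, copy, free_end_gaps=True)
        chars = ["-"] * slen
        ins = [""] * (slen + 1)
        spos = 0
        for a, b in zip(aln.gapped_a, aln.gapped_b):
            if a == "-":
                ins[spos] += b
            else:
                if b != "-":
                    chars[spos] = b
                spos += 1
        aligned_chars.append(chars)
        insertions.append(ins)

    max_ins = [max(len(ins[j]) for ins in insertions) for j in range(slen + 1)]
    rows: list[tuple[str, str]] = []
    for copy, chars, ins in zip(copies, aligned_chars, insertions):
        parts: list[str] = []
        for j in range(slen):
            parts.append(ins[j].ljust(max_ins[j], "-"))
            parts.append(chars[j])
        parts.append(ins[slen].ljust(max_ins[slen], "-"))
        rows.append((copy.id, "".join(parts)))
    return MultipleAlignment(rows)


def majority_consensus(
    msa: MultipleAlignment,
    min_fraction: float = 0.5,
    gap_rule: float = 0.5,
    consensus_id: str = "consensus",
) -> NucSequence:
    """Per-column plurality consensus.

    Columns whose gap frequency exceeds *gap_rule* are dropped. Otherwise the
    most frequent base among non-gap characters is emitted when its frequency
    reaches *min_fraction*, else 'N'. Base ties break alphabetically.
    """
    out: list[str] = []
    n = len(msa.rows)
    for j in range(msa.width):
        col = msa.column(j)
        gaps = col.count("-")
        if gaps / n > gap_rule:
            continue
        bases = [c for c in col if c != "-"]
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        base, cnt = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append(base if cnt / len(bases) >= min_fraction else "N")
    return NucSequence(consensus_id, "".join(out))


def identity_profile(copies: list[NucSequence], consensus: NucSequence) -> ConsensusProfile:
    """Identity of every copy to the consensus (global, free terminal gaps),
    with the exact min / median / max order statistics."""
    if not copies:
        raise SequenceError("empty copy list")
    if not str(consensus):
        raise SequenceError("empty consensus")
    idents = {c.id: seqcore.identity(c, consensus, free_end_gaps=True) for c in copies}
    vals = sorted(idents.values())
    return ConsensusProfile(
        consensus=consensus,
        per_copy_identity=idents,
        min_identity=vals[0],
        median_identity=statistics.median(vals),
        max_identity=vals[-1],
    )


def build_family_consensus(
    copies: list[NucSequence],
    min_fraction: float = 0.5,
    gap_rule: float = 0.5,
    consensus_id: str = "consensus",
) -> tuple[NucSequence, ConsensusProfile]:
    """Star-align copies, derive the majority consensus, and profile it."""
    msa = star_msa(copies)
    cons = majority_consensus(msa, min_fraction, gap_rule, consensus_id)
    return cons, identity_profile(copies, cons)


def write_profile_tsv(profile: ConsensusProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tidentity\n")
        for cid, ident in profile.per_copy_identity.items():
            fh.write(f"{cid}\t{ident:.4f}\n")
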