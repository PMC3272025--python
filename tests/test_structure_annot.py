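"""Hallmark annotation checks: TSD search against a brute-force oracle and
the published examples, promoter scans against a sliding-window oracle, head
classification, tail repeats, 3' motifs, and truncation calls."""

import numpy as np
import pytest

from sinekit import structure_annot as sa
from sinekit import synthetic_data as sd
from sinekit import seqcore as sc
from sinekit.seqcore import NucSequence

from conftest import random_seq


def brute_force_tsd(lf, rf, min_len=5, max_len=19, max_edits=1, window=30, max_offset=10):
    """Independent exhaustive enumeration of all substring pairs with a plain
    DP edit distance; same ranking as the production search."""

    def edit_distance(a, b):
        m, n = len(a), len(b)
        d = [[0] * (n + 1) for _ in range(m + 1)]
        for i in range(m + 1):
            d[i][0] = i
        for j in range(n + 1):
            d[0][j] = j
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                d[i][j] = min(
                    d[i - 1][j] + 1,
                    d[i][j - 1] + 1,
                    d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                )
        return d[m][n]

    lwin, rwin = lf[-window:], rf[:window]
    best = None
    for llen in range(min_len, min(max_len, len(lwin)) + 1):
        for lstart in range(len(lwin) - llen + 1):
            loff = len(lwin) - lstart - llen
            if loff > max_offset:
                continue
            for rlen in range(min_len, min(max_len, len(rwin)) + 1):
                if abs(rlen - llen) > max_edits:
                    continue
                for rstart in range(min(max_offset, len(rwin) - rlen) + 1):
                    ed = edit_distance(lwin[lstart : lstart + llen], rwin[rstart : rstart + rlen])
                    if ed > max_edits:
                        continue
                    length = max(llen, rlen)
                    key = (length - 3 * ed, length, -ed, -(loff + rstart))
                    if best is None or key > best[0]:
                        best = (key, lwin[lstart : lstart + llen], rwin[rstart : rstart + rlen])
    return best


class TestFindTsd:
    def test_published_perfect_16bp(self):
        # 16 bp perfect duplication flanking a truncated element
        t = "AGAGCTGAATCAGCTG"
        hit = sa.find_tsd("ATTGCACCGGTAAC" + t, t + "GGTACCGATTACGA")
        assert hit is not None
        assert (hit.left_seq, hit.length, hit.edits) == (t, 16, 0)

    def test_published_single_edit_14bp(self):
        # left atcctctacagtc / right atcctctaGcagtc: one insertion
        hit = sa.find_tsd("GGCCGGTTAACCAATT" + "ATCCTCTACAGTC", "ATCCTCTAGCAGTC" + "AACCGGTT")
        assert hit is not None
        assert (hit.length, hit.edits) == (14, 1)
        assert hit.left_seq == "ATCCTCTACAGTC"
        assert hit.right_seq == "ATCCTCTAGCAGTC"

    def test_absent_tsd_is_none(self, rng):
        misses = 0
        for _ in range(30):
            if sa.find_tsd(random_seq(rng, 50), random_seq(rng, 50), min_len=8, max_edits=0) is None:
                misses += 1
        assert misses >= 29  # random flanks essentially never share a perfect 8+ bp repeat

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(25):
            lf, rf = random_seq(rng, 40), random_seq(rng, 40)
            # plant a duplication half the time
            if rng.random() < 0.5:
                t = random_seq(rng, int(rng.integers(5, 15)))
                lf, rf = lf[: 40 - len(t)] + t, t + rf[: 40 - len(t)]
            got = sa.find_tsd(lf, rf)
            expect = brute_force_tsd(lf, rf)
            if expect is None:
                assert got is None
            else:
                assert got is not None
                assert (got.left_seq, got.right_seq) == (expect[1], expect[2])

    def test_stable_under_padding_outside_window(self, rng):
        lf, rf = random_seq(rng, 30), random_seq(rng, 30)
        t = "GATTACAGATT"
        lf, rf = lf[:19] + t, t + rf[:19]
        base = sa.find_tsd(lf, rf)
        padded = sa.find_tsd(random_seq(rng, 100) + lf, rf + random_seq(rng, 100))
        assert base == padded

    def test_more_edits_never_shorter(self, rng):
        for _ in range(10):
            lf, rf = random_seq(rng, 40), random_seq(rng, 40)
            t = random_seq(rng, 9)
            lf, rf = lf[:31] + t, t + rf[:31]
            h0 = sa.find_tsd(lf, rf, max_edits=0)
            h1 = sa.find_tsd(lf, rf, max_edits=1)
            if h0 is not None:
                assert h1 is not None and h1.length >= h0.length


def oracle_motif_scan(head, pattern, max_mm):
    sets = {k: v for k, v in sa._IUPAC_SETS.items()}
    out = []
    for i in range(len(head) - len(pattern) + 1):
        mm = sum(1 for j, p in enumerate(pattern) if head[i + j] not in sets[p])
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


class TestPromoterScans:
    def test_planted_type2_boxes(self):
        head = "CCCC" + "TAGCAAAACAAG" + "C" * 29 + "GTTCAAAAC" + "C" * 26
        p = sa.scan_type2_promoter(head)
        assert p.promoter_type == "type2_AB"
        assert [b.name for b in p.boxes] == ["A", "B"]
        assert p.boxes[0].start == 5 and p.spacing_ok

    def test_boxes_in_reverse_order_rejected(self):
        head = "CCCC" + "GTTCAAAAC" + "C" * 29 + "TAGCAAAACAAG" + "C" * 26
        assert sa.scan_type2_promoter(head).promoter_type == "none"

    def test_random_heads_rarely_match_strictly(self, rng):
        n_hits = 0
        for _ in range(50):
            head = random_seq(rng, 80)
            p = sa.scan_type2_promoter(head, max_mismatches=0)
            oracle_a = oracle_motif_scan(head, sa.AnnotConfig.box_a, 0)
            if not oracle_a:
                assert p.promoter_type == "none"
            n_hits += p.promoter_type != "none"
        assert n_hits <= 5

    def test_motif_scan_equals_oracle(self, rng):
        for _ in range(20):
            head = random_seq(rng, 90)
            got = [(b.start, b.mismatches) for b in sa.scan_motif(head, "TRGCNNARYNNG", 2)]
            assert got == oracle_motif_scan(head, "TRGCNNARYNNG", 2)

    def test_planted_type1_boxes(self):
        # exact instances of the default A / IE / C patterns with canonical gaps
        head = "AA" + "TAGCAAAACAAG" + "CC" + "AGATAA" + "CCCC" + "AGGTTTACTTTTTAGTTA" + "AA" * 20
        p = sa.scan_type1_promoter(head)
        assert p.promoter_type == "type1_AIEC"
        assert [b.name for b in p.boxes] == ["A", "IE", "C"]

    def test_type1_missing_c_box(self):
        head = "AA" + "TAGCAAAACAAG" + "CC" + "AGATAA" + "CT" * 30
        assert sa.scan_type1_promoter(head).promoter_type == "none"


class TestClassifyHead:
    def test_exact_reference_copy(self, reference_rnas):
        cls, ident, ref = sa.classify_head(sd.DEFAULT_HEAD, reference_rnas)
        assert (cls, ident, ref) == ("tRNA", 1.0, "trnaGlu_ref")

    def test_mutated_5s_head(self, reference_rnas, rng):
        ref5s = str(reference_rnas[1])
        mutated, _ = sd.mutate_copy(ref5s, 0.2, 0.0, rng)
        cls, ident, ref = sa.classify_head(mutated, reference_rnas)
        assert cls == "5S" and ref == "ref_5S"
        assert ident == pytest.approx(0.8, abs=0.08)

    def test_random_head_is_unknown(self, reference_rnas, rng):
        unknown = 0
        for _ in range(30):
            cls, ident, _ = sa.classify_head(random_seq(rng, 70), reference_rnas)
            unknown += cls == "unknown"
        assert unknown >= 28

    def test_empty_reference_library_rejected(self):
        with pytest.raises(sc.SequenceError):
            sa.classify_head("ACGT" * 20, [])


class TestTailRepeat:
    UPSTREAM = "ACGTGCTAGCTAGGCTAACGGATCGAATCGTTGCACGTAGCTAACGTTAGCAAGTCCGAT"

    def test_perfect_tga_tail(self):
        t = sa.find_tail_repeat(self.UPSTREAM + "TGATGATGATGA")
        assert (t.unit, t.copies, t.purity) == ("TGA", 4.0, 1.0)
        assert t.distance_from_3prime == 0

    def test_imperfect_tail_purity(self):
        t = sa.find_tail_repeat(self.UPSTREAM + "TGATGGTGATGA")
        assert t.unit == "TGA"
        assert t.copies == 4.0
        assert t.purity == pytest.approx(11 / 12)

    def test_non_repetitive_end_is_none(self):
        assert sa.find_tail_repeat("ACGTGCTAGCTAGGCTAACGGATCGAATCG") is None

    def test_poly_a_tail(self):
        t = sa.find_tail_repeat(self.UPSTREAM[:-1] + "C" + "A" * 12)
        assert t.unit == "A" and t.copies >= 12


class TestMotifNear3Prime:
    def test_purine_motif_found(self):
        pos, matched = sa.find_motif_near_3prime("G" * 50 + "ATAAAAACCGG", window=20)
        assert (pos, matched) == (51, "ATAAAAA")

    def test_absent_motif(self):
        assert sa.find_motif_near_3prime("GC" * 40, window=20) is None

    def test_agrees_with_regex_oracle(self, rng):
        import re

        for _ in range(100):
            s = random_seq(rng, 120)
            got = sa.find_motif_near_3prime(s, "ATAAAAA", window=60)
            window_start = len(s) - 60
            m = re.search("ATAAAAA", s[window_start:])
            if m is None:
                assert got is None
            else:
                assert got == (window_start + m.start() + 1, "ATAAAAA")


class TestTruncation:
    def test_identical_copy_full_length(self, family_consensus):
        assert sa.classify_truncation(family_consensus, family_consensus) == ("full_length", 0)

    def test_half_deleted_copy(self, family_consensus):
        cons = str(family_consensus)
        status, missing = sa.classify_truncation(cons[200:], family_consensus)
        assert status == "five_prime_truncated"
        assert missing == pytest.approx(200, abs=10)

    def test_scattered_substitutions_still_full_length(self, family_consensus, rng):
        cons = list(str(family_consensus))
        for i in rng.choice(len(cons), size=5, replace=False):
            cons[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cons[i]]
        assert sa.classify_truncation("".join(cons), family_consensus)[0] == "full_length"


class TestAnnotateElement:
    def test_planted_copy_fully_annotated(self, family_consensus, reference_rnas, rng):
        # mirror the generator: mutated core plus a pristine appended tail
        cons = str(family_consensus)
        copy, _ = sd.mutate_copy(cons[:-15], 0.05, 0.0, rng)
        copy += "TGA" * 5
        tsd = "GATTACAGAT"
        left = NucSequence("l", random_seq(rng, 60) + tsd)
        right = NucSequence("r", tsd + random_seq(rng, 60))
        ann = sa.annotate_element(
            NucSequence("copy1", copy), left, right, family_consensus, reference_rnas
        )
        assert ann.truncation == "full_length"
        assert ann.tsd is not None and ann.tsd.left_seq == tsd
        assert ann.head_class == "tRNA"
        assert ann.tail is not None
        assert ann.tail.unit in ("TGA", "GAT", "ATG")  # rotation depends on run phase

    def test_no_tsd_leaves_other_fields(self, family_consensus, reference_rnas, rng):
        ann = sa.annotate_element(
            NucSequence("c", str(family_consensus)),
            NucSequence("l", random_seq(rng, 60)),
            NucSequence("r", random_seq(rng, 60)),
            family_consensus,
            reference_rnas,
        )
        # at most a weak chance repeat, never a confident planted-quality TSD
        assert ann.tsd is None or (ann.tsd.length - 3 * ann.tsd.edits) < 8
        assert ann.head_class == "tRNA"

    def test_truncated_copy_has_no_promoter(self, family_consensus, reference_rnas, rng):
        cons = str(family_consensus)
        ann = sa.annotate_element(
            NucSequence("t", cons[250:]),
            NucSequence("l", random_seq(rng, 60)),
            NucSequence("r", random_seq(rng, 60)),
            family_consensus,
            reference_rnas,
        )
        assert ann.truncation == "five_prime_truncated"
        assert ann.promoter.promoter_type == "none"
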