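import math
import random

import pytest

from isomirpipe.annotation import load_catalog
from isomirpipe.calling import (
    AlignedRead, assign_read, count_sam, filter_read, format_notation,
    group_endpoints, mismatch_budget, parse_notation,
)
from conftest import (
    EXPECTED_HAND_GROUPS, make_genome, sam_line, write_toy_annotation,
)


def _read(length=22, mism=0, indel=False, unique=True, start=100, strand="+"):
    return AlignedRead("chrT", strand, start, start + length, length,
                       mismatches=mism, has_indel=indel, is_unique=unique)


class TestFilterRead:
    @pytest.mark.parametrize("length,mism,indel,unique,keep,reason", [
        (15, 0, False, True, False, "too_short"),
        (16, 0, False, True, True, None),
        (22, 0, False, True, True, None),
        (22, 0, False, False, False, "multimapped"),
        (22, 0, True, True, False, "indel"),
        (22, 1, False, True, False, "mismatch_rate"),   # floor(0.88) = 0
        (25, 1, False, True, True, None),               # floor(1.0) = 1
        (50, 2, False, True, True, None),
        (50, 3, False, True, False, "mismatch_rate"),
    ])
    def test_filter_rules(self, length, mism, indel, unique, keep, reason):
        got_keep, got_reason = filter_read(_read(length, mism, indel, unique))
        assert (got_keep, got_reason) == (keep, reason)

    def test_mismatch_budget_is_floor_of_rate(self):
        # oracle: direct evaluation of floor(0.04 L)
        for L in range(16, 31):
            assert mismatch_budget(L) == math.floor(0.04 * L)
            r = _read(L, mism=mismatch_budget(L))
            assert filter_read(r)[0]
            r = _read(L, mism=mismatch_budget(L) + 1)
            assert filter_read(r) == (False, "mismatch_rate")

    def test_missing_uniqueness_evidence_modes(self):
        r = _read(unique=None)
        assert filter_read(r, unique_mode="strict") == (False, "multimapped")
        assert filter_read(r, unique_mode="lenient")[0]


class TestAssignment:
    def test_exact_mature_read_assigned_with_zero_offsets(self, toy_catalog):
        arm_id, status = assign_read(_read(22, start=100), toy_catalog)
        assert (arm_id, status) == ("toy-mir-1-5p", "assigned")

    def test_read_past_window_end_unassigned(self, toy_catalog):
        # toy-mir-2-3p window is [194, 228); a read ending at 229 leaks out
        r = _read(30, start=199, strand="-")
        assert assign_read(r, toy_catalog) == (None, "unassigned")

    def test_read_in_two_overlapping_windows_is_ambiguous(self, toy_catalog):
        r = _read(16, start=112)
        arm_id, status = assign_read(r, toy_catalog)
        assert (arm_id, status) == (None, "ambiguous")
        # oracle: exhaustive scan finds two containing windows
        hits = toy_catalog.windows_containing("chrT", "+", 112, 128)
        assert len(hits) == 2

    def test_wrong_strand_not_assigned(self, toy_catalog):
        r = _read(22, start=100, strand="-")
        assert assign_read(r, toy_catalog) == (None, "unassigned")


class TestGroupEndpoints:
    def test_same_endpoints_merge_despite_mismatches(self, toy_catalog):
        reads = [(_read(22, start=100, mism=0), "toy-mir-1-5p"),
                 (_read(22, start=100, mism=1), "toy-mir-1-5p")]
        groups = group_endpoints(reads, toy_catalog)
        assert groups == {"toy-mir-1-5p": {(0, 0): 2}}

    def test_plus_strand_offsets(self, toy_catalog):
        r = AlignedRead("chrT", "+", 99, 124, 25)
        groups = group_endpoints([(r, "toy-mir-1-5p")], toy_catalog)
        assert list(groups["toy-mir-1-5p"]) == [(-1, 2)]

    def test_minus_strand_offsets_via_independent_flip_oracle(self, toy_catalog):
        # independent oracle: flip to mature-strand coordinates by hand
        arm = toy_catalog["toy-mir-2-3p"].arm  # [200, 222) on '-'
        for (s, e) in [(200, 223), (198, 222), (201, 221)]:
            r = AlignedRead("chrT", "-", s, e, e - s)
            groups = group_endpoints([(r, "toy-mir-2-3p")], toy_catalog)
            (got,) = groups["toy-mir-2-3p"]
            # on the minus strand the genomic end is the 5' terminus
            exp5 = arm.end - e
            exp3 = arm.start - s
            assert got == (exp5, exp3)
        # spec of the convention: genomic end one past mature end -> off5 = -1
        r = AlignedRead("chrT", "-", 200, 223, 23)
        (got,) = group_endpoints([(r, "toy-mir-2-3p")], toy_catalog)["toy-mir-2-3p"]
        assert got == (-1, 0)


class TestNotation:
    def test_paper_style_example(self):
        assert format_notation(-1, 2) == "[5´end-1][3´end+2]"

    def test_zero_offsets_have_explicit_plus_zero(self):
        assert format_notation(0, 0) == "[5´end+0][3´end+0]"

    @pytest.mark.parametrize("off5", range(-6, 7))
    @pytest.mark.parametrize("off3", [-6, -1, 0, 1, 6])
    def test_round_trip(self, off5, off3):
        assert parse_notation(format_notation(off5, off3), flank=6) == (off5, off3)

    def test_en_dash_and_minus_accepted(self):
        assert parse_notation("[5´end–1][3´end+2]") == (-1, 2)
        assert parse_notation("[5´end−1][3´end+2]") == (-1, 2)

    def test_out_of_window_offset_rejected(self):
        with pytest.raises(ValueError, match="window"):
            parse_notation("[5´end-7][3´end+0]", flank=6)

    def test_malformed_string_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_notation("[5end-1][3´end+2]")


class TestCountSam:
    def test_hand_built_fixture_matches_hand_enumeration(
            self, hand_built_sam, toy_catalog):
        counts, tally = count_sam(hand_built_sam, toy_catalog)
        got = {arm: dict(c) for arm, c in counts.items()}
        assert got == EXPECTED_HAND_GROUPS
        assert tally.total == 12
        assert tally.assigned == 6
        assert dict(tally.rejected) == {"too_short": 1, "multimapped": 1,
                                        "indel": 1, "mismatch_rate": 1}
        assert tally.unassigned == 1
        assert tally.ambiguous == 1
        assert tally.check_conservation()

    def test_count_conservation_per_arm(self, hand_built_sam, toy_catalog):
        counts, tally = count_sam(hand_built_sam, toy_catalog)
        assert sum(sum(c.values()) for c in counts.values()) == tally.assigned

    def test_order_independence(self, tmp_path, hand_built_sam, toy_catalog):
        lines = hand_built_sam.read_text().splitlines(keepends=True)
        header, body = lines[:2], lines[2:]
        random.Random(5).shuffle(body)
        shuffled = tmp_path / "shuffled.sam"
        shuffled.write_text("".join(header + body))
        c1, t1 = count_sam(hand_built_sam, toy_catalog)
        c2, t2 = count_sam(shuffled, toy_catalog)
        assert c1 == c2 and dict(t1.rejected) == dict(t2.rejected)

    def test_strand_symmetry(self, tmp_path):
        """Reverse-complementing the genome and flipping all coordinates
        leaves every (off5, off3) count unchanged."""
        L = 400
        genome = make_genome(L, seed=9)
        from isomirpipe.annotation import reverse_complement
        flipped_genome = reverse_complement(genome)

        arms = [("armP", 100, 122, "+"), ("armM", 200, 222, "-")]
        arms_flipped = [(n, L - e, L - s, "-" if st == "+" else "+")
                        for n, s, e, st in arms]
        d1 = tmp_path / "fwd"; d1.mkdir()
        d2 = tmp_path / "rev"; d2.mkdir()
        gff1, fa1 = write_toy_annotation(d1, genome, arms)
        gff2, fa2 = write_toy_annotation(d2, flipped_genome, arms_flipped)
        cat1 = load_catalog(gff1, fa1)
        cat2 = load_catalog(gff2, fa2)

        reads = [(99, 124, "+"), (100, 122, "+"), (199, 223, "-"), (202, 220, "-")]
        header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrT\tLN:{L}\n"
        fwd, rev = [], []
        for i, (s, e, st) in enumerate(reads):
            seq = genome[s:e] if st == "+" else reverse_complement(genome[s:e])
            fwd.append(sam_line(f"r{i}", 0 if st == "+" else 16, s,
                                f"{e - s}M", seq))
            fs, fe = L - e, L - s
            fst = "-" if st == "+" else "+"
            fseq = flipped_genome[fs:fe] if fst == "+" else \
                reverse_complement(flipped_genome[fs:fe])
            rev.append(sam_line(f"r{i}", 0 if fst == "+" else 16, fs,
                                f"{fe - fs}M", fseq))
        p1 = d1 / "fwd.sam"; p1.write_text(header + "".join(fwd))
        p2 = d2 / "rev.sam"; p2.write_text(header + "".join(rev))
        c1, _ = count_sam(p1, cat1)
        c2, _ = count_sam(p2, cat2)
        assert {a: dict(c) for a, c in c1.items()} == \
            {a: dict(c) for a, c in c2.items()}
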