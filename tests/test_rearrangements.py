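import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliconlens.rearrangements import (
    DELETION_TYPE,
    DUPLICATION_TYPE,
    HEAD_TO_HEAD,
    INTERCHROMOSOMAL,
    INTRAGENIC,
    OUTSIDE,
    TAIL_TO_TAIL,
    UPSTREAM_WINDOW,
    Breakend,
    FoldBack,
    Junction,
    assign_fgfr1_window,
    call_nsd3_disruption,
    classify_junction,
    detect_foldbacks,
    read_bedpe,
    read_vcf_bnd,
    write_junction_tsv,
)


def J(pos_a, side_a, pos_b, side_b, chrom_a="chr8", chrom_b="chr8", support=10):
    return Junction(
        Breakend(chrom_a, pos_a, side_a),
        Breakend(chrom_b, pos_b, side_b),
        support=support,
    )


class TestClassifyJunction:
    def test_both_left_is_tail_to_tail(self):
        assert classify_junction(J(100, "left", 500, "left")) == TAIL_TO_TAIL

    def test_s00674_style_pair_both_right_is_head_to_head(self):
        j = J(36_417_297, "right", 36_418_017, "right")
        assert classify_junction(j) == HEAD_TO_HEAD
        assert j.span == 720

    def test_interchromosomal(self):
        j = J(100, "left", 500, "right", chrom_b="chr9")
        assert classify_junction(j) == INTERCHROMOSOMAL

    def test_left_right_is_deletion(self):
        assert classify_junction(J(100, "left", 500, "right")) == DELETION_TYPE

    def test_right_left_is_duplication(self):
        assert classify_junction(J(100, "right", 500, "left")) == DUPLICATION_TYPE

    @settings(max_examples=50, deadline=None)
    @given(
        pa=st.integers(0, 10**6),
        pb=st.integers(0, 10**6),
        sa=st.sampled_from(["left", "right"]),
        sb=st.sampled_from(["left", "right"]),
    )
    def test_invariant_under_breakend_swap(self, pa, pb, sa, sb):
        j1 = Junction(Breakend("chr8", pa, sa), Breakend("chr8", pb, sb))
        j2 = Junction(Breakend("chr8", pb, sb), Breakend("chr8", pa, sa))
        assert classify_junction(j1) == classify_junction(j2)
        assert (j1.a, j1.b) == (j2.a, j2.b)


class TestDetectFoldbacks:
    def test_close_head_to_head_detected(self):
        j = J(36_417_297, "right", 36_418_017, "right")
        (fb,) = detect_foldbacks([j])
        assert fb.span == 720

    def test_distant_tail_to_tail_not_a_foldback(self):
        j = J(1_000_000, "left", 6_000_000, "left")
        assert detect_foldbacks([j]) == []

    def test_matches_brute_force_filter(self):
        import random

        rnd = random.Random(7)
        juncs = []
        for _ in range(200):
            chrom_b = rnd.choice(["chr8", "chr9"])
            juncs.append(
                J(
                    rnd.randrange(0, 2_000_000),
                    rnd.choice(["left", "right"]),
                    rnd.randrange(0, 2_000_000),
                    rnd.choice(["left", "right"]),
                    chrom_b=chrom_b,
                )
            )
        expected = [
            j
            for j in juncs
            if j.a.chrom == j.b.chrom
            and j.a.retained_side == j.b.retained_side
            and abs(j.a.pos - j.b.pos) <= 100_000
        ]
        got = [fb.junction for fb in detect_foldbacks(juncs)]
        assert got == expected

    def test_foldback_type_rejects_non_inverted(self):
        with pytest.raises(ValueError):
            FoldBack(J(100, "left", 500, "right"))


class TestReadBedpe:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    def test_strand_mapping(self, tmp_path):
        p = tmp_path / "j.bedpe"
        self._write(p, [
            ("chr8", 100, 101, "chr8", 500, 501, "tt", 12, "+", "+"),
            ("chr8", 100, 101, "chr8", 500, 501, "hh", 5, "-", "-"),
            ("chr8", 100, 101, "chr8", 500, 501, "del", 3, "+", "-"),
        ])
        tt, hh, dl = read_bedpe(p)
        assert classify_junction(tt) == TAIL_TO_TAIL
        assert classify_junction(hh) == HEAD_TO_HEAD
        assert classify_junction(dl) == DELETION_TYPE
        assert tt.support == 12

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        self._write(p, [("chr8", 100, 101, "chr8", 500, 501, "x", 1, "+")])
        with pytest.raises(ValueError, match="10 columns"):
            read_bedpe(p)

    def test_negative_coordinates(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        self._write(p, [("chr8", -5, 101, "chr8", 500, 501, "x", 1, "+", "+")])
        with pytest.raises(ValueError, match="negative"):
            read_bedpe(p)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr8,length=146364022>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestReadVcfBnd:
    def _write(self, path, body):
        path.write_text(VCF_HEADER + body)

    def test_tail_to_tail_bracket_decoding(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write(
            p,
            "chr8\t101\tb1\tN\tN]chr8:501]\t.\t.\tSVTYPE=BND;MATEID=b2\n"
            "chr8\t501\tb2\tN\tN]chr8:101]\t.\t.\tSVTYPE=BND;MATEID=b1\n",
        )
        (j,) = read_vcf_bnd(p)
        assert classify_junction(j) == TAIL_TO_TAIL
        assert (j.a.pos, j.b.pos) == (100, 500)

    def test_head_to_head_bracket_decoding(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write(
            p,
            "chr8\t101\tb1\tN\t[chr8:501[N\t.\t.\tSVTYPE=BND;MATEID=b2\n"
            "chr8\t501\tb2\tN\t[chr8:101[N\t.\t.\tSVTYPE=BND;MATEID=b1\n",
        )
        (j,) = read_vcf_bnd(p)
        assert classify_junction(j) == HEAD_TO_HEAD

    def test_three_mated_pairs_match_hand_decoded_table(self, tmp_path):
        # hand decoding: t]p] -> (left,left); [p[t -> (right,right);
        # t[p[ -> (left,right); ]p]t -> (right,left)
        p = tmp_path / "a.vcf"
        self._write(
            p,
            "chr8\t101\tm1a\tN\tN]chr8:901]\t.\t.\tSVTYPE=BND;MATEID=m1b;SUPPORT=9\n"
            "chr8\t901\tm1b\tN\tN]chr8:101]\t.\t.\tSVTYPE=BND;MATEID=m1a;SUPPORT=9\n"
            "chr8\t201\tm2a\tN\tN[chr8:801[\t.\t.\tSVTYPE=BND;MATEID=m2b\n"
            "chr8\t801\tm2b\tN\t]chr8:201]N\t.\t.\tSVTYPE=BND;MATEID=m2a\n"
            "chr8\t301\tm3a\tN\t[chr8:701[N\t.\t.\tSVTYPE=BND;MATEID=m3b\n"
            "chr8\t701\tm3b\tN\t[chr8:301[N\t.\t.\tSVTYPE=BND;MATEID=m3a\n",
        )
        js = read_vcf_bnd(p)
        assert len(js) == 3
        expected = {
            (100, "left", 900, "left"),
            (200, "left", 800, "right"),
            (300, "right", 700, "right"),
        }
        got = {
            (j.a.pos, j.a.retained_side, j.b.pos, j.b.retained_side) for j in js
        }
        assert got == expected

    def test_unmatched_mate_warns_and_skips(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write(
            p,
            "chr8\t101\tb1\tN\tN]chr8:501]\t.\t.\tSVTYPE=BND;MATEID=nope\n",
        )
        with pytest.warns(UserWarning, match="unmatched MATEID"):
            js = read_vcf_bnd(p)
        assert js == []


class TestFgfr1Window:
    def test_h1581_coordinate_in_upstream_window(self, fgfr1):
        j = J(38_595_657, "left", 38_650_000, "left")
        assert assign_fgfr1_window(j, fgfr1) == UPSTREAM_WINDOW

    def test_breakend_inside_orf_is_intragenic(self, fgfr1):
        span = fgfr1.transcript.span
        j = J((span.start + span.end) // 2, "left", 38_650_000, "left")
        assert assign_fgfr1_window(j, fgfr1) == INTRAGENIC

    def test_one_mb_upstream_is_outside(self, fgfr1):
        j = J(fgfr1.tss + 1_000_000, "left", fgfr1.tss + 1_100_000, "left")
        assert assign_fgfr1_window(j, fgfr1) == OUTSIDE

    def test_window_boundary_half_open(self, fgfr1):
        tss = fgfr1.tss
        at_tss = J(tss, "left", tss + 900_000, "left")
        assert assign_fgfr1_window(at_tss, fgfr1) == INTRAGENIC  # gene body
        at_limit = J(tss + 400_000, "left", tss + 900_000, "left")
        assert assign_fgfr1_window(at_limit, fgfr1) == UPSTREAM_WINDOW
        past_limit = J(tss + 400_001, "left", tss + 900_000, "left")
        assert assign_fgfr1_window(past_limit, fgfr1) == OUTSIDE

    @settings(max_examples=100, deadline=None)
    @given(pos=st.integers(38_000_000, 39_000_000))
    def test_partition_exhaustive_and_exclusive(self, pos, fgfr1):
        j = J(pos, "left", pos + 1, "left")
        assert assign_fgfr1_window(j, fgfr1) in (
            INTRAGENIC,
            UPSTREAM_WINDOW,
            OUTSIDE,
        )


class TestNsd3Disruption:
    def test_deletion_of_set_exons_disrupts(self, nsd3):
        tr = nsd3.transcript
        i15_16 = (tr.exons[14].end + tr.exons[15].start) // 2
        j = J(i15_16, "left", tr.span.end + 5_000, "right")
        ev = call_nsd3_disruption([j], nsd3)
        assert ev.disrupted
        assert ev.affected_exons == (16, 24)
        assert ev.junctions == [j]

    def test_out_of_frame_fusion_at_exon_15_disrupts(self, nsd3):
        tr = nsd3.transcript
        e15 = tr.exons[14]
        j = J((e15.start + e15.end) // 2, "left", 41_510_000, "left")
        ev = call_nsd3_disruption([j], nsd3)
        assert ev.disrupted

    def test_downstream_junction_leaves_intact(self, nsd3):
        tr = nsd3.transcript
        j = J(tr.span.end + 50_000, "left", tr.span.end + 90_000, "left")
        ev = call_nsd3_disruption([j], nsd3)
        assert not ev.disrupted

    def test_break_after_set_exons_is_intact(self, nsd3):
        tr = nsd3.transcript
        # breakend in the last intron, 3' of the SET-encoding exons
        i23_24 = (tr.exons[22].end + tr.exons[23].start) // 2
        j = J(i23_24, "left", tr.span.end + 9_000, "right")
        assert not call_nsd3_disruption([j], nsd3).disrupted


class TestJunctionTsv:
    def test_annotated_output(self, tmp_path, fgfr1):
        p = tmp_path / "out.tsv"
        js = [
            J(38_595_657, "left", 38_650_000, "left", support=40),
            J(100, "right", 820, "right", support=1),
        ]
        write_junction_tsv(js, fgfr1, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("name\t")
        assert len(lines) == 3
        first = lines[1].split("\t")
        assert first[8] == TAIL_TO_TAIL
        assert first[10] == UPSTREAM_WINDOW
        second = lines[2].split("\t")
        assert second[9] == "true"  # span 720 fold-back
        assert second[11] == "true"  # support 1 < min_support
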