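"""Cutsite arithmetic, window read selection, union consensus, edit calls."""

import numpy as np
import pytest

from grnavar import (
    call_editing,
    compute_cutsite,
    detect_editing,
    load_exon_index,
    union_consensus,
    window_reads,
)
from grnavar.editing import EditingError, WindowRead

from conftest import make_bam


class TestComputeCutsite:
    def test_plus_strand_arithmetic(self):
        w = compute_cutsite("g1", "GENE1", "chr1", 1000, "+")
        assert w.cutsite == 997
        assert (w.window_start, w.window_end) == (972, 1023)
        assert w.width == 51

    def test_minus_strand_mirrors(self):
        w = compute_cutsite("g1", "GENE1", "chr1", 1000, "-")
        assert w.cutsite == 1003
        assert (w.window_start, w.window_end) == (978, 1029)

    def test_even_window_rejected(self):
        with pytest.raises(EditingError, match="odd"):
            compute_cutsite("g1", "GENE1", "chr1", 1000, "+", window=50)

    def test_bad_strand_rejected(self):
        with pytest.raises(EditingError, match="strand"):
            compute_cutsite("g1", "GENE1", "chr1", 1000, ".")


def _window(cutsite=100):
    half = 25
    return compute_cutsite("g1", "GENE1", "chrT", cutsite + 3, "+")


def _ref(rng, length=300):
    return "".join(rng.choice(list("ACGT"), size=length))


def _wread(ref, start, length=40, cigar=None, seq=None, cb="c1", umi="u1"):
    seq = seq if seq is not None else ref[start : start + length]
    cigar = cigar or ((0, len(seq)),)
    return WindowRead(cb, umi, start, cigar, seq)


class TestUnionConsensus:
    def test_two_reads_tile_the_whole_window(self):
        rng = np.random.default_rng(0)
        ref = _ref(rng)
        w = _window(100)
        ref_win = ref[w.window_start : w.window_end]
        left = _wread(ref, w.window_start - 5, length=30)
        right = _wread(ref, w.window_start + 20, length=40)
        union = union_consensus([left, right], w, ref_win)
        assert set(union) == set(range(w.window_start, w.window_end))

    def test_single_read_union_is_that_read(self):
        rng = np.random.default_rng(1)
        ref = _ref(rng)
        w = _window(100)
        read = _wread(ref, w.window_start + 3, length=10)
        union = union_consensus([read], w, ref[w.window_start : w.window_end])
        assert set(union) == set(range(w.window_start + 3, w.window_start + 13))

    def test_deletion_covered_by_one_of_two_reads_is_kept(self):
        rng = np.random.default_rng(2)
        ref = _ref(rng)
        w = _window(100)
        dstart = w.cutsite - 2
        seq = ref[dstart - 10 : dstart] + ref[dstart + 6 : dstart + 16]
        del_read = _wread(ref, dstart - 10, cigar=((0, 10), (2, 6), (0, 10)), seq=seq)
        other = _wread(ref, w.window_start, length=20)
        union = union_consensus([del_read, other], w, ref[w.window_start : w.window_end])
        assert all(union[p] == "D" for p in range(dstart, dstart + 6))

    def test_conflict_tie_resolves_to_reference_match(self):
        rng = np.random.default_rng(3)
        ref = _ref(rng)
        w = _window(100)
        p = w.cutsite
        good = _wread(ref, p - 5, length=10)
        bad_seq = list(ref[p - 5 : p + 5])
        bad_seq[5] = "A" if ref[p] != "A" else "C"
        bad = _wread(ref, p - 5, seq="".join(bad_seq))
        union = union_consensus([good, bad], w, ref[w.window_start : w.window_end])
        assert union[p] == ref[p]

    def test_reads_outside_window_do_not_contribute(self):
        rng = np.random.default_rng(4)
        ref = _ref(rng)
        w = _window(100)
        outside = _wread(ref, w.window_end + 10, length=20)
        union = union_consensus([outside], w, ref[w.window_start : w.window_end])
        assert union == {}

    def test_wrong_reference_length_rejected(self):
        w = _window(100)
        with pytest.raises(EditingError):
            union_consensus([], w, "ACGT")


class TestCallEditing:
    def _setup(self, seed=5):
        rng = np.random.default_rng(seed)
        ref = _ref(rng)
        w = _window(100)
        return ref, w, ref[w.window_start : w.window_end]

    def test_deletion_across_cutsite_is_cas9(self):
        ref, w, ref_win = self._setup()
        dstart = w.cutsite - 2
        seq = ref[dstart - 10 : dstart] + ref[dstart + 5 : dstart + 15]
        read = _wread(ref, dstart - 10, cigar=((0, 10), (2, 5), (0, 10)), seq=seq)
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "cutsite_deletion"
        assert "D:" in call.events

    def test_offsite_indel_reported_but_not_cas9(self):
        ref, w, ref_win = self._setup()
        dstart = w.cutsite + 10
        seq = ref[dstart - 10 : dstart] + ref[dstart + 3 : dstart + 13]
        read = _wread(ref, dstart - 10, cigar=((0, 10), (2, 3), (0, 10)), seq=seq)
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "other_indel"
        assert call.events != "none"

    def test_insertion_elsewhere_is_other_indel(self):
        ref, w, ref_win = self._setup()
        p = w.cutsite - 10
        seq = ref[p - 5 : p] + "GGG" + ref[p : p + 5]
        read = _wread(ref, p - 5, cigar=((0, 5), (1, 3), (0, 5)), seq=seq)
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "other_indel"

    def test_perfect_match_is_unedited(self):
        ref, w, ref_win = self._setup()
        read = _wread(ref, w.window_start, length=w.width)
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "unedited" and call.events == "none"

    def test_mismatch_only(self):
        ref, w, ref_win = self._setup()
        p = w.cutsite - 7
        seq = list(ref[p - 5 : p + 5])
        seq[5] = "A" if ref[p] != "A" else "C"
        read = _wread(ref, p - 5, seq="".join(seq))
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "mismatch_only"

    def test_splice_gap_is_never_a_deletion(self):
        ref, w, ref_win = self._setup()
        start = w.cutsite - 10
        seq = ref[start : start + 8] + ref[start + 28 : start + 38]
        read = _wread(ref, start, cigar=((0, 8), (3, 20), (0, 10)), seq=seq)
        call = call_editing(union_consensus([read], w, ref_win), w, ref_win)
        assert call.klass == "unedited"


class TestWindowReads:
    def _gtf(self, tmp_path):
        lines = []
        for gene, (s, e) in {"GENE1": (50, 200), "GENE2": (180, 400)}.items():
            attrs = f'gene_id "{gene}"; gene_name "{gene}";'
            for feat in ("gene", "exon"):
                lines.append(
                    "\t".join(["chrT", "t", feat, str(s + 1), str(e), ".", "+", ".", attrs])
                )
        p = tmp_path / "genes.gtf"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_gene_assignment_and_window_overlap(self, tmp_path):
        rng = np.random.default_rng(6)
        ref = _ref(rng, 500)
        w = _window(100)  # window [75,126) inside GENE1 only
        gtf = self._gtf(tmp_path)
        reads = [
            {"name": "in_gene", "contig": "chrT", "pos": 80, "cigar": [(0, 40)],
             "seq": ref[80:120], "tags": {"CB": "c1-1", "UB": "u1"}},
            {"name": "ambiguous", "contig": "chrT", "pos": 100, "cigar": [(0, 100)],
             "seq": ref[100:200], "tags": {"CB": "c1-1", "UB": "u2"}},
            {"name": "no_tags", "contig": "chrT", "pos": 85, "cigar": [(0, 40)],
             "seq": ref[85:125]},
            {"name": "outside", "contig": "chrT", "pos": 300, "cigar": [(0, 40)],
             "seq": ref[300:340], "tags": {"CB": "c1-1", "UB": "u3"}},
        ]
        bam = make_bam(tmp_path / "expr.bam", {"chrT": 500}, reads)
        kept = window_reads(bam, w, load_exon_index(gtf))
        assert [r.umi for r in kept] == ["u1"]

    def test_detect_editing_end_to_end(self, tmp_path):
        rng = np.random.default_rng(7)
        ref = _ref(rng, 500)
        w = _window(100)
        gtf = self._gtf(tmp_path)
        dstart = w.cutsite - 2
        del_seq = ref[dstart - 10 : dstart] + ref[dstart + 6 : dstart + 16]
        reads = [
            {"name": "edited", "contig": "chrT", "pos": dstart - 10,
             "cigar": [(0, 10), (2, 6), (0, 10)], "seq": del_seq,
             "tags": {"CB": "c1-1", "UB": "u1"}},
            {"name": "clean", "contig": "chrT", "pos": 80, "cigar": [(0, 40)],
             "seq": ref[80:120], "tags": {"CB": "c2-1", "UB": "u2"}},
        ]
        bam = make_bam(tmp_path / "expr.bam", {"chrT": 500}, reads)
        calls = detect_editing(bam, [w], load_exon_index(gtf), {"chrT": ref})
        byumi = calls.set_index("umi").klass.to_dict()
        assert byumi == {"u1": "cutsite_deletion", "u2": "unedited"}
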