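import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pregbs.io import SequenceRecord
from pregbs.motif import (
    GR_MOTIF_PATTERN,
    IUPAC_SETS,
    compile_motif,
    reverse_complement,
    scan_genome,
    scan_sequence,
)

# The two strands printed for the binding assays: the modern GBS duplex
# carries one motif match, the CpG-retaining pre-GBS duplex carries none.
GBS_ASSAY_STRAND = "TGAGAACAGAGTGTTCTTT"
PRE_GBS_ASSAY_STRAND = "CCAGAACGGAGCGTTCTGA"


def naive_scan(motif, sequence: str) -> set[tuple[int, int]]:
    """Independent window-by-window checker over both strands."""
    seq = sequence.upper()
    rc_pattern = reverse_complement(motif.pattern)
    hits = set()
    for pattern in (motif.pattern.upper(), rc_pattern):
        for start in range(len(seq) - len(pattern) + 1):
            window = seq[start : start + len(pattern)]
            if all(
                w in IUPAC_SETS[p] and w in "ACGT"
                for w, p in zip(window, pattern)
            ):
                hits.add((start, start + len(pattern)))
    return hits


class TestCompile:
    def test_gr_motif_partition(self, gr_motif):
        assert gr_motif.length == 13
        assert gr_motif.wildcard_positions == frozenset({2, 6, 7, 8, 12})
        assert {p: "".join(sorted(s)) for p, s in gr_motif.fixed_positions.items()} == {
            1: "G", 3: "A", 4: "C", 5: "A", 9: "T", 10: "G", 11: "T", 13: "C"
        }

    def test_no_wildcards(self):
        motif = compile_motif("ACGT")
        assert motif.length == 4 and not motif.wildcard_positions

    def test_illegal_code_named(self):
        with pytest.raises(ValueError, match="'Z'"):
            compile_motif("GnACZ")

    def test_empty_pattern(self):
        with pytest.raises(ValueError):
            compile_motif("")


class TestReverseComplement:
    def test_gr_motif_is_palindromic(self, gr_motif):
        assert reverse_complement(GR_MOTIF_PATTERN) == GR_MOTIF_PATTERN.upper()
        assert gr_motif.is_palindromic

    @pytest.mark.parametrize("seq,expected", [("A", "T"), ("", ""), ("acgt", "ACGT")])
    def test_simple(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_illegal_character(self):
        with pytest.raises(ValueError):
            reverse_complement("AXT")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestScan:
    def test_printed_gbs_strand_single_hit(self, gr_motif):
        occ = scan_sequence(gr_motif, SequenceRecord("assay", GBS_ASSAY_STRAND))
        assert [(o.interval.start, o.interval.end) for o in occ] == [(3, 16)]
        assert occ[0].matched_seq == "GAACAGAGTGTTC"

    def test_printed_pre_gbs_strand_no_hit(self, gr_motif):
        assert scan_sequence(gr_motif, SequenceRecord("assay", PRE_GBS_ASSAY_STRAND)) == []

    def test_empty_sequence(self, gr_motif):
        assert scan_sequence(gr_motif, SequenceRecord("e", "")) == []

    def test_window_with_n_never_matches(self, gr_motif):
        seq = GBS_ASSAY_STRAND[:3] + "GAACAGAGNGTTC" + GBS_ASSAY_STRAND[16:]
        assert scan_sequence(gr_motif, SequenceRecord("n", seq)) == []

    def test_soft_masked_lowercase_matches(self, gr_motif):
        occ = scan_sequence(gr_motif, SequenceRecord("lc", GBS_ASSAY_STRAND.lower()))
        assert len(occ) == 1

    def test_palindromic_dedup_single_interval(self, gr_motif):
        """The palindromic motif matches both strands but is reported once."""
        occ = scan_sequence(gr_motif, SequenceRecord("assay", GBS_ASSAY_STRAND))
        assert len(occ) == 1 and occ[0].interval.strand == "+"

    def test_reverse_strand_hit_mapped_to_forward(self):
        motif = compile_motif("GGGACT")  # not palindromic
        seq = "TT" + reverse_complement("GGGACT") + "AA"
        occ = scan_sequence(motif, SequenceRecord("m", seq))
        assert [(o.interval.start, o.interval.strand) for o in occ] == [(2, "-")]
        assert occ[0].matched_seq == "AGTCCC"

    def test_matched_seq_rematches_motif(self, gr_motif, random_sequence):
        rec = random_sequence(20_000, seed=3)
        for occ in scan_sequence(gr_motif, rec):
            assert gr_motif.matches(occ.matched_seq) or gr_motif.matches(
                reverse_complement(occ.matched_seq)
            )

    def test_oracle_equivalence_random_motifs(self, random_sequence):
        rng = np.random.default_rng(11)
        rec = random_sequence(5_000, seed=4, alphabet="ACGTN")
        for _ in range(20):
            pattern = "".join(
                rng.choice(list("ACGTN"), p=[0.2, 0.2, 0.2, 0.2, 0.2], size=8)
            )
            motif = compile_motif(pattern)
            got = {(o.interval.start, o.interval.end) for o in scan_sequence(motif, rec)}
            assert got == naive_scan(motif, rec.sequence)

    def test_palindromic_closure(self, gr_motif, random_sequence):
        """Occurrence intervals are invariant under reverse-complementing the genome."""
        rec = random_sequence(10_000, seed=5)
        fwd = {(o.interval.start, o.interval.end) for o in scan_sequence(gr_motif, rec)}
        rc = SequenceRecord("rc", reverse_complement(rec.sequence))
        n = len(rec.sequence)
        back = {
            (n - o.interval.end, n - o.interval.start)
            for o in scan_sequence(gr_motif, rc)
        }
        assert fwd == back


class TestScanGenome:
    def test_two_contigs(self, gr_motif):
        genome = [
            SequenceRecord("c1", GBS_ASSAY_STRAND),
            SequenceRecord("c2", "T" * 5 + GBS_ASSAY_STRAND),
        ]
        occ = scan_genome(gr_motif, genome)
        assert [(o.interval.chrom, o.interval.start) for o in occ] == [("c1", 3), ("c2", 8)]

    def test_all_n_genome(self, gr_motif):
        assert scan_genome(gr_motif, [SequenceRecord("n", "N" * 100)]) == []

    def test_no_cross_record_windows(self, gr_motif):
        left, right = GBS_ASSAY_STRAND[:9], GBS_ASSAY_STRAND[9:]
        occ = scan_genome(gr_motif, [SequenceRecord("a", left), SequenceRecord("b", right)])
        assert occ == []

    def test_chroms_filter(self, gr_motif):
        genome = [SequenceRecord("c1", GBS_ASSAY_STRAND), SequenceRecord("c2", GBS_ASSAY_STRAND)]
        occ = scan_genome(gr_motif, genome, chroms={"c2"})
        assert {o.interval.chrom for o in occ} == {"c2"}
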