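import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tcrep.annotate import (
    AnnotatedRead,
    annotate_read,
    annotate_reads,
    extract_cdr3,
    filter_by_identity,
    merge_pairs,
    read_rearrangements,
    write_rearrangements,
)
from tcrep.germline import GermlineDB, GermlineSegment
from tcrep.simulate import RepertoireModel, revcomp, simulate_repertoire


def _write_fastq(path, records):
    recs = []
    for rid, seq, quals in records:
        r = SeqRecord(Seq(seq), id=rid, description="")
        r.letter_annotations["phred_quality"] = quals
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


class TestMergePairs:
    def test_exact_overlap_arithmetic(self, tmp_path, rng):
        bases = np.array(list("ACGT"))
        frag = "".join(bases[rng.integers(0, 4, 90)])
        r1 = frag[:60]
        r2 = revcomp(frag[30:])
        _write_fastq(tmp_path / "1.fq", [("p", r1, [40] * 60)])
        _write_fastq(tmp_path / "2.fq", [("p", r2, [40] * 60)])
        merged, report = merge_pairs(tmp_path / "1.fq", tmp_path / "2.fq")
        assert report.merged == 1
        assert len(merged[0].sequence) == 60 + 60 - 30
        assert merged[0].sequence == frag

    def test_unmergeable_pair_dropped_and_counted(self, tmp_path):
        _write_fastq(tmp_path / "1.fq", [("p", "A" * 40, [40] * 40)])
        _write_fastq(tmp_path / "2.fq", [("p", "C" * 40, [40] * 40)])
        merged, report = merge_pairs(
            tmp_path / "1.fq", tmp_path / "2.fq", max_mismatch_rate=0.1
        )
        assert merged == []
        assert report.dropped == 1

    def test_higher_quality_base_wins_at_mismatch(self, tmp_path):
        # overlap of 5 with one mismatch: mate-1 T (q40) vs mate-2 A (q10)
        r1 = "AAAAATTTTT"
        r2c = "TTTTAGGGGG"
        q2c = [10] * 10
        _write_fastq(tmp_path / "1.fq", [("p", r1, [40] * 10)])
        _write_fastq(tmp_path / "2.fq", [("p", revcomp(r2c), q2c[::-1])])
        merged, _ = merge_pairs(
            tmp_path / "1.fq", tmp_path / "2.fq", min_overlap=5, max_mismatch_rate=0.25
        )
        assert merged[0].sequence == "AAAAATTTTTGGGGG"

    def test_length_mismatch_is_pairing_error(self, tmp_path):
        _write_fastq(tmp_path / "1.fq", [("p", "ACGT" * 10, [40] * 40)])
        _write_fastq(
            tmp_path / "2.fq",
            [("p", "ACGT" * 10, [40] * 40), ("q", "ACGT" * 10, [40] * 40)],
        )
        with pytest.raises(ValueError, match="pairing"):
            merge_pairs(tmp_path / "1.fq", tmp_path / "2.fq")


class TestAlignment:
    def test_v_suffix_j_prefix_self_match_is_100_percent(self, toy_db):
        v = toy_db.get("TRBV9*01")
        j = toy_db.get("TRBJ1-2*01")
        read = v.sequence[30:] + j.sequence[:20]
        ann = annotate_read("r", read, toy_db)
        assert ann.v_call == "TRBV9*01"
        assert ann.j_call == "TRBJ1-2*01"
        assert ann.v_identity == pytest.approx(100.0)
        assert ann.j_identity == pytest.approx(100.0)

    def test_random_read_fails_identity_filter(self, toy_db):
        # oracle: the best alignment over the whole toy DB stays below 70%
        r = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        read = "".join(bases[r.integers(0, 4, 120)])
        ann = annotate_read("r", read, toy_db)
        assert max(ann.v_identity, ann.j_identity) < 70
        assert not ann.pass_filter

    def test_equal_scoring_alleles_tie_break_lexicographic(self):
        v_seq = "A" * 20 + "TTATCCGGAACCGGTAACGGAACCA" + "TGTGCAGCT"
        db = GermlineDB(
            [
                GermlineSegment("TRBV1*02", "V", v_seq, anchor_pos=45),
                GermlineSegment("TRBV1*01", "V", v_seq, anchor_pos=45),
                GermlineSegment("TRBD1*01", "D", "GGGGGG"),
                GermlineSegment("TRBJ1-1*01", "J", "ACGACGACG" + "TTC" + "GGTGGTGGTGGC", anchor_pos=9),
            ]
        )
        read = v_seq + "GGG" + db.get("TRBJ1-1*01").sequence
        ann = annotate_read("r", read, db)
        assert ann.v_call == "TRBV1*01"


class TestIdentityFilter:
    @pytest.mark.parametrize(
        "v_id,j_id,kept",
        [(100.0, 100.0, True), (69.9, 100.0, False), (70.0, 70.0, True)],
    )
    def test_boundary_inclusive(self, v_id, j_id, kept):
        read = AnnotatedRead("r", "ACGT", v_identity=v_id, j_identity=j_id, cdr3_nt="AAA")
        passing, report = filter_by_identity([read], threshold=70.0)
        assert (len(passing) == 1) == kept
        assert report.kept + report.excluded == 1

    def test_monotone_in_threshold(self, rng):
        reads = [
            AnnotatedRead(
                f"r{i}",
                "ACGT",
                v_identity=float(rng.uniform(40, 100)),
                j_identity=float(rng.uniform(40, 100)),
                cdr3_nt="AAA",
            )
            for i in range(100)
        ]
        previous = None
        for threshold in (50, 60, 70, 80, 90):
            kept, _ = filter_by_identity(reads, threshold=threshold)
            ids = {r.read_id for r in kept}
            if previous is not None:
                assert ids <= previous
            previous = ids


class TestCdr3Extraction:
    def test_printed_dominant_clone_sequence(self, toy_db):
        # junction encoding C-A-T-A-G-L-A-G-E-T-Q-Y-F between the TRBV15
        # anchor and the TRBJ2-5 anchor -> CDR3 "ATAGLAGETQY"
        v = toy_db.get("TRBV15*01")
        j = toy_db.get("TRBJ2-5*01")
        read = v.sequence[: v.anchor_pos + 3] + "GCTACTGCAGGTCTCGCAGGG" + j.sequence
        cdr3_nt, cdr3_aa, productive = extract_cdr3(read, v.segment_id, j.segment_id, toy_db)
        assert cdr3_aa == "ATAGLAGETQY"
        assert productive

    def test_internal_stop_codon_unproductive(self, toy_db):
        v = toy_db.get("TRBV2*01")
        j = toy_db.get("TRBJ1-1*01")
        read = v.sequence + "TAATAA" + j.sequence
        ann = annotate_read("r", read, toy_db)
        assert ann.cdr3_aa is not None and "*" in ann.cdr3_aa
        assert not ann.productive

    def test_frameshift_unproductive(self, toy_db):
        v = toy_db.get("TRBV2*01")
        j = toy_db.get("TRBJ1-1*01")
        read = v.sequence + "GGGA" + j.sequence  # anchor span = 3k + 1
        ann = annotate_read("r", read, toy_db)
        assert not ann.productive

    def test_anchor_not_covered_marks_fail(self, toy_db):
        v = toy_db.get("TRBV2*01")
        j = toy_db.get("TRBJ1-1*01")
        read = v.sequence[:30] + "GGG" + j.sequence  # V anchor absent
        cdr3_nt, cdr3_aa, productive = extract_cdr3(read, v.segment_id, j.segment_id, toy_db)
        assert cdr3_aa is None
        assert not productive

    def test_invariant_to_bases_outside_anchor_span(self, toy_db, rng):
        bases = np.array(list("ACGT"))
        truth = simulate_repertoire(RepertoireModel(n_clones=5, seed=21), toy_db)
        for row in truth.itertuples():
            plain = annotate_read("r", row.sequence, toy_db)
            flanked = annotate_read(
                "r",
                "".join(bases[rng.integers(0, 4, 12)])
                + row.sequence
                + "".join(bases[rng.integers(0, 4, 12)]),
                toy_db,
            )
            assert flanked.cdr3_nt == plain.cdr3_nt == row.cdr3_nt


def test_annotation_recovers_truth_for_99_percent_of_reads(toy_db):
    """Error-free reads from the simulator must annotate back to the true V
    family, J family and CDR3 amino-acid sequence almost always."""
    truth = simulate_repertoire(RepertoireModel(n_clones=300, seed=13), toy_db)
    rng = np.random.default_rng(13)
    counts = rng.multinomial(10_000, truth["frequency"].to_numpy())
    annotated = annotate_reads(
        [(cid, s) for cid, s in zip(truth["clone_id"], truth["sequence"])], toy_db
    )
    correct = 0
    for ann, row, n in zip(annotated, truth.itertuples(), counts):
        if (
            ann.v_family == row.v_family
            and ann.j_family == row.j_family
            and ann.cdr3_aa == row.cdr3_aa
            and ann.pass_filter
        ):
            correct += n
    assert correct / counts.sum() >= 0.99


def test_rearrangement_table_round_trip(toy_db, tmp_path):
    truth = simulate_repertoire(RepertoireModel(n_clones=10, seed=17), toy_db)
    annotated = annotate_reads(
        [(cid, s) for cid, s in zip(truth["clone_id"], truth["sequence"])], toy_db
    )
    write_rearrangements(annotated, tmp_path / "rearr.tsv")
    back = read_rearrangements(tmp_path / "rearr.tsv")
    assert [r.cdr3_nt for r in back] == [r.cdr3_nt for r in annotated]
    assert [r.v_call for r in back] == [r.v_call for r in annotated]
    assert [r.productive for r in back] == [r.productive for r in annotated]
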