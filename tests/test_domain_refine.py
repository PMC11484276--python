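import importlib.resources
import io

import numpy as np
import pytest

from varclade.msa_io import Alignment, ProteinSequence
from varclade.refmap import build_reference_map
from varclade.domain_refine import (
    CurationConfig,
    CurationError,
    DomainDefinition,
    DomainTableError,
    curate,
    filter_incomplete,
    mask_near_indels,
    pairwise_global,
    partition_reference,
    read_domain_table,
    realign_segment,
    reassemble,
    slice_alignment,
)


def dicer1_table() -> str:
    ref = importlib.resources.files("varclade") / "data" / "dicer1_domains.tsv"
    return ref.read_text()


class TestDomainTable:
    def test_dicer1_table_parses_to_seven_sorted_domains(self):
        domains = read_domain_table(io.StringIO(dicer1_table()))
        assert len(domains) == 7
        first = domains[0]
        assert first.name.startswith("Helicase ATP-binding")
        assert (first.rule_id, first.start, first.end) == ("PRU00541", 51, 227)
        assert domains[-1].end == 1914

    def test_overlap_is_an_error_naming_both_domains(self):
        tsv = "name\trule_id\tstart\tend\nA\t.\t10\t20\nB\t.\t15\t30\n"
        with pytest.raises(DomainTableError, match="A.*B"):
            read_domain_table(io.StringIO(tsv))

    def test_inverted_span_is_an_error(self):
        tsv = "name\trule_id\tstart\tend\nA\t.\t20\t10\n"
        with pytest.raises(DomainTableError):
            read_domain_table(io.StringIO(tsv))

    def test_shuffled_rows_sort_identically(self):
        lines = dicer1_table().strip().split("\n")
        shuffled = [lines[0]] + [lines[i] for i in (3, 1, 7, 5, 2, 6, 4)]
        a = read_domain_table(io.StringIO(dicer1_table()))
        b = read_domain_table(io.StringIO("\n".join(shuffled) + "\n"))
        assert a == b

    def test_thousands_separators_accepted(self):
        tsv = "name\trule_id\tstart\tend\nPAZ\tPRU00142\t891\t1,042\n"
        assert read_domain_table(io.StringIO(tsv))[0].end == 1042


class TestPartition:
    def test_dicer1_partition_has_fifteen_segments(self):
        domains = read_domain_table(io.StringIO(dicer1_table()))
        segments = partition_reference(domains, 1922)
        assert len(segments) == 15
        assert (segments[0].kind, segments[0].start, segments[0].end) == ("initial", 1, 50)
        assert segments[1].kind == "domain"
        assert segments[1].name.startswith("Helicase ATP-binding")
        assert (segments[1].start, segments[1].end) == (51, 227)
        assert segments[-1].kind == "terminal"

    def test_single_domain_spanning_everything_gives_one_segment(self):
        segs = partition_reference([DomainDefinition("d", ".", 1, 30)], 30)
        assert len(segs) == 1 and segs[0].kind == "domain"

    def test_domain_beyond_reference_is_an_error(self):
        with pytest.raises(DomainTableError):
            partition_reference([DomainDefinition("d", ".", 5, 50)], 30)

    def test_tiling_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(10, 200))
            # random non-overlapping domains by splitting a sorted point set
            points = sorted(rng.choice(np.arange(1, L + 1), size=min(L, 8), replace=False))
            domains = []
            for a, b in zip(points[::2], points[1::2]):
                domains.append(DomainDefinition(f"d{a}", ".", int(a), int(b)))
            segs = partition_reference(domains, L)
            # brute-force: label every position, then count runs
            label = {}
            for p in range(1, L + 1):
                owner = next((d.name for d in domains if d.start <= p <= d.end), None)
                label[p] = owner
            runs = 1
            for p in range(2, L + 1):
                if label[p] != label[p - 1]:
                    runs += 1
            assert len(segs) == runs
            # exact tiling, in order
            covered = [p for s in segs for p in range(s.start, s.end + 1)]
            assert covered == list(range(1, L + 1))

    def test_segment_count_law_2k_plus_1(self):
        domains = [DomainDefinition(f"d{i}", ".", 10 * i, 10 * i + 5) for i in range(1, 5)]
        segs = partition_reference(domains, 100)
        assert len(segs) == 2 * 4 + 1


class TestSliceAndReassemble:
    @pytest.fixture
    def gapped(self):
        # reference has an insertion column (col 3) interior to positions 3-4
        return Alignment(
            [
                ("ref", "MKV-LDHE"),
                ("s1", "MKVALDHE"),
                ("s2", "M-VAL-HE"),
            ]
        )

    def test_slice_carries_interior_insertion_columns(self, gapped):
        m = build_reference_map(gapped, "ref")
        seg = partition_reference([DomainDefinition("d", ".", 2, 4)], 7)[1]
        piece = slice_alignment(gapped, m, seg, next_start=5)
        assert piece.row("ref") == "KV-L"
        assert piece.row("s1") == "KVAL"

    def test_whole_partition_slices_concatenate_to_original(self, gapped):
        m = build_reference_map(gapped, "ref")
        domains = [DomainDefinition("d", ".", 3, 5)]
        segs = partition_reference(domains, m.length)
        pieces = []
        for k, seg in enumerate(segs):
            nxt = segs[k + 1].start if k + 1 < len(segs) else None
            pieces.append((seg, slice_alignment(gapped, m, seg, nxt)))
        back, flagged = reassemble(pieces)
        assert back == gapped
        assert flagged == {}
        # degapping the reference across slices reproduces the reference
        ref = "".join(p.row("ref") for _, p in pieces).replace("-", "")
        assert ref == gapped.degap("ref")

    def test_full_span_slice_is_identity(self, gapped):
        m = build_reference_map(gapped, "ref")
        seg = partition_reference([DomainDefinition("d", ".", 1, m.length)], m.length)[0]
        assert slice_alignment(gapped, m, seg, None) == gapped

    def test_gap_fill_pads_rows_missing_from_a_segment(self):
        seg_a = Alignment([("ref", "MK"), ("s1", "MK")])
        seg_b = Alignment([("ref", "VD")])
        segs = partition_reference([DomainDefinition("d", ".", 1, 2)], 4)
        out, flagged = reassemble([(segs[0], seg_a), (segs[1], seg_b)])
        assert out.row("s1") == "MK--"
        assert flagged == {"s1": ["terminal"]}

    def test_global_policy_drops_rows_missing_anywhere(self):
        seg_a = Alignment([("ref", "MK"), ("s1", "MK")])
        seg_b = Alignment([("ref", "VD")])
        segs = partition_reference([DomainDefinition("d", ".", 1, 2)], 4)
        out, _ = reassemble([(segs[0], seg_a), (segs[1], seg_b)], drop_policy="global")
        assert out.ids == ["ref"]


class TestFilterAndMask:
    def test_fully_gapped_row_removed_at_half_coverage(self):
        aln = Alignment([("ref", "MKVD"), ("s1", "----"), ("s2", "MKVD")])
        kept, removed = filter_incomplete(aln, 0.5, "ref")
        assert removed == ["s1"] and kept.ids == ["ref", "s2"]

    def test_threshold_zero_removes_nothing(self):
        aln = Alignment([("ref", "MKVD"), ("s1", "----")])
        kept, removed = filter_incomplete(aln, 0.0, "ref")
        assert removed == [] and kept == aln

    def test_masked_residues_do_not_count_as_coverage(self):
        aln = Alignment([("ref", "MKVD"), ("s1", "xxxD")])
        _, removed = filter_incomplete(aln, 0.5, "ref")
        assert removed == ["s1"]

    def test_planted_truncations_match_generator_truth(self):
        from varclade.synthetic import FixtureSpec, generate_msa

        spec = FixtureSpec(
            n_rows=30, L=60, indel_rate=0.0, truncation_fraction=0.3,
            ambiguous_rate=0.0, paralog_rows=0, seed=23,
        )
        aln, truth = generate_msa(spec)
        # truncations remove 1/3..2/3 of the sequence, so a 0.67 threshold
        # catches exactly the truncated rows
        _, removed = filter_incomplete(aln, 0.67, "ref")
        assert set(removed) == truth.truncated

    def test_window_zero_is_identity(self, toy_alignment):
        assert mask_near_indels(toy_alignment, 0, "ref") == toy_alignment

    def test_residues_flanking_gap_run_are_masked(self):
        aln = Alignment([("ref", "AKVVVD"), ("s1", "AK--VD")])
        out = mask_near_indels(aln, 1, "ref")
        assert out.row("s1") == "Ax--xD"
        assert out.row("ref") == "AKVVVD"  # reference never masked

    def test_masking_matches_distance_transform_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            row = "".join(rng.choice(list("AKVD-"), size=n))
            window = int(rng.integers(1, 4))
            aln = Alignment([("ref", "A" * n), ("s1", row)])
            got = mask_near_indels(aln, window, "ref").row("s1")
            # oracle: per-column distance to the nearest gap in the same row
            gaps = [i for i, c in enumerate(row) if c == "-"]
            expect = list(row)
            for i, c in enumerate(row):
                if c != "-" and gaps and min(abs(i - g) for g in gaps) <= window:
                    expect[i] = "x"
            assert got == "".join(expect)


class TestRealign:
    def test_single_sequence_aligns_to_itself(self):
        aln = realign_segment([ProteinSequence("ref", "MKVD")])
        assert aln.rows() == [("ref", "MKVD")]

    def test_two_identical_sequences_align_gaplessly(self):
        aln = realign_segment(
            [ProteinSequence("ref", "MKVD"), ProteinSequence("s1", "MKVD")], ref_id="ref"
        )
        assert aln.row("ref") == "MKVD" and aln.row("s1") == "MKVD"

    def test_realignment_preserves_residue_content(self):
        seqs = [
            ProteinSequence("ref", "MKVLDHEWK"),
            ProteinSequence("s1", "MKVDHEWK"),
            ProteinSequence("s2", "MKVLDHEAWK"),
            ProteinSequence("s3", "KVLDHEW"),
        ]
        aln = realign_segment(seqs, ref_id="ref")
        for s in seqs:
            assert aln.degap(s.id) == s.residues

    def test_mask_marks_survive_realignment(self):
        seqs = [ProteinSequence("ref", "MKVLD"), ProteinSequence("s1", "MxVLD")]
        aln = realign_segment(seqs, ref_id="ref")
        assert aln.degap("s1") == "MxVLD"

    def test_pairwise_scores_match_independent_dp_oracle(self):
        """Affine-gap scores agree exactly with Biopython's global aligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        oracle = Align.PairwiseAligner()
        oracle.substitution_matrix = substitution_matrices.load("BLOSUM62")
        oracle.open_gap_score = -10
        oracle.extend_gap_score = -1
        oracle.mode = "global"

        rng = np.random.default_rng(29)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            a = "".join(rng.choice(aa, size=int(rng.integers(1, 13))))
            b = "".join(rng.choice(aa, size=int(rng.integers(1, 13))))
            ga, gb, score = pairwise_global(a, b)
            assert ga.replace("-", "") == a and gb.replace("-", "") == b
            assert score == pytest.approx(oracle.score(a, b))

    def test_external_aligner_failure_carries_diagnostics(self):
        with pytest.raises(CurationError, match="exit"):
            realign_segment([ProteinSequence("ref", "MKVD")], aligner="false # {in} {out}")

    def test_external_mafft_preserves_residue_content(self):
        seqs = [
            ProteinSequence("ref", "MKVLDHEWKAGH"),
            ProteinSequence("s1", "MKVDHEWKAGH"),
            ProteinSequence("s2", "MKVLDHEWWKAGH"),
        ]
        aln = realign_segment(seqs, aligner="mafft --quiet --auto {in} > {out}")
        for s in seqs:
            assert aln.degap(s.id) == s.residues


class TestCuratePipeline:
    def test_trivial_single_domain_curation_preserves_residues(self):
        aln = Alignment(
            [
                ("ref", "MKVLDHE"),
                ("s1", "MKV-DHE"),
                ("s2", "MKVLDAE"),
                ("s3", "MRVLDHE"),
                ("s4", "MKVLDHE"),
            ]
        )
        domains = [DomainDefinition("whole", ".", 1, 7)]
        refined, report = curate(aln, domains, "ref", CurationConfig(indel_mask_window=0))
        assert report.n_segments == 1
        for i in refined.ids:
            assert refined.degap(i) == aln.degap(i)

    def test_row_failing_one_domain_is_gap_filled_there_only(self):
        # s1 covers the second domain fully but only 1/4 of the first
        aln = Alignment(
            [
                ("ref", "MKVDWHEA"),
                ("s1", "---DWHEA"),
                ("s2", "MKVDWHEA"),
                ("s3", "MKVEWHEA"),
            ]
        )
        domains = [
            DomainDefinition("d1", ".", 1, 4),
            DomainDefinition("d2", ".", 5, 8),
        ]
        cfg = CurationConfig(min_segment_coverage=0.5, indel_mask_window=0)
        refined, report = curate(aln, domains, "ref", cfg)
        assert refined.row("s1")[:4] == "----"
        assert refined.row("s1")[4:] == "WHEA"
        actions = {(e[0], e[1], e[2]) for e in report.events}
        assert ("s1", "d1", "removed") in actions
        assert ("s1", "d1", "gap_filled") in actions
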