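"""Synthetic genomes, planted SVs, reads and truth alignments."""

import numpy as np
import pytest

from stacktail import alignment_io as aio
from stacktail.junctions import build_junction_sequence
from stacktail.simulator import (
    SimConfig,
    SVPlan,
    emit_truth_alignments,
    plant_svs,
    replica_bookkeeping,
    replica_design,
    replica_reference,
    simulate_reads,
    simulate_reference,
    simulate_replica_sample,
    write_fastq,
)
from stacktail.stacks import find_breakpoint_candidates


@pytest.fixture(scope="module")
def reference():
    return simulate_reference(SimConfig(n_chroms=2, chrom_length=30_000, seed=21))


class TestReference:
    def test_deterministic(self):
        cfg = SimConfig(n_chroms=2, chrom_length=5000, seed=13)
        assert simulate_reference(cfg) == simulate_reference(cfg)
        other = simulate_reference(SimConfig(n_chroms=2, chrom_length=5000, seed=14))
        assert other != simulate_reference(cfg)

    def test_total_length(self):
        ref = simulate_reference(SimConfig(n_chroms=2, chrom_length=100_000, seed=1))
        assert sum(len(s) for s in ref.values()) == 200_000

    def test_gc_fraction_near_half(self):
        ref = simulate_reference(SimConfig(n_chroms=1, chrom_length=100_000, seed=2))
        seq = ref["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01  # ~6 sigma for a binomial at n=1e5

    def test_repeat_block_planted(self):
        ref = simulate_reference(
            SimConfig(n_chroms=1, chrom_length=5000, seed=3),
            repeat_block=("chr1", 1000, "ACGT", 100),
        )
        assert ref["chr1"][1000:1400] == "ACGT" * 100


class TestPlantSVs:
    def test_interchromosomal_join(self, reference):
        plan = SVPlan("translocation", "chr1", 10_000, "chr2", 20_000)
        donor, truth = plant_svs(reference, [plan])
        assert set(donor.chroms) == {"der_chr1_chr2"}
        assert len(truth) == 1
        der = donor.chroms["der_chr1_chr2"]
        assert der.seq == reference["chr1"][:10_000] + reference["chr2"][20_000:]

    def test_reciprocal_emits_both_derivatives_and_conserves_length(self, reference):
        plan = SVPlan("translocation", "chr1", 10_000, "chr2", 20_000, reciprocal=True)
        donor, truth = plant_svs(reference, [plan])
        assert len(truth) == 2
        assert donor.total_length == sum(len(s) for s in reference.values())

    def test_inversion_junctions_and_conservation(self, reference):
        plan = SVPlan("inversion", "chr1", 8000, "chr1", 18_000)
        donor, truth = plant_svs(reference, [plan])
        assert len(truth) == 2
        assert {t.sv_class for t in truth} == {"inversion"}
        c = donor.chroms["chr1"]
        assert len(c.seq) == len(reference["chr1"])
        assert c.seq[8000:18_000] == aio.revcomp(reference["chr1"][8000:18_000])

    def test_deletion_removes_exactly(self, reference):
        plan = SVPlan("deletion", "chr1", 5000, "chr1", 7000)
        donor, truth = plant_svs(reference, [plan])
        assert len(donor.chroms["chr1"].seq) == len(reference["chr1"]) - 2000
        assert truth[0].sv_class == "deletion"

    def test_duplication_adds_exactly(self, reference):
        plan = SVPlan("duplication", "chr1", 5000, "chr1", 7000)
        donor, truth = plant_svs(reference, [plan])
        c = donor.chroms["chr1"]
        assert len(c.seq) == len(reference["chr1"]) + 2000
        assert c.seq[5000:9000] == reference["chr1"][5000:7000] * 2
        assert truth[0].sv_class == "insertion/duplication"
        # reference-contiguous pieces are merged: only the dup junction remains
        assert len(c.segments) == 2

    def test_overlapping_plans_fatal(self, reference):
        plans = [
            SVPlan("deletion", "chr1", 5000, "chr1", 7000),
            SVPlan("inversion", "chr1", 7200, "chr1", 9000),
        ]
        with pytest.raises(ValueError, match="overlap"):
            plant_svs(reference, plans, min_separation=1000)

    def test_donor_junction_context_matches_built_junction(self, reference):
        """Cross-module oracle: donor sequence around each planted junction
        equals the independently constructed candidate junction sequence
        (up to reverse complement for canonically flipped junctions)."""
        plans = [
            SVPlan("translocation", "chr1", 10_000, "chr2", 20_000, reciprocal=True),
        ]
        donor, truth = plant_svs(reference, plans)
        flank = 120
        for t, donor_name, donor_pos in [
            (truth[0], "der_chr1_chr2", 10_000),
            (truth[1], "der_chr2_chr1", 20_000),
        ]:
            j = build_junction_sequence(t.spec, flank, reference)
            context = donor.chroms[donor_name].seq[donor_pos - flank : donor_pos + flank]
            assert j.seq in (context, aio.revcomp(context))

        donor2, truth2 = plant_svs(reference, [SVPlan("inversion", "chr1", 8000, "chr1", 18_000)])
        for t, donor_pos in zip(truth2, (8000, 18_000)):
            j = build_junction_sequence(t.spec, flank, reference)
            context = donor2.chroms["chr1"].seq[donor_pos - flank : donor_pos + flank]
            assert j.seq in (context, aio.revcomp(context))


class TestReads:
    def test_read_count_formula(self, reference):
        donor, _ = plant_svs(reference, [])
        cfg = SimConfig(read_length=100, coverage=30, seed=5)
        reads = simulate_reads(donor, cfg)
        assert len(reads) == round(30 * 60_000 / 100)

    def test_error_free_reads_are_donor_substrings(self, reference):
        donor, _ = plant_svs(reference, [])
        cfg = SimConfig(read_length=100, coverage=1, seed=6)
        for r in simulate_reads(donor, cfg):
            piece = donor.chroms[r.donor_chrom].seq[r.start : r.end]
            assert r.seq == (aio.revcomp(piece) if r.reverse else piece)

    def test_error_rate_binomial(self, reference):
        donor, _ = plant_svs(reference, [])
        rate = 0.01
        cfg = SimConfig(read_length=100, coverage=10, substitution_error_rate=rate, seed=7)
        reads = simulate_reads(donor, cfg)
        n_mismatch = n_bases = 0
        for r in reads:
            piece = donor.chroms[r.donor_chrom].seq[r.start : r.end]
            machine = aio.revcomp(piece) if r.reverse else piece
            n_mismatch += sum(a != b for a, b in zip(r.seq, machine))
            n_bases += len(r.seq)
        sigma = (n_bases * rate * (1 - rate)) ** 0.5
        assert abs(n_mismatch - n_bases * rate) < 3 * sigma

    def test_error_rate_does_not_shift_positions(self, reference):
        """Separate RNG streams: error injection leaves sampling untouched."""
        donor, _ = plant_svs(reference, [])
        a = simulate_reads(donor, SimConfig(read_length=100, coverage=2, seed=8))
        b = simulate_reads(
            donor, SimConfig(read_length=100, coverage=2, substitution_error_rate=0.05, seed=8)
        )
        assert [(r.donor_chrom, r.start, r.reverse) for r in a] == [
            (r.donor_chrom, r.start, r.reverse) for r in b
        ]

    def test_determinism_byte_identical_outputs(self, reference, tmp_path):
        donor, _ = plant_svs(reference, [SVPlan("deletion", "chr1", 5000, "chr1", 7000)])
        cfg = SimConfig(read_length=80, coverage=3, substitution_error_rate=0.01, seed=9)
        files = []
        for tag in ("a", "b"):
            reads = simulate_reads(donor, cfg)
            alignments, _ = emit_truth_alignments(reads, donor)
            fq, sam = tmp_path / f"{tag}.fastq", tmp_path / f"{tag}.sam"
            write_fastq(reads, fq)
            aio.write_alignments(alignments, sam, {c: len(s) for c, s in reference.items()})
            files.append((fq.read_bytes(), sam.read_bytes()))
        assert files[0] == files[1]


class TestTruthAlignments:
    def test_interior_read_full_match(self, reference):
        donor, _ = plant_svs(reference, [SVPlan("translocation", "chr1", 10_000, "chr2", 20_000)])
        from stacktail.simulator import SimRead

        r = SimRead("r", "der_chr1_chr2", 500, 600, False,
                    donor.chroms["der_chr1_chr2"].seq[500:600], [35] * 100)
        (aln,), flagged = emit_truth_alignments([r], donor)
        assert aln.cigar == [("M", 100)] and aln.chrom == "chr1" and aln.ref_start == 500
        assert not flagged

    def test_junction_read_soft_clip_structure(self, reference):
        """60 bases left of the junction, 40 right -> 60M40S at the left locus
        with the clip exactly at the junction coordinate."""
        donor, _ = plant_svs(reference, [SVPlan("translocation", "chr1", 10_000, "chr2", 20_000)])
        from stacktail.simulator import SimRead

        seq = donor.chroms["der_chr1_chr2"].seq[9940:10_040]
        r = SimRead("r", "der_chr1_chr2", 9940, 10_040, False, seq, [35] * 100)
        (aln,), _ = emit_truth_alignments([r], donor)
        assert aln.cigar == [("M", 60), ("S", 40)]
        assert aln.chrom == "chr1" and aln.ref_end == 10_000
        (clip,) = aio.extract_clipped_reads([aln], min_tail=10)
        assert (clip.clip_side, clip.clip_pos) == ("right", 10_000)

    def test_minus_strand_segment_read(self, reference):
        """A read inside an inverted segment maps reverse-strand, full match."""
        donor, _ = plant_svs(reference, [SVPlan("inversion", "chr1", 8000, "chr1", 18_000)])
        from stacktail.simulator import SimRead

        seq = donor.chroms["chr1"].seq[9000:9100]
        r = SimRead("r", "chr1", 9000, 9100, False, seq, [35] * 100)
        (aln,), _ = emit_truth_alignments([r], donor)
        assert aln.strand == "-" and aln.cigar == [("M", 100)]
        # donor[9000:9100] is revcomp(ref[16900:17000])
        assert aln.ref_start == 16_900
        assert aln.seq == reference["chr1"][16_900:17_000]

    def test_end_to_end_breakpoint_recovery(self, reference, tmp_path):
        """Clip extraction + stacking on the emitted SAM recovers every planted
        junction coordinate exactly (error-free, high coverage)."""
        plans = [SVPlan("translocation", "chr1", 10_000, "chr2", 20_000, reciprocal=True)]
        donor, truth = plant_svs(reference, plans)
        cfg = SimConfig(read_length=100, coverage=15, seed=10)
        reads = simulate_reads(donor, cfg)
        alignments, _ = emit_truth_alignments(reads, donor)
        sam = tmp_path / "truth.sam"
        aio.write_alignments(alignments, sam, {c: len(s) for c, s in reference.items()})
        clipped = aio.extract_clipped_reads(aio.read_alignments(sam), min_tail=10)
        cands = find_breakpoint_candidates(clipped, min_stack_reads=2)
        found = {(c.chrom, c.pos, c.clip_side) for c in cands}
        for t in truth:
            for bp in (t.spec.bpA, t.spec.bpB):
                assert (bp.chrom, bp.pos, bp.side) in found


    def test_breakpoints_exact_under_substitution_errors(self, reference):
        """Substitution errors never move soft-clip boundaries, so planted
        coordinates are still recovered exactly at 1% error."""
        donor, truth = plant_svs(
            reference, [SVPlan("translocation", "chr1", 10_000, "chr2", 20_000)]
        )
        cfg = SimConfig(read_length=100, coverage=15, substitution_error_rate=0.01, seed=12)
        alignments, _ = emit_truth_alignments(simulate_reads(donor, cfg), donor)
        clipped = aio.extract_clipped_reads(alignments, min_tail=10)
        cands = find_breakpoint_candidates(clipped, min_stack_reads=2)
        found = {(c.chrom, c.pos, c.clip_side) for c in cands}
        t = truth[0]
        assert (t.spec.bpA.chrom, t.spec.bpA.pos, "right") in found
        assert (t.spec.bpB.chrom, t.spec.bpB.pos, "left") in found


class TestReplicaPreset:
    def test_bookkeeping_counts(self):
        counts = replica_bookkeeping()
        assert counts["n_samples"] == 23
        assert counts["n_regions"] == 8
        assert counts["n_translocations"] == 31
        assert counts["n_normal_instances"] == 153

    def test_training_cohort_has_seven_junctions(self):
        train = [s for s in replica_design() if s.role == "train"]
        assert len(train) == 4
        assert sum(s.n_junctions for s in train) == 7

    def test_sample_simulation_is_deterministic(self):
        ref = replica_reference(3)
        sample = [s for s in replica_design() if s.role == "test"][1]
        r1, t1 = simulate_replica_sample(ref, sample, 3)
        r2, t2 = simulate_replica_sample(ref, sample, 3)
        assert [(a.read_id, a.chrom, a.ref_start, a.seq) for a in r1] == [
            (a.read_id, a.chrom, a.ref_start, a.seq) for a in r2
        ]
        assert [t.spec.key for t in t1] == [t.spec.key for t in t2]
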