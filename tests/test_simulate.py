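"""Synthetic data generator: reference, planted SVs, reads, truth projection."""

import numpy as np
import pysam
import pytest

from svdelver import (SimConfig, generate_reference, plant_variants,
                      simulate_dataset, simulate_reads, write_fastq)
from svdelver._util import revcomp
from svdelver.simulate import Block, project_alignments, read_truth, write_truth


class TestReference:
    def test_seed_determinism(self):
        assert generate_reference(10_000, 7) == generate_reference(10_000, 7)
        assert generate_reference(10_000, 7) != generate_reference(10_000, 8)

    def test_base_composition_uniform(self):
        seq = generate_reference(1_000_000, 3)["chr1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.005

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(0, 1)


class TestPlanting:
    def test_deletion_arithmetic(self):
        ref = generate_reference(20_000, 1)
        donor, rc, truth, _ = plant_variants(ref, {"DEL": 1}, (1000, 1000), 2)
        assert len(donor["chr1"]) == 19_000
        assert len(rc["chr1"]) == 20_000
        (t,) = truth
        assert t.sv_type == "DEL" and t.size == 1000
        assert rc["chr1"][t.start:t.end] not in donor["chr1"]

    def test_tandem_duplication_doubles_in_place(self):
        ref = generate_reference(20_000, 1)
        donor, rc, truth, _ = plant_variants(ref, {"DUP": 1}, (500, 500), 2)
        (t,) = truth
        assert len(donor["chr1"]) == 20_500
        seg = rc["chr1"][t.start:t.end]
        assert seg + seg in donor["chr1"]

    def test_inversion_reverse_complements(self):
        ref = generate_reference(20_000, 1)
        donor, rc, truth, _ = plant_variants(ref, {"INV": 1}, (800, 800), 2)
        (t,) = truth
        assert donor["chr1"][t.donor_start:t.donor_end] == revcomp(rc["chr1"][t.start:t.end])

    def test_translocation_excised_to_contig(self):
        ref = generate_reference(30_000, 1)
        donor, rc, truth, _ = plant_variants(ref, {"TRA": 1}, (2000, 2000), 2)
        (t,) = truth
        assert len(donor["chr1"]) == 30_000  # donor keeps the segment in place
        assert len(rc["chr1"]) == 28_000
        assert len(rc[t.chrom2]) == 2000
        # the excised contig re-inserted at the insertion point restores the donor
        restored = rc["chr1"][:t.start] + rc[t.chrom2] + rc["chr1"][t.start:]
        assert restored == donor["chr1"]

    def test_events_are_non_overlapping(self):
        ref = generate_reference(500_000, 1)
        _, _, truth, _ = plant_variants(ref, {"DEL": 7, "DUP": 7, "INV": 6},
                                        (500, 5000), 5)
        spans = sorted((t.start, t.end) for t in truth)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_oversized_footprint_rejected(self):
        ref = generate_reference(10_000, 1)
        with pytest.raises(ValueError, match="footprint"):
            plant_variants(ref, {"DEL": 10}, (1000, 1000), 2)

    def test_truth_table_roundtrip(self, tmp_path):
        ref = generate_reference(50_000, 1)
        _, _, truth, _ = plant_variants(ref, {"DEL": 2, "TRA": 1}, (600, 900), 2)
        path = write_truth(truth, str(tmp_path / "t.tsv"))
        assert read_truth(path) == truth


class TestReads:
    CFG = SimConfig(coverage=15, read_length=75, insert_mean=300, insert_sd=30)

    def test_pair_count_formula(self):
        donor = generate_reference(10_000, 1)
        batch = simulate_reads(donor, self.CFG, seed=1)
        assert len(batch) == 1000  # 15 * 10000 / (2 * 75)

    def test_error_free_reads_are_donor_substrings(self):
        donor = generate_reference(30_000, 2)
        cfg = SimConfig(coverage=5, error_rate=0.0)
        batch = simulate_reads(donor, cfg, seed=1)
        from svdelver._util import decode
        seq = donor["chr1"]
        for i in range(0, len(batch), 97):
            assert decode(batch.seq1[i]) == seq[batch.start1[i]:batch.start1[i] + 75]
            assert decode(batch.seq2[i]) == seq[batch.start2[i]:batch.start2[i] + 75]

    def test_error_rate_within_binomial_bounds(self):
        donor = generate_reference(100_000, 3)
        batch = simulate_reads(donor, SimConfig(coverage=3, error_rate=0.01), seed=4)
        n_bases = 2 * len(batch) * 75
        rate = (batch.n_errors1.sum() + batch.n_errors2.sum()) / n_bases
        assert 0.008 <= rate <= 0.012

    def test_insert_below_twice_read_length_rejected(self):
        donor = generate_reference(10_000, 1)
        with pytest.raises(ValueError, match="insert"):
            simulate_reads(donor, SimConfig(insert_mean=100.0), seed=1)

    def test_fastq_matches_donor_orientation(self, tmp_path):
        donor = generate_reference(20_000, 5)
        cfg = SimConfig(coverage=2, error_rate=0.0)
        batch = simulate_reads(donor, cfg, seed=2)
        fq1, fq2 = write_fastq(batch, str(tmp_path / "r"))
        from svdelver._util import decode
        with open(fq2) as fh:
            lines = fh.read().splitlines()
        # mate 2 is sequenced on the reverse strand of the fragment
        assert lines[1] == revcomp(decode(batch.seq2[0]))


class TestProjection:
    def test_null_genome_is_fully_concordant(self, null_dataset):
        assert null_dataset.stats["single_anchored"] == 0
        with pysam.AlignmentFile(null_dataset.bam) as af:
            assert all(not r.is_unmapped for r in af.fetch(until_eof=True))

    def test_deletion_straddling_pairs_gain_its_size(self, del_dataset):
        t = del_dataset.truth[0]
        inflated = 0
        with pysam.AlignmentFile(del_dataset.bam) as af:
            for r in af.fetch("chr1", max(0, t.start - 400), t.start):
                if r.template_length > 0 and r.reference_start < t.start < r.reference_start + r.template_length:
                    if abs(r.template_length - (300 + t.size)) < 300:
                        inflated += 1
        assert inflated >= 2

    def test_junction_reads_unmapped_with_anchored_mate(self, del_dataset):
        t = del_dataset.truth[0]
        near = []
        with pysam.AlignmentFile(del_dataset.bam) as af:
            for r in af.fetch("chr1", t.start - 600, t.start + 600):
                if r.is_unmapped and not r.mate_is_unmapped:
                    near.append(r)
        assert len(near) >= 2  # junction-crossing reads become split candidates
        for r in near:
            assert abs(r.next_reference_start - t.start) < 600

    def test_bam_is_sorted_indexed_and_valid(self, del_dataset):
        with pysam.AlignmentFile(del_dataset.bam) as af:
            assert af.header["HD"].get("SO") == "coordinate"
            af.fetch("chr1", 0, 1000)  # requires a valid index

    def test_occurrence_mapq_flags_repeated_reads(self):
        rng = np.random.default_rng(8)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        repeat = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = core[:1000] + repeat + core[1000:2000] + repeat + core[2000:]
        contigs = {"chr1": seq}
        cfg = SimConfig(coverage=8, error_rate=0.0, mapq_policy="occurrence",
                        genome_length=len(seq))
        batch = simulate_reads(contigs, cfg, seed=3)
        blocks = [Block(0, len(seq), "chr1", 0, len(seq), "+")]
        import tempfile, os
        with tempfile.TemporaryDirectory() as tmp:
            bam = os.path.join(tmp, "r.bam")
            project_alignments(batch, blocks, contigs, cfg, bam)
            mapqs = {}
            with pysam.AlignmentFile(bam) as af:
                for r in af.fetch(until_eof=True):
                    inside_repeat = any(s <= r.reference_start and r.reference_end <= s + 400
                                        for s in (1000, 1000 + 400 + 1000))
                    mapqs.setdefault(inside_repeat, set()).add(r.mapping_quality)
        assert 0 in mapqs[True] and mapqs[False] == {60}


class TestEndToEnd:
    def test_error_free_deletions_all_recovered(self, tmp_path):
        """Caller on the truth-projected alignments finds every planted
        deletion >= 500 bp with exact breakpoints when reads are error-free."""
        from svdelver import discover
        from svdelver.bench import match_calls
        cfg = SimConfig(genome_length=800_000, n_del=8, coverage=15,
                        error_rate=0.0, seed=77)
        ds = simulate_dataset(cfg, str(tmp_path / "e2e"))
        res = discover([ds.bam], ds.fasta)
        imax = max(p.insert_max for p in res.profiles.values())
        sr = [c for c in res.final if c.precise]
        assert match_calls(sr, ds.truth, "DEL", imax) == {"TP": 8, "FP": 0, "FN": 0}
        by_pos = {t.start: t for t in ds.truth}
        for c in sr:
            t = min(ds.truth, key=lambda t: abs(t.start - c.start))
            hom = c.microhomology
            assert abs(c.start - t.start) <= hom and abs(c.end - t.end) <= hom

    def test_dataset_generation_is_deterministic(self, tmp_path):
        cfg = SimConfig(genome_length=150_000, n_del=3, seed=9)
        a = simulate_dataset(cfg, str(tmp_path / "a"))
        b = simulate_dataset(cfg, str(tmp_path / "b"))
        assert a.truth == b.truth
        assert open(a.fasta).read() == open(b.fasta).read()
        va = pysam.view(a.bam)
        vb = pysam.view(b.bam)
        assert va == vb
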