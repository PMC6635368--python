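"""Simulator ground truth: transcripts, reads, errors, subsampling."""

import numpy as np
import pytest

from longvdj.align import local_align
from longvdj.seqs import read_fastq, revcomp, translate
from longvdj.simulate import (
    ADAPTER_3,
    ADAPTER_5,
    ErrorProfile,
    SimulateConfig,
    apply_errors,
    apply_shm,
    build_read,
    recombine_vdj,
    simulate_run,
    subsample_reads,
)


class TestRecombine:
    def test_zero_junction_joins_anchors_in_frame(self, reference):
        transcript, truth = recombine_vdj(reference, "TRA", "TRAV1", "TRAJ1", 0, seed=1)
        v_seg = reference.by_gene("TRA", "V", "TRAV1")
        aa = translate(transcript[v_seg.v_anchor :])
        assert aa[0] == "C" and aa[1] in "WF"  # Cys...Trp/Phe across the join
        assert truth.junction_nt == ""

    def test_same_seed_reproduces_transcript(self, reference):
        a = recombine_vdj(reference, "TRB", "TRBV1", "TRBJ2", 12, c="TRBC", seed=9)
        b = recombine_vdj(reference, "TRB", "TRBV1", "TRBJ2", 12, c="TRBC", seed=9)
        assert a[0] == b[0]

    def test_unknown_gene_raises(self, reference):
        with pytest.raises(KeyError):
            recombine_vdj(reference, "TRA", "TRAV99", "TRAJ1", 0, seed=1)

    def test_nonproductive_junction_shifts_frame(self, reference):
        transcript, truth = recombine_vdj(
            reference, "TRA", "TRAV1", "TRAJ1", 9, seed=1, productive=False
        )
        assert len(truth.junction_nt) % 3 != 0


class TestShm:
    def test_zero_mutations_is_identity(self, reference):
        transcript, truth = recombine_vdj(reference, "TRA", "TRAV2", "TRAJ1", 6, seed=2)
        mutated, positions = apply_shm(transcript, 0, truth.v_interval, seed=1)
        assert mutated == transcript and positions == []

    def test_alignment_recovers_exact_mutation_set(self, reference):
        transcript, truth = recombine_vdj(reference, "TRB", "TRBV3", "TRBJ1", 9, seed=3)
        v_seg = reference.by_gene("TRB", "V", "TRBV3")
        anchor = (v_seg.v_anchor, v_seg.v_anchor + 3)
        mutated, positions = apply_shm(
            transcript, 8, truth.v_interval, seed=5, exclude=(anchor,)
        )
        aln = local_align(mutated, v_seg.sequence)
        assert sorted(r for _, r in aln.mismatch_positions()) == [p for p, _, _ in positions]
        assert all(not anchor[0] <= p < anchor[1] for p, _, _ in positions)

    def test_interval_outside_transcript_raises(self):
        with pytest.raises(ValueError):
            apply_shm("ACGT" * 10, 1, (0, 100), seed=1)

    def test_more_mutations_than_positions_raises(self):
        with pytest.raises(ValueError):
            apply_shm("ACGT" * 10, 11, (0, 10), seed=1)


class TestBuildRead:
    def test_forward_layout_and_length(self):
        transcript = "ACGT" * 375  # 1500 nt
        barcode, umi = "A" * 16, "C" * 10
        read = build_read(transcript, barcode, umi, "fwd")
        assert len(read) == 22 + 16 + 10 + 20 + 1500 + 15
        assert read[22:38] == barcode
        assert read[38:48] == umi
        assert read.startswith(ADAPTER_5) and read.endswith(ADAPTER_3)
        assert read[68 : 68 + 1500] == revcomp(transcript)

    def test_reverse_orientation_is_revcomp_of_forward(self):
        transcript = "ACGTTGCA" * 50
        fwd = build_read(transcript, "G" * 16, "T" * 10, "fwd")
        rev = build_read(transcript, "G" * 16, "T" * 10, "rev")
        assert rev == revcomp(fwd)

    def test_length_violations_raise(self):
        with pytest.raises(ValueError):
            build_read("ACGT" * 100, "A" * 15, "C" * 10)
        with pytest.raises(ValueError):
            build_read("ACGT" * 100, "A" * 16, "C" * 9)


class TestErrors:
    def test_zero_rates_are_identity(self):
        read = "ACGTTGCAACGT" * 100
        assert apply_errors(read, ErrorProfile(0, 0, 0), seed=1) == read

    def test_max_substitution_rate_changes_many_bases(self):
        read = "ACGT" * 500
        out = apply_errors(read, ErrorProfile(0.2, 0.0, 0.0), seed=2)
        assert len(out) == len(read)
        frac = sum(a != b for a, b in zip(out, read)) / len(read)
        assert 0.15 < frac < 0.25

    def test_substitution_fraction_concentrates_on_the_rate(self):
        rng = np.random.default_rng(3)
        read = "".join(rng.choice(list("ACGT"), size=10000))
        out = apply_errors(read, ErrorProfile(0.05, 0.0, 0.0), seed=4)
        observed = sum(a != b for a, b in zip(out, read)) / len(read)
        assert abs(observed - 0.05) < 0.01

    def test_rates_above_cap_rejected(self):
        with pytest.raises(ValueError):
            ErrorProfile(0.5, 0, 0)


class TestRun:
    def test_truth_conservation_and_whitelist(self, reference, tmp_path):
        run = simulate_run(
            reference, n_cells=6, reads_per_cell=10,
            profile=ErrorProfile(0, 0, 0),
            config=SimulateConfig(t_fraction=0.34, b_fraction=0.33, chimera_rate=0.0),
            seed=5, out_dir=tmp_path,
        )
        assert len(run.truth.reads) == 60
        whitelist = set((tmp_path / "sim_whitelist.txt").read_text().split())
        assert whitelist == set(run.truth.cells)
        for barcode, locus, _ in run.truth.reads.values():
            assert barcode in whitelist
        background = [c for c in run.truth.cells.values() if c.cell_type == "background"]
        assert background and all(not c.chains for c in background)
        t_cells = [c for c in run.truth.cells.values() if c.cell_type == "T"]
        assert all({ch.locus for ch in c.chains} == {"TRA", "TRB"} for c in t_cells)

    def test_fastq_read_count_matches_truth(self, reference, tmp_path):
        run = simulate_run(reference, n_cells=4, reads_per_cell=7, seed=8, out_dir=tmp_path)
        assert len(read_fastq(run.fastq_path)) == len(run.truth.reads) == 28


class TestSubsample:
    def _write(self, tmp_path, n, name="in.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i in range(n):
                barcode = "AAAA" if i % 2 == 0 else "CCCC"
                fh.write(f"@r{i:03d} barcode={barcode}\nACGTACGT\n+\nIIIIIIII\n")
        return path

    def test_depth_equal_to_total_is_identity(self, tmp_path):
        src = self._write(tmp_path, 10)
        out = tmp_path / "out.fastq"
        subsample_reads(src, 5, seed=1, out_path=out)  # 5 per group = all
        assert read_fastq(out) == read_fastq(src)

    def test_same_seed_same_output(self, tmp_path):
        src = self._write(tmp_path, 40)
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        subsample_reads(src, 7, seed=3, out_path=a)
        subsample_reads(src, 7, seed=3, out_path=b)
        assert a.read_text() == b.read_text()

    def test_stepwise_subsamples_are_nested(self, tmp_path):
        src = self._write(tmp_path, 100)
        s50, s20 = tmp_path / "s50.fastq", tmp_path / "s20.fastq"
        subsample_reads(src, 25, seed=4, out_path=s50)
        subsample_reads(s50, 10, seed=5, out_path=s20)
        ids50 = {h for h, _, _ in read_fastq(s50)}
        ids20 = {h for h, _, _ in read_fastq(s20)}
        assert ids20 < ids50
        per_group = {}
        for h in ids20:
            per_group.setdefault(h.split("barcode=")[1], []).append(h)
        assert all(len(v) == 10 for v in per_group.values())
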