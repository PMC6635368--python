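"""V(D)J annotation: assignment, indel correction, CDR3, productivity,
constant-region calling, on-target classification."""

import numpy as np
import pytest

from longvdj.align import local_align
from longvdj.annotate import (
    annotate_contig,
    assign_constant,
    assign_segment,
    classify_on_target,
    correct_indels,
    count_v_mutations,
)
from longvdj.refdata import GermlineSegment
from longvdj.seqs import random_seq
from longvdj.simulate import apply_shm, build_read, recombine_vdj


@pytest.mark.parametrize("locus,c_id", [("TRA", "TRAC"), ("TRB", "TRBC"),
                                        ("IGH", "IGHA1-membrane"), ("IGL", "IGLC")])
def test_clean_transcripts_annotate_to_truth(reference, locus, c_id):
    """Error-free end-to-end identity: V, J, C, form, CDR3 all exact."""
    v = reference.get(locus, "V")[1].gene_name
    j = reference.get(locus, "J")[0].gene_name
    transcript, truth = recombine_vdj(reference, locus, v, j, 12, c=c_id, seed=21)
    ann = annotate_contig(transcript, reference)
    assert (ann.locus, ann.v_call, ann.j_call) == (locus, v, j)
    assert ann.c_call == truth.c_call
    if locus == "IGH":
        assert ann.c_form == truth.c_form
    assert ann.cdr3_nt == truth.cdr3_nt
    assert ann.cdr3_aa and ann.cdr3_aa[0] == "C"
    assert ann.productive and ann.v_mutations == 0 and not ann.indel_corrected


def test_indel_correction_restores_the_clean_annotation(reference):
    transcript, truth = recombine_vdj(reference, "TRB", "TRBV2", "TRBJ1", 9, c="TRBC", seed=4)
    # two indels inside V: a 1-nt insertion and a 1-nt deletion
    damaged = transcript[:80] + "G" + transcript[80:200] + transcript[201:]
    ann = annotate_contig(damaged, reference)
    clean = annotate_contig(transcript, reference)
    assert ann.indel_corrected
    assert (ann.v_call, ann.j_call, ann.cdr3_nt, ann.productive) == (
        clean.v_call, clean.j_call, clean.cdr3_nt, clean.productive
    )
    assert ann.v_mutations == 0


def test_correction_preserves_substitutions(reference):
    """Indel correction touches indels only; hypermutations survive it."""
    transcript, truth = recombine_vdj(reference, "IGH", "IGHV1", "IGHJ2", 9,
                                      c="IGHG1-secreted", seed=5)
    v_seg = reference.by_gene("IGH", "V", "IGHV1")
    anchor = (v_seg.v_anchor, v_seg.v_anchor + 3)
    mutated, positions = apply_shm(transcript, 6, truth.v_interval, seed=6, exclude=(anchor,))
    damaged = mutated[:150] + "T" + mutated[150:]
    ann = annotate_contig(damaged, reference)
    assert ann.indel_corrected
    assert ann.v_mutations == 6
    assert sorted(ann.v_mutation_ref_positions) == [p for p, _, _ in positions]


def test_correct_indels_is_identity_without_indels(reference):
    transcript, _ = recombine_vdj(reference, "TRA", "TRAV1", "TRAJ1", 6, c="TRAC", seed=7)
    v_seg = reference.by_gene("TRA", "V", "TRAV1")
    j_seg = reference.by_gene("TRA", "J", "TRAJ1")
    v_aln = local_align(transcript, v_seg.sequence)
    j_aln = local_align(transcript, j_seg.sequence)
    corrected, changed = correct_indels(transcript, (v_seg, v_aln), (j_seg, j_aln))
    assert corrected == transcript and not changed


def test_random_contig_is_unannotated(reference):
    rng = np.random.default_rng(8)
    ann = annotate_contig(random_seq(rng, 1200), reference)
    assert not ann.annotated
    assert ann.locus is None and ann.cdr3_nt is None


def test_assign_segment_ties_break_lexicographically():
    seq = "ACGTACGTACGTACGTACGTACGTACGTTGT"
    twin = lambda name: GermlineSegment(
        segment_id=name, locus="TRA", segment_type="V", gene_name=name,
        sequence=seq, v_anchor=len(seq) - 3,
    )
    result = assign_segment(seq + "AAAA", [twin("TRAV9"), twin("TRAV2")], min_score=10)
    assert result[0].gene_name == "TRAV2"


def test_nonproductive_junctions_are_flagged(reference):
    # frame-shifting junction
    shifted, _ = recombine_vdj(reference, "TRA", "TRAV1", "TRAJ1", 9, c="TRAC",
                               seed=9, productive=False)
    assert not annotate_contig(shifted, reference).productive
    # in-frame junction containing a stop codon
    transcript, truth = recombine_vdj(reference, "TRA", "TRAV1", "TRAJ1", 9, c="TRAC", seed=9)
    v_end = truth.v_interval[1]
    stopped = transcript[:v_end] + "TAAGGGTAA" + transcript[v_end + 9 :]
    ann = annotate_contig(stopped, reference)
    assert ann.cdr3_nt is not None and not ann.productive


def test_mutation_rate_arithmetic(reference):
    transcript, truth = recombine_vdj(reference, "TRB", "TRBV1", "TRBJ1", 6, c="TRBC", seed=10)
    v_seg = reference.by_gene("TRB", "V", "TRBV1")
    mutated, _ = apply_shm(transcript, 3, (0, 285), seed=11)
    aln = local_align(mutated, v_seg.sequence)
    mutations, aligned, rate = count_v_mutations(aln)
    assert (mutations, aligned) == (3, 288)
    assert rate == pytest.approx(100 * 3 / 288)


class TestConstantCalling:
    def _fixture(self, reference, coverage, identity, seed=0):
        c_seg = reference.segments["IGHM-secreted"]
        span = int(round(coverage * len(c_seg.sequence)))
        n_sub = int(round((1 - identity) * span))
        rng = np.random.default_rng(seed)
        seq = list(c_seg.sequence[:span])
        for pos in np.linspace(10, span - 11, n_sub).astype(int):
            seq[pos] = [b for b in "ACGT" if b != seq[pos]][rng.integers(0, 3)]
        return "".join(seq)

    def test_full_secreted_tail_called_with_form(self, reference):
        contig = self._fixture(reference, 1.0, 1.0)
        call = assign_constant(contig, reference.get("IGH", "C"))
        assert call is not None
        assert call[0].isotype == "IGHM" and call[0].form == "secreted"

    @pytest.mark.parametrize(
        "coverage,identity,called",
        [(0.96, 0.91, True), (0.96, 0.89, False), (0.94, 0.91, False), (0.90, 1.0, False)],
    )
    def test_coverage_and_identity_thresholds_are_strict(
        self, reference, coverage, identity, called
    ):
        contig = self._fixture(reference, coverage, identity)
        call = assign_constant(contig, reference.get("IGH", "C"))
        assert (call is not None) == called


def test_on_target_classification(reference):
    c_segments = [s for s in reference.segments.values() if s.segment_type == "C"]
    c_segments.sort(key=lambda s: s.segment_id)
    rng = np.random.default_rng(12)
    receptor, _ = recombine_vdj(reference, "TRB", "TRBV1", "TRBJ1", 9, c="TRBC", seed=13)
    on_reads = [
        (f"on{i}", build_read(receptor, "A" * 16, "C" * 10, ("fwd", "rev")[i % 2]))
        for i in range(14)
    ]
    off_reads = [
        (f"off{i}", build_read(random_seq(rng, 800), "A" * 16, "C" * 10, "fwd"))
        for i in range(6)
    ]
    fraction_on, _ = classify_on_target(on_reads, c_segments)
    fraction_off, _ = classify_on_target(off_reads, c_segments)
    fraction_mix, _ = classify_on_target(on_reads + off_reads, c_segments)
    assert fraction_on == 1.0
    assert fraction_off == 0.0
    assert fraction_mix == pytest.approx(0.7)
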