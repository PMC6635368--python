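"""Chain filtering/selection, clonotypes, invariant flags, UA, networks,
mutation summaries, and clone-expression similarity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from longvdj.annotate import VDJAnnotation, annotate_contig
from longvdj.params import PipelineParams
from longvdj.repertoire import (
    build_clone_network,
    clonal_expression_similarity,
    define_clonotypes,
    filter_chains,
    find_expanded_and_shared,
    hamming,
    infer_ua,
    mutation_summary,
    nearest_neighbor_edges,
    select_cell_chains,
)
from longvdj.seqs import translate
from longvdj.simulate import apply_shm_viable, recombine_vdj


def make_ann(locus, v="V1", j="J1", cdr3="TGTGCAGCATGG", v_mutations=0,
             n_reads=10, productive=True, cell_id="cell", isotype=None, form="none"):
    return VDJAnnotation(
        contig_id=f"{locus}|{v}|{j}|{cdr3}|{n_reads}",
        cell_id=cell_id, locus=locus, v_call=v, j_call=j,
        c_call=isotype, c_form=form,
        cdr3_nt=cdr3, cdr3_aa=translate(cdr3), productive=productive,
        v_mutations=v_mutations, v_aligned_length=288, n_reads=n_reads,
    )


class TestFiltering:
    def test_mutation_thresholds_are_strictly_greater(self, params):
        anns = [
            make_ann("TRB", v_mutations=5),
            make_ann("TRB", v_mutations=6),
            make_ann("IGH", v_mutations=40),
            make_ann("IGH", v_mutations=41),
        ]
        kept = {a.contig_id for a in filter_chains(anns, params)}
        assert kept == {anns[0].contig_id, anns[2].contig_id}

    def test_nonproductive_chains_are_removed_even_unmutated(self, params):
        assert filter_chains([make_ann("TRA", productive=False)], params) == []


class TestSelection:
    def test_tcr_prefers_least_mutated_within_a_vj_group(self):
        a = make_ann("TRB", cdr3="TGTGCAGCATGG", v_mutations=0, n_reads=5)
        b = make_ann("TRB", cdr3="TGTGCAGCCTGG", v_mutations=2, n_reads=50)
        cell = select_cell_chains("c", [a, b])
        assert cell.primary("TRB").annotation is a

    def test_bcr_prefers_greatest_read_support(self):
        a = make_ann("IGH", cdr3="TGTGCAGCATGG", n_reads=40, v_mutations=9)
        b = make_ann("IGH", cdr3="TGTGCAGCCTGG", n_reads=12, v_mutations=0)
        cell = select_cell_chains("c", [a, b])
        assert cell.primary("IGH").annotation is a

    def test_pairing_status_labels(self):
        assert select_cell_chains("c", [make_ann("TRA")]).pairing_status["TCRab"] == "alpha_only"
        assert select_cell_chains("c", [make_ann("TRB")]).pairing_status["TCRab"] == "beta_only"
        both = select_cell_chains("c", [make_ann("TRA"), make_ann("TRB")])
        assert both.pairing_status["TCRab"] == "paired"
        gd = select_cell_chains("c", [make_ann("TRG"), make_ann("TRD")])
        assert gd.pairing_status["TCRgd"] == "gd_paired"
        bcr = select_cell_chains("c", [make_ann("IGH"), make_ann("IGK")])
        assert bcr.pairing_status["BCR"] == "paired"

    def test_secondary_chain_is_retained(self):
        a = make_ann("TRA", v="V1", cdr3="TGTGCAGCATGG", n_reads=30)
        b = make_ann("TRA", v="V2", cdr3="TGTGCCGCATGG", n_reads=10)
        cell = select_cell_chains("c", [a, b])
        ranks = {c.rank: c.annotation for c in cell.chains["TRA"]}
        assert ranks["primary"] is a and ranks["secondary"] is b

    def test_selection_is_order_independent(self):
        anns = [
            make_ann("TRB", v="V1", cdr3="TGTGCAGCATGG", v_mutations=1, n_reads=7),
            make_ann("TRB", v="V1", cdr3="TGTGCAGCCTGG", v_mutations=1, n_reads=7),
            make_ann("TRB", v="V2", cdr3="TGTCCAGCATGG", v_mutations=0, n_reads=9),
            make_ann("TRB", v="V1", cdr3="TGTGCAGCGTGG", v_mutations=3, n_reads=20),
        ]
        reference_choice = None
        for perm in itertools.permutations(anns):
            cell = select_cell_chains("c", list(perm))
            chosen = tuple(c.annotation.contig_id for c in cell.chains["TRB"])
            reference_choice = reference_choice or chosen
            assert chosen == reference_choice


class TestClonotypes:
    def test_tcr_requires_exact_cdr3_amino_acids(self, params):
        cells = [
            select_cell_chains("t1", [make_ann("TRA"), make_ann("TRB", cdr3="TGTGCATGGGCA")]),
            select_cell_chains("t2", [make_ann("TRA"), make_ann("TRB", cdr3="TGTGCATGGGCT")]),
            select_cell_chains("t3", [make_ann("TRA"), make_ann("TRB", cdr3="TGTGCATGGCCT")]),
        ]
        clones = define_clonotypes(cells, "TCRab", params)
        sizes = sorted(c.size for c in clones)
        assert sizes == [1, 2]  # synonymous nt difference co-clusters

    @pytest.mark.parametrize("cdr3_b,together", [("AACCGGTTAT", True), ("AACCGGTTGT", False)])
    def test_bcr_90pct_nucleotide_rule(self, params, cdr3_b, together):
        def bcell(cid, cdr3_h):
            return select_cell_chains(cid, [make_ann("IGH", cdr3=cdr3_h), make_ann("IGL")])

        clones = define_clonotypes(
            [bcell("b1", "AACCGGTTAC"), bcell("b2", cdr3_b)], "BCR", params
        )
        assert (len(clones) == 1) == together

    def test_unequal_cdr3_lengths_never_cocluster(self, params):
        def bcell(cid, cdr3_h):
            return select_cell_chains(cid, [make_ann("IGH", cdr3=cdr3_h), make_ann("IGL")])

        clones = define_clonotypes(
            [bcell("b1", "AACCGGTTAC"), bcell("b2", "AACCGGTTACGGG")], "BCR", params
        )
        assert len(clones) == 2

    def test_single_chain_mode_keys_on_one_locus(self, params):
        cells = [
            select_cell_chains("c1", [make_ann("TRB", cdr3="TGTGCATGGGCA")]),
            select_cell_chains("c2", [make_ann("TRB", cdr3="TGTGCATGGGCA"),
                                      make_ann("TRA")]),
        ]
        clones = define_clonotypes(cells, "single_chain", params, single_chain_locus="TRB")
        assert len(clones) == 1 and clones[0].size == 2

    def test_expanded_and_shared_annotations(self, params):
        cells = [
            select_cell_chains("c1", [make_ann("TRA"), make_ann("TRB")], sample_id="lymph_node"),
            select_cell_chains("c2", [make_ann("TRA"), make_ann("TRB")], sample_id="tumor"),
            select_cell_chains("c3", [make_ann("TRA"), make_ann("TRB", cdr3="TGTCCATGGGCA")],
                               sample_id="tumor"),
        ]
        clones = define_clonotypes(cells, "TCRab", params)
        expanded = [c for c in clones if c.expanded]
        assert len(expanded) == 1
        assert expanded[0].shared_tissues == {"lymph_node", "tumor"}
        singleton = [c for c in clones if not c.expanded][0]
        assert singleton.size == 1

    def test_seeded_shared_clones_are_recovered_exactly(self, params):
        cells = []
        for k in range(3):  # three cross-tissue clones
            for tissue in ("lymph_node", "tumor"):
                cdr3 = "TGTGCATGG" + ("GCA", "TTA", "CGT")[k]  # distinct aa per clone
                cells.append(
                    select_cell_chains(
                        f"clone{k}-{tissue}",
                        [make_ann("TRA"), make_ann("TRB", cdr3=cdr3)],
                        sample_id=tissue,
                    )
                )
        for i in range(4):  # singleton background
            cells.append(
                select_cell_chains(
                    f"s{i}",
                    [make_ann("TRA"), make_ann("TRB", v="V9", cdr3="TGT" + "GCA" * i + "TGG")],
                    sample_id="tumor",
                )
            )
        clones = find_expanded_and_shared(define_clonotypes(cells, "TCRab", params))
        shared = [c for c in clones if len(c.shared_tissues) > 1]
        assert len(shared) == 3


class TestInvariantFlags:
    @pytest.mark.parametrize(
        "v,j,expected",
        [
            ("TRAV1-2", "TRAJ33", {"MAIT"}),
            ("TRAV1-2", "TRAJ20", {"MAIT"}),
            ("TRAV1-2", "TRAJ12", {"MAIT"}),
            ("TRAV1-2", "TRAJ9", {"GEM"}),
            ("TRAV8-4", "TRAJ33", set()),
            ("TRAV1-2", "TRAJ3", set()),
        ],
    )
    def test_mait_and_gem_gene_usage(self, v, j, expected):
        cell = select_cell_chains("c", [make_ann("TRA", v=v, j=j)])
        assert cell.invariant_flags == frozenset(expected)


class TestHamming:
    def test_examples(self):
        assert hamming("QTWGTGFWV", "QTWGTGFWV") == 0
        assert hamming("AAA", "AAT") == 1
        with pytest.raises(ValueError):
            hamming("AA", "AAA")

    def test_matches_position_loop_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=n))
            assert hamming(a, b) == sum(1 for i in range(n) if a[i] != b[i])


def _clone_family(reference, seed, n_members=4, shm=(0, 8)):
    rng = np.random.default_rng(seed)
    params = PipelineParams()
    transcripts = {}
    for locus, c_id in (("IGH", "IGHM-secreted"), ("IGL", "IGLC")):
        transcripts[locus] = recombine_vdj(
            reference, locus, reference.get(locus, "V")[0].gene_name,
            reference.get(locus, "J")[0].gene_name, 9, c=c_id, seed=rng,
        )
    cells = []
    for i in range(n_members):
        anns = []
        for locus in ("IGH", "IGL"):
            transcript, truth = transcripts[locus]
            v_seg = reference.by_gene(locus, "V", truth.v_call)
            anchor = (v_seg.v_anchor, v_seg.v_anchor + 3)
            n_mut = int(rng.integers(shm[0], shm[1] + 1))
            mutated, _ = apply_shm_viable(
                transcript, n_mut, truth.v_interval, seed=rng, exclude=(anchor,)
            )
            anns.append(annotate_contig(mutated, reference, cell_id=f"m{i}"))
        cells.append(select_cell_chains(f"m{i}", filter_chains(anns, params)))
    return transcripts, cells


class TestUnmutatedAncestor:
    def test_zero_shm_members_equal_their_ua(self, reference):
        transcripts, cells = _clone_family(reference, seed=21, n_members=3, shm=(0, 0))
        heavy = [c.primary("IGH") for c in cells]
        ua = infer_ua(heavy, reference)
        assert all(h.annotation.vdj_nt == ua for h in heavy)

    def test_single_member_ua_reverts_exactly_its_mutations(self, reference):
        transcript, truth = recombine_vdj(
            reference, "IGH", "IGHV2", "IGHJ2", 12, c="IGHA1-secreted", seed=22
        )
        v_seg = reference.by_gene("IGH", "V", "IGHV2")
        mutated, positions = apply_shm_viable(
            transcript, 2, truth.v_interval, seed=23,
            exclude=((v_seg.v_anchor, v_seg.v_anchor + 3),),
        )
        ann = annotate_contig(mutated, reference, cell_id="m0")
        cell = select_cell_chains("m0", [ann])
        ua = infer_ua([cell.primary("IGH")], reference)
        member = cell.primary("IGH").annotation.vdj_nt
        assert len(ua) == len(member)
        diffs = [i for i, (x, y) in enumerate(zip(ua, member)) if x != y]
        assert diffs == [p for p, _, _ in positions]

    def test_ua_recovers_the_simulated_ancestor(self, reference):
        recovered = 0
        for seed in range(24, 34):
            transcripts, cells = _clone_family(reference, seed=seed)
            heavy = [c.primary("IGH") for c in cells]
            if any(h is None for h in heavy):
                continue
            transcript, truth = transcripts["IGH"]
            j_len = len(reference.by_gene("IGH", "J", truth.j_call).sequence)
            ancestor = transcript[: truth.v_interval[1] + len(truth.junction_nt) + j_len]
            recovered += infer_ua(heavy, reference) == ancestor
        assert recovered >= 9

    def test_discordant_vj_calls_raise(self, reference):
        _, cells_a = _clone_family(reference, seed=40, n_members=1, shm=(0, 0))
        transcript, _ = recombine_vdj(
            reference, "IGH", "IGHV3", "IGHJ1", 9, c="IGHM-secreted", seed=41
        )
        ann = annotate_contig(transcript, reference, cell_id="x")
        other = select_cell_chains("x", [ann])
        with pytest.raises(ValueError, match="discordant"):
            infer_ua([cells_a[0].primary("IGH"), other.primary("IGH")], reference)


class TestCloneNetwork:
    def test_identical_cells_collapse_to_one_node_plus_ua(self, reference):
        transcripts, cells = _clone_family(reference, seed=35, n_members=3, shm=(2, 2))
        # force identical mutations by reusing one cell's chains
        cells = [cells[0]] * 3
        networks = build_clone_network(cells, reference)
        assert len(networks) == 1
        network = networks[0]
        assert len(network.nodes) == 2  # the shared sequence + the UA
        assert len(network.edges) == 1
        assert network.nodes[network.ua_node] == 0

    def test_edges_match_brute_force_on_random_nodes(self):
        rng = np.random.default_rng(36)
        nodes = {
            "".join(rng.choice(list("ACDEFGHIKL"), size=12)): int(rng.integers(1, 4))
            for _ in range(50)
        }
        edges = nearest_neighbor_edges(nodes)
        expected = set()
        seqs = sorted(nodes)
        for seq in seqs:
            dmin = min(hamming(seq, o) for o in seqs if o != seq)
            for other in seqs:
                if other != seq and hamming(seq, other) == dmin:
                    expected.add((min(seq, other), max(seq, other), dmin))
        assert set(edges) == expected

    def test_star_family_descendants_neighbor_the_ancestor(self):
        ancestor = "MKTAYIAKQR"
        nodes = {ancestor: 5}
        for i, aa in enumerate("CDEF"):
            nodes[ancestor[:i] + aa + ancestor[i + 1 :]] = 1
        edges = nearest_neighbor_edges(nodes, ua=ancestor)
        for node in nodes:
            if node == ancestor:
                continue
            assert (min(node, ancestor), max(node, ancestor), 1) in edges


class TestSummaries:
    def test_mutation_summary_mean(self):
        cells = [
            select_cell_chains(f"c{i}", [make_ann("IGH", v_mutations=m, isotype="IGHM",
                                                  form="secreted", cell_id=f"c{i}")])
            for i, m in enumerate((0, 0, 9))
        ]
        for cell, rate in zip(cells, (0.0, 0.0, 100 * 9 / 288)):
            assert cell.primary("IGH").annotation.v_mutation_rate == pytest.approx(rate)
        summary, crosstab = mutation_summary(cells)
        assert summary.loc[0, "mean"] == pytest.approx(100 * 3 / 288)
        assert crosstab.loc["IGHM", "secreted"] == 3

    def test_jaccard_extremes_and_paired_test(self):
        rng = np.random.default_rng(37)
        genes = [f"g{i}" for i in range(400)]
        n_pairs = 15
        rows = {}
        clone_pairs, control_pairs = [], []
        for k in range(n_pairs):
            shared_clone = rng.permutation(400)
            base = np.zeros(400)
            # clone pairs share 80% of their top-50 genes, controls 40%
            for label, overlap in (("clone", 0.8), ("ctrl", 0.4)):
                top_a = list(shared_clone[:50])
                n_common = int(50 * overlap)
                top_b = top_a[:n_common] + list(shared_clone[50 : 100 - n_common])
                for suffix, top in (("a", top_a), ("b", top_b)):
                    expr = base.copy()
                    expr[top] = rng.uniform(10, 100, size=50)
                    rows[f"{label}{k}{suffix}"] = expr
                if label == "clone":
                    clone_pairs.append((f"{label}{k}a", f"{label}{k}b"))
                else:
                    control_pairs.append((f"{label}{k}a", f"{label}{k}b"))
        expression = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
        # identical and disjoint extremes
        clonal, control, stat, p = clonal_expression_similarity(
            [("clone0a", "clone0a")], expression, [("clone0a", "clone0b")], top_n=50
        )
        assert clonal[0] == 1.0
        clonal, _, _, _ = clonal_expression_similarity(
            [("clone0a", "ctrl1a")], expression, [("clone0a", "clone0b")], top_n=50
        )
        assert clonal[0] < 0.2
        # power at the stated effect size
        clonal, control, stat, p = clonal_expression_similarity(
            clone_pairs, expression, control_pairs, top_n=50
        )
        assert np.mean(clonal) > np.mean(control)
        assert p < 0.05
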