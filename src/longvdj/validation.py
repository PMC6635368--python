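"""Self-contained validation experiments over the whole pipeline.

Each function runs one property-based experiment on simulated, ground-truthed
data and returns plain numbers: closed-form barcode recovery, exhaustive
alignment-oracle agreement, the error-free identity limit, consensus recovery
and depth titration under the default error model, somatic-hypermutation
precision/recall, the filtering/threshold boundary behavior, unmutated-ancestor
and clonal-network correctness, clonotype rules, and byte-level run
determinism. The test suite asserts on these numbers; ``scripts/acceptance.py``
reports them.
"""

from __future__ import annotations

import filecmp
import os
import tempfile

import numpy as np

from . import annotate as _annotate
from . import consensus as _consensus
from . import demux as _demux
from . import repertoire as _repertoire
from . import simulate as _simulate
from .align import ScoringParams, local_align
from .annotate import VDJAnnotation, annotate_contig, assign_constant
from .params import PipelineParams
from .pipeline import depth_titration, run_pipeline
from .refdata import make_synthetic_germline
from .repertoire import nearest_neighbor_edges
from .simulate import ErrorProfile, SimulateConfig, apply_shm_viable, recombine_vdj

# ------------------------------------------------------------------ oracle


def gotoh_local_score(a: str, b: str, scoring: ScoringParams = ScoringParams()) -> int:
    """Reference optimal local alignment score by explicit Gotoh DP.

    Independent of :func:`longvdj.align.local_align` (pure-Python three-state
    dynamic program; the first gap base costs gap_open, later ones gap_extend).
    Quadratic and meant for short sequences in validation only.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in a match column
    e = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    f = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i - 1][j] + scoring.gap_open, e[i - 1][j] + scoring.gap_extend)
            f[i][j] = max(h[i][j - 1] + scoring.gap_open, f[i][j - 1] + scoring.gap_extend)
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return int(best)


def alignment_oracle_check(seed: int, n_pairs: int = 200, max_len: int = 12) -> dict:
    """Fraction of random short pairs where local_align's score equals the
    independent Gotoh oracle (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, max_len + 1)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, max_len + 1)))
        agree += local_align(a, b).score == gotoh_local_score(a, b)
    return {"agreement": agree / n_pairs, "n": n_pairs}


# ------------------------------------------------------------------- demux


def barcode_recovery_experiment(
    seed: int, n_reads: int = 2000, sub_rate: float = 0.01
) -> dict:
    """Assigned fraction under substitution-only errors vs the closed form
    (1 - e)^16 for exact matching of a 16-nt barcode."""
    reference = make_synthetic_germline(seed=1)
    n_cells, reads_per_cell = 40, n_reads // 40
    with tempfile.TemporaryDirectory() as tmp:
        run = _simulate.simulate_run(
            reference,
            n_cells=n_cells,
            reads_per_cell=reads_per_cell,
            profile=ErrorProfile(sub_rate, 0.0, 0.0),
            config=SimulateConfig(chimera_rate=0.0),
            seed=seed,
            out_dir=tmp,
        )
        _, stats = _demux.demultiplex_run(run.fastq_path, run.whitelist_path)
    expected = (1.0 - sub_rate) ** 16
    fraction = stats.assigned_fraction()
    se = (expected * (1 - expected) / stats.total) ** 0.5
    return {
        "assigned_fraction": fraction,
        "expected": expected,
        "standard_error": se,
        "n": stats.total,
    }


# --------------------------------------------------------- identity limit


def _recovery_counts(result) -> dict:
    """Pairing and exact-CDR3 recovery of a pipeline run against its truth."""
    found = {cell.cell_id: cell for cell in result.cells}
    n_t = n_b = t_paired = b_paired = n_chains = n_exact = 0
    n_cells_any = n_cells_total = 0
    for barcode, truth_cell in result.truth.cells.items():
        cell = found.get(barcode)
        if truth_cell.cell_type == "T":
            n_t += 1
            t_paired += cell is not None and cell.pairing_status["TCRab"] == "paired"
        elif truth_cell.cell_type == "B":
            n_b += 1
            b_paired += cell is not None and cell.pairing_status["BCR"] == "paired"
        if not truth_cell.chains:
            continue
        n_cells_total += 1
        cell_hit = False
        for chain in truth_cell.chains:
            n_chains += 1
            primary = cell.primary(chain.locus) if cell else None
            if primary is not None and primary.annotation.cdr3_nt == chain.cdr3_nt:
                n_exact += 1
                cell_hit = True
        n_cells_any += cell_hit
    return {
        "n_t": n_t, "t_paired": t_paired,
        "n_b": n_b, "b_paired": b_paired,
        "n_chains": n_chains, "chains_exact": n_exact,
        "n_receptor_cells": n_cells_total, "cells_with_exact_cdr3": n_cells_any,
    }


def identity_limit_experiment(seed: int, n_cells: int = 20) -> dict:
    """Error-free simulation: every receptor chain should be recovered with an
    exact CDR3 and every T/B cell correctly paired."""
    with tempfile.TemporaryDirectory() as tmp:
        result = run_pipeline(
            {
                "out_dir": os.path.join(tmp, "run"),
                "seed": seed,
                "simulate": {
                    "n_cells": n_cells, "reads_per_cell": 40,
                    "sub_rate": 0.0, "ins_rate": 0.0, "del_rate": 0.0,
                    "chimera_rate": 0.0,
                },
            }
        )
        counts = _recovery_counts(result)
    return {
        "t_paired_pct": 100.0 * counts["t_paired"] / max(1, counts["n_t"]),
        "b_paired_pct": 100.0 * counts["b_paired"] / max(1, counts["n_b"]),
        "cdr3_exact_pct": 100.0 * counts["chains_exact"] / max(1, counts["n_chains"]),
        "n": n_cells,
    }


# ------------------------------------------------- consensus under errors


def consensus_recovery_experiment(
    seed: int, n_cells: int = 50, reads_per_cell: int = 100
) -> dict:
    """Default error profile (10% total): fraction of receptor-bearing cells
    yielding a contig whose annotated CDR3 matches truth exactly."""
    with tempfile.TemporaryDirectory() as tmp:
        result = run_pipeline(
            {
                "out_dir": os.path.join(tmp, "run"),
                "seed": seed,
                "simulate": {
                    "n_cells": n_cells,
                    "reads_per_cell": reads_per_cell,
                    "chimera_rate": 0.0,
                },
            }
        )
        counts = _recovery_counts(result)
    return {
        "cell_recovery_pct": 100.0
        * counts["cells_with_exact_cdr3"]
        / max(1, counts["n_receptor_cells"]),
        "chain_recovery_pct": 100.0 * counts["chains_exact"] / max(1, counts["n_chains"]),
        "n": counts["n_receptor_cells"],
    }


def depth_titration_experiment(
    seed: int,
    n_cells: int = 12,
    depths: tuple[int, ...] = (1000, 500, 250, 100, 50),
    raw_reads_per_cell: int = 5600,
) -> dict:
    """Chain recovery and CDR3 accuracy vs per-cell (demultiplexed) read depth.

    Cells are simulated with enough raw reads that every cell retains at least
    max(depths) demultiplexed reads, mirroring a titration run on cells with
    >=1000 reads. Returns the per-depth table plus the monotonicity slope and
    the accuracy gap between the deepest and shallowest depths.
    """
    reference = make_synthetic_germline(seed=1)
    params = PipelineParams()
    with tempfile.TemporaryDirectory() as tmp:
        run = _simulate.simulate_run(
            reference,
            n_cells=n_cells,
            reads_per_cell=raw_reads_per_cell,
            config=SimulateConfig(t_fraction=0.5, b_fraction=0.5, chimera_rate=0.0),
            seed=seed,
            out_dir=tmp,
        )
        groups, _ = _demux.demultiplex_run(run.fastq_path, run.whitelist_path, params)
    table = depth_titration(reference, groups, run.truth, depths=depths, params=params, seed=seed)
    table = table.sort_values("depth").reset_index(drop=True)
    slope = float(np.polyfit(table["depth"], table["recovery"], 1)[0])
    gap = float(
        abs(
            table.loc[table["depth"].idxmax(), "cdr3_accuracy"]
            - table.loc[table["depth"].idxmin(), "cdr3_accuracy"]
        )
    )
    return {
        "table": table,
        "recovery_slope": slope,
        "accuracy_gap_pp": 100.0 * gap,
        "min_depth_accuracy_pct": 100.0 * float(table["cdr3_accuracy"].iloc[0]),
        "max_depth_accuracy_pct": 100.0 * float(table["cdr3_accuracy"].iloc[-1]),
        "n": n_cells,
    }


# ------------------------------------------------------------ SHM recovery


def shm_recovery_experiment(
    seed: int, n_cells: int = 30, reads_per_cell: int = 500
) -> dict:
    """Precision/recall of per-cell V-region mutation calls against truth.

    B cells carry 0-15 substitutions per chain; reads are emitted at the
    default error profile with enough raw reads for ~100x demultiplexed
    coverage. Detected mutation positions (germline V coordinates) are compared
    against the simulated truth positions.
    """
    with tempfile.TemporaryDirectory() as tmp:
        result = run_pipeline(
            {
                "out_dir": os.path.join(tmp, "run"),
                "seed": seed,
                "simulate": {
                    "n_cells": n_cells,
                    "reads_per_cell": reads_per_cell,
                    "t_fraction": 0.0,
                    "b_fraction": 1.0,
                    "chimera_rate": 0.0,
                },
            }
        )
        found = {cell.cell_id: cell for cell in result.cells}
        tp = fp = fn = 0
        n_chains = 0
        corrected_recall_violations = 0
        for barcode, truth_cell in result.truth.cells.items():
            cell = found.get(barcode)
            for chain in truth_cell.chains:
                primary = cell.primary(chain.locus) if cell else None
                if primary is None:
                    continue
                n_chains += 1
                truth_pos = {p for p, _, _ in chain.shm_positions}
                detected = set(primary.annotation.v_mutation_ref_positions)
                tp += len(truth_pos & detected)
                fp += len(detected - truth_pos)
                fn += len(truth_pos - detected)
                if primary.annotation.indel_corrected and truth_pos - detected:
                    corrected_recall_violations += 1
    precision = 100.0 * tp / max(1, tp + fp)
    recall = 100.0 * tp / max(1, tp + fn)
    return {
        "precision_pct": precision,
        "recall_pct": recall,
        "n_chains": n_chains,
        "corrected_chains_missing_truth": corrected_recall_violations,
        "n": n_cells,
    }


# ------------------------------------------------------ threshold fixtures


def _fixture_annotation(locus, v_mutations, productive=True, n_reads=10, cdr3="TGTGCATGG"):
    from .seqs import translate

    return VDJAnnotation(
        contig_id=f"{locus}-{v_mutations}",
        cell_id="cell",
        locus=locus,
        v_call=f"{locus}V1",
        j_call=f"{locus}J1",
        cdr3_nt=cdr3,
        cdr3_aa=translate(cdr3),
        productive=productive,
        v_mutations=v_mutations,
        v_aligned_length=288,
        n_reads=n_reads,
    )


def threshold_boundary_checks() -> dict:
    """Boundary behavior of the mutation filters and constant-region calling.

    TCR chains at 5/6 and BCR chains at 40/41 V mutations (strictly-greater
    removal), and constant-region fixtures at coverage 0.94/0.96 crossed with
    identity 0.89/0.91 (only the 0.96/0.91 combination may be called).
    """
    params = PipelineParams()
    checks: list[bool] = []

    anns = [
        _fixture_annotation("TRB", 5),
        _fixture_annotation("TRB", 6),
        _fixture_annotation("IGH", 40),
        _fixture_annotation("IGH", 41),
        _fixture_annotation("TRA", 0, productive=False),
    ]
    kept = _repertoire.filter_chains(anns, params)
    kept_ids = {a.contig_id for a in kept}
    checks.append(kept_ids == {"TRB-5", "IGH-40"})

    reference = make_synthetic_germline(seed=1)
    c_seg = reference.segments["IGHM-secreted"]
    c_candidates = reference.get("IGH", "C")
    rng = np.random.default_rng(0)
    for coverage in (0.94, 0.96):
        for identity in (0.89, 0.91):
            span = int(round(coverage * len(c_seg.sequence)))
            n_sub = int(round((1.0 - identity) * span))
            seq = list(c_seg.sequence[:span])
            # evenly spaced substitutions away from the alignment ends
            positions = np.linspace(10, span - 11, n_sub).astype(int)
            for pos in positions:
                options = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = options[rng.integers(0, 3)]
            call = assign_constant(
                "".join(seq), c_candidates,
                min_coverage=params.c_min_coverage, min_identity=params.c_min_identity,
            )
            expected_called = coverage > 0.95 and identity > 0.90
            called_right = (
                call is not None
                and call[0].segment_id == "IGHM-secreted"
                if expected_called
                else call is None
            )
            checks.append(bool(called_right))

    return {"pass_fraction": sum(checks) / len(checks), "n": len(checks)}


# ------------------------------------------------------- UA and networks


def _simulate_clone_family(reference, rng, n_members: int, max_shm: int = 15):
    """One B-cell clone family: shared ancestor, independent per-cell SHM."""
    params = PipelineParams()
    loci = (("IGH", "IGHM-secreted"), ("IGL", "IGLC"))
    ancestors = {}
    cells = []
    choices = {}
    for locus, c_id in loci:
        v = reference.get(locus, "V")[int(rng.integers(0, 4))].gene_name
        j = reference.get(locus, "J")[int(rng.integers(0, 3))].gene_name
        transcript, truth = recombine_vdj(
            reference, locus, v, j, int(rng.integers(0, 8)) * 3, c=c_id, seed=rng
        )
        ancestors[locus] = (transcript, truth)
        choices[locus] = (v, j)
    for i in range(n_members):
        annotations = []
        for locus, _ in loci:
            transcript, truth = ancestors[locus]
            v_seg = reference.by_gene(locus, "V", choices[locus][0])
            anchor = (v_seg.v_anchor, v_seg.v_anchor + 3)
            mutated, _ = apply_shm_viable(
                transcript, int(rng.integers(0, max_shm + 1)), truth.v_interval,
                seed=rng, exclude=(anchor,),
            )
            annotations.append(annotate_contig(mutated, reference, cell_id=f"m{i}"))
        kept = _repertoire.filter_chains(annotations, params)
        cells.append(_repertoire.select_cell_chains(f"m{i}", kept))
    return ancestors, cells


def ua_network_experiment(seed: int, n_families: int = 100) -> dict:
    """Unmutated-ancestor recovery and network-edge correctness over many
    simulated clone families (>=3 members, <=15 substitutions per chain)."""
    reference = make_synthetic_germline(seed=1)
    rng = np.random.default_rng(seed)
    ua_exact = 0
    families_scored = 0
    network_instances = network_agree = 0
    for _ in range(n_families):
        ancestors, cells = _simulate_clone_family(
            reference, rng, n_members=int(rng.integers(3, 7))
        )
        heavy = [c.primary("IGH") for c in cells]
        light = [c.primary("IGL") for c in cells]
        if any(h is None or l is None for h, l in zip(heavy, light)):
            continue  # a chain drawn non-productive despite redraws: skip family
        families_scored += 1
        ua_h = _repertoire.infer_ua(heavy, reference)
        ua_l = _repertoire.infer_ua(light, reference)

        def true_vdj(locus):
            transcript, truth = ancestors[locus]
            v_end = truth.v_interval[1]
            j_len = len(reference.by_gene(locus, "J", truth.j_call).sequence)
            return transcript[: v_end + len(truth.junction_nt) + j_len]

        ua_exact += ua_h == true_vdj("IGH") and ua_l == true_vdj("IGL")

        networks = _repertoire.build_clone_network(cells, reference)
        for network in networks:
            network_instances += 1
            expected = _brute_force_min_edges(network.nodes)
            network_agree += sorted(network.edges) == expected
    return {
        "ua_recovery_pct": 100.0 * ua_exact / max(1, families_scored),
        "network_agreement": network_agree / max(1, network_instances),
        "n": families_scored,
        "n_networks": network_instances,
    }


def _brute_force_min_edges(nodes: dict[str, int]):
    """Independent nearest-neighbor edge oracle: full pairwise distance scan."""
    seqs = sorted(nodes)
    edges = set()
    for seq in seqs:
        dists = []
        for other in seqs:
            if other == seq or len(other) != len(seq):
                continue
            dists.append((sum(x != y for x, y in zip(seq, other)), other))
        if not dists:
            continue
        dmin = min(d for d, _ in dists)
        for d, other in dists:
            if d == dmin:
                edges.add((min(seq, other), max(seq, other), d))
    return sorted(edges)


# -------------------------------------------------------- clonotype rules


def clonotype_rule_checks() -> dict:
    """B-cell 90%-identity CDR3 clustering, T-cell exact-match keys, and
    invariant-TCR (MAIT/GEM) flags on constructed fixtures."""
    checks: list[bool] = []
    params = PipelineParams()

    def bcr_cell(cell_id, cdr3_h, cdr3_l="TGTGCAGCATGG"):
        anns = [
            _fixture_annotation("IGH", 0, cdr3=cdr3_h),
            _fixture_annotation("IGL", 0, cdr3=cdr3_l),
        ]
        return _repertoire.select_cell_chains(cell_id, anns)

    base = "AACCGGTTAC"  # length 10
    one_off = "AACCGGTTAT"  # identity 0.90: co-clusters (inclusive threshold)
    two_off = "AACCGGTTGT"  # identity 0.80: separates
    pair_90 = _repertoire.define_clonotypes(
        [bcr_cell("b1", base), bcr_cell("b2", one_off)], "BCR", params
    )
    checks.append(len(pair_90) == 1 and pair_90[0].size == 2)
    pair_80 = _repertoire.define_clonotypes(
        [bcr_cell("b1", base), bcr_cell("b3", two_off)], "BCR", params
    )
    checks.append(len(pair_80) == 2)

    def t_cell(cell_id, cdr3_a, cdr3_b="TGTGCAGCATGG"):
        anns = [
            _fixture_annotation("TRA", 0, cdr3=cdr3_a),
            _fixture_annotation("TRB", 0, cdr3=cdr3_b),
        ]
        return _repertoire.select_cell_chains(cell_id, anns)

    # synonymous nucleotide difference, identical amino acids -> same clone;
    # different amino acid -> different clone
    t_cells = [
        t_cell("t1", "TGTGCATGGGCA"),
        t_cell("t2", "TGTGCATGGGCT"),
        t_cell("t3", "TGTGCATGGCCA"),
    ]
    t_clones = _repertoire.define_clonotypes(t_cells, "TCRab", params)
    t_assignment = {}
    for clone in t_clones:
        for cid, _ in clone.member_cells:
            t_assignment[cid] = clone.clonotype_id
    checks.append(t_assignment["t1"] == t_assignment["t2"])
    checks.append(t_assignment["t1"] != t_assignment["t3"])

    def tra_cell(cell_id, v_call, j_call):
        ann = _fixture_annotation("TRA", 0)
        ann.v_call, ann.j_call = v_call, j_call
        return _repertoire.select_cell_chains(cell_id, [ann])

    checks.append(tra_cell("m", "TRAV1-2", "TRAJ33").invariant_flags == {"MAIT"})
    checks.append(tra_cell("m", "TRAV1-2", "TRAJ20").invariant_flags == {"MAIT"})
    checks.append(tra_cell("m", "TRAV1-2", "TRAJ12").invariant_flags == {"MAIT"})
    checks.append(tra_cell("g", "TRAV1-2", "TRAJ9").invariant_flags == {"GEM"})
    checks.append(tra_cell("x", "TRAV8-4", "TRAJ33").invariant_flags == frozenset())

    return {"pass_fraction": sum(checks) / len(checks), "n": len(checks)}


# ------------------------------------------------------------ determinism


def determinism_experiment(seed: int, n_cells: int = 10, reads_per_cell: int = 40) -> dict:
    """Two identically seeded end-to-end runs must produce byte-identical
    output trees."""
    config = {
        "seed": seed,
        "simulate": {"n_cells": n_cells, "reads_per_cell": reads_per_cell},
    }
    with tempfile.TemporaryDirectory() as tmp:
        dir_a, dir_b = os.path.join(tmp, "a"), os.path.join(tmp, "b")
        run_pipeline({**config, "out_dir": dir_a})
        run_pipeline({**config, "out_dir": dir_b})
        names_a, names_b = sorted(os.listdir(dir_a)), sorted(os.listdir(dir_b))
        identical = names_a == names_b and all(
            filecmp.cmp(os.path.join(dir_a, n), os.path.join(dir_b, n), shallow=False)
            for n in names_a
        )
    return {"identical": 1.0 if identical else 0.0, "n_files": len(names_a)}
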