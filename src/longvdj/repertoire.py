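"""Cell-level receptor assignment, clonotypes, and clonal networks.

Implements the filtering and tie-break rules on annotated chains:
non-productive chains are removed, as are BCR chains with more than 40 and TCR
chains with more than five V-segment mutations (boundary values kept). Within
a cell, chains sharing V and J but differing in CDR3 collapse to the
least-mutated (TCR) or best-supported (BCR) candidate; the highest-read-count
survivor per locus is the cell's primary chain, the next distinct survivor its
secondary.

Clonotypes: T cells group on exact (V, J, CDR3 amino acid) keys per chain;
B cells on shared V/J with >=90% CDR3 nucleotide identity (Hamming-based on
equal-length CDR3s, single-linkage). Expanded clones are those with more than
one member cell; tissue sharing is the set of sample labels among members.
Invariant T cells are flagged from gene usage (MAIT: TRAV1-2 with
TRAJ33/20/12; GEM: TRAV1-2 with TRAJ9).

B-cell clonal evolution: the unmutated ancestor (UA) of a clone family is the
germline-reverted sequence (germline V and J with the majority junction), and
the clonal network links each unique heavy+light amino-acid sequence to its
nearest neighbors by Hamming distance, the UA included as a zero-member node.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotate import VDJAnnotation
from .params import PipelineParams
from .refdata import BCR_LOCI, GermlineReference
from .seqs import translate

logger = logging.getLogger(__name__)

MAIT_V = "TRAV1-2"
MAIT_J = frozenset({"TRAJ33", "TRAJ20", "TRAJ12"})
GEM_J = frozenset({"TRAJ9"})

RECEPTOR_CLASSES = ("TCRab", "TCRgd", "BCR")
_CLASS_LOCI = {"TCRab": ("TRA", "TRB"), "TCRgd": ("TRG", "TRD"), "BCR": ("IGH", "light")}


@dataclass
class ReceptorChain:
    annotation: VDJAnnotation
    cell_id: str
    sample_id: str = ""
    rank: str = "primary"

    @property
    def locus(self) -> str:
        return self.annotation.locus

    @property
    def key(self) -> tuple:
        a = self.annotation
        return (a.locus, a.v_call, a.j_call, a.cdr3_nt)


@dataclass
class CellReceptors:
    cell_id: str
    sample_id: str = ""
    chains: dict[str, list[ReceptorChain]] = field(default_factory=dict)
    pairing_status: dict[str, str] = field(default_factory=dict)
    invariant_flags: frozenset[str] = frozenset()

    def primary(self, locus: str) -> ReceptorChain | None:
        for chain in self.chains.get(locus, []):
            if chain.rank == "primary":
                return chain
        return None


@dataclass
class Clonotype:
    clonotype_id: str
    receptor_class: str
    key: tuple
    member_cells: list[tuple[str, str]] = field(default_factory=list)  # (cell, sample)
    expanded: bool = False
    shared_tissues: frozenset[str] = frozenset()

    @property
    def size(self) -> int:
        return len(self.member_cells)


@dataclass
class CloneNetwork:
    """Nearest-neighbor mutation graph over unique receptor aa sequences."""

    nodes: dict[str, int]  # concatenated heavy+light aa -> member-cell count
    ua_node: str
    edges: list[tuple[str, str, int]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for seq, count in self.nodes.items():
            g.add_node(seq, size=count, is_ua=(seq == self.ua_node))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\thamming\n")
            for a, b, w in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{w}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


# ----------------------------------------------------------------- filters


def filter_chains(
    annotations: list[VDJAnnotation],
    params: PipelineParams = PipelineParams(),
) -> list[VDJAnnotation]:
    """Drop non-productive chains and over-mutated V regions.

    Strictly-greater thresholds: a TCR chain with exactly 5 and a BCR chain
    with exactly 40 V mutations are retained.
    """
    kept = []
    for ann in annotations:
        if not ann.annotated or not ann.productive or not ann.cdr3_nt:
            continue
        limit = (
            params.bcr_max_v_mutations
            if ann.locus in BCR_LOCI
            else params.tcr_max_v_mutations
        )
        if ann.v_mutations > limit:
            continue
        kept.append(ann)
    return kept


def select_cell_chains(
    cell_id: str,
    annotations: list[VDJAnnotation],
    sample_id: str = "",
) -> CellReceptors:
    """Apply the per-cell tie-break rules and compute pairing status.

    Within a (V, J) group holding several CDR3s, TCR chains keep the least
    V-mutated candidate (ties to the greatest read support), BCR chains the
    greatest read support. Across groups the best-supported survivor is the
    primary chain, the next distinct one the secondary. The rules are total
    orders, so the outcome is independent of input order.
    """
    cell = CellReceptors(cell_id=cell_id, sample_id=sample_id)
    by_locus: dict[str, list[VDJAnnotation]] = {}
    for ann in annotations:
        by_locus.setdefault(ann.locus, []).append(ann)

    for locus, group in sorted(by_locus.items()):
        survivors = []
        groups: dict[tuple, list[VDJAnnotation]] = {}
        for ann in group:
            groups.setdefault((ann.v_call, ann.j_call), []).append(ann)
        for (_, _), candidates in sorted(groups.items()):
            if locus in BCR_LOCI:
                candidates.sort(key=lambda a: (-a.n_reads, a.cdr3_nt))
            else:
                candidates.sort(key=lambda a: (a.v_mutations, -a.n_reads, a.cdr3_nt))
            survivors.append(candidates[0])
        survivors.sort(key=lambda a: (-a.n_reads, a.v_mutations, a.cdr3_nt))
        chains = []
        for rank, ann in zip(("primary", "secondary"), survivors[:2]):
            chains.append(
                ReceptorChain(annotation=ann, cell_id=cell_id, sample_id=sample_id, rank=rank)
            )
        cell.chains[locus] = chains

    def status(heavy: str, light_loci: tuple[str, ...], labels: tuple[str, str, str]):
        has_heavy = cell.primary(heavy) is not None
        has_light = any(cell.primary(l) is not None for l in light_loci)
        paired, heavy_only, light_only = labels
        if has_heavy and has_light:
            return paired
        if has_heavy:
            return heavy_only
        if has_light:
            return light_only
        return "none"

    cell.pairing_status["TCRab"] = status(
        "TRB", ("TRA",), ("paired", "beta_only", "alpha_only")
    )
    cell.pairing_status["TCRgd"] = status(
        "TRD", ("TRG",), ("gd_paired", "delta_only", "gamma_only")
    )
    cell.pairing_status["BCR"] = status(
        "IGH", ("IGK", "IGL"), ("paired", "heavy_only", "light_only")
    )
    cell.invariant_flags = flag_invariant_tcr(cell)
    return cell


def flag_invariant_tcr(cell: CellReceptors) -> frozenset[str]:
    """MAIT/GEM flags from semi-invariant TRA gene usage."""
    flags = set()
    for chain in cell.chains.get("TRA", []):
        if chain.annotation.v_call != MAIT_V:
            continue
        if chain.annotation.j_call in MAIT_J:
            flags.add("MAIT")
        if chain.annotation.j_call in GEM_J:
            flags.add("GEM")
    return frozenset(flags)


# -------------------------------------------------------------- clonotypes


def hamming(a: str, b: str) -> int:
    """Number of differing positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _light_locus(cell: CellReceptors) -> str | None:
    for locus in ("IGK", "IGL"):
        if cell.primary(locus) is not None:
            return locus
    return None


def _bcr_cluster(entries, identity_threshold: float):
    """Single-linkage clustering of equal-length CDR3 pairs at >= threshold
    nucleotide identity (1 - hamming/length) on every compared chain."""
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        ok = True
        for a, b in zip(entries[i], entries[j]):
            if len(a) != len(b):
                ok = False
                break
            if 1.0 - hamming(a, b) / len(a) < identity_threshold:
                ok = False
                break
        if ok:
            parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def define_clonotypes(
    cells: list[CellReceptors],
    receptor_class: str,
    params: PipelineParams = PipelineParams(),
    single_chain_locus: str | None = None,
) -> list[Clonotype]:
    """Group cells into clonotypes under the class's identity rule.

    ``receptor_class`` one of TCRab, TCRgd, BCR, or single_chain (with a
    designated locus, e.g. TRB for the cross-tissue beta-chain analysis).
    T-cell keys require exact CDR3 amino-acid identity; B-cell CDR3s
    co-cluster at >=90% nucleotide identity (equal lengths only).
    """
    if receptor_class == "single_chain":
        if single_chain_locus is None:
            raise ValueError("single_chain mode needs a locus")
        loci = (single_chain_locus,)
        fuzzy = single_chain_locus in BCR_LOCI
    elif receptor_class in ("TCRab", "TCRgd"):
        loci = _CLASS_LOCI[receptor_class]
        fuzzy = False
    elif receptor_class == "BCR":
        loci = ("IGH", "light")
        fuzzy = True
    else:
        raise ValueError(f"unknown receptor class {receptor_class!r}")

    eligible = []
    for cell in cells:
        chains = []
        for locus in loci:
            actual = _light_locus(cell) if locus == "light" else locus
            chain = cell.primary(actual) if actual else None
            if chain is None:
                chains = None
                break
            chains.append(chain)
        if chains:
            eligible.append((cell, chains))

    clonotypes: list[Clonotype] = []

    if not fuzzy:
        by_key: dict[tuple, list] = {}
        for cell, chains in eligible:
            key = tuple(
                (c.annotation.locus, c.annotation.v_call, c.annotation.j_call,
                 c.annotation.cdr3_aa)
                for c in chains
            )
            by_key.setdefault(key, []).append(cell)
        for key in sorted(by_key):
            members = by_key[key]
            clonotypes.append(
                Clonotype(
                    clonotype_id="",
                    receptor_class=receptor_class,
                    key=key,
                    member_cells=[(c.cell_id, c.sample_id) for c in members],
                )
            )
    else:
        # group on V/J genes and CDR3 lengths, then single-linkage at >=90% nt
        by_vj: dict[tuple, list] = {}
        for cell, chains in eligible:
            vj = tuple(
                (c.annotation.locus, c.annotation.v_call, c.annotation.j_call,
                 len(c.annotation.cdr3_nt))
                for c in chains
            )
            by_vj.setdefault(vj, []).append((cell, chains))
        for vj in sorted(by_vj):
            group = by_vj[vj]
            cdr3s = [tuple(c.annotation.cdr3_nt for c in chains) for _, chains in group]
            labels = _bcr_cluster(cdr3s, params.bcr_cdr3_identity)
            clusters: dict[int, list] = {}
            for (cell, chains), label in zip(group, labels):
                clusters.setdefault(label, []).append((cell, chains))
            for label in sorted(clusters):
                members = clusters[label]
                rep = members[0][1]
                key = tuple(
                    (c.annotation.locus, c.annotation.v_call, c.annotation.j_call,
                     c.annotation.cdr3_nt)
                    for c in rep
                )
                clonotypes.append(
                    Clonotype(
                        clonotype_id="",
                        receptor_class=receptor_class,
                        key=key,
                        member_cells=[(c.cell_id, c.sample_id) for c, _ in members],
                    )
                )

    clonotypes.sort(key=lambda c: (-c.size, c.key))
    for i, clone in enumerate(clonotypes, start=1):
        clone.clonotype_id = f"{receptor_class}-{i:04d}"
    return find_expanded_and_shared(clonotypes)


def find_expanded_and_shared(clonotypes: list[Clonotype]) -> list[Clonotype]:
    """Expanded = found in more than one cell; shared = spanning tissues."""
    for clone in clonotypes:
        clone.expanded = clone.size > 1
        clone.shared_tissues = frozenset(s for _, s in clone.member_cells if s)
    return clonotypes


def clonotypes_to_frame(clonotypes: list[Clonotype]) -> pd.DataFrame:
    rows = []
    for clone in clonotypes:
        rows.append(
            {
                "clonotype_id": clone.clonotype_id,
                "receptor_class": clone.receptor_class,
                "key": ";".join("|".join(str(x) for x in chain) for chain in clone.key),
                "n_cells": clone.size,
                "expanded": clone.expanded,
                "tissues": ",".join(sorted(clone.shared_tissues)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clonotype_id", "receptor_class", "key", "n_cells", "expanded", "tissues"],
    )


# ------------------------------------------------- clonal evolution (BCR)


def infer_ua(
    chains: list[ReceptorChain],
    reference: GermlineReference,
) -> str:
    """Unmutated ancestor of one clone's chains (same locus, same V/J).

    Every germline-templated position reverts to the germline base (germline V
    through its anchor codon, germline J from its anchor); the untemplated
    junction takes the per-position majority base across members.
    """
    if not chains:
        raise ValueError("no chains")
    keys = {(c.annotation.locus, c.annotation.v_call, c.annotation.j_call) for c in chains}
    if len(keys) > 1:
        raise ValueError(f"discordant V/J calls in clone: {sorted(keys)}")
    locus, v_call, j_call = next(iter(keys))
    v_seg = reference.by_gene(locus, "V", v_call)
    j_seg = reference.by_gene(locus, "J", j_call)

    junctions = [c.annotation.cdr3_nt[3:-3] for c in chains]
    lengths = {len(j) for j in junctions}
    if len(lengths) > 1:
        raise ValueError("junction length heterogeneity within clone")
    junction = "".join(
        min(Counter(col).most_common(), key=lambda kv: (-kv[1], kv[0]))[0]
        for col in zip(*junctions)
    ) if junctions[0] else ""
    return v_seg.sequence[: v_seg.v_anchor + 3] + junction + j_seg.sequence[j_seg.j_anchor :]


def build_clone_network(
    cells: list[CellReceptors],
    reference: GermlineReference,
) -> list[CloneNetwork]:
    """Nearest-neighbor network over unique heavy+light amino-acid sequences.

    Nodes are unique concatenated heavy+light V(D)J amino-acid sequences (the
    inferred UA included with member count 0); each node is connected to every
    node at its minimal pairwise Hamming distance. Cells whose concatenated
    sequences differ in length are partitioned by length and a network is
    built per partition (logged).
    """
    heavy_chains, light_chains, concat = [], [], []
    for cell in cells:
        heavy = cell.primary("IGH")
        light_locus = _light_locus(cell)
        light = cell.primary(light_locus) if light_locus else None
        if heavy is None or light is None:
            continue
        heavy_chains.append(heavy)
        light_chains.append(light)
        concat.append(heavy.annotation.vdj_aa + light.annotation.vdj_aa)

    if not concat:
        return []

    by_length: dict[int, list[int]] = {}
    for i, seq in enumerate(concat):
        by_length.setdefault(len(seq), []).append(i)
    if len(by_length) > 1:
        logger.info(
            "clone spans %d distinct sequence lengths; building one network per length",
            len(by_length),
        )

    networks = []
    for length in sorted(by_length, key=lambda l: -len(by_length[l])):
        idx = by_length[length]
        ua_aa = translate(infer_ua([heavy_chains[i] for i in idx], reference)) + translate(
            infer_ua([light_chains[i] for i in idx], reference)
        )
        counts = Counter(concat[i] for i in idx)
        nodes = dict(sorted(counts.items()))
        nodes.setdefault(ua_aa, 0)
        if len(ua_aa) != length:
            logger.warning("UA length differs from members; keeping UA as isolated node")
        edges = nearest_neighbor_edges(nodes, ua_aa)
        networks.append(CloneNetwork(nodes=nodes, ua_node=ua_aa, edges=edges))
    return networks


def nearest_neighbor_edges(nodes: dict[str, int], ua: str | None = None):
    """For every node, edges to all nodes at its minimal Hamming distance."""
    seqs = sorted(nodes)
    edges = set()
    for seq in seqs:
        candidates = [
            (other, hamming(seq, other))
            for other in seqs
            if other != seq and len(other) == len(seq)
        ]
        if not candidates:
            continue
        dmin = min(d for _, d in candidates)
        for other, d in candidates:
            if d == dmin:
                edges.add((min(seq, other), max(seq, other), d))
    return sorted(edges)


# ------------------------------------------------------------- summaries


def mutation_summary(
    cells: list[CellReceptors],
    groups: dict[str, str] | None = None,
    locus: str = "IGH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group V-mutation-rate summary and isotype x splice-form crosstab."""
    rows = []
    for cell in cells:
        chain = cell.primary(locus)
        if chain is None:
            continue
        rows.append(
            {
                "cell_id": cell.cell_id,
                "group": (groups or {}).get(cell.cell_id, "all"),
                "v_mutation_rate": chain.annotation.v_mutation_rate,
                "isotype": chain.annotation.c_call or "none",
                "form": chain.annotation.c_form,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["cell_id", "group", "v_mutation_rate", "isotype", "form"]
    )
    if frame.empty:
        return frame, frame
    summary = (
        frame.groupby("group")["v_mutation_rate"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    crosstab = pd.crosstab(frame["isotype"], frame["form"])
    return summary, crosstab


def clonal_expression_similarity(
    clone_pairs: list[tuple[str, str]],
    expression: pd.DataFrame,
    control_pairs: list[tuple[str, str]],
    top_n: int = 250,
) -> tuple[list[float], list[float], float, float]:
    """Jaccard similarity of the top-N most-abundant gene sets, clonal pairs
    versus matched control pairs, with a paired one-sided Wilcoxon test.

    ``expression`` is a cells x genes DataFrame indexed by cell_id. Returns
    (clonal Jaccards, control Jaccards, statistic, p-value).
    """
    if len(clone_pairs) != len(control_pairs):
        raise ValueError("clonal and control pairs must be matched 1:1")

    def top_set(cell_id: str) -> frozenset[str]:
        row = expression.loc[cell_id]
        expressed = row[row > 0]
        if len(expressed) < top_n:
            logger.warning(
                "cell %s expresses %d < %d genes; using all", cell_id, len(expressed), top_n
            )
        return frozenset(expressed.nlargest(min(top_n, len(expressed))).index)

    def jaccard(pair: tuple[str, str]) -> float:
        a, b = top_set(pair[0]), top_set(pair[1])
        union = a | b
        return len(a & b) / len(union) if union else 0.0

    clonal = [jaccard(p) for p in clone_pairs]
    control = [jaccard(p) for p in control_pairs]
    diffs = np.array(clonal) - np.array(control)
    if np.all(diffs == 0):
        return clonal, control, 0.0, 1.0
    statistic, pvalue = stats.wilcoxon(clonal, control, alternative="greater")
    return clonal, control, float(statistic), float(pvalue)
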