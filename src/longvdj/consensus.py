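"""Per-cell read clustering and majority-vote consensus contigs.

Full-length cDNA reads of one cell are grouped into transcript clusters by
shared-k-mer similarity and each cluster is collapsed to a polished consensus:
a center-star alignment of every member against the representative (the
longest read), a per-column majority vote over {A, C, G, T, gap} with
gap-majority columns deleted, then iterative re-alignment of all members to
the current consensus and re-voting ("polishing", default four rounds, which
also repairs indels the first vote inherited from the representative).

Reads shorter than 200 nt are discarded and pairwise evidence spanning less
than 100 nt of estimated overlap is ignored. Clustering is deterministic:
reads are processed longest-first (ties by read id) and join the first
existing cluster whose representative they match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .demux import DemuxedRead
from .params import PipelineParams

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_GAP = 4
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"


@dataclass
class ReadCluster:
    cell_barcode: str
    cluster_id: str
    member_read_ids: list[str]
    representative: str  # read_id of the representative (longest) member


@dataclass
class Contig:
    contig_id: str
    cell_barcode: str
    sequence: str
    n_reads: int
    polish_rounds_applied: int = 0


def _kmers(seq: str, k: int) -> dict[str, int]:
    """Distinct k-mers mapped to their first occurrence position."""
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], i)
    return out


def cluster_reads(
    reads: list[DemuxedRead],
    params: PipelineParams = PipelineParams(),
) -> list[ReadCluster]:
    """Greedy single-linkage clustering on k-mer containment.

    A read joins the first cluster whose representative shares enough distinct
    k-mers: containment (shared / read's distinct k-mers) at least
    ``kmer_containment`` and the span of shared k-mers on the representative at
    least ``min_overlap_length``.
    """
    usable = [r for r in reads if len(r.trimmed_sequence) >= params.consensus_min_read_length]
    usable.sort(key=lambda r: (-len(r.trimmed_sequence), r.read_id))
    k = params.kmer_size
    clusters: list[ReadCluster] = []
    rep_kmers: list[dict[str, int]] = []
    barcode = reads[0].barcode if reads else ""
    for read in usable:
        kms = _kmers(read.trimmed_sequence, k)
        placed = False
        for idx, cluster in enumerate(clusters):
            shared = kms.keys() & rep_kmers[idx].keys()
            if not shared:
                continue
            containment = len(shared) / len(kms)
            positions = [rep_kmers[idx][s] for s in shared]
            span = max(positions) - min(positions) + k
            if span >= params.min_overlap_length and containment >= params.kmer_containment:
                cluster.member_read_ids.append(read.read_id)
                placed = True
                break
        if not placed:
            clusters.append(
                ReadCluster(
                    cell_barcode=read.barcode or barcode,
                    cluster_id=f"c{len(clusters)}",
                    member_read_ids=[read.read_id],
                    representative=read.read_id,
                )
            )
            rep_kmers.append(kms)
    return clusters


def _vote(template: str, member_seqs: list[str]) -> str:
    """Align members to ``template`` and take the per-column majority.

    Ties go to the template's base; a column is deleted only when gap strictly
    wins it. An insertion (relative to the template) is emitted only when a
    strict majority of members supports it.
    """
    n_members = len(member_seqs)
    length = len(template)
    # matches dominate, so they get a cheap per-column cover count; only
    # substituted and gapped columns go through the full 5-way tally
    match_cover = np.zeros(length, dtype=np.int32)
    counts = np.zeros((length + 1, 5), dtype=np.int32)
    insertions: dict[int, dict[str, int]] = {}

    for seq in member_seqs:
        result = edlib.align(seq, template, task="path", mode="NW")
        qpos = tpos = 0
        for m in _CIGAR_RE.finditer(result["cigar"]):
            run, op = int(m.group(1)), m.group(2)
            if op == "=":
                match_cover[tpos : tpos + run] += 1
                qpos += run
                tpos += run
            elif op in "XM":
                for i in range(run):
                    counts[tpos + i, _BASE_INDEX.get(seq[qpos + i], 0)] += 1
                qpos += run
                tpos += run
            elif op == "D":  # consumes template only: member lacks these bases
                counts[tpos : tpos + run, _GAP] += 1
                tpos += run
            else:  # 'I': consumes member only: insertion relative to template
                bucket = insertions.setdefault(tpos, {})
                frag = seq[qpos : qpos + run]
                bucket[frag] = bucket.get(frag, 0) + 1
                qpos += run

    # columns never touched by a substitution or gap resolve to the template
    # base without a vote; only the (sparse) contested columns are tallied
    out = list(template)
    deleted: set[int] = set()
    for t in np.flatnonzero(counts[:length].any(axis=1)):
        t = int(t)
        col = counts[t].copy()
        template_code = _BASE_INDEX.get(template[t], 0)
        col[template_code] += match_cover[t]
        winners = np.flatnonzero(col == col.max())
        if template_code in winners:
            winner = template_code
        else:
            winner = int(winners[0])  # A<C<G<T<gap order: deterministic
        if winner == _GAP:
            deleted.add(t)
        else:
            out[t] = _INDEX_BASE[winner]

    # insertion fragments are emitted only on strict-majority support
    accepted_insertions: dict[int, str] = {}
    for tpos, bucket in insertions.items():
        if sum(bucket.values()) * 2 > n_members:
            accepted_insertions[tpos] = min(bucket, key=lambda f: (-bucket[f], f))

    if not deleted and not accepted_insertions:
        return "".join(out)
    pieces: list[str] = []
    for t in range(length):
        if t in accepted_insertions:
            pieces.append(accepted_insertions[t])
        if t not in deleted:
            pieces.append(out[t])
    if length in accepted_insertions:
        pieces.append(accepted_insertions[length])
    return "".join(pieces)


def build_consensus(
    cluster: ReadCluster,
    reads_by_id: dict[str, DemuxedRead],
) -> Contig:
    """Center-star majority-vote consensus of a cluster's members."""
    if not cluster.member_read_ids:
        raise ValueError("empty cluster")
    members = [reads_by_id[rid].trimmed_sequence for rid in cluster.member_read_ids]
    template = reads_by_id[cluster.representative].trimmed_sequence
    sequence = template if len(members) == 1 else _vote(template, members)
    return Contig(
        contig_id=cluster.cluster_id,
        cell_barcode=cluster.cell_barcode,
        sequence=sequence,
        n_reads=len(members),
    )


def polish(
    contig: Contig,
    reads: list[DemuxedRead],
    rounds: int = 4,
) -> Contig:
    """Iteratively re-align all supporting reads and re-vote each column.

    Stops early at a fixed point (a converged consensus re-votes to itself).
    ``rounds=0`` returns the contig unchanged.
    """
    member_seqs = [r.trimmed_sequence for r in reads]
    sequence = contig.sequence
    applied = 0
    for _ in range(rounds):
        if not member_seqs:
            break
        updated = _vote(sequence, member_seqs)
        applied += 1
        if updated == sequence:
            break
        sequence = updated
    return Contig(
        contig_id=contig.contig_id,
        cell_barcode=contig.cell_barcode,
        sequence=sequence,
        n_reads=contig.n_reads,
        polish_rounds_applied=applied,
    )


def assemble_cell(
    reads: list[DemuxedRead],
    params: PipelineParams = PipelineParams(),
    cell_barcode: str | None = None,
) -> list[Contig]:
    """cluster -> consensus -> polish for one cell; contigs by read support.

    A cell with no usable reads (the monocyte analog) yields an empty list.
    """
    if not reads:
        return []
    barcode = cell_barcode or reads[0].barcode
    reads_by_id = {r.read_id: r for r in reads}
    contigs = []
    for cluster in cluster_reads(reads, params):
        contig = build_consensus(cluster, reads_by_id)
        members = [reads_by_id[rid] for rid in cluster.member_read_ids]
        contig = polish(contig, members, rounds=params.polish_rounds)
        contigs.append(contig)
    contigs.sort(key=lambda c: (-c.n_reads, c.contig_id))
    for i, contig in enumerate(contigs, start=1):
        contig.contig_id = f"{barcode}|contig{i}"
    return contigs


def write_contigs_fasta(contigs: list[Contig], path) -> None:
    """Headers encode cell barcode, contig id and read support."""
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.contig_id}|reads={contig.n_reads}\n")
            for i in range(0, len(contig.sequence), 80):
                fh.write(contig.sequence[i : i + 80] + "\n")
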