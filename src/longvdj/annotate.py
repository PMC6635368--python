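"""Two-pass V(D)J annotation of consensus contigs against a germline reference.

Pass 1 assigns the best V and J segment per locus by affine-gap local
alignment (the locus with the highest combined V+J score wins) and calls the
constant region on the uncorrected contig. Insertions and deletions inside the
germline-aligned V and J intervals are then reverted to the germline (query
insertions removed, query deletions filled with the germline base,
substitutions untouched, the junction untouched) — the long-read error mode
that otherwise shifts the CDR3 reading frame. Pass 2 re-aligns the corrected
contig, extracts the CDR3 between the conserved V-cysteine and J-tryptophan/
phenylalanine anchor codons (anchor-inclusive at the nucleotide level), and
scores productivity and V-region mutations.

Constant regions are called at >95% reference coverage and >90% identity;
for IGH the winning entry's splice form gives the membrane-vs-secreted call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import Alignment, ScoringParams, local_align, local_align_score
from .consensus import Contig
from .params import PipelineParams
from .refdata import GermlineReference, GermlineSegment
from .seqs import translate

logger = logging.getLogger(__name__)

# search intervals on the (transcript-sense) contig: V sits at the 5' end,
# J directly after it, C downstream of J
V_SEARCH_SPAN = 700
J_SEARCH_SPAN = 420


@dataclass
class VDJAnnotation:
    contig_id: str
    cell_id: str = ""
    locus: str | None = None
    v_call: str | None = None
    j_call: str | None = None
    c_call: str | None = None
    c_form: str = "none"
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    cdr3_interval: tuple[int, int] | None = None  # on the corrected contig
    productive: bool = False
    v_mutations: int = 0
    v_aligned_length: int = 0
    v_mutation_ref_positions: tuple[int, ...] = ()
    indel_corrected: bool = False
    n_reads: int = 1
    sequence: str = ""  # indel-corrected contig
    vdj_nt: str = ""  # corrected contig from V start through J end
    v_identity: float = 0.0

    @property
    def v_mutation_rate(self) -> float:
        """Percent of aligned V-region nucleotides mutated from germline."""
        if not self.v_aligned_length:
            return 0.0
        return 100.0 * self.v_mutations / self.v_aligned_length

    @property
    def vdj_aa(self) -> str:
        return translate(self.vdj_nt)

    @property
    def annotated(self) -> bool:
        return self.locus is not None


AIRR_COLUMNS = (
    "sequence_id",
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "c_form",
    "junction",
    "junction_aa",
    "productive",
    "v_identity",
    "v_mutation_count",
    "v_mutation_rate",
    "consensus_count",
    "indel_corrected",
)


def annotation_to_airr_row(ann: VDJAnnotation) -> dict:
    return {
        "sequence_id": ann.contig_id,
        "cell_id": ann.cell_id,
        "locus": ann.locus or "",
        "v_call": ann.v_call or "",
        "j_call": ann.j_call or "",
        "c_call": ann.c_call or "",
        "c_form": ann.c_form,
        "junction": ann.cdr3_nt or "",
        "junction_aa": ann.cdr3_aa or "",
        "productive": "T" if ann.productive else "F",
        "v_identity": f"{ann.v_identity:.4f}",
        "v_mutation_count": ann.v_mutations,
        "v_mutation_rate": f"{ann.v_mutation_rate:.4f}",
        "consensus_count": ann.n_reads,
        "indel_corrected": "T" if ann.indel_corrected else "F",
    }


def write_airr_tsv(annotations: list[VDJAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(AIRR_COLUMNS) + "\n")
        for ann in annotations:
            row = annotation_to_airr_row(ann)
            fh.write("\t".join(str(row[c]) for c in AIRR_COLUMNS) + "\n")


# ------------------------------------------------------------- assignment


def assign_segment(
    contig: str,
    candidates: list[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
    search_interval: tuple[int, int] | None = None,
    min_score: int = 50,
) -> tuple[GermlineSegment, Alignment] | None:
    """Best-scoring candidate segment, or None below ``min_score``.

    Ties break by higher identity, then lexicographic gene name.
    """
    if not candidates:
        raise ValueError("no candidate segments")
    best: tuple[float, float, str] | None = None
    result = None
    for seg in sorted(candidates, key=lambda s: (s.gene_name, s.segment_id)):
        aln = local_align(contig, seg.sequence, scoring, query_interval=search_interval)
        key = (-aln.score, -aln.identity, seg.gene_name)
        if best is None or key < best:
            best = key
            result = (seg, aln)
    if result is None or result[1].score < min_score:
        return None
    return result


def correct_indels(
    contig: str,
    v_alignment: tuple[GermlineSegment, Alignment],
    j_alignment: tuple[GermlineSegment, Alignment] | None,
    scoring: ScoringParams = ScoringParams(),
) -> tuple[str, bool]:
    """Revert indels inside the germline-aligned V and J intervals.

    Query insertions are deleted, query deletions are filled with the germline
    base; substitutions and the junction between the aligned intervals are
    untouched. Returns the corrected contig and whether anything was corrected.
    Overlapping V/J intervals are handled by correcting V first and realigning
    J on the corrected sequence.
    """

    def corrected_region(seg: GermlineSegment, aln: Alignment) -> str:
        q, r = aln.query_interval[0], aln.ref_interval[0]
        pieces = []
        for op, n in aln.ops:
            if op in "=X":
                pieces.append(contig[q : q + n])
                q += n
                r += n
            elif op == "I":
                q += n  # drop insertion
            else:  # D: fill with germline
                pieces.append(seg.sequence[r : r + n])
                r += n
        return "".join(pieces)

    v_seg, v_aln = v_alignment
    regions = [(v_aln.query_interval, corrected_region(v_seg, v_aln), v_aln.has_indels)]
    j_deferred = False
    if j_alignment is not None:
        j_seg, j_aln = j_alignment
        if j_aln.query_interval[0] < v_aln.query_interval[1]:
            logger.info("V/J aligned intervals overlap; realigning J after V correction")
            j_deferred = True
        else:
            regions.append(
                (j_aln.query_interval, corrected_region(j_seg, j_aln), j_aln.has_indels)
            )

    changed = any(flag for _, _, flag in regions)
    corrected = contig
    for (lo, hi), replacement, _ in sorted(regions, reverse=True):
        corrected = corrected[:lo] + replacement + corrected[hi:]

    if j_deferred:
        j_seg, _ = j_alignment
        new_j = local_align(corrected, j_seg.sequence, scoring)
        if new_j.score > 0 and new_j.has_indels:
            lo, hi = new_j.query_interval
            corrected = corrected[:lo] + corrected_region(j_seg, new_j) + corrected[hi:]
            changed = True
    return corrected, changed


def extract_cdr3(
    contig: str,
    v: tuple[GermlineSegment, Alignment],
    j: tuple[GermlineSegment, Alignment],
) -> tuple[str, str | None, tuple[int, int]] | None:
    """CDR3 between the V-Cys and J-Trp/Phe anchors, both codons included.

    Returns None when an anchor maps outside its aligned interval. The amino
    acid string is reported only for in-frame junctions.
    """
    v_seg, v_aln = v
    j_seg, j_aln = j
    q_v = v_aln.query_pos_of_ref(v_seg.v_anchor)
    q_j = j_aln.query_pos_of_ref(j_seg.j_anchor)
    if q_v is None or q_j is None or q_j + 3 > len(contig) or q_j <= q_v:
        return None
    cdr3_nt = contig[q_v : q_j + 3]
    cdr3_aa = translate(cdr3_nt) if len(cdr3_nt) % 3 == 0 else None
    return cdr3_nt, cdr3_aa, (q_v, q_j + 3)


def assess_productivity(
    contig: str,
    v: tuple[GermlineSegment, Alignment],
    j: tuple[GermlineSegment, Alignment],
    cdr3_interval: tuple[int, int],
) -> bool:
    """In-frame junction and no stop codon from the V start through the J end."""
    _, v_aln = v
    _, j_aln = j
    q_v, cdr3_end = cdr3_interval
    if (cdr3_end - q_v) % 3 != 0:
        return False
    # translate in the V frame (the anchor codon start defines the frame)
    start = v_aln.query_interval[0]
    start += (q_v - start) % 3
    end = j_aln.query_interval[1]
    aa = translate(contig[start:end])
    return "*" not in aa


def count_v_mutations(v_alignment: Alignment) -> tuple[int, int, float]:
    """Substitutions in the V-aligned interval, aligned length, and rate (%)."""
    mutations = v_alignment.n_mismatches
    aligned = v_alignment.n_matches + mutations
    rate = 100.0 * mutations / aligned if aligned else 0.0
    return mutations, aligned, rate


def assign_constant(
    contig: str,
    c_candidates: list[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
    min_coverage: float = 0.95,
    min_identity: float = 0.90,
    search_interval: tuple[int, int] | None = None,
) -> tuple[GermlineSegment, Alignment] | None:
    """Constant-region call: best score among candidates passing strict
    coverage (>min_coverage of the spliced reference) and identity
    (>min_identity) thresholds; the winning entry fixes isotype and splice
    form. None when no candidate passes."""
    best_key = None
    result = None
    for seg in sorted(c_candidates, key=lambda s: s.segment_id):
        aln = local_align(contig, seg.sequence, scoring, query_interval=search_interval)
        if aln.ref_coverage <= min_coverage or aln.identity <= min_identity:
            continue
        key = (-aln.score, -aln.identity, seg.segment_id)
        if best_key is None or key < best_key:
            best_key = key
            result = (seg, aln)
    return result


def _assign_vj(
    contig: str,
    reference: GermlineReference,
    locus: str,
    scoring: ScoringParams,
    params: PipelineParams,
):
    v_candidates = reference.get(locus, "V")
    if not v_candidates:
        return None
    v = assign_segment(
        contig, v_candidates, scoring,
        search_interval=(0, min(len(contig), V_SEARCH_SPAN)),
        min_score=params.min_v_score,
    )
    if v is None:
        return None
    j_candidates = reference.get(locus, "J")
    j = None
    if j_candidates:
        v_end = v[1].query_interval[1]
        j = assign_segment(
            contig, j_candidates, scoring,
            search_interval=(max(0, v_end - 10), min(len(contig), v_end + J_SEARCH_SPAN)),
            min_score=params.min_j_score,
        )
    return v, j


def annotate_contig(
    contig: Contig | str,
    reference: GermlineReference,
    scoring: ScoringParams | None = None,
    params: PipelineParams = PipelineParams(),
    cell_id: str = "",
) -> VDJAnnotation:
    """Two-pass annotation of one contig (see module docstring)."""
    if isinstance(contig, str):
        contig = Contig(contig_id="contig", cell_barcode=cell_id, sequence=contig, n_reads=1)
    scoring = scoring or params.scoring
    seq = contig.sequence
    ann = VDJAnnotation(
        contig_id=contig.contig_id,
        cell_id=cell_id or contig.cell_barcode,
        n_reads=contig.n_reads,
        sequence=seq,
    )
    if not seq:
        return ann

    # ---- pass 1: best locus by combined V+J score on the raw contig
    best = None
    for locus in reference.loci():
        vj = _assign_vj(seq, reference, locus, scoring, params)
        if vj is None:
            continue
        v, j = vj
        combined = v[1].score + (j[1].score if j else 0)
        if best is None or combined > best[0]:
            best = (combined, locus, v, j)
    if best is None:
        return ann
    _, locus, v1, j1 = best
    ann.locus = locus

    # ---- constant region: called on the uncorrected contig
    c_candidates = reference.get(locus, "C")
    if c_candidates:
        anchor_end = (j1 or v1)[1].query_interval[1]
        c = assign_constant(
            seq, c_candidates, scoring,
            min_coverage=params.c_min_coverage,
            min_identity=params.c_min_identity,
            search_interval=(max(0, anchor_end - 20), len(seq)),
        )
        if c is not None and c[1].score >= params.min_c_score:
            ann.c_call = c[0].isotype
            ann.c_form = c[0].form if c[0].form != "not_applicable" else "none"

    # ---- indel correction, then pass 2 on the corrected contig
    corrected, changed = correct_indels(seq, v1, j1, scoring)
    ann.indel_corrected = changed
    ann.sequence = corrected
    vj2 = _assign_vj(corrected, reference, locus, scoring, params)
    if vj2 is None:
        return ann
    v2, j2 = vj2
    ann.v_call = v2[0].gene_name
    ann.v_identity = v2[1].identity
    mutations, aligned, _ = count_v_mutations(v2[1])
    ann.v_mutations = mutations
    ann.v_aligned_length = aligned
    ann.v_mutation_ref_positions = tuple(r for _, r in v2[1].mismatch_positions())
    if j2 is None:
        return ann
    ann.j_call = j2[0].gene_name
    # full V(D)J span: extrapolate to germline position 0 of V and the last
    # germline position of J, so edge substitutions (which a local alignment
    # trims) do not shorten the reported sequence
    v_start = max(0, v2[1].query_interval[0] - v2[1].ref_interval[0])
    j_end = min(
        len(corrected),
        j2[1].query_interval[1] + (len(j2[0].sequence) - j2[1].ref_interval[1]),
    )
    ann.vdj_nt = corrected[v_start:j_end]

    cdr3 = extract_cdr3(corrected, v2, j2)
    if cdr3 is None:
        return ann
    ann.cdr3_nt, ann.cdr3_aa, ann.cdr3_interval = cdr3
    ann.productive = assess_productivity(corrected, v2, j2, ann.cdr3_interval)
    return ann


def classify_on_target(
    reads,
    c_segments: list[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
    min_score: int = 50,
) -> tuple[float, dict[str, bool]]:
    """Flag reads whose best local alignment to any constant region exceeds
    ``min_score`` (the capture-enrichment 'on-target' measure). ``reads`` is an
    iterable of (read_id, sequence); both strands are checked. Candidate
    segments are screened by shared 13-mers (seed-and-extend style) and ranked
    by seed count; the call itself is always made on the alignment score."""
    from .seqs import revcomp

    k = 13
    seg_kmers = [
        (seg, frozenset(seg.sequence[i : i + k] for i in range(len(seg.sequence) - k + 1)))
        for seg in c_segments
    ]
    flags: dict[str, bool] = {}
    for read_id, seq in reads:
        on_target = False
        for query in (seq, revcomp(seq)):
            read_kmers = {query[i : i + k] for i in range(len(query) - k + 1)}
            candidates = sorted(
                ((len(read_kmers & kmers), seg) for seg, kmers in seg_kmers),
                key=lambda t: (-t[0], t[1].segment_id),
            )
            for n_seeds, seg in candidates:
                if n_seeds == 0:
                    break  # seed filter: no shared 13-mer, treat as no hit
                if local_align_score(query, seg.sequence, scoring) > min_score:
                    on_target = True
                    break
            if on_target:
                break
        flags[read_id] = on_target
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return fraction, flags
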