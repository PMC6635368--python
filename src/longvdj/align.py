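"""Affine-gap local alignment with an explicit edit-operation path.

This is the scoring machinery behind segment assignment, indel correction and
anchor mapping. ``local_align`` computes an optimal Smith-Waterman/Gotoh local
alignment (via Bio.Align.PairwiseAligner, which runs the dynamic program in C)
and converts the traceback into a compact run-length op list:

    '=' aligned, identical      'X' aligned, substitution
    'I' insertion in the query  'D' deletion from the query (germline base absent)

Gap scoring convention: the first base of a gap costs ``gap_open`` and each
further base ``gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scores; defaults penalize long-read-style indels mildly."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or max(self.mismatch, self.gap_open, self.gap_extend) >= 0:
            raise ValueError("match must be positive; penalties negative")


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


@dataclass
class Alignment:
    """A local alignment of a query against a reference segment."""

    score: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    ops: list[tuple[str, int]] = field(default_factory=list)
    ref_length: int = 0

    @property
    def n_mismatches(self) -> int:
        return sum(n for op, n in self.ops if op == "X")

    @property
    def n_query_insertions(self) -> int:
        return sum(n for op, n in self.ops if op == "I")

    @property
    def n_query_deletions(self) -> int:
        return sum(n for op, n in self.ops if op == "D")

    @property
    def n_matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def aligned_columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def aligned_ref_columns(self) -> int:
        """Columns that consume the reference ('=', 'X', 'D')."""
        return sum(n for op, n in self.ops if op in "=XD")

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.n_matches / cols if cols else 0.0

    @property
    def ref_coverage(self) -> float:
        if not self.ref_length:
            return 0.0
        return (self.ref_interval[1] - self.ref_interval[0]) / self.ref_length

    @property
    def has_indels(self) -> bool:
        return any(op in "ID" for op, _ in self.ops)

    def query_pos_of_ref(self, ref_pos: int) -> int | None:
        """Map a reference coordinate to the query coordinate aligned to it.

        Returns None when ``ref_pos`` lies outside the aligned reference
        interval or falls in a run deleted from the query.
        """
        q, r = self.query_interval[0], self.ref_interval[0]
        if not self.ref_interval[0] <= ref_pos < self.ref_interval[1]:
            return None
        for op, n in self.ops:
            if op in "=X":
                if r <= ref_pos < r + n:
                    return q + (ref_pos - r)
                q += n
                r += n
            elif op == "I":
                q += n
            else:  # D
                if r <= ref_pos < r + n:
                    return None
                r += n
        return None

    def mismatch_positions(self) -> list[tuple[int, int]]:
        """(query_pos, ref_pos) of every substituted column."""
        out = []
        q, r = self.query_interval[0], self.ref_interval[0]
        for op, n in self.ops:
            if op == "X":
                out.extend((q + i, r + i) for i in range(n))
            if op in "=X":
                q += n
                r += n
            elif op == "I":
                q += n
            else:
                r += n
        return out


def _empty_alignment(ref: str) -> Alignment:
    return Alignment(score=0, query_interval=(0, 0), ref_interval=(0, 0),
                     ops=[], ref_length=len(ref))


def local_align(
    query: str,
    ref: str,
    scoring: ScoringParams = ScoringParams(),
    query_interval: tuple[int, int] | None = None,
) -> Alignment:
    """Optimal affine-gap local alignment of ``query`` against ``ref``.

    ``query_interval`` restricts the search to a slice of the query (the
    reported coordinates stay in full-query space). Among co-optimal
    alignments one deterministic traceback is reported; the score is always
    the optimum.
    """
    if not query or not ref:
        raise ValueError("sequences must be non-empty")
    offset = 0
    q = query
    if query_interval is not None:
        lo, hi = max(0, query_interval[0]), min(len(query), query_interval[1])
        if lo >= hi:
            return _empty_alignment(ref)
        q, offset = query[lo:hi], lo

    aligner = _aligner(scoring)
    score = aligner.score(q, ref)
    if score <= 0:
        return _empty_alignment(ref)
    aln = aligner.align(q, ref)[0]
    coords = aln.coordinates  # row 0: positions in q, row 1: positions in ref

    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for k in range(coords.shape[1] - 1):
        dq = int(coords[0, k + 1] - coords[0, k])
        dr = int(coords[1, k + 1] - coords[1, k])
        if dq and dr:  # aligned block: split into '=' / 'X' runs
            qs, rs = int(coords[0, k]), int(coords[1, k])
            run_op, run_len = "", 0
            for i in range(dq):
                op = "=" if q[qs + i] == ref[rs + i] else "X"
                if op == run_op:
                    run_len += 1
                else:
                    push(run_op, run_len)
                    run_op, run_len = op, 1
            push(run_op, run_len)
        elif dq:
            push("I", dq)
        elif dr:
            push("D", dr)

    return Alignment(
        score=int(score),
        query_interval=(int(coords[0, 0]) + offset, int(coords[0, -1]) + offset),
        ref_interval=(int(coords[1, 0]), int(coords[1, -1])),
        ops=ops,
        ref_length=len(ref),
    )


def local_align_score(
    query: str, ref: str, scoring: ScoringParams = ScoringParams()
) -> int:
    """Optimal local alignment score only (no traceback; faster)."""
    if not query or not ref:
        raise ValueError("sequences must be non-empty")
    return max(0, int(_aligner(scoring).score(query, ref)))
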