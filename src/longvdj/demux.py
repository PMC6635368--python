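"""Exact-match cell-barcode demultiplexing of long reads.

Reads longer than 250 nt are scanned in their first and last 200 nt for exact
(0 mismatches, 0 indels) occurrences of whitelist barcodes, forward or
reverse-complemented. Reads with exactly one distinct barcode are assigned:
the 13 nt downstream of the barcode (the 10-nt UMI plus a 3-nt buffer) are
removed and recorded, the barcode and the adapter remnant between it and the
nearer read end are trimmed, and the remainder is reverse-complemented into
transcript (mRNA) sense so every downstream stage sees a single canonical
strand. Reads with two or more distinct barcodes are chimera candidates and
binned as multi_barcode; reads of 250 nt or shorter are binned too_short;
reads with no exact match are unassigned.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field

from .params import PipelineParams
from .seqs import read_fastq, revcomp, write_fastq

logger = logging.getLogger(__name__)

CATEGORIES = ("assigned", "multi_barcode", "too_short", "unassigned")


class WhitelistError(ValueError):
    pass


@dataclass
class BarcodeWhitelist:
    """The set of trusted 16-nt cell barcodes (from short-read sequencing)."""

    barcodes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise WhitelistError("whitelist is empty")
        lengths = {len(bc) for bc in self.barcodes}
        if lengths != {16}:
            raise WhitelistError(f"barcodes must all be 16 nt, got lengths {lengths}")
        collisions = [bc for bc in self.barcodes if revcomp(bc) in self.barcodes]
        if collisions:
            logger.warning(
                "%d barcode(s) equal the reverse complement of another; "
                "orientation of their reads is ambiguous", len(collisions)
            )
        # exact-match lookup: sequence -> (barcode identity, orientation)
        self.lookup: dict[str, tuple[str, str]] = {}
        for bc in self.barcodes:
            self.lookup[bc] = (bc, "fwd")
            self.lookup.setdefault(revcomp(bc), (bc, "revcomp"))

    @classmethod
    def from_file(cls, path, min_count: int = 0) -> "BarcodeWhitelist":
        """Load one barcode per line; an optional tab-separated count column
        enables filtering of low-coverage barcodes via ``min_count``."""
        barcodes = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) > 1 and min_count and int(parts[1]) < min_count:
                    continue
                barcodes.append(parts[0])
        return cls(frozenset(barcodes), source=str(path))


@dataclass
class DemuxedRead:
    read_id: str
    barcode: str
    umi: str
    trimmed_sequence: str  # transcript-sense (canonical)
    trimmed_quality: str
    matched_orientation: str  # fwd | revcomp, in the original read
    match_position: int  # 0-based offset of the barcode in the original read


@dataclass
class DemuxStats:
    counts: Counter = field(default_factory=Counter)
    barcode_counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def assigned_fraction(self) -> float:
        return self.counts["assigned"] / self.total if self.total else 0.0

    def write(self, stats_path, barcode_counts_path) -> None:
        with open(stats_path, "w") as fh:
            fh.write("category\tcount\n")
            for category in CATEGORIES:
                fh.write(f"{category}\t{self.counts.get(category, 0)}\n")
        with open(barcode_counts_path, "w") as fh:
            fh.write("barcode\tn_reads\n")
            for bc in sorted(self.barcode_counts):
                fh.write(f"{bc}\t{self.barcode_counts[bc]}\n")


@dataclass
class DemuxResult:
    category: str
    read: DemuxedRead | None = None
    barcodes_found: tuple[str, ...] = ()


def _scan(seq: str, lookup, window: int, bc_len: int):
    """Exact barcode occurrences in the first/last ``window`` nt of ``seq``."""
    n = len(seq)
    starts = set(range(0, min(window, n) - bc_len + 1))
    starts.update(range(max(0, n - window), n - bc_len + 1))
    hits = []
    for pos in sorted(starts):
        entry = lookup.get(seq[pos : pos + bc_len])
        if entry is not None:
            hits.append((pos, entry[0], entry[1]))
    return hits


def demultiplex_read(
    read_id: str,
    seq: str,
    qual: str,
    whitelist: BarcodeWhitelist,
    params: PipelineParams = PipelineParams(),
) -> DemuxResult:
    """Classify one read and, when assigned, trim and canonicalize it."""
    if len(seq) != len(qual):
        logger.warning("read %s: sequence/quality length mismatch; skipped", read_id)
        return DemuxResult("unassigned")
    if len(seq) <= params.demux_min_read_length:
        return DemuxResult("too_short")

    hits = _scan(seq, whitelist.lookup, params.scan_window, params.barcode_length)
    distinct = sorted({bc for _, bc, _ in hits})
    if not distinct:
        return DemuxResult("unassigned")
    if len(distinct) > 1:
        return DemuxResult("multi_barcode", barcodes_found=tuple(distinct))

    pos, barcode, orientation = hits[0]
    bl, trim = params.barcode_length, params.trim_downstream
    # work in barcode-forward sense
    if orientation == "fwd":
        fseq, fqual, fpos = seq, qual, pos
    else:
        fseq, fqual = revcomp(seq), qual[::-1]
        fpos = len(seq) - pos - bl
    umi = fseq[fpos + bl : fpos + bl + params.umi_length]
    if fpos <= len(fseq) - fpos - bl:
        # barcode nearer the 5' end: drop everything through barcode + 13 nt
        start = fpos + bl + trim
        remainder, rem_qual = fseq[start:], fqual[start:]
    else:
        # barcode nearer the 3' end: drop it and the tail beyond it
        remainder, rem_qual = fseq[:fpos], fqual[:fpos]
    # canonicalize to transcript sense (the barcode-forward remainder carries
    # the reverse complement of the transcript)
    demuxed = DemuxedRead(
        read_id=read_id,
        barcode=barcode,
        umi=umi,
        trimmed_sequence=revcomp(remainder),
        trimmed_quality=rem_qual[::-1],
        matched_orientation=orientation,
        match_position=pos,
    )
    return DemuxResult("assigned", read=demuxed, barcodes_found=(barcode,))


def demultiplex_run(
    fastq_path,
    whitelist: BarcodeWhitelist | str,
    params: PipelineParams = PipelineParams(),
    out_dir=None,
) -> tuple[dict[str, list[DemuxedRead]], DemuxStats]:
    """Partition a FASTQ into per-barcode read groups plus category stats.

    When ``out_dir`` is given, writes a single tagged FASTQ (headers carry
    ``barcode=`` and ``umi=`` fields), demux_stats.tsv and barcode_counts.tsv.
    """
    if not isinstance(whitelist, BarcodeWhitelist):
        whitelist = BarcodeWhitelist.from_file(whitelist)
    groups: dict[str, list[DemuxedRead]] = {}
    stats = DemuxStats()
    tagged = []
    for header, seq, qual in read_fastq(fastq_path):
        read_id = header.split()[0]
        result = demultiplex_read(read_id, seq, qual, whitelist, params)
        stats.counts[result.category] += 1
        if result.category == "assigned":
            read = result.read
            stats.barcode_counts[read.barcode] += 1
            groups.setdefault(read.barcode, []).append(read)
            tagged.append(
                (
                    f"{read_id} barcode={read.barcode} umi={read.umi}",
                    read.trimmed_sequence,
                    read.trimmed_quality,
                )
            )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fastq(os.path.join(out_dir, "demultiplexed.fastq"), tagged)
        stats.write(
            os.path.join(out_dir, "demux_stats.tsv"),
            os.path.join(out_dir, "barcode_counts.tsv"),
        )
    return groups, stats
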