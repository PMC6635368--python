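"""Ground-truthed simulation of barcoded long cDNA reads.

Emulates droplet-based 3'-barcoded single-cell libraries sequenced on an
error-prone long-read platform: each simulated cell owns a 16-nt barcode and a
small set of full-length receptor transcripts (T cells one TRA + one TRB
species, B cells one IGH + one light-chain species, background cells a decoy
non-receptor transcript). Reads carry, in barcode-forward sense,

    adapter(22) + barcode(16) + UMI(10) + polyT(20) + revcomp(transcript) + adapter(15)

so the 13-nt trim downstream of a barcode removes exactly the UMI plus a 3-nt
buffer. Reads are emitted on a random strand and passed through an independent
per-base substitution/insertion/deletion error process. Every read and every
cell has a truth row, which downstream accuracy measurements compare against.

Somatic hypermutation is substitution-only (the dominant mode of AID-induced
mutation) and confined to the V region, never touching the anchor codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .refdata import GermlineReference, GermlineSegment, LIGHT_LOCI
from .seqs import random_seq, read_fastq, revcomp, write_fastq

logger = logging.getLogger(__name__)

ADAPTER_5 = "AATGTACTTCGTTCAGTTACGT"  # 22 nt, arbitrary fixed library adapter
ADAPTER_3 = "GCAATACGTAACTGA"  # 15 nt
POLY_T = "T" * 20


@dataclass(frozen=True)
class ErrorProfile:
    """Independent per-base error rates of the simulated read process."""

    sub_rate: float = 0.05
    ins_rate: float = 0.025
    del_rate: float = 0.025

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= rate <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass
class ChainTruth:
    """Ground truth for one receptor transcript species of one cell."""

    transcript_id: str
    locus: str
    v_call: str
    j_call: str
    c_call: str | None
    c_form: str
    junction_nt: str
    cdr3_nt: str
    transcript: str
    germline_transcript: str  # pre-SHM sequence
    shm_positions: list[tuple[int, str, str]] = field(default_factory=list)
    v_interval: tuple[int, int] = (0, 0)

    @property
    def cdr3_aa(self) -> str:
        from .seqs import translate

        return translate(self.cdr3_nt)


@dataclass
class SimulatedCell:
    barcode: str
    cell_type: str  # T | B | background
    chains: list[ChainTruth] = field(default_factory=list)
    isotype: str | None = None
    form: str | None = None

    def chain(self, locus: str) -> ChainTruth:
        for chain in self.chains:
            if chain.locus == locus:
                return chain
        raise KeyError(locus)


@dataclass
class TruthTable:
    """Per-read and per-cell ground truth of a simulated run."""

    reads: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    # read_id -> (barcode, locus, transcript_id); chimeric reads carry
    # barcode "bc1;bc2" and locus "chimera"
    cells: dict[str, SimulatedCell] = field(default_factory=dict)

    def write(self, reads_path, cells_path) -> None:
        with open(reads_path, "w") as fh:
            fh.write("read_id\tbarcode\tlocus\ttranscript_id\n")
            for read_id, (bc, locus, tid) in self.reads.items():
                fh.write(f"{read_id}\t{bc}\t{locus}\t{tid}\n")
        with open(cells_path, "w") as fh:
            fh.write(
                "barcode\tcell_type\tlocus\tv_call\tj_call\tc_call\tc_form"
                "\tjunction_nt\tcdr3_nt\tn_shm\tshm_positions\n"
            )
            for cell in self.cells.values():
                if not cell.chains:
                    fh.write(f"{cell.barcode}\t{cell.cell_type}" + "\t" * 9 + "\n")
                for chain in cell.chains:
                    shm = ";".join(f"{p}:{o}>{m}" for p, o, m in chain.shm_positions)
                    fh.write(
                        f"{cell.barcode}\t{cell.cell_type}\t{chain.locus}"
                        f"\t{chain.v_call}\t{chain.j_call}\t{chain.c_call or ''}"
                        f"\t{chain.c_form}\t{chain.junction_nt}\t{chain.cdr3_nt}"
                        f"\t{len(chain.shm_positions)}\t{shm}\n"
                    )


@dataclass
class SimulateConfig:
    """Composition and structure of a simulated run."""

    t_fraction: float = 0.40
    b_fraction: float = 0.45  # remainder are receptor-free background cells
    junction_len_choices: tuple[int, ...] = (3, 6, 9, 12, 15, 18, 21)
    b_shm_range: tuple[int, int] = (0, 15)  # inclusive, per B-cell chain
    emit_both_igh_forms: bool = False
    igh_secreted_fraction: float = 0.7  # read ratio when both forms emitted
    chimera_rate: float = 0.01  # two-barcode chimeric reads (doublet analog)
    decoy_transcript_length: int = 1000

    def __post_init__(self) -> None:
        if self.t_fraction + self.b_fraction > 1.0 + 1e-9:
            raise ValueError("t_fraction + b_fraction must be <= 1")


# ------------------------------------------------------------ transcripts


def recombine_vdj(
    reference: GermlineReference,
    locus: str,
    v: str,
    j: str,
    junction_len: int,
    c: str | None = None,
    seed: int | np.random.Generator = 0,
    productive: bool = True,
) -> tuple[str, ChainTruth]:
    """Join a V, a random junction, a J tail, and a constant region.

    The transcript is ``V[:v_anchor+3] + junction + J[j_anchor:] + C``. The
    junction length is adjusted to the nearest frame-preserving value (a
    multiple of 3, since the V prefix ends on a codon boundary) unless
    ``productive=False``, in which case it is shifted by one to force a
    frameshift.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_seg = reference.by_gene(locus, "V", v)
    j_seg = reference.by_gene(locus, "J", j)
    c_seg: GermlineSegment | None = None
    if c is not None:
        candidates = [
            s
            for s in reference.get(locus, "C")
            if s.segment_id == c or s.gene_name == c or s.isotype == c
        ]
        if not candidates:
            raise KeyError(f"no constant segment {c!r} in locus {locus}")
        c_seg = candidates[0]

    length = max(0, min(30, junction_len))
    length = 3 * round(length / 3)
    if productive:
        # frame-preserving and stop-free: the junction sits on a codon
        # boundary after the V prefix, so stop-free codons keep the open
        # reading frame intact through the J tail
        from .seqs import random_orf

        junction = random_orf(rng, length // 3)
    else:
        length = length + 1 if length < 30 else length - 1
        junction = random_seq(rng, length)

    v_part = v_seg.sequence[: v_seg.v_anchor + 3]
    j_part = j_seg.sequence[j_seg.j_anchor :]
    transcript = v_part + junction + j_part + (c_seg.sequence if c_seg else "")
    cdr3 = transcript[v_seg.v_anchor : v_seg.v_anchor + 3 + length + 3]
    truth = ChainTruth(
        transcript_id=f"{locus}:{v}:{j}",
        locus=locus,
        v_call=v_seg.gene_name,
        j_call=j_seg.gene_name,
        c_call=c_seg.isotype if c_seg else None,
        c_form=c_seg.form if c_seg else "not_applicable",
        junction_nt=junction,
        cdr3_nt=cdr3,
        transcript=transcript,
        germline_transcript=transcript,
        v_interval=(0, v_seg.v_anchor + 3),
    )
    return transcript, truth


def apply_shm(
    transcript: str,
    n_mutations: int,
    v_region_interval: tuple[int, int],
    seed: int | np.random.Generator = 0,
    exclude: tuple[tuple[int, int], ...] = (),
) -> tuple[str, list[tuple[int, str, str]]]:
    """Introduce exactly ``n_mutations`` distinct substitutions in the V region.

    Positions inside any ``exclude`` interval (the anchor codons) are never
    touched. Returns the mutated transcript and the truth list of
    ``(position, original, mutated)``.
    """
    lo, hi = v_region_interval
    if not 0 <= lo <= hi <= len(transcript):
        raise ValueError("v_region_interval outside transcript")
    allowed = [
        p
        for p in range(lo, hi)
        if not any(a <= p < b for a, b in exclude)
    ]
    if n_mutations > len(allowed):
        raise ValueError("more mutations requested than mutable positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = sorted(rng.choice(allowed, size=n_mutations, replace=False))
    seq = list(transcript)
    truth = []
    for pos in positions:
        original = seq[pos]
        options = [b for b in "ACGT" if b != original]
        mutated = options[rng.integers(0, 3)]
        seq[pos] = mutated
        truth.append((int(pos), original, mutated))
    return "".join(seq), truth


def apply_shm_viable(
    transcript: str,
    n_mutations: int,
    v_region_interval: tuple[int, int],
    seed: int | np.random.Generator = 0,
    exclude: tuple[tuple[int, int], ...] = (),
    max_tries: int = 100,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Like :func:`apply_shm`, but models a viable B cell: draws that create
    an in-frame stop codon in the V region (a non-productive receptor that
    selection would remove) are redrawn."""
    from .seqs import translate

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        mutated, positions = apply_shm(
            transcript, n_mutations, v_region_interval, seed=rng, exclude=exclude
        )
        if "*" not in translate(mutated[: v_region_interval[1]]):
            return mutated, positions
    return mutated, positions


# ------------------------------------------------------------------ reads


def build_read(
    transcript: str,
    barcode: str,
    umi: str,
    orientation: str = "fwd",
    seed: int | None = None,  # accepted for interface symmetry; layout is fixed
) -> str:
    """Assemble the error-free read layout around a transcript.

    Barcode-forward sense: 5' adapter, barcode, UMI, polyT, reverse complement
    of the transcript, 3' adapter. ``orientation="rev"`` returns the reverse
    complement of the whole read.
    """
    if len(barcode) != 16:
        raise ValueError("barcode must be 16 nt")
    if len(umi) != 10:
        raise ValueError("UMI must be 10 nt")
    read = ADAPTER_5 + barcode + umi + POLY_T + revcomp(transcript) + ADAPTER_3
    if orientation == "rev":
        read = revcomp(read)
    elif orientation != "fwd":
        raise ValueError("orientation must be 'fwd' or 'rev'")
    return read


_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def apply_errors(
    read: str,
    profile: ErrorProfile,
    seed: int | np.random.Generator = 0,
) -> str:
    """Per-base independent substitution / insertion / deletion process.

    Each base is deleted with probability ``del_rate``, else substituted with
    probability ``sub_rate`` (to a uniformly chosen different base); an extra
    uniform base is inserted after each position with probability ``ins_rate``.
    """
    if not read:
        return read
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _BASE_LUT[np.frombuffer(read.encode(), dtype=np.uint8)].astype(np.int64)
    n = codes.size
    u = rng.random(n)
    deleted = u < profile.del_rate
    substituted = (~deleted) & (u < profile.del_rate + profile.sub_rate)
    inserted = rng.random(n) < profile.ins_rate
    if substituted.any():
        codes[substituted] = (
            codes[substituted] + rng.integers(1, 4, size=int(substituted.sum()))
        ) % 4
    keep = ~deleted
    counts = keep.astype(np.int64) + inserted
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out[starts[keep]] = _BASE_ARR[codes[keep]]
    if inserted.any():
        ins_pos = starts[inserted] + keep[inserted]
        out[ins_pos] = _BASE_ARR[rng.integers(0, 4, size=int(inserted.sum()))]
    return out.tobytes().decode()


# -------------------------------------------------------------------- runs


@dataclass
class SimulatedRun:
    fastq_path: str
    whitelist_path: str
    truth: TruthTable
    reference: GermlineReference


def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    barcodes: set[str] = set()
    while len(barcodes) < n:
        bc = random_seq(rng, 16)
        if revcomp(bc) not in barcodes:
            barcodes.add(bc)
    return sorted(barcodes)


def _make_cell(
    reference: GermlineReference,
    barcode: str,
    cell_type: str,
    config: SimulateConfig,
    rng: np.random.Generator,
) -> SimulatedCell:
    cell = SimulatedCell(barcode=barcode, cell_type=cell_type)
    if cell_type == "background":
        return cell

    def pick(options):
        return options[rng.integers(0, len(options))]

    if cell_type == "T":
        loci = [l for l in ("TRA", "TRB") if reference.get(l, "V")]
        shm_range = (0, 0)
    else:
        light = sorted(set(reference.loci()) & LIGHT_LOCI)
        loci = ["IGH"] + ([pick(light)] if light else [])
        shm_range = config.b_shm_range
        isotypes = sorted({s.isotype for s in reference.get("IGH", "C")})
        cell.isotype = pick(isotypes)
        cell.form = pick(["membrane", "secreted"])

    for locus in loci:
        v = pick(reference.get(locus, "V")).gene_name
        j = pick(reference.get(locus, "J")).gene_name
        if locus == "IGH":
            c_id = f"{cell.isotype}-{cell.form}"
        else:
            c_segs = reference.get(locus, "C")
            c_id = c_segs[0].segment_id if c_segs else None
        junction_len = int(pick(list(config.junction_len_choices)))
        transcript, truth = recombine_vdj(
            reference, locus, v, j, junction_len, c=c_id, seed=rng
        )
        n_shm = int(rng.integers(shm_range[0], shm_range[1] + 1))
        if n_shm:
            v_seg = reference.by_gene(locus, "V", v)
            anchor = (v_seg.v_anchor, v_seg.v_anchor + 3)
            mutated, positions = apply_shm_viable(
                transcript, n_shm, truth.v_interval, seed=rng, exclude=(anchor,)
            )
            truth.transcript = mutated
            truth.shm_positions = positions
            truth.cdr3_nt = mutated[
                v_seg.v_anchor : v_seg.v_anchor + len(truth.cdr3_nt)
            ]
        cell.chains.append(truth)
    return cell


def simulate_run(
    reference: GermlineReference,
    n_cells: int,
    reads_per_cell: int,
    profile: ErrorProfile = ErrorProfile(),
    config: SimulateConfig | None = None,
    seed: int = 0,
    out_dir=".",
    prefix: str = "sim",
) -> SimulatedRun:
    """Simulate a full run: FASTQ, barcode whitelist, and truth tables."""
    import os

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    config = config or SimulateConfig()
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(rng, n_cells)

    n_t = int(round(config.t_fraction * n_cells))
    n_b = int(round(config.b_fraction * n_cells))
    n_t = min(n_t, n_cells)
    n_b = min(n_b, n_cells - n_t)
    types = ["T"] * n_t + ["B"] * n_b + ["background"] * (n_cells - n_t - n_b)
    rng.shuffle(types)

    truth = TruthTable()
    cells = []
    for barcode, cell_type in zip(barcodes, types):
        cell = _make_cell(reference, barcode, cell_type, config, rng)
        truth.cells[barcode] = cell
        cells.append(cell)

    records = []
    read_no = 0
    for cell in cells:
        # species to emit and their sampling weights
        if cell.cell_type == "background":
            decoy = random_seq(rng, config.decoy_transcript_length)
            species = [(f"decoy:{cell.barcode}", "none", decoy)]
            weights = [1.0]
        else:
            species = [(c.transcript_id, c.locus, c.transcript) for c in cell.chains]
            weights = [1.0] * len(species)
            if (
                cell.cell_type == "B"
                and config.emit_both_igh_forms
                and cell.isotype is not None
            ):
                igh = cell.chain("IGH")
                other_form = "membrane" if cell.form == "secreted" else "secreted"
                # same V(D)J (and SHM) as the primary form, different C tail
                c_primary = reference.segments[f"{cell.isotype}-{cell.form}"]
                c_alt = reference.segments[f"{cell.isotype}-{other_form}"]
                body_len = len(igh.transcript) - len(c_primary.sequence)
                alt_seq = igh.transcript[:body_len] + c_alt.sequence
                sec = config.igh_secreted_fraction
                for i, (tid, locus, _) in enumerate(species):
                    if tid == igh.transcript_id:
                        weights[i] = sec if cell.form == "secreted" else 1 - sec
                species.append((f"IGH:{igh.v_call}:{igh.j_call}:{other_form}", "IGH", alt_seq))
                weights.append(1 - sec if cell.form == "secreted" else sec)
        weights = np.array(weights) / np.sum(weights)
        choice = rng.choice(len(species), size=reads_per_cell, p=weights)
        for k in range(reads_per_cell):
            tid, locus, transcript = species[int(choice[k])]
            umi = random_seq(rng, 10)
            orientation = "fwd" if rng.random() < 0.5 else "rev"
            read = build_read(transcript, cell.barcode, umi, orientation)
            bc_truth, locus_truth = cell.barcode, locus
            if config.chimera_rate and rng.random() < config.chimera_rate:
                other = cells[int(rng.integers(0, len(cells)))]
                if other.barcode != cell.barcode:
                    extra = build_read(
                        other.chains[0].transcript
                        if other.chains
                        else random_seq(rng, 400),
                        other.barcode,
                        random_seq(rng, 10),
                        "fwd",
                    )
                    read = read + extra
                    bc_truth = f"{cell.barcode};{other.barcode}"
                    locus_truth = "chimera"
            read = apply_errors(read, profile, seed=rng)
            read_id = f"{prefix}_r{read_no:07d}"
            read_no += 1
            truth.reads[read_id] = (bc_truth, locus_truth, tid)
            records.append((read_id, read, "I" * len(read)))

    os.makedirs(out_dir, exist_ok=True)
    fastq_path = os.path.join(out_dir, f"{prefix}.fastq")
    whitelist_path = os.path.join(out_dir, f"{prefix}_whitelist.txt")
    write_fastq(fastq_path, records)
    with open(whitelist_path, "w") as fh:
        for bc in barcodes:
            fh.write(bc + "\n")
    truth.write(
        os.path.join(out_dir, f"{prefix}_truth_reads.tsv"),
        os.path.join(out_dir, f"{prefix}_truth_cells.tsv"),
    )
    return SimulatedRun(fastq_path, whitelist_path, truth, reference)


def subsample_reads(
    fastq_path,
    depth: int,
    seed: int,
    out_path,
    group_key=None,
) -> None:
    """Seeded per-group subsampling without replacement.

    Reads are grouped by ``group_key(header)`` (default: the ``barcode=...``
    tag demultiplexing writes into headers, else one global group) and up to
    ``depth`` reads are kept per group, preserving input order so that
    stepwise subsampling (a subsample of a subsample) stays well-defined. If a
    group holds fewer than ``depth`` reads, all are kept with a warning.
    """
    records = read_fastq(fastq_path)

    def default_key(header: str) -> str:
        for token in header.split():
            if token.startswith("barcode="):
                return token[8:]
        return ""

    key = group_key or default_key
    groups: dict[str, list[int]] = {}
    for i, (header, _, _) in enumerate(records):
        groups.setdefault(key(header), []).append(i)

    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for group in sorted(groups):
        indices = groups[group]
        if depth >= len(indices):
            if depth > len(indices):
                logger.warning(
                    "group %r has %d reads < depth %d; keeping all",
                    group, len(indices), depth,
                )
            keep.update(indices)
        else:
            chosen = rng.choice(len(indices), size=depth, replace=False)
            keep.update(indices[int(c)] for c in chosen)
    write_fastq(out_path, [records[i] for i in sorted(keep)])
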