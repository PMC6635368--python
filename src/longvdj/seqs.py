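"""Small nucleotide-sequence helpers shared across the package.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
CYS_CODONS = frozenset({"TGT", "TGC"})
TRP_PHE_CODONS = frozenset({"TGG", "TTT", "TTC"})

#: the 61 sense codons, sorted; used by the synthetic germline generator to
#: build open reading frames that stay stop-free by construction
SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in STOP_CODONS
    )
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon (standard code).

    A trailing partial codon is dropped. Stops translate to ``*``.
    """
    n = len(seq) - len(seq) % 3
    return "".join(_CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame, stop-free coding sequence of ``n_codons`` codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a plain-text FASTQ file into ``(header, sequence, quality)`` tuples.

    The header is the full ``@`` line minus the prefix (id + description).
    """
    records = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            records.append((header[1:].rstrip("\n"), seq, qual))
    return records


def write_fastq(path, records) -> None:
    """Write ``(header, sequence, quality)`` tuples as plain-text FASTQ."""
    with open(path, "w") as fh:
        for header, seq, qual in records:
            fh.write(f"@{header}\n{seq}\n+\n{qual}\n")
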