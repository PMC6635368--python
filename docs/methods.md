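# Methods

This note documents the models and procedures `longvdj` implements, the
defaults and why they hold, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Read model and demultiplexing

A simulated read, in barcode-forward sense, is

```
adapter(22) + barcode(16) + UMI(10) + polyT(20) + revcomp(transcript) + adapter(15)
```

emitted on a random strand. This is the bead-oligo layout of 3'-barcoded
droplet libraries: the barcode precedes the UMI, so removing the **13 nt
downstream of a matched barcode** deletes exactly the 10-nt UMI plus a 3-nt
buffer against local insertions. Demultiplexing scans the first and last
**200 nt** of every read longer than **250 nt** for an exact (0-mismatch,
0-indel) occurrence of a whitelist barcode, forward or reverse-complemented.
Exact matching trades recall for precision deliberately: under independent
per-base errors at total rate *e* the probability that a barcode survives
intact is approximately (1−e)^16 — about 85% at e=0.01 and about 20% at the
default e=0.1 — and the package verifies the closed form by Monte Carlo.
Repeated occurrences of the *same* barcode count once; only distinct barcodes
make a read a chimera candidate (`multi_barcode`). Beyond the 13-nt trim
rule, the barcode itself and the adapter remnant between it and the nearer
read end are also removed, so constant library sequence cannot leak into
consensus; and every kept read is reverse-complemented into transcript sense,
so all downstream stages see one strand. Both choices are information-
preserving conveniences, recorded here because the underlying protocol is
silent on them.

Whitelist hygiene: barcodes must be 16 nt and unique; a barcode equal to the
reverse complement of another (or of itself) makes strand assignment
ambiguous and is warned about. An optional count column supports dropping
low-coverage barcodes upstream.

## Consensus

Full-length cDNA reads of one cell are **clustered, not assembled**: every
read spans its whole transcript, so the computation needed is a per-transcript
consensus. Reads shorter than **200 nt** are discarded and evidence spanning
less than **100 nt** of estimated overlap is ignored (the same roles these two
values play as minimum read length and minimum overlap in long-read
assemblers). Clustering is greedy and deterministic: reads sorted by length
(ties by id) join the first cluster whose representative shares enough
distinct 13-mers — containment ≥ 0.03 and a shared-k-mer span ≥ 100 nt.

The containment default follows from the error model: two reads of the same
transcript at total error rate *e* share a given 13-mer only if it is intact
in both, with probability (1−e)^(2·13) ≈ 0.065 at e=0.1, while reads of
unrelated transcripts share ≈ 0.005 of their k-mers by chance. 0.03 sits
between the two regimes. It is configurable (`PipelineParams.kmer_containment`)
and should be raised for cleaner reads.

Consensus is center-star: each member is aligned to the representative
(edit-distance alignment via edlib; affine scoring buys nothing for voting)
and each column takes the majority over {A, C, G, T, gap}, ties to the
representative's base, gap-majority columns deleted, insertions emitted only
on strict-majority support. **Polishing** re-aligns all members to the current
consensus and re-votes, by default **4 rounds**, stopping early at a fixed
point; this also repairs indels the first vote inherited from the
representative. With per-column error ≲ 10% the majority vote is wrong with
probability that decays exponentially in read depth, which is why accuracy
plateaus by ~50 reads per cell.

## Annotation

Segment assignment is optimal affine-gap local alignment (Gotoh) with defaults
match +2, mismatch −2, gap open −4, gap extend −2 — mild indel penalties
suited to long-read error. The dynamic program runs in C
(`Bio.Align.PairwiseAligner`); scores are exactly optimal (the test suite
checks them against an independent exhaustive DP), and one deterministic
traceback is reported. A V call requires score ≥ 50 (≈ 25 matched bases); the
best locus is the one maximizing V+J score.

**Indel correction** then reverts, inside the V- and J-aligned intervals only,
every query insertion (deleted) and deletion (filled with the germline base);
substitutions and the untemplated junction are never touched. The contig is
re-annotated once (two passes total). This mirrors the practical fix for
long-read V(D)J calling: a single indel upstream of the junction shifts the
CDR3 reading frame, while substitution-only hypermutation is preserved
exactly — the suite verifies that correction never changes the mismatch set.

The **CDR3** spans the contig positions aligned to the conserved V cysteine-104
codon through the J tryptophan/phenylalanine-118 codon, both codons included
(AIRR junction convention). A chain is **productive** when the junction
preserves the V reading frame into J and the translation from V start through
J end contains no stop codon. **V mutations** are the substitution count in
the post-correction V alignment; the mutation rate is 100·mutations/aligned
length.

**Constant regions** are called on the *uncorrected* contig (as in practice:
the C call precedes correction and tolerates indels through its identity
margin) against pre-spliced C transcripts, requiring coverage > 0.95 of the C
reference and identity > 0.90, best score among passing candidates. For IGH
every isotype is present as a membrane and a secreted entry differing in their
3' tail; the winning entry fixes both isotype and splice form. A ~150-nt
divergent tail leaves the wrong form below the coverage threshold, which is
what makes the call well-posed.

On-target classification (the capture-enrichment measure) flags a read whose
best local alignment to any constant region exceeds the score threshold; a
shared-13-mer seed filter ranks candidates and skips hopeless ones, but the
call itself is always the alignment score.

## Repertoire rules

Filtering: non-productive chains are removed; BCR chains with **more than 40**
and TCR chains with **more than 5** V-segment mutations are removed (strictly
greater: 40 and 5 survive). Within a cell, chains sharing V and J but
differing in CDR3 collapse to the least-mutated candidate for TCR (ties by
read support) and the best-supported candidate for BCR; across groups the
best-supported survivor is the primary chain and the next distinct one
secondary. All tie-breaks are total orders, so assignment is independent of
input order.

Clonotypes: T cells require identical V and J genes and identical CDR3 amino
acids (per chain, both chains for paired classes); B cells require the same V
and J genes with CDR3 nucleotide identity ≥ 0.90, computed as 1 − Hamming/length
between equal-length CDR3s and grouped by single linkage — unequal lengths
never co-cluster, because Hamming identity is undefined across lengths. Both
chains of a paired B clonotype must satisfy the rule. A single-chain mode
supports keying on one locus (e.g. TCRβ for cross-tissue sharing). A clone is
*expanded* when it spans more than one cell; *shared tissues* is the set of
sample labels among members. MAIT cells are flagged by TRAV1-2 with
TRAJ33/TRAJ20/TRAJ12, GEM cells by TRAV1-2 with TRAJ9 — string equality on
gene names, configurable.

The **unmutated ancestor** of a clone family is germline V (through its anchor
codon) plus the per-position majority junction plus germline J (from its
anchor): every germline-templated substitution reverts, the untemplated
junction is estimated by vote. The **clone network** has one node per unique
concatenated heavy+light V(D)J amino-acid sequence (the UA included with
member count 0); each node connects to every node at its minimal Hamming
distance, edge weight that distance. Length-heterogeneous clones are
partitioned by length with one network per partition.

Clone-expression similarity takes each cell's top-250 most abundant genes as a
set, computes the Jaccard coefficient per pair, and compares clonal pairs with
matched controls by a paired one-sided Wilcoxon signed-rank test.

## The synthetic reference and simulator

The generator emits, per locus, random V segments (~290 nt stop-free ORFs
ending in a Cys codon), J segments (~50 nt beginning with a Trp/Phe anchor
codon followed by an in-frame stop-free tail), and constant regions (TCR and
light-chain C ~450 nt; IGH isotypes as membrane/secreted pairs sharing a
~900 nt body with divergent ~150 nt tails). Anchors sit at the segment
boundaries that recombination uses, so anchor mapping through alignment is
exact by construction; random same-type segments are pairwise far below 85%
identity, so best-hit assignment is well-posed.

A transcript is `V[:anchor+3] + junction + J[anchor:] + C`. Productive
junctions (0–30 nt, frame-preserving) are drawn from sense codons, and
hypermutation draws that would create an in-frame V-region stop are redrawn:
the simulator models *viable* cells whose receptors are productive, the
population the pipeline is meant to recover (cells with stop-bearing receptors
exist in reality and are correctly filtered as non-productive — they are
simply not part of the recovery ground truth). SHM is substitution-only,
confined to the V region, never touching anchors; this reflects the dominance
of point substitutions in AID-induced mutation and keeps the indel-correction
contract cleanly testable. Read errors are per-base independent
(substitution/insertion/deletion, defaults 5%/2.5%/2.5%); cell composition
defaults to 40% T, 45% B, 15% receptor-free background cells emitting a decoy
transcript; chimeric two-barcode reads are generated at a configurable rate
(default 1%).

What the simulator does **not** model: homopolymer-biased or otherwise
structured long-read error, raw-signal information, PCR duplication and
barcode-count distortion, UMI collisions, splice variation beyond the
membrane/secreted IGH forms, allelic diversity within a gene, and real IMGT
sequence composition. Passing tests therefore demonstrate the correctness of
the algorithms under a faithful but idealized error process, not performance
on any particular instrument's data. With a real germline reference (FASTA +
anchor sidecar TSV) and real FASTQs, the same pipeline applies unchanged.

## Problem sizes and numerical choices

Validation experiments run at desk scale: 2,000 reads for the barcode closed
form; 20 error-free cells for the identity limit; 50 cells × 100 reads at the
default 10% error for consensus recovery; 12 cells titrated stepwise over
1000/500/250/100/50 demultiplexed reads per cell; 30 B cells at ~100×
demultiplexed coverage for hypermutation precision/recall; 100 simulated clone
families for UA and network checks. Determinism is enforced by seeding every
random source, processing cells and clusters in sorted order, and breaking
every tie totally (alignment traceback, vote ties toward the current
consensus, lexicographic gene names); the run manifest records parameters,
seeds and checksums, and omits wall-clock timestamps by default so reruns are
byte-identical.

Known limitations: no D-segment calls (the V–J junction subsumes D and N
nucleotides; nothing downstream uses D), no E-value statistics for assignment
(a fixed minimum score replaces them), gene-level rather than allele-level
calls, one indel-correction pass rather than iteration to convergence, and no
UMI-based deduplication before consensus.
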