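"""Turn aligned reads into deduplicated single-nucleotide signal points.

Mirrors the pre-profiling pipeline for high-throughput sequencing data:
uniform-length / no-N / MAPQ filtering of alignments, per-replicate
duplicate removal, reduction of each read to its center (ChIP-Seq,
CLIP-Seq) or 5' end (GRO-Seq), and pooling of biological replicates.  The
number of replicates pooled bounds how often one (chromosome, position,
strand) coordinate can recur, which downstream testing uses as the
max-possible read capacity per bin.

Also provides a brute-force mappability enumerator for small genomes: every
read of a fixed length over a region (plus flanks) is checked for unique
occurrence in the genome concatenated with its reverse complement, and the
centers of the unique ones form a mappability track.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from profileseq.records import GenomicInterval, SignalPoint

__all__ = [
    "AlignedRead",
    "PooledPointSet",
    "filter_aligned_reads",
    "reduce_read",
    "deduplicate_and_pool",
    "deduplicate_reads",
    "reads_from_sam",
    "enumerate_mappable_centers",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """A single-end alignment in closed 1-based coordinates."""

    chrom: str
    start: int
    read_length: int
    strand: str
    mapq: int = 0
    sequence: str | None = None

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.read_length:
            raise ValueError("sequence length disagrees with read_length")

    @property
    def end(self) -> int:
        return self.start + self.read_length - 1


@dataclass
class PooledPointSet:
    """Reduced signal points pooled over replicates.

    ``max_repeats`` is the maximum number of times one (chrom, position,
    strand) coordinate may recur — after per-replicate deduplication this
    equals the number of replicates pooled.
    """

    points: list = field(default_factory=list)
    max_repeats: int = 1
    n_replicates: int = 1

    def __post_init__(self):
        counts = Counter((p.chrom, p.position, p.strand) for p in self.points)
        if counts and max(counts.values()) > self.max_repeats:
            key, n = counts.most_common(1)[0]
            raise ValueError(
                f"coordinate {key} occurs {n} times, exceeds max_repeats="
                f"{self.max_repeats}"
            )

    def __len__(self) -> int:
        return len(self.points)


def filter_aligned_reads(
    reads: Iterable[AlignedRead],
    required_length: int,
    min_mapq_exclusive: int = 30,
) -> list[AlignedRead]:
    """Keep reads of exactly ``required_length``, with no 'N', and MAPQ
    strictly above ``min_mapq_exclusive`` (default drops MAPQ <= 30)."""
    if required_length < 1:
        raise ValueError("required_length must be >= 1")
    kept = []
    for read in reads:
        if read.read_length != required_length:
            continue
        if read.sequence is not None and "N" in read.sequence.upper():
            continue
        if read.mapq <= min_mapq_exclusive:
            continue
        kept.append(read)
    return kept


def reduce_read(read: AlignedRead, mode: str = "center") -> SignalPoint:
    """Reduce a read to one nucleotide: its center (half-integers rounded
    up) or its 5' end (start on +, end on −)."""
    if mode == "center":
        position = (read.start + read.end + 1) // 2
    elif mode == "five_prime":
        position = read.start if read.strand == "+" else read.end
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    return SignalPoint(read.chrom, position, read.strand)


def deduplicate_reads(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Per-replicate duplicate removal on the full read span
    (chrom, start, end, strand), keeping first occurrence; reads are
    reduced to points only afterwards."""
    seen = set()
    out = []
    for read in reads:
        key = (read.chrom, read.start, read.end, read.strand)
        if key not in seen:
            seen.add(key)
            out.append(read)
    return out


def deduplicate_and_pool(
    replicates: Sequence[Sequence[SignalPoint]],
) -> PooledPointSet:
    """Deduplicate each replicate on (chrom, position, strand), then pool.

    The pooled set is sorted by (chrom, position, strand); its
    ``max_repeats`` equals the number of replicates, since after
    per-replicate deduplication a coordinate can appear at most once per
    replicate.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    pooled = []
    for replicate in replicates:
        seen = set()
        for point in replicate:
            key = (point.chrom, point.position, point.strand)
            if key not in seen:
                seen.add(key)
                pooled.append(point)
    pooled.sort(key=lambda p: (p.chrom, p.position, p.strand))
    return PooledPointSet(
        points=pooled, max_repeats=len(replicates), n_replicates=len(replicates)
    )


def reads_from_sam(path, mapq_field: bool = True) -> list[AlignedRead]:
    """Ingest single-end alignments from a SAM file via pysam.

    Unmapped, secondary and supplementary records are skipped.  Coordinates
    come back 1-based closed; the span is the reference span of the
    alignment.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            start = aln.reference_start + 1  # pysam is 0-based half-open
            length = aln.reference_length or len(aln.query_sequence or "")
            if length < 1:
                continue
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    start=start,
                    read_length=length,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality if mapq_field else 0,
                    sequence=aln.query_sequence,
                )
            )
    return reads


def enumerate_mappable_centers(
    genome: Mapping[str, str],
    region: GenomicInterval,
    read_length: int,
    flank: int = 2000,
) -> list[SignalPoint]:
    """Enumerate centers of uniquely-mapping reads over ``region`` ± flanks.

    Every read of length ``read_length`` starting at ``region.start - flank
    + i`` for i = 0 … (end + flank - start - read_length + 1) is extracted
    (clipped to chromosome bounds).  A read is mappable iff its sequence
    occurs exactly once in the text formed by the genome plus its reverse
    complement; the center (half-up midpoint) of each mappable read is
    emitted as an unstranded point.

    Intended for desk-scale genomes; quadratic-free via a k-mer occurrence
    table over the forward and reverse-complement sequences.
    """
    chrom_seq = genome[region.chrom].upper()
    r = read_length
    counts: Counter = Counter()
    for seq in genome.values():
        s = seq.upper()
        for text in (s, reverse_complement(s)):
            for i in range(len(text) - r + 1):
                counts[text[i : i + r]] += 1

    first = max(1, region.start - flank)
    last_start = min(len(chrom_seq) - r + 1, region.end + flank - r + 1)
    out = []
    for start in range(first, last_start + 1):
        kmer = chrom_seq[start - 1 : start - 1 + r]
        if len(kmer) < r or "N" in kmer:
            continue
        if counts[kmer] == 1:
            center = (start + start + r - 1 + 1) // 2
            out.append(SignalPoint(region.chrom, center, "."))
    return out
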