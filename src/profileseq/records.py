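"""Coordinate records and readers/writers for the track formats the tool uses.

All records are held internally in 1-based, fully-closed coordinates (the
first nucleotide of a sequence is position 1, and both interval ends are
included).  Readers and writers accept either this dialect or the standard
half-open 0-based convention of BED, selected explicitly — formats are never
sniffed.

Formats:

* ``bed`` — BED6; columns beyond the sixth (e.g. broadPeak statistics) are
  ignored on input and omitted on output.
* ``pos`` — three columns ``chrom  position  strand``; a single-nucleotide
  signal point per line.
* ``ref`` — four columns ``id  chrom  position  strand``; an anchored
  reference position per line.  A dot-separated, id-first variant (fields
  joined by ``.``) is accepted and written behind the ``dot_separated`` flag.
* ``gtf_minimal`` — 9-column GTF restricted to the fields needed for
  internal-exon extraction; the attribute string is kept as a key → value
  map with unknown attributes preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "ReferencePoint",
    "SignalPoint",
    "AnnotationRecord",
    "TrackParseError",
    "convert_interval_dialect",
    "parse_track",
    "write_track",
]

STRANDS = ("+", "-", ".")

#: Recognised coordinate dialects.
DIALECTS = ("closed_1based", "half_open_0based")


class TrackParseError(ValueError):
    """A malformed line in a track file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _check_strand(strand: str, allowed: Sequence[str] = STRANDS) -> str:
    if strand not in allowed:
        raise ValueError(f"unknown strand symbol {strand!r}")
    return strand


@dataclass(frozen=True)
class GenomicInterval:
    """A closed, 1-based genomic interval; ``length = end - start + 1``.

    Closed 1-based intervals have ``start >= 1``; a start of 0 is tolerated
    only so the type can carry a half-open 0-based coordinate pair through
    an explicit dialect conversion.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        _check_strand(self.strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def center(self) -> int:
        """Midpoint position, half-integers rounded up."""
        return (self.start + self.end + 1) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end


@dataclass(frozen=True)
class ReferencePoint:
    """An anchor position around which signal is profiled (one ``.ref`` line)."""

    id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        _check_strand(self.strand, ("+", "-"))


@dataclass(frozen=True)
class SignalPoint:
    """A single-nucleotide signal coordinate (one ``.pos`` line)."""

    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        _check_strand(self.strand)


@dataclass(frozen=True)
class AnnotationRecord:
    """A minimal GTF-derived feature (exon, transcript, UTR or TSS)."""

    feature: str
    interval: GenomicInterval
    transcript_id: str | None = None
    gene_id: str | None = None
    attributes: tuple = field(default_factory=tuple)
    source: str = "."

    @property
    def attribute_map(self) -> dict:
        return dict(self.attributes)


def convert_interval_dialect(
    interval: GenomicInterval, from_dialect: str, to_dialect: str
) -> GenomicInterval:
    """Re-express an interval's coordinates in another dialect.

    The same genomic nucleotides are covered before and after; converting
    back is the identity.  ``half_open_0based`` intervals are represented
    with ``GenomicInterval`` fields holding the raw (start, end) pair, so a
    half-open interval of length 1 has ``end = start + 1``.
    """
    for d in (from_dialect, to_dialect):
        if d not in DIALECTS:
            raise ValueError(f"unknown dialect {d!r}")
    if from_dialect == to_dialect:
        return interval
    if from_dialect == "half_open_0based":
        start, end = interval.start + 1, interval.end
    else:
        start, end = interval.start - 1, interval.end
    if start < (1 if to_dialect == "closed_1based" else 0) or end < start:
        raise ValueError(
            f"interval ({interval.start}, {interval.end}) invalid after "
            f"conversion to {to_dialect}"
        )
    return GenomicInterval(interval.chrom, start, end, interval.strand, interval.id)


# GenomicInterval validates start >= 1, which a raw half-open start of 0
# would violate; half-open records are therefore carried through parsing as
# plain tuples and only materialised after conversion to closed coordinates.
def _closed_from_dialect(chrom, start, end, strand, name, dialect, lineno):
    if dialect == "half_open_0based":
        start, end = start + 1, end
    if start < 1 or end < start:
        raise TrackParseError(
            f"invalid coordinates ({start}, {end}) after dialect conversion", lineno
        )
    return GenomicInterval(chrom, start, end, strand, name)


def _parse_attributes(attr_string: str) -> tuple:
    """Parse a GTF attribute column into ((key, value), ...) preserving order."""
    out = []
    for chunk in attr_string.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 1:
            out.append((parts[0], ""))
        else:
            key, value = parts
            out.append((key, value.strip().strip('"')))
    return tuple(out)


def _point_position(raw: int, dialect: str) -> int:
    return raw + 1 if dialect == "half_open_0based" else raw


def parse_track(
    path,
    format: str,
    dialect: str = "closed_1based",
    dot_separated: bool = False,
):
    """Read a track file into typed records (internal closed 1-based coords).

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"bed", "pos", "ref", "gtf_minimal"}
        Declared format; never sniffed.
    dialect : {"closed_1based", "half_open_0based"}
        Coordinate dialect of the file.  GTF is 1-based closed by
        definition and ignores this flag.
    dot_separated : bool
        Accept the dot-separated, id-first ``.ref`` variant.

    Returns
    -------
    list of SignalPoint | ReferencePoint | GenomicInterval | AnnotationRecord
        One record per non-comment, non-blank line, in file order.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    seen_ref_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            try:
                records.append(
                    _parse_line(line, format, dialect, dot_separated, lineno)
                )
            except TrackParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise TrackParseError(str(exc), lineno) from exc
            if format == "ref":
                rid = records[-1].id
                if rid in seen_ref_ids:
                    raise TrackParseError(f"duplicate reference id {rid!r}", lineno)
                seen_ref_ids.add(rid)
    return records


def _parse_line(line, format, dialect, dot_separated, lineno):
    if format == "pos":
        fields = line.split("\t")
        if len(fields) < 3:
            raise TrackParseError("pos line needs chrom, position, strand", lineno)
        chrom, raw, strand = fields[0], int(fields[1]), fields[2]
        return SignalPoint(chrom, _point_position(raw, dialect), strand)
    if format == "ref":
        fields = line.split(".") if dot_separated else line.split("\t")
        if len(fields) < 4:
            raise TrackParseError(
                "ref line needs id, chrom, position, strand", lineno
            )
        rid, chrom, raw, strand = fields[0], fields[1], int(fields[2]), fields[3]
        return ReferencePoint(rid, chrom, _point_position(raw, dialect), strand)
    if format == "bed":
        fields = line.split("\t")
        if len(fields) < 3:
            raise TrackParseError("bed line needs chrom, start, end", lineno)
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 else "."
        _check_strand(strand)
        return _closed_from_dialect(chrom, start, end, strand, name, dialect, lineno)
    if format == "gtf_minimal":
        fields = line.split("\t")
        if len(fields) < 9:
            raise TrackParseError("gtf line needs 9 tab-separated columns", lineno)
        chrom, source, feature = fields[0], fields[1], fields[2]
        start, end = int(fields[3]), int(fields[4])
        strand = fields[6]
        _check_strand(strand)
        attrs = _parse_attributes(fields[8])
        amap = dict(attrs)
        interval = GenomicInterval(chrom, start, end, strand)
        return AnnotationRecord(
            feature=feature,
            interval=interval,
            transcript_id=amap.get("transcript_id"),
            gene_id=amap.get("gene_id"),
            attributes=attrs,
            source=source,
        )
    raise ValueError(f"unknown format {format!r}")


def write_track(
    records: Iterable,
    path,
    format: str,
    dialect: str = "closed_1based",
    dot_separated: bool = False,
) -> None:
    """Serialize homogeneous records; round-trips with :func:`parse_track`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(_format_line(rec, format, dialect, dot_separated) + "\n")


def _format_line(rec, format, dialect, dot_separated):
    offset = -1 if dialect == "half_open_0based" else 0
    if format == "pos":
        return f"{rec.chrom}\t{rec.position + offset}\t{rec.strand}"
    if format == "ref":
        fields = [rec.id, rec.chrom, str(rec.position + offset), rec.strand]
        return ".".join(fields) if dot_separated else "\t".join(fields)
    if format == "bed":
        start = rec.start - 1 if dialect == "half_open_0based" else rec.start
        name = rec.id if rec.id is not None else "."
        return f"{rec.chrom}\t{start}\t{rec.end}\t{name}\t0\t{rec.strand}"
    if format == "gtf_minimal":
        attrs = []
        amap = dict(rec.attributes)
        if rec.gene_id is not None and "gene_id" not in amap:
            attrs.append(("gene_id", rec.gene_id))
        if rec.transcript_id is not None and "transcript_id" not in amap:
            attrs.append(("transcript_id", rec.transcript_id))
        attrs.extend(rec.attributes)
        attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
        iv = rec.interval
        return (
            f"{iv.chrom}\t{rec.source}\t{rec.feature}\t{iv.start}\t{iv.end}"
            f"\t.\t{iv.strand}\t.\t{attr_str}"
        )
    raise ValueError(f"unknown format {format!r}")
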