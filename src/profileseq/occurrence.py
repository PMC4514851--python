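"""The occurrence-counting engine: bin signal points around reference points.

For each reference point, signal points are counted into fixed-width bins
at signed offsets measured in transcript orientation: for a ``+`` strand
reference at position p a point at genomic position q has offset q − p; for
a ``-`` strand reference the axis is mirrored (offset p − q), so bin 0
always starts at the reference position and reads downstream of the
reference in the direction of transcription.  Bin b covers offsets
[b·w, (b+1)·w − 1].

The result is an occurrence matrix (the ``.occ`` artifact): one integer row
per reference region, one column per bin, carrying the bin geometry, the
maximum-repeat bound of the point set and the strandedness used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from profileseq.records import ReferencePoint
from profileseq.signal_prep import PooledPointSet

__all__ = ["BinGeometry", "OccurrenceMatrix", "count_occurrences"]

STRANDEDNESS = ("unstranded", "sense", "antisense")


@dataclass(frozen=True)
class BinGeometry:
    """Bin width (nt) and the number of bins up- and downstream of the
    reference.  Bin indices run −n_bins_upstream … n_bins_downstream − 1."""

    bin_width: int
    n_bins_upstream: int
    n_bins_downstream: int

    def __post_init__(self):
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.n_bins_upstream < 0 or self.n_bins_downstream < 0:
            raise ValueError("bin counts must be >= 0")
        if self.n_bins_upstream + self.n_bins_downstream < 1:
            raise ValueError("at least one bin required")

    @property
    def n_bins(self) -> int:
        return self.n_bins_upstream + self.n_bins_downstream

    @property
    def bin_indices(self) -> np.ndarray:
        return np.arange(-self.n_bins_upstream, self.n_bins_downstream)


@dataclass
class OccurrenceMatrix:
    """Per-reference-region, per-bin occurrence counts.

    Row order follows the reference file; column order follows
    ``geometry.bin_indices``.
    """

    ref_ids: list
    counts: np.ndarray
    geometry: BinGeometry
    max_repeats: int = 1
    strandedness: str = "unstranded"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.ref_ids), self.geometry.n_bins):
            raise ValueError(
                f"counts shape {self.counts.shape} disagrees with "
                f"{len(self.ref_ids)} refs x {self.geometry.n_bins} bins"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.strandedness not in STRANDEDNESS:
            raise ValueError(f"unknown strandedness {self.strandedness!r}")

    @property
    def n_regions(self) -> int:
        return len(self.ref_ids)

    def bin_totals(self) -> np.ndarray:
        """Counts summed over regions, one value per bin."""
        return self.counts.sum(axis=0)

    def select_rows(self, indices) -> "OccurrenceMatrix":
        indices = list(indices)
        return OccurrenceMatrix(
            ref_ids=[self.ref_ids[i] for i in indices],
            counts=self.counts[indices],
            geometry=self.geometry,
            max_repeats=self.max_repeats,
            strandedness=self.strandedness,
        )

    def write_occ(self, path) -> None:
        g = self.geometry
        with open(path, "w") as fh:
            fh.write(
                "#occ\tbin_width={}\tn_bins_upstream={}\tn_bins_downstream={}"
                "\tmax_repeats={}\tstrandedness={}\n".format(
                    g.bin_width,
                    g.n_bins_upstream,
                    g.n_bins_downstream,
                    self.max_repeats,
                    self.strandedness,
                )
            )
            for rid, row in zip(self.ref_ids, self.counts):
                fh.write(str(rid) + "\t" + "\t".join(map(str, row)) + "\n")

    @classmethod
    def read_occ(cls, path) -> "OccurrenceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#occ"):
                raise ValueError(f"{path}: missing #occ header")
            meta = dict(
                item.split("=", 1) for item in header.split("\t")[1:] if "=" in item
            )
            geometry = BinGeometry(
                bin_width=int(meta["bin_width"]),
                n_bins_upstream=int(meta["n_bins_upstream"]),
                n_bins_downstream=int(meta["n_bins_downstream"]),
            )
            ref_ids, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                ref_ids.append(fields[0])
                rows.append([int(x) for x in fields[1:]])
        return cls(
            ref_ids=ref_ids,
            counts=np.array(rows, dtype=np.int64).reshape(
                len(ref_ids), geometry.n_bins
            ),
            geometry=geometry,
            max_repeats=int(meta.get("max_repeats", 1)),
            strandedness=meta.get("strandedness", "unstranded"),
        )


_STRAND_CODE = {"+": 1, "-": -1, ".": 0}


def count_occurrences(
    points: PooledPointSet,
    refs: Sequence[ReferencePoint],
    geometry: BinGeometry,
    strandedness: str = "unstranded",
) -> OccurrenceMatrix:
    """Count signal points into bins around each reference point.

    ``sense`` counts only points whose strand equals the reference strand,
    ``antisense`` the opposite, ``unstranded`` both plus strandless points.
    A point inside the windows of several reference regions is counted once
    in each (rows stay self-contained for the shuffle-split FDR).  A
    reference on a chromosome with no points simply yields a zero row.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    if strandedness not in STRANDEDNESS:
        raise ValueError(f"unknown strandedness {strandedness!r}")
    ids = [r.id for r in refs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")

    # index points per chromosome as sorted position arrays + strand codes
    by_chrom: dict[str, list] = {}
    for p in points.points:
        by_chrom.setdefault(p.chrom, []).append(p)
    arrays = {}
    for chrom, pts in by_chrom.items():
        pts.sort(key=lambda p: p.position)
        arrays[chrom] = (
            np.array([p.position for p in pts], dtype=np.int64),
            np.array([_STRAND_CODE[p.strand] for p in pts], dtype=np.int8),
        )

    w = geometry.bin_width
    up, down = geometry.n_bins_upstream, geometry.n_bins_downstream
    counts = np.zeros((len(refs), geometry.n_bins), dtype=np.int64)
    for row, ref in enumerate(refs):
        if ref.chrom not in arrays:
            continue
        positions, strands = arrays[ref.chrom]
        p = ref.position
        if ref.strand == "+":
            lo, hi = p - up * w, p + down * w - 1
        else:
            lo, hi = p - (down * w - 1), p + up * w
        i0 = np.searchsorted(positions, lo, side="left")
        i1 = np.searchsorted(positions, hi, side="right")
        if i0 == i1:
            continue
        q = positions[i0:i1]
        s = strands[i0:i1]
        offsets = (q - p) if ref.strand == "+" else (p - q)
        if strandedness != "unstranded":
            ref_code = _STRAND_CODE[ref.strand]
            want = ref_code if strandedness == "sense" else -ref_code
            mask = s == want
            offsets = offsets[mask]
            if offsets.size == 0:
                continue
        bins = np.floor_divide(offsets, w) + up
        np.add.at(counts[row], bins, 1)
    return OccurrenceMatrix(
        ref_ids=ids,
        counts=counts,
        geometry=geometry,
        max_repeats=points.max_repeats,
        strandedness=strandedness,
    )
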