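"""Deterministic synthetic datasets for exercising the full pipeline.

Two generators:

* :func:`generate_profile_dataset` — reference points with surrounding
  point signal at a controllable background rate, optional fold enrichment
  inside chosen bin windows of the test set, and optional mappability /
  input auxiliary tracks.  Points are drawn position-by-position without
  replacement inside each bin, so the pooled set always respects the
  max-repeats capacity that downstream testing assumes.

* :func:`generate_annotation_fixture` — a miniature annotation (transcripts
  with known internal exons), peaks placed at scripted distances from
  chosen exons, junction counts with scripted inclusion levels, and a
  random genome sequence with optionally scripted duplicated k-mers for
  mappability checks.

Both are pure functions of their configuration (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from profileseq.occurrence import BinGeometry, OccurrenceMatrix, count_occurrences
from profileseq.records import (
    AnnotationRecord,
    GenomicInterval,
    ReferencePoint,
    SignalPoint,
)
from profileseq.signal_prep import PooledPointSet

__all__ = [
    "FixtureConfig",
    "ProfileDataset",
    "AnnotationFixture",
    "PeakPlan",
    "generate_profile_dataset",
    "generate_annotation_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a synthetic profile dataset.

    ``background_rate`` is the expected number of signal points per
    nucleotide per region per replicate (the per-position Bernoulli
    probability); inside ``enrichment_windows`` (inclusive bin-index
    ranges) the test-set rate is multiplied by ``enrichment_fold``.
    """

    seed: int = 0
    n_refs: int = 200
    geometry: BinGeometry = field(
        default_factory=lambda: BinGeometry(25, 20, 20)
    )
    background_rate: float = 0.08
    enrichment_windows: tuple = ()
    enrichment_fold: float = 1.0
    n_replicates: int = 1
    plus_strand_fraction: float = 1.0
    with_aux: bool = False

    def __post_init__(self):
        if self.background_rate < 0 or self.enrichment_fold < 0:
            raise ValueError("rates and folds must be >= 0")
        per_pos = self.background_rate * self.enrichment_fold
        if per_pos > 1.0:
            raise ValueError(
                f"per-position rate {per_pos:.3f} exceeds 1: demanded "
                "expectation exceeds bin capacity"
            )
        lo = -self.geometry.n_bins_upstream
        hi = self.geometry.n_bins_downstream - 1
        for a, b in self.enrichment_windows:
            if a > b or a < lo or b > hi:
                raise ValueError(f"enrichment window ({a}, {b}) outside geometry")


class ProfileDataset(NamedTuple):
    test: PooledPointSet
    control: PooledPointSet
    test_refs: list
    control_refs: list
    aux_test: OccurrenceMatrix | None
    aux_control: OccurrenceMatrix | None


def _make_refs(prefix: str, chrom: str, config: FixtureConfig, rng) -> list:
    g = config.geometry
    span = (g.n_bins_upstream + g.n_bins_downstream) * g.bin_width
    gap = span + 2 * g.bin_width  # windows never overlap
    refs = []
    for i in range(config.n_refs):
        position = g.n_bins_upstream * g.bin_width + 1 + i * gap
        strand = "+" if rng.random() < config.plus_strand_fraction else "-"
        refs.append(ReferencePoint(f"{prefix}{i}", chrom, position, strand))
    return refs


def _sample_points(refs, config: FixtureConfig, enriched: bool, rng) -> PooledPointSet:
    g = config.geometry
    w = g.bin_width
    window_set = set()
    if enriched:
        for a, b in config.enrichment_windows:
            window_set.update(range(a, b + 1))
    replicates = []
    for _ in range(config.n_replicates):
        points = []
        for ref in refs:
            for b in g.bin_indices:
                rate = config.background_rate
                if b in window_set:
                    rate *= config.enrichment_fold
                if rate <= 0:
                    continue
                hits = np.flatnonzero(rng.random(w) < rate)
                for j in hits:
                    offset = b * w + int(j)
                    position = (
                        ref.position + offset
                        if ref.strand == "+"
                        else ref.position - offset
                    )
                    points.append(SignalPoint(ref.chrom, position, ref.strand))
        replicates.append(points)
    pooled = [p for rep in replicates for p in rep]
    pooled.sort(key=lambda p: (p.chrom, p.position, p.strand))
    return PooledPointSet(
        points=pooled,
        max_repeats=config.n_replicates,
        n_replicates=config.n_replicates,
    )


def _uniform_aux(refs, config: FixtureConfig) -> OccurrenceMatrix:
    """Aux occurrence matrix with every position covered once per region
    (all-positions mappability; equally, a flat one-read-per-position
    input)."""
    g = config.geometry
    counts = np.full((len(refs), g.n_bins), g.bin_width, dtype=np.int64)
    return OccurrenceMatrix(
        ref_ids=[r.id for r in refs],
        counts=counts,
        geometry=g,
        max_repeats=1,
        strandedness="unstranded",
    )


def generate_profile_dataset(config: FixtureConfig) -> ProfileDataset:
    """Generate matched test/control point sets around synthetic references.

    The control set is drawn at the background rate everywhere; the test
    set additionally multiplies the rate by ``enrichment_fold`` inside the
    configured bin windows.  With ``with_aux``, uniform full-coverage aux
    matrices are returned (under which mappable/input normalization is
    equivalent to the max-possible capacity model).
    """
    rng = np.random.default_rng(config.seed)
    test_refs = _make_refs("t", "chrT", config, rng)
    control_refs = _make_refs("c", "chrC", config, rng)
    test = _sample_points(test_refs, config, enriched=True, rng=rng)
    control = _sample_points(control_refs, config, enriched=False, rng=rng)
    aux_test = _uniform_aux(test_refs, config) if config.with_aux else None
    aux_control = _uniform_aux(control_refs, config) if config.with_aux else None
    return ProfileDataset(test, control, test_refs, control_refs, aux_test, aux_control)


# ---------------------------------------------------------------------------
# annotation fixture


class PeakPlan(NamedTuple):
    """Scripted peak placement: ``exon_index`` is the 0-based internal-exon
    index within the transcript's genomic exon order (0 = second exon)."""

    transcript: int
    exon_index: int
    side: str  # "US" or "DS", transcript orientation
    d: int  # distance from peak center to the nearest splice site
    width: int = 101  # odd width so the center is exact


class AnnotationFixture(NamedTuple):
    records: list
    peaks: list
    junction_counts: dict
    genome: dict
    internal_exons: list
    expected_assignments: list


def generate_annotation_fixture(
    seed: int = 0,
    n_transcripts: int = 4,
    exons_per_transcript: int = 5,
    peak_plan: Sequence[PeakPlan] = (),
    scripted_psi: Sequence[tuple[int, int, int]] = ((3, 3, 1),),
    exon_length: int = 150,
    intron_length: int = 3000,
    duplicated_kmer: tuple[int, int, int] | None = None,
    strand_cycle: str = "+-",
) -> AnnotationFixture:
    """Build a miniature annotation with known ground truth.

    Transcripts are laid out sequentially on one chromosome with introns
    long enough (default 3 kb) that every non-terminal exon has clean 1 kb
    flanks.  ``peak_plan`` entries place peaks at exact distances from
    chosen internal exons so the expected flank assignments are known a
    priori.  ``scripted_psi`` gives (i3, i5, e) junction counts assigned
    cyclically to internal exons.  ``duplicated_kmer = (pos1, pos2, k)``
    copies the k-mer at pos1 to pos2 in the genome so mappability checks
    have a scripted non-unique region.

    Returns records, peaks, per-exon junction counts, the genome, the
    expected internal-exon list and the expected flank assignments.
    """
    from profileseq.annotation import (
        CenteredPeak,
        FlankAssignment,
        InternalExon,
        _shifted_position,
    )

    if exons_per_transcript < 3:
        raise ValueError("need at least 3 exons per transcript")
    if intron_length <= 2000 + max((p.width for p in peak_plan), default=0):
        raise ValueError("introns too short for clean flanks plus peaks")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    records = []
    internal: list[InternalExon] = []
    internal_by_transcript: dict[int, list[InternalExon]] = {}

    cursor = 2500  # leave room upstream of the first transcript
    for t in range(n_transcripts):
        strand = strand_cycle[t % len(strand_cycle)]
        tid = f"tx{t}"
        gid = f"gene{t}"
        exon_ivs = []
        pos = cursor
        for _ in range(exons_per_transcript):
            exon_ivs.append(GenomicInterval(chrom, pos, pos + exon_length - 1, strand))
            pos += exon_length + intron_length
        tx_iv = GenomicInterval(chrom, exon_ivs[0].start, exon_ivs[-1].end, strand)
        attrs = (("gene_id", gid), ("transcript_id", tid))
        records.append(
            AnnotationRecord("transcript", tx_iv, tid, gid, attrs, source="synthetic")
        )
        for iv in exon_ivs:
            records.append(
                AnnotationRecord("exon", iv, tid, gid, attrs, source="synthetic")
            )
        mids = [
            InternalExon(interval=iv, transcript_id=tid) for iv in exon_ivs[1:-1]
        ]
        internal.extend(mids)
        internal_by_transcript[t] = mids
        cursor = pos + 2500  # inter-transcript gap beyond the flank window

    peaks: list[CenteredPeak] = []
    expected_assignments: list[FlankAssignment] = []
    for plan in peak_plan:
        exon = internal_by_transcript[plan.transcript][plan.exon_index]
        center = _shifted_position(exon, plan.side, plan.d)
        half = plan.width // 2
        iv = GenomicInterval(chrom, center - half, center + half, ".")
        pk = CenteredPeak(interval=iv, center=center)
        peaks.append(pk)
        expected_assignments.append(
            FlankAssignment(exon=exon, peak=pk, side=plan.side, d=plan.d)
        )

    junction_counts = {}
    for i, exon in enumerate(internal):
        i3, i5, e = scripted_psi[i % len(scripted_psi)]
        key = (exon.interval.chrom, exon.interval.start, exon.interval.end)
        junction_counts[key] = (i3, i5, e)

    genome_length = cursor + 2500
    seq = rng.choice(list("ACGT"), size=genome_length)
    if duplicated_kmer is not None:
        pos1, pos2, k = duplicated_kmer
        seq[pos2 - 1 : pos2 - 1 + k] = seq[pos1 - 1 : pos1 - 1 + k]
    genome = {chrom: "".join(seq)}

    internal.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return AnnotationFixture(
        records=records,
        peaks=peaks,
        junction_counts=junction_counts,
        genome=genome,
        internal_exons=internal,
        expected_assignments=expected_assignments,
    )
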