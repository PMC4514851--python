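"""Annotation-side procedures supporting profile construction.

Covers: extraction of internal exons with clean intronic flanks from a
minimal GTF annotation; splice-site scoring windows; percent-spliced-in
(PSI) from junction read counts; replicate-reproducible ChIP-Seq peaks;
assignment of peaks to the 1 kb regions flanking internal exons (US/DS, in
transcript orientation); construction of matched control exons and control
reference positions that preserve the peak-to-splice-site distance;
rank-sum-matched control sampling on splice-site score, exon length and GC
content; TSS-distance matching of test/control pairs; and the 2×2 overlap
tables between ChIP-Seq peaks and ChIA-PET interaction pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, wilcoxon

from profileseq.records import AnnotationRecord, GenomicInterval, ReferencePoint
from profileseq.testing import ContingencyTable

__all__ = [
    "InternalExon",
    "JunctionCounts",
    "FlankAssignment",
    "ControlPair",
    "InteractionPair",
    "CenteredPeak",
    "DEFAULT_ANNOTATION_BLACKLIST",
    "extract_internal_exons",
    "splice_site_windows",
    "compute_psi",
    "reproducible_peaks",
    "assign_flanking_peaks",
    "pair_control_exons",
    "match_controls_by_wilcoxon",
    "match_tss_distance",
    "chiapet_tables",
    "gc_content",
]

#: Annotation keywords whose records are discarded before exon extraction
#: (mitochondrial entries plus non-coding/low-confidence biotypes).
DEFAULT_ANNOTATION_BLACKLIST = (
    "chrM",
    "pseudogene",
    "processed_transcript",
    "TEC",
    "PUTATIVE",
)


@dataclass(frozen=True)
class InternalExon:
    """An exon that is neither first nor last in its transcript and whose
    ±flank intronic windows are clear of other annotated features.

    The 3'SS is the intron→exon boundary (acceptor) and the 5'SS the
    exon→intron boundary (donor): on + the exon start and end, mirrored
    on −.
    """

    interval: GenomicInterval
    transcript_id: str
    flank: int = 1000
    ss3_score: float | None = None
    ss5_score: float | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def ss3(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def ss5(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class JunctionCounts:
    """Junction reads for one exon: i3/i5 inclusion reads at the 3'/5'
    splice sites and e skipping reads."""

    i3: int
    i5: int
    e: int

    def __post_init__(self):
        if min(self.i3, self.i5, self.e) < 0:
            raise ValueError("junction counts must be non-negative")

    @property
    def i(self) -> int:
        return self.i3 + self.i5


@dataclass(frozen=True)
class CenteredPeak:
    """A peak interval with its midpoint (half-up) precomputed."""

    interval: GenomicInterval
    center: int

    @classmethod
    def from_interval(cls, interval: GenomicInterval) -> "CenteredPeak":
        return cls(interval=interval, center=interval.center())

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class FlankAssignment:
    """A peak assigned to the upstream (US) or downstream (DS) 1 kb flank
    of an internal exon; ``d`` is the distance from the peak center to the
    nearest splice site (1 ≤ d ≤ window)."""

    exon: InternalExon
    peak: CenteredPeak
    side: str
    d: int

    def __post_init__(self):
        if self.side not in ("US", "DS"):
            raise ValueError("side must be 'US' or 'DS'")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass(frozen=True)
class ControlPair:
    """A peak-flanked test exon paired with a same-transcript, peak-free
    control exon; the control reference position sits d nt from the control
    exon's nearest splice site on the same side, preserving the
    peak-to-splice-site distance."""

    assignment: FlankAssignment
    control_exon: InternalExon
    control_position: ReferencePoint

    @property
    def test_position(self) -> int:
        return self.assignment.peak.center


@dataclass(frozen=True)
class InteractionPair:
    """One ChIA-PET interaction: two anchor intervals (unordered) from one
    replicate."""

    half1: GenomicInterval
    half2: GenomicInterval
    replicate: str = "rep1"


# ---------------------------------------------------------------------------
# internal-exon extraction


def _is_blacklisted(record: AnnotationRecord, blacklist) -> bool:
    haystacks = [record.interval.chrom, record.feature, record.source]
    haystacks += [v for _, v in record.attributes]
    return any(word in hay for word in blacklist for hay in haystacks)


def extract_internal_exons(
    annotation: Iterable[AnnotationRecord],
    flank: int = 1000,
    blacklist: Sequence[str] = DEFAULT_ANNOTATION_BLACKLIST,
) -> list[InternalExon]:
    """Extract internal exons with clean ±``flank`` intronic windows.

    After dropping blacklisted records, exons are grouped by transcript and
    ordered along the transcript; exons that are first or last are
    discarded, as is any exon whose upstream or downstream ``flank`` nt
    window overlaps another exon, a UTR, or a TSS (transcript 5' ends)
    anywhere in the filtered annotation.  Duplicates by coordinate are
    collapsed; output is sorted by coordinate.
    """
    records = [r for r in annotation if not _is_blacklisted(r, blacklist)]

    by_transcript: dict[str, list[AnnotationRecord]] = defaultdict(list)
    blockers: list[GenomicInterval] = []
    tss_points: list[tuple[str, int]] = []
    for rec in records:
        if rec.feature == "exon":
            if rec.transcript_id is None:
                raise ValueError("exon record lacks a transcript_id")
            by_transcript[rec.transcript_id].append(rec)
            blockers.append(rec.interval)
        elif rec.feature == "UTR":
            blockers.append(rec.interval)
        elif rec.feature == "transcript":
            iv = rec.interval
            tss = iv.start if iv.strand == "+" else iv.end
            tss_points.append((iv.chrom, tss))
        elif rec.feature == "TSS":
            tss_points.append((rec.interval.chrom, rec.interval.start))

    blockers_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in blockers:
        blockers_by_chrom[iv.chrom].append(iv)
    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in tss_points:
        tss_by_chrom[chrom].append(pos)

    def window_clean(chrom: str, lo: int, hi: int, self_iv: GenomicInterval) -> bool:
        for iv in blockers_by_chrom.get(chrom, ()):
            if iv == self_iv:
                continue
            if iv.start <= hi and iv.end >= lo:
                return False
        for pos in tss_by_chrom.get(chrom, ()):
            if lo <= pos <= hi:
                return False
        return True

    seen = set()
    out = []
    for tid, exon_records in by_transcript.items():
        if len(exon_records) < 3:
            continue
        ordered = sorted(exon_records, key=lambda r: r.interval.start)
        for rec in ordered[1:-1]:
            iv = rec.interval
            up_lo, up_hi = iv.start - flank, iv.start - 1
            dn_lo, dn_hi = iv.end + 1, iv.end + flank
            if up_lo < 1:
                continue
            if not window_clean(iv.chrom, up_lo, up_hi, iv):
                continue
            if not window_clean(iv.chrom, dn_lo, dn_hi, iv):
                continue
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key in seen:
                continue
            seen.add(key)
            out.append(InternalExon(interval=iv, transcript_id=tid, flank=flank))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return out


def splice_site_windows(exon: InternalExon) -> tuple[GenomicInterval, GenomicInterval]:
    """Sequence windows used for splice-site strength scoring.

    The 3'SS window covers 20 intronic + 3 exonic nt (23 nt) and the 5'SS
    window 3 exonic + 6 intronic nt (9 nt), in transcript orientation.
    """
    iv = exon.interval
    if exon.strand == "+":
        w3 = (iv.start - 20, iv.start + 2)
        w5 = (iv.end - 2, iv.end + 6)
    else:
        w3 = (iv.end - 2, iv.end + 20)
        w5 = (iv.start - 6, iv.start + 2)
    if w3[0] < 1 or w5[0] < 1:
        raise ValueError("splice-site window extends past chromosome start")
    return (
        GenomicInterval(iv.chrom, *w3, strand=exon.strand),
        GenomicInterval(iv.chrom, *w5, strand=exon.strand),
    )


def compute_psi(counts: JunctionCounts):
    """Percent spliced in from junction reads.

    PSI = i/(i+2e) with i = i3+i5; 3' PSI = i3/(i3+e); 5' PSI = i5/(i5+e).
    A value is None when its denominator is zero.
    """
    i = counts.i
    psi = i / (i + 2 * counts.e) if (i + 2 * counts.e) > 0 else None
    psi3 = (
        counts.i3 / (counts.i3 + counts.e)
        if (counts.i3 + counts.e) > 0
        else None
    )
    psi5 = (
        counts.i5 / (counts.i5 + counts.e)
        if (counts.i5 + counts.e) > 0
        else None
    )
    return psi, psi3, psi5


# ---------------------------------------------------------------------------
# peaks


def reproducible_peaks(
    rep_a: Sequence[GenomicInterval],
    rep_b: Sequence[GenomicInterval],
    min_fraction: float = 0.5,
    primary: str = "A",
) -> list[CenteredPeak]:
    """Keep primary-replicate peaks reproduced in the other replicate.

    A peak is kept when some partner peak overlaps it by at least
    ``min_fraction`` of the smaller of the two peak lengths.  One output
    per kept primary peak, carrying its center (half-up midpoint).
    """
    if primary not in ("A", "B"):
        raise ValueError("primary must be 'A' or 'B'")
    keep_from, other = (rep_a, rep_b) if primary == "A" else (rep_b, rep_a)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in other:
        by_chrom[iv.chrom].append(iv)
    out = []
    for peak in keep_from:
        for partner in by_chrom.get(peak.chrom, ()):
            ov = peak.overlap_length(partner)
            if ov >= min_fraction * min(peak.length, partner.length):
                out.append(CenteredPeak.from_interval(peak))
                break
    return out


def assign_flanking_peaks(
    peaks: Sequence[CenteredPeak],
    exons: Sequence[InternalExon],
    window: int = 1000,
) -> list[FlankAssignment]:
    """Assign peak centers to the 1 kb flanks of internal exons.

    In transcript orientation: US = within ``window`` nt upstream of the
    3'SS, DS = within ``window`` nt downstream of the 5'SS; d is the
    distance from the peak center to that splice site.  One peak may be
    assigned to several exons.
    """
    centers_by_chrom: dict[str, list[CenteredPeak]] = defaultdict(list)
    for pk in peaks:
        centers_by_chrom[pk.chrom].append(pk)
    out = []
    for exon in exons:
        for pk in centers_by_chrom.get(exon.interval.chrom, ()):
            c = pk.center
            if exon.strand == "+":
                d_us = exon.ss3 - c
                d_ds = c - exon.ss5
            else:
                d_us = c - exon.ss3
                d_ds = exon.ss5 - c
            if 1 <= d_us <= window:
                out.append(FlankAssignment(exon=exon, peak=pk, side="US", d=d_us))
            if 1 <= d_ds <= window:
                out.append(FlankAssignment(exon=exon, peak=pk, side="DS", d=d_ds))
    return out


def _shifted_position(exon: InternalExon, side: str, d: int) -> int:
    """Genomic position d nt from the exon's nearest SS on the given side,
    in transcript orientation."""
    if side == "DS":
        return exon.ss5 + d if exon.strand == "+" else exon.ss5 - d
    return exon.ss3 - d if exon.strand == "+" else exon.ss3 + d


def pair_control_exons(
    assignments: Sequence[FlankAssignment],
    transcript_exons: Mapping[str, Sequence[InternalExon]],
) -> list[ControlPair]:
    """Pair each peak-flanked exon with a peak-free exon of its transcript.

    Candidates are same-transcript exons with no peak assigned on the same
    side; the candidate whose length is closest to the test exon's is
    chosen (ties broken by smaller genomic start).  Exons with no candidate
    are dropped.  The control reference position is placed d nt from the
    control exon's nearest splice site on the same side, so the distance to
    the splice site is preserved exactly.
    """
    flanked: dict[tuple, set] = defaultdict(set)
    for a in assignments:
        iv = a.exon.interval
        flanked[(a.exon.transcript_id, a.side)].add(
            (iv.chrom, iv.start, iv.end, iv.strand)
        )
    out = []
    for a in assignments:
        candidates = []
        taken = flanked[(a.exon.transcript_id, a.side)]
        for exon in transcript_exons.get(a.exon.transcript_id, ()):
            iv = exon.interval
            if (iv.chrom, iv.start, iv.end, iv.strand) in taken:
                continue
            candidates.append(exon)
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda e: (abs(e.length - a.exon.length), e.interval.start),
        )
        pos = _shifted_position(best, a.side, a.d)
        iv = a.exon.interval
        control_position = ReferencePoint(
            id=f"{iv.chrom}:{iv.start}-{iv.end}:{a.side}:ctrl",
            chrom=best.interval.chrom,
            position=pos,
            strand=best.strand,
        )
        out.append(
            ControlPair(
                assignment=a, control_exon=best, control_position=control_position
            )
        )
    return out


# ---------------------------------------------------------------------------
# matched controls


def gc_content(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


#: Attribute keys compared between test set and sampled control subsets.
MATCH_ATTRIBUTES = ("ss_score", "length", "gc_up", "gc_body", "gc_down")


def match_controls_by_wilcoxon(
    test_attributes: Mapping[str, Sequence[float]],
    pool_attributes: Mapping[str, Sequence[float]],
    profile_source: Callable[[np.ndarray], np.ndarray],
    p_cutoff: float = 0.5,
    max_iterations: int = 33,
    seed: int | np.random.Generator | None = None,
    attributes: Sequence[str] = MATCH_ATTRIBUTES,
    max_attempts: int = 100000,
):
    """Build a matched-control profile by rank-sum-filtered subsampling.

    The control pool is first trimmed to pool members whose splice-site
    score lies within the test set's [min, max] score range.  Then, until
    ``max_iterations`` subsets are accepted: a pool subset of test-set size
    is sampled without replacement and accepted iff the two-sample
    rank-sum p-value between test and subset exceeds ``p_cutoff`` for every
    attribute (splice-site score, exon length, and the three GC windows
    separately).  ``profile_source`` maps the accepted subset's pool
    indices to its per-bin counts; the matched profile is the per-bin
    median over accepted subsets.

    Returns (median per-bin profile, diagnostics dict).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    test = {k: np.asarray(test_attributes[k], dtype=float) for k in attributes}
    pool = {k: np.asarray(pool_attributes[k], dtype=float) for k in attributes}
    n_test = len(next(iter(test.values())))
    if n_test == 0:
        raise ValueError("empty test set")

    lo, hi = test["ss_score"].min(), test["ss_score"].max()
    in_range = np.flatnonzero((pool["ss_score"] >= lo) & (pool["ss_score"] <= hi))
    if len(in_range) < n_test:
        raise ValueError(
            "control pool smaller than the test set after trimming to the "
            "test splice-site score range"
        )

    accepted_profiles = []
    accepted = 0
    attempts = 0
    while accepted < max_iterations:
        if attempts >= max_attempts:
            if accepted == 0:
                raise RuntimeError(
                    "no control subset satisfied the rank-sum criterion; "
                    "lower p_cutoff or enlarge the pool"
                )
            break
        attempts += 1
        subset = in_range[
            rng.choice(len(in_range), size=n_test, replace=False)
        ]
        ok = True
        for key in attributes:
            a, b = test[key], pool[key][subset]
            if np.array_equal(np.sort(a), np.sort(b)):
                continue  # identical distributions; rank-sum p is 1
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            if p <= p_cutoff:
                ok = False
                break
        if not ok:
            continue
        accepted += 1
        accepted_profiles.append(np.asarray(profile_source(subset), dtype=float))

    median_profile = np.median(np.vstack(accepted_profiles), axis=0)
    diagnostics = {
        "accepted": accepted,
        "attempts": attempts,
        "pool_size_after_trim": int(len(in_range)),
    }
    return median_profile, diagnostics


def _nearest_tss_distance(chrom: str, position: int, tss_by_chrom) -> int | None:
    positions = tss_by_chrom.get(chrom)
    if positions is None or len(positions) == 0:
        return None
    arr = np.asarray(positions)
    return int(np.abs(arr - position).min())


def match_tss_distance(
    pairs: Sequence[ControlPair],
    tss: Sequence[tuple[str, int] | ReferencePoint],
    max_pair_diff: int = 10000,
    min_dist: int = 1100,
    total_diff_target: int = 800,
):
    """Balance test and control reference positions on TSS distance.

    Phase 1 drops pairs whose test/control TSS-distance difference exceeds
    ``max_pair_diff`` or where either position lies closer than
    ``min_dist`` to a TSS.  Phase 2 greedily removes the pair with the
    largest discrepancy until the absolute difference of summed distances
    falls below ``total_diff_target``.  Returns (kept pairs, paired
    rank-test p-value on the final distance sets, or None when fewer than
    two pairs survive or all discrepancies are zero).
    """
    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    for t in tss:
        if isinstance(t, ReferencePoint):
            tss_by_chrom[t.chrom].append(t.position)
        else:
            tss_by_chrom[t[0]].append(t[1])

    survivors = []
    for pair in pairs:
        chrom_t = pair.assignment.peak.chrom
        dt = _nearest_tss_distance(chrom_t, pair.test_position, tss_by_chrom)
        dc = _nearest_tss_distance(
            pair.control_position.chrom, pair.control_position.position, tss_by_chrom
        )
        if dt is None or dc is None:
            continue
        if dt < min_dist or dc < min_dist:
            continue
        if abs(dt - dc) > max_pair_diff:
            continue
        survivors.append((pair, dt, dc))

    while survivors:
        total = sum(dt for _, dt, _ in survivors) - sum(dc for _, _, dc in survivors)
        if abs(total) < total_diff_target:
            break
        worst = max(range(len(survivors)), key=lambda i: abs(survivors[i][1] - survivors[i][2]))
        survivors.pop(worst)

    kept = [pair for pair, _, _ in survivors]
    p_value = None
    if len(survivors) >= 2:
        dts = np.array([dt for _, dt, _ in survivors], dtype=float)
        dcs = np.array([dc for _, _, dc in survivors], dtype=float)
        if np.any(dts != dcs):
            p_value = float(wilcoxon(dts, dcs).pvalue)
    return kept, p_value


# ---------------------------------------------------------------------------
# ChIA-PET overlap tables


def _center_in_half(pk: CenteredPeak, half: GenomicInterval) -> bool:
    return half.contains(pk.chrom, pk.center)


def chiapet_tables(
    peaks: Sequence[CenteredPeak],
    interactions: Sequence[Sequence[InteractionPair]],
    assignments: Sequence[FlankAssignment],
    tss: Sequence[tuple[str, int] | ReferencePoint] = (),
    table_kind: str = "overlap",
    min_interactions_per_replicate: int = 10000,
    tss_window: int = 1000,
) -> ContingencyTable:
    """Build the peak × interaction-overlap 2×2 table.

    A peak overlaps the interaction data when its center falls inside
    either half of some interaction in *every* retained replicate
    (replicates below ``min_interactions_per_replicate`` pairs are
    dropped).  ``overlap`` kind: rows are {US/DS-flanking peaks, remaining
    genome-wide peaks}, columns {overlapping, not}.  ``tss`` kind:
    restricted to overlapping peaks, columns split on whether the other
    half's center of any containing interaction lies within ``tss_window``
    of a TSS.
    """
    if not peaks:
        raise ValueError("empty peak set")
    if table_kind not in ("overlap", "tss"):
        raise ValueError(f"unknown table_kind {table_kind!r}")
    retained = [
        rep for rep in interactions if len(rep) >= min_interactions_per_replicate
    ]

    flank_keys = {
        (a.peak.chrom, a.peak.center, a.peak.interval.start, a.peak.interval.end)
        for a in assignments
    }

    def peak_key(pk: CenteredPeak):
        return (pk.chrom, pk.center, pk.interval.start, pk.interval.end)

    def overlapping_halves(pk: CenteredPeak, replicate) -> list[GenomicInterval]:
        others = []
        for pair in replicate:
            if _center_in_half(pk, pair.half1):
                others.append(pair.half2)
            if _center_in_half(pk, pair.half2):
                others.append(pair.half1)
        return others

    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    for t in tss:
        if isinstance(t, ReferencePoint):
            tss_by_chrom[t.chrom].append(t.position)
        else:
            tss_by_chrom[t[0]].append(t[1])

    def near_tss(half: GenomicInterval) -> bool:
        center = half.center()
        dist = _nearest_tss_distance(half.chrom, center, tss_by_chrom)
        return dist is not None and dist <= tss_window

    n = {"11": 0, "12": 0, "21": 0, "22": 0}
    for pk in peaks:
        per_rep = [overlapping_halves(pk, rep) for rep in retained]
        overlaps = bool(retained) and all(per_rep)
        row = "1" if peak_key(pk) in flank_keys else "2"
        if table_kind == "overlap":
            col = "1" if overlaps else "2"
            n[row + col] += 1
        else:
            if not overlaps:
                continue
            has_tss = any(near_tss(h) for halves in per_rep for h in halves)
            col = "1" if has_tss else "2"
            n[row + col] += 1
    return ContingencyTable(n["11"], n["12"], n["21"], n["22"])
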