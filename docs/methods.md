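# Methods

This note records the statistical model, the conventions the implementation
commits to, and the reasoning behind parameter defaults, so results can be
interpreted and reproduced without reading the source.

## Coordinates and formats

All records are held internally in 1-based, fully-closed coordinates; the
first nucleotide of a chromosome is position 1 and both interval ends are
included. Readers and writers accept either this dialect or the half-open
0-based convention of BED, selected explicitly — formats are never sniffed.
Four formats are supported: BED6, `.pos` (chrom/position/strand signal
points), `.ref` (id/chrom/position/strand reference points, with a
dot-separated id-first variant), and a minimal 9-column GTF. The `.occ`
matrix serializes per-region per-bin counts with the bin geometry,
max-repeats and strandedness in a header line, so counting and testing can
run as separate stages.

## Signal preparation

Aligned reads are filtered to a single required length, to sequences
without `N`, and to MAPQ strictly greater than 30. Each read is reduced to
a single nucleotide: its 5′ end, or its center with half-integer positions
rounded up. Duplicates are removed per replicate on (chromosome, position,
strand), then replicates are pooled, so one coordinate can recur at most
once per replicate; the pool records this capacity (`max_repeats`), which
the exact test later uses as the per-position ceiling.

Mappability is computed by brute-force enumeration: a read of length *r*
starting at a position is unique if its *r*-mer occurs exactly once in the
genome plus its reverse complement. Unique reads are reduced to strandless
center points, forming an auxiliary track with the same shape as the
signal.

## Binning

A bin geometry is (bin width *w*, bins upstream *u*, bins downstream *d*).
Bin *b* covers offsets [*b·w*, (*b*+1)*·w* − 1] from the reference point;
bin 0 starts **at** the reference point. For a + strand reference at *p*,
a point at *q* has offset *q* − *p*; for a − strand reference the axis is
mirrored (offset *p* − *q*), so profiles are reported in transcript
orientation. Strandedness is `unstranded`, `sense` or `antisense`;
strandless points are counted only in unstranded mode. Points falling in
the windows of several reference regions are counted in each.

## Per-bin exact test

Each bin yields a 2×2 table: occupied positions in the reference set
(n11 = pooled count in that bin over all regions) against the control set,
with the complementary cells given by the normalization mode:

- **max_possible** — capacity is `max_repeats · w · n_regions`;
  n12 = capacity − n11. The reported value is the percentage of possible
  positions occupied.
- **mappable** — capacity is `max_repeats ·` (mappable positions in the
  bin, from the auxiliary track); value is the percentage of mappable
  positions.
- **input** — the second cell is the input count itself; value is the
  reads-per-input ratio.

The two-sided Fisher's exact test sums, over all tables with the observed
margins, the hypergeometric probabilities that are at most the observed
probability times 1 + 1e-7. The relative slack makes ties robust to
floating-point error and matches the convention of the standard R
implementation; p-values are computed from `scipy.stats.hypergeom.pmf`
sums and capped at 1. Degenerate margins give p = 1. Bins with zero
capacity are skipped (value 0, p = NaN) and listed explicitly rather than
silently dropped; a bin whose count exceeds its capacity is an error, not
a clamp.

Significant bins are graded on the cutoff ladder 1e-2, 1e-3, …, 1e-10 and
merged into maximal runs of consecutive graded bins, reported as
(first bin, last bin, minimum p).

## Center-versus-flank test

For a center window of *c* nt symmetric about the reference point and two
flanks of *c*/2 nt each, one Fisher table compares center occupancy to
flank occupancy under the same normalization modes. *c* must be divisible
by 2*w* so the windows align with whole bins, and must fit inside the
profile extent. For very large effects the p-value underflows double
precision and is reported as 0.

## Empirical FDR

Reference and control count matrices are stacked (with their auxiliary
rows, kept paired), row-permuted, and split into halves, dropping one
uniformly-chosen row when the total is odd. Each split is tested per bin
and the null p-values pooled across iterations. The FDR at a cutoff is the
fraction of pooled null p-values below it; iteration stops when the
estimate at the probe cutoff (0.01) moves by less than 0.001 for 10
consecutive iterations, or after 1000 iterations (reported as
non-converged rather than silently accepted). All randomness comes from a
caller-supplied seed.

## Annotation procedures

**Internal exons.** Records whose chromosome, feature, source or attribute
values contain any of chrM, pseudogene, processed_transcript, TEC or
PUTATIVE are discarded. Exons are ordered per transcript; an internal exon
is neither first nor last in its transcript and its ±1 kb flanks must not
overlap any other exon, UTR, or transcription start site (transcript 5′
ends or explicit TSS features). Duplicated coordinates collapse to one
exon. "Internal" is evaluated per transcript, working from the
transcript-ordered exon list.

**Splice-site windows.** The 3′SS window is 23 nt ([s − 20, s + 2] on the
+ strand) and the 5′SS window 9 nt ([e − 2, e + 6]); both are mirrored on
the − strand.

**PSI.** From inclusion junction counts i3, i5 and skipping count e:
psi = (i3 + i5) / (i3 + i5 + 2e), psi3 = i3/(i3 + e), psi5 = i5/(i5 + e);
undefined (None) on zero denominators.

**Peaks.** Replicate peak sets are intersected, keeping peaks whose
overlap is at least 50% of the smaller peak's length; each kept peak is
reduced to its center (midpoint, half-up). A peak is assigned US if its
center lies within 1 kb upstream of an internal exon's 3′SS, DS if within
1 kb downstream of its 5′SS, in transcript orientation, with distance d
(1 ≤ d ≤ 1000); one peak may serve several exons.

**Matched controls.** Each peak-flanked exon is paired with a
same-transcript exon with no peak on that side, choosing the closest
length (ties to the smaller genomic start); the control reference position
is placed exactly d nt from the control exon's corresponding splice site,
so test and control distances match exactly. Attribute-matched control
sampling trims the candidate pool to the test set's splice-site score
range, then repeatedly samples subsets, accepting those whose unpaired
rank-sum p-value exceeds the cutoff (default 0.5) on all five attributes
(ss score, length, and GC content upstream/body/downstream, GC windows
being the closed kilobase flanks of the splice site); the reported profile
is the per-bin median over accepted subsets. TSS-distance balancing drops
pairs whose test/control TSS-distance difference exceeds 10 kb or that lie
closer than 1100 nt to a TSS, then greedily removes the pair with the
largest discrepancy until the total difference is below 800 nt, reporting
a paired rank test on the final sets.

**ChIA-PET tables.** Interaction replicates with fewer than 10,000 pairs
are discarded. A peak overlaps interactions when its center falls inside
either half of some pair in *every* retained replicate. The overlap table
is {US/DS peaks, remaining peaks} × {overlapping, not}; the TSS variant
restricts to overlapping peaks and splits on whether the other half's
center lies within 1 kb of a TSS.

## Synthetic fixtures

Profile datasets place non-overlapping reference windows on separate test
and control chromosomes and draw signal per position as independent
Bernoulli trials (expectation = background rate, multiplied by the
enrichment fold inside chosen bin windows of the test set only). Sampling
positions without replacement within each replicate means the generated
pools can never violate the deduplication capacity, and configurations
whose demanded expectation exceeds one point per position are rejected
up front. Optional auxiliary tracks are uniform full-coverage matrices,
under which the mappable and input modes provably coincide with
max_possible — a testable equivalence the suite asserts. Annotation
fixtures lay out transcripts with introns long enough for clean flanks,
place peaks at scripted distances from chosen internal exons, assign
scripted junction counts, and generate a random genome with optional
duplicated k-mers for mappability checks. All generators are pure
functions of (configuration, seed).

## Verification approach

Every numerical component is checked against an independent oracle: the
binning engine against a per-point/per-region double loop (exact integer
equality, 50 random instances), and the exact test against exhaustive
exact-rational enumeration of all margin-fixed tables with total ≤ 60
(agreement to 1e-9 relative, the residual being float pmf summation) plus
a cross-check against `scipy.stats.fisher_exact` on random tables. Null
calibration uses exchangeable test/control fixtures: about 1.3% of null
bins reach p < 0.01 over 20 seeds and the converged empirical FDR at 0.01
is ≈ 0.009–0.02. Injected 3-fold enrichment in five central bins of a
200-region dataset is recovered completely at ≥ 95% specificity with and
without auxiliary tracks. Annotation procedures are verified by closed
loops on scripted fixtures.

Problem sizes in the test and acceptance suites (200 regions × 40 bins,
1000 × 50 oracle instances, tables to total 60) were chosen to run on one
CPU in minutes while keeping the law-of-large-numbers checks stable; they
are the package's own choice of desk-scale verification, not a claim about
production scale. Published genome-scale profile figures require external
genome-wide datasets and are out of scope; one published contingency value
(the HNRNPL-binding comparison printing 0.018) reproduces only when the
full no-peak pool size is used as the second-row total, and the table
builder accordingly exposes the explicit-count construction used there.

## Limitations

- Mappability enumeration is brute force and intended for fixture-scale
  genomes, not full assemblies.
- PSI consumes a junction-count table; junction extraction from raw
  alignments and model-based PSI estimation are out of scope, as are
  splice-site strength scoring and motif scanning.
- The exact test treats positions as exchangeable within a bin; replicate
  structure enters only through the pooled max-repeats capacity.
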