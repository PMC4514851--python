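"""Per-bin enrichment testing, center-vs-flank testing, and empirical FDR.

For each bin, a 2×2 contingency table is built from the test and control
occurrence totals together with a per-bin capacity:

====================  =======================================================
mode                  complement cells (n12, n22)
====================  =======================================================
``max_possible``      maximum possible reads in the bin
                      (max_repeats × bin_width × n_regions) minus the
                      observed reads
``mappable``          max_repeats × mappable-position occurrences in the bin
                      minus the observed reads
``input``             the chromatin-input read counts in the bin (no
                      subtraction; the plotted value becomes a reads-per-
                      input ratio)
====================  =======================================================

A two-sided Fisher's exact test p-value is computed per bin, graded against
a ladder of cutoffs (1e-2 … 1e-10), and maximal runs of significant bins
are reported as significant regions.  An empirical false discovery rate is
obtained by pooling the test and control rows, shuffling the labels,
splitting into two equal halves and re-testing, iterating until the
proportion of null p-values below 0.01 stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from profileseq.occurrence import OccurrenceMatrix

__all__ = [
    "ContingencyTable",
    "ProfileResult",
    "CenterFlankSpec",
    "FDRReport",
    "DEFAULT_CUTOFF_LADDER",
    "fisher_exact_two_sided",
    "build_bin_table",
    "profile_compare",
    "center_flank_test",
    "empirical_fdr",
]

#: Significance-grade cutoffs, most permissive first.
DEFAULT_CUTOFF_LADDER = tuple(10.0 ** -k for k in range(2, 11))

MODES = ("max_possible", "mappable", "input")

# Relative slack when comparing hypergeometric probabilities against the
# observed table's probability: tables whose probability is within this
# factor above the observed one still count as "at least as extreme".
# Matches the convention of R's fisher.test, which the grade cutoffs were
# calibrated against.
_TIE_SLACK = 1 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: row 1 = test, row 2 = control; column 1 = observed
    signal, column 2 = complement (or input) reads."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact test p-value.

    With margins fixed, sums the hypergeometric probabilities of every
    table whose probability is at most the observed table's probability
    (with a 1 + 1e-7 relative tie slack).  An empty margin yields p = 1 by
    convention.
    """
    n11, n12, n21, n22 = table.n11, table.n12, table.n21, table.n22
    row1 = n11 + n12
    col1 = n11 + n21
    N = table.total
    if row1 == 0 or col1 == 0 or row1 == N or col1 == N:
        return 1.0
    k_min = max(0, row1 + col1 - N)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, N, col1, row1)
    observed = pmf[n11 - k_min]
    p = float(pmf[pmf <= observed * _TIE_SLACK].sum())
    return min(p, 1.0)


def build_bin_table(
    test_count: int,
    control_count: int,
    mode: str = "max_possible",
    *,
    bin_width: int | None = None,
    max_repeats: int = 1,
    n_test_regions: int | None = None,
    n_control_regions: int | None = None,
    aux_test: int | None = None,
    aux_control: int | None = None,
) -> ContingencyTable:
    """Build the per-bin 2×2 table for the requested normalization mode."""
    if mode == "max_possible":
        if bin_width is None or n_test_regions is None or n_control_regions is None:
            raise ValueError(
                "max_possible mode needs bin_width and region counts"
            )
        cap_test = max_repeats * bin_width * n_test_regions
        cap_control = max_repeats * bin_width * n_control_regions
        n12 = cap_test - test_count
        n22 = cap_control - control_count
    elif mode == "mappable":
        if aux_test is None or aux_control is None:
            raise ValueError("mappable mode needs aux occurrence counts")
        n12 = max_repeats * aux_test - test_count
        n22 = max_repeats * aux_control - control_count
    elif mode == "input":
        if aux_test is None or aux_control is None:
            raise ValueError("input mode needs input read counts")
        n12, n22 = aux_test, aux_control
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n12 < 0 or n22 < 0:
        raise ValueError(
            "observed count exceeds bin capacity; max_repeats or the aux "
            "track is inconsistent with the signal"
        )
    return ContingencyTable(test_count, n12, control_count, n22)


@dataclass
class ProfileResult:
    """Per-bin profile values with significance annotation.

    ``values`` are percentages of possible (or mappable) reads for
    max_possible/mappable mode and reads-per-input ratios for input mode.
    ``grades[i]`` is the index of the deepest ladder cutoff the bin's
    p-value beats (−1: not significant); ``pvalues`` is NaN where a bin was
    skipped for zero capacity (also recorded in ``skipped_bins``).
    ``significant_regions`` are maximal runs of graded bins as
    (first_bin, last_bin, min_p) in bin-offset units.
    """

    bin_indices: np.ndarray
    values: np.ndarray
    pvalues: np.ndarray | None
    grades: np.ndarray | None
    significant_regions: list
    mode: str
    cutoff_ladder: tuple = DEFAULT_CUTOFF_LADDER
    skipped_bins: list = field(default_factory=list)


def _grade(p: float, ladder) -> int:
    g = -1
    for i, cutoff in enumerate(ladder):
        if p < cutoff:
            g = i
        else:
            break
    return g


def _merge_significant(bin_indices, pvalues, grades) -> list:
    regions = []
    run = None
    for b, p, g in zip(bin_indices, pvalues, grades):
        if g >= 0:
            if run is None:
                run = [b, b, p]
            else:
                run[1] = b
                run[2] = min(run[2], p)
        elif run is not None:
            regions.append(tuple(run))
            run = None
    if run is not None:
        regions.append(tuple(run))
    return regions


def _bin_values(n11s, n12s, mode):
    """Plotted value per bin: percentage of possible reads, or input ratio."""
    n11s = np.asarray(n11s, dtype=float)
    n12s = np.asarray(n12s, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "input":
            values = np.where(n12s > 0, n11s / np.where(n12s > 0, n12s, 1), 0.0)
        else:
            denom = n11s + n12s
            values = np.where(denom > 0, 100.0 * n11s / np.where(denom > 0, denom, 1), 0.0)
    return values


def _capacity_arrays(occ, mode, aux):
    """Per-bin complement cells before subtracting counts (mode-dependent)."""
    n = occ.bin_totals()
    if mode == "max_possible":
        cap = np.full(
            occ.geometry.n_bins,
            occ.max_repeats * occ.geometry.bin_width * occ.n_regions,
            dtype=np.int64,
        )
        return n, cap - n
    if mode == "mappable":
        cap = occ.max_repeats * aux.bin_totals()
        comp = cap - n
        if (comp < 0).any():
            raise ValueError("signal exceeds mappable capacity in some bin")
        return n, comp
    if mode == "input":
        return n, aux.bin_totals().copy()
    raise ValueError(f"unknown mode {mode!r}")


def _check_geometry(*mats):
    g = mats[0].geometry
    for m in mats[1:]:
        if m is not None and m.geometry != g:
            raise ValueError("occurrence matrices must share bin geometry")


def profile_compare(
    test: OccurrenceMatrix,
    control: OccurrenceMatrix,
    mode: str = "max_possible",
    aux_test: OccurrenceMatrix | None = None,
    aux_control: OccurrenceMatrix | None = None,
    cutoff_ladder=DEFAULT_CUTOFF_LADDER,
) -> tuple[ProfileResult, ProfileResult]:
    """Compare test and control profiles bin by bin.

    Returns (test-side result carrying the p-values, control-side result
    carrying only the plotted values).  Bins where either side has zero
    capacity get value 0 and a NaN p-value, listed in ``skipped_bins``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "max_possible" and (aux_test is None or aux_control is None):
        raise ValueError(f"mode {mode!r} requires aux matrices")
    _check_geometry(test, control, aux_test, aux_control)

    n11, comp_t = _capacity_arrays(test, mode, aux_test)
    n21, comp_c = _capacity_arrays(control, mode, aux_control)
    bin_indices = test.geometry.bin_indices

    pvalues = np.full(len(bin_indices), np.nan)
    grades = np.full(len(bin_indices), -1, dtype=int)
    skipped = []
    for i in range(len(bin_indices)):
        if mode == "input":
            defined = comp_t[i] > 0 and comp_c[i] > 0
        else:
            defined = (n11[i] + comp_t[i]) > 0 and (n21[i] + comp_c[i]) > 0
        if not defined:
            skipped.append(int(bin_indices[i]))
            continue
        p = fisher_exact_two_sided(
            ContingencyTable(int(n11[i]), int(comp_t[i]), int(n21[i]), int(comp_c[i]))
        )
        pvalues[i] = p
        grades[i] = _grade(p, cutoff_ladder)

    values_t = _bin_values(n11, comp_t, mode)
    values_c = _bin_values(n21, comp_c, mode)
    finite = ~np.isnan(pvalues)
    regions = _merge_significant(
        bin_indices[finite], pvalues[finite], grades[finite]
    )
    test_result = ProfileResult(
        bin_indices=bin_indices,
        values=values_t,
        pvalues=pvalues,
        grades=grades,
        significant_regions=regions,
        mode=mode,
        cutoff_ladder=tuple(cutoff_ladder),
        skipped_bins=skipped,
    )
    control_result = ProfileResult(
        bin_indices=bin_indices,
        values=values_c,
        pvalues=None,
        grades=None,
        significant_regions=[],
        mode=mode,
        cutoff_ladder=tuple(cutoff_ladder),
        skipped_bins=skipped,
    )
    return test_result, control_result


@dataclass(frozen=True)
class CenterFlankSpec:
    """A centered window of ``center_length`` nt compared against two
    flanking windows whose lengths sum to the center length."""

    center_length: int
    flank_upstream: int | None = None
    flank_downstream: int | None = None

    def __post_init__(self):
        a = self.flank_upstream
        b = self.flank_downstream
        if a is None and b is None:
            if self.center_length % 2:
                raise ValueError("center_length must be even for equal flanks")
            object.__setattr__(self, "flank_upstream", self.center_length // 2)
            object.__setattr__(self, "flank_downstream", self.center_length // 2)
        elif (a or 0) + (b or 0) != self.center_length:
            raise ValueError("flank lengths must sum to the center length")


def center_flank_test(
    occ: OccurrenceMatrix,
    spec: CenterFlankSpec,
    mode: str = "max_possible",
    aux: OccurrenceMatrix | None = None,
):
    """Test the window centered on the reference point against its flanks.

    The center window spans ``center_length`` nt symmetric about the
    reference point; the flanks are the immediately adjacent windows.  All
    window bounds must fall on bin boundaries.  Returns
    (p_value, center_density, flank_density) where densities follow the
    same convention as the profile values.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "max_possible" and aux is None:
        raise ValueError(f"mode {mode!r} requires an aux matrix")
    if aux is not None:
        _check_geometry(occ, aux)
    g = occ.geometry
    w = g.bin_width
    c, a, b = spec.center_length, spec.flank_upstream, spec.flank_downstream
    if c % (2 * w) or a % w or b % w:
        raise ValueError("center and flank lengths must be whole (even) bins")
    half_bins = c // (2 * w)
    center_bins = np.arange(-half_bins, half_bins)
    left_bins = np.arange(-half_bins - a // w, -half_bins)
    right_bins = np.arange(half_bins, half_bins + b // w)
    lo = min(left_bins.min(), center_bins.min())
    hi = max(right_bins.max(), center_bins.max())
    if lo < -g.n_bins_upstream or hi > g.n_bins_downstream - 1:
        raise ValueError("center/flank windows exceed the profile extent")

    totals = occ.bin_totals()
    idx = lambda bins: bins + g.n_bins_upstream  # noqa: E731
    n11 = int(totals[idx(center_bins)].sum())
    n21 = int(totals[idx(left_bins)].sum() + totals[idx(right_bins)].sum())
    m, nreg = occ.max_repeats, occ.n_regions
    if mode == "max_possible":
        n12 = m * c * nreg - n11
        n22 = m * (a + b) * nreg - n21
    else:
        aux_totals = aux.bin_totals()
        aux_center = int(aux_totals[idx(center_bins)].sum())
        aux_flanks = int(
            aux_totals[idx(left_bins)].sum() + aux_totals[idx(right_bins)].sum()
        )
        if mode == "mappable":
            n12 = m * aux_center - n11
            n22 = m * aux_flanks - n21
        else:
            n12, n22 = aux_center, aux_flanks
    if n12 < 0 or n22 < 0:
        raise ValueError("window counts exceed capacity; inconsistent max_repeats")
    p = fisher_exact_two_sided(ContingencyTable(n11, n12, n21, n22))
    center_density, flank_density = _bin_values([n11, n21], [n12, n22], mode)
    return p, float(center_density), float(flank_density)


@dataclass
class FDRReport:
    """Shuffle-split null calibration of the per-bin p-values.

    ``proportions[i]`` is the fraction of pooled null p-values below
    ``cutoffs[i]``; ``fdr_trace`` is the per-iteration FDR at the probe
    cutoff; ``converged`` is True when the trace moved by less than epsilon
    for the required number of consecutive iterations.
    """

    cutoffs: tuple
    proportions: np.ndarray
    n_iterations: int
    converged: bool
    seed: int | None
    probe_cutoff: float
    fdr_trace: list = field(default_factory=list)
    n_null_pvalues: int = 0


def empirical_fdr(
    test: OccurrenceMatrix,
    control: OccurrenceMatrix,
    mode: str = "max_possible",
    aux_test: OccurrenceMatrix | None = None,
    aux_control: OccurrenceMatrix | None = None,
    epsilon: float = 0.001,
    streak: int = 10,
    probe_cutoff: float = 0.01,
    seed: int | np.random.Generator | None = None,
    max_iterations: int = 1000,
    cutoff_ladder=DEFAULT_CUTOFF_LADDER,
) -> FDRReport:
    """Estimate the empirical FDR of the per-bin test by label shuffling.

    Each iteration pools all test and control rows (each row keeping its
    mappability/input counterpart), permutes them uniformly at random,
    splits them into two equal halves (one uniformly chosen row is dropped
    when the pooled count is odd), and recomputes the per-bin p-values
    between the halves.  P-values accumulate across iterations; the FDR at
    the probe cutoff is the fraction of accumulated null p-values below it.
    Iteration stops once the FDR changes by less than ``epsilon`` for
    ``streak`` consecutive iterations, or at ``max_iterations`` with the
    convergence flag left False.
    """
    _check_geometry(test, control, aux_test, aux_control)
    n_rows = test.n_regions + control.n_regions
    if n_rows < 2:
        raise ValueError("need at least two pooled rows to shuffle")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    # pooled row store: counts plus optional aux counts, row-aligned
    all_counts = np.vstack([test.counts, control.counts])
    all_aux = (
        np.vstack([aux_test.counts, aux_control.counts])
        if aux_test is not None
        else None
    )
    geometry = test.geometry
    m = max(test.max_repeats, control.max_repeats)

    def matrix(rows, aux_rows):
        occ = OccurrenceMatrix(
            ref_ids=[f"r{i}" for i in range(len(rows))],
            counts=rows,
            geometry=geometry,
            max_repeats=m,
            strandedness=test.strandedness,
        )
        aux_m = None
        if aux_rows is not None:
            aux_m = OccurrenceMatrix(
                ref_ids=occ.ref_ids,
                counts=aux_rows,
                geometry=geometry,
                max_repeats=m,
                strandedness=test.strandedness,
            )
        return occ, aux_m

    null_pvalues: list[np.ndarray] = []
    fdr_trace: list[float] = []
    converged = False
    consecutive = 0
    iteration = 0
    while iteration < max_iterations:
        iteration += 1
        order = rng.permutation(n_rows)
        if len(order) % 2:
            drop = rng.integers(len(order))
            order = np.delete(order, drop)
        half = len(order) // 2
        rows_a, rows_b = all_counts[order[:half]], all_counts[order[half:]]
        aux_a = all_aux[order[:half]] if all_aux is not None else None
        aux_b = all_aux[order[half:]] if all_aux is not None else None
        occ_a, aux_ma = matrix(rows_a, aux_a)
        occ_b, aux_mb = matrix(rows_b, aux_b)
        result, _ = profile_compare(
            occ_a, occ_b, mode, aux_ma, aux_mb, cutoff_ladder
        )
        ps = result.pvalues[~np.isnan(result.pvalues)]
        null_pvalues.append(ps)
        pool = np.concatenate(null_pvalues)
        fdr = float((pool < probe_cutoff).mean()) if pool.size else 0.0
        if fdr_trace and abs(fdr - fdr_trace[-1]) < epsilon:
            consecutive += 1
        else:
            consecutive = 0
        fdr_trace.append(fdr)
        if consecutive >= streak:
            converged = True
            break

    pool = np.concatenate(null_pvalues) if null_pvalues else np.array([])
    cutoffs = tuple(cutoff_ladder)
    proportions = np.array(
        [float((pool < c).mean()) if pool.size else 0.0 for c in cutoffs]
    )
    return FDRReport(
        cutoffs=cutoffs,
        proportions=proportions,
        n_iterations=iteration,
        converged=converged,
        seed=seed_val,
        probe_cutoff=probe_cutoff,
        fdr_trace=fdr_trace,
        n_null_pvalues=int(pool.size),
    )
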