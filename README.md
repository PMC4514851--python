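# profileseq

Quantitative comparison of genome-based signal profiles around reference
points, with per-bin exact tests, mappability/input correction, and an
empirical false-discovery-rate estimate.

Given a set of single-nucleotide signal coordinates (reduced ChIP-Seq,
CLIP-Seq or RNA-Seq reads, motif hits, peak centers, …) and two sets of
anchored reference positions — a *reference* set of interest and a
*control* set to compare against — the tool:

1. bins the signal at fixed offsets around each reference point,
   strand-aware, into an occurrence (`.occ`) matrix;
2. tests each bin with a two-sided Fisher's exact test comparing the
   reference and control counts, under one of three normalizations
   (maximum possible positions, mappable positions, or chromatin input);
3. grades significant bins on a ladder of cutoffs (1e-2 … 1e-10) and
   merges them into maximal significant regions;
4. optionally runs a center-versus-flank exact test around the reference
   point and a shuffle-split empirical FDR calibration of the per-bin
   p-values.

Supporting procedures cover the surrounding analysis workflow: internal-exon
extraction from a GTF with clean intronic flanks, splice-site windows,
percent-spliced-in (PSI) from junction counts, reproducible-peak
intersection, upstream/downstream (US/DS) peak-to-exon assignment, matched
control selection (distance-preserving exon controls, rank-sum attribute
matching, TSS-distance balancing), and ChIA-PET overlap contingency tables.
A deterministic synthetic-fixture generator makes the whole pipeline
testable without any external data.

## Worked example

Generate a synthetic dataset of 200 reference regions (40 bins of 25 nt)
with a 3-fold signal enrichment injected into the five central bins of the
test set only, then count and test:

```
$ cat config.json
{
  "n_refs": 200,
  "geometry": {"bin_width": 25, "n_bins_upstream": 20, "n_bins_downstream": 20},
  "background_rate": 0.08,
  "enrichment_windows": [[-2, 2]],
  "enrichment_fold": 3.0
}
$ profileseq make-fixtures --config config.json --seed 11 --out-prefix demo
$ profileseq count-occurrences --points demo.test.pos --refs demo.test.ref \
    --bin-width 25 --bins-up 20 --bins-down 20 --strand sense --out test.occ
$ profileseq count-occurrences --points demo.control.pos --refs demo.control.ref \
    --bin-width 25 --bins-up 20 --bins-down 20 --strand sense --out control.occ
$ profileseq profile --test test.occ --control control.occ --out-prefix profile
$ cat profile.regions.tsv
first_bin	last_bin	min_p
-2	2	1.18597e-113
$ head -5 profile.test.tsv
bin	value	p_value	grade
-20	7.84	0.183337	-1
-19	8.46	0.971368	-1
-18	8.3	0.855723	-1
-17	7.8	0.735689	-1
```

The injected enrichment is recovered as a single significant region
covering exactly bins −2 … 2; `value` is the percentage of possible
positions occupied and `grade` indexes the cutoff ladder (−1 = not
significant). The center-vs-flank test on the same profile:

```
$ profileseq peaks --occ test.occ --center 150
p_value	0
center_density	21.0333
flank_density	7.98
```

(the exact p-value underflows double precision for this effect size and is
reported as 0). The empirical FDR calibration shuffles reference/control
labels, splits, and re-tests until the estimate stabilizes:

```
$ profileseq fdr --test test.occ --control control.occ --seed 3 --out fdr.tsv
$ head -4 fdr.tsv
#iterations=50	converged=True	n_null_pvalues=2000
cutoff	proportion_below
0.01	0.017
0.001	0.0045
```

A published 2×2 overlap table can be re-tested directly:

```
$ profileseq chiapet-table --n11 414 --n12 282 --n21 16091 --n22 14809
fisher_p	0.000105016
```

which rounds to the published value of 0.00011 for the overlap of
downstream CTCF peaks with chromatin interactions.

## Library use

```python
from profileseq import (
    BinGeometry, FixtureConfig, count_occurrences,
    generate_profile_dataset, profile_compare,
)

config = FixtureConfig(seed=11, n_refs=200, enrichment_windows=((-2, 2),),
                       enrichment_fold=3.0)
data = generate_profile_dataset(config)
occ_t = count_occurrences(data.test, data.test_refs, config.geometry)
occ_c = count_occurrences(data.control, data.control_refs, config.geometry)
result, _ = profile_compare(occ_t, occ_c)
print(result.significant_regions)   # [(-2, 2, 1.18...e-113)]
```

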