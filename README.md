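# chromdyn

Developmental chromatin-accessibility analysis for staged DNaseI-seq
experiments, with a synthetic-data generator for end-to-end validation.

During early *Drosophila* embryogenesis, the repertoire of accessible
regulatory DNA — DNaseI hypersensitive sites (DHSs) marking enhancers,
promoters and insulators — is extensively remodelled as a blastoderm of
undifferentiated cells becomes a patterned embryo. Profiling DNaseI cleavage
at several developmental stages (5, 9, 10, 11, 14) turns that remodelling
into a quantitative signal: which sites are accessible when, which turn on
or off, and where along the genome temporally coherent changes cluster.
`chromdyn` implements the full analysis stack for such data:

1. **Accessible-region ("hotspot") calling.** For each cleavage tag, the tag
   count `n_w` in a `W = 250` bp scan window is compared against a binomial
   model of the surrounding `L = 50` kb (`n_L` tags, `p = W/L`):

   `z = (n_w − n_L·p) / sqrt(n_L·p·(1 − p))`.

   The calling threshold `T` is set empirically at a 1% false-discovery rate
   by counting regions formed by a matched uniform-random tag set; tags with
   `z ≥ T` merge into accessible regions.
2. **DHS peak calling.** Tag density is binned (20-bp bins, 150-bp sliding
   window); 150-bp DHS peaks are placed greedily on local density maxima
   inside accessible regions, retained only when they overlap a DHS from the
   other replicate by ≥ 75 bp, and unified across stages into a consensus
   list with per-stage presence flags and a stage of temporal origin.
3. **Rank expectation** — the differential statistic. To test whether signal
   A is enriched over signal B at a bin, B's bins are ranked low→high and A
   is permuted into that order (A′). Each A′ value is scored with a Gaussian
   z against the median and `1.4826·MAD` of a large centred window of A′,
   giving a one-sided p-value. With two replicates per stage there are four
   measurements per ordered stage pair; a bin shows *consistent enrichment*
   when ≥ 3 of 4 are significant under Benjamini–Hochberg control. Adjacent
   bins with identical enrichment signatures merge into developmentally
   dynamic elements (DDEs), classified as stage-specific, early, late or
   mixed, and clustered by their five-stage profiles.
4. **Dynamic domains.** A per-bin track records the base pairs covered by
   DDEs within 10 kb; density peaks are scored against a bootstrap null
   (elements scattered uniformly with resampled sizes) with BH control at
   α = 0.05 and extended to domains. The ρ score,
   `ρ = Σ w_s·d_s / Σ d_s` with stage weights `w = (+2, +1, 0, −1, −2)`,
   summarises each element's temporal lean, and a binomial neighbour test
   asks whether nearby elements share early/late patterns.
5. **Annotation statistics.** Genomic-category assignment of DHSs
   (TSS ± 100 bp > 5′UTR > CDS > intron > 3′UTR > intergenic), binomial
   interval-overlap significance, conservation of elements versus matched
   random non-coding placements, hypergeometric expression-term enrichment,
   k-means clustering of core-promoter (−60..+40) accessibility profiles
   with per-cluster motif fractions, and peri-exonic accessibility
   clustering against early (pre-zygotic) expression.

Because genome-scale cleavage data are impractical for testing, the package
ships a generator (`chromdyn.simulate`) that plants accessible sites with
known stage profiles (stage-specific, early, late, mixed, constitutive) in
Poisson background at configurable enrichment, plus toy gene annotations,
promoter-motif labels, exon expression values and a conservation track —
all recorded in a truth table so every caller can be scored exactly.

## Worked example

Run the packaged demo — a 0.8-Mb two-chromosome genome carrying ~200
planted sites, including one 30-kb cluster of early-patterned sites and one
of late-patterned sites:

```sh
chromdyn run-all --seed 1 --out-dir demo_out
```

or equivalently from Python:

```python
from chromdyn import RunConfig, run_pipeline
results = run_pipeline(RunConfig.demo(seed=1), "demo_out")
```

`demo_out/summary.txt` then reports (seed 1):

```
Per-stage DHS landscape (replicate-concordant)
stage   dhs_count  percent_of_genome
5       156        3.62
9       127        2.77
10      89         1.96
11      86         1.90
14      204        4.61
all     310        8.61
```

— per-stage replicate-concordant DHS counts and the fraction of the genome
they cover, plus the cross-stage consensus ("all"). The temporal-class
tabulation of the 557 dynamic elements found:

```
Temporal class tabulation
temporal_class  count  percentage
stage5     13    2.33
stage9      7    1.26
stage10     6    1.08
stage11    12    2.15
stage14    26    4.67
early     210   37.70
late      212   38.06
mixed      71   12.75
```

shows the planted structure: most dynamic elements belong to graded early-
or late-peaking classes, with stage-14-specific elements the largest
single-stage class. `demo_out/ddds.tsv` contains the two recovered dynamic
domains — exactly the two planted clusters:

```
chrom  start   end     peak_density  p_value  q_value   nearest_gene
chr2L  298340  320060  3180.0        0.0001   0.003133  gene0024
chr2R  299460  321600  2960.0        0.0001   0.003133  gene0049
```

and the neighbour-pattern test confirms that lag-1 element pairs share
temporal direction far beyond chance (154/160 sign agreements,
p < 10⁻15). Stage outputs (tag densities as bedGraph, regions/DHSs/DDEs as
BED, presence and origin tables as TSV) are written alongside.

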