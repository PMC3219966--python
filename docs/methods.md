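# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the places where the
design was genuinely open.

## Coordinate conventions

All in-memory intervals are 0-based half-open; GFF input (1-based closed)
is converted on read. Density bin `i` covers `[20i, 20i+20)` with midpoint
`20i + 10`; its score counts tags in `[mid − 75, mid + 75)` (right
half-open), so one interior tag contributes to 7 or 8 bins depending on
alignment.

## Accessible-region calling

Each tag's 250-bp scan window is compared with a binomial model of the
surrounding 50 kb: with `n_L` background tags and `p = W/L_eff`,
`z = (n_w − n_L p)/sqrt(n_L p (1−p))`. At chromosome ends the background
window is truncated (not shifted) and `p` recomputed with the effective
span, which keeps the binomial model honest at edges; a position with an
empty background has no defined z and is skipped. z is evaluated per tag
(regions are collections of tags), and qualifying tags within `merge_gap =
W = 250` bp merge into regions expanded by `W/2` on each side.

The threshold `T` is the smallest observed z at which the number of
*regions* formed by a matched uniform-random tag set (same per-chromosome
totals) is at most `fdr` times the number of observed regions. Region
counts as a function of the descending threshold are computed incrementally
(union–find over tags activated in z order), so the scan over all candidate
thresholds is O(n log n + n·k) with k the tags per merge window. An
element-wise variant (`fdr_threshold`) that compares score counts directly
is kept for score-list use; at nominal 1% it realized ~6% region-level FDR
on planted data, which is why the pipeline thresholds on region counts.
Exact-position deduplication before scanning is available behind a flag and
off by default.

## DHS peaks, concordance, consensus

Within each region, plateau local maxima of the binned density are
candidate peaks (leftmost bin of an equal run wins — determinism);
candidates are accepted greedily by descending density, each spawning a
150-bp DHS centred on the peak bin midpoint, and candidates whose DHS would
overlap an accepted one are skipped. A DHS may extend past its region
boundary (the width is fixed, containment is not). Replicate concordance
keeps DHSs overlapping a partner by ≥ 75 bp and merges kept intervals to
their union, which preserves the ≥150-bp footprint for downstream overlap
tests; the cross-stage consensus merges transitively and carries per-stage
presence flags, from which the stage of temporal origin is the earliest
stage present.

## Rank expectation

B's 20-bp bin scores are ranked low→high (ties broken by genomic order via
a stable sort), A is permuted into that order (A′), and each position is
scored against the median `m` and scale `s = 1.4826·MAD` of the centred
`local_window` of A′ (truncated at the ends): `z = (A′ − m)/s`, one-sided
upper-tail Gaussian p, mapped back to genomic bins. `s = 0` defines
`z = 0` (p = 0.5). Bins where both signals are zero are excluded by
default — the genome is mostly empty and massive zero ties would swamp the
windows — and can be kept with a flag. The exact sliding median and MAD are
computed by a numba kernel that maintains a sorted window buffer and
extracts the MAD by an outward two-pointer walk from the median
(O(n·w) worst case, ~1 s for 40,000 bins at w = 10,001).

**Window scaling.** The statistic assumes that the window around a bin in
A′ contains bins of comparable B score. At the top of the ranking this
holds only when elevated (site) bins outnumber the half-window; otherwise a
site that is high in *both* signals sits among background bins and is
falsely called enriched. The default `local_window = 10,001` bins (200 kb)
is proportioned to a full ~120-Mb genome with tens of thousands of
accessible sites; the packaged demo (40,000 bins, ~200 sites ≈ 1,600
elevated bins) therefore uses 1,001 bins (`RunConfig.demo()`). Rule of
thumb: keep the half-window well below the expected number of elevated
bins.

Per ordered stage pair the four replicate cross-comparisons are each
BH-adjusted genome-wide (a single dataset, not per chromosome) and a bin is
flagged on ≥ 3 of 4 votes — conservative by construction. Adjacent flagged
bins with identical 20-pair signatures merge into DDEs. Classification:
stage-s-specific iff s is consistently enriched over every other stage;
else early iff the density peak is at stages 5–10 with no later-over-earlier
enrichment; else late iff the peak is at stages 11–14 with no
earlier-over-later enrichment; else mixed. The early/late rules are this
package's operationalisation — the class names are standard but no exact
decision rule is fixed by them. Profile clustering is k-means on unit-max
profiles with a fixed seed, clusters relabelled by the stage of their mean
profile's peak; with all-identical profiles the assignment degenerates to a
single non-empty cluster.

## Dynamic domains

The density track records bp covered by DDEs within `radius = 10 kb` of
each bin midpoint (read as a radius, i.e. a 20-kb window; exposed as a
parameter). Two bootstrap nulls are provided:

- `ddd_null`: the single-window null — k ~ Binomial(n, span/G) elements
  with resampled sizes placed uniformly in one window. This is the correct
  reference for a *prespecified* window.
- `ddd_peak_null` (used by the pipeline): the genome-wide *maximum* window
  density when all n elements are scattered uniformly (chromosomes
  concatenated). Density peaks are selected maxima over window placements;
  scoring them against the single-window null is anticonservative — in
  uniform-scatter simulations it produced spurious domains in 11–15% of
  runs, versus 0/20 with the maximum-calibrated null, while a planted
  20-element/30-kb cluster is still recovered at p = 1/(n_boot+1).

Peak p-values use the add-one estimator `(r+1)/(n_boot+1)`; BH control at
α = 0.05 over peaks; significant peaks extend to the surrounding run of
bins above the null's (1−α) quantile (the boundary rule is this package's
choice — peaks are defined, boundaries are not), and overlapping domains
merge. `n_boot = 10,000` resolves p down to 10⁻⁴, ample at demo scale;
raise it for finer p-values.

ρ = Σ w_s d_s / Σ d_s with w = (+2, +1, 0, −1, −2) over stages
(5, 9, 10, 11, 14): zero for flat profiles, ±2 for pure terminal-stage
profiles, scale-invariant. The weights satisfy the behaviour the score is
defined by (large positive for stage-5-specific, ≈0 for constitutive); the
exact published constants are not recoverable, so they are parameters. The
neighbour test counts sign agreement of ρ between lag-k element pairs where
both |ρ| > τ (τ = 0.5 — pairs must lean early or late; an eligibility
threshold is needed but unspecified anywhere) against Binomial(n, ½).

## Annotation statistics

Category assignment uses the DHS central nucleotide with precedence
TSS(±100 bp) > 5′UTR > CDS > intron > 3′UTR > intergenic; the precedence
order is a package choice (the categories are mutually exclusive but
unordered in their definition). Interval-overlap significance uses the
merged-subject coverage fraction as the binomial success probability — the
simplest exchangeable-placement null; it matches Monte-Carlo placement
within sampling error for point-like queries and is slightly conservative
for long queries. Conservation comparison draws a size-matched random set
uniformly from non-coding sequence and reports medians with 95%
percentile-bootstrap CIs (1,000 resamples). Promoter "peak density" is the
maximum bin value in the strand-oriented −60..+40 window (max tag count in
sub-windows being the undocumented alternative); metaclusters call a
cluster up/down when the terminal-stage mean exceeds 1.5× the opposite end
(an operationalisation of constitutive/down/up). The exon filter defaults
(length ≥ 320 bp, both flanking introns ≥ 300 bp) follow the stricter of
the two stated variants; the >600-bp total-length variant and the
expression threshold (default 25; 50 is the other stated value) are
parameters. The IUPAC matcher is plumbing for toy motif truth — motif
presence is normally an input computed by a dedicated scanner.

## Synthetic data

Tags are an inhomogeneous Poisson process: uniform background
(`background_rate`, default 0.05 tags/bp — about the real per-sample
coverage of ~14 M tags on ~118 Mb) plus per-site bumps. A unimodal site is
a Gaussian bump with sd = width/4 (±2 sd spans the 150-bp site); a
camelback site is two Gaussians 150 bp apart (sd = width/8) — the
double-peaked promoter morphology. The added intensity at a site's peak is
`site_enrichment × background_rate × stage_profile[stage]`; the expected
extra tags per site are therefore ≈ `enr × rate × √(2π) × width/4` (~23 at
the defaults), chosen so that the scan statistic's power at 5× enrichment
matches the intended ≥90% recall operating point of the region caller.
Replicates are independent draws under the same intensity (separate
digestions of pooled nuclei, not read-level thinning); strand is ignored
(cleavage events are strandless points). All randomness flows from one
integer seed through `numpy.random.SeedSequence(seed, spawn_key=...)`
streams: 0 = tags (stage index, replicate), 1 = annotation,
2 = conservation; pipeline stages derive sub-seeds the same way.

The toy annotation places non-overlapping gene models (5′UTR, three CDS
exons with introns sized to pass the peri-exonic filters, 3′UTR) on random
strands, assigns promoter motifs by per-motif Bernoulli fractions, exon
expression values log-normally (median 15, σ = 1), regulator flags and
expression-pattern terms. The demo configuration plants ~one site per 4 kb
(half constitutive), matching real per-stage site density — important
because the rank statistic's window assumption (above) is a property of
that density — plus two 30-kb clusters of 20 similarly patterned dynamic
sites as domain analogues.

**What the generator does not emulate:** mappability and sequence
composition biases, duplicate-read artifacts, copy-number variation,
cell-population heterogeneity within an embryo, correlated noise between
replicates, and realistic gene architecture (UTR introns, nested or
overlapping genes). Passing tests therefore demonstrate the correctness
and calibration of the statistics under the stated model, not robustness
to those artifacts.

## Problem sizes and determinism

The validation suite runs at desk scale by design: 0.8–2-Mb genomes,
~50,000 tags per sample, 10⁴ bootstrap resamples, 20-seed calibration
loops. The full demo pipeline takes ~20 s; the complete test suite a few
minutes. Everything is single-threaded and two runs with the same seed
produce byte-identical output files (floats are written with fixed
formats; no wall-clock values are recorded).

## Known limitations

- The rank-expectation window must be rescaled with genome/site density
  (see above); no automatic selection is attempted.
- Genome-wide counts from real data (tens of thousands of DHSs and
  thousands of dynamic elements) require the real sequencing data and are
  out of scope; the desk-scale analogues recover planted truth instead.
- The domain caller reports merged intervals without sub-domain structure,
  and its nearest-gene annotation is by TSS distance only.
- `ddd_peak_null` treats the genome as one concatenated line, which very
  slightly overstates the null maximum near chromosome junctions
  (conservative direction).
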