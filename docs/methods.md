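# Methods notes

This note documents the models, algorithms and numerical choices behind
`cenloop`, in the order data flows through the pipeline.

## Coordinates and binning

All coordinates are 0-based half-open; GFF3 input (1-based closed) is
converted on read.  A position `p` belongs to bin `p // bin_size`; an
interval contributes to every bin it overlaps, weighted by overlap length
where a weight is needed (the ChIP simulator) and unweighted where the
operation is a per-bin reduction (site window means, gene-body means).
Centromeres are stored as the midpoint of the annotated CEN interval;
distance-to-centromere is measured from that midpoint (the alternative —
the CEN edge — differs by at most ~60 bp in yeast and is not exposed
because no analysis here resolves it).

## Spike-in calibration

The occupancy ratio `OR = (ChIP_t * input_s) / (input_t * ChIP_s)` is
evaluated literally on the four non-redundant read totals; zero
denominators raise rather than propagate infinity.  `NF = OR_treated /
OR_control` against a declared control.  The nFE track rescales the raw
binned ChIP vector to a genome-wide total of `1,500,000 * NF` and the input
vector to `1,500,000`, then takes the per-bin ratio.  Two policies are
deliberate:

* **No pseudocounts.**  Bins whose raw input coverage is below
  `min_input_reads` (default 1 read) are masked, not smoothed: a ratio at
  an uncovered bin would be an invention.  Masked bins are excluded from
  every downstream statistic.
* **Symmetric scaling constant.**  The input track uses the same
  1,500,000 constant as the ChIP track.  Only the ratio of the two
  constants matters for nFE, so this choice fixes the overall scale; it is
  an assumption, documented here, not a measured quantity.

Peak calling is a thresholding rule: maximal runs of unmasked bins with
nFE >= threshold (default 2.0), runs separated by at most `merge_gap_bins`
(default 0) merged, runs shorter than `min_width_bins` (default 1) dropped.
Summits take the center of the maximum bin, leftmost on ties, which makes
the caller fully deterministic.  No smoothing is applied before
thresholding by default (a boxcar is available via `smooth_bins`).

## Site statistics

"nFE at a site" is the mean over unmasked bins overlapping a 400-bp window
centered on the site summit; the window is configurable, and 400 bp (four
100-bp bins) matches the scale of a cohesin footprint plus binning jitter.
Quartile groups sort ascending (ties broken by genomic coordinate, then
input order) and split into four contiguous groups; remainders go to the
lower quartiles, so 10 sites split (3, 3, 2, 2).  Ratio analysis divides
per-site numerator/denominator ratios by the *median of the control
ratios* and reports the median of the normalized ratios in linear scale;
the statistic is invariant to common rescaling of both tracks, i.e. to
sequencing depth.  Aggregate-profile confidence bands are normal-theory
`mean ± 1.96 * sd/sqrt(n)` per offset; a site-resampling bootstrap is
available and agrees with the normal band to within ~15% at 50 sites.

## Contact maps

Matrices are cis-only, symmetric, one per chromosome, stored as plain-text
upper-triangle COO with a header carrying the grid.  `total` is the full
matrix sum (off-diagonal pairs counted twice, diagonal once).

**Depth normalization** is seeded binomial thinning by default (each count
`c` is replaced by `Binomial(c, target/total)`), or exact multiplicative
scaling.

**Balancing** is iterative correction: bins whose marginal is below 10% of
the median nonzero marginal are masked, then weights are updated by
`w <- w / sqrt(rowsum / mean rowsum)` until the row-sum coefficient of
variation falls below `tol` (default 1e-8); weights are scaled so balanced
row sums equal 1.  Iterative correction converges to the same
doubly-stochastic target as Knight-Ruiz; the substitution is exact in the
limit and immaterial at the tolerances used.

**Expected model.**  `expected(s)` is the mean balanced contact over
unmasked pairs at bin distance `s`, computed separately for each arm
(split at the centromere bin).  Pairs spanning the centromere — which
arise in windows centered on centromere-anchored loops — fall back to a
chromosome-wide curve, since a per-arm expected is undefined for them.

**Decay curves** average contacts per distance, pool over chromosomes
weighted by pair counts, smooth onto geometric distance bins (factor 1.12)
and differentiate log10 P against log10 s by central differences.
`decay_slope` fits a least-squares line over a stated range; on simulated
power-law maps with `alpha` in {1, 1.5} at depth 5e6 over 1 Mb the slope is
recovered within 0.01.

**Insulation** is the diamond score: for each bin, the sum of balanced
contacts between the `w` bins to its left and the `w` bins to its right
(windows 5 and 10 kb at 1-kb resolution), log2-relative to the
chromosome-wide mean of that sum, hence invariant to global scaling.
Scores are computed wherever the window fits inside the chromosome — not
only inside one arm — because the centromere profile (the average score in
a ±20-kb window around all centromeres) is precisely about contacts
crossing the centromere.  Boundary candidates are local minima whose delta
(mean of the flanking maxima minus the minimum) exceeds 0.01; each
candidate's p-value is the Gaussian upper tail of its delta against the
chromosome-wide delta distribution, BH-corrected at q <= 0.01.  An
empirical rank p-value was rejected because it is floor-bounded at 1/N and
can never reach q <= 0.01 after correction on a yeast-sized chromosome.
Masked bins contribute zero to diamond sums (an approximation; maps here
have near-complete coverage).

**Loop calling** is a simplified HICCUPS-style scan at 1-kb resolution.
For every candidate pixel (same arm, distance >= 5 kb), four local
neighborhoods — donut, lower-left quadrant, horizontal and vertical strips,
outer radius 16 px, inner exclusion 8 px — each yield a local expected:
`(sum of balanced observed in the footprint / sum of expected in the
footprint) * expected at the pixel`, converted to the raw-count scale
through the balancing weights for a one-sided Poisson test.  A pixel is
significant when it exceeds all four local expectations and all four
p-values pass Benjamini-Hochberg FDR <= 0.1 (applied per filter, jointly
across all candidate pixels of the chromosome).  Significant pixels within
2.5 kb (Euclidean) merge into one call at their centroid; anchors are
reported as bin-width intervals.  Single-pixel clusters are kept only when
unambiguous — worst-filter p below the family-wise level `fdr/n_candidates`,
BH q <= 0.02, and >= 2-fold over the donut and lower-left expectations.
This replaces HICCUPS' lambda-chunking, which exists to stop exactly the
failure mode observed without it: with hundreds of true-dot discovery
pixels in the BH set, pooled FDR 0.1 tolerates tens of scattered false
single-pixel discoveries, each of which would otherwise become a spurious
loop.  Measured operating characteristics (see `scripts/acceptance.py`):
recall 1.0 for enrichment-5 dots at 30–130-kb separations at depth 3e6 on a
600-kb chromosome, ~0 false calls per null map, anchor error well under
2.5 kb.  Dots whose per-pixel expected drops to ~2 counts (very long range
at modest depth) can be missed — that is a depth limit, not a caller bug.

**Pile-ups (APA)** average observed/expected submatrices in a ±10-kb
window around locus pairs (off-diagonal; pairs closer than 5 kb or with
windows leaving the chromosome are skipped and counted) or around single
loci (on-diagonal).  The central score is the mean of the central 3x3
pixels.  Two systematic effects keep a recovered central score slightly
below the injected dot enrichment: the Gaussian dot profile decays within
the 3x3 center (~3% for a 4-kb-wide dot at 1-kb bins), and injected dots
inflate the expected curve at their own distances (~1–2% at the problem
sizes used).  Both are properties of the measurement, shared with APA on
real data.

**Classification.**  A loop is *centromere-originated* when either anchor
midpoint lies within 5 kb of the centromere midpoint (the operational
radius is a configuration choice; no analysis here is sensitive to it
between 2 and 10 kb), else *cohesin-anchored* when both anchors intersect
a cohesin site, else *other*.  A cohesin site is an *anchor site* when it
intersects (±`tolerance`) the non-centromeric anchor of a
centromere-originated loop; the pipeline default tolerance of 2.5 kb
matches the caller's merge radius and anchor precision, while the bare
function defaults to exact intersection.

## Gene context

For each cohesin site the nearest non-containing gene on each side is
found; the pair is *convergent* when their 3' ends face the site.  The
centromere-distal flank transcribed toward the centromere is the
*CEN-oriented* gene; the centromere-proximal flank transcribed away is the
*TEL-oriented* gene; flanks violating the rule stay unlabeled.  The
labeling is mirror-symmetric between arms.  Group comparisons use the
two-sided Mann-Whitney U test: exact enumeration when min(n, m) <= 8 and
the pooled sample is tie-free, otherwise the normal approximation with tie
and continuity corrections (scipy's implementation; the test suite checks
it against a full enumeration oracle for all shapes with n + m <= 12 and
against a permutation oracle at n = m = 30).

## Synthetic data

The generators are the package's study conditions, not merely fixtures.

*ChIP.*  Reads are multinomial over bins: input weights are per-bin DNA
content times cell equivalents (target:spike mixing ratio, default 2:1;
5:1 for low-abundance targets); ChIP weights multiply the target genome by
a global chromatin-bound fraction and per-site enrichment factors over a
flat background.  With unit enrichments the expected OR equals the bound
fraction, so the bound-fraction ratio between conditions is the ground
truth NF must recover; at depth 1e6, NF lands within 5% of truth in
effectively 100% of replicates.  Optional gamma noise on input weights
models non-uniform samplability (off by default).  Multinomial and Poisson
are the simplest models consistent with count data; overdispersion beyond
counting noise (chromatin accessibility, PCR) is *not* modeled, so passing
recovery tests bound statistical, not technical, error.

*Contacts.*  `lambda(i,j) = C |i-j|^(-alpha)` times domain boosts, times
truncated (3 sigma) 2-D Gaussian loop dots of enrichment E and width
sigma, times an attenuation factor for pairs spanning the centromere; `C`
normalizes the full-matrix sum to the configured depth; counts are Poisson,
symmetrized from the upper triangle.  `expectation=True` returns lambda
itself — the noise-free control used wherever a test needs obs == exp.

*Scenarios.*  A deterministic four-chromosome toy genome (350–800 kb,
~2.3 Mb total, 111 cohesin sites in convergent intergenic regions spaced
16–24 kb, genes flanking every site) encodes the two study conditions on
shared annotation.  `wt_like`: loops between adjacent same-arm cohesin
sites plus short (12/20-kb reach) pericentromeric loops, enrichment 4;
Scc2 arm-site enrichment 1.3; mild centromere insulation (factor 0.8).
`wpl1_eco1_like`: six centromere-anchored loops per chromosome at 25–130-kb
distances (mean ~67 kb), enrichment 6; cohesin bound fraction reduced to
0.6; strong centromere insulation (0.3); anchor sites carry long
(3–4.5-kb), strongly transcribed CEN-oriented genes.  The mutant Scc2
arm-site enrichment is not hand-set: it is solved (Brent root-finding on
the generator's noise-free expectation pushed through the full calibration
math) so the expected Scc2/Scc1 median fold versus wild type is exactly
2.53.  Every injected feature is exported in a manifest for recovery
tests.  Problem sizes (ChIP depth 4e6 reads per fraction at 100-bp bins,
contact depth 3e6 per chromosome at 1-kb bins) were chosen so that
counting noise on the recovered quantities is a few percent — small
against every tolerance tested.

## Pipeline

`run_pipeline` spawns child seeds from one `SeedSequence` per stage, so a
fixed seed yields byte-identical reports.  Stage failures abort with the
stage name.  In the wild-type condition each sample is its own calibration
control (NF exactly 1); in the mutant condition matched wild-type control
samples are simulated with separate child seeds.  The report JSON carries
every stage's metrics plus provenance (scenario, seed, version, config
echo); `compare_conditions` walks two reports and emits deltas and folds,
marking metrics absent on one side rather than failing.

## Known limitations

* The loop caller reimplements HICCUPS' logic, not its code: lambda-chunked
  FDR is replaced by the singleton rule above, and exact Juicer thresholds
  are not reproduced.  Calls on real data would differ in marginal cases.
* Trans contacts, A/B compartments and stripe calling are out of scope;
  stripes can be inspected via pile-ups over user-supplied anchors.
* The synthetic genome has no repeats, mappability gaps or copy-number
  structure, so masked-bin handling is exercised only lightly.
* Insulation boundary calls on rough, low-depth maps retain some false
  positives; the boundary statistic is secondary to the score profile in
  every analysis here.
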