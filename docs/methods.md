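# Methods

`epirevert` re-implements, as a tested pipeline on synthetic data, the
bespoke computations used to track the gain and loss of MEK-inhibitor
(MEKi) resistance in pancreatic cancer cell lines: differential methylation
and its reversion after drug withdrawal, genomic-context annotation and
matched-random-region enrichment, variant-allele-fraction (VAF) clonality
analysis with bisulfite-aware validation, and dose-response/Loewe synergy
quantification.  This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Study design being emulated

Two cell lines are observed in four states: *parental* (treatment-naive),
*resistant* (after chronic MEKi exposure), and *P5*/*P12* (5 and 12 passages
after drug withdrawal, during which MEKi sensitivity returns).  Whole-genome
bisulfite sequencing (WGBS) gives per-CpG methylation levels per state; WGS
gives variant tables with per-sample VAFs; RNA-seq gives gene-level log2
fold changes; viability assays give dose-response matrices.  The synthetic
generator (`epirevert.simulate`) reproduces the *structure* of these data
with planted ground truth, so every downstream claim the package makes can
be checked against a known answer.

## Synthetic data

* **Genome** — chromosomes with CpGs from a homogeneous Poisson background
  (default 0.01 CpG/bp) plus denser CpG islands (0.10 CpG/bp, 500–2000 bp),
  and non-overlapping gene models with alternating exon/intron structure.
  All coordinates are 0-based half-open.
* **Methylomes** — each non-DMR CpG has one per-(line, CpG) baseline level
  shared across all four states, drawn Beta(8, 2) outside islands (mostly
  methylated, as in somatic genomes) and Beta(2, 8) inside islands.  The
  non-DMR background distribution is not dictated by the emulated study and
  is configurable.  Planted DMRs are non-overlapping runs of 4–30 CpGs,
  separated by at least one background CpG, that shift the resistant level
  by ±`dmr_delta` in *both* lines (96% hypermethylated by default).
  `dmr_delta` defaults to 0.5: the 0.4 value is the *calling threshold*, and
  planting effects exactly at the detection threshold makes recovery
  ill-posed under sampling noise.  A fraction (10% by default, matching the
  observed ~217/2191 reverting share) returns to the parental level at P12
  with the P5 level strictly between resistant and P12; non-reverting DMRs
  stay at the resistant level.  Observed levels are beta-binomial draws at
  Poisson(30×) coverage with precision 100 (mild overdispersion,
  intra-class correlation ≈ 0.01); `noiseless=True` returns the true
  levels.
* **Variants** — VpRs carry the alternate allele on 1 of `ploidy` (default
  4) haplotypes of the resistant clone: true VAF 1/ploidy in resistant and
  P12, 0 in parental.  VpPs mirror this in the parental state; VpPRs carry
  1–ploidy copies everywhere.  Observed VAFs are Binomial(40×, true)/40.
  Substitution types are drawn uniformly over the 12 SNV classes.
* **Dose-response** — three-parameter log-logistic single-agent curves
  (Hill slope 1) with IC50 defaults 12.70 nM (MEKi) and 500 nM (the
  DNMT-inhibitor-like partner), top 100, bottom 0, Gaussian noise (sd 2
  viability %); the combination surface is the Loewe expectation plus a
  planted synergy offset scaled by joint receptor occupancy (zero on the
  margins).

What the generator does **not** emulate: read-level data and bisulfite
conversion chemistry, mapping artefacts, copy-number heterogeneity along
chromosomes, linked methylation haplotypes, batch effects, or impurity
(purity is fixed at 1, as appropriate for cultured lines).  Passing tests
therefore demonstrate correctness of the *computations*, not robustness to
every artefact of real sequencing data.

## DMR calling

Tracks are smoothed with a coverage-weighted running mean over a window of
`smoothing_window` CpGs (default 5, window 1 = identity).  This is a
deliberately simple, documented stand-in for local-likelihood smoothing; it
is configurable and the calling criterion does not depend on the smoother's
internals.  A DMR is a maximal run of consecutive CpGs (inner-joined across
the four parental/resistant samples) where the smoothed resistant−parental
difference has the same sign and magnitude ≥ 0.4 in both lines, with ≥ 4
CpGs.  Runs separated by even one non-qualifying CpG are not merged.  The
two-line requirement is implemented as the per-CpG intersection of
qualifying runs, with the CpG minimum re-checked on the intersection.

Because a centred mean dilutes the first and last ~`window/2` CpGs of a
region, the per-CpG-on-smoothed-levels semantics structurally cannot
recover 4–5-CpG DMRs for any window ≥ 3.  The caller therefore also offers
`delta_mode="region_mean"`: runs are seeded by cross-line sign agreement of
the raw differences and the 0.4 threshold is applied to the run-mean
difference per line.  On the desk-scale benchmark (50 planted DMRs,
Δ = 0.5, 4–30 CpGs, 30× coverage, 10 Mb) region-mean mode with
`smoothing_window=1` reaches recall 0.92–0.96 at precision 1.0 over five
seeds, versus recall ≈ 0.88 for the smoothed per-CpG mode; the acceptance
suite uses the region-mean configuration and the brute-force oracle checks
the per-CpG mode exactly.  DMR ends cover the final CpG dinucleotide but
never extend over the next CpG.

Amplicon-level validation of a DMR requires |mean_resistant −
mean_parental| ≥ 0.2 in the amplicon, with the sign matching the WGBS call
when a direction is supplied.

## Reversion scores

For a DMR with per-state mean methylation m_P, m_R, m_P12, let
d1 = m_R − m_P and d2 = m_P12 − m_R.  The methylation reversion score is

    s = clamp(−d2 / d1, 0, 1),

the fraction of the resistance shift undone at P12: 0 if P12 stayed at the
resistant level or drifted further, 1 if it reached or overshot the
parental level, and s > 0.5 exactly when P12 is closer to the parental than
to the resistant level (verified over 10⁵ random triples).  The two
saturated cases reproduce the zero/one cases of the piecewise definition;
the open form was chosen because a ratio of |Δ(P, P12)| to |Δ(P, R)| is
*small* when P12 ≈ parental, which contradicts the stated interpretation
and cannot yield a continuum with a meaningful 90% quantile.  The per-DMR
score across two lines is the arithmetic mean of per-line scores (no
aggregation rule is dictated by the emulated analysis); a DMR is
*reverting* when its score is strictly above the empirical 90% quantile of
all scores, so the flagged fraction is 10% ± 1/N by construction.

The transcript score from l1 = log2FC(parental, resistant) and
l2 = log2FC(P12, resistant) is 0 if −1 < l1 < 1 or l1·l2 < 0, and
max(|l1|, |l2|)/min(|l1|, |l2|) otherwise (≈ 1 when the P12 expression
change mirrors the parental one).  The denominator is floored at a small
constant (default 1e−9) to guard l2 = 0.  No threshold for calling a
transcript reverting is defined; raw scores are returned.

P5 intermediacy is the fraction of DMRs whose P5 mean lies inclusively
between the resistant and P12 means in every line.

## Genomic context

Shores are the 2 kb flanking CpG islands, shelves the 2 kb flanking shores,
with precedence island > shore > shelf and everything else ocean; the four
interval sets tile each chromosome exactly (checked per-bp).  Gene context
is exon > intron (gene span minus exons) > intergenic.  Region composition
is counted in bp; compositions of disjoint region sets add.  Composition is
compared to the genome-background composition by Pearson chi-square on bp
counts with expected counts from background fractions (so toy genomes are
valid backgrounds).  Nearest flanking genes are assigned by TSS distance on
each side (0 if a TSS lies inside the region), ties broken by lower
coordinate then gene id; strand affects only where a gene's TSS sits.
Expression labels: up if log2FC > 1, down if < −1, else neutral (strict).

## Enrichment against matched random regions

Each observed region is matched, per iteration, with a random genomic
region of the same length (trivially within the 10% length tolerance) and a
CpG count within max(1, ⌈10% · c⌉) of the template's.  Placements are
uniform over qualifying windows: rejection sampling normally, with an exact
sliding-window enumeration fallback when the projected rejection cost
exceeds the attempt budget (short CpG-dense templates).  The per-iteration
statistic is the count of regions overlapping ≥ 1 feature interval
(half-open semantics; one hit per region); `exceed_fraction` is the share
of iterations in which the observed count strictly exceeds the random one,
and a feature is enriched at level ℓ ∈ {0.05, 0.01, 0.001} when
exceed_fraction ≥ 1 − ℓ.  The iteration count defaults to 10⁴ for desk
scale (the emulated analysis used 10⁶; reachable by configuration, and the
"one random set per iteration" reading of that design is implemented).
Each track in a panel gets its own random stream derived from the seed and
the track name, so results do not depend on track order.  Random regions
may overlap each other and the originals unless `exclude_originals` is set.
Under null feature placement the 0.05 call rate is ≤ 7% over 200 replicate
runs (tested).

## Clonality

VAF-trajectory classes: VpP (parental VAF > 0, resistant = 0), VpR
(parental = 0, resistant > 0.1), VpPR (both > 0); parental = 0 with
0 < resistant ≤ 0.1, and double zeros, remain *unclassified* and are
reported as such.  "= 0" means exact zero from the caller, with a
configurable epsilon (default 0).  The expected clonal VAF is
purity·copies / (purity·ploidy + (1 − purity)·2); one copy on four alleles
gives the tetraploid 0.25 mode.  VAF densities use a Gaussian kernel with
bandwidth Silverman's rule clipped to [0.01, 0.1] and floored at the
observed lattice spacing of the data — fixed-depth VAFs live on a k/depth
grid, where Silverman's rule undersmooths and the mode estimate would
otherwise jump between adjacent lattice points.  Modes are local maxima
above 10% of the global maximum, highest first.  Per-chromosome summaries
flag chromosomes with < 10 variants as low-support.  Bisulfite validation
keeps only A>T and T>A SNVs covered strictly above 15× in the validating
sample, because conversion of unmethylated C confounds every class
involving C or G; persistence in P12 means VAF > 0 there, and variants
without a P12 measurement are excluded and counted separately.

## Pharmacology

Single-agent curves follow R(d) = bottom + (top − bottom)/(1 + d/IC50)
(the three-parameter "log(inhibitor) vs. response" model, Hill slope 1;
a four-parameter variant with a free slope is available but off by
default).  Fitting is least squares over (log IC50, top, bottom), requiring
≥ 4 dose points; a flat response, non-convergence, or an IC50 more than
100× outside the tested dose range is a fit failure.  Viability is in
percent of untreated (DMSO-normalised); per-plate re-normalisation before
synergy analysis is left to the caller.  The Loewe-additive expectation for
a dose pair solves dA/A(E) + dB/B(E) = 1 by bracketed root-finding on the
effects attainable by both curves, reducing to the single-agent curve when
one dose is zero and clamping (with a warning) outside the attainable
range.  Synergy is observed − expected viability per grid cell (negative =
synergistic killing), zero on the single-agent margins by convention; a
drug sham-combined with itself yields |mean synergy| < 0.02 at zero noise.

## Numerical choices and degenerate inputs

Windows with zero total coverage fall back to unweighted means; smoothed
levels are clipped to [0, 1].  Empty tracks smooth to empty tracks; an
empty DMR list summarises to zeros with an explicit empty flag.  The
reversion score is an error when m_R = m_P (the region was not
differential).  Chi-square requires a non-zero observed total and positive
background mass wherever observations fall.  The KDE needs ≥ 2 values.
Interval sets are merged half-open integer arrays; a shared endpoint is not
an overlap.  All randomness flows through `numpy.random.default_rng` with
explicit seeds; identical configuration + seed reproduces every output
bit for bit, and the pipeline manifest records parameters, seed, version
and content checksums.

## Problem sizes

The test suite and the reproduction script run at desk scale: genomes of
1–10 Mb with ~10⁴–10⁵ CpGs, 50–100 planted DMRs, 10³–3·10³ variants,
2·10³–10⁴ enrichment iterations and 100–200 replicate runs.  These sizes
were chosen so the full statistical behaviour (recovery rates, calibration,
convergence of VAF modes) is measurable in seconds to minutes on one CPU;
all of them scale up by configuration only.

## Known limitations

The smoother is a running mean, not a local-likelihood fit; DMRs of 4–5
CpGs are only recoverable in region-mean mode.  The headline counts of the
emulated study (2191 DMRs, 217 reverting, thousands of VpRs per line)
require the original sequencing data and are out of scope; the package
validates the *methods* on planted truth instead.  Enrichment matching is
marginal on length and CpG count only (no GC or repeat matching).  The
expression score is returned unthresholded.  VCF support is a minimal
AF:DP subset, not the full specification.
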