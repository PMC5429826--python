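# Methods

## Scope and model

`covqc` scores cohort exome coverage per *region*: a maximal merged
exon of a gene, optionally fragmented by intersection with the capture
targets, restricted to autosomes 1–22. Coverage is consumed as per-base
integer read depth (BEDTools `coverage -d` or `genomecov -d` output);
the package makes no assumptions about how reads were mapped or
deduplicated — the depth file is ground truth. Bases missing from a
depth file are depth 0, not missing data: an uncovered base is exactly
what the sparseness score must count.

Two metrics are computed per region of length `L_R`.

**Cohort Coverage Sparseness.** For each sample the deficient fraction
is `#(c_i < t) / L_R` with cutoff `t = 10` reads (strict `<`; a base at
exactly 10X is adequate). CCS is the median of these fractions across
samples; for even cohorts the median is the midpoint of the two
central order statistics. Gene-level CCS pools all of a gene's exonic
bases into one region of interest (denominator = total exonic length)
rather than averaging exon scores — the score is defined on a region's
base set, and a gene's region of interest is the union of its exons; a
per-exon-median aggregation is available as an option. Genes classify
as adequate (CCS ≤ 0.2), low (0.2 < CCS ≤ 0.5) or severe (CCS > 0.5).

**Unevenness.** Per region: (1) the per-base median depth across
samples; (2) LOWESS smoothing; (3) hill-climbing extremum detection;
(4) peak geometry; (5) `U_E = Σ_peaks (H/B) / (W/L_R)`, floored at 1,
with an empty peak set defined as exactly 1 (uniform coverage).
`H` is the *absolute* smoothed coverage at the apex, not the height
above baseline: this is what makes the score library-size invariant —
if all coverage scales by a constant, H and B scale together and every
ratio is unchanged — while a region where coverage collapses to zero
breaks the proportionality (H grows, B does not) and the score rises.

## Numerical and algorithmic choices

*LOWESS.* The span is proportional: the window at each base holds
`k = max(ceil(span · L_R), 4)` nearest positions (default span 0.03),
so short exons keep fine structure while the same absolute wiggle is
smoothed away in long exons. Ties in neighbour distance break toward
the lower index; weights are tricube in distance scaled by the window's
maximum distance; the local fit is degree-1 weighted least squares with
no robustness iterations. A window whose values are all equal
short-circuits to that value — this keeps an exactly constant profile
exactly constant, which matters because the downstream extremum scan
compares floating-point values for equality. Zero-variance windows in
x fall back to the weighted mean. statsmodels' `lowess` is close but
not bit-compatible (different window-size rule), so the smoother is
implemented here and verified in the tests against an independently
written reference with the same pinned definitions.

*Extremum detection.* The smoothed curve is scanned for positions with
no increasing or decreasing neighbour. A plateau (maximal run of equal
values) collapses to one candidate at `floor((start+end)/2)` and
classifies by the values flanking the run; a run touching a region
boundary classifies by its single interior flank. The boundary
positions themselves are never peaks — a monotone edge is an artifact
of where the region was cut, not capture unevenness — but an edge
plateau wide enough that its centre is interior does count. That
refinement is deliberate: in an otherwise flat region with a central
coverage hole, the flat shoulders are edge plateaus, and they must
register as peaks for the hole to raise the score (the dropout
sensitivity the metric exists to deliver). Endpoints remain
trough-eligible, since they delimit peak bases. Between consecutive
peaks exactly one trough is kept (the lowest value; leftmost on ties),
enforcing alternation.

*Peak geometry.* Flanking troughs are the nearest detected trough on
each side, falling back to the region endpoint. `B` is the mean of the
two flanking trough values, floored at 0.5 reads (half the minimum
countable read) so a zero-coverage trough yields a finite `H/B`;
`W` is the distance in bp between the flanks. `H` and the smoothed
values stay in floating point throughout.

*Short regions.* CCS is well defined at any length; U_E needs a curve,
so regions shorter than 4 bp are skipped for U_E with a logged notice.

*Statistics.* Pearson correlation and the chromosome contingency test
use scipy (`pearsonr`, `chi2_contingency` without continuity
correction; df = K−1 over K chromosomes, with a flag when any expected
count falls below 1). The Friedman test is computed from average ranks
with the standard tie correction and a chi-square approximation on
K−1 degrees of freedom; it is implemented in-package so that matched
designs with K = 2 platforms are accepted, and it is checked against
scipy for K ≥ 3. Displayed p-values floor at `< 2.2e-16`; the raw value
is always emitted alongside.

## Synthetic cohorts

The simulator draws per-base depths as
`noise(base_mean_depth × bump × dropout × GC multipliers)`, with noise
none, Poisson, or negative binomial (mean–dispersion parameterisation,
variance `μ + μ²/k`, drawn as a Poisson–gamma mixture). Bumps are
Gaussian multiplicative excesses emulating probe pile-ups; dropouts
multiply a sub-interval's depth by a factor in [0, 1], emulating
repeat- or GC-driven capture failure; the optional GC response maps a
region's GC fraction to a depth multiplier. Defaults — 100X mean depth
(comfortably above the 75X QC cut typical of production exomes),
Poisson noise, lognormal exon lengths with ~200 bp median — are chosen
once to represent a realistic well-behaved capture cohort.
Determinism: each sample draws from `default_rng((seed, sample_index))`,
so outputs are byte-identical across runs and platforms for a given
config. A companion generator writes synthetic reference sequence
realising prescribed per-region GC fractions, and `make_fixture_suite`
emits named fixtures (uniform, single/two-bump, edge-dropout,
GC-graded, repeat-trough) used by tests and examples.

What the simulator does *not* emulate: read-level artifacts (mapping
ambiguity, fragment-length effects, strand bias), correlated noise
along the genome, and inter-sample library-size variation beyond a
scalar mean. Passing tests therefore demonstrate that the metrics
recover planted coverage structure under idealised counting noise, not
that they characterise any particular real capture platform.

## Known limitations

- Under counting noise the cohort-median profile retains ±1-read
  micro-wiggles that the short proportional-span window does not
  flatten, and each surviving micro-peak contributes roughly
  `L_R / W`. U_E of a noisy-but-flat region therefore sits far above
  the theoretical fixed point of 1, at any cohort size. The score is
  accordingly a *comparative* statistic — rank regions within a cohort
  processed identically — not an absolute one; the exact U_E = 1
  identity holds in the noise-free limit the acceptance checks use.
- Both metrics are blind to regions that are consistently well covered
  in every sample but wrongly mapped, and to low coverage that is
  uniform across the cohort *and* across the region (CCS sees it, U_E
  does not).
- The exact original definitions of a peak's base and width are not
  recoverable from the method's published description; the choices
  here (mean of flanking troughs; trough-to-trough width; 0.5-read
  floor) are pinned, configurable (`--b-floor`, `--span`), and stated
  so results are reproducible against this implementation.
- GC content uses unambiguous bases only; regions that are entirely N
  report GC as NaN and are excluded from banding.
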