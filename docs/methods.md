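# Methods

## Data model and orientations

Three layers share one container (`ExpressionMatrix`): a feature × sample
matrix of log2-scale values bound to a `TimeCourseDesign`. The RNA axis
has seven ordered time points (E12, E14, E16, E18, P2, P10, Adult; two
replicates each by default), spanning the pseudoglandular through
alveolar stages of lung development and adulthood. The protein axis has
six (E13.5, E16, E18, P2, P14, Adult); the partial map between the axes
pairs E14↔E13.5, E16↔E16, E18↔E18, P2↔P2, P10↔P14, Adult↔Adult, leaving
E12 unmapped. Time points are categorical labels with an explicit order —
never parsed from the strings — so "Adult" needs no special-casing.

qPCR ΔCT values behave as *negative* log2 abundance (one PCR cycle ≈ one
doubling), so matrices carry an explicit orientation tag (`dct` vs
`expression`). The dynamic filter for miRNAs runs on ΔCT (Min is
thresholded, because an abundant miRNA has a *small* ΔCT); correlation
runs on −ΔCT so that a negative Pearson r means biological
anti-correlation on every layer. Applying the negation twice is an error.
The alternative convention (correlating raw ΔCT, where anti-correlation
appears with positive sign) remains available through the pipeline's
`mirna_orientation` option, since published analyses are not always
explicit about it.

## qPCR preprocessing

Censoring maps undetected values and CT > 35 to exactly 35 (idempotent;
negative CT is a hard error, CT = 0 a warning). ΔCT is computed per
sample against that sample's own U6 value — U6 is a per-card internal
control, so a global U6 mean would leak between-card variation into every
miRNA. Copies per cell uses the calibration line
`10^((40 − CT)/3.34) / 22` (slope 3.34 cycles per 10-fold, from a
synthetic standard; 30 pg total RNA per cell is interpretive metadata).
The implementation keeps the U6 reference cycle as an explicit parameter
(default 18.0 in the simulator): copy numbers quoted for a ΔCT value
depend on it, e.g. ΔCT 0.14 on a U6 cycle of 18.0 gives ≈ 1.59 × 10⁵
copies. The exactness property copies(ct)/copies(ct + 3.34) = 10 holds to
machine precision and is tested. All downstream statistics run on the
log2/ΔCT scale; copies per cell is a report column only.

## Dynamic filter

Descriptive statistics are computed on per-time-point *means* (replicates
averaged first): Max, Min, Range = Max − Min, fold change = 2^Range. The
Range definition is "across time points", which fixes the mean-profile
reading; computing extrema on raw replicate samples would inflate Range
by replicate noise.

The test is classical one-way fixed-effects ANOVA with time point as the
single factor — df (6, 7) for the default design — implemented as
vectorized sums of squares with the F survival function from
`scipy.stats.f` (and checked in the suite against `scipy.stats.f_oneway`
to 10 significant digits on random matrices). Degenerate features
(zero within-group variance) are flagged: all-constant features get
p = 1 and can never pass (conservative and well defined); perfectly
separated features get the smallest positive double.

FDR control is Benjamini–Hochberg step-up via
`statsmodels.stats.multitest.multipletests`, verified against a textbook
enumeration oracle on all permutations of short p-vectors. The filter
keeps a feature iff extremum AND Range AND q < 0.05 all hold; an audit
table records which condition(s) each rejected feature failed, and the
pass set is monotone under threshold loosening. Effective post-hoc p
cutoffs sometimes quoted alongside BH (e.g. "p < 0.03") are descriptive
consequences of the q-filter, not independent thresholds — the filter
uses q only.

Time-course–specific alternatives to ANOVA (spline-based statistics such
as EDGE) are deliberately not reimplemented; the pipeline accepts a
second feature list and reports overlap counts and percentages so such a
comparison can be audited.

## Temporal clustering

Profiles are the 7 per-time-point means, row-standardized (mean 0,
sd 1 — making the clustering invariant to per-feature affine transforms
a·x + b, a > 0), with distance 1 − Pearson r, average linkage, and a
maxclust cut at k (defaults 6 mRNA / 5 miRNA, matching the number of
temporal patterns typically reported; the cut rule itself is a user
parameter because dendrogram-cut conventions vary across tools).
Zero-variance profiles cannot be standardized and go to a reserved
"flat" cluster (id 0) with a warning. Clusters are renumbered by
descending size; features are sorted by id first so the result is
order-invariant. Centroids for labeling use relative-to-adult profiles
(log2 ratio to the Adult mean) so that "peak at E18" refers to actual
relative expression; the labeler calls monotone_up/monotone_down within a
tolerance of ε = 0.1 standardized units, then interior peaks/troughs that
clear both endpoints by ε, else "other".

## Correlation screening and direct targets

Pairs are scored by the sample Pearson correlation of per-time-point
mean profiles — n = 7 on the RNA axis, n = 6 after protein alignment
(the time-point-level reading follows from the analysis being defined
"across 7 time points"; correlating the 14 replicate samples would mix
replicate noise into the temporal signal). Cutoff comparisons are strict
(|r| > 0.9 mRNA, > 0.8 protein). Zero-variance profiles are skipped and
logged. A negative pair is a *direct* target call iff the prediction
table, mapped through transcript → probe ids, contains that (miRNA,
probe) combination; positive pairs are never direct. The direct set
shrinks monotonically as the cutoff rises. Correlation p-values are
intentionally not computed: with n = 6–7 the r threshold is the filter.

## Protein integration

Spectral counts from the three organelle fractions (nuclear,
mitochondrion, cytosol) are combined per protein and time point by
summation — counts are additive sampling evidence — with "mean" and
"max" available as alternatives, then transformed log2(x + 1); the
pseudocount handles the many zeros of shotgun proteomics and is a
parameter. A fraction absent from the table is a zero count. Alignment
restricts the RNA profile to the six mapped time points in axis order;
every protein-layer correlation therefore reports n = 6, which the tests
treat as a contract.

## Regulation classification

Per (miRNA, gene) edge, with genes canonicalized through probe↔protein
id maps (unmappable proteins are skipped and logged):

| mRNA-direct | protein-direct | gene in dynamic mRNA set | mode |
|---|---|---|---|
| yes | yes | — | both |
| yes | no | — | pattern1_mrna_down |
| no | yes | no | pattern2_translational |
| no | yes | yes | unsupported |

"No detectable mRNA change" is operationalized as absence from the
dynamic mRNA set produced by the filter stage; an optional stricter
variant additionally requires |r(miRNA, mRNA)| ≤ a ceiling (default 0.5
when enabled). Mode labels partition the edge set. The summary reports
the translational fraction over protein-level direct *pairs* and over
distinct *genes*, since the two denominators differ whenever a protein
is targeted by several miRNAs.

Genomic clusters chain loci per chromosome by single linkage on start
positions with gap ≤ 1 Mb, emitting chains with ≥ 3 members ("more than
two"). The gap reading of "within 1 Mb" was chosen over the total-span
reading; the span is reported so users can re-filter. Coordinates are
0-based half-open (BED).

## Synthetic data

The generator plants five miRNA archetypes (gradual rise to an adult
peak; peaks at E18 or P10 from a low embryonic start; a high-embryonic
E18 peak; a monotone decline) and six mRNA archetypes as piecewise-linear
templates over the seven time points — idealizations of the temporal
patterns seen in lung development, exposed as configuration rather than
ground truth. Scales are chosen so planted features clear the filters
with realistic margins: miRNA log2 expression 2–6 (ΔCT −6 to −2,
Range 4), mRNA log2 8–12 on flat decoys at 9, replicate noise sd 0.1
log2 units (typical array replicate noise), two replicates, U6 at
cycle 18.

Mode-A targets are affine negative transforms of their miRNA's realized
latent profile (noiseless limit: r = −1 exactly); mode-B targets have
flat mRNA and a protein latent equal to a negative transform of the
miRNA profile on the six mapped time points. Proteins of mode-A targets
and of decoy genes track their own mRNA (latent − 4), which is why
recovered mode-A edges classify as `both`. Spectral counts are Poisson
(negative binomial via a dispersion parameter) around
2^latent, split 0.5/0.3/0.2 across fractions — means of roughly 16–256
counts, so Poisson noise is small relative to the planted 16-fold
amplitude. Decoy predictions point at flat genes, so they are never
anti-correlated beyond chance. The default instance plants 20 mode-A and
10 mode-B edges among 30 miRNAs and 200 mRNAs (translational fraction
1/3). Loci include one planted trio within 1 Mb on chr14.

What the generator does **not** emulate: probe-level hybridization
effects and cross-hybridization, amplification-efficiency variation
between assays, missing-not-at-random MS dropout, correlated replicate
noise, and many-to-many target structure at realistic density. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated noise model, not expected sensitivity on real
array/MS data, where anti-correlation screens are far noisier.

## Problem sizes and numerical choices

The simulation suites use 30 × 200 × 120-feature instances (50 seeds for
the translational-fraction recovery; 200 null matrices of 100 features
for the FDR calibration) — large enough for stable fractions, small
enough that the full suite runs in seconds on one CPU. Determinism comes
from `numpy.random.default_rng(seed)` throughout; the acceptance script
derives all simulation seeds from its `--seed` argument. TSV round-trips
write floats with `%.17g` and read with pandas' round-trip parser, so
write→read is bit-exact. Pearson values are clipped to [−1, 1] against
floating-point overshoot. Ties in cluster renumbering break on the
smaller dendrogram label; ties in locus sorting on the miRNA id.

## Known limitations

- The filter assumes ≥ 1 replicate per time point and needs df_within ≥ 1
  for ANOVA; single-replicate designs are rejected rather than silently
  approximated.
- Correlation at n = 6–7 has high variance; the strict |r| cutoffs trade
  sensitivity for specificity exactly as the screening design intends,
  and no p-values are attached.
- GO/pathway enrichment, RMA normalization of raw arrays, and prediction
  algorithms themselves (the table is consumed as-is, conservation
  filtering unknown) are out of scope.
- The "unsupported" class absorbs protein-direct edges whose mRNA is
  dynamic but not itself direct; biologically these may be mixed-mode
  regulation, and the evidence columns are retained for re-analysis.
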