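# Methods

## Site definitions and scanning

A **seed site** is an exact Watson–Crick match between the mRNA and the
miRNA 5′ region, in three classes: **7mer-m8** (match to miRNA
positions 2–8), **7mer-A1** (match to positions 2–7 with an adenosine
in the mRNA opposite position 1), and **8mer** (both). Following the
TargetScanS convention the A1 adenosine is required in the target
regardless of the miRNA's own first nucleotide; 6mer matches are not
counted. A **centered site** is an 11-nt duplex between the mRNA and
an 11-mer miRNA window starting at position 3, 4 or 5 (1-based from
the 5′ end). Pairing is antiparallel: window position *j* pairs with
site position 12 − *j*, with the site read 5′→3′ on the mRNA.

Each of the 11 pairs is classified Watson–Crick (A:U, U:A, G:C, C:G),
wobble (G:U, U:G), or mismatch. Centered classes are assigned by
precedence — WC 0MM > GU 0MM > WC 1MM > GU 1MM — so classes are
mutually exclusive, which the downstream 2×2 and regression analyses
require. Defaults: unlimited wobbles qualify a site for the GU
classes (a `max_gu` cap is available), at most one mismatch
(`max_mm`), and the mismatch must lie at an *interior* window position
(2–10). The interior-only rule is our reading of "one mismatch in the
middle of the site": a mismatch at a terminal window position would
simply be a shorter duplex, not a centered site with an internal
defect. Both the cap and the interior rule are parameters.

**Merging.** A single duplex can be hit by up to three window starts
and several adjacent positions. Overlapping raw hits are chained and
each chain reports one site — the most stringent class in the chain,
ties broken by smallest start — so covariates count duplexes, not
window hits. Raw unmerged hits are available (`merge=False`).

**Regions.** Transcripts carry a 5′UTR/CDS/3′UTR partition
(0-based half-open offsets). A site belongs to exactly one region,
decided by its midpoint, so per-class region counts always sum to the
class total. Site **density** is sites per kilobase of region; a
zero-length region has density 0 and is flagged. The canonical
transcript of a gene is the longest (ties broken by id).

The scanner is vectorized (per-position pair-class table lookups); the
test suite holds it equal to an independent per-position brute-force
enumeration on random transcripts, and to closed constructions for
every class.

## Enrichment calling

Replicate pull-down and control arrays are filtered to probes detected
(detection *p* < 0.01) in **every** control sample, log2-transformed,
and quantile-normalized (within-sample ranks preserved, ties broken by
row order; every sample shares the column-mean sorted vector
afterwards). This deliberately replaces the variance-stabilizing
transform + robust spline stack used with Illumina arrays: it is
deterministic, dependency-free, and adequate for synthetic data — so
probe counts from any specific array study are not comparison targets.

Differential abundance uses an empirical-Bayes moderated *t*. With
per-probe pooled variance s² on d degrees of freedom and the
hierarchical model s² ~ s₀²·F(d, d₀), the prior (d₀, s₀²) is fitted by
moment matching on log s²: Var[log s²] = ψ′(d/2) + ψ′(d₀/2) is solved
for d₀ by bracketed root finding on the trigamma function, and the
mean relation gives s₀². When the observed spread of log s² does not
exceed the sampling noise ψ′(d/2), the prior degrees of freedom are
infinite (full shrinkage, a z-statistic with variance s₀²); if the
inversion fails numerically the caller falls back to the ordinary *t*
with a warning. The posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀ + d), the statistic
t = logFC / (s̃·√(1/n₁+1/n₂)) on d₀ + d degrees of freedom, and the
one-sided upper-tail *p* tests enrichment in the pull-down only.
Benjamini–Hochberg q-values (step-up, stable tie order) at q ≤ 0.05
define enriched probes. Target transcripts are the exact matches of
enriched probes; transcripts also matched by a retained non-enriched
probe are *ambiguous* and excluded by default.

## Association statistics

`fisher_exact_upper` conditions on the margins of the 2×2 table and
reports P[X ≥ w] from the hypergeometric distribution. The odds ratio
is the sample cross-product (w/x)/(y/z) with the Haldane–Anscombe
+0.5 correction when any cell is empty (flagged), and the 95% CI is
the Woolf logit interval. This is a deliberate simplification of the
conditional-MLE odds ratio printed by some statistical packages; the
p-value is exact either way, but printed ORs from analyses using the
conditional MLE will differ slightly.

The logistic regression of enrichment status on site counts (or
densities) is fitted by iteratively reweighted least squares with Wald
standard errors from the observed information; zero-variance
covariates are dropped and recorded, complete separation raises an
error naming the separating covariate, and the intercept-only model
provides L₀ for the Nagelkerke pseudo-r²
r²_N = (1 − e^{2(L₀−L₁)/n}) / (1 − e^{2L₀/n}). All three regions are
available as covariates and the region subset is a parameter. The fit
is cross-checked against an independent GLM implementation in the
tests. The one-sided KS shift test uses the asymptotic two-sample
statistic by default (the alternative that the in-set fold-changes are
stochastically greater); the exact small-sample computation is behind
a flag because its p-values are discrete and conservative at small n.
No multiplicity correction is applied across the many Fisher tests by
default (raw p-values are reported); BH is available.

## AGO-peak offsets

Peaks are sequence windows with a known center. Sites found inside a
peak contribute the signed offset of their **midpoint** from the
center (the midpoint is symmetric for 7/8/11-mers, unlike the 5′ end);
offsets beyond ±half-window (default 200 nt, parameterized) are
discarded. Concentration at the center is summarized by the
population-moment excess kurtosis g₂ = m₄/m₂² − 3 (defined for ≥4
offsets with positive variance); closed forms anchor the tests
(symmetric two-point −2, uniform −1.2, normal 0). Site presence in
differential vs unchanged peaks is tested with the upper-tailed exact
test.

## Synthetic study generator

The generator emulates the inputs of a biotin pull-down study and
writes machine-readable truth. All randomness flows from one master
seed through named substreams (`SeedSequence` spawn keys derived from
operation labels), so each stage reproduces independently of the
others and the whole pipeline is bitwise deterministic per seed.

**Transcriptome.** Region lengths are log-normal per region
(defaults: 5′UTR e^N(5.0, 0.7²) ≈ 150 nt median, CDS e^N(7.0, 0.5²) ≈
1100 nt, 3′UTR e^N(6.5, 0.8²) ≈ 660 nt — typical of human mRNAs),
clipped at minima (20/90/60 nt); bases are i.i.d. with composition
A/C/G/U = 0.27/0.23/0.24/0.26 (≈47% GC). A fraction (0.2) of genes
carries a second, 3′UTR-truncated isoform so the canonical-transcript
rule is exercised.

**Planting.** Sites of each class are written into a chosen region at
configured per-transcript rates, at uniform positions. Construction is
exact — e.g. a GU 1MM site receives ≥1 wobble conversion and exactly
one interior mismatch — and every plant is **post-verified with the
scanner**: if the realized merged class or position differs from the
request (for example, an overlapping window accidentally upgrades the
class), the bases are reverted and the plant is re-drawn. Truth
records therefore hold scanner-confirmed coordinates, and recovery
checks are exact. Background sequence also contains sites by chance —
notably GU 1MM centered sites, whose per-window match probability is
high enough that most kilobase-scale transcripts carry one, exactly as
imperfect centered sites are ubiquitous in real transcriptomes — so
enrichment truth is always computed from *scanned* counts, not from
planting records alone.

**Pull-down expression.** The deterministic log2 shift of transcript
*i* is Δᵢ = β₀ + Σ β₍a,b₎·x₍a,b,i₎ with scanned counts x, default
β₀ = −1.2 and positive per-class effects ordered seed > centered and
3′UTR > CDS (0.2–1.2 log2 units per site). True enrichment status is
Δᵢ > 0. Pull-down samples add the *rectified* shift max(0, Δᵢ) plus
N(0, 0.3²) replicate noise to a shared N(7, 1²) baseline; controls add
noise only. The rectification is deliberate: a pull-down enriches
bound transcripts and leaves unbound ones unchanged — it does not
deplete them — and adding negative shifts to most of the array would
make quantile normalization recenter the samples and turn
"less-depleted" null probes into false positives. With rectification,
null probes are exchangeable between groups and the q ≤ 0.05 calls
control the false-discovery proportion (verified over hundreds of
simulated experiments). Replicates default to 3 + 3; detection
p-values are emitted with a 2% undetected fraction so the detection
filter does real work. The generative shift is linear rather than
logistic, so the logistic fit estimates a monotone transform of the
planted effects; analyses of the study therefore check signs and
orderings of coefficients, while exact coefficient recovery is
checked separately with status drawn from the logistic model itself
(`simulate_logistic_status`).

**Peaks.** Peak sequences are 2·half-window + 1 nt of background with
the center at the midpoint. A differential fraction (default 0.05 of
2,000 peaks) receives a planted site at a Gaussian offset from the
center (s.d. 15 nt, required < half-window); unchanged peaks receive
sites at a background rate (0.1) at uniform offsets. Because
accidental GU 1MM sites arise uniformly across all peaks, the
offset-kurtosis summary is most informative restricted to differential
peaks — there planted, center-concentrated sites dominate and g₂ is
strongly positive, mirroring the centering of sites in
miRNA-dependent AGO peaks.

## Problem sizes and numerical choices

- Default study scale is 5,000 transcripts; the acceptance script runs
  a 2,000-transcript study and 100 calibration experiments of 1,000
  probes, the package's desk-scale configuration.
- Logistic parameter-recovery studies scan one 5,000-transcript
  covariate table and redraw Bernoulli status per replicate: the
  covariates are ancillary to the coefficient estimand, so re-growing
  the transcriptome each replicate would add cost without information.
- IRLS converges on a step max-norm < 1e-10 (cap 100 iterations,
  non-convergence flagged); a ridge of 1e-12 stabilizes the solve;
  separation is declared when coefficients exceed 30 with residuals
  under 1e-6.
- BH ties are ordered stably by (p, probe id); quantile-normalization
  ties by row order. Floats are written with 6 significant digits,
  p/q-values in scientific notation, LF endings — writers are
  deterministic.
- Transcript coordinates are uniformly 0-based half-open; miRNA
  positions are the only 1-based quantity.

## What the synthetic data does and does not show

Passing tests demonstrate that the scanner is exactly equivalent to
its definition, that planted truth is recovered without class
upgrades, that the statistical machinery is calibrated (FDR,
Wald type-I rates, CI coverage) and directionally correct on data
generated under the package's own model. The generator does not
emulate microarray physics (probe affinities, saturation, background),
sequence composition beyond i.i.d. bases, isoform structure beyond a
truncated 3′UTR, or correlated expression noise; conclusions about any
specific biological dataset require that dataset. Published figures
derived from deposited array/CLIP data additionally depend on a
normalization stack this package intentionally simplifies, so those
printed values are not reproduction targets.

## Known limitations

- 3′-supplementary/compensatory sites, G-bulge sites, and seed-like
  sites with wobble are out of scope, as are thermodynamic or
  conservation scores.
- The exact-test OR/CI are sample-based (Haldane–Anscombe/Woolf), not
  conditional-MLE.
- The moderated-t prior assumes a common variance distribution across
  probes; heavy-tailed variance outliers would call for robust
  estimation, which is not implemented.
- `read_region_table` accepts transcript-space annotations only; no
  genome-coordinate GFF/GTF lifting.
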