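# Methods

## Scope and coordinates

The package analyzes windowed MeDIP-seq enrichment counts for a two-group
(mutant vs. wild-type) patient comparison. All coordinates are 0-based,
half-open, in every in-memory structure and every BED/TSV the package reads
or writes; 1-based inclusive ids (`chrom:start+1-end`) appear only in
human-readable output. The genome is tiled with fixed 250-bp windows; the
final window of a contig is truncated and kept (it is only ever removed by
the CpG-density filter, never by position).

## Quantification model

MeDIP read density confounds methylation with CpG density, library size
and background pull-down. The package's contract is deliberately explicit
and invertible:

    E[y_ws / lambda_s] = (E_s(g_w) - gamma_s) * beta_ws + gamma_s

- `lambda_s` — library scale, counts-per-million over **all** windows
  (simple and reproducible; any common rescaling of a sample's counts
  cancels out of beta and CNV estimates).
- `gamma_s` — background: mean normalized count over CpG-free autosomal
  windows. These windows cannot carry immunoprecipitation signal, so their
  depth estimates antibody-independent carry-over.
- `E_s(g)` — enrichment profile: expected normalized depth of a fully
  methylated window with `g` CpGs. Estimated from calibration windows
  (beta > 0.80 in >= 95% of a reference cohort, strict/inclusive exactly as
  written) by averaging within each exact CpG-count stratum and smoothing
  with weighted isotonic regression. Isotonic (PAVA) smoothing pools
  sparse, non-monotone strata with their neighbors automatically, which
  stabilizes the CGI tail without breaking the noise-free exactness of the
  round trip; `min_windows_per_bin` optionally forces adjacent strata to be
  merged to a minimum support (useful on noisy data, default off).
  Evaluation between tabulated strata interpolates linearly and clamps at
  the ends.
- `beta_ws` — the inversion, `clip((y/lambda - gamma) / (E(g) - gamma), 0, 1)`.

Two accuracy regimes matter. Per (window, sample), the negative-binomial
dispersion imposes a noise floor: sd(beta_hat) >= sqrt(phi) x (total
depth / enrichment signal), about 0.2 at phi = 0.05 **at any sequencing
depth**. Window-level methylation is therefore aggregated across samples;
for unbiased window means at fully (un)methylated windows, average the
*unclipped* per-sample estimates (`estimate_beta(clip=False)`) and clip the
mean — per-sample clipping would bias boundary windows inward by ~0.1.

Copy number uses only CpG-free windows (pure background, linear in copy
ratio): per sample, counts are summed per 2-Mb autosomal bin, divided by
the sample's total CpG-free count, and referenced as log2 against the
cross-sample median of the bin. Discrete gain/loss calls (|log2| > 0.4)
are advisory. A planted copy-ratio segment also shifts the carrier
sample's background estimate; this contamination is inherent to the design
(the assay cannot separate them) and is small when the segment is a small
fraction of the autosomes.

## Differential testing

Per analyzable window (>= 4 CpGs, autosomal), counts are modeled negative
binomial with mean `mu_ws = lambda_s (E_s(g_w) - gamma_s) beta +
lambda_s gamma_s` and variance `mu + phi_w mu^2`. The likelihood is
profiled over `beta in [0, 1]` by a vectorized golden-section search
(interval tolerance 1e-8, all windows simultaneously; terms independent of
`mu` cancel in the ratio and are dropped). The null shares one beta, the
alternative fits one per genotype; the LRT has 1 df. BH adjustment runs
over all tested windows; zero-count windows are skipped and excluded from
the BH family.

Dispersion: per-window method-of-moments around group-fitted means with an
n/(n - G) degrees-of-freedom correction, then empirical-Bayes shrinkage
toward the across-window median with weight `tau^2 / (tau^2 + v_w)`, where
`v_w ~ 2/(n - G) (1/mu_bar + phi_med)^2` approximates the estimator's
sampling variance and `tau^2` is the excess of the robust (MAD-based)
across-window variance over the mean `v_w`. When dispersions are
homogeneous the weight collapses to ~0 (pooled median), which keeps the
extreme tail of the null LRT calibrated — a fixed 50/50 shrinkage was
measured to inflate p < 1e-5 events ~3-fold and produce spurious BH calls;
genuine heterogeneity re-opens the weight.

Fold change is defined on pseudocount-stabilized group beta estimates,
`log2((beta_mut + 0.01) / (beta_wt + 0.01))`, so the |log2FC| >= 1 call
threshold is interpretable on the methylation scale. Call boundaries follow
the published wording exactly: FDR strictly `< 0.05`, fold change inclusive
`>= 1`. One DMR = one significant window; adjacent windows are not merged.
Genotype is the only model covariate; IGHV status is carried in metadata
for stratified reporting only.

Null behavior: the chi-squared(1) reference applies at interior
methylation. Windows whose true beta sits at 0 or 1 produce a boundary
mixture (approximately half a point mass at zero), so null-calibration
checks evaluate interior-beta windows; boundary windows only ever make the
test conservative there.

## Enrichment analyses

The enrichment unit is the window and the universe is the analyzable
(tested) window set. Each feature gives a 2x2 table (DMR status x >= 1-bp
feature overlap), a two-sided Fisher exact p, an odds ratio (ad/bc, +0.5 in
every cell when any cell is zero) and a BH q within its batch (genomic
features; TFs; chromatin states — one family per batch, matching per-panel
star annotations: * <0.05 through **** <0.0001). Promoters are TSS +/- 2 kb
(strand-free by symmetry); CGI shores are the 2-kb flanks minus any
CGI base; a distal CGI is any CGI outside promoters. Chromosomal density
compares observed DMRs per contig against expectations proportional to
analyzable windows (optionally CGI-overlapping windows); contigs with
expected < 1 are dropped and expectations renormalized. Subtelomeric
summaries count DMRs within 5/10/15 Mb of a contig end against the
background fraction with an exact binomial test. Enhancer DMRs link to
genes with expression FDR < 0.05 whose TSS lies within 1 Mb of the DMR
midpoint (no fold-change threshold). The PCA input is the top-1000
CGI-overlapping windows by across-sample beta variance, ties broken by
genomic order.

## Programming subtypes and decomposition

Sample assignment to the low/intermediate/high-programmed (LP/IP/HP)
subtypes uses per-locus methylation: the mean beta of 250-bp bins
overlapping a classifier locus by >= 145 bp (more than half a bin). Query
samples are clustered jointly with a labeled reference cohort (Euclidean
distance, complete linkage, raw beta values — no centering, a documented
open choice), the tree is cut at three clusters, each cluster takes the
majority label of its reference members, and queries in reference-free
clusters fall back to the nearest reference-subtype centroid, which
guarantees totality. Residual missing locus values are imputed with the
reference mean.

DMR decomposition: deltas are later-stage minus earlier-stage group means
among wild-type samples (IP - LP, HP - IP; developmental methylation gain
is positive). A DMR is `development_LP_IP` when |IP - LP| >= 0.20
(absolute beta difference, inclusive — "20%" read as 20 percentage
points), else `development_IP_HP` when evaluable and |HP - IP| >= 0.20,
else `stable` (mutation-specific). The mutant LP->IP delta is reported
alongside for contrast. External CpG catalogs overlap at >= 1 bp; a
hypomethylated DMR is concordant with an external site that gains
methylation during development (and vice versa).

## Validation assay

EpiTYPER-style CpG units are excluded when (i) fewer than 50% of samples
have a value (exactly 50% is kept), (ii) another unit of the same amplicon
has an identical fragment mass after rounding to 0.1 Da (all colliding
units drop; the tolerance is a package choice, none is published), or
(iii) the unit spans more than 3 CpGs. Region methylation is the
per-sample mean of retained units; concordance with the sequencing-based
estimates is a Pearson correlation over complete (region, sample) pairs.

## The synthetic cohort

The generator emulates the stated study design so the closed loop — its
generative model is the exact inverse of the quantification contract — is
the test surface:

- Genome: four 10-Mb autosomes plus a 5-Mb X; CpGs from an inhomogeneous
  point process (background 0.02/bp; ~2 CpG islands per Mb, 0.5–1.5 kb,
  0.12/bp), so the grid holds CpG-free, CpG-poor and island windows.
- Cohort: 14 wild-type / 13 mutant; subtype mixes (0.4, 0.3, 0.3) and
  (0.6, 0.4, 0.0) over (LP, IP, HP) via largest-remainder allocation — no
  mutant sample is high-programmed, as observed for this mutation.
- Methylation landscape: 60% of windows fully methylated (the bulk
  genome), 25% intermediate U(0.3, 0.7), 15% island-like U(0.02, 0.2).
  100 planted DMRs at baseline 0.5, hypomethylated by 0.3 in mutants; 30
  LP->IP and 10 IP->HP developmental windows shifting by 0.25; 18
  classifier loci (two adjacent windows each) at subtype baselines
  (0.15, 0.5, 0.85) with per-locus jitter.
- Counts: `mu = lambda_s c_ws (alpha_s f(g) beta + gamma)` with the
  saturating enrichment curve `f(g) = g/(g + 10)`, per-sample scale
  alpha ~ U(2, 3), background gamma = 0.3, libraries U(6, 9) million
  fragments, negative-binomial noise phi = 0.05 via gamma-Poisson; `c` is
  the local copy ratio (default: one hemizygous 4-Mb deletion in the first
  sample). `noise="none"` returns exact expectations for round-trip
  identities.
- Every CpG-count stratum present among analyzable windows is guaranteed
  one fully methylated window (`ensure_calibration_coverage`), so
  calibration support spans the analyzable range and the noise-free round
  trip is exact rather than interpolated.
- Validation data: per-DMR amplicons with 2–4 CpG units, Gaussian noise
  (sd 0.05) clipped to [0, 1], 10% missingness; `plant_qc_violations`
  plants exactly one unit per QC rule (the mass collision pairs with the
  4-CpG unit so three exclusions result).

What the generator does **not** emulate — and what a green test therefore
does not establish: mappability and GC bias, fragment-length variation,
correlated methylation along the genome, subclonal heterogeneity, batch
effects, and IGHV-linked global methylation structure. Cohort-scale
published numbers (e.g. the count of DMRs in the real patient set) depend
on non-deposited patient data and are not asserted anywhere.

## Numerical and statistical choices

- Golden-section likelihood maximization: fixed iteration count to an
  interval < 1e-8; beta reported as the bracket midpoint.
- The LRT is clipped at zero; p-values from `chi2.sf(LR, 1)`.
- BH is the textbook step-up (cross-checked against statsmodels in tests).
- Fisher p equals hypergeometric tail enumeration (checked to N = 1000).
- Degenerate inputs raise: empty layouts, zero-read samples, empty
  calibration sets, `E(g) <= gamma`, single-sample groups, fewer than 3
  samples for the CNV median, absent wild-type LP/IP strata.
- Determinism: every stochastic step draws from a substream of one
  top-level seed (`SeedSequence([seed, stage])`), so disabling one stage
  does not shift another's randomness and reruns are byte-identical.

## Known limitations

- Per-sample, per-window beta values carry the NB noise floor
  (~sqrt(phi)); single-window single-sample estimates should not be
  over-interpreted at realistic dispersions.
- The enrichment profile of the sparse CGI tail (strata with few
  calibration windows genome-wide) is proportionally noisier; the
  min-support merge bounds but does not eliminate this.
- A large copy-number segment shifts its carrier's background estimate and
  hence all of that sample's beta values slightly; no correction is
  attempted (the estimator matches the published behavior of reporting
  CNV separately).
- The 10-run average of per-seed false-discovery proportions under a
  complete null is granular (each run contributes 0 or 1): with the
  procedure exactly at its nominal 5% any-rejection rate (measured 2/40
  seeds), such an average exceeds 0.075 in ~40% of seed decades. The
  corresponding acceptance test reports the faithful measurement.
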