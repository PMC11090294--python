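# Methods

## The analysis problem

The package targets a single genomic region known to harbor a major
body-weight QTL in a chicken advanced intercross line (AIL) derived
from two lines divergently selected for 8-week body weight (BW8).
Within such a region a single additive scan is not enough: peaks may
reflect distinct haplotypes in incomplete LD, and loci may interact so
that their effects surface as *variance* heterogeneity rather than
mean shifts. The pipeline therefore layers five views over the same
cohort: mean-effect GWAS with conditional rescans, Brown-Forsythe
vGWAS, haplotype and ancestry-class association, NOIA epistasis
modelling with genotype-stratified scans, and an annotation/
conservation screen for candidate causal variants.

## Fixed-effect association model

Body weight is regressed per marker on an intercept, a binary sex
indicator, generation as an unordered factor (one level per
generation; a yearly batch is confounded with generation, so the
factor absorbs both), optional conditioning-marker allele counts, and
the tested marker's ALT-allele count. Degenerate factor levels (a
single sex or generation in the subset) are dropped rather than left
collinear. Inference is a two-sided t-test at the residual degrees of
freedom. Missingness is handled by case-wise deletion per marker; no
imputation is performed anywhere.

Scans residualize the phenotype and all complete genotype columns on
the shared covariate block (QR projection) and fit each marker as a
simple regression on the residuals — by the Frisch–Waugh theorem this
is numerically identical to the full per-marker OLS fit (verified to
1e-8 against a normal-equations oracle) and keeps a 2,000-marker x
3,000-sample scan under a second. Markers with missing calls fall back
to the explicit fit. Perfect fits report p = 0 with a `degenerate`
flag (so noise-free tests are expressible); collinear designs are
flagged `rank_deficient` with undefined effect; monomorphic markers
are skipped with a reason. Scans report raw p and -log10 p; a
Bonferroni line is provided for plotting but never filters output.

Stepwise selection alternates forward inclusion (best added-last p <
alpha_in = 0.05) and backward elimination (worst jointly-fitted p >
alpha_out = 0.05) with sex and generation always retained;
deterministic tie-breaks (smaller p, then lower marker position). An
AIC mode is available because p-value thresholds are a convention, not
the only defensible criterion. The reported ANOVA uses sequential
(type-I) sums of squares in the order sex, generation, markers in
selection order — one fitted model, one residual mean square, which is
also what makes the published table's rows mutually reconstructable.

Group summaries normalize BW8 within each (sex, generation) cell
(z-score, n-1 SD) and report per-genotype mean/SD/count with an LSD
compact-letter display: pooled within-group variance
sum((n_i-1) s_i^2)/sum(n_i-1), pairwise t with df = sum(n_i-1),
letters by the insert-and-absorb construction. Letter characters
follow input order; the induced partition is order-invariant.

## Brown-Forsythe vGWAS

Normalization happens once per cohort, before the scan. Per marker,
each genotype class's absolute deviations from its class median (even
classes: midpoint of the central order statistics) are compared by
one-way ANOVA; p from the F distribution. Classes below `min_class_n`
(default 10 — the F approximation degrades in tiny classes; the data
sources are silent on a floor) are dropped with the degrees of freedom
adjusted. All-zero deviations yield a degenerate flag with p = 1.
The implementation matches `scipy.stats.levene(center="median")` to
1e-10 and a 2,000-permutation null on small samples.

## Haplotype blocks and haplotype/ancestry association

Pairs are classified from unphased-equivalent two-locus genotype
counts: the likelihood of the 3x3 table (double heterozygotes
contribute both phase configurations) is evaluated on a 201-point grid
of |D'| at the MLE allele frequencies and the better-supported sign of
D; the central 90% of the normalized likelihood gives the CI. Strong
LD: lower >= 0.70 and upper >= 0.98; strong recombination: upper <
0.90. Candidate spans of consecutive eligible markers (MAF >= 0.05)
are accepted longest-first when >= 95% of informative pairs are
strong; accepted blocks never overlap, so blocks partition a subset of
markers. Thresholds are exposed because "default settings" of block
finders differ across toolkits.

Haplotypes within a block are read from phase (statistical phasing is
out of scope; the simulator provides truth phase and real data is
expected pre-phased), ranked by frequency, labeled H1, H2, ..., with
haplotypes rarer than 1% pooled into OTHER. Association replaces the
marker term with dosage columns of each non-reference label and tests
them jointly by F; collinear label columns are pooled with a flag.
With single-marker blocks this reproduces the marker scan exactly
(t^2 = F), a useful end-to-end identity. Ancestry association is the
same model with donor-breed dosages taken from an external painting
table; a sample enters only when both haplotypes carry one donor label
across the whole segment.

## NOIA

The statistical NOIA parameterization is used with *observed* sample
genotype frequencies, which makes in-sample orthogonality exact: the
additive column is x_a(g) = g - (p12 + 2 p22) and the dominance column
(-2 p12 p22, 4 p11 p22, -2 p11 p12)/(p11 + p22 - (p11 - p22)^2),
satisfying the three frequency-weighted orthogonality identities to
1e-12. Consequences used as invariants: the intercept equals the
reference point R (the frequency-weighted mean genotype value, equal
to the sample mean of the fitted phenotype), dropping the dominance
column leaves the additive estimate unchanged, and at Hardy-Weinberg
frequencies the additive effect equals the textbook average
allele-substitution effect.

Multi-locus fits include all per-locus a/d columns and, at order 2,
all pairwise aa/ad/da/dd Kronecker products (ad = a of the first-named
locus x d of the second). Two-locus frequencies enter as the product
of marginals — a linkage-equilibrium reference; deviation shows up as
non-orthogonality between interaction columns and is reported through
flags rather than corrected. Columns made collinear by empty joint
genotype cells are detected by pivoted QR and flagged inestimable.
Interaction significance uses per-coefficient t-tests; a Bonferroni
column is emitted alongside but does not filter.

Conditional scans stratify the cohort by genotype at a conditioning
marker (strata under 10 samples omitted) and re-run the scan within
each stratum on the pre-normalized phenotype (intercept + marker
model); a `refit_covariates` option refits sex/generation within
strata instead, for cohorts where normalization is in doubt. The
two-locus 3x3 grid of (mean, SD, count) against a focal marker
accompanies the scan.

## Prioritization

The conservation threshold is the nearest-rank top-q value (default
q = 0.05) over a configurable score universe — the analyzed region's
markers by default, a genome-wide score table when supplied, since
either universe is defensible. Candidates must additionally exceed a
MAF floor (default 0.1, computed from cohort genotypes when
available, not annotation-file frequencies) and are ordered by
association p with position as tie-break. The missense table applies
the same conservation cut to `missense_variant` rows only.

## The synthetic AIL generator

The generator emulates the *statistical structure* of a
bidirectional-selection intercross, not any particular dataset: two
founder lines with divergent per-marker ALT frequencies (defaults 0.9
vs 0.1, standing in for 40 generations of divergent selection), an F1
formed from HIGH x LOW pairs, and intercross generations bred by
random non-full-sib mating. Meiosis uses Haldane's map function
(independent Bernoulli crossovers per interval, no interference) — the
simplest defensible model when no interference estimate exists.
Defaults: 2 x 20 founders, F1 of 80, generations F2-F18 of 176 each
(~3,000 phenotyped birds), 2,000 markers evenly spaced on one 100-cM
chromosome. Phenotypes follow

    bw8 = intercept + sex_effect*1[M] + generation_effect
          + sum additive*count + sum dominance*1[het]
          + epistatic grid lookups + eps,
    eps ~ N(0, residual_sd * prod vqtl multipliers)

with defaults intercept 900 g, male effect +120 g, residual SD 150 g —
plausible magnitudes for an 8-week intercross cohort — and a small
linear generation trend so the generation covariate is non-degenerate.
Founders and F1 are unphenotyped, as in a design where only intercross
birds are measured. Epistasis is specified as explicit 3x3
genotype-value grids (the most general form; NOIA effects are then
derivable ground truth) and vQTL loci as per-genotype residual-SD
multipliers.

What the generator does **not** emulate: sequencing noise, coverage,
imputation error, genotyping error, selection within the AIL, crossover
interference, and polygenic background beyond the explicit
architecture. Tests passing on this generator therefore demonstrate
the statistical machinery under a clean intercross; they do not certify
behavior under imputation artifacts or pervasive background signal.

## Simulation studies and problem sizes

The standard studies (in `ailqtl.studies`) use sizes chosen as the
package's own balance of precision and runtime: type-I-error
calibration on the full default panel (2,000 markers, ~3,000 birds),
pooled over 40 independent replicates because long-range admixture LD
leaves only a few dozen effectively independent tests per replicate,
making single-replicate rejection fractions noisy; ±2·se coverage with 500
replicates (additive, n = 800), 300 replicates (NOIA a/d/aa,
n = 3,000) and 400 replicates (haplotype effect, n = 600); vQTL power
with 200 replicates of a 500-marker, 0.2-cM-spacing panel at the full
cohort size, with SD multipliers (1, 1, 2) and success defined as the
causal marker ranking top of the panel; masking epistasis as a -40 g
per-ALT-allele focal effect silenced in hub ALT homozygotes; and an
ancestral-haplotype contrast of +26 g vs -3 g donors against a neutral
background donor.

## Numerical choices and edge cases

OLS via `numpy.linalg.lstsq`/QR; rank decisions at a relative 1e-9
diagonal tolerance; residualized columns with squared norm below
1e-6·n are treated as collinear. Zero-residual fits are flagged rather
than erroring. Medians of even-sized groups are midpoints. D' CIs
clamp haplotype frequencies at 1e-12 before taking logs. The
VCF reader keeps only biallelic SNPs (skips counted), codes genotypes
as ALT counts without frequency re-polarization, and retains phase
only when every genotype in the file is phased. All coordinates are
1-based VCF conventions.

## Known limitations

No mixed-model/kinship correction (fixed-effects OLS by design, which
is anti-conservative under strong structure not captured by
generation); no statistical phasing; no third-order epistasis; no BCF
or structural-variant support; the D' CI grid resolution (201 points)
limits CI granularity to 0.005; ancestry painting must be computed
externally.
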