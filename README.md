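# ailqtl

Dissection of a polygenic QTL region in an advanced intercross line
(AIL): single-marker and conditional GWAS, variance-heterogeneity GWAS
(vGWAS), haplotype-block and ancestry-class association, NOIA
orthogonal epistasis modelling, genotype-stratified epistasis scans,
and conservation/annotation-based candidate prioritization — together
with a synthetic AIL generator that emulates a bidirectional-selection
chicken cross (divergent HIGH/LOW founder lines, intercross
generations F2 onward, ~3,000 phenotyped birds, 8-week body weight in
grams).

It is written for quantitative geneticists who want to go beyond a
single additive scan of a region: to ask whether two peaks are
independent, whether a locus shapes the *variance* of the trait rather
than its mean, and whether loci interact.

## Models

**GWAS** — ordinary least squares per marker *j*:

    y = 1 mu + S beta_S + g beta_g + A_j a_j + eps

with *y* body weight, *S* a sex indicator, *g* generation as an
unordered factor, and *A_j* the count of VCF ALT alleles (0/1/2).
Conditional scans add other markers' allele counts as covariates.

**vGWAS** — Brown-Forsythe test on phenotypes normalized within each
sex-generation cell: per genotype class *j* with median *phi_j*, the
absolute deviations

    y*_ij = | y_ij - phi_j |

are compared across classes by one-way ANOVA; a large F flags a vQTL.

**Haplotype association** — the marker term is replaced by dosages
(0/1/2 copies) of block haplotypes, `y = 1 mu + S beta_S + g beta_g +
H_j h_j + eps`, tested jointly by F-test. Blocks come from the D'
confidence-interval rule (strong-LD pair: 90% CI lower bound >= 0.70
and upper >= 0.98; a span is a block when >= 95% of informative pairs
are strong). The same model with donor-breed dosages gives the
ancestry-class association.

**NOIA** — per-locus additive/dominance design columns orthogonal
under the observed genotype frequencies (p11, p12, p22):

    x_a(g) = g - (p12 + 2 p22)
    x_d    = (-2 p12 p22, 4 p11 p22, -2 p11 p12) / (p11 + p22 - (p11 - p22)^2)

Two-locus designs are Kronecker combinations giving aa/ad/da/dd
interaction columns; the intercept is the reference point
R = p11 G11 + p12 G12 + p22 G22. Orthogonality makes the estimates
invariant to model reduction. Epistasis is also probed directly by
re-running the scan within each genotype stratum of a conditioning
marker.

**Prioritization** — candidates are markers with strong association,
minor-allele frequency above a floor (default 0.1) and a phyloP
conservation score in the top 5% (nearest-rank percentile), with
missense variants tabulated separately from snpEff `ANN` annotations.

## Worked example

`examples/03_variance_gwas.py` simulates a 300-marker AIL whose locus
`m00150` doubles the residual SD in ALT homozygotes but has no mean
effect, then runs both scans:

```
vGWAS top: m00150  F = 273.7  -log10 p = 109.2
  per-genotype medians: {0: 0.031, 1: -0.017, 2: -0.022}
same marker in the mean-effect scan: -log10 p = 0.42
```

The variance scan pins the simulated vQTL while the mean-effect scan
is null there — the signature that motivates scanning for variance
heterogeneity at all. The other examples cover simulation and export
(`01`), conditional GWAS (`02`), haplotype blocks and ancestry
association (`04`), NOIA interaction networks and genotype-stratified
scans (`05`), and candidate prioritization (`06`); each prints a short
interpretation of its numbers.

A thin CLI mirrors the library: `ailqtl simulate | gwas | vgwas |
hapassoc | noia | prioritize` (see `--help`).

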