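# Methods

`polygs` implements the genomic-selection evaluation workflow for conifer
progeny tests: a synthetic-data generator for polycross and partial-diallel
mating designs, SNP quality control and imputation, marker-based parentage
recovery, pedigree and genomic relationship matrices, REML fitting of the
individual-tree mixed model, family-stratified cross-validation, and
expected genetic gain per unit time.

## The model

All genetic analyses fit the individual-tree mixed model ("animal model")

    y = X b + Z1 a + Z2 sa + e,

where `b` holds the overall mean, breeding group (when the design has
groups), site, and block-within-site; `a ~ N(0, s2_a K)` is the additive
genetic effect with `K` either a pedigree numerator matrix **A** (tabular
method; "partial" = dams only, "full" = dams plus recovered sires) or the
VanRaden genomic matrix **G** = (M−2p)(M−2p)′ / (2Σ p q); `sa ~ N(0,
s2_sa I_s ⊗ K)` is the site-specific additive deviation; and `e ~ N(0,
s2_e I)`.  Because each tree grows on exactly one site, the Kronecker term
reduces at the observation level to `s2_sa · (K ∘ same-site)` — the
implementation exploits this equivalence.  An optional dominance term uses
the zero-mean genomic dominance matrix **D** (codes {0,1,2} →
{−2p², 2pq, −2q²}) or a realised-cross family factor.

Derived parameters: narrow-sense heritability `h² = s2_a/(s2_a+s2_sa+s2_e)`;
type-B (across-site additive) correlation `r_B = s2_a/(s2_a+s2_sa)`;
per-individual theoretical accuracy `r̂ = sqrt(1 − SE²/((1+F_i) s2_a))`
with `SE` the prediction-error standard error and `F_i` the kernel
diagonal minus one.  Standard errors of the variance ratios come from the
delta method with the inverse average-information matrix as the component
covariance.

## REML algorithm

Estimation maximises the restricted likelihood in the V-parametrisation
`V = Σ s2_k C_k + s2_e I` by average-information (AI) updates with step
halving and an EM fallback; each iteration costs one Cholesky of V plus
elementwise traces, so fits at n ≈ 1000 take roughly a second.
Convergence: |ΔlogL| < 1e−6 together with relative parameter change
< 1e−5, maximum 200 iterations.  Variances are floored at 1e−8 × the
phenotypic variance; a component pinned at the floor with a negative
score for two consecutive iterations is frozen there and flagged as a
boundary estimate, and a likelihood flat for ten consecutive iterations
ends the fit (boundary components can otherwise oscillate indefinitely).
Starting values split the phenotypic variance evenly; fits are
deterministic given the data.  For nested dominance comparisons the full
model is warm-started at the reduced optimum so the nested likelihood
ordering survives boundary cases.

One-df likelihood-ratio p-values for variance components are reported
from the plain chi-squared(1) reference.  Because the null value lies on
the boundary, the usual correction is a 50:50 mixture of chi²(0) and
chi²(1), which would halve the p-values; the plain version is
conservative and is what the calibration tests verify (empirical type-I
rate ≈ 2.5% at nominal 5%).

Breeding values for any kernel individual — phenotyped or not — are
`â = s2_a K[·,obs] P y`, with prediction-error variances from the same
projection; this is what lets cross-validation withhold a fold's
phenotypes while keeping its kernel rows.

## Parentage recovery

The pair LOD at each locus compares P(offspring genotype | candidate
parents) against P(offspring genotype | random parents at the observed
allele frequencies); genotyping error is modelled by mixing the Mendelian
transmission probability with a Hardy–Weinberg draw at the error rate
(applied to the offspring call).  Allele frequencies are floored at
1/(2N+1).  Maternal verification requires a positive single-parent LOD
and an opposite-homozygote mismatch fraction below 2.5%.  Paternity needs
the best candidate pair to beat the runner-up by a critical delta — the
smallest value at which, in a simulation of offspring under the stated
error rate and sampled-father fraction, the accepted set is ≥95% correct
— plus a positive sire LOD; exact ties are never assigned.  Offspring
with no accepted sire are clustered into putative paternal families on a
relatedness graph (edge when genomic relatedness, minus 0.25 for pairs
sharing a mother, exceeds 0.125 — halfway between unrelated and paternal
half-sib); this replaces full-pedigree sibship-likelihood reconstruction
and is validated against simulated truth.  Clusters below a configurable
minimum family size (default 7) are flagged as pollen contamination and
excluded from model fitting.

## Synthetic-data generator

The generator states a polycross world shaped like an operational spruce
program: 38 maternal parents crossed with a common 19-male polymix (three
parents used in both roles), ~23 offspring per mother over 3 sites × 4
blocks, 4092 unlinked SNPs with frequencies uniform on [0.01, 0.5],
genotyping error 0.1% and missingness 0.2%, and pollen contamination at
2.6%.  Paternal contributions follow one symmetric Dirichlet draw per
realisation (concentration 3 by default, giving max/min paternal family
ratios near the observed-order ~7–10); contaminant sires are foreign
Hardy–Weinberg genotypes, re-used across events with probability 0.2 so a
single foreign tree can appear in several maternal families.  The partial
diallel produces 54 full-sib crosses over 42 parents in 3 breeding
groups.

Traits default to the growth/wood-quality panel of a mature progeny trial
(height 941.4 cm CV 20.5%, DBH 132.4 mm CV 23.0%, volume 61.2 dm³ CV
58.2%, acoustic velocity 3.3 km/s CV 13.8%, wood density 374.1 kg/m³ CV
7.8%) with GBLUP-tier heritabilities 0.20–0.41 and type-B correlations
0.60–1.0.  Stem volume obeys the regional allometry `V = 0.0344 ·
DBH^1.8329 · H^1.1793` (dm³ from cm and m).

Additive values are calibrated on the base-population (founder) scale:
marker effects are i.i.d. normal with variance `s2_a/(2Σ p q)`, which
gives offspring covariance `s2_a · A_ij` in expectation for unlinked loci
— the reference a pedigree analysis estimates.  (An early design that
rescaled components to exact sample variance was discarded: it silently
re-references the variance to the realised, related sample and biases
pedigree REML.)  Site-specific deviations use independent effect vectors
per site, calibrated against `s2_sa`, which realises the target type-B
correlation.

The additive architecture has two tiers: a marker-tagged part (default
70% of `s2_a`, and of `s2_sa`) and an infinitesimal polygenic part
transmitted through the true pedigree (founder values plus Mendelian
sampling).  A SNP chip with one SNP per gene locus tags most but not all
genic variance; consequently GBLUP is slightly attenuated relative to a
correct full pedigree, reproducing the field observation that genomic
heritabilities sit at or below full-pedigree ones.  Setting
`marker_tagged_fraction = 1` gives the pure marker world used to validate
the REML estimator against its own model.

What a green test does NOT establish: markers are unlinked (no LD decay,
no linkage maps), sites differ only through shifted means and independent
additive deviations (no heteroscedasticity), error is genotype-frequency
noise rather than platform-specific clustering artifacts, and parental
genotypes carry no selection signature.  Quantities that depend on those
features of real data (e.g. LD-driven imputation accuracy) are exercised
only qualitatively.

## Cross-validation and gains

Ten-fold cross-validation stratifies folds within family (members dealt
round-robin after a seeded shuffle, so per-family fold counts differ by
at most one), repeats ten times, and pools predictions across folds
before correlating with adjusted phenotypes (fixed-effects-only OLS
residuals).  PACC = PA/√h² uses the GBLUP heritability for every
compared model, so model contrasts reflect PA only.  Training folds refit
REML variances by default; a re-use flag skips that (order-of-magnitude
cheaper, near-identical components) and is what the heavy test suites
use.  With few families, pooled PA under a zero-heritability null is
biased negative by roughly −1/(number of families) because adjusted
phenotypes share an estimated grand mean across folds; this is a property
of the estimator, not a defect.

Expected gain takes the top 5% of out-of-fold GEBVs (forward selection
without own phenotype), expresses their mean as a percentage of the raw
phenotypic mean, multiplies by PACC, and divides by years to deployment —
7 for a polycross scheme (2-year crossing) and 9 for a partial diallel
(4-year crossing), both configurable.  Diversity of the selected set is
summarised by the status number `Ns = 1/(2θ)` with θ the group coancestry
(mean pairwise kinship including self-pairs) from the full relationship
matrix.

## Numerical and design choices

* G is the plain VanRaden matrix with sample allele frequencies; a
  0.99·G + 0.01·I blend is available for consumers that must invert G
  itself, but the V-parametrised REML never does, and blending by default
  would break the exact GBLUP ≡ marker-ridge equivalence.
* Monomorphic SNPs are dropped from G/D with a log message; missing calls
  must be imputed first.
* The segregation filter uses an exact multinomial test of offspring
  genotype counts against Mendelian ratios per full-sib family (the table
  construction a generic "exact test" leaves open); families with fewer
  than two offspring are skipped.
* The kNN imputer ranks markers by squared allele-count correlation with
  the target marker and votes over the k nearest individuals on those l
  markers; ties break by marker index for determinism.  It is a
  simplification of LD-kNNi tuned for unlinked-marker simulations, where
  neighbour information comes from family structure rather than LD.
* The critical-delta estimator returns 0 when every simulated assignment
  already meets the confidence level (the unambiguous limit).
* Tie-breaks in top-fraction selection are by individual id.

## Known limitations

Single-trait REML only; no spatial residual structure; no multi-
generation selection; the paternal-skew mechanism produces only a ~7%
inflation of the partial-pedigree additive variance (the same order as
implied by realised polycross father counts), so single-dataset contrasts
between partial- and full-pedigree heritabilities are dominated by
sampling noise — the package's directional tests therefore average over
seeds, and the partial-vs-full heritability ordering is reported as the
weakly-identified comparison it is.
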