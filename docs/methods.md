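# Methods

`famgwas` implements a family-based association analysis for quantitative
neurodevelopmental-style traits in nuclear families (mostly child–mother–father
trios, a minority of duos and two-child families), with explicit modeling of
parent-of-origin effects (POEs). This note records the statistical model, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducibility.

## The association model

Only children contribute phenotypes; parents contribute genotypes. For a
family with `k` phenotyped children the trait vector is modeled as
multivariate normal,

    y ~ N(X b, Sigma),     Sigma = Ve*I + Vg*K + Va*Pi

with three variance components: environmental (`Ve`, i.i.d.), polygenic
(`Vg`, scaled by the kinship matrix `K`: 1 on the diagonal, 0.5 between full
siblings) and an additive major-locus component (`Va`, scaled by the expected
single-marker IBD-sharing matrix `Pi`). The mean model always contains an
intercept and a sex covariate (female = 0, male = 1; the direction of this
coefficient is a package convention, not a comparable quantity), optionally a
high-risk-status (HRS) covariate, plus the genotype term of the test mode:

| mode       | null model      | full model                | tested term            |
|------------|-----------------|---------------------------|------------------------|
| general    | covariates      | + dosage `X` (0/1/2)      | combined between/within child effect |
| paternal   | covariates      | + paternal count (0/1)    | paternally inherited allele |
| maternal   | covariates      | + maternal count (0/1)    | maternally inherited allele |
| difference | covariates + `X`| + maternal count          | `Xmat` given `X`       |

Each test is a 1-df likelihood-ratio test; `chi2 = 2 (ll_full − ll_null)`,
clamped at zero, with a one-sided upper-tail chi-square(1) p-value. The
"total" model is used throughout (genotype terms are plain fixed effects, not
decomposed into between/within components); it is the more powerful choice
when population stratification is controlled upstream. POE effect sizes are
always reported from the model that contains only the parental-origin term,
never alongside a child-dosage term. The difference mode exists to separate a
genuine POE from a child effect that merely *appears* in both single-parent
scans: significant POE associations whose difference test fails the corrected
threshold are filtered out. The same allele can pass with opposite signs in
the two parental scans — that is the configuration the difference test keeps.

The effect allele defaults to the minor allele in founders; dosages and origin
counts are re-oriented per marker accordingly.

### Identifiability and the collapsed model

With one phenotyped child per family, `Ve`, `Vg`, `Va` enter only through
their sum, so the model collapses to a single residual variance and the fit is
closed-form Gaussian ML — identical to an OLS likelihood-ratio test
(`chi2 = n log(RSS0/RSS1)`), which the test suite verifies against an
independent OLS oracle to 1e-6. Whenever at least one family contributes two
or more phenotyped probands, the full three-component likelihood is maximized
numerically: log-variance parameterization (non-negativity by construction),
mean parameters profiled out by GLS at every variance point, L-BFGS-B with a
fixed deterministic start (empirical trait variance split equally across the
three components), relative tolerance 1e-10, max 500 iterations, and a single
perturbed restart on non-convergence. The full model's optimization starts
from the null model's variance estimates, which together with GLS profiling
guarantees `ll_full >= ll_null` up to optimizer tolerance.

### Informative probands

A child enters the general test whenever its own call (and the trait and
covariates) are non-missing. For the POE tests a child is informative when

- rule (i): both parents genotyped, one parent homozygous or the parental
  genotypes differ, and the *tested* parent heterozygous; or
- rule (ii): the tested parent's genotype is missing but the other parent is
  homozygous, which pins down the missing parent's transmitted allele;

and in every case the tested parent's transmitted allele is determinate under
Mendelian logic (the triple-heterozygote configuration never is). Children
failing a mode's rules are excluded from that mode entirely, which is why the
proband count varies per marker and per mode. The difference test runs on the
maternal-informative proband set (its full model needs maternal counts). An
exhaustive truth table over all call configurations (including missing calls)
is checked against an independent rule interpreter in the tests.

### Single-marker sib-pair IBD

`Pi` off-diagonals are the exact conditional expectation of the proportion of
alleles a sib pair shares IBD given the four genotypes, under a uniform prior
over which parental copy each child inherited (0.5 when any needed genotype is
missing or the configuration is inconsistent). Note that a homozygous parent
is uninformative for *which copy* it transmitted, so e.g. father AB / mother
AA with sibs AA and AB gives paternal sharing 0, maternal sharing 0.5, total
0.25. This deterministic single-marker computation replaces multipoint IBD
estimation; with at most a handful of multi-child families it has negligible
influence on the tests.

## Quality control

Fixed cascade, in order: (1) Mendelian screen — per-child and per-marker
inconsistency rates over informative comparisons (child plus at least one
called parent), removal above 1%, then residual inconsistencies blanked for
the whole trio at that marker; each error is attributed to the child of the
comparison. (2) Marker QC — missingness > 5% (computed over individuals with
any genotype data, so entirely ungenotyped parents do not penalize markers),
founder exact Hardy–Weinberg test at p < 1e-6 (standard exact test, no mid-p),
founder MAF < 1%; one primary reason per removal, checked in that order.
(3) Heterozygosity outliers — individuals outside mean ± 3 SD (population SD)
of the per-individual heterozygosity rate; a degenerate zero SD removes
nobody. (4) Duplicate positions — one survivor per (chromosome, position):
first-listed when allele codes match, otherwise rs-prefixed IDs are
prioritized. Founder status follows PLINK semantics: an individual with no
resolvable parent row is a founder. The cascade is idempotent on clean data.

## Binary child-trend test

The high-risk status is a per-family binary label copied to children. The
genotype relative risk is multiplicative with the two-allele risk constrained
to the square of the one-allele risk (`R2 = R1**2`; never a free parameter).
The likelihood is retrospective on the child genotype under a rare-outcome
approximation: case genotypes follow HWE frequencies tilted by `R1**g`,
control genotypes follow the HWE frequencies themselves; ML is over `(q, R1)`
with the null fixing `R1 = 1`, and the LRT is referred to chi-square(1). This
deliberately omits mating-type stratification and parental risk/imprinting
parameters — it is a reduced model that preserves the trend constraint and
the LRT form. Controls can be required to have at least one genotyped parent
(`require_parent_for_controls`, default on), mirroring the design choice of
not using controls without parents. Markers monomorphic in the tested
children are flagged non-testable.

## Post-scan statistics

- SE reconstruction: `SE = sqrt(effect^2 / chi2)` (Wald-style; asymptotically
  equivalent to the LRT the engine actually runs).
- `PVE = 2 b^2 f(1-f) / [2 b^2 f(1-f) + SE^2 * 2N * f(1-f)]` with founder MAF
  `f` and proband count `N` (the MAF factors cancel; kept for fidelity to the
  reporting formula).
- Genomic inflation: median observed chi-square divided by the chi-square(1)
  median (computed, not hard-coded), over all tested markers of a scan.
- Four-criterion filter: (i) p <= 5e-8; (ii) POE rows need a difference-test
  p below 0.05/n_diff, with n_diff the realized number of post hoc tests in
  the current run; (iii) p <= 0.05/(markers x scans), recomputed from the
  actual scan dimensions; (iv) >= 30 children in the sample carry the minor
  allele — counted over all genotyped children, not informative probands.
  Tier A = (i)+(ii); tier B additionally (iii)+(iv). The filter is monotone
  in every threshold (property-tested).
- Report formatting: effect and SE to 3 decimals, chi-square to 2, p to one
  significant figure; full precision is kept internally.

## Synthetic data

The generator draws founder genotypes under HWE at uniform founder MAFs,
produces children by recorded Mendelian transmission (so the true parental
origin of every allele is known), and builds traits as

    y = sex_effect*sex + sum(causal terms) + c_fam + u + e

where `c_fam ~ N(0, Vg/2)` is shared within a family and `u ~ N(0, Vg/2)` is
child-specific — exact polygenic covariance `Vg*K` for nuclear families — and
`e ~ N(0, Ve)`. A causal marker may tag an unobserved QTL coupled at
haplotype level with configurable D' and QTL frequency; trait effects apply
to the QTL alleles, so the typed-marker association is diluted by r^2 exactly
as in a tagging design. Locus heritability is parameterized at the QTL:
`beta = sqrt(h2 / (2 q (1-q)))` with `Ve + Vg = 1 - h2` in power scenarios,
giving unit total variance.

Defaults were fixed once to mirror the cohort structure the analysis targets:
400 nuclear families; sibship 1 with probability 0.97 and 2 with 0.03 (about
3% of the families in such cohorts include a sibling); each parent entirely
ungenotyped with probability 0.15, which reproduces a roughly 70/25/5 split
of trios, duos and parentless children; 1% sporadic missing calls and missing
phenotypes; founder MAFs uniform on [0.01, 0.5]; standardized traits with
`Vg = 0.4`, `Ve = 0.6` (a moderate polygenic share typical of cognitive
scores) and a 0.1 SD sex effect; 60% of families labeled high-risk, matching
an oversampled high-risk design. HRS is a family-level label copied to
children and can optionally be driven by a designated marker with relative
risk `hrs_r1` for testing the trend model. Ungenotyped parents keep their
pedigree rows (all calls missing) so duo/trio structure survives the file
round trip.

Not emulated: linkage disequilibrium beyond one marker–QTL pair, genotyping
array error models, phenotype ascertainment, age structure, non-normal trait
distributions, and population stratification. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed model,
not robustness to those real-data features — in particular the normality
assumption of the variance-components likelihood is satisfied by construction
here, while real trait scores often deviate from it.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo bands
meaningful on a single CPU: null calibration and inflation on 2000 null
markers in 500 genotyped trios (99% binomial bands); maternal-effect recovery
as the mean over 200 replicates of 400 trios; the power scenario (480
one-child families, h2 = 0.1, q = 0.5, maximum D', alpha = 0.001) at 1000
replicates with a Clopper–Pearson 95% CI. Under the total-association model
this power computes to essentially 100%; published figures around 97% for the
same scenario refer to the orthogonal (within-family) model, whose
non-centrality is roughly half — the total model's advantage absent
stratification is expected, and the package reports the computed value with
its CI rather than adjusting the scenario.

## Known limitations

- The orthogonal (within-only) model, multipoint IBD, dominance/epistatic
  components and X-chromosome models are out of scope.
- The trend test's rare-outcome approximation misstates control genotype
  frequencies when the outcome is common *and* the genotype effect is strong;
  with ~60% high-risk families this matters only for effect-size
  interpretation, not for the null distribution of the LRT.
- The LRT's chi-square(1) reference is asymptotic; for markers whose
  informative-proband set is very small (rare alleles in POE modes) p-values
  are approximate. The minimum-carrier criterion (iv) exists precisely to
  de-prioritize such associations.
- Sex is the only built-in covariate besides HRS; arbitrary covariate columns
  in the phenotype table are accepted by the scan API but are the caller's
  responsibility to standardize.
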