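# Methods

This note records the statistical models, the synthetic-data generator, the
numerical choices, and the known limits of what the test suite demonstrates.

## The scientific design

A familial-longevity study enrolls families through a long-lived proband.
Probands, their siblings and the siblings'/probands' offspring constitute
the "longevity member" group; everyone related only by marriage (spouses in
either generation) is a married-in control.  The comparison of interest is
the *rate* of disease-associated risk alleles per genotyped allele slot
between the two groups.  Age is deliberately never adjusted for: by
construction of the design it is collinear with the longevity indicator.

## Risk-score panels

Panels are built from a GWAS-catalog-format association table (tab-separated
columns `SNPS`, `DISEASE/TRAIT`, `P-VALUE`, `STRONGEST SNP-RISK ALLELE`,
optional `ALLELES`):

1. keep records with p < 5×10⁻⁸ (strict inequality), a parseable risk
   allele (the `rsID-A` convention; `rsID-?` is retained but unusable), and
   at most two listed alleles;
2. deduplicate rsIDs within a disease group keeping the smallest p-value
   (the catalog lists one row per trait association, so a SNP can recur);
3. merge supplemental literature SNPs, catalog entries winning ties, with a
   hard error on contradictory risk alleles;
4. LD-prune: compute pairwise r² as the squared Pearson correlation of
   risk-allele dosages over pairwise-complete observations, and while any
   pair exceeds the threshold remove one member of the first violating pair
   in rsID order (which member is a seeded uniform choice).  Iterating to
   closure — rather than a single pass over pairs — is a deliberate choice:
   it makes "no remaining pair above threshold" a guaranteed, testable
   postcondition even for LD chains A–B–C.

Trait-to-disease-group assignment is a keyword table
(`famgrs.panel.DEFAULT_GROUP_KEYWORDS`), editable by the caller, covering
Alzheimer's disease, cardiovascular disease and stroke, type 2 diabetes,
and cancers.

Published-GRS subsets intersect a panel with an external SNP list carrying
per-SNP exclusion flags (no risk allele, ambiguous coding, multiple risk
alleles, poor imputation quality); every listed SNP receives a logged
disposition.

Every stage appends to a provenance log, so `kept + removed = input` is
verifiable at each step.

## Scores and offsets

GRS_i = Σ_j x_ij over non-missing hard-call dosages x_ij ∈ {0,1,2} oriented
to the risk allele (ALT count, or 2 − ALT count when the risk allele is the
REF allele; strand-ambiguous A/T and C/G SNPs are kept by default and can
be dropped by policy — synthetic data has known strand, real catalogs do
not).  Each record carries the offset log(2·n_i), n_i = number of called
panel SNPs.  Individuals with no called panel SNP have no defined rate and
are dropped with a warning.  Scores are unweighted by design: the question
concerns the absolute number of disease alleles, not their aggregate
predicted effect.

## Models

**Poisson GLMM (primary).**  Count ~ Poisson, log link, offset, Gaussian
random intercept per family.  Because the intercept is constant within a
family, the per-family likelihood depends only on S_f = Σ y_i,
B_f = Σ exp(x_iᵀβ + offset_i) and a constant, so the marginal likelihood is

  ℓ_f = log ∫ exp(C_f + S_f u − B_f e^u) φ(u; 0, σ²) du,

evaluated by adaptive Gauss–Hermite quadrature: the integrand's mode û_f is
found by a per-family Newton iteration (vectorised across families), the
nodes are centred and scaled by the local curvature, and 9 nodes are the
default (1 node = Laplace; the log-likelihood is stable to <10⁻⁸ between 9
and 25 nodes on test fixtures and matches a dense-grid trapezoid oracle to
~10⁻⁸).  The optimizer is L-BFGS-B over (β, σ) with σ bounded at zero (no
negative variance; at the boundary the model degrades continuously to the
GLM, which the implementation handles analytically below σ = 10⁻⁸).  A
failed line search near the boundary is polished by a derivative-free
Nelder–Mead pass.  Standard errors come from the observed information
(central-difference Hessian).  Inference for the longevity coefficient is
the likelihood-ratio test against the model without it, referred to χ²₁
(no boundary mixture correction is applied — the tested parameter is a
fixed effect, and the variance component is present in both models); the
Wald z and p are always reported alongside, since published tables mix the
two conventions.

**Poisson GLM.**  Same mean model without the random intercept
(statsmodels IRLS); included to show the anti-conservativeness of ignoring
family clustering, which the tests quantify (type-I error inflates well
above nominal once the intercept SD is large).

**GEE.**  Marginal Poisson model, exchangeable working correlation, robust
sandwich covariance (statsmodels).  On singleton clusters it reproduces the
GLM to machine precision; under clustering its Wald test is calibrated.

**Kinship LMM.**  The rate y_i = count_i/(2 n_i) treated as approximately
Gaussian with covariance σ²_g·2Φ + σ²_e·I, Φ the pedigree kinship matrix.
Fit by spectral-decomposition REML: eigendecompose the additive
relationship matrix 2Φ once, rotate, and profile the REML criterion over
the variance ratio δ = σ²_e/σ²_g (41-point log-grid then bounded Brent).
No installed Python package fits an LMM with an arbitrary kinship
covariance, so this component is implemented here; with Φ = I/2 it
reproduces OLS exactly, which anchors the implementation.  Its longevity
coefficient is on the rate (not log) scale, so no rate ratio is reported
for it.

**Analysis suite.**  For each disease group × stratum (generation one,
generation two, both) × model, a crude and an adjusted fit (sex within a
generation; sex + generation pooled) are produced in a publication-style
table.

## The synthetic cohort

The generator emulates the study's structure, not human genetics at large:

* **Pedigrees.**  583 families by default: one proband each, 804 siblings
  scattered multinomially (so generation-one blood members total 1387), 175
  married-in generation-one spouses (total G1 = 1562), 1861 offspring
  assigned to random blood parents, and generation-two spouses at a 0.40
  spouse fraction (1241; total G2 = 3102).  The published tables give the
  generation-one control composition but no generation-two breakdown; 0.40
  is a recorded assumption, configurable.  Parents of generation-one
  siblings are latent founders referenced in the parent columns but not
  sampled, the usual .fam convention; kinship and gene-dropping treat them
  as unrelated non-inbred founders.
* **Genotypes.**  Founder haplotypes are drawn per LD block from an
  equicorrelated Gaussian copula; one allele frequency per block, uniform
  on (0.1, 0.9), and the latent correlation is solved by tetrachoric
  inversion so the within-block dosage r² hits the configured target
  (blocks are independent).  Children receive one whole block per gamete —
  no recombination within a block, free recombination between blocks —
  which preserves block LD across generations while inducing the kinship
  correlation the models must absorb.  Missing calls are masked uniformly
  at random (default 1%).
* **Longevity effect.**  A rate ratio r < 1 is injected by binomial
  thinning: each risk allele carried by a longevity member is retained
  with probability r·exp(u_f), u_f ~ N(0, sd²) a shared family modulation
  (default sd = 0.01); r > 1 boosts empty allele slots using the empirical
  allele frequency, with a hard error if any per-slot rate would exceed 1.
  Controls are never modified, and r = 1 is an exact no-op — the family
  term modulates the injected effect, so with no effect there is nothing
  to thin.  With sd = 0 the member/control rate ratio is exactly r; with
  the default sd it holds to O(sd²).
* **What it does not emulate.**  Realistic human haplotype maps, imputation
  uncertainty, the X chromosome, genotyping batch effects, assortative
  mating, or disease phenotypes.  Passing tests therefore demonstrate that
  the *statistical machinery* behaves as specified under the study's
  sampling structure — not that any biological conclusion transfers to
  real cohorts.

The engineered demonstration catalog (`famgrs.demo`) additionally fixes the
LD structure so the whole filtering cascade has exact expected outcomes:
1143 significant risk-allele-annotated records of which 12 are multiallelic,
perfect-LD pairs forcing exactly 20/90/55/58 removals at r² > 0.8 (panels
93/239/155/431, total 918), moderate-LD pairs (r² ≈ 0.45) giving the
stricter 83/218/137/386 panels at r² > 0.2, and published lists reproducing
the 11→8, 18→14, 29→20 and 13→12 subsets.

## Power simulation

Counts are simulated directly from the fitted model's own data-generating
process on the emulated family structure: per family an intercept
N(log(2m·baseline_rate), sd²), per individual λ = exp(intercept + β·member),
GRS ~ Poisson(λ), then the Poisson GLMM is refit and the LRT evaluated at
α = 0.05 (two-sided).  A c% score difference means β = log(1 − c/100);
1% → log(0.99) = −0.0101.  Power is the rejection fraction over replicates
(default 100) with its Monte-Carlo standard error; non-converged replicates
are counted and excluded from the denominator.

The source study never states the simulated λ scale or the random-intercept
variance, so baseline_rate = 0.5 (λ = m, half of the 2m allele slots) and
intercept SD = 0.01 are this package's defaults, recorded as configuration.
Consequences: the saturated cells (large panels, pooled generations)
reproduce power 1.00 exactly, while mid-range cells are matched only
qualitatively — power rises with panel size and with sample size, which the
tests assert with Monte-Carlo slack — and a closed-form two-group Wald
power formula (Var(β̂) = 1/Σλ₁ + 1/Σλ₀) serves as the internal truth
standard at zero intercept SD.

## Reproducibility and problem sizes

All randomness flows from one root integer seed through a documented split
(`SeedSequence([seed, crc32(stage_name)])`), so every pipeline output is
byte-identical across reruns.  The test suite runs the full-size structure
(4664 individuals, 583 families) where the check concerns that structure —
the power saturation cell and the parameter-recovery check — and scaled-down
cohorts (≈150–1300 individuals) for calibration studies that need hundreds
of refits, e.g. the 500-replicate type-I-error check of the GLMM LRT; the
reduced sizes are the package's own choice of desk-scale fixtures and are
stated in the tests.  The GLMM implementation is cross-validated three
ways: a dense-grid integration oracle, the exact GLM limit at σ = 0, and
R's `lme4::glmer` on a small fixture.

## Known limitations

* Hard-call dosages only; fractional (imputed) dosages are out of scope.
* The LRT at the σ = 0 boundary uses the naive χ²₁ reference for the fixed
  effect; variance-component testing is not offered.
* LD pruning uses unphased-dosage r²; EM-based composite LD is not
  implemented.
* The kinship LMM assumes Gaussian rates, an approximation that degrades
  for small panels where counts are far from Gaussian.
* External-control substitution models the replacement cohort as singleton
  families drawn from the same allele-frequency spectrum; real external
  cohorts differ by platform, ancestry and era.
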