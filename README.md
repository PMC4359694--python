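# famgrs — family-based genetic risk score burden analysis

`famgrs` asks a question from the genetics of human longevity: do members of
families selected for exceptional longevity carry **fewer disease-associated
risk alleles** than the spouses who married into those families, or does
familial longevity rest on protective variants instead?  The package
implements the full analysis as a reusable, tested pipeline that runs
end-to-end on synthetic data emulating a two-generation family study
(583 families; 1562 generation-one participants of whom 175 are married-in
controls; 3102 generation-two participants).

## The model

For individual *i* and a disease-specific panel of *m* SNPs, the unweighted
genetic risk score is the count of risk alleles

&nbsp;&nbsp;&nbsp;&nbsp;GRS_i = Σ_{j=1..m} x_ij,&nbsp;&nbsp;x_ij ∈ {0, 1, 2},

summed over the SNPs with a genotype call.  Scores are compared between
longevity members (probands and their blood relatives) and married-in
controls with a Poisson log-linear rate model with a per-family random
intercept:

&nbsp;&nbsp;&nbsp;&nbsp;GRS_i | u_f ~ Poisson(μ_i),&nbsp;&nbsp;
log μ_i = log(2·n_i) + β₀ + β·longevity_i + γᵀz_i + u_f,&nbsp;&nbsp;
u_f ~ N(0, σ²),

where n_i is the number of successfully genotyped panel SNPs (so the offset
log(2·n_i) makes the model a rate of risk alleles per allele slot), z_i are
sex and generation adjustments, and exp(β) is the ratio of expected
risk-allele counts between groups — e.g. β = −0.01067 means members carry
100·(1 − e^β) = 1.06% fewer risk alleles than controls.  The mixed model is
fit by maximum likelihood with adaptive Gauss–Hermite quadrature and β is
tested by the likelihood-ratio test; GLM-ignoring-correlation, GEE with a
sandwich estimator, and a linear mixed model with kinship covariance
(σ²_g·2Φ + σ²_e·I, REML) are provided as robustness alternatives.

Around the model sit the supporting stages: GWAS-catalog-style panel
construction (p < 5×10⁻⁸, risk-allele-annotated, biallelic, iterative LD
pruning at r² > 0.8), a sensitivity battery (targeted SNP removal, stricter
r² > 0.2 pruning, published-GRS subsets, external-control substitution), and
a family-structured Monte-Carlo power study.

## Worked example

Simulate a cohort of 150 families, thin longevity members' risk alleles by
5% (rate ratio 0.95), score a 431-SNP panel, and fit the Poisson mixed
model:

```python
import pandas as pd
from famgrs import (CohortConfig, generate_pedigrees, generate_genotypes,
                    inject_longevity_effect, SNPPanel)
from famgrs.grs import compute_grs
from famgrs.models import prepare_model_frame, fit_poisson_glmm, rate_ratio_report

cfg = CohortConfig(
    n_families=150,
    g1_sibs_per_family={"kind": "multinomial_total", "total": 210},
    g1_spouses_total=120,
    g2_offspring_per_family={"kind": "multinomial_total", "total": 480},
    missing_rate=0.0,
    seed=31,
)
ped = generate_pedigrees(cfg)
gm = generate_genotypes(ped, 431, cfg)
gm = inject_longevity_effect(gm, ped, rate_ratio=0.95, family_intercept_sd=0.0, seed=77)
panel = SNPPanel("cancer", pd.DataFrame({"snp_id": gm.snps, "risk_allele": gm.risk_allele}))
fit = fit_poisson_glmm(prepare_model_frame(compute_grs(gm, panel), ped))
rr, pct = rate_ratio_report(fit.beta["longevity_member"])
```

This prints (via the obvious format calls):

```
n = 1280 individuals in 150 families
beta(longevity) = -0.04456  se = 0.00295
z = -15.12  LRT p = 2.16e-51
rate ratio = 0.956  percent fewer alleles = 4.36
```

The fitted rate ratio 0.956 recovers the injected 0.95 within sampling
error: members of longevity families carry about 4.4% fewer risk alleles
per genotyped allele slot than married-in controls, and the deficit is
overwhelmingly significant at this effect size — whereas at the 1% effect
the same design is underpowered in a single generation, which is exactly
what the power grid quantifies.

## Command line

The full pipeline (simulate → build-panels → score → fit → sensitivity →
power) runs from one YAML config and one root seed:

```sh
famgrs all --seed 7 --out run/          # everything, default full-scale cohort
famgrs power --seed 7 --out run/ --effect 1 --panel-size 431 --reps 100
```

Outputs are plain TSV/VCF/JSON files plus a `manifest.json` recording row
counts and derived stage seeds; reruns with the same seed are
byte-identical.

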