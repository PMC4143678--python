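# egvkit

Estimated genetic values (EGVs) and measured-genotype association in
extended human pedigrees — with a gene-drop simulator so the whole
pipeline is testable end to end without restricted family data.

## The problem

In livestock and crop breeding, an individual's *breeding value* — the
additive-genetic deviation of its phenotype from the population mean —
is routinely predicted by BLUP (best linear unbiased prediction) from
its own phenotype, its relatives' phenotypes, and a relationship
matrix.  The same idea applies to human family studies: replacing a
noisy phenotype (say, systolic blood pressure) by its estimated genetic
value strips much of the environmental variation and might push
causal variants from "suggestive" into "significant" in a genome-wide
association (GWA) scan.  `egvkit` implements that workflow for
quantitative traits in extended pedigrees and provides the simulation
machinery to measure, with a fully known causal architecture, what the
substitution buys in power and what it costs in false discoveries.

## The model

For phenotype vector `y` with fixed effects `X` (age, sex, leading
principal components of genotype), the polygenic model is

    y ~ N(X b, sigma_g^2 R + sigma_e^2 I)

where `R = 2 Phi` is a relatedness matrix: expected (pedigree) kinship,
or marker-based KING-robust kinship from common (`snp`) or all (`seq`)
variants, repaired to the nearest correlation matrix (Higham's
alternating projections) when indefinite.  The EGV is the BLUP of the
additive genetic effect,

    EGV = (I + R^-1 * lambda)^-1 (y - X b),    lambda = sigma_e^2 / sigma_g^2,

with prediction-error variance `E = sigma_g^2 R - sigma_g^2 R (R + lambda I)^-1 R`.

Association uses the measured-genotype (MGA) likelihood-ratio test: each
SNP enters as one additive fixed effect, the trait covariance is

    Omega = sigma_p^2 (2 Phi h^2 + I e^2 + E eps),   h^2 + e^2 + eps = 1,

all variance proportions are re-estimated under the null and the
alternative, and `LRT = 2 (ll_alt - ll_null) ~ chi^2(1)`.  Significant
SNPs are adjudicated against the known simulated causal genes: a hit is
a true positive iff its r² with a causal SNP of a gene on the same
chromosome reaches 0.2, giving an exact false-discovery rate.

## Worked example

```python
import numpy as np
from egvkit import (SimulationConfig, simulate_study, expected_relatedness,
                    KinshipEigen, fit_polygenic, residualize, compute_egv)

cfg = SimulationConfig(n_replicates=1)          # 20 families, ~850 people
study = simulate_study(cfg, seed=1)
eig = KinshipEigen.from_matrix(expected_relatedness(study.ped))

cov = study.covariates.reindex(study.ped.ids)
X = np.column_stack([np.ones(len(study.ped)), cov["age"],
                     (cov["sex"] == 2).astype(float)])
y = (study.pheno[study.pheno.replicate == 1]
     .set_index("id")["y"].reindex(study.ped.ids).to_numpy())

fit = fit_polygenic(y, X, eig)
egv = compute_egv(residualize(y, X, fit), eig, fit.sigma_g2, fit.sigma_e2)
```

prints, with the diagnostics shown in the example script:

```
n = 830, raw-trait h2 = 0.331 (sigma_g2 = 56.9, sigma_e2 = 114.8)
EGV h2 = 1.000  (lambda = 2.02)
corr(EGV, true genetic value) = 0.710
corr(raw residual, true genetic value) = 0.607
```

The simulated trait carries a designed heritability of ~0.39 (polygenic
0.2 plus five causal genes); a single replicate estimates 0.33.  The
EGV, being a shrinkage of the residual toward family-genetic structure,
is almost purely genetic (refit heritability at the upper boundary) and
tracks the true per-individual genetic values better than the raw
residuals do — the accuracy gain BLUP is designed to deliver.

## Command line

The same pipeline runs from a shell, one stage per subcommand, with a
YAML config and a hash-stamped manifest:

```bash
egvkit all --config cfg.yaml --out run/ --seed 17
# or stage by stage:
egvkit simulate --out run/ --seed 17
egvkit kinship --out run/
egvkit covariates --out run/
egvkit egv --out run/ --source all
egvkit scan --out run/
egvkit evaluate --out run/
```

`evaluate` writes `table1.csv` (per-method hit counts, MAF breakdown,
FDR, conditional FDR for hits absent from the raw-phenotype scan) and
`table2.csv` (per-gene detection counts across replicates).

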