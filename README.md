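# mirnorm

Integrated hierarchical Bayesian normalization, missing-data imputation and
differential-expression selection for left-censored miRNA microarray data —
plus the standard comparison arms (quantile normalization, a VSN-style
variance-stabilizing transform, no normalization, each followed by a
moderated t-test) and an AUC/AUPRC simulation benchmark.

## The problem

miRNA microarrays differ from mRNA arrays in two ways that break the
assumptions of standard normalization: a large fraction of probes can be
truly differentially expressed (often >15%), and a large fraction of
measurements fall below the instrument's detection limit (DL), producing
non-ignorable left-censored missingness. Normalizing, imputing and testing
sequentially propagates errors between the steps. `mirnorm` instead fits one
joint model by MCMC, so array-effect normalization, below-DL imputation and
feature selection inform each other.

## The model

For natural-log expression *y<sub>gcr</sub>* of gene *g* on replicate array
*r* of condition *c* ∈ {1, 2}:

```
y_g1r ~ N(α_g − δ_g/2 + β_g1r, σ²_g)
y_g2r ~ N(α_g + δ_g/2 + β_g2r, σ²_g)
β_gcr = a0_cr·α_g + a1_cr,   with mean_r a0_cr = mean_r a1_cr = 0 per condition
σ²_g  ~ logNormal(μ, η²)
δ_g   ~ ξ₁·δ₀ + ξ₂·N(μ₊, σ₊²)|₍₀,∞₎ + ξ₃·N(μ₋, σ₋²)|₍₋∞,₀₎
```

Array effects are gene-dependent (linear in α<sub>g</sub>) and constrained to
average out within each condition. The point mass at zero in the mixture
prior on the differential effect δ<sub>g</sub> corrects the winner's curse
(Beavis effect): effect sizes of genes that look significant by chance are
shrunk back toward zero, and genes are ranked by |posterior mean δ<sub>g</sub>|.
Cells below the array's detection limit L<sub>cr</sub> are treated as latent
values bounded above by L<sub>cr</sub> and resampled by truncated-normal data
augmentation inside the chain. All Normal(m, v) notation is mean/variance;
Gamma(a, b) is shape/rate on precisions.

A bespoke Metropolis-within-Gibbs sampler draws every parameter: exact
Gaussian conditionals for gene and array effects (the sum-to-zero constraints
imposed by exact Gaussian conditioning), marginalized closed-form component
weights for the (z, δ) mixture, random-walk Metropolis on log σ²<sub>g</sub>,
and conjugate updates for the hyperparameters.

## Worked example

```python
import numpy as np
from mirnorm import BayesianCensoredDE, SimulationConfig, simulate_dataset

# 300 genes, 5 replicate arrays per condition, 20% truly DE, 20% censored
data, truth = simulate_dataset(SimulationConfig(n_genes=300, sp=0.2, m=0.2, seed=0))
model = BayesianCensoredDE(n_iterations=4000, random_state=0).fit(data)
top = model.rank().head(3)
print(top[["gene_id", "score", "prob_de"]])
print("corr(truth, estimate):", round(np.corrcoef(truth.delta, model.delta_mean_)[0, 1], 3))
```

prints

```
  gene_id     score  prob_de
0    g100  1.223064   0.9985
1    g295  1.205981   0.9935
2     g71  1.201322   0.9985
```

and `corr(truth, estimate): 0.839`. `score` is the winner's-curse-corrected
effect size |posterior mean δ| (natural-log fold change; log 3 ≈ 1.1 is a
3-fold change), and `prob_de` is the posterior probability that the gene is
differentially expressed at all. Genes whose apparent effect is explainable
by chance get scores near zero even when their raw group difference is large.

The same workflows are available from the shell:

```bash
mirnorm simulate --sp 0.2 --m 0.2 --seed 0 --out sim/
mirnorm fit --matrix sim/matrix.tsv --samples sim/samples.tsv --seed 0 --out fit/
mirnorm normalize --matrix sim/matrix.tsv --samples sim/samples.tsv --method quantile --out qn/
mirnorm benchmark --sp-grid 0.2,0.4 --m-grid 0,0.2 --replicates 5 --iterations 4000 --seed 0 --out bench/
mirnorm evaluate --ranking fit/ranked.tsv --truth sim/truth_genes.tsv --out report.json
```

Matrices are tab-delimited (gene ids in the first column, censored cells
coded `NA`, natural-log scale declared in a header comment) with a sample
sheet giving each array's condition, replicate index and detection limit.

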