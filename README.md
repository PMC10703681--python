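# phenocomplete

Imputation of missing phenotypes in biobank-style datasets with a mixed-type
denoising autoencoder trained by **copy-masking**, together with the
evaluation, multiple-imputation and GWAS-adjacent utilities needed to use the
imputed phenotypes in genetic analysis.

## The problem

Population biobanks measure hundreds of phenotypes across hundreds of
thousands of individuals, but most entries are missing — questionnaires are
administered to subsets, invasive or expensive measurements are rare, and
whole blocks of columns vanish together for an individual. Filling in these
entries accurately increases the effective sample size of downstream
association studies. Two features make the problem hard: phenotypes are a mix
of continuous and binary traits, and the missingness is *structured* (whole
instruments missing jointly), so methods that assume entries are missing
uniformly at random misjudge both training and evaluation.

## The model

Let X̃ be the N×P phenotype matrix and M the observedness mask (M_ij = 1 iff
phenotype j is observed for individual i), with columns ordered so the first
C phenotypes are continuous (ordinal traits are treated as continuous). A
feed-forward autoencoder h maps a zero-filled row through leaky-rectified
hidden layers back to all P phenotypes:

    h⁽¹⁾ = Φ(W⁽¹⁾ X̃ᵢ,: + b⁽¹⁾),   Φ(x) = max(0, x) + l_Φ · min(0, x)
    h(X̃ᵢ,:) = ({h_j}_{j≤C}, {s(h_j)}_{j>C}),   s(x) = 1 / (1 + e⁻ˣ)

Training minimizes a joint reconstruction loss over every *originally
observed* cell — squared error for continuous, cross-entropy for binary —
while **copy-masking** hides inputs: with probability ρ a row's input mask is
ANDed with a mask row m̃ sampled from the data itself, so simulated
missingness reproduces the real block structure and the model learns to
reconstruct values it cannot see. The imputed matrix passes observed values
through verbatim:

    X̂ᵢ,: = Mᵢ,: · X̃ᵢ,: + (1 − Mᵢ,:) · h(X̃ᵢ,:)

Binary imputations are probabilities in [0, 1]. Accuracy on withheld cells is
measured as squared Pearson correlation r² (plus AUPR/AUROC for binary
phenotypes) with bootstrap standard errors; imputation-model uncertainty is
propagated by bootstrap multiple imputation (m models refit on resampled
individuals, each imputing the original data) pooled with Rubin's rule
T = W̄ + (1 + 1/m)B. Utilities cover the effective sample size
N_eff = N_obs + r²·N_imp, a variance-ratio imputation QC, exact binomial
sign-concordance tests and 1-Mb locus clumping.

The network is implemented in plain numpy (explicit backprop, SGD with
momentum, Kaiming-uniform initialization); at the package's intended desk
scale it trains in seconds on one CPU.

## Worked example

```python
import phenocomplete as pc
from phenocomplete import benchmarks as bm

# synthetic biobank: 5,000 individuals x 40 phenotypes (30 continuous,
# 10 binary), questionnaire-block missingness
ds = pc.generate(pc.SyntheticConfig(seed=7))
print(ds.data.observed_fraction)            # 0.642

train, _, test = pc.split_individuals(ds.data, 0.5, 0.0, seed=8)
em = pc.simulate_missingness_copy(test, 0.10, seed=9)
print(em.n_cells, em.achieved_fraction)     # 6425 0.1001

res = pc.fit(train, bm.desk_scale_config(seed=10))
completed = pc.impute(em.apply(test), res.params, res.spec, res.stats)
report = pc.evaluate_imputation(em, completed, test.schema, seed=11)
print(report.aggregates)
# mean_r2        0.2585   <- squared correlation, imputed vs withheld truth
# mean_r2_binary 0.2083   <- r2 restricted to binary phenotypes
# mean_aupr      0.5550   mean_auroc 0.7934
# mean_r2_se     0.0118   (50 bootstrap replicates)
```

The withheld 10% of observed test cells are simulated missing by copying
real missingness patterns; `mean_r2 = 0.2585` says the model recovers about a
quarter of the variance of those hidden values (the generator's noise-free
ceiling is 0.5).

A command-line interface wraps the same pipeline:

```bash
phenocomplete synth --n 5000 --seed 7 --outdir data/
phenocomplete fit --data data/masked.tsv --schema data/schema.json \
    --rho 0.8 --epochs 500 --seed 10 --out model.ckpt.npz
phenocomplete impute --data data/masked.tsv --schema data/schema.json \
    --model model.ckpt.npz --out imputed.tsv
phenocomplete mi --data data/masked.tsv --schema data/schema.json \
    --m 10 --seed 1 --outdir mi/
phenocomplete clump --in pooled.tsv --p 5e-8 --window 1000000
```

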