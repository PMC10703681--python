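# Methods

## Model

The imputation model is a feed-forward autoencoder over a fixed list of P
phenotypes per individual. Missing entries are zero-filled at the input after
encoding; hidden layers apply an affine map followed by the leaky rectifier
Φ(x) = max(0,x) + l_Φ·min(0,x) with l_Φ = 0.01 fixed (not learned); the
output layer is affine, with a sigmoid applied to the binary block (columns
C+1..P) so binary reconstructions are probabilities. One printed formulation
of the leaky rectifier elsewhere uses Φ(x) = max(0,x) − l_Φ·min(0,x), which
maps negative inputs to small *positive* values; we treat that as a sign
anomaly and default to the conventional LeakyReLU, but the variant is
available as `ModelSpec(printed_phi=True)` for exact comparison.

**Input encoding.** Continuous (and ordinal) phenotypes are z-scored with
training-split statistics; observed binary values are recoded −0.5/+0.5 at
the encoder input so the zero fill sits at the neutral point between classes.
Loss targets keep binary values on the 0/1 scale (cross-entropy) and
continuous values z-scored. Inside `fit` the normalization statistics are
computed on the sub-training rows only (validation rows excluded) — slightly
stricter than fitting on the full training half, and immaterial at these
sizes; the population (divide-by-N) standard deviation is used, recorded in
`NormalizationStats` for reproducibility.

**Architecture.** Default: a single hidden layer of width ceil(1.5·P) — the
one-hidden-layer feed-forward form written out above. We evaluated a deeper
default (hidden widths ceil(1.5P), ceil(0.7P)) and found it consistently
less accurate at desk scale (mean withheld-cell r² ≈ 0.19 vs ≈ 0.23 over
three seeds at the default benchmark) while the Bayes bound computed from
the true generative covariance is ≈ 0.35; with a few thousand training rows
the extra layer mostly adds optimization difficulty. Any depth/width can be
configured through `ModelSpec.hidden_widths`.

**Loss.** Joint reconstruction loss summed over all originally observed
cells: squared error on the continuous block, cross-entropy on the binary
block. Cells hidden from the input by copy-masking still contribute whenever
they were originally observed — the denoising objective. Sigmoid outputs are
clipped to [1e−12, 1−1e−12] so saturated activations remain strictly inside
(0,1) in float arithmetic.

**Optimization.** Minibatch SGD with momentum 0.9 and Kaiming-uniform
initialization sized for the leaky-rectifier gain. Gradients of the summed
loss are scaled by 1/(batch_rows·P) ("cell" scaling); this is the
normalization under which the reference learning rate 0.1 is stable —
scaling by 1/batch_rows alone (available as
`TrainConfig(gradient_scaling="row")`) requires a learning rate roughly P
times smaller and diverges at the defaults. The final short batch of an
epoch is used. A scheduler halves the learning rate after
`scheduler_patience` epochs without validation improvement; early stopping
is off by default (training runs to `max_epochs` with checkpointing).

**Checkpointing.** The validation objective is the joint loss on the
validation rows under a copy-mask drawn once before training (seed-frozen),
so the criterion matches the imputation task and is comparable across
epochs. Parameters are checkpointed whenever it improves; `fit` returns the
best checkpoint, and `FitResult.validation_bundle` allows the logged best
loss to be re-verified from the returned parameters.

**Training configurations.** `TrainConfig` defaults mirror the tuned
biobank-scale settings (learning rate 0.1, momentum 0.9, batch 2,048, up to
500 epochs, copy-mask probability ρ = 0.8, 20% validation split). Those
assume hundreds of thousands of rows; with a few thousand rows a 2,048-row
batch gives one SGD step per epoch and underfits badly. The benchmark suite
therefore uses `benchmarks.desk_scale_config`: batch 256, learning rate 0.3,
patience-30 halving, same ρ and epoch budget.

## Copy-masking

Copy-masking withholds observed entries by applying missingness patterns
sampled from other individuals' actual mask rows, preserving the
block structure of real missingness. It is used (a) as a training
augmentation — each row receives, with probability ρ, a pattern m̃ drawn
uniformly from the training split's mask rows (never test rows), the
effective input mask being Mᵢ AND m̃, one pattern per row per pass, fresh
draws each epoch — and (b) to simulate evaluation missingness: donor and
recipient rows are drawn uniformly with replacement and the recipient's
observed cells at the donor's missing positions are withheld, until the
withheld count first crosses target_fraction × (observed cells). The final
donor application is applied in full, so the achieved fraction can overshoot
by less than one pattern's worth and is always reported; draws that withhold
nothing count toward a futile-draw limit (100·N) before erroring. A uniform
baseline withholds cells drawn uniformly without replacement.

The uniform *training* ablation hides each cell of a selected row
independently with probability equal to the mean missingness of the pattern
source, so the two arms match in expected corruption and differ only in
structure.

## Evaluation

Primary metric: squared Pearson correlation between imputed and true values
at withheld cells, per phenotype — for binary phenotypes between the imputed
probability and the 0/1 truth — plus AUPR (step-wise precision-recall area)
and AUROC (Mann–Whitney concordance, ties half) for binary phenotypes.
Phenotypes with zero-variance truth or predictions in an evaluation have
undefined metrics; they are listed by name and excluded from aggregates,
which are unweighted means over phenotypes. Bootstrap uncertainty resamples
the withheld cells within each phenotype: 50 replicates for standard errors
and 100 for percentile 95% CIs by default (both configurable); the aggregate
SE averages per-phenotype replicate means sharing a replicate index. Method
comparisons use z = (m_a − m_b)/√(SE_a² + SE_b²) with a two-tailed normal
p-value (the SEs being bootstrap-derived) and a Bonferroni per-phenotype
threshold α/P.

For real data without withheld truth, the variance-ratio QC
Var(imputed portion)/Var(observed portion) flags over-shrunk imputations;
the recommended pass level is > 0.2.

## Multiple imputation and downstream utilities

`bootstrap_multiple_impute` refits the model m = 10 times, each on a
bootstrap resample of individuals with replicate-specific seeds
(master + r + 1, recorded in the manifest) driving initialization, shuffling
and copy-mask draws; each fitted model imputes the *original* data, so
observed cells are identical across imputations and only imputed cells vary.
Rubin's rule pools per-imputation estimates: Q̄ the mean estimate, W̄ the
mean squared SE, B the (m−1)-denominator variance of estimates,
T = W̄ + (1 + 1/m)B, SE = √T. The p-value uses a t reference with
df = (m−1)(1 + W̄/((1+1/m)B))², falling back to normal when B = 0 or m = 1
(`reference="normal"` forces the normal). Association tables pool per
variant with consistency checks on positions.

The effective sample size is N_eff = N_obs + r²·N_imp with the fold increase
(N_eff − N_obs)/N_obs. Sign concordance uses the exact two-sided binomial
test under p = 0.5 with the minimum-likelihood two-sided convention (equal
to twice the tail for this symmetric null). Locus clumping takes, per
chromosome, the most significant remaining variant below threshold and
discards significant variants within 1 Mb (inclusive; ties in p break toward
the smaller position), repeating until none remain.

## Synthetic data generator

The generator emulates the data regime the method targets, not any
particular cohort. Each individual carries k = 4 standard-normal latent
factors; phenotype j loads on them through a unit-norm vector scaled by
`loading_scale` (default 1), plus N(0, `noise_sd`²) noise (default 1), so
the per-column noise-free r² ceiling is 0.5. Binary phenotypes (10 of the
default P = 40) threshold a liability sharing the same factors at the
empirical quantile of their target prevalence (default 0.25), giving the
mixed loss cross-type structure to exploit. Missingness is the union of
questionnaire-block skips — 5 blocks of 8 columns; the first block never
missing (biobanks always carry complete demographics such as age and sex),
the rest skipped by 20–70% of individuals — and 2% cellwise MCAR.
`block_factor_share` optionally routes part of the signal variance through a
block-specific factor (items of one instrument co-varying beyond the shared
factors); it is 0 in the default configuration and 0.4 in the
psychiatric-style `questionnaire_config` (skips up to 95%), the hard regime
where whole instruments must be reconstructed from other blocks.

What the generator does **not** emulate: value-dependent (MNAR) skip
behaviour, nonlinear trait dependencies, measurement batch effects, and
biobank sample sizes. Passing benchmarks here demonstrates correct mechanics
and sensible recovery on linear-Gaussian structure at desk scale; absolute
accuracies on real cohorts depend on their dependence structure and
missingness rates.

## Benchmark protocol and problem sizes

The end-to-end protocol (`benchmarks.end_to_end_accuracy`) generates a
dataset, reserves 50% of individuals for testing, copy-simulates 10%
missingness on the test split, trains on the training split and scores the
withheld cells. The default benchmark runs at the generator's full
N = 5,000; the signal-strength monotonicity grid (loading_scale 0.6/1.0/1.5,
3 seeds) and the copy-vs-uniform ablation (5 seeds) run at N = 2,500, sizes
chosen to keep the full battery in the minutes range on one CPU. The
column-mean baseline fills withheld cells with the phenotype's observed
training mean; its within-phenotype r² is undefined (zero prediction
variance), i.e. zero recovered signal.

**Copy-mask vs uniform-mask training at desk scale.** With matched expected
corruption, uniform-mask training reproducibly edges out copy-mask training
on this generator at N ≈ 2,000–2,500 training rows (≈5–15% relative mean
r², across block designs, skip intensities, P up to 100 and budgets up to
2,000 epochs). Our reading: with few rows, the greater corruption
*diversity* of uniform masking acts as regularization that outweighs the
benefit of matching the evaluation-mask distribution, whereas at
biobank-scale row counts data diversity is abundant and the distribution
match dominates — consistent with the copy-mask probability being a
dataset-tuned quantity. The package reports both arms; the direction at
desk scale should not be extrapolated to large cohorts.

## Numerical choices and degenerate inputs

- Missing sentinels on read: empty field, "NA", "NaN" (case-insensitive);
  output writes "NA". Duplicate sample IDs are an error.
- Zero-variance or unobserved continuous training columns raise errors
  naming the column.
- `simulate_missingness_*` require a target fraction in (0,1) and at least
  one observed cell; fully observed pattern sources stall the copy loop and
  raise after the futile-draw limit.
- `joint_loss` validates binary predictions strictly inside (0,1) and
  binary targets in {0,1}.
- Training aborts with the epoch and last finite losses if the loss becomes
  non-finite.
- Checkpoint archives (npz with a JSON header) carry a format version.

## Known limitations

- The numpy implementation is single-threaded and CPU-bound; it is intended
  for datasets up to roughly 10⁵ rows × a few hundred columns, not for
  accelerator-scale work.
- Ordinal phenotypes are treated as continuous throughout (the schema
  retains the label so reports can flag them).
- The uniform-training ablation direction at desk scale differs from the
  large-cohort regime (see above).
- Association regressions themselves (covariates, genotype handling) are out
  of scope; the pooling utilities consume externally produced summary
  statistics.
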