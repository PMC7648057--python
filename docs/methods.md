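# Methods

## Models

### VAE

The encoder is a stack of tanh hidden layers (defaults 1000-1000 at full
scale over 978 landmark genes; 64-64 in the desk-scale examples) whose last
hidden layer feeds two affine heads: the posterior mean mu(x) and the
log-variance. The "covariance vector" Sigma(x) is a diagonal covariance,
parameterized as exp(logvar) so positivity holds by construction; logvar is
clipped to [-15, 15] purely for numerical safety (with the gradient zeroed
at the clip, which is never active in practice). The heads themselves are
affine — tanh is applied to hidden activations only — so the latent is
unbounded, as an N(0, I) prior requires.

The decoder mirrors the encoder; its final affine output passes through
tanh and is multiplied by `output_scale` (default 10), so reconstructions
lie strictly inside the z-score range. Because the data themselves are
produced by a tanh squash (see the generator below), this output map is
well matched to the data support and never saturates into point masses at
the boundary.

The objective is reconstruction + KL. The reconstruction term is the
**per-sample sum of squared errors averaged over the batch** (equivalently
per-element MSE times the gene count), which is the Gaussian-likelihood
ELBO scaling; the per-element MSE is logged alongside so both the per-gene
and per-sample readings of reconstruction error are available. Using the
bare per-element mean instead would underweight reconstruction by a factor
of the gene count against the dimension-summed KL and collapse the
posterior at desk scale. The KL term is the closed-form Gaussian
divergence summed over latent dimensions and averaged over the batch —
never estimated by sampling.

Training: Adam (beta1 = 0.9, beta2 = 0.999), seeded mini-batches, a
seeded random 9/10 train / 1/10 validation split (not stratified by
perturbagen; the split question is genuinely open and plain random was
chosen), full-scale defaults 300 epochs, batch 512, learning rate 1e-3.
Weights use uniform fan-in initialization U(±1/sqrt(n_in)) from a single
generator, so a run is reproducible bit-for-bit from one seed on one CPU
thread. Divergence (non-finite loss) aborts with a diagnostic rather than
continuing silently.

Representation extraction for all downstream analyses uses the
deterministic mu(x) at the top layer — reproducibility was preferred over
stochastic faithfulness; `vae_loss(..., sample=True)` exists where a
reparameterized draw is wanted. Decoder-layer representations are the
post-activation hidden values obtained by continuing the forward pass from
mu(x).

### S-VQ-VAE

One embedding per class: E in R^{Y x D}, label-indexed during training
(z_q = e_y) and nearest-neighbor-indexed at test time, with Euclidean ties
broken to the lowest index. The loss implements the five terms exactly as
written in the README, with stop-gradients placed so that

* the decoder receives gradient only from reconstruction,
* the encoder receives the straight-through copy of the reconstruction
  gradient plus the commitment and divergence gradients,
* codebook rows receive gradient only from the dictionary and
  misclass-dictionary terms.

The subtracted group's gamma scales only the commitment-like part (the
divergence loss); the misclass dictionary part is unscaled. The nearest
index k is recomputed for every batch element at every step.
`straight_through_check` verifies the whole contract against central
finite differences of a surrogate objective in which the stop-gradient
arguments and the quantization detour are frozen at the reference forward
pass; agreement is ~1e-9 on toy models, far inside the 1e-4 bound the test
asserts.

Codebook initialization is small uniform noise (scale 0.05) from the run
seed; `codebook_init="class_means"` initializes each code at the mean
initial encoding of its class instead. Across seeds neither dominates
(class-means helped in 3 of 5 replicates tried), so the simpler uniform
default stands.

The validation split is **stratified by class** so every code is evaluated
— a plain random split can drop a rare class from training entirely, which
is exactly the error case the trainer guards against. Full-scale defaults:
single hidden layer of 1000, D = 1000, 900 epochs, batch 256, learning
rate 1e-4, beta = 0.25, gamma = 0.1 (performance is robust to both
coefficients over [0, 1]).

Class-conditional generation decodes z ~ N(e_y, diag(sigma2_y)) where
sigma2_y is the diagonal sample variance of the class's training
encodings (no estimator was prescribed; the plain within-class variance is
the obvious choice). Unconditional generation first draws the class from
the training-set multinomial.

## Synthetic data generator

The generator emulates level-5 L1000 z-score matrices with known ground
truth. Per class c a latent centroid m_c ~ class_sep * N(0, I) is drawn in
an n_latent_true-dimensional space (defaults 10 latent dimensions, 100
genes, 8 classes, 250 samples per class); each sample is
W (m_c + eps) with a fixed random linear decoder W (entries
N(0, 1/sqrt(latent))), plus gene-space observation noise, then squashed by
center + half_range * tanh(pre / squash_scale) into [-10, 10]. The squash
is smooth, so no probability mass piles up at the clip bounds.
`noise_sd` (default 0.3) drives all three stochastic deviations — latent
scatter, observation noise, and the centroid offset of knockdown twins
(half noise_sd) — so noise_sd = 0 collapses each class to a single profile
and makes twins correlate exactly. class_sep = 3 with noise_sd = 0.3 gives
classes that are well separated but overlapping in gene space, a regime
where recovery is meaningful rather than trivial. Class priors are uniform
by default with a geometric-decay "skewed" option mimicking unevenly
populated classes.

What this emulates — and what it does not: real L1000 data have
heavy-tailed per-gene noise, batch and cell-line structure, dose/time
covariates, and classes that are not Gaussian in any latent space. Passing
the recovery tests here shows the algorithms are implemented correctly and
can recover planted low-dimensional class structure through a nonlinearity;
it does not certify performance on LINCS-scale data.

The drug-target benchmark gives a fraction of drug classes a knockdown
"twin" class whose centroid equals the drug's plus small noise, plus (by
default) 20 distractor knockdown classes with independent centroids. Truth
is the drug -> twin-gene table; retrieval should rank twin genes first and
must beat a rotated-truth control.

## Downstream analyses

**Signature nodes.** Per-node mean absolute activation over a reference
dataset is split into two groups by an exact 1-d 2-means (scan of all
sorted split points, globally optimal and deterministic — no restart
dependence); the high group is returned, with per-node variances attached
and both group means reported. Mean |activation| is the clustering
statistic and variance is reported because both readings of "high" are
defensible; on planted data they agree. A warning (not an error) fires
when the group means differ by less than 2x, since a unimodal statistic
makes the split arbitrary. The signature count is data-driven, not
hard-coded.

**Pattern-conditioned generation.** A class pattern is the mean signature-
node activation over the class's samples (computed only for classes with
at least `major_min` samples; 150 at full scale, 100 in the desk-scale
runs so all 8 synthetic classes qualify). Generation fixes the signature
positions to the pattern and draws the rest from N(0, 1), decodes, and
evaluates by exhaustive Euclidean nearest real neighbor. A sign-only probe
(pattern replaced by sign(pattern) * c) confirms the direction of each
node, not its precise value, carries the class identity.

**Mixing score protocol.** Generated and real samples (n_each each,
default 2000 full scale / 500 desk scale) are pooled, clustered with
scipy's average-linkage hierarchical clustering under 1 - Pearson
distance (the linkage is not prescribed anywhere authoritative; average
linkage is recorded in the output metadata), cut at k = 10, scored, and
repeated (50 repeats full scale / 10 desk scale) with the 2.5/97.5
percentiles across repeats as the interval. Constant profiles are
rejected explicitly since correlation distance is undefined for them.

**PCL graph.** Rows (codebook vectors or signature patterns) are compared
by Pearson correlation; each class's maximal-correlation partner
contributes one directed edge (partner -> class, weight = correlation), so
every node has exactly one incoming "nearest" edge and no self-loops.
Louvain (resolution 1, weighted, seeded) assigns communities and the
modularity of that partition is reported; a `randomized_restarts` option
keeps the best-modularity partition over multiple seeds.

**Classification harness.** Logistic regression (lbfgs) and a linear SVM,
10-fold stratified cross-validation, mean accuracy and Cohen's kappa per
representation type, with the frequency-weighted guessing baseline
sum_c (n_c/N)^2 attached. Classes with fewer samples than folds are merged
into a pooled label with a warning. Kappa is defined as 0 for constant
predictions.

**Drug-target retrieval.** For each drug-treated sample, Pearson
correlations against every knockdown sample's representation; a gene's
score is its best-correlated knockdown sample (a gene with several
knockdown samples is represented by its closest signature); genes are
ranked by decreasing score with ties broken lexically by symbol for
determinism. Per sample the best known-target rank is recorded; per drug,
top_rank = min and mean_rank = mean over samples (averaging is per-sample,
not per cell line). recall@n and hit@n pool all samples. Drug ids
differing only in case/whitespace are one perturbagen; drugs absent from
the truth table are skipped with a notice. Pearson invariance makes the
results unaffected by gene order or positive affine transforms of the
representations.

## Dataset assembly

"Major cell line" means strictly more than `major_cell_line_min` samples
(default 10000) of the relevant perturbagen type; "major PCL" means at
least `major_pcl_min` treated samples (default 150) — the strict/inclusive
asymmetry follows the definitions' wording ("over" vs "at least"). Roles:
SMP (small molecules, major cell lines), GP (knockdowns likewise), SMGP
(union minus the excluded outlier perturbagens — by default the proteasome
inhibitors bortezomib and MG-132, which form an outlier distribution in
merged sets), SMC (SMP with a PCL label), SMCNP (SMC minus excluded
perturbagens). Assembled datasets carry per-rule removal counts in their
provenance, and exclusion/threshold filters commute. Whether vehicle
controls belong in training sets is genuinely unsettled, so the assembly
spec exposes `include_controls` (default False) rather than hard-coding a
guess. Gene symbols are matched as exact strings; no alias resolution.

## Problem sizes and numerical choices

The shipped examples, tests and the acceptance script run at 100 genes,
8 classes x 250 samples, a 64-64-16 VAE trained 150 epochs, and a
64/D=32 S-VQ-VAE trained 200 epochs — sizes chosen so the whole suite
trains dozens of models in well under a minute while leaving every
recovery margin wide (reconstruction ~2% of data variance against a 10%
bound; mixing score ~0.59 against a 0.7 bound; codebook correlations
>0.9). The full-scale presets reproduce the 978-1000-1000-100 / 900-epoch
settings but need LINCS-scale data to be meaningful.

All float64. Determinism contract: every public entry point takes a seed;
derived seeds come from one generator stream; checkpoints are zip archives
of raw .npy payloads with fixed timestamps so identical runs are
byte-identical. Degenerate inputs fail loudly and specifically: constant
profiles (undefined correlation), empty filter results, unknown labels,
dimension mismatches, non-finite losses.

## Known limitations

* The networks are plain-numpy MLPs; no GPU, no KL annealing or warm-up,
  no importance-weighted bounds, single codebook only.
* The generator's linear-decoder-plus-tanh model matches the model family
  being fitted; recovery results are therefore a correctness check, not
  evidence about misspecified real data.
* Louvain on small graphs (8 nodes in the desk-scale runs) yields
  modularities that vary with the nearest-neighbor structure; the value is
  reported, not asserted against a constant.
* GCT support is the #1.2 text dialect; binary GCTX/HDF5 LINCS releases
  are out of scope, as are GEO download helpers and probe re-annotation.
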