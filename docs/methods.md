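# Methods

`agescreen` implements an in silico gene-perturbation screen for
nominating pro- and anti-aging gene candidates from single-cell RNA-seq.
The workflow is: discretize each cell's raw counts into expression-rank
tokens, train a binary cell-age classifier (mid-age 20–59 y vs old-age
60–100 y donors) on a donor-wise split, then for each gene compare the
classifier's predicted old-age probability under simulated knockout versus
strong overexpression, test the contrast nonparametrically with
familywise-error correction, and keep genes whose call is stable across
repeated balanced subsampling of cells. All components run at desk scale
on synthetic cohorts with planted effects, so every claim the test suite
makes is about quantities the package itself computes.

## Expression binning

Raw counts are discretized per cell into `n_bins` = 51 tokens. Zeros map
to token 0. The quantile edges for a cell are computed from that cell's
nonzero values at probabilities k/(n_bins−1), k = 1..n_bins−2; a nonzero
value receives token 1 + (number of edges strictly below it), i.e.
right-closed bins. Entries equal to the cell's maximum are forced into the
top bin, so the empirical maximum always maps to token n_bins−1 even when
few distinct values make the quantile edges coincide. This keeps the
overexpression perturbation (writing the top token) inside the observed
per-cell range. Because the scheme is a per-cell rank transform it is
invariant to library size, so counts are binned raw, with no depth
normalization; it also absorbs the simulator's scalar per-donor depth
shifts. Genes expressed in fewer than 1% of cells are removed first
(boundary inclusive: exactly 1% is kept).

## Classifiers

Both backends expose the same contract: `predict_old_prob` returns one
probability per cell, clamped to [1e−12, 1−1e−12] so downstream log-ratios
stay finite, and predictions are deterministic for a fitted model.

**MLP head over a trainable surrogate encoder.** The head is designed as
a fine-tuning head of the kind trained on top of a frozen pretrained
transcriptome foundation model. No pretrained encoder is bundled here, so
the encoder is replaced by trainable embedding tables while the head
architecture and training recipe are kept fixed. Each (gene g, token b) pair is embedded as

    e(g, b) = gene_emb[g] + bin_emb[b] + gene_mod[g] ⊙ bin_value[b]

and the cell embedding is the mean of e(g, token_g) over genes. The
multiplicative value-modulation term is essential under mean pooling: with
purely additive tables the gene embedding contributes the same constant to
every cell and the pooled vector collapses to the token histogram, losing
which gene carries which token — such a model cannot represent
gene-specific age signal and its perturbation responses are
gene-nonspecific. With modulation, the pooled vector carries a
random-projection sketch of the expression profile (`gene_mod` directions
weighted by a shared per-token value curve), which a linear readout can
decode. `bin_value` is initialized as a monotone ramp in the bin index
(pretrained encoders represent expression magnitude smoothly);
`gene_mod` starts at scale 1.0 and the additive tables at 0.02, so the
sketch dominates the initial representation. Embedding width is 256: at 64
dims the sketch itself caps a perfect linear readout near AUC 0.80 on the
reference cohort, while 256 retains the signal, and head compute is
dominated by the 1024×1024 layers either way.

The head is: layer normalization of the pooled embedding, five linear
layers of 1024 units interleaved with GELU and dropout 0.4, and a final
affine map to one logit; P(old) = sigmoid(logit). The final layer is
zero-initialized — the logit starts at zero and the optimizer builds the
readout coherently, which matters because a small cohort yields only on
the order of 10² optimizer steps at the fixed recipe. Training minimizes
class-weighted binary cross-entropy on logits, with weights
w_c = n/(2 n_c) from the training labels (this makes the loss invariant to
replicating one class), using AdamW at learning rate 1e−4 and decoupled
weight decay 1e−7, 20 epochs of shuffled minibatches of 256. The network
is implemented in float32 numpy with explicit backpropagation; training
and inference are bit-reproducible given the seed, and inference disables
dropout.

**Logistic baseline.** Per-gene token values standardized to zero mean and
unit variance with training statistics (unit divisor for constant
columns), then L1-penalized logistic regression at regularization strength
C = 1 (the cited solver's default). It is fit as a binary model; a
two-class multinomial parameterization is redundant with it.

ROC-AUC is evaluated on held-out donors as the rank statistic
P(score_old > score_mid) + ½P(tie); the test suite checks it against a
brute-force pair count.

## Donor-wise evaluation

Train/test splits are at donor level, stratified by age group: a fraction
(default 0.25; at least one donor per group on each side) of each group's
donors is held out, so no donor contributes cells to both sides. The split
fraction is a package default; donor-wise splitting is the invariant that
matters, the ratio is configurable.

## Perturbation screen

For one tissue, one screen draws a balanced subsample (default 150 cells
per age group, i.e. 300 cells per screen — balancing removes confounding
from age-group composition), bins it over the model's gene set, and for
every gene g forms
two virtual conditions: knockout (gene's token set to 0 in every cell) and
strong overexpression (token set to n_bins−1, the empirical per-cell
maximum bin). Perturbation acts in token space rather than raw space:
under per-cell quantile binning a raw zero maps to token 0 and a
tissue-maximal value to the top token, while re-binning a perturbed raw
profile would spuriously shift every other gene's tokens. The effect size
is

    effect = log2( mean_c P(old | knockout) / mean_c P(old | overexpression) )

(ratio of group means, one number per screen; the group means are floored
at 1e−12). A two-sided Mann–Whitney U test compares the two probability
samples; the two samples come from the same cells, but the test is
deliberately applied unpaired — a paired alternative would be more
powerful but changes the procedure being implemented, and is out of
scope. Holm's step-down adjustment
is applied across all genes screened together in one iteration (the
familywise unit). A gene with adjusted p < α (default 0.05) is labelled
anti-aging if its effect is positive (knockout looks older than
overexpression, so raising the gene rejuvenates the prediction) and
pro-aging if negative; an effect of exactly zero is never called, since it
carries no direction.

The Mann–Whitney p-value is exact when both samples have fewer than 20
observations: the null distribution of the rank sum is enumerated by
dynamic programming over doubled midranks, which stays valid under ties
(library "exact" methods are tie-unaware), and the two-sided p is the null
probability of a U at least as far from nm/2 as observed. At 20
observations and above, the tie-corrected normal approximation with
continuity correction is used, with p = 1 returned when the pooled sample
is constant (the fully tied case, e.g. a model that ignores the gene).
Holm is implemented directly from its step-down definition and is
cross-checked in the tests against an independent brute-force
implementation and against statsmodels.

## Stability across subsampling

The screen is repeated `n_iterations` = 10 times, each drawing a fresh
independent balanced subsample (seeds base_seed + i, recorded in output)
with the fitted model held fixed — resampling cells, not retraining,
isolates screen variance from classifier variance. Per gene, stability is
the fraction of iterations called anti-aging (resp. pro-aging); effect
mean and standard deviation are taken over all iterations, significant or
not; and the worst-case significance is summarized as the maximum over
iterations of log10 adjusted p. Genes are ranked by best-direction
stability, ties by |mean effect|, then symbol.

## Annotation overlap and reporting

Stable candidates are compared against a curated aging-gene table (one
symbol per row with a confidence level from {highest, high, moderate, low,
lowest}), optionally restricted to high-confidence entries. The overlap
fraction over an empty candidate set is reported as undefined (None), not
zero. The plot-ready volcano table reports x = mean effect, y = −log10 of
the maximal adjusted p (the least significant iteration), error-bar
half-width = effect SD, direction, and table membership. Mitochondrial
(`MT-` prefixed, hyphen required) and heat-shock
(HSPA/HSPB/HSPD/HSPE/HSPH/HSP90 families) genes are removed from reported
tables, as their expression often reflects technical artifacts of droplet
scRNA-seq; the prefix list is fixed here because the artifact class is
usually named but not patterned.

## Synthetic cohorts

The simulator emulates the structure of a multi-donor two-age-group
single-cell atlas: several donors per group in one tissue, a per-donor
scalar log-shift (depth/quality), per-cell log-normal library-size
variation, and negative-binomial counts parameterized by mean and
dispersion θ (variance μ + μ²/θ). A chosen minority of genes is planted
with an age-group-dependent fold change: for cell c of donor d, gene g,

    μ[c,g] = exp(log μ_g + δ_d + ℓ_c + 1[old]·s_g·log FC_g),   K ~ NB(μ, θ)

with δ_d ~ N(0, donor_effect_sd), ℓ_c ~ N(0, libsize_log_sd), s_g = +1 for
up-in-old and −1 for down-in-old. A gene up-regulated in old cells is a
ground-truth pro-aging candidate (overexpression pushes P(old) up, so the
knockout/overexpression ratio is below 1), and a down-regulated gene is
anti-aging.

Defaults define the reference study cohort used by the tests and the
acceptance script: 6 donors per group × 200 cells (2,400 cells), 200
genes, 10 up- and 10 down-regulated at fold change 4, θ = 5,
donor_effect_sd = 0.1, libsize_log_sd = 0.3, baseline log-abundance
N(0, 1) (median mean ≈ 1 count, ≈ 40% zeros at the median — typical
moderate-depth scRNA-seq sparsity for a curated panel). Causal genes draw
their baseline from the upper half of that distribution (half-normal above
the mean): the screen's real input panel is a curated list of genes
already called significantly age-associated upstream, which conditions on
detectable expression — a fold-4 down-regulation of a gene averaging 0.25
counts in the old group is statistically invisible at any desk-scale
cohort size and would never enter such a panel.

The generator does not model cell-type heterogeneity, batch effects,
ambient RNA or zero-inflation beyond the NB (moderate NB means already
produce realistic sparsity). Passing tests therefore demonstrate correct
recovery of planted group-level expression shifts under donor structure
and overdispersion, not robustness to cell-type composition or protocol
artifacts in real atlases.

## Numerical and procedural choices

- Probabilities are clamped to [1e−12, 1−1e−12]; screen group means are
  floored at 1e−12; adjusted p-values are floored at 1e−300 before log10.
- The network runs in float32; statistics in float64; exact Mann–Whitney
  counts in exact integer arithmetic.
- Donor splits sort donor ids before seeded drawing; all sampling
  (splits, subsamples, initialization, minibatch order, dropout) derives
  from explicit seeds, so every result is reproducible.
- The pipeline writes one TSV per stage and a JSON manifest (config echo,
  seeds, stage timings, per-tissue row counts); a rerun with the same
  config reproduces stage TSVs byte-identically.
- Reference problem sizes throughout (tests and acceptance script): the
  2,400-cell planted cohort above; screens of all 200 genes at 150 cells
  per group; 10 stability iterations; type-I experiments over 20 screens
  of 100 unplanted genes.

## Known limitations

- **Reliance concentration of the surrogate.** The planted up-genes (and
  likewise the down-genes) are mutually redundant predictors of age. Any
  regularized classifier concentrates its reliance on a sufficient subset,
  and the desk-scale surrogate — lacking a pretrained encoder's gene–gene
  couplings — does so more than the system it stands in for. In practice
  the screen over the surrogate head recovers roughly 50–75% of planted
  genes at stability ≥ 0.8 (the misses are the weakest-expressed
  down-regulated genes), and the L1-logistic screen 75–90%, with
  essentially no stable false positives among unplanted genes. Ranking,
  directions and null behaviour are robust; exhaustive recovery of
  redundant planted genes is not guaranteed.
- **Type-I control is a property of the operating regime.** The
  Mann–Whitney test compares model outputs under two perturbations; its
  null holds only for genes the model is (numerically) independent of. A
  classifier fitted to data with no age signal at all still acquires small
  noise-driven dependences on many genes, and because a rank test is
  scale-free, such screens produce large numbers of "significant" calls.
  Familywise error behaves as designed when the classifier carries genuine
  age signal that dominates prediction spread — the regime the method is
  meant for, and the one the type-I experiment measures (screens of
  unplanted genes through a signal-bearing model). Even there the control
  is approximate: a trained model occasionally retains a weak, persistent
  noise-driven dependence on an unplanted gene, and because the dependence
  is a property of the fixed model, such a gene can recur across
  independent cell subsamples (measured across reference runs: 0–9
  significant calls per 2,000 null gene-screens, typically from one or two
  recurring genes). Screens of models trained on signal-free data are not a
  supported use.
- Perturbations are single-gene, extreme (token 0 or top bin) and local in
  token space; graded doses, combinatorial perturbations and propagation
  through gene–gene couplings are out of scope, as are multi-class age
  prediction and continuous-age regression.
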