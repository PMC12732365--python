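# agescreen

In silico gene-perturbation screening for pro- and anti-aging candidate
genes from single-cell RNA-seq age classifiers.

## The problem

Transcriptome-based aging clocks tell you *that* gene expression predicts
age, not *which* genes to intervene on. `agescreen` implements a
hypothesis-generation workflow for geroscience: train a classifier that
predicts a cell's donor age group (mid-age, 20–59 y, vs old-age,
60–100 y) from binned single-cell expression, then interrogate the fitted
model gene by gene — force each gene's expression to zero (simulated
knockout) or to its empirical maximum (simulated strong overexpression)
and measure how the predicted old-age probability P(old) shifts. Genes
whose simulated overexpression *lowers* the predicted age are candidate
anti-aging perturbations; genes whose overexpression *raises* it are
candidate pro-aging perturbations. The screen is aimed at cohorts
structured like multi-donor aging atlases (several donors per age group
per tissue, raw counts, curated age-associated gene panels) and at
readers who want ranked, statistically vetted candidate lists — not causal
claims.

## The method

For each gene *g* in a balanced subsample of cells (150 per age group):

    effect(g) = log2 [ mean_c P(old | knockout of g) /
                       mean_c P(old | overexpression of g) ]

Perturbations act in token space: counts are discretized per cell into 51
expression-rank bins (zeros → bin 0, the cell maximum → bin 50), so
knockout writes token 0 and overexpression the top token. A two-sided
Mann–Whitney U test compares the two probability samples, Holm's
step-down correction controls the familywise error across all screened
genes, and significant genes are labelled anti-aging (effect > 0) or
pro-aging (effect < 0). The screen is repeated on 10 independent
subsamples; a gene's *stability* is the fraction of iterations in which
its call recurs, and stable candidates are compared against a curated
aging-gene table (Open Genes-style TSV with confidence levels).

Two classifier backends sit behind one probability contract: a
classification head (layer norm, five 1024-unit GELU layers, dropout 0.4,
class-weighted binary cross-entropy, AdamW) over a trainable surrogate
encoder of gene/bin embeddings with multiplicative value modulation, and
a standardized L1 logistic-regression baseline. Training and evaluation
are always split at the *donor* level so no individual contributes cells
to both sides. A negative-binomial cohort simulator with donor structure
and planted fold-change genes provides ground truth for testing the whole
chain. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import agescreen as ag
from agescreen.simulate import CausalGene, SyntheticSpec

# one-tissue cohort: 6 donors per age group x 100 cells, 100 genes, of
# which 5 are up- and 5 down-regulated in the old group at fold change 4
causal = [CausalGene(i, "up_in_old", 4.0) for i in range(5)] + \
         [CausalGene(i, "down_in_old", 4.0) for i in range(5, 10)]
spec = SyntheticSpec(n_donors_per_group=6, cells_per_donor=100,
                     n_genes=100, causal_genes=causal, seed=0)
adata, truth = ag.generate_cohort(spec)

filtered = ag.filter_genes(adata)                       # >= 1% of cells
split = ag.split_by_donor(filtered, 0.25, seed=1)       # donor-wise
train = filtered[split.train_mask(filtered)].copy()
test = filtered[split.test_mask(filtered)].copy()

model = ag.fit_logistic_baseline(ag.bin_expression(train),
                                 train.obs["age_group"], seed=0)
auc = ag.evaluate_auc(model, ag.bin_expression(test), test.obs["age_group"])
print(f"held-out ROC-AUC: {auc:.3f}")

summaries = ag.run_stability(model, adata, None,
                             ag.ScreenConfig(n_per_group=100),
                             n_iterations=10, base_seed=0)
stable = [s for s in ag.rank_by_stability(summaries) if s.stability >= 0.8]
print(f"{len(stable)} stable candidates:")
for s in stable:
    label = "pro-aging " if s.stability_pro >= s.stability_anti else "anti-aging"
    print(f"  {s.gene}  {label}  stability={s.stability:.1f}  "
          f"effect={s.effect_mean:+.2f}")
```

Output:

```
held-out ROC-AUC: 0.999
8 stable candidates:
  G0001  pro-aging   stability=1.0  effect=-0.23
  G0004  pro-aging   stability=1.0  effect=-0.23
  G0003  pro-aging   stability=1.0  effect=-0.23
  G0002  pro-aging   stability=1.0  effect=-0.22
  G0008  anti-aging  stability=1.0  effect=+0.21
  G0005  anti-aging  stability=1.0  effect=+0.17
  G0000  pro-aging   stability=1.0  effect=-0.15
  G0009  anti-aging  stability=1.0  effect=+0.14
```

All eight stable candidates are planted genes with the correct direction:
up-in-old genes (G0000–G0004) are called pro-aging — their knockout makes
cells look younger than their overexpression, so the effect (the log2
knockout/overexpression probability ratio) is negative — and down-in-old
genes anti-aging, while no unplanted gene reaches the stability bar. The
same workflow is available from the shell
(`agescreen simulate / preprocess / train / screen / stability / report`),
or end to end with `agescreen all --config run.yaml`.

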