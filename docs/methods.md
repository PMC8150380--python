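# Methods

## The synthetic twin-species world

The generator builds two species, each a genes × features table plus the
side files a real analysis would consume (GFF3 gene models, protein FASTA,
heterochromatin BED, reference essentiality probabilities, a phenotype
database).

**Latent model.** A subset of the *shared* features is informative. Shared
coefficients have magnitude `effect_size` with random sign; each species
uses a relative perturbation of them, cₛ = c·(1 + N(0, `coef_jitter_sd`)),
and the per-gene latent score is z = X·cₛ + N(0, `noise_sd`). The jitter is
relative rather than additive so a null shared effect (`effect_size = 0`)
is exactly null in both species; at the default effect size 1 the relative
and additive forms coincide in distribution. Jittering rather than
resampling the coefficients is what makes cross-species transfer learnable
by construction, and scaling the jitter up dials the transferable signal
down.

**Reference probabilities.** logistic(z) is rescaled piecewise-affinely
within three rank bands so that exactly the top `essential_prevalence`
fraction of genes exceeds 0.7 and everything below the unlabeled band falls
below 0.1. The downstream label thresholds are fixed constants, so the
generator must guarantee non-empty classes at those cut-offs; within each
band the ordering and relative spacing of the logistic values are preserved.
The true essential flag is the top `essential_prevalence` fraction by latent
score and therefore coincides with the >0.7 band.

**Genome layout.** Genes (0.5–5 kb, 1–6 exons) are placed uniformly on
equal-length chromosomes. Each chromosome carries two terminal
heterochromatin blocks covering `het_fraction` of its length. An essential
gene landing inside heterochromatin is re-drawn outside with probability
1 − `het_depletion`: 0 empties heterochromatin of essential genes, 1 leaves
placement unbiased.

**Proteins and phenotypes.** Proteins are uniform random sequences of
80–160 canonical residues; a `near_duplicate_fraction` of genes instead
copy another gene's protein with 10% point mutations, giving ~90%-identity
pairs that exercise the redundancy filter. The phenotype database covers
each gene with probability `phen_coverage` and draws a lethal flag from
class-conditional rates given true essentiality.

**Defaults** (the package's standard study conditions): 3000 genes per
species; 120 shared + 15 private features, 20 informative; effect size 1.0;
jitter sd 0.3 (planted cross-species coefficient correlation ≈ 0.9, strong
but imperfect transfer); latent noise sd 0.5; essential prevalence 0.04
with an 0.11 unlabeled band (≈ 120 essential / 2550 non-essential / 330
unlabeled per species); 5 × 20 Mb chromosomes, 20% heterochromatin,
`het_depletion` 0.2; phenotype coverage 0.6 with lethal rates 0.9 / 0.02.
The non-essential lethal rate is set below half the marginal lethal
prevalence so that a good ranking separates the two ends of the cumulative
lethal-ratio curve by construction; a rate as high as 0.05 would place the
bottom-of-list ratio above half the prevalence no matter how good the
ranking is.

**What the generator does not emulate:** correlated features (real omics
columns are strongly collinear), heavy-tailed counts, shared orthology
structure between the species' gene sets, realistic protein evolution, and
feature missingness. Tests passing on this world show the protocol's
mechanics are correct and that planted signal of realistic strength is
recovered; they do not show the features of any real species are this
clean.

## Labels and harmonization

Features are matched by name across the two species and z-scored within
each species (never pooled): a model trained on one species' standardized
table can then score the other's. Features constant in either species are
dropped from both. Labels come from reference probabilities with strict
thresholds — essential above 0.7, non-essential below 0.1 — and genes
between the thresholds are excluded from training but always scored at
prediction time. Missing feature values are imputed to the within-species
feature median on read, with a per-feature count kept in an imputation log.

## Consensus feature selection

Two selectors with different inductive biases vote, and only features both
keep survive:

* **Elastic net** — `LogisticRegressionCV` (saga) over an L1-ratio grid ×
  a penalty path, winner by cross-validated deviance; selected = nonzero
  coefficients. On planted-signal data this selector has high recall but
  admits noise features (its CV-optimal penalty under-shrinks).
* **Ensemble SPLS** — sparse partial least squares for a univariate
  response: per component, Z = Xᵀy_res, w ∝ sign(Z)(|Z| − η·max|Z|)₊
  normalized, score t = Xw, then X and y deflated by their regression on t.
  y is encoded ±1 and centered (regression-mode PLS on a binary response).
  The fit is repeated on B stratified subsamples (default B = 100, 80%
  subsample) and a feature is selected when its nonzero-weight frequency
  reaches `freq_threshold` (0.5); with threshold 0 the rule degenerates to
  the union of per-run selections. The frequency filter is what removes the
  elastic net's noise admissions from the consensus.

Defaults: η = 0.7, K = 3 components, 9-point L1-ratio grid, 5-fold CV.
K = 3 rather than 2 because with heterogeneous planted effect sizes each
component's soft threshold keeps only features within 30% of that
component's largest covariance; two components capture two "tiers" of
effect sizes and systematically miss weaker-but-real features, while a
third component recovers them without admitting noise (the ensemble
frequencies of noise features stay near zero). Reduced-budget settings used
by the demo and the acceptance script (3-point alpha grid, 6 penalties,
3-fold CV, saga tolerance 1e-3) give the same selections on the standard
world at a fraction of the cost.

Feature importance across fitted families is aggregated as the median of
per-model permutation importances (held-out drop in ROC-AUC under column
shuffling), each model rescaled so its maximum is 100; ranking ties break
lexicographically. Permutation importance is used uniformly because the
families' native importance measures are not comparable.

## Models and metrics

Six families behind one contract — GBM and RF (scikit-learn ensembles), XGB
(xgboost, `hist`, single-threaded for determinism), GLM (logistic
regression), SVM (RBF, Platt probabilities), NN (one hidden layer of 32,
early stopping). `fit` runs an inner 3-fold stratified grid search
maximizing ROC-AUC over a deliberately small grid (≤ 4 configurations per
family) and refits on the full input; inside large resampling loops the
first grid configuration is fitted directly. Class imbalance is left
untouched — no over- or under-sampling — because prevalence is part of the
prediction problem; all evaluation uses threshold-independent metrics.

ROC-AUC (Mann–Whitney with half-credit ties) and PR-AUC (average precision
with tied scores grouped) are implemented in closed form in-repo and are
checked in the test suite against brute-force pair counting and a
threshold-staircase oracle to 1e-12, and against scikit-learn.

## Evaluation protocols

* **Training-fraction grid** — stratified splits at fractions 0.1…0.9
  (default 5 repeats each), feature selection re-run inside every training
  split (selection outside the split would leak test information), all
  requested families fitted, metrics on the held-out part. Each split also
  fits a background model on permuted training labels (logistic family);
  its ROC-AUC hovering at 0.5 is the negative control. Splits leaving
  fewer than two members of a class are skipped with a warning.
* **Bootstrap** — B stratified 90/10 resamples (default 1000,
  config-reducible; the acceptance script uses 50), per-replicate metrics
  and 5–95% summary intervals. Per-replicate seeds derive from the master
  seed, so the whole set is reproducible.
* **Non-redundancy control** — greedy centroid clustering of proteins in
  descending length order: a sequence joins the first centroid whose global
  alignment (match +1, mismatch −1, gap −2) has identity
  (matches / alignment length) above 0.25, else founds a new cluster; only
  centroids are retained. At ~0.26 ms per alignment the full labelled set
  of the standard world (~2700 proteins, ~3.5M pairs) is out of desk-scale
  reach, so the robustness analysis runs on a seeded stratified 1000-gene
  subsample (~0.5M alignments); the filtered median ROC/PR-AUC is compared
  against the unfiltered bootstrap's 5–95% interval on the same subsample.

## Transfer and validation

Transfer fits the chosen family (XGB by default) on **all** labelled genes
of the source species over the cross-species consensus features and scores
every target gene, including unlabeled ones. Rankings sort by descending
probability with ties broken by gene id so outputs are byte-reproducible.
The within-species control uses the identical code path with source =
target.

The cumulative lethal-ratio curve walks the ranking from the top (and
separately from the bottom) and reports, at every k, the lethal fraction
among phenotype-database-covered genes seen so far. Genes absent from the
database are excluded from numerator and denominator — counting them as
non-lethal would conflate database incompleteness with benign phenotype —
and coverage counts are reported alongside. Prefixes with no covered gene
carry a missing ratio. Both directions necessarily meet at the overall
covered-gene lethal prevalence at k = N.

## Landscape

Each ranked gene becomes a BedGraph record (0-based half-open span, scored
by probability) and a (midpoint, probability) point; per-bin gene counts
(default 100 kb) give the density track. The heterochromatin summary
classifies genes by 1-based midpoint against half-open intervals, reports
the fraction of high-probability (> 0.5) genes inside heterochromatin, and
compares inside vs outside probabilities with a two-sided rank-sum test
(normal approximation). With no intervals supplied the inside fraction is
undefined and flagged rather than zero.

## Pipeline determinism

Every stage's seed is blake2b(stage-name : master-seed) reduced below 2³¹,
so adding stages never perturbs existing ones. `manifest.json` echoes the
config, the per-stage seeds and SHA-256 checksums of every output; re-runs
from the same config are byte-identical.

## Known limitations

* With only 20 informative features, the angle between the two species'
  jittered coefficient vectors has irreducible sampling spread
  (sd ≈ 1/√20), and any mean-centred jitter leaves their expected inner
  product positive. Large jitter therefore drives transfer accuracy toward
  chance only in expectation, with heavy seed-to-seed variance; single
  worlds can retain appreciable residual transfer even at 10× the default
  jitter. Conclusions about "destroyed" cross-species signal need averaging
  over many worlds.
* The permuted-label background's bootstrap median varies more across
  worlds than independent-replicate arithmetic suggests (replicates share
  the gene set), so it should be read as "near 0.5", not as a tight null.
* Greedy length-ordered clustering is order-dependent near the identity
  threshold; it is a control, not a reference clustering.
* The elastic-net/SPLS hyperparameters are defensible defaults, all
  config-exposed; no claim of optimality is made.
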