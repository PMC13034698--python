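# Methods

`cometdr` re-implements a two-stage multimodal workflow for prioritizing
protein biomarkers of diabetic retinopathy (DR): a recurrent encoder is
pretrained on longitudinal EHR data from a large cohort, frozen, and
transferred into a multimodal classifier fine-tuned on a small cohort
with both EHR and aqueous-humor proteomics; integrated-gradients
importance fold changes against a non-pretrained baseline nominate
candidate proteins, which are then tested statistically in an
independent validation cohort. Patient-level data of this kind cannot be
shared, so the package ships a fully specified synthetic generator that
plants the cross-modal structure the method is designed to exploit, and
every pipeline stage is exercised end-to-end on those cohorts.

## Synthetic cohorts

Three cohorts are drawn from one generative law per run: an EHR-only
pretraining cohort (default 2,000 patients at desk scale), a multimodal
discovery cohort (101 patients, 14 cases — the emulated study design),
and an independent validation cohort (164 patients, 17 cases). Each
patient carries independent standard-normal latent factors with distinct
cross-modal footprints:

- **z0 — systemic confounder.** Expressed in concept occurrences and
  contaminating the "EHR-rooted" proteins, but not itself part of the
  multimodal outcome. It *is* part of the pretraining cohort's outcome:
  that cohort is labeled by a diagnosis-code style phenotype scoring
  `(z0+z1)/√2`, reflecting what a health record can see.
- **z1 — clinical severity.** Expressed in concepts and driving the
  outcome.
- **z2 — molecular severity.** Carried by the rooted proteins and
  driving the outcome, invisible to the record.

The multimodal outcome score is `(z1+z2)/√2`; labels are assigned by
quota (the top `n_cases` patients by score), so prevalences are exact.
Cases are substratified into "PDR" (top half by score) and "NPDR".

Concept occurrences are Bernoulli per (patient, day, concept) with base
rates log-uniform on [0.001, 0.05] (realistic sparsity, ~2 events per
patient-day at 150–300 concepts). Planted effect concepts split into two
halves whose occurrence log-odds rise by `concept_effect × z0` and
`concept_effect × z1` (logistic link, default slope 1.0 — a moderate,
clearly-visible clinical signal). A patient's index date is their last
event day, the end-of-record analog of truncating at biopsy or onset.

Proteins are log2-normal intensities (RFU-like). Planted marginal-effect
proteins (default 15) are mean-shifted in cases by `protein_d ×
noise_sd` on the log2 scale with `protein_d = 1.4` and `noise_sd = 1.9`
(the reported effect magnitude: median log fold change ≈ 2.6, d ≈ 1.4),
so the population Cohen's d equals `protein_d` by construction. Their
residuals share a common factor at pairwise correlation 0.5, emulating
pathway co-regulation — independent noise would overstate multivariate
separability relative to real co-expressed panels. EHR-rooted proteins
(default 5) load on the cross-modal mix `(z0+z2)/√2` at correlation
`cross_modal_rho = 0.8` and carry a weak marginal shift (d = 0.4). The
validation matrix is generated in two batches with per-batch,
per-protein multiplicative scale drift (log2 SD 0.3) and calibrator
rows, so calibrator-based batch scaling is exercised.

What the generator does *not* model: concept-code semantics or ontology
structure, visit patterns, treatment dynamics, within-day ordering,
censoring, demographic confounding, or assay limits of detection.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behavior of transfer learning on planted structure — not
performance on real clinical data.

## Concept embeddings and patient sequences

Concept codes are organized chronologically by patient and day; same-day
events have no reliable order, so each day is shuffled once (seeded)
into a "sentence". A skip-gram model with negative sampling (trained
directly on numpy: context window 25, 5 negatives, unigram^0.75 noise
distribution, linearly decaying learning rate from 0.025, scores clipped
to ±6, per-row gradient averaging within each pair minibatch for
stability) maps each concept to a dense vector; the original study used
400 dimensions, the scaled default here is 32. A patient-day is
summarized as the arithmetic mean of that day's concept vectors, and the
model consumes the most recent 32 **event-days** of summaries (days with
at least one code — summaries only exist for such days), left-padded
with zero rows and a padding mask. Daily summaries are standardized
per dimension (fit on the pretraining cohort's unmasked rows) before
entering the network; without this the recurrent optimization can stall
at the base-rate solution. The same embedding and scaler, fitted on the
pretraining corpus, are applied to the multimodal cohort by default:
two independently trained embedding spaces are not mutually aligned, and
a frozen encoder only transfers meaningfully inside the space it was
trained in (`embedding_source="separate"` is available for completeness).
Concepts missing from the vocabulary are skipped in the daily average; a
day with only unknown concepts contributes a zero row with mask false.

## Model and training

All four variants share one architecture: a stacked GRU over the
sequence rows whose final hidden state at the last unmasked position is
the EHR latent representation (hidden size 400 in the original protocol;
32 scaled), a linear EHR logit head, a single linear omics head, a
linear joint head on the concatenation of latent and standardized
protein vector, and a **bias-free** linear combiner over the active
component logits followed by a sigmoid. Component *logits* (not
probabilities) are combined: a single sigmoid after a bias-free
combination implies pre-sigmoid aggregation, and zeroing all component
logits yields probability exactly 0.5. In single-modality variants the
combiner degenerates to one bias-free weight.

Training minimizes binary cross entropy with plain SGD (optional L2
weight decay, default off), multiplicative per-epoch learning-rate decay
`lr ← lr·(1−lr_decay)`, and early stopping with patience 5 on a held-out
split, restoring the best-held-out weights. Batch sizes are 512 for
pretraining and 16 for the multimodal cohort in the original protocol;
the scaled pipeline uses 32 for its 2,000-patient pretraining cohort
(512 would give a single update per epoch at that size). Omics
intensities are median-normalized, log2-transformed, and per-protein
z-scored before entering the network. In the transfer variant the
encoder weights are copied and frozen (bit-identity is asserted by
SHA-256 parameter checksums before and after fine-tuning); layers,
hidden size, and dropout are fixed to the pretraining values while
learning rate and decay are re-tuned. The EHR head is re-trained — only
the recurrent weights are frozen. Dropout (between stacked GRU layers,
training only) is disabled at evaluation, so repeated evaluation passes
are identical. Everything is float64 numpy on a small in-repo
reverse-mode autodiff; given a seed, training is bit-reproducible.

## Evaluation protocol

Hyperparameters are selected by grid search under threefold stratified
cross-validation (each fold's training portion donates 20% for early
stopping; ties go to the earlier grid point). The chosen configuration
runs through 25 Monte Carlo iterations of stratified 70/15/15
train/test/validation splits — stratified because at 14/101 prevalence
unstratified 15% splits are frequently case-free; rounding is floor for
test and validation with the remainder to train. Early stopping uses the
15% test split; predictions are collected on the 15% validation split;
each patient's final prediction is the mean over the iterations in which
they fell in validation (patients never sampled into validation are
dropped with a logged count). AUROC (Mann–Whitney convention, ties ½)
and AUPRC (step-interpolated average precision) are computed on the
averaged predictions via scikit-learn, with 95% percentile bootstrap
intervals over 1,000 patient-level resamples; degenerate single-class
resamples are redrawn so all 1,000 replicates are used.

## Prioritization

Integrated gradients attribute the **pre-sigmoid combined logit** (the
probability saturates and flattens attributions) along the straight path
from a baseline to the input, with a right-rule Riemann grid (default
128 steps; completeness `Σattr → F(x)−F(baseline)` is tested to <1% at
256 steps). The baseline is the zero vector in standardized protein
space (the cohort mean profile) and a zero-content sequence under the
patient's own mask — the continuous analog of an all-padding sequence,
since a mask change is discrete and would break the interpolation path.
Per-protein cohort importance is the mean absolute attribution across
all multimodal patients, normalized to sum to one; the fold change of
this relative importance between the pretrained and the non-pretrained
joint model ranks proteins (rank 1 = largest fold change; proteins with
baseline importance below 1e-12 are excluded as undefined ratios). The
non-pretrained joint model is the default baseline; the proteomics-only
model is available behind the same interface.

**Known limitation.** On the planted cohorts, this fold-change ranking
does *not* reliably surface the EHR-rooted proteins: with purely
additive heads a frozen informative latent *substitutes* for proteins
correlated with EHR-expressed factors (their shared variance is
explained away), and once the latent path saturates the logit, omics
gradients vanish and the omics profile freezes near its
marginal-covariance shape. Both effects push rooted proteins down, not
up. A regularized logistic oracle given explicit concept frequencies
*does* rank the planted rooted proteins above a label-permuted control
in 10/10 replicates, so the planted structure is recoverable in
principle — by a de-confounding (suppressor) mechanism this
architecture's training protocol does not reach at n=101. The
repeated-cohort experiment (`experiments.prioritization_recovery_experiment`)
measures this honestly and currently fails its ≥70% recovery target;
the corresponding acceptance test is expected to be red.

## Alignment

The Pearson correlation matrix over all variables (binary EHR features
as 0/1, hence point-biserial against proteins; zero-variance variables
dropped) is embedded in 2-D by t-SNE (perplexity 30, 1,000 iterations,
PCA initialization, seeded), treating each variable's correlation row as
its feature vector. Separately, every (latent dimension, protein) pair
is tested by exact-t Pearson correlation; reported are the significant
pair count (unadjusted two-sided p < 0.05 by default, BH-adjustable),
the mean absolute R over defined pairs, per-protein coverage (percent of
latent dimensions significant), and a two-sided Mann–Whitney comparison
of the |R| distributions between the pretrained and baseline models.

## Post hoc statistics

Batch correction multiplies each batch by reference-calibrator /
batch-calibrator per protein (first batch is the reference); median
normalization scales each sample so all sample medians equal the grand
median (idempotent). Differential expression uses pooled-variance
unpaired t-tests on log2 intensities (Welch behind a flag), BH
adjustment across the candidate set, and significance at adjusted
p < 0.05; variance moderation is deliberately not applied — at these
group sizes and a ~15-protein candidate set it is immaterial, and the
reported quantities are exactly the plain-model ones. An optional
Shapiro–Wilk advisory warns on clear non-normality but never gates.
Cohen's d follows the summary convention d = |median log2 FC| / SD
(2.6/1.9 → 1.368, reported 1.4). Power uses the exact noncentral t:
noncentrality `d·√(n1·n2/(n1+n2))`, df `n1+n2−2`; at d = 2.6/1.9, 87 vs
14, two-sided α = 0.05 it evaluates to 99.7%. Sample sizes are the
smallest integers meeting target power under either a fixed allocation
ratio or a fixed smaller group; the published "127 controls and 7
cases for 90% power at d=1.4" does not follow from this calculation
under any allocation we tried (fixed n2=7 needs only 37 controls), so
allocation is exposed as a parameter and the discrepancy is documented
rather than resolved. α defaults to 0.05 two-sided throughout.

## Cell types of origin

A cell type is called an origin of a protein's gene when its mean
expression is at least `k_sd` (default 2) standard deviations above the
gene's mean across all cell types — inclusive inequality, population
(n-denominator) SD across cell types within the gene row (sample SD
behind a flag). Constant rows yield no origins. The rule is
scale-invariant per gene and anti-monotone in `k_sd`; links are emitted
as a sorted (protein, cell type) table for Sankey rendering.

## Repeated-cohort experiments and scaled sizes

Two directional experiments quantify the transfer-learning claims. Both
pretrain one encoder on one 2,000-patient cohort (pretraining learning
rate chosen from {0.2, 0.05, 0.01} by held-out loss, the scaled analog
of the tuning grid) and redraw the 101-patient multimodal cohort from
the *same* generative frame every repetition, with matched seeds and
splits between arms.

- **Transfer benefit** uses a two-factor law (both outcome factors
  EHR-expressed, weak marginal protein effects d = 0.5): the condition
  in which the EHR carries the decisive signal but, at 150 concepts and
  16-dimensional embeddings, a from-scratch encoder at n=101 stays near
  chance (AUROC ≈ 0.5) while the pretrained encoder transfers at ≈ 0.75.
  Each arm is scored by Monte Carlo cross-validation (4 iterations) and
  the pretrained arm is expected to reach at least the non-pretrained
  arm's AUROC in ≥ 70% of 20 repetitions. How cleanly this regime is hit
  varies with the generative frame: concept base rates are drawn
  log-uniform per frame, and frames whose effect concepts land at high
  base rates make the structure learnable from 101 patients too, in
  which case the two arms tie near their ceiling and the win fraction
  drops toward one half. The claim is therefore a statement about the
  scratch-hard regime, not about every frame the generator can produce.
- **Prioritization recovery** uses the three-factor confounder law with
  strong marginal (d = 1.4) vs weak rooted (d = 0.4, ρ = 0.8) proteins
  and compares the rooted proteins' median fold-change rank against a
  label-permuted control; see the limitation above.

Problem sizes throughout the default pipeline are scaled to desk size:
2,000 pretraining patients (study: 319,896), 150–300 concepts (2,531),
16–32 embedding and hidden dimensions (400/800), 80–200 proteins, 48–64
observation days. The protocol constants — 32-day window, 70/15/15
splits, 3 folds, patience 5, 25 Monte Carlo iterations, 1,000
bootstraps, batch 16 for multimodal fine-tuning — are kept at their
stated values.

## Numerical choices

Float64 throughout; seeded `numpy.random.Generator` for every stochastic
step; grid-search ties break to the earlier declared configuration;
skip-gram scores clip at ±6; BCE uses the stable
`max(z,0) − yz + log1p(e^−|z|)` form; t-test p-values are clipped away
from exact zero before BH adjustment; correlation matrices are
symmetrized against floating-point drift; zero-variance latent or
protein columns are excluded from correlation summaries with a log
message; all-padding sequences produce the encoder's initial (zero)
state by construction.
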