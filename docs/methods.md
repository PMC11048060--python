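# Methods

This note documents the models, the synthetic data, and every numerical
choice the package makes, in the spirit of a model-description appendix.

## The task and the model

A chest study is 1–3 grayscale views plus the findings section of its
report.  The generator is a vision encoder–decoder (VED):

* **Encoder.**  Each view is split into non-overlapping `patch_size²`
  patches (default 16×16 on 64×64 images → 16 tokens per view), linearly
  embedded, given learned per-patch positional embeddings, and passed
  through a pre-LayerNorm transformer (default depth 2, 4 heads).  Views
  share weights and carry no view-index embedding, so encoder output is
  exactly permutation-equivariant over views; the per-view sequences are
  concatenated in study order.  A hierarchical shifted-window encoder could
  be substituted behind the same interface; at this scale a plain patch
  transformer is the appropriate reference encoder.
* **Decoder.**  A 3-layer cross-attention autoregressive transformer
  (pre-LN, 4 heads) over a word-level vocabulary built from the training
  reports (lower-cased, sentence-final periods tokenized separately;
  reserved PAD/BOS/EOS/UNK ids).  The decoder adds its own positional
  embedding to the visual features before cross-attending, which makes
  generation sensitive to visual token order.  Word-level rather than
  subword decoding is used throughout; a subword mode is reserved in the
  vocabulary interface but intentionally not implemented.
* **Width.**  The package default is `dim = 128` with feed-forward width
  `2·dim`.  In the scan that fixed this default, width was the single
  strongest factor in how well generation grounds on the image (validation
  graph-F1 after the NLL stage: 0.29 at dim 64 vs 0.49 at dim 128 under
  identical conditions); smaller widths produce fluent but prior-driven
  reports.

Everything runs in float64 on a small reverse-mode autodiff engine
(`rrg._tensor`); decoding uses a KV-cached incremental replica of the same
arithmetic (`rrg.model._IncrementalDecoder`), whose outputs re-score under
teacher forcing to < 1e-5 (tested).

## Decoding strategies

* **Greedy** — argmax per step, gradient-free; the SCST baseline Yg.
* **Beam** — standard beam search, cumulative log-probability ranking
  during search, length-normalized ranking of the final pool (can be
  disabled).  Width 1 reduces exactly to greedy; a width covering the whole
  prefix space equals exhaustive search (both tested).  Beam search (width
  4) is the inference decoder for validation and test in both stages.
* **Beam-multinomial sampling** — per step each live beam draws its
  continuations *without replacement* from its next-token distribution via
  Gumbel top-k; candidates are ranked by cumulative log-probability.  At
  width 1 this is plain ancestral multinomial sampling.  A `logit_scale`
  knob sharpens the draw; as it grows the strategy provably collapses onto
  deterministic beam search (tested).

PAD and BOS are structural tokens and are suppressed at decode time; the
recorded per-token log-probabilities are always the model's own
(unsuppressed) values, so log Pr(Ys) is exact.

## Two-stage training

**Stage 1 (NLL).**  Teacher-forced cross-entropy, mean over non-PAD target
positions (BOS is never a target, EOS is).  Defaults: 12 epochs, base LR
3e-4.

**Stage 2 (SCST).**  Per study the greedy baseline Yg and a sampled Ys are
decoded from the same weights.  Rewards, each in [0, 1]:

* `f1_entity_relation` — set-F1 over pooled entity tuples (text, label) and
  relation triples of the rule-annotated graphs of hypothesis and
  reference;
* `embed_similarity_f1` — greedy cosine-matching token F1.

Per metric, `Loss = −(r(Ys) − r(Yg)) · log Pr(Ys)` with rewards treated as
constants and log Pr(Ys) the raw sum of per-token log-probabilities of Ys
including EOS (no length normalization).  The total is the exact weighted
sum `α·Loss_embed + β·Loss_graph + γ·Loss_NLL`, α = β = 0.495, γ = 0.010
(no renormalization); the NLL term is the teacher-forced loss on the
reference, recomputed with gradients in the same pass family.  Gradients
reach the parameters through a differentiable teacher-forced re-scoring of
Ys (identical values to the decode-time log-probabilities).

Two choices here were forced by experiment:

* **Ys is a width-1 sample** (`ModelConfig.n_samples`, default 1).
  Returning the best of k sampled beams ranked by cumulative
  log-probability biases Ys toward short, high-probability sequences — up
  to the empty report — and the self-critical advantage collapses
  (observed: validation graph-F1 0.29 → 0.16).  A plain ancestral draw is
  the unbiased estimator and trains stably.
* **The embedding reward uses a frozen random table by default**
  (`StageConfig.reward_embeddings = "random"`; `"learned"` switches to a
  per-epoch snapshot of the decoder's own embeddings).  With learned
  embeddings the reward degenerates: co-occurring tokens converge to
  similar vectors, so repetitive garbage containing common tokens scores
  well, and the α-weighted term actively rewards degeneration (observed as
  immediate collapse of validation F1).  Random vectors are near-orthogonal,
  making the reward a soft token-overlap F1 — stable, and the closest
  static analogue of a pretrained-embedding score.

**Stage-2 learning rate and batch size.**  Stage defaults are 15 epochs at
base LR 1e-5.  The RL learning rate was selected by the same procedure the
workflow prescribes at full scale — a grid search scored on validation
graph-F1 — because the stability threshold depends on model and dataset
scale: too-high rates produce exactly the repetitive-report collapse the
full-scale analysis describes.  Rates at or above 3e-5 destroy the policy
at this scale; rates around 1e-5 improve it.  The RL batch size (16)
matters for the same reason: the single-sample self-critical gradient is
extremely noisy, and an adaptive optimizer turns unaveraged noise into
full-size parameter steps.  At batch 4 the stage drifts; at 16 the greedy
reward climbs steadily.  The NLL stage instead defaults to batch 2: its
gradient is well-behaved, and within the fixed 12 epochs the extra
optimizer steps are what let the text-augmented variant reach fluency —
undertrained, a TA model collapses onto a single paraphrase template and
loses both accuracy and diversity, inverting the augmentation's intended
effect.

**Schedule.**  Both stages decay the LR linearly to exactly zero over the
planned batches of the stage (`linear_lr`).  Hard-negative-mining revisit
batches reuse the last scheduled rate of their epoch and their errors do
not re-enter the epoch ledger.

**Hard negative mining.**  After each epoch, samples whose error exceeds
the epoch mean plus one *population* standard deviation (strict inequality;
fewer than two samples select nothing) are re-run before the epoch counter
advances.  The per-sample error is the quantity the stage optimizes:
teacher-forced NLL in stage 1, `1 − r_f1er(Ys, Yref)` in stage 2.

**Augmentation.**  Text augmentation re-draws a uniform permutation of the
report's sentences independently per sample per epoch, in both stages,
never at validation/test.  Image augmentation: random affine (translation
≤ 10 % of the side, scale 0.9–1.1, rotation ≤ 10°), then brightness ± 0.1
and contrast 0.9–1.1, clipped to [0, 1].  Both default to off, matching the
workflow's baseline configuration; ablation runs enable them explicitly.

**Optimizer.**  AdamW (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, decoupled weight
decay 0.01 on weight matrices only), global gradient-norm clip 1.0.
Checkpoint selection: the epoch with the best validation graph-F1 under
beam decoding, both stages.

## Synthetic corpus

The generator emulates the *structure* of credentialed chest-X-ray report
corpora without any of their content:

* Per study, each of K pathologies (default 6, drawn from the standard
  chest pathology label list) independently receives a status with
  prevalence present 0.3 / absent 0.3 / uncertain 0.1 / unmentioned 0.3.
  Studies with no mentioned finding are rejected and resampled (limit 100,
  then an error) — empty-findings studies never occur.
* Views (1–3, uniform) render each pathology at a fixed grid cell:
  present = solid glyph at 0.9, uncertain = solid at 0.5, absent = hollow
  outline at 0.9, unmentioned = background 0.1.  The hollow-outline
  encoding for "absent" is deliberate: explicit absence is a *finding*
  (it appears in the report and the graph), so it must be visible in the
  image, or pixels could never determine the report.  A hand-written
  pixel rule (`decode_findings_from_pixels`) recovers the findings of
  every generated study exactly (tested), so a perfect encoder could in
  principle reach graph-F1 1.  Additional views are affine-jittered
  (± 2 px) copies with a per-view corner marker; additive uniform noise
  (amplitude 0.05) and 8-bit quantization finish each view.  Quantization
  makes PNG round-trips lossless.
* Reports: one sentence per mentioned finding, drawn from ≥ 2 paraphrase
  templates per status; lexical status cues ("no", "possible", "cannot be
  excluded") are what the rule-based annotator keys on.  Sentence order is
  *habitual with random deviations*: the fixed pathology order perturbed by
  independent adjacent swaps (p = 0.1).  This mirrors how reporting style
  behaves in practice and is load-bearing: were generation-time order
  uniform, training-time sentence shuffling would add no information and
  its diversity benefit could not exist.  The stored ground-truth graph (2 entities + 1 `located_at` relation
  per mentioned finding) equals the annotator's output on the report text
  (tested for every generated study).

What the toy corpus does **not** emulate: anatomical image content,
comorbidity structure between pathologies (statuses are independent),
abbreviations and free-form phrasing, view-specific information (extra
views are redundant evidence), and report length/style variability beyond
sentence order and paraphrase choice.  Passing tests therefore demonstrate
that the training workflow and its incentives behave as designed — not
performance on real radiology data.

## Metrics

* Graph F1: set semantics over (text, label) entities plus
  ((head), (tail), type) relations; both empty → 1, one empty → 0.  The
  same definition serves reward and evaluation.
* Label F1: the annotator projected to per-pathology labels
  (positive/negative/uncertain/unmentioned; positive > uncertain > negative
  on conflicting mentions), micro-averaged F1 across the corpus with
  "positive" as the positive class.
* BLEU4: geometric mean of modified n-gram precisions (n ≤ 4) with brevity
  penalty; zero counts smoothed by ε = 1e-9.
* ROUGE-L: LCS F-measure with β = 1.2.
* Diversity: distinct token n-grams (n = 1..4) pooled over a generated
  corpus, same tokenizer as training.

Evaluation averages per-study scores (label F1 is corpus-micro) and
multiplies by 100 for display.

## Problem sizes

Training-dynamics checks and the acceptance pipeline run on a 200/40/40
study corpus with the model defaults above; decoding-statistics checks use
10,000 draws; the determinism check uses a reduced 16-study pipeline.
These sizes keep a full pipeline run in the minutes range on one CPU while
leaving the qualitative contrasts (NLL → RL improvement, TA diversity gain)
measurable.

## Known limitations

* The embedding reward is static (no context), so it cannot reward
  paraphrase beyond token identity — with the shipped template language
  that is a minor loss.
* SCST here uses a single sample per study; variance is correspondingly
  high and desk-scale RL gains are a few validation-F1 points, not the
  10+-point gains reported for full-scale training on real corpora.
* The rule-based annotator only understands the template language;
  free-form text outside it is (intentionally) annotated as silence.
* The stochastic workflow tests characterize one seeded trajectory per
  configuration; they are regression guards, not statistical estimates.
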