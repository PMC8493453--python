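# Methods

## Problem and model overview

Health-screening providers that pool free-text examination reports from
many institutions triage each thyroid report into one of three ordinal
classes — *healthy*, *caution required*, *critical* — historically by
trained nurses applying keyword-based guidelines. `scentnlp` reproduces an
automated version of that triage as a pair of ensemble text classifiers:

* **SCENT-v1** (accuracy-oriented): soft vote of a *static* word-embedding
  CNN ensemble and a *contextual* transformer ensemble; the label is the
  argmax of the averaged class-probability rows.
* **SCENT-v2** (workload-oriented): the transformer ensemble decides
  first; only rows it calls *healthy* are re-decided by a CNN+LSTM soft
  vote. Caution/critical decisions of the base ensemble are never touched,
  which bounds the false-negative behaviour of the severe classes by the
  base model's and lets the override recover non-healthy reports the base
  missed.

Each single-architecture ensemble is a *seed ensemble*: the same network
trained several times from different seeds, probability outputs averaged
(soft voting). Probability averaging happens post-softmax; argmax ties
break toward the more severe class, consistent with the system's goal of
minimizing false negatives under the healthy prediction.

## Data model and synthetic corpus

A record is (diagnosis text, hormone status ∈ {normal, abnormal,
not_conducted}, optional comprehensive report, label). The model input is
the concatenation diagnosis + canonical hormone sentence + comprehensive
report. The real corpora such systems train on are private EMR text, so
the package ships a generator that emulates their documented properties:

* **Keyword-determined labels with severity precedence.** The default rule
  set: healthy — no abnormalities/normal, simple cyst, tubular cyst,
  thyroid resection (thyroidectomy), benign calcification; caution —
  hypothyroidism, unequal parenchyma, internal thyroid disease,
  thyroiditis, nodule, thyromegaly, hyper-/hypoechoic lesions and nodules,
  cystic lesions; critical — tumor, malignant, biopsy, fine-needle
  aspiration cytology. A document's label is the most severe class whose
  keywords appear; keyword-free text defaults to healthy.
* **Severe imbalance**: class proportions default to 68.6 / 30.4 / 1.0 %.
* **Structure**: the comprehensive report is missing with probability 0.1
  (a free choice; how often real screening reports omit the section is not
  documented) and rendered as an enumerated phrase list rather than sentences
  with probability 0.3.
* **Noise**: per-word typo/space-perturbation probability 0.05 applied to
  filler sentences, emulating inconsistent grammar and spacing.

The diagnosis templates always carry the class keyword in their first
sentence, so every cumulative sentence prefix of a document still carries
its label's signal. The generator verifies after assembly that the keyword
rule recovers the intended label and never lets noise corrupt a keyword.

What the generator does *not* emulate: real morphological variety (the
emulated records are Korean EMR text; templates here are English
pseudo-clinical phrases), label noise from human annotators, documents whose label depends
on cross-report context ("no change since last year"), and realistic
vocabulary breadth. Passing the end-to-end test therefore shows the
pipeline machinery recovers a keyword-driven label structure under noise
and imbalance — not clinical-grade performance on real EMR text.

## Preprocessing

* **Cleaning** keeps letters, digits, the whitelist `% ' / ~ ² - , .` and
  single spaces; everything else becomes a space. Idempotent.
* **Sentence boundaries**: `.?!` followed by whitespace or end-of-text; a
  decimal point inside a number is never a boundary. No standard boundary
  definition exists for this kind of text, so this rule is the package's
  own.
* **Split**: stratified 7:1:2 train/validation/test per class with
  largest-remainder rounding (exactly 7/1/2 for a 10-document class).
* **Augmentation**: training documents of the rare class are expanded into
  cumulative sentence prefixes (an n-sentence document becomes n). Applied
  after splitting and only to training data, so augmented lineages never
  cross splits.
* **Class balancing**: after augmentation the training classes are
  equalized by downsampling the larger classes to the minority count; the
  emulated training condition is three equal-size classes, and this step
  reproduces it at any corpus scale. Validation/test keep the natural
  imbalance.
* **Trimming** (transformer route only): a comprehensive report is cut to
  the window from one sentence before the first "thyroid"-bearing sentence
  through the end; keyword-free reports pass through unchanged. Diagnosis
  and hormone sentences are always kept.

## Tokenization and embeddings

Two routes mirror the static/contextual split:

* **Word route (CNN, LSTM)**: rule-based pre-segmentation (whitespace,
  punctuation, letter/digit boundaries; decimal numbers kept whole), with
  numeric tokens canonicalized to a single `[NUM]` symbol — raw
  measurements are near-unique strings that would otherwise flood the OOV
  bucket. Embeddings are skip-gram negative-sampling (SGNS) vectors
  trained on the synthetic corpus itself (an external unlabeled corpus can be supplied instead): context window 5, 5 negatives
  drawn ∝ count^{3/4}, dimension 300 at paper scale / 64 at desk scale,
  plain SGD with a linearly decaying rate. The CNN supports random, frozen
  pretrained, and trainable pretrained embedding modes.
* **Subword route (transformer)**: the pre-segmentation is a pluggable
  interface (a language-specific morphological analyzer can be plugged in; the
  default is rule-based); subwords are induced WordPiece-style, starting from the
  full character inventory (so UNK arises only for unseen characters) and
  greedily admitting the merge with the highest likelihood-gain score
  `count(ab)/(count(a)·count(b))`, ties broken lexicographically. Encoding
  is greedy longest-match-first with `##` continuation markers, framed by
  `[CLS]`/`[SEP]`. Transformer inputs sum token, segment and fixed
  sinusoidal position embeddings `PE(p,2i)=sin(p/10000^{2i/d})`,
  `PE(p,2i+1)=cos(·)`; learned position embeddings are not used.

## Classifiers

All three networks are implemented over a small reverse-mode autodiff
engine (`scentnlp.autodiff`) whose every backward rule is validated
against central finite differences in the test suite. Arithmetic is
float64.

* **CNN**: a stem summing two stacked 3-kernel convolutions (each with
  batch normalization and ReLU) and a 1-kernel linear projection, mapping
  embeddings to 250 channels at paper scale; then `block_repeats` blocks of
  max-pool (size 3, stride 2) + two conv-BN-ReLU layers + identity
  shortcut (channel count constant, so no projection is needed); global
  max-pool; BN → dropout 0.5 → softmax head (pool → BN → dropout → softmax
  ordering, chosen among the plausible arrangements).
* **LSTM**: standard gate equations (`c_t = f⊙c_{t-1} + i⊙g`,
  `h_t = o⊙tanh(c_t)`), 5 layers × 650 units at paper scale with shortcut
  connections adding layer 1's output to layer 3's input and layer 3's to
  layer 5's; bidirectional variant runs 310 units per direction and
  concatenates. Non-recurrent dropout between layers. Additive attention
  pooling over the last layer's hidden states (`u_i = tanh(W_u h_i + b_u)`,
  `α = softmax(u_i·u_c)` with a jointly learned context vector,
  `v = Σ α_i h_i`), applied to the concatenated states in the
  bidirectional case; then a softmax head.
* **Transformer**: post-layer-norm encoder blocks — multi-head scaled
  dot-product self-attention (`softmax(QKᵀ/√d_k)V`, heads concatenated
  through `W^O`) and a two-layer ReLU feed-forward, each wrapped in
  residual + layer norm; 12 layers × 12 heads × d=768 at paper scale.
  Classification reads the first-position `[CLS]` vector through a tanh
  pooler. Corpus-scale pretraining objectives are out of scope; at desk scale the
  encoder trains from scratch, which exercises the same downstream
  classification mechanics.

**Padding** is excluded from every statistic that could leak it: pad
embeddings are zeroed, features re-zeroed after each convolution, pooling
counts only windows fully inside a sample's valid span, global max and
attention use additive −∞ masks, and the bidirectional LSTM reverses each
sequence within its own valid length. Consequently model outputs are
independent of batch composition (tested). Batch-norm statistics during
training do include the zero-padded positions; at inference running
statistics are used.

**Training**: Adam (β₁=0.9, β₂=0.999, ε=1e-8), categorical cross-entropy
(class weights are off because training classes are balanced), global-norm gradient clipping at 5, and
for CNN/LSTM a reduce-on-plateau schedule — the learning rate is
multiplied by 0.7 whenever validation loss fails to decrease within
`patience` epochs. The transformer uses a fixed rate. Non-finite loss
aborts with a diagnostic. Deterministic under the config seed.

## Scale profiles

| | paper profile | desk profile |
|---|---|---|
| members per ensemble | 10 | 3 |
| CNN | 250 ch × 6 blocks, lr 1e-3, batch 64, 30 epochs | 32 ch × 2 blocks, lr 1e-3, batch 16, 60 epochs |
| LSTM | 5 × 650, shortcuts (1,3),(3,5), lr 2e-4, batch 32, 30 epochs | 2 × 64, lr 2e-3, batch 16, 30 epochs |
| transformer | 12 × 12 × 768, d_ff 3072, lr 2e-5, batch 8, 15 epochs | 2 × 2 × 64, d_ff 128, lr 5e-4, batch 16, 40 epochs |
| max tokens | 2240 words / 512 subwords | 128 / 128 |
| embedding dim | 300 | 64 |
| plateau patience | 1 | 3 |

The paper profile records the full-scale reference hyperparameters and
is not meant to run on a desk machine. Desk-profile choices: training runs long enough
for the small balanced training set (a few hundred documents) to converge;
patience is 3 rather than 1 because validation loss computed from ~200
documents at batch 16 is noisy enough that patience 1 collapses the rate
before convergence; the transformer's higher-than-paper rate reflects
training from scratch rather than fine-tuning. The desk learning-rate/epoch
settings were fixed by watching training/validation losses converge on
generated corpora.

## Ensembling and evaluation

Seed-ensemble members differ only in seed (member i uses master seed + i);
per-member variation of epochs/batch sizes is supported through config
overrides but off by default, for reproducibility. SCENT-v1 averages the
two ensemble-level matrices (not the 20 member matrices — identical when
member counts are equal). A generic hierarchical combiner
(`hierarchical_generic`) exposes the base/override rule for any gate
class; SCENT-v2 is the gate-on-healthy special case.

Evaluation reports the 3×3 confusion matrix, per-class and macro
precision/recall/F1 (0/0 ratios set to 0; percentages printed to 2
decimals), and the healthy-vs-rest binary collapse (TN = healthy
predicted healthy, FN = healthy gold predicted non-healthy, etc.).

## Numerical and design notes

* Argmax ties in ensembles resolve to the more severe class; a tie between
  caution and critical is called critical.
* Greedy longest-match encoding is verified against an independent
  brute-force longest-match oracle over random words.
* Empty documents at prediction time receive a uniform probability row
  rather than aborting the batch.
* Degenerate pooling (sequence shorter than the pool window) clamps the
  window to the sequence.
* Subword decode joins `##`-continuation pieces and separates words with
  spaces; morpheme-level joins without whitespace (a property of
  agglutinative scripts) are out of scope.

## Known limitations

* The synthetic corpus is far more separable than real EMR text; headline
  metrics from the desk run characterize the machinery, not clinical
  performance.
* The bidirectional LSTM and the word-route models are trained and
  evaluated here only at desk scale; paper-scale runs require GPU-class
  resources.
* No pretraining objectives (masked-LM / replaced-token detection) are
  implemented; the transformer trains from scratch.
* No probability calibration, ROC-threshold tuning, or weighted/stacked
  ensembling.
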