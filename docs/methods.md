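# Methods

## Generative model

A corpus is organised into T time slices (calendar years mapped to
contiguous indices in ascending order; empty years are dropped).  The model
has K topics represented as vectors α_k^t in the L-dimensional
word-embedding space, a word-embedding table ρ (L×V), and a per-slice prior
mean η_t (K) for topic-proportion logits.

* β_k^t = softmax(ρᵀ α_k^t) — topic–word distributions, rows strictly
  positive and summing to 1 (softmax is max-subtracted, so arbitrarily
  large embedding magnitudes do not overflow).
* α_k^t and η_t follow Gaussian random walks with scales γ and δ; slice 0
  is standard normal.  Both quantities are unconstrained, so the walks are
  plain Gaussians; the logistic (softmax) map appears only where a simplex
  is required (θ and β).
* θ_d = softmax(N(η_t, ε²I)) — logistic-normal document topic proportions;
  each token draws z ~ Cat(θ_d), w ~ Cat(β_z^t).

ε, δ, γ are scales (standard deviations), all strictly positive; defaults
0.01.  K and L have no universal default in the library; the CLI defaults
to K = 20 and L = 200 (the dimension of common pretrained biomedical
embedding releases).  ρ may be initialized from a whitespace-format
embedding table or randomly; it is trainable by default with a
`freeze_embeddings` flag.

## Inference and training

Per-document posteriors are amortized: a feed-forward network (two hidden
ReLU layers of width 256, dropout 0.1, softplus scale head with a 1e-6
floor) maps the concatenation of the normalized bag-of-words vector and
η_t to (μ_ν(d), σ_ν(d)); samples are softmax(μ + σ⊙noise)
(reparameterized; one Monte-Carlo sample per step by default).  The batch
ELBO is

    Σ_d Σ_w count·log(Σ_k θ_k β^t_{k,w} + 1e-10) − Σ_d KL(q_d ‖ N(η_t, ε²I)),

rescaled by N_t/|batch| so each step is an unbiased estimate of the
full-data objective; minibatches are drawn within a single slice so every
batch has a well-defined η_t.

α and η are treated as point-estimated (MAP) parameters: their random-walk
priors enter the objective as the quadratic dynamics penalty
Σ_t‖α_t−α_{t−1}‖²/(2γ²) + ‖α_0‖²/2 (plus the analogous η terms).  This is
the only treatment fully determined by the ELBO as written; a DETM-style
amortized posterior for η (a tanh recurrent network over per-slice mean
bag-of-words summaries, with a chained KL to the random-walk prior) is
available via `TrainConfig.eta_posterior = "amortized"`.

The minimized scalar is `(−ELBO) + dynamics penalty − λ₁·TD + λ₂·CE`.  The
topic-diversity term is the sum over slices and unordered topic pairs of
Euclidean embedding distances — written with the sign that *rewards*
spread, since minimizing a positive sum of distances would collapse topics,
the opposite of its stated purpose.  Restricting to unordered distinct
pairs (rather than all ordered pairs including i=j) changes the term by a
constant factor absorbed by λ₁.  CE is the batch-mean cross-entropy of a
one-hidden-layer (width 64, tanh) classifier head on the sampled θ;
averaging rather than summing over documents is likewise absorbed by λ₂.
Because the ELBO is a full-corpus sum (order 10⁵ nats at the test scale
used here) while TD is order 10, the diversity term is a weak nudge at
λ₁ = 1; this matches the objective as specified and is observable in the
ablation (the λ₁ = 1 runs never score lower TD, often tying).

Optimization is Adam (lr 1e-3 default, β = 0.9/0.999) with L2 weight decay
1.2e-6 ("small weight decay", value not prescribed anywhere; it only needs
to be small relative to the priors).  Gradients come from autograd over the
pure-numpy forward pass.  All randomness flows from one seed through named
substreams (init / shuffle / noise / dropout), so training is reproducible
bit for bit on a fixed machine; the per-epoch log records deterministic
full-data diagnostics (ELBO at the variational mean, KL, TD, CE) and, when
a validation corpus is supplied, a validation ELBO used to select the
returned checkpoint.

## Preprocessing

Tokens are lowercased (`[a-z][a-z0-9'-]*`), lemmatized by a pluggable
callable (identity by default, so no linguistic resources are required —
a WordNet lemmatizer can be passed where its data is available), and
filtered: stop words (small built-in English list, user-replaceable), words
in more than `max_df` = 80% of documents, words with corpus-wide count
below `min_count` = 10, then documents with fewer than `min_doc_len` = 10
surviving tokens.  Because dropping documents changes document frequencies,
the two filters are iterated to a fixpoint, which makes preprocessing
idempotent (one extra pass in practice).  The corpus-wide reading of the
minimum-count rule is deliberate: a per-document threshold of 10 would
empty realistic vocabularies.  Splits are per-slice (stratified by year)
with largest-remainder rounding, so exactly representable fractions are
honoured exactly; slices smaller than the number of parts go entirely to
training with a warning.

## Synthetic-data generator

`sample_corpus` runs the generative process forward and records every
latent (α, η, θ, per-token z, labels), enabling recovery tests against
known truth.  Labels come from a pluggable mechanism; the default draws a
fixed M×K Gaussian matrix W once per corpus and sets
`label = argmax(Wθ_d)` (a temperature softens this to a categorical draw),
so labels are a deterministic function of topic proportions and the
classification loss has learnable signal.  Document length is a constant
or a user sampler.

What the generator emulates: per-slice document counts, smoothly drifting
topics in embedding space, logistic-normal document heterogeneity and
labels correlated with topic proportions.  What it does not emulate: real
lexical semantics (words are exchangeable symbols, so coherence against a
reference corpus carries no meaning beyond its mathematical definition),
vocabulary burstiness, document-length variation, label noise or
slice-varying label sets.  Passing recovery tests therefore demonstrates
correctness of the inference machinery, not performance on real grant
text.

### Identifiability at small ε

With the default ε = 0.01 the document prior LN(η_t, ε²I) has logit
standard deviation 0.01, so every document in a slice has essentially the
same θ ≈ softmax(η_t).  Tokens are then iid draws from the single mixture
p_t = Σ_k θ_k β_k^t and the individual β_k are not identified by the data:
training reaches the likelihood of the true parameters to within ~0.02
nats/token while converging to a different decomposition of p_t.  The
recovery *control* therefore also runs the generator at ε = 1.0, where θ
varies across documents (per-coordinate std ≈ 0.1–0.25 on the simplex) and
the decomposition is identifiable; there the pipeline recovers
Hungarian-matched β at mean cosine ≈ 0.9 and per-document θ at cosine
≈ 0.98.  A related degeneracy at small ε and δ: the argmax label mechanism
makes labels nearly constant within (and across) slices, so classification
accuracies measured in that regime are trivially high.

## Evaluation

* Coherence: top-p words per topic (p = 10 by default; ties broken by
  probability then lexicographically) scored by the mean pairwise
  association over the p(p−1)/2 pairs — the standard unordered-pair
  convention; the "all ordered pairs including i=j" normalization differs
  only by a constant factor and does not affect rankings.  NPMI uses
  document-level co-occurrence with smoothing 1e-12; C_A uses the same NPMI
  confirmation on sliding context windows of width 5 (bag-of-words input
  expands each document in vocabulary order, since BOW carries no word
  order); C_P uses Fitelson's confirmation
  [P(j|i) − P(j|¬i)]/[P(j|i) + P(j|¬i)] of each word by every higher-ranked
  word on document-level counts.  The reference corpus is the training
  split; a dynamic model is scored on its time-averaged β unless a slice is
  requested.
* Topic diversity: distinct words among the K×p top words (p = 25 by
  default) divided by K·p; bounded by [1/K, 1].
* Perplexity: document completion — each test document's canonical token
  expansion is split by alternating positions, θ is the variational mean
  inferred from the first half, and the second half is scored;
  perplexity = exp(−log-lik / tokens).  Documents with fewer than two
  tokens are excluded and counted.  A whole-document variational-mean
  protocol is available via `protocol="bound"`.  The uniform model
  (all-zero α) scores exactly V under either protocol, which is used as an
  exact functional test.

## Downstream analyses

Word trends divide β^t_{k,w} by its value at a base slice (base value
exactly 1 by construction).  Topic hierarchies correlate (Pearson)
time-averaged topic vectors of two models; β space is the default because
independently trained models with fine-tuned ρ do not share an embedding
space — α-space comparison is offered for frozen-ρ models.  Classification
uses variational-mean θ features with a seeded random forest (any
`fit`/`predict_proba` estimator is pluggable); top-k accuracy is
non-decreasing in k by construction, and classes unseen in training count
as misses.  The 2-D embedding uses UMAP with a fixed `random_state`.

## Experiment sizes

The test suite and `scripts/acceptance.py` use a reference simulation of
K = 3 topics, V = 200 words, L = 16 dimensions, T = 4 slices, 500
documents of 60 tokens per slice (120k tokens), trained for 200 epochs
(full-slice batches); ablations use 40–60 epochs.  These sizes were chosen
so every statistic is estimated from thousands of documents while the full
suite completes in minutes on one CPU.

## Known limitations

* Training cost grows linearly with V through the dense β softmax; the
  implementation targets desk-scale corpora (V up to a few thousand), not
  the full 35k-word vocabulary of a national grant archive.
* The recurrent η posterior is a minimal tanh RNN, intended as an
  alternative treatment rather than a tuned component.
* No sparse-document streaming: slices are densified for training.
* Coherence on synthetic corpora is mathematically exercised but
  semantically meaningless (see the generator section).
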