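# Methods

## Task and model

Clinical relation extraction is cast as classification of candidate
entity pairs: every unordered pair of entity mentions in a sentence
whose types form one of seven admissible pair categories
(disease–position, symptom–position, test–disease, test–position,
test–symptom, treatment–disease, treatment–position) is an instance,
labeled with one of eleven relation categories (DAP, SAP, SNAP, TeRD,
TeAP, TeCP, TeRS, TeAS, TrAD, TrRD, TrAP) or the reserved `unknown`
("no relation"). Instances store the pair in the category's canonical
type order, so the classifier never sees mirrored duplicates.

The model is character-level. Each character c_i maps to

  x_i = [x_i^w ; x_i^p1 ; x_i^p2],   d_v = d_w + 2 d_p,

a trainable character embedding (d_w = 300 at published defaults,
initialized from skip-gram pretraining on all record text and
fine-tuned) concatenated with two position embeddings (d_p = 25)
indexed by the character's signed distance to the first character of
each target entity, clipped to [−p_max, p_max] and offset to be
non-negative; PAD positions have dedicated all-zero rows frozen at
zero.

Two encoders read the embedded sentence in parallel:

- **Residual convolutional stack.** A multi-window stem (windows 3/5/7,
  128 filters each, channel-concatenated → d_c = 384) followed by
  residual blocks, each holding two window-3 same-padded convolutions
  with ReLU after each and an identity shortcut,
  ĉ = ReLU(c_{l+1} + c). Depth counts convolutions: 1 stem + 2 per
  block; the default depth is 11 (5 blocks). No batch normalization,
  no projection shortcuts, no pooling (attention replaces pooling).
- **Stacked bidirectional GRU.** Standard gates
  z_t = σ(W_z[h_{t−1}, X_t] + b_z), r_t likewise,
  h̃_t = tanh(W_h[r_t ⊙ h_{t−1}, X_t] + b_h),
  h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t,
  with ⊙ the elementwise product. Three stacked bidirectional layers of
  512 units; per-position output is the stitched [→h_t ; ←h_t]
  (dimension 1024). The backward direction runs over the reversed
  unpadded prefix only, so padding never leaks into real states;
  outputs beyond the true length are zero.

Each branch is pooled by its own attention: scalar scores
u_i = tanh(w·H_i + b) over unmasked positions, softmax weights a
(masked positions get exactly zero), summary S = Σ a_i H_i. The two
summaries are fused by concatenation — their dimensions differ (384 vs
1024), which rules out the additive reading — giving a 1408-vector at
defaults, followed by dropout, a fully connected layer and softmax
over the r categories (the 11 relations + `unknown`; `unknown` is a
trainable class but is excluded from all reported metrics).

## Implementation

No deep-learning framework is available in the target environment, so
the network is implemented in NumPy with hand-written backward passes
for every layer (im2col convolutions, backpropagation through time for
the GRU, the masked-softmax attention Jacobian, embedding
scatter-adds). Gradient correctness is enforced by a finite-difference
check on a miniature end-to-end model: per parameter group, the
analytic gradient agrees with central differences to < 1e-4 relative
error in float64. The check runs at a generic point (biases perturbed
off zero) because zero-initialized biases leave PAD-region
preactivations exactly on the ReLU kink, where finite differences are
undefined. Word2vec pretraining is likewise a minimal NumPy skip-gram
with negative sampling (window 5, 10 epochs, 5 negatives,
unigram^0.75 negative table); the PAD row is zeroed.

Training minimizes mean cross-entropy with Adam. Published defaults
(batch 64, learning rate 0.015, dropout 0.5) are kept as `TrainConfig`
defaults; desk-scale synthetic runs use the documented fallback
learning rate 1e-3 — 0.015 is tuned for the authors' corpus scale and
diverges on small synthetic sets. Early stopping monitors held-out
micro-F1 (10% stratified split) with patience 5 (desk-scale pipelines
use longer schedules); the best checkpoint is chosen by validation
micro-F1 with validation loss breaking ties, because micro-F1 is
coarse on small validation splits and can sit at zero while the model
still improves. `TrainConfig.restarts` trains several independent runs
and keeps the best by validation: single runs on 200-instance sets are
high-variance (observed seed-to-seed micro-F1 spread 0.53–0.75).

## Bootstrapping

Self-training follows the accept/merge/retrain scheme: the current
model predicts the unlabeled pool U; instances with max-softmax
confidence strictly greater than λ = 0.7 move to the reliable buffer R
with their predicted label (at most N_r = 1000 per round, ranked by
confidence, ties broken by instance id); when |R| ≥ N_r the buffer
merges into the labeled set L and the model retrains from scratch on
the grown L. The loop ends when U empties, a round accepts nothing
(stall guard), or `max_rounds` is reached; a residual buffer is merged
with one final retrain. Pseudo-labels are frozen once merged. The
instance multiset is conserved across rounds and |U| is non-increasing
(both asserted at run time). A fixed held-out test set is created
before bootstrapping; re-splitting train/test inside the loop would
let pseudo-labeled items leak into evaluation. On synthetic fixtures
the unlabeled pool carries hidden true labels (never visible to
training, never serialized) from which each round's pseudo-label error
— the semantic-drift signal — is reported.

## Synthetic world

The generator emits symbolic sentences over a 60-symbol alphabet: 11
reserved trigger symbols (one per relation label), five disjoint
4-symbol blocks for entity surfaces (one per entity type), and neutral
filler. Each sentence holds 2–5 entities of *distinct* types at random
positions; for each admissible pair, with a category-mass-scaled
probability a relation is planted by writing the label's trigger —
three copies of its reserved symbol — strictly between the pair.
Unplanted admissible pairs are gold `unknown` (about
`unknown_fraction` = 0.6 of pairs). `noise_rate` corrupts exactly one
of the three trigger symbols, so the label stays recoverable from the
survivors.

Three design choices matter and are deliberate:

- **Type-recognizable surfaces.** Clinical mentions are recognizable
  from their form; with type-blind random surfaces, an `unknown` pair
  that happens to contain another pair's trigger between its entities
  is indistinguishable *from the text* from a true relation pair, and
  no classifier could beat ~0.62 micro-F1 for structural reasons.
- **Distinct types per sentence.** A planted trigger is then never
  admissible for any other pair in the sentence, which makes the
  trigger-matching oracle exact (micro-F1 = 1.0, the upper bound every
  model score is checked against) and keeps empirical label
  frequencies exactly proportional to `class_proportions` (verified by
  a chi-square audit at n ≥ 5000). The optional `nested` flag adds
  nested mentions and voids both guarantees.
- **Single-symbol corruption.** Noise perturbs trigger realizations
  without introducing label noise, so oracle exactness holds at any
  noise rate while the learning problem still gets harder.

A green test on this world establishes that the architecture can read
character identity, entity-type surface structure, and relative
position; it does not establish robustness to real clinical
vocabulary, nested or fuzzy entity boundaries, or annotation noise.

## Desk-scale pipelines

`pipelines.planted_recovery` restricts the world to four labels across
four distinct pair categories (SAP, TeRD, TrAD, DAP, proportions from
the annotated-corpus counts), downsamples `unknown` to ≤ 2× the
labeled count (the preprocessing default), and trains a reduced model
(d_w 32, d_p 8, window-3 depth-5 stack with 64 filters, one BiGRU
layer of 64 units) on 2000 instances, testing on 500.
`pipelines.bootstrap_study` self-trains a slightly wider variant
(96 filters / 96 hidden, dropout 0.25) from 200 seed instances over
2000 unlabeled with the default λ and N_r, after skip-gram pretraining
on all record text.

Reduced models clip positions at p_max = 16: position ids are
independent random embeddings per exact distance, so a small radius —
consistent with the motivation that only characters near the entities
are informative — collapses all far offsets onto the boundary id and
makes the tables learnable from hundreds rather than thousands of
instances.

## Known limitations

- Self-training shows genuine semantic drift at 200-seed scale: the
  first accepted batch is ~90–94% correct, but its errors concentrate
  on cluttered multi-entity sentences, the retrain learns them, and
  later rounds either confidently mislabel the hard residue (round
  drift ~0.3) or stall below λ with part of the pool unlabeled. This
  mirrors the published discussion of bootstrapping's drift problem
  and is reported per round by the drift hook rather than hidden.
- Published absolute scores are out of scope: they require the
  authors' 75k-sentence corpus and GPU-scale training.
- The skip-gram pretrainer is a reference implementation, not an
  optimized one; pretraining cost grows linearly with corpus size.
- `learning_rate` 0.015 (the published value) is kept as the default
  but is not appropriate for small synthetic corpora; use the 1e-3
  fallback there.
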