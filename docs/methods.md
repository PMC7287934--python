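# Methods

## Task and model

Single-step retrosynthesis is cast as sequence transduction: the source is
the tokenized SMILES of the target product (optionally preceded by a
`<RX_k>` reaction-class token), the target is the tokenized dot-joined
SMILES of the reactant set. Tokenization is longest-match with four token
classes — bracket atoms `[...]`, two-digit ring closures `%NN`, the
two-letter halogens `Br`/`Cl`, and single characters — the de-facto
standard for SMILES sequence models; concatenating tokens always
reproduces the source string exactly.

Two encoder-decoder cores share one training/decoding interface:

* **seq2seq.** The encoder is a stack of bidirectional LSTM layers (one
  cell reads the sequence forward, one backward; their hidden states are
  concatenated). PAD positions are excluded from state updates so the
  backward pass over a padded batch matches the unpadded sequence. The
  decoder is a unidirectional LSTM whose input concatenates the previous
  target embedding with an additive-attention context
  `score(s, h) = vᵀ tanh(W_q h + U_k s)` over the encoder states; the
  output layer mixes the decoder state and context through a tanh
  projection before the vocabulary logits. Decoder initial states are
  bridged from the masked mean of the encoder outputs.
* **transformer.** Sinusoidal position encodings; multi-head scaled
  dot-product attention with fused Q/K/V projection for self-attention;
  position-wise feed-forward (ReLU); residual connections applied
  *before* layer normalization (post-norm residual order); causally
  masked decoder self-attention plus encoder-decoder cross-attention. The
  reference-scale configuration uses six identical encoder and decoder
  layers; the output projection is tied to the token embedding.

Both cores run on `retroseq.nn`, a compact reverse-mode autodiff engine
over numpy arrays (tape-based, with fused softmax / layer-norm / masked
cross-entropy primitives and a no-grad inference mode). Incremental
decoding is numpy-only: the transformer keeps per-layer key/value caches,
the LSTM carries its recurrent state, so beam search costs O(T) decoder
steps rather than O(T²) prefix recomputation.

## Vocabulary and transfer

The token vocabulary is built once over the union of the pretraining and
fine-tuning corpora — reserved specials first (PAD=0, BOS, EOS, UNK), then
the ten class tokens when configured, then observed tokens sorted — and
frozen, so every weight shape is identical at pretrain and fine-tune time.
Transfer loads *all* pretrained weights (no layer freezing) and simply
continues training on the small corpus; a vocabulary or shape mismatch
raises rather than partially loading. The baseline arm differs from the
transfer arm only in initialization: same configuration, same data, same
step budget, same seeds.

## Training

Teacher-forced cross-entropy with PAD positions excluded; Adam
(β₁=0.9, β₂=0.98) with global-norm gradient clipping at 1.0. The
transformer uses linear warmup to the peak rate followed by inverse-sqrt
decay; the seq2seq default is a constant rate. Batches are length-bucketed
(a seeded shuffle stably sorted by coarse target length, with batch order
reshuffled) to cut padding waste. Every `eval_every` steps — and at step 0,
before any update — greedy top-1 accuracy on a validation subset is
recorded with the wall-clock time, producing the accuracy-versus-time
curves; the best-validation checkpoint (ties resolved toward the
further-trained weights, step-0 excluded) is restored at the end. Batch
order and dropout masks derive from the config seed per epoch/step, so
runs are bit-reproducible and resumable.

## Beam search and confidence

Decoding uses an absorbing-EOS beam: continuations are selected by
cumulative log-probability; a hypothesis that emits EOS moves to the
completed pool and frees its slot, so width 1 is exactly greedy decoding.
Completed hypotheses are ranked by mean per-token log-probability (EOS
included); the reported confidence is `exp(mean log-prob)`, a thresholdable
score in (0, 1] monotone in the ranking. Ties break by earlier completion
step, then lexicographic token order. If nothing completes within the
length limit the best unfinished hypotheses are returned flagged
incomplete, and an incomplete candidate never counts as a match.

## Matching and metrics

A prediction matches the ground truth iff the two multisets of
canonicalized dot-separated components are equal — invariant to reactant
order and alternative SMILES writings, but not to duplicate collapse.
Canonicalization is pluggable: RDKit (`toolkit`) for real corpora,
identity (`passthrough`) for the synthetic grammar, whose emitter is
canonical-by-construction. An unparseable *prediction* counts as a
non-match; an unparseable *ground truth* raises (corpus defect).

Contingency classification uses a strict "above" (score > threshold;
"below" is ≤), making TP/FN/FP/TN exhaustive and disjoint. When no
threshold is given, the F1-maximizing threshold over the evaluated
predictions is chosen and recorded. Fractions are computed in exact
rational arithmetic from the integer counts before conversion to float.

## Synthetic reaction grammar

Each of the ten reaction classes is one deterministic, invertible string
rewrite over a pool of branched-alkyl fragments (e.g. ester → acid +
alcohol; biaryl → aryl bromide + boronic acid; Boc-amine ↔ free amine for
protection/deprotection; ketone ↔ alcohol for oxidation/reduction). The
emitted strings are valid, RDKit-parseable SMILES and deliberately exercise
ring-closure digits, branches, a bracket stereocentre (`[C@H]`) and
multi-character halogen tokens. Because fragment pools are pure-carbon and
each template's marker substring is unique, (fragment-pair → product) is
injective per class and product patterns are disjoint across classes, so
every (product, reactant-set) key is unique and the product→reactants map
is a function — the grammar is exactly learnable in principle.

Defaults: 20 000 large-pool and 2 000 small-pool reactions (a 10:1 ratio,
mirroring the ~380K/50K structure of the patent corpora at desk scale);
small-pool class counts multinomial in the classified patent set's
proportions (30.3, 23.8, 11.3, 1.8, 1.3, 16.5, 9.2, 1.6, 3.7, 0.5 percent
for classes 1–10); fragment pool of 120 (shortest-first enumeration);
novelty fraction 0.2, realized as withholding the two rarest classes
(protection and FGA) from the pretraining pool so fine-tuning contains
genuinely novel reaction types. Large-pool class counts follow the same
proportions renormalized over the eight shared classes. Per-class
fragment-pair combinations are permuted once per seed and sliced
disjointly for the two pools, which guarantees uniqueness within and
across corpora without rejection sampling.

What the grammar does *not* emulate: mechanism or reagent chemistry,
stereochemical consequences of reactions, yield/condition metadata, the
heavy-tailed molecule-size distribution of patent data, and corpus noise
(duplicates and malformed records occur in tests only via hand-built
fixtures). A passing transfer experiment therefore shows that the
*pipeline* — preprocessing, weight transfer, decoding, scoring — behaves
as described, and that pretraining transfers on a corpus with this
statistical shape; it does not certify accuracy numbers on real patent
corpora.

## Desk-scale experiment configuration

The default experiment (`ExperimentPlan()`) uses the tiny transformer
preset: model_dim 64, 4 heads, ff_dim 128, 2 encoder and 2 decoder layers,
tied embeddings, dropout 0 (the grammar is deterministic, so
regularization only slows convergence at this scale; the reference-scale
default keeps dropout 0.1), peak learning rate 2·10⁻³ with 200-step
warmup then inverse-sqrt decay, batch 64. Budgets: 2 000 pretraining
steps, 300 fine-tuning steps per arm, three seeds, beam width 20 (so
top-20 is always defined), 200 test products scored per arm. Problem
sizes were chosen so the full experiment runs in roughly a quarter of an
hour on one CPU core. With these budgets pretraining reaches >90%
held-out top-1 on the large pool, the transfer arm starts fine-tuning
near that level while the baseline starts at zero, and the transfer arm's
mean test top-1 ends far above the baseline's — the desk-scale analogue
of the published comparison. Fine-tuning runs without class tokens by
default: the pretraining pool is unclassified, and a token-free
comparison isolates the effect of weight transfer; both modes are
supported and the plan records the choice.

## Numerical and design notes

* Weights are float32; exact reproducibility holds for a fixed BLAS.
* The 8:1:1 split is a seeded uniform shuffle cut at ⌊0.8n⌋ and ⌊0.9n⌋
  (not class-stratified).
* Duplicate and cross-corpus overlap keys are canonical
  (product-set, reactant-set) pairs, so re-written duplicates cannot leak
  across the pretrain/test boundary.
* Degenerate metric denominators (e.g. TP+FP=0) return 0 with a
  `degenerate` flag instead of failing.
* Beam-search candidate selection is by cumulative log-probability while
  the final ranking is length-normalized; like all practical beams this
  can miss a longer sequence whose normalized score would rank higher
  than a shorter completed one when the beam is narrow.
* `max_sequence_length` (96 at desk scale, 200 at reference scale) bounds
  both the position-encoding table and decode length; decoding past it
  raises rather than extrapolating.

## Known limitations

* The numpy engine is single-threaded per op and desk-scale by design;
  reference-scale corpora would need days, not minutes.
* Beam search processes one product at a time (the beam itself is the
  batch); evaluation cost grows linearly in test-set size.
* The F1-maximizing default threshold is chosen on the evaluated
  predictions themselves; for honest generalization claims pass a
  threshold selected on a validation split.
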