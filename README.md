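# retroseq

Transfer-learning retrosynthesis on SMILES sequence models.

## The problem

Single-step retrosynthesis asks: given a target product, which reactant set
could produce it? Treating molecules as SMILES strings turns this into a
translation task — the model reads the product SMILES and emits the
reactant-set SMILES. Data-driven retrosynthesis models trained only on a
small curated corpus (tens of thousands of reactions) plateau at modest
accuracy; pretraining the same encoder-decoder on a large uncurated reaction
pool and then fine-tuning on the small corpus transfers general "chemical
language" skills (valence patterns, ring closures, chirality tokens,
common disconnections) and lifts accuracy from the very first fine-tuning
step.

`retroseq` implements that pipeline end to end for two encoder-decoder
cores:

* **seq2seq** — bidirectional-LSTM encoder, LSTM decoder with additive
  (Bahdanau) attention;
* **transformer** — multi-head self-attention encoder/decoder with
  position-wise feed-forward blocks, post-norm residual connections and a
  causally masked decoder (six identical decoder layers at reference
  scale).

Both are built on the package's own compact numpy autodiff engine
(`retroseq.nn`), train with teacher-forced cross-entropy, and decode with a
length-normalized beam search whose per-candidate confidence is
`exp(mean token log-probability)` ∈ (0, 1].

Because the patent-mined corpora behind the published experiments are far
too large for a desk machine, the package ships a synthetic reaction
grammar (`retroseq.synth`): ten string-rewrite disconnection templates, one
per standard reaction class (heteroatom alkylation, acylation, C–C bond
formation, heterocycle formation, protection, deprotection, reduction,
oxidation, FGI, FGA), emitting RDKit-valid SMILES with the class
proportions of the classified 50K patent set. A large unclassified pool
and a small classified pool are generated with zero overlap, and two rare
classes are withheld from pretraining to emulate the corpus mismatch.

## Core statistics

For ranked predictions the package computes, exactly as defined in the
retrosynthesis literature:

* **top-N accuracy** — fraction of test products whose ground-truth
  reactant set (as a multiset of canonicalized molecules) matches one of
  the first N candidates;
* the confidence-thresholded **contingency table** (match & above
  threshold → TP, match & below → FN, non-match & above → FP, non-match &
  below → TN);
* `precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`,
  `F1 = 2PR/(P+R)`, `accuracy = (TP+TN)/N`, and
  **delta-accuracy** `= accuracy − [(TP+FN)(TP+FP)+(TN+FN)(TN+FP)]/N²`
  (accuracy minus the chance agreement of the table's marginals).

## Worked example

```python
>>> from retroseq.evaluation import ContingencyTable, precision_recall_f1, delta_accuracy, accuracy
>>> t = ContingencyTable(tp=2021, fp=776, fn=1191, tn=1016, threshold=0.5)
>>> p, r, f1, _ = precision_recall_f1(t)
>>> round(100 * f1, 1), round(100 * accuracy(t), 1), round(100 * delta_accuracy(t), 1)
(67.3, 60.7, 9.0)
```

These are the published top-1 contingency counts of a transformer after
transfer learning on the 5004-reaction patent test set: an F1 of 67.3%, a
top-1 accuracy of 60.7%, and a delta-accuracy of 9.0% (the model is nine
points better than the chance agreement its own marginals would produce).

Running the full synthetic transfer experiment from the shell:

```sh
retroseq experiment --seed 0 --outdir experiment/
```

generates the default corpora (20 000 pretraining / 2 000 fine-tuning
reactions), pretrains a tiny transformer, fine-tunes a transfer arm and a
matched fresh-initialization baseline arm for three seeds, and writes
`report.json`, a `topn_table.tsv` mirroring the published table layout,
and per-arm accuracy-versus-time curves. On this grammar the transfer arm
is already accurate at fine-tune step 0 while the baseline starts at zero,
and its mean test top-1 ends far above the baseline's (see
`docs/methods.md` for the exact configuration).

Other subcommands: `simulate` (corpora only), `prepare` (preprocess a raw
`reactants>reagents>products` corpus into 8:1:1 split token files),
`pretrain`, `finetune`, `predict`, `evaluate`.

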