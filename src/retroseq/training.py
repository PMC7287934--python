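"""Teacher-forced training loop with periodic greedy validation.

Training minimizes token-level cross-entropy on teacher-forced decoder
inputs, with PAD positions excluded from the loss. Every ``eval_every``
steps (and at step 0, before any update) a greedy top-1 accuracy is
computed on a validation subset and appended to the history together with
the wall-clock time, which is what the accuracy-versus-training-time curves
are drawn from. The best-validation weights are retained and restored at
the end of the run.

Batch order and dropout masks are derived per-epoch / per-step from the
config seed, so a run is reproducible and an interrupted run can be resumed
to the same trajectory by passing the optimizer and start step back in.
"""

from __future__ import annotations

import time
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import SeqPair
from .nn import Adam, cross_entropy_logits, no_grad
from .smiles import detokenize, reactant_set_match
from .vocab import TokenVocabulary

__all__ = ["encode_pairs", "train", "greedy_decode", "greedy_top1"]


def encode_pairs(pairs: Sequence[SeqPair], vocab: TokenVocabulary) -> Tuple[list, list, int]:
    """Encode pairs to index lists; returns (sources, targets, n_unk)."""
    sources, targets, n_unk = [], [], 0
    for p in pairs:
        s = vocab.encode(p.source)
        t = vocab.encode(p.target)
        n_unk += s.count(vocab.unk_id) + t.count(vocab.unk_id)
        sources.append(s)
        targets.append(t)
    return sources, targets, n_unk


def _pad_batch(seqs: List[List[int]], pad: int = 0) -> np.ndarray:
    width = max(len(s) for s in seqs)
    out = np.full((len(seqs), width), pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def _batch_loss(model, src: np.ndarray, tgt_in: np.ndarray, tgt_out: np.ndarray):
    logits = model.forward_teacher(src, tgt_in, train=True)
    B, T, V = logits.shape
    weights = (tgt_out != 0).astype(np.float32).reshape(-1)
    return cross_entropy_logits(logits.reshape(B * T, V), tgt_out.reshape(-1), weights)


def train(
    model,
    train_pairs: Sequence[SeqPair],
    valid_pairs: Sequence[SeqPair],
    optimizer: Optional[Adam] = None,
    start_step: int = 0,
    restore_best: bool = True,
    log=None,
) -> Tuple[List[dict], Adam]:
    """Train in place; returns (history, optimizer) for resumption.

    History entries are ``{"step", "wall_seconds", "train_loss",
    "valid_top1"}``; the step-0 entry records the untrained validation
    accuracy with ``train_loss=None``.
    """
    cfg = model.config
    if not train_pairs:
        raise ValueError("empty training set")
    vocab = model.vocab
    sources, targets, n_unk = encode_pairs(train_pairs, vocab)
    if n_unk and log:
        log(f"UNK substitutions in training encoding: {n_unk}")
    valid_sub = list(valid_pairs)[: cfg.eval_subset]

    if optimizer is None:
        optimizer = Adam(
            model.params,
            lr=cfg.learning_rate,
            grad_clip=cfg.grad_clip,
            schedule=cfg.schedule,
            warmup_steps=cfg.warmup_steps,
        )
        optimizer.t = start_step

    history: List[dict] = []
    t0 = time.perf_counter()
    best = (-1.0, None)

    def evaluate(step: int, loss_val):
        nonlocal best
        top1 = greedy_top1(model, valid_sub) if valid_sub else 0.0
        # strictly increasing wall clock even on very fast evaluations
        wall = time.perf_counter() - t0 + 1e-6 * len(history)
        history.append(
            {"step": step, "wall_seconds": wall, "train_loss": loss_val, "valid_top1": top1}
        )
        # best checkpoint among post-update evaluations; ties prefer the
        # later (further-trained) weights
        if step > 0 and top1 >= best[0]:
            best = (top1, model.state_dict())
        if log:
            log(f"step {step}: loss={loss_val} valid_top1={top1:.3f}")

    n = len(sources)
    step = start_step
    if step == 0:
        evaluate(0, None)
    last_loss = None
    epoch = start_step * cfg.batch_size // max(n, 1)  # resume near the right epoch
    while step < cfg.max_steps:
        rng_epoch = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101, epoch]))
        perm = rng_epoch.permutation(n)
        # length-bucketed batches (stable sort keeps the shuffle within a
        # bucket) so that padding waste stays low; batch order is shuffled
        lens = np.array([len(targets[i]) for i in perm])
        perm = perm[np.argsort(lens // 8, kind="stable")]
        batches = [perm[lo : lo + cfg.batch_size] for lo in range(0, n, cfg.batch_size)]
        for b in rng_epoch.permutation(len(batches)):
            if step >= cfg.max_steps:
                break
            idx = batches[b]
            src = _pad_batch([sources[i] for i in idx])
            tgt_in = _pad_batch([[vocab.bos_id] + targets[i] for i in idx])
            tgt_out = _pad_batch([targets[i] + [vocab.eos_id] for i in idx])
            model._dropout_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 103, step])
            )
            loss = _batch_loss(model, src, tgt_in, tgt_out)
            last_loss = float(loss.data)
            if not np.isfinite(last_loss):
                raise RuntimeError(
                    f"non-finite training loss at step {step}: {last_loss} "
                    f"(lr={optimizer._rate():.2e}, batch={len(idx)})"
                )
            for p in model.params.values():
                p.grad = None
            loss.backward()
            optimizer.step()
            optimizer.zero_grad()
            step += 1
            if cfg.eval_every and step % cfg.eval_every == 0:
                evaluate(step, last_loss)
        epoch += 1
    if not history or history[-1]["step"] != step:
        evaluate(step, last_loss)
    if restore_best and best[1] is not None:
        model.load_state_dict(best[1])
    return history, optimizer


def greedy_decode(
    model, sources: Sequence[Sequence[str]], max_len: Optional[int] = None, batch_size: int = 128
) -> List[List[str]]:
    """Batched greedy decoding; returns predicted token lists (specials stripped)."""
    vocab = model.vocab
    max_len = max_len or model.config.decode_max_len
    out: List[List[str]] = []
    for lo in range(0, len(sources), batch_size):
        chunk = sources[lo : lo + batch_size]
        src = _pad_batch([vocab.encode(s) for s in chunk])
        B = src.shape[0]
        with no_grad():
            memory = model.encode(src, train=False)
        state = model.init_state(memory)
        prev = np.full(B, vocab.bos_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        tokens: List[List[int]] = [[] for _ in range(B)]
        for _ in range(max_len):
            logp = model.step(state, prev)
            nxt = logp.argmax(axis=-1)
            nxt = np.where(done, vocab.pad_id, nxt)
            for i in range(B):
                if not done[i]:
                    if nxt[i] == vocab.eos_id:
                        done[i] = True
                    else:
                        tokens[i].append(int(nxt[i]))
            if done.all():
                break
            prev = nxt
        out.extend(vocab.decode(t) for t in tokens)
    return out


def greedy_top1(model, pairs: Sequence[SeqPair], batch_size: int = 128) -> float:
    """Greedy top-1 accuracy under the model's configured match backend."""
    if not pairs:
        return 0.0
    preds = greedy_decode(model, [p.source for p in pairs], batch_size=batch_size)
    backend = model.config.eval_backend
    hits = 0
    for pred, pair in zip(preds, pairs):
        truth = detokenize(list(pair.target))
        cand = detokenize(pred)
        if cand and reactant_set_match(cand, truth, backend=backend):
            hits += 1
    return hits / len(pairs)
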