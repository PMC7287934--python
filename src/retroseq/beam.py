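"""Length-normalized beam search producing ranked reactant candidates.

The beam selects continuations by cumulative log-probability; a hypothesis
that emits EOS is absorbed into the completed pool and frees its slot, so
the search ends when every slot has completed (or ``max_len`` is reached).
Completed hypotheses are finally ranked by mean per-token log-probability
(EOS included), and the reported confidence is ``exp(mean log-prob)``,
which lies in (0, 1] and is monotone in the ranking score. Ties are broken
by earlier completion step, then by lexicographic token order. With
``beam_width=1`` the procedure is exactly greedy decoding.

If no hypothesis emits EOS within ``max_len`` steps the best unfinished
hypotheses are returned flagged incomplete; an incomplete candidate is
never counted as a match downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import no_grad
from .smiles import detokenize
from .training import _pad_batch

__all__ = ["Candidate", "RankedPrediction", "beam_search", "predict", "write_predictions_tsv"]


@dataclass(frozen=True)
class Candidate:
    smiles: str
    confidence: float
    complete: bool = True


@dataclass
class RankedPrediction:
    """Ordered candidate reactant sets for one source (product) sequence."""

    source: Tuple[str, ...]
    candidates: List[Candidate] = field(default_factory=list)

    def top(self, n: int) -> List[Candidate]:
        return self.candidates[:n]


def beam_search(model, source: Sequence[str], beam_width: int = 20, max_len: Optional[int] = None) -> RankedPrediction:
    """Decode one source sequence with a fixed-width beam.

    Returns at most ``beam_width`` candidates with non-increasing
    confidence.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    vocab = model.vocab
    max_len = max_len or model.config.decode_max_len
    V = len(vocab)

    src = _pad_batch([vocab.encode(source)])
    with no_grad():
        memory = model.encode(src, train=False)
    state = model.init_state(memory)

    prev = np.full(1, vocab.bos_id, dtype=np.int64)
    sums = np.zeros(1, dtype=np.float64)
    lengths = np.zeros(1, dtype=np.int64)
    beam_tokens: List[List[int]] = [[]]
    slots = beam_width  # live slots; completion absorbs one slot each
    # completed: (mean_logprob, completion_step, token_ids)
    completed: List[Tuple[float, int, Tuple[int, ...]]] = []

    for t in range(1, max_len + 1):
        logp = model.step(state, prev).astype(np.float64)  # (live,V)
        flat = (sums[:, None] + logp).reshape(-1)
        n_take = min(slots, flat.size)
        top = np.argpartition(-flat, n_take - 1)[:n_take] if n_take < flat.size else np.arange(flat.size)
        top = top[np.argsort(-flat[top], kind="stable")][:n_take]
        new_live: List[Tuple[int, int, float]] = []  # (parent, token, sum)
        for f in top:
            if not np.isfinite(flat[f]):
                continue
            b, tok = divmod(int(f), V)
            if tok == vocab.eos_id:
                completed.append((flat[f] / (lengths[b] + 1), t, tuple(beam_tokens[b])))
                slots -= 1
            else:
                new_live.append((b, tok, flat[f]))
        new_live = new_live[:slots]
        if slots <= 0 or not new_live:
            break
        back = np.array([b for b, _, _ in new_live], dtype=np.int64)
        state = model.reorder_state(state, back)
        prev = np.array([tok for _, tok, _ in new_live], dtype=np.int64)
        sums = np.array([s for _, _, s in new_live], dtype=np.float64)
        lengths = lengths[back] + 1
        beam_tokens = [beam_tokens[b] + [tok] for b, tok, _ in new_live]

    completed.sort(key=lambda c: (-c[0], c[1], c[2]))
    candidates = [
        Candidate(
            smiles=detokenize(vocab.decode(tokens)),
            confidence=float(np.exp(mean)),
            complete=True,
        )
        for mean, _, tokens in completed[:beam_width]
    ]
    if not candidates:
        # nothing finished within max_len: report best unfinished hypotheses
        means = sums / np.maximum(lengths, 1)
        for b in np.argsort(-means, kind="stable")[:beam_width]:
            if not np.isfinite(sums[b]):
                continue
            candidates.append(
                Candidate(
                    smiles=detokenize(vocab.decode(beam_tokens[b])),
                    confidence=float(np.exp(means[b])),
                    complete=False,
                )
            )
    return RankedPrediction(source=tuple(source), candidates=candidates)


def predict(
    model,
    sources: Sequence[Sequence[str]],
    beam_width: int = 20,
    max_len: Optional[int] = None,
    progress=None,
) -> List[RankedPrediction]:
    """Beam-search every source; returns one RankedPrediction per source."""
    out = []
    for i, s in enumerate(sources):
        out.append(beam_search(model, s, beam_width=beam_width, max_len=max_len))
        if progress and (i + 1) % 50 == 0:
            progress(i + 1, len(sources))
    return out


def write_predictions_tsv(predictions: Sequence[RankedPrediction], path) -> None:
    """TSV: source, rank, candidate SMILES, confidence, complete flag."""
    from pathlib import Path

    lines = ["source\trank\tcandidate\tconfidence\tcomplete"]
    for p in predictions:
        src = detokenize(list(p.source))
        for rank, c in enumerate(p.candidates, start=1):
            lines.append(f"{src}\t{rank}\t{c.smiles}\t{c.confidence:.6g}\t{int(c.complete)}")
    Path(path).write_text("\n".join(lines) + "\n")
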