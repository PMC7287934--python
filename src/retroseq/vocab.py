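"""Token vocabulary shared between pretraining and fine-tuning.

The vocabulary is built once over the union of the pretraining and
fine-tuning corpora and then frozen: weight matrices are shaped by it, so
rebuilding it at fine-tune time would make pretrained weights
untransferable. Index layout is deterministic — reserved specials first
(PAD is always 0), then the ten reaction-class tokens when configured, then
all observed tokens in lexicographic order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Sequence

from .data import Corpus, N_CLASSES, class_token, to_seq_pairs

__all__ = ["TokenVocabulary", "build_vocabulary"]

PAD, BOS, EOS, UNK = "<PAD>", "<BOS>", "<EOS>", "<UNK>"
RESERVED = (PAD, BOS, EOS, UNK)


class TokenVocabulary:
    def __init__(self, tokens: Sequence[str]):
        if tuple(tokens[: len(RESERVED)]) != RESERVED:
            raise ValueError("vocabulary must start with the reserved tokens")
        self.tokens: List[str] = list(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    # PAD must be 0 so that zero-padding batches is also index-padding.
    pad_id = 0
    bos_id = 1
    eos_id = 2
    unk_id = 3

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        return isinstance(other, TokenVocabulary) and self.tokens == other.tokens

    def encode(self, tokens: Iterable[str]) -> List[int]:
        """Map tokens to indices, substituting UNK for unknown tokens."""
        return [self.index.get(t, self.unk_id) for t in tokens]

    def decode(self, ids: Iterable[int], strip_special: bool = True) -> List[str]:
        out = []
        for i in ids:
            t = self.tokens[i]
            if strip_special and t in RESERVED:
                continue
            out.append(t)
        return out

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps({"tokens": self.tokens}, indent=0) + "\n")

    @classmethod
    def load(cls, path: Path | str) -> "TokenVocabulary":
        return cls(json.loads(Path(path).read_text())["tokens"])


def build_vocabulary(corpora: Sequence[Corpus], use_class_token: bool = False) -> TokenVocabulary:
    """Build the frozen union vocabulary over one or more corpora.

    Class tokens get indices immediately after the reserved block when
    requested, whether or not every corpus is classified (the pretraining
    pool is not, but the embedding rows must exist for fine-tuning).
    """
    if not corpora:
        raise ValueError("need at least one corpus")
    observed = set()
    for corpus in corpora:
        for pair in to_seq_pairs(corpus, use_class_token=False):
            observed.update(pair.source)
            observed.update(pair.target)
    tokens = list(RESERVED)
    if use_class_token:
        tokens.extend(class_token(k) for k in range(1, N_CLASSES + 1))
    tokens.extend(sorted(observed - set(tokens)))
    return TokenVocabulary(tokens)
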