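"""Reaction-corpus preprocessing: parsing, filtering, splitting, pairing.

The pipeline mirrors how patent-mined reaction corpora are prepared for
retrosynthesis models: reagents are stripped (only reactants and products are
kept), duplicate/incomplete/erroneous records are filtered as noise, any
record of the large pretraining pool that also occurs in the small
fine-tuning pool is removed, each corpus is split 8:1:1 into
train/validation/test, and finally reactions are turned into
(product -> reactant-set) token-sequence pairs, optionally with a reaction
class token prepended to the source.

Line format: one reaction per line, ``reactants>reagents>products`` with an
optional tab-separated integer class label; lines starting with ``#`` are
comments. Duplicate and overlap detection use the canonical
(product-set, reactant-set) key so that the same reaction written with a
different atom order cannot leak across the pretrain/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .smiles import CanonicalizationError, canonicalize, tokenize_smiles

__all__ = [
    "Reaction",
    "Corpus",
    "SplitCorpus",
    "SeqPair",
    "FilterReport",
    "parse_reaction_line",
    "read_corpus",
    "write_corpus",
    "strip_reagents",
    "filter_noise",
    "remove_overlap",
    "split_8_1_1",
    "to_seq_pairs",
    "write_seq_pairs",
]

N_CLASSES = 10


class ReactionParseError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    """One reaction record: reactant/reagent/product SMILES lists.

    ``class_label`` (1-10), when present, identifies the reaction class of a
    classified corpus; ``source_id`` is an opaque provenance tag.
    """

    reactants: Tuple[str, ...]
    reagents: Tuple[str, ...]
    products: Tuple[str, ...]
    class_label: Optional[int] = None
    source_id: str = ""

    def to_line(self) -> str:
        line = ">".join(
            ".".join(side) for side in (self.reactants, self.reagents, self.products)
        )
        if self.class_label is not None:
            line += f"\t{self.class_label}"
        return line


@dataclass
class Corpus:
    reactions: List[Reaction]
    name: str = ""
    classified: bool = False

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)


@dataclass
class SplitCorpus:
    train: Corpus
    valid: Corpus
    test: Corpus


@dataclass(frozen=True)
class SeqPair:
    """A model-ready example: source = product tokens, target = reactant tokens."""

    source: Tuple[str, ...]
    target: Tuple[str, ...]
    class_label: Optional[int] = None


@dataclass
class FilterReport:
    duplicates: int = 0
    incomplete: int = 0
    erroneous: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "duplicates": self.duplicates,
            "incomplete": self.incomplete,
            "erroneous": self.erroneous,
        }


def parse_reaction_line(line: str, line_number: int = 0) -> Reaction:
    """Parse one ``reactants>reagents>products[\\t class]`` line."""
    body, _, label_field = line.rstrip("\n").partition("\t")
    fields = body.split(">")
    if len(fields) != 3:
        raise ReactionParseError(
            f"line {line_number}: expected 'reactants>reagents>products' "
            f"(3 '>'-separated fields), got {len(fields)}"
        )
    sides = tuple(tuple(p for p in f.split(".") if p) for f in fields)
    label: Optional[int] = None
    if label_field.strip():
        label = int(label_field.strip())
        if not 1 <= label <= N_CLASSES:
            raise ReactionParseError(
                f"line {line_number}: class label {label} outside 1..{N_CLASSES}"
            )
    return Reaction(
        reactants=sides[0],
        reagents=sides[1],
        products=sides[2],
        class_label=label,
        source_id=f"line{line_number}" if line_number else "",
    )


def read_corpus(path: Path | str, name: str = "") -> Corpus:
    """Read a reaction corpus from text; ``#`` lines are comments."""
    path = Path(path)
    reactions = []
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        reactions.append(parse_reaction_line(raw, line_number=i))
    classified = bool(reactions) and all(r.class_label is not None for r in reactions)
    return Corpus(reactions, name=name or path.stem, classified=classified)


def write_corpus(corpus: Corpus, path: Path | str, header: str = "") -> None:
    path = Path(path)
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(r.to_line() for r in corpus.reactions)
    path.write_text("\n".join(lines) + "\n")


def strip_reagents(reaction: Reaction) -> Reaction:
    """Drop the reagent field, keeping reactants and products untouched."""
    if not reaction.reagents:
        return reaction
    return replace(reaction, reagents=())


def canonical_key(reaction: Reaction, backend: str) -> Tuple[tuple, tuple]:
    """Canonical (product-set, reactant-set) identity key of a reaction."""
    prod = tuple(sorted(canonicalize(s, backend=backend) for s in reaction.products))
    reac = tuple(sorted(canonicalize(s, backend=backend) for s in reaction.reactants))
    return prod, reac


def filter_noise(corpus: Corpus, backend: str = "toolkit") -> Tuple[Corpus, FilterReport]:
    """Remove duplicate, incomplete and erroneous reactions.

    Incomplete records have an empty reactant or product side; erroneous
    records fail canonicalization on any molecule under the active backend;
    duplicates share a canonical (product-set, reactant-set) key with an
    earlier record (first occurrence wins). Returns the cleaned corpus and a
    per-category count report.
    """
    report = FilterReport()
    seen = set()
    kept: List[Reaction] = []
    for r in corpus.reactions:
        if not r.reactants or not r.products:
            report.incomplete += 1
            continue
        try:
            key = canonical_key(r, backend)
        except CanonicalizationError:
            report.erroneous += 1
            continue
        if key in seen:
            report.duplicates += 1
            continue
        seen.add(key)
        kept.append(r)
    return Corpus(kept, name=corpus.name, classified=corpus.classified), report


def remove_overlap(large: Corpus, small: Corpus, backend: str = "toolkit") -> Corpus:
    """Drop from ``large`` every reaction whose canonical key occurs in ``small``."""
    small_keys = {canonical_key(r, backend) for r in small.reactions}
    kept = [r for r in large.reactions if canonical_key(r, backend) not in small_keys]
    return Corpus(kept, name=large.name, classified=large.classified)


def split_8_1_1(corpus: Corpus, seed: int) -> SplitCorpus:
    """Seeded uniform shuffle, then 8:1:1 contiguous cut.

    Train gets ``floor(0.8 n)``; the cut points are ``floor(0.8 n)`` and
    ``floor(0.9 n)``, so the remainder is divided as evenly as possible
    between validation and test.
    """
    n = len(corpus)
    if n < 10:
        raise ValueError(f"corpus too small to split 8:1:1: n={n} < 10")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [corpus.reactions[i] for i in order]
    n_train = int(np.floor(0.8 * n))
    n_valid = int(np.floor(0.9 * n)) - n_train
    parts = (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_valid],
        shuffled[n_train + n_valid :],
    )
    mk = lambda rs, tag: Corpus(list(rs), name=f"{corpus.name}-{tag}", classified=corpus.classified)
    return SplitCorpus(mk(parts[0], "train"), mk(parts[1], "valid"), mk(parts[2], "test"))


def class_token(label: int) -> str:
    return f"<RX_{label}>"


def to_seq_pairs(corpus: Corpus, use_class_token: bool = False) -> List[SeqPair]:
    """Convert reactions to retrosynthesis-direction sequence pairs.

    Source = tokenized dot-joined product SMILES, optionally preceded by the
    single class token ``<RX_k>``; target = tokenized dot-joined reactant
    SMILES. Reactions must already be reagent-free.
    """
    if use_class_token and not corpus.classified:
        raise ValueError("use_class_token requires a classified corpus")
    pairs = []
    for r in corpus.reactions:
        if r.reagents:
            raise ValueError("to_seq_pairs requires reagent-free reactions; run strip_reagents")
        src = tuple(tokenize_smiles(".".join(r.products)))
        if use_class_token:
            src = (class_token(r.class_label),) + src
        tgt = tuple(tokenize_smiles(".".join(r.reactants)))
        pairs.append(SeqPair(source=src, target=tgt, class_label=r.class_label))
    return pairs


def write_seq_pairs(pairs: Iterable[SeqPair], src_path: Path | str, tgt_path: Path | str) -> None:
    """Write aligned space-separated token files (one sequence per line)."""
    src_lines, tgt_lines = [], []
    for p in pairs:
        src_lines.append(" ".join(p.source))
        tgt_lines.append(" ".join(p.target))
    Path(src_path).write_text("\n".join(src_lines) + "\n")
    Path(tgt_path).write_text("\n".join(tgt_lines) + "\n")


def write_report(report: FilterReport, path: Path | str, extra: Optional[dict] = None) -> None:
    payload = dict(report.as_dict())
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
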