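"""Synthetic reaction grammar: desk-scale surrogate corpora.

Patent-mined reaction corpora are far too large to train against in tests,
so this module generates surrogate corpora with the same *statistical
structure*: a large unclassified pretraining pool and a small pool labelled
with the ten standard retrosynthesis reaction classes (heteroatom
alkylation/arylation, acylation, C-C bond formation, heterocycle formation,
protection, deprotection, reduction, oxidation, FGI, FGA) in the class
proportions observed in the classified 50K patent set.

Each class is one deterministic string-rewrite disconnection template over
a pool of alkyl fragments, e.g. ester -> acid + alcohol for acylation or
biaryl -> aryl halide + boronic acid for C-C bond formation. The emitted
strings are valid SMILES (they parse under RDKit) and include ring-closure
digits, branches, a bracket stereocentre and multi-character halogen
tokens, so they exercise the same token classes as real corpora. Because
every product string is produced by exactly one (template, fragment-pair)
combination, the emitter is canonical-by-construction and corpora are
matched exactly under the pass-through canonicalization backend.

A configurable fraction of the ten classes (by default the two rarest) is
withheld from the pretraining pool, emulating the mismatch between an
unclassified pretraining corpus and a classified fine-tuning corpus; the
(product, reactant-set) keys of the two pools are disjoint by
construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .data import Corpus, Reaction

__all__ = [
    "ReactionTemplate",
    "GeneratorConfig",
    "TABLE_CLASS_PROPORTIONS",
    "CLASS_NAMES",
    "build_fragment_pool",
    "build_template_roster",
    "generate_corpora",
]

# Class shares of the classified 50K patent corpus (percent / 100).
TABLE_CLASS_PROPORTIONS: Tuple[float, ...] = (
    0.303, 0.238, 0.113, 0.018, 0.013, 0.165, 0.092, 0.016, 0.037, 0.005
)

CLASS_NAMES: Dict[int, str] = {
    1: "heteroatom alkylation and arylation",
    2: "acylation and related processes",
    3: "C-C bond formation",
    4: "heterocycle formation",
    5: "protection",
    6: "deprotection",
    7: "reduction",
    8: "oxidation",
    9: "functional group interconversion (FGI)",
    10: "functional group addition (FGA)",
}

_BOC_ANHYDRIDE = "CC(C)(C)OC(=O)OC(=O)OC(C)(C)C"
_BOC = "C(=O)OC(C)(C)C"


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReactionTemplate:
    """One reaction class as an invertible string rewrite.

    ``assemble(a, b)`` builds the product SMILES from two fragment strings;
    ``disconnect(product)`` recovers the reactant SMILES list from the
    product alone (the retrosynthetic rewrite rule).
    """

    class_label: int
    class_name: str
    assemble: Callable[[str, str], str]
    disconnect: Callable[[str], List[str]]


def _split_once(product: str, marker: str, label: int) -> Tuple[str, str]:
    i = product.find(marker)
    if i < 0:
        raise ValueError(f"class {label}: product {product!r} lacks marker {marker!r}")
    return product[:i], product[i + len(marker):]


def build_template_roster() -> List[ReactionTemplate]:
    """The ten disconnection templates, one per reaction class."""

    def t(label, assemble, disconnect):
        return ReactionTemplate(label, CLASS_NAMES[label], assemble, disconnect)

    def d1(p):  # ether -> alkyl bromide + alcohol
        a, b = _split_once(p, "O", 1)
        return [a + "Br", b + "O"]

    def d2(p):  # ester -> acid + alcohol
        a, b = _split_once(p, "C(=O)O", 2)
        return [a + "C(=O)O", b + "O"]

    def d3(p):  # biaryl chain -> aryl bromide + boronic acid
        a, b = _split_once(p, "c1ccc(", 3)
        b = b[: -len(")cc1")]
        return [a + "c1ccc(Br)cc1", b + "B(O)O"]

    def d4(p):  # saturated O-heterocycle -> open-chain halo-alcohol
        a, b = _split_once(p, "C1CCC(", 4)
        b = b[: -len(")O1")]
        return [a + "C(O)CCC(" + b + ")Br"]

    def d5(p):  # Boc-protected amine -> free amine + Boc anhydride
        a, b = _split_once(p, "N(", 5)
        b = b[: -len(")" + _BOC)]
        return [a + "N" + b, _BOC_ANHYDRIDE]

    def d6(p):  # free secondary amine -> Boc-protected amine
        a, b = _split_once(p, "N", 6)
        return [a + "N(" + b + ")" + _BOC]

    def d7(p):  # stereo alcohol -> ketone
        a, b = _split_once(p, "[C@H](O)", 7)
        return [a + "C(=O)" + b]

    def d8(p):  # ketone -> alcohol
        a, b = _split_once(p, "C(=O)", 8)
        return [a + "C(O)" + b]

    def d9(p):  # alkyne -> dibromoalkene
        a, b = _split_once(p, "C#C", 9)
        return [a + "C(Br)=C(Br)" + b]

    def d10(p):  # alkyl chloride -> alcohol
        a, b = _split_once(p, "C(Cl)", 10)
        return [a + "C(O)" + b]

    return [
        t(1, lambda a, b: f"{a}O{b}", d1),
        t(2, lambda a, b: f"{a}C(=O)O{b}", d2),
        t(3, lambda a, b: f"{a}c1ccc({b})cc1", d3),
        t(4, lambda a, b: f"{a}C1CCC({b})O1", d4),
        t(5, lambda a, b: f"{a}N({b}){_BOC}", d5),
        t(6, lambda a, b: f"{a}N{b}", d6),
        t(7, lambda a, b: f"{a}[C@H](O){b}", d7),
        t(8, lambda a, b: f"{a}C(=O){b}", d8),
        t(9, lambda a, b: f"{a}C#C{b}", d9),
        t(10, lambda a, b: f"{a}C(Cl){b}", d10),
    ]


def build_fragment_pool(size: int) -> List[str]:
    """Deterministic pool of branched-alkyl fragment SMILES.

    Fragments are carbon chains with an optional methyl/ethyl branch at each
    interior position, enumerated shortest-first; both the first and the
    last atom keep an open valence, so a fragment can sit on either side of
    a template's functional group.
    """
    candidates = set()
    for length in range(1, 9):
        interior = max(length - 2, 0)
        for branches in itertools.product(("", "(C)", "(CC)"), repeat=interior):
            s = "C"
            for b in branches:
                s += "C" + b
            if length >= 2:
                s += "C"
            candidates.add(s)
    pool = sorted(candidates, key=lambda s: (len(s), s))
    if len(pool) < size:
        raise GenerationError(f"cannot build {size} fragments; increase enumeration depth")
    return pool[:size]


@dataclass
class GeneratorConfig:
    """Corpus-generation settings.

    Defaults emulate the patent-corpus structure at desk scale: a
    10:1 large/small ratio, class proportions from the classified patent
    set, and one-fifth of the classes (the two rarest) withheld from
    pretraining.
    """

    n_large: int = 20000
    n_small: int = 2000
    class_proportions: Tuple[float, ...] = TABLE_CLASS_PROPORTIONS
    fragment_pool_size: int = 120
    novelty_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_large <= 0 or self.n_small <= 0:
            raise ValueError("corpus sizes must be positive")
        if len(self.class_proportions) != 10:
            raise ValueError("need exactly 10 class proportions")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 <= self.novelty_fraction < 1.0:
            raise ValueError("novelty_fraction must be in [0, 1)")

    def withheld_classes(self) -> List[int]:
        """Classes absent from pretraining: the rarest ones by proportion."""
        k = int(round(self.novelty_fraction * 10))
        order = sorted(range(10), key=lambda i: (self.class_proportions[i], i))
        return sorted(order[i] + 1 for i in range(k))


def generate_corpora(cfg: GeneratorConfig) -> Tuple[Corpus, Corpus]:
    """Generate the (large unclassified, small classified) corpus pair.

    Small-corpus class counts are multinomial in ``class_proportions``; the
    large corpus draws from the non-withheld templates with proportions
    renormalized over them. Every (product, reactant-set) key is unique
    within and across the two corpora, byte-reproducibly for a given seed.
    """
    roster = {t.class_label: t for t in build_template_roster()}
    fragments = build_fragment_pool(cfg.fragment_pool_size)
    withheld = set(cfg.withheld_classes())
    props = np.asarray(cfg.class_proportions, dtype=np.float64)

    rng_counts = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    small_counts = rng_counts.multinomial(cfg.n_small, props / props.sum())
    shared = [c for c in range(1, 11) if c not in withheld]
    shared_props = np.array([props[c - 1] for c in shared])
    large_shared = rng_counts.multinomial(cfg.n_large, shared_props / shared_props.sum())
    large_counts = np.zeros(10, dtype=np.int64)
    for c, k in zip(shared, large_shared):
        large_counts[c - 1] = k

    large_rx: List[Reaction] = []
    small_rx: List[Reaction] = []
    for label in range(1, 11):
        template = roster[label]
        need = int(large_counts[label - 1] + small_counts[label - 1])
        combos = list(itertools.product(fragments, fragments))
        if need > len(combos):
            raise GenerationError(
                f"class {label}: need {need} unique reactions but the fragment pool "
                f"yields only {len(combos)} combinations; increase fragment_pool_size"
            )
        rng_cls = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, label]))
        order = rng_cls.permutation(len(combos))
        take = [combos[i] for i in order[:need]]
        n_l = int(large_counts[label - 1])
        for j, (a, b) in enumerate(take):
            product = template.assemble(a, b)
            reactants = tuple(template.disconnect(product))
            if j < n_l:
                large_rx.append(
                    Reaction(reactants=reactants, reagents=(), products=(product,),
                             source_id=f"large-{label}-{j}")
                )
            else:
                small_rx.append(
                    Reaction(reactants=reactants, reagents=(), products=(product,),
                             class_label=label, source_id=f"small-{label}-{j - n_l}")
                )

    rng_shuffle = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    large_rx = [large_rx[i] for i in rng_shuffle.permutation(len(large_rx))]
    small_rx = [small_rx[i] for i in rng_shuffle.permutation(len(small_rx))]
    large = Corpus(large_rx, name="synthetic-large", classified=False)
    small = Corpus(small_rx, name="synthetic-small", classified=True)
    return large, small
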