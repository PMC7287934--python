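"""SMILES tokenization, canonicalization and reactant-set matching.

SMILES strings are the model's "language": a retrosynthesis model translates
the product SMILES into the reactant-set SMILES. Everything downstream
(vocabulary construction, sequence batching, accuracy scoring) is defined in
terms of the token sequences and canonical forms produced here.

Tokenization is character-level with three multi-character classes treated as
single tokens: bracket atoms ``[...]`` (which carry charge, isotope and
stereo annotations), two-digit ring closures ``%NN``, and the two-letter
organic-subset halogens ``Br``/``Cl``. This is the de-facto standard
tokenization for SMILES sequence models.

Canonicalization is pluggable. The ``toolkit`` backend delegates to RDKit and
maps every writing of a molecule to one representative string; the
``passthrough`` backend is the identity and is appropriate for corpora whose
emitter is canonical-by-construction (the synthetic reaction grammar in
:mod:`retroseq.synth`).
"""

from __future__ import annotations

import re
from typing import List

__all__ = [
    "TokenizationError",
    "CanonicalizationError",
    "tokenize_smiles",
    "detokenize",
    "canonicalize",
    "reactant_set_match",
]


class TokenizationError(ValueError):
    """Raised for malformed SMILES input (e.g. an unclosed bracket atom)."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class CanonicalizationError(ValueError):
    """Raised when a SMILES string cannot be parsed by the active backend."""


# Longest-match-first token classes: bracket atom, %NN ring closure,
# two-letter halogens, then any single character.
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|%\d\d|Br|Cl|.)")


def tokenize_smiles(smiles: str) -> List[str]:
    """Split a SMILES string into model tokens.

    The token list partitions the input: ``"".join(tokens) == smiles``.

    Parameters
    ----------
    smiles
        Non-empty SMILES string without whitespace.

    Raises
    ------
    TokenizationError
        If the string is empty, contains whitespace, or has an unclosed
        bracket atom; the error reports the character offset.
    """
    if not smiles:
        raise TokenizationError("empty SMILES", 0)
    ws = re.search(r"\s", smiles)
    if ws:
        raise TokenizationError("whitespace in SMILES", ws.start())
    open_bracket = None
    depth = 0
    for i, ch in enumerate(smiles):
        if ch == "[":
            if depth:
                raise TokenizationError("nested '[' in bracket atom", i)
            depth, open_bracket = 1, i
        elif ch == "]":
            if not depth:
                raise TokenizationError("unmatched ']'", i)
            depth = 0
    if depth:
        raise TokenizationError("unclosed bracket atom", open_bracket)
    return _TOKEN_RE.findall(smiles)


def detokenize(tokens: List[str]) -> str:
    """Concatenate a token sequence back into the source string."""
    return "".join(tokens)


def canonicalize(smiles: str, backend: str = "toolkit") -> str:
    """Map a molecule SMILES to its canonical representative.

    ``backend="toolkit"`` uses RDKit's canonical SMILES writer so that two
    writings of the same molecule (``OCC`` and ``CCO``) collapse to one
    string. ``backend="passthrough"`` returns the input unchanged and is
    meant for corpora that are canonical-by-construction. Both backends are
    idempotent.

    Raises
    ------
    CanonicalizationError
        If the toolkit backend cannot parse the string.
    ValueError
        For an unknown backend name.
    """
    if backend == "passthrough":
        return smiles
    if backend != "toolkit":
        raise ValueError(f"unknown canonicalization backend: {backend!r}")
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise CanonicalizationError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _canonical_multiset(multi_smiles: str, backend: str) -> tuple:
    parts = [p for p in multi_smiles.split(".") if p]
    return tuple(sorted(canonicalize(p, backend=backend) for p in parts))


def reactant_set_match(predicted: str, truth: str, backend: str = "toolkit") -> bool:
    """Decide whether a predicted reactant set matches the ground truth.

    Both arguments are dot-separated multi-molecule SMILES. The match is the
    equality of the two *multisets* of canonicalized components, so it is
    invariant to reactant order and to alternative writings of a molecule,
    but not to duplicate collapse (``CCO`` does not match ``CCO.CCO``).

    A prediction that fails canonicalization can never match and yields
    ``False``; a ground truth that fails canonicalization is a corpus defect
    and raises :class:`CanonicalizationError`.
    """
    truth_key = _canonical_multiset(truth, backend)  # raises on corpus defect
    try:
        pred_key = _canonical_multiset(predicted, backend)
    except CanonicalizationError:
        return False
    return pred_key == truth_key
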