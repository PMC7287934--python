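"""Corpus parsing, noise filtering, overlap removal and splitting."""

import numpy as np
import pytest

from conftest import make_corpus
from retroseq.data import (
    Corpus,
    Reaction,
    ReactionParseError,
    filter_noise,
    parse_reaction_line,
    read_corpus,
    remove_overlap,
    split_8_1_1,
    strip_reagents,
    to_seq_pairs,
    write_corpus,
    canonical_key,
)


def test_parse_reaction_line_fields():
    r = parse_reaction_line("CCO.CC(=O)O>>CC(=O)OCC")
    assert r.reactants == ("CCO", "CC(=O)O")
    assert r.reagents == ()
    assert r.products == ("CC(=O)OCC",)
    r = parse_reaction_line("CCBr>[Na+]>CCO\t3")
    assert r.reagents == ("[Na+]",)
    assert r.class_label == 3


def test_parse_reaction_line_errors():
    with pytest.raises(ReactionParseError):
        parse_reaction_line("CCO>CC", line_number=4)
    with pytest.raises(ReactionParseError):
        parse_reaction_line("CCO>>CC\t42")  # label outside 1..10


def test_strip_reagents_idempotent():
    r = parse_reaction_line("CCBr>[Na+]>CCO")
    s = strip_reagents(r)
    assert s.reagents == () and s.reactants == r.reactants and s.products == r.products
    assert strip_reagents(s) == s


def test_filter_noise_categories():
    corpus = make_corpus(
        [
            "CCO.CC(=O)O>>CC(=O)OCC",
            "CC(=O)O.CCO>>CC(=O)OCC",  # duplicate under canonical key
            ">>CCO",  # incomplete: empty reactant side
            "((((>>CCO",  # erroneous under the toolkit backend
            "CCBr>>CCO",
        ]
    )
    clean, report = filter_noise(corpus, backend="toolkit")
    assert len(clean) == 2
    assert report.as_dict() == {"duplicates": 1, "incomplete": 1, "erroneous": 1}
    # idempotence
    clean2, report2 = filter_noise(clean, backend="toolkit")
    assert len(clean2) == 2
    assert report2.as_dict() == {"duplicates": 0, "incomplete": 0, "erroneous": 0}


def test_remove_overlap_canonical(tiny_large, tiny_small):
    # total overlap and no overlap
    assert len(remove_overlap(tiny_small, tiny_small, backend="passthrough")) == 0
    kept = remove_overlap(tiny_large, tiny_small, backend="passthrough")
    assert len(kept) == len(tiny_large)  # generator guarantees disjoint pools
    # a shared reaction written with different atom order is still dropped
    large = make_corpus(["OCC>>CCBr", "CCCO>>CCCBr"])
    small = make_corpus(["CCO>>CCBr"])
    out = remove_overlap(large, small, backend="toolkit")
    assert [r.products for r in out] == [("CCCBr",)]
    keys = {canonical_key(r, "toolkit") for r in out}
    assert not keys & {canonical_key(r, "toolkit") for r in small}


def test_split_8_1_1_sizes_and_determinism(tiny_large):
    split = split_8_1_1(tiny_large, seed=5)
    n = len(tiny_large)
    assert len(split.train) == int(np.floor(0.8 * n))
    assert len(split.train) + len(split.valid) + len(split.test) == n
    assert abs(len(split.valid) - len(split.test)) <= 1
    again = split_8_1_1(tiny_large, seed=5)
    assert [r.source_id for r in split.train] == [r.source_id for r in again.train]
    other = split_8_1_1(tiny_large, seed=6)
    assert [r.source_id for r in split.train] != [r.source_id for r in other.train]
    # partition: union of ids equals input ids
    ids = sorted(r.source_id for part in (split.train, split.valid, split.test) for r in part)
    assert ids == sorted(r.source_id for r in tiny_large)


def test_split_exact_ratio_n10():
    corpus = make_corpus([f"CC{'C' * i}O>>CC{'C' * i}Br" for i in range(10)])
    split = split_8_1_1(corpus, seed=0)
    assert (len(split.train), len(split.valid), len(split.test)) == (8, 1, 1)
    with pytest.raises(ValueError):
        split_8_1_1(make_corpus(["CCO>>CCBr"]), seed=0)


def test_to_seq_pairs_direction_and_class_token(tiny_small):
    pairs = to_seq_pairs(tiny_small, use_class_token=True)
    for pair, r in zip(pairs, tiny_small):
        assert pair.source[0] == f"<RX_{r.class_label}>"
        assert "".join(pair.source[1:]) == ".".join(r.products)
        assert "".join(pair.target) == ".".join(r.reactants)
    plain = to_seq_pairs(tiny_small, use_class_token=False)
    assert all(not p.source[0].startswith("<RX_") for p in plain)


def test_to_seq_pairs_guards(tiny_large):
    with pytest.raises(ValueError):
        to_seq_pairs(tiny_large, use_class_token=True)  # unclassified corpus
    corpus = make_corpus(["CCBr>[Na+]>CCO"])
    with pytest.raises(ValueError):
        to_seq_pairs(corpus)  # reagents not stripped


def test_corpus_io_roundtrip(tmp_path, tiny_small):
    path = tmp_path / "small.txt"
    write_corpus(tiny_small, path, header="seed=11")
    back = read_corpus(path)
    assert back.classified
    assert [r.to_line() for r in back] == [r.to_line() for r in tiny_small]
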