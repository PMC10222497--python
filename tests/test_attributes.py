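"""Tokenizer and attribute-extraction behaviour."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semicorr.attributes import (
    AttributeKey,
    Dialect,
    SmilesParseError,
    extract_attributes,
    profile_smiles,
    tokenize,
)
from semicorr.descriptor import build_vocabulary

# hand-enumerated token oracle: (smiles, expected tokens)
HAND_TOKENIZED = [
    ("C=O", ["C", "=", "O"]),
    ("", []),
    ("C%11", ["C", "%11"]),
    ("ClCCl", ["Cl", "C", "Cl"]),
    ("BrBr", ["Br", "Br"]),
    ("CCO", ["C", "C", "O"]),
    ("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"]),
    ("CC(=O)N", ["C", "C", "(", "=", "O", ")", "N"]),
    ("[N+](=O)[O-]", ["[N+]", "(", "=", "O", ")", "[O-]"]),
    ("C[C@@H](N)C", ["C", "[C@@H]", "(", "N", ")", "C"]),
    ("C@@C", ["C", "@@", "C"]),
    ("O=S(=O)(N)c1ccc(Cl)cc1", ["O", "=", "S", "(", "=", "O", ")", "(", "N", ")",
                                "c", "1", "c", "c", "c", "(", "Cl", ")", "c", "c", "1"]),
    ("C%12%34C", ["C", "%12", "%34", "C"]),
    ("[Cu]", ["[Cu]"]),
    ("N#CC#N", ["N", "#", "C", "C", "#", "N"]),
    ("CC1=CC(Br)=CC=C1", ["C", "C", "1", "=", "C", "C", "(", "Br", ")",
                          "=", "C", "C", "=", "C", "1"]),
    ("C/C=C/C", ["C", "/", "C", "=", "C", "/", "C"]),
    ("c1ccc2ccccc2c1", ["c", "1", "c", "c", "c", "2", "c", "c", "c", "c", "c", "2", "c", "1"]),
    ("[nH]1cccc1", ["[nH]", "1", "c", "c", "c", "c", "1"]),
    ("ClC(Cl)(Cl)Cl", ["Cl", "C", "(", "Cl", ")", "(", "Cl", ")", "Cl"]),
]


@pytest.mark.parametrize("smiles,expected", HAND_TOKENIZED, ids=[s or "empty" for s, _ in HAND_TOKENIZED])
def test_tokenize_hand_oracle(smiles, expected):
    assert tokenize(smiles) == expected


@pytest.mark.parametrize("smiles,expected", HAND_TOKENIZED)
def test_tokenize_round_trip(smiles, expected):
    assert "".join(tokenize(smiles)) == smiles


_token = st.sampled_from(
    ["C", "c", "N", "O", "S", "Cl", "Br", "=", "#", "(", ")", "1", "2", "%11", "%99", "[N+]", "[nH]", "@@"]
)


@settings(derandomize=True, max_examples=200)
@given(st.lists(_token, max_size=30))
def test_tokenize_inverts_concatenation(tokens):
    """Concatenating dialect tokens and re-tokenizing recovers the sequence."""
    assert tokenize("".join(tokens)) == tokens


@pytest.mark.parametrize(
    "bad,pos",
    [("C[NO", 1), ("C%1", 1), ("%aa", 0), ("C O", 1), ("C\tO", 1)],
)
def test_tokenize_rejects_bad_input_with_position(bad, pos):
    with pytest.raises(SmilesParseError) as exc:
        tokenize(bad)
    assert exc.value.position == pos


def test_dialect_is_configurable():
    plain = Dialect(multi_char_tokens=(), bracket_blocks=False, percent_ring_bonds=False)
    assert tokenize("ClC", plain) == ["C", "l", "C"]


@settings(derandomize=True, max_examples=100)
@given(st.lists(_token, min_size=3, max_size=25))
def test_window_count_identity(tokens):
    """m atoms yield m S, m-1 SS and m-2 SSS attributes with multiplicity."""
    prof = extract_attributes(tokens)
    m = len(tokens)
    by_kind = Counter()
    for key, mult in prof.items():
        by_kind[key.kind] += mult
    assert by_kind["S"] == m
    assert by_kind["SS"] == m - 1
    assert by_kind["SSS"] == m - 2


@settings(derandomize=True, max_examples=100)
@given(st.lists(_token, min_size=1, max_size=25))
def test_canonical_symmetry_under_reversal(tokens):
    """Pair/triple keys are direction-free: a reversed atom sequence gives
    identical SS/SSS multisets."""
    fwd = extract_attributes(tokens)
    rev = extract_attributes(tokens[::-1])
    assert fwd == rev


def test_extract_single_atom():
    prof = extract_attributes(["C"])
    assert prof == Counter({AttributeKey.make(["C"]): 1})


def test_extract_enumerated_windows():
    prof = extract_attributes(["C", "=", "O"])
    expected = Counter(
        {
            AttributeKey.make(["C"]): 1,
            AttributeKey.make(["="]): 1,
            AttributeKey.make(["O"]): 1,
            AttributeKey.make(["C", "="]): 1,
            AttributeKey.make(["=", "O"]): 1,
            AttributeKey.make(["C", "=", "O"]): 1,
        }
    )
    assert prof == expected


def test_extract_repeated_atoms_multiplicity():
    prof = extract_attributes(["C", "C", "C", "C"])
    assert prof[AttributeKey.make(["C"])] == 4
    assert prof[AttributeKey.make(["C", "C"])] == 3
    assert prof[AttributeKey.make(["C", "C", "C"])] == 2


class TestVocabulary:
    def test_threshold_semantics(self):
        profiles = [profile_smiles(s) for s in ["CCO", "CCN", "CCC"]]
        t1 = build_vocabulary(profiles, T=1)
        key_o = AttributeKey.make(["O"])
        key_c = AttributeKey.make(["C"])
        assert not t1.entries[key_c].rare  # in 3 compounds
        assert not t1.entries[key_o].rare  # in 1 compound, T=1
        t2 = build_vocabulary(profiles, T=2)
        assert t2.entries[key_o].rare
        assert t2.entries[key_o].cw == 0.0

    def test_document_frequency_not_occurrence(self):
        # 'C' occurs 4 times in one compound but in only 1 document
        t = build_vocabulary([profile_smiles("CCCC")], T=2)
        key_c = AttributeKey.make(["C"])
        assert t.entries[key_c].document_frequency == 1
        assert t.entries[key_c].rare

    @pytest.mark.parametrize("smiles_set", [["CCO", "CNO", "CCS", "OCO", "C=O"]])
    def test_monotone_shrinkage(self, smiles_set):
        """The non-rare set at T+1 is a subset of the non-rare set at T."""
        profiles = [profile_smiles(s) for s in smiles_set]
        prev = None
        for T in (1, 2, 3):
            nr = set(build_vocabulary(profiles, T).non_rare_keys())
            if prev is not None:
                assert nr <= prev
            prev = nr

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([], T=1)
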