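"""SMILES tokenization and attribute extraction.

The descriptor machinery treats a SMILES line purely as a symbol sequence:
a "SMILES atom" is one indivisible token — a single printable character, or
a group that cannot be examined separately (a two-letter element symbol such
as ``Cl``, a bracket atom block ``[N+]``, a two-digit ring-bond escape
``%11``, or the chirality mark ``@@``). Attributes are the single tokens
(S), adjacent pairs (SS), and adjacent triples (SSS) of a compound's token
sequence; pairs and triples are canonicalized so that the same fragment read
in either direction maps to one key.

No chemistry is perceived here: strings are not canonicalized, hydrogens are
not expanded, and validity (valence, aromaticity) is never checked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Dialect",
    "DEFAULT_DIALECT",
    "SmilesParseError",
    "AttributeKey",
    "tokenize",
    "extract_attributes",
    "profile_smiles",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized.

    Carries the zero-based ``position`` of the offending character.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class Dialect:
    """Token table of the lexer.

    The token inventory is configurable so that alternative dialects of the
    descriptor literature can be swapped in; the default keeps bracket-atom
    blocks whole, recognises the two-letter organic-subset halogens and the
    ``@@`` chirality mark, and treats ``%NN`` ring-bond escapes as single
    tokens. Everything else is one character.
    """

    multi_char_tokens: tuple[str, ...] = ("Cl", "Br", "@@")
    bracket_blocks: bool = True
    percent_ring_bonds: bool = True

    def __post_init__(self):
        # longest-match-first resolution order
        object.__setattr__(
            self,
            "_by_length",
            tuple(sorted(self.multi_char_tokens, key=len, reverse=True)),
        )


DEFAULT_DIALECT = Dialect()

_KINDS = {1: "S", 2: "SS", 3: "SSS"}


class AttributeKey(NamedTuple):
    """One SMILES attribute: a canonical run of 1 (S), 2 (SS) or 3 (SSS) atoms."""

    kind: str
    atoms: tuple[str, ...]

    @classmethod
    def make(cls, atoms: Sequence[str]) -> "AttributeKey":
        """Build the canonical key for a run of adjacent atoms.

        The run and its reverse map to the same key (the lexicographically
        smaller tuple is stored), so fragment direction never double-counts.
        """
        atoms = tuple(atoms)
        if len(atoms) not in _KINDS:
            raise ValueError(f"attribute must have 1-3 atoms, got {len(atoms)}")
        rev = atoms[::-1]
        return cls(_KINDS[len(atoms)], min(atoms, rev))

    @property
    def token(self) -> str:
        """Display encoding; '·' joins atoms (never a printable-ASCII SMILES char)."""
        return "·".join(self.atoms)


def _is_plain_char(c: str) -> bool:
    return " " < c <= "~"  # printable ASCII, excluding space


def tokenize(smiles: str, dialect: Dialect = DEFAULT_DIALECT) -> list[str]:
    """Split a SMILES string into its ordered list of SMILES atoms.

    The concatenation of the returned tokens always equals the input.
    An empty string yields an empty list (a degenerate compound, not an
    error); an unrecognized character raises :class:`SmilesParseError`
    naming its position.
    """
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if dialect.bracket_blocks and c == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesParseError("unclosed bracket atom", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if dialect.percent_ring_bonds and c == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError("'%' must be followed by two digits", i)
            tokens.append(smiles[i : i + 3])
            i += 3
            continue
        for tok in dialect._by_length:  # type: ignore[attr-defined]
            if smiles.startswith(tok, i):
                tokens.append(tok)
                i += len(tok)
                break
        else:
            if not _is_plain_char(c):
                raise SmilesParseError(f"unrecognized character {c!r}", i)
            tokens.append(c)
            i += 1
    return tokens


def extract_attributes(atoms: Sequence[str]) -> Counter:
    """Extract the S/SS/SSS attribute multiset of a token sequence.

    Every token yields an S key, every adjacent pair an SS key and every
    adjacent triple an SSS key, with multiplicities; for ``m`` atoms the
    totals are ``m``, ``max(m-1, 0)`` and ``max(m-2, 0)``.
    """
    profile: Counter = Counter()
    m = len(atoms)
    for k in range(m):
        profile[AttributeKey.make(atoms[k : k + 1])] += 1
    for k in range(m - 1):
        profile[AttributeKey.make(atoms[k : k + 2])] += 1
    for k in range(m - 2):
        profile[AttributeKey.make(atoms[k : k + 3])] += 1
    return profile


def profile_smiles(smiles: str, dialect: Dialect = DEFAULT_DIALECT) -> Counter:
    """Tokenize and extract in one step."""
    return extract_attributes(tokenize(smiles, dialect))
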