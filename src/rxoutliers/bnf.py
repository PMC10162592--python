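"""Pseudo-BNF code parsing and analysis scope.

The public English prescribing extract classifies every dispensed product
with a *pseudo-BNF* code: an uppercase alphanumeric string of 8-15
characters organised as a positional hierarchy.  The levels used here:

======================  ==========================================
characters              level
======================  ==========================================
1-2                     chapter (body system, ``01``-``23``)
1-7                     subparagraph (drug class, e.g. quinolones)
1-9                     chemical (active ingredient / INN)
1-15                    presentation (product, strength, form)
======================  ==========================================

The outlier statistic compares a chemical's items against its
subparagraph's items, so these two prefixes define the whole analysis.
Only chapters 1-15 follow the chemical/subparagraph structure (later
chapters cover dressings, appliances and other non-medicinal products)
and the analysis scope is restricted accordingly.
"""

from __future__ import annotations

import logging
import re
from typing import NamedTuple

import pandas as pd

log = logging.getLogger(__name__)

CHAPTER_MIN = 1
CHAPTER_MAX = 23
#: chapters with a chemical/subparagraph structure; the analysis scope
SCOPE_CHAPTERS = frozenset(range(1, 16))

SUBPARAGRAPH_LEN = 7
CHEMICAL_LEN = 9

_CODE_RE = re.compile(r"^[0-9A-Z]{8,15}$")


class BNFCodeError(ValueError):
    """A malformed pseudo-BNF code; the message names the offending code."""


class ChemicalKey(NamedTuple):
    """A chemical (active-ingredient) grouping: 9-character code + name."""

    chemical_code: str
    name: str


class SubparagraphKey(NamedTuple):
    """A drug-class grouping: 7-character code + name (e.g. "Quinolones")."""

    subparagraph_code: str
    name: str


def validate_code(code: str) -> str:
    """Check pseudo-BNF well-formedness and return the code unchanged.

    Raises :class:`BNFCodeError` for anything that is not 8-15 uppercase
    alphanumeric characters starting with a two-digit chapter in 01-23.
    """
    if not isinstance(code, str) or _CODE_RE.match(code) is None:
        raise BNFCodeError(
            f"malformed BNF code {code!r}: expected 8-15 uppercase "
            "alphanumeric characters"
        )
    if not code[:2].isdigit():
        raise BNFCodeError(
            f"malformed BNF code {code!r}: first two characters must be the "
            "chapter digits"
        )
    chapter = int(code[:2])
    if not CHAPTER_MIN <= chapter <= CHAPTER_MAX:
        raise BNFCodeError(
            f"malformed BNF code {code!r}: chapter {chapter:02d} outside "
            f"{CHAPTER_MIN:02d}-{CHAPTER_MAX:02d}"
        )
    return code


def chapter_of(code: str) -> int:
    """BNF chapter number (1-23) parsed from the first two characters."""
    validate_code(code)
    return int(code[:2])


def chemical_code_of(code: str) -> str:
    """Collapse a code to its 9-character chemical prefix.

    Presentation-level codes (15 characters) collapse to the chemical that
    contains them.  Codes shorter than 9 characters carry no chemical and
    are rejected: the extract occasionally prints 8-character groupings
    and we refuse to guess a padding rule for them.
    """
    validate_code(code)
    if len(code) < CHEMICAL_LEN:
        log.warning("rejecting %r: too short for a chemical code", code)
        raise BNFCodeError(
            f"malformed BNF code {code!r}: {len(code)} characters is too "
            f"short for a chemical code (need >= {CHEMICAL_LEN})"
        )
    return code[:CHEMICAL_LEN]


def subparagraph_of(chemical_code: str) -> str:
    """7-character subparagraph (drug class) prefix of a chemical code."""
    validate_code(chemical_code)
    if len(chemical_code) < CHEMICAL_LEN:
        raise BNFCodeError(
            f"malformed chemical code {chemical_code!r}: need >= "
            f"{CHEMICAL_LEN} characters"
        )
    return chemical_code[:SUBPARAGRAPH_LEN]


def in_scope(code: str) -> bool:
    """True iff the code's chapter is in the analysis scope (1-15)."""
    return chapter_of(code) in SCOPE_CHAPTERS


_LOOKUP_COLUMNS = (
    "chemical_code",
    "chemical_name",
    "subparagraph_code",
    "subparagraph_name",
)


def load_name_lookup(source) -> pd.DataFrame:
    """Load a chemical/subparagraph name lookup table.

    ``source`` is a CSV path or a DataFrame with columns
    ``chemical_code, chemical_name, subparagraph_code, subparagraph_name``.
    Each chemical code must extend its subparagraph code as a prefix.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    missing = [c for c in _LOOKUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"name lookup is missing columns: {missing}")
    df = df.loc[:, list(_LOOKUP_COLUMNS)].astype(str)
    bad = df[
        df.apply(
            lambda r: not r["chemical_code"].startswith(r["subparagraph_code"]),
            axis=1,
        )
    ]
    if not bad.empty:
        raise ValueError(
            "chemical codes must extend their subparagraph code: "
            f"{bad['chemical_code'].tolist()[:5]}"
        )
    return df.drop_duplicates(subset="chemical_code").reset_index(drop=True)
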