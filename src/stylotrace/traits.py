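"""Reproductive-system trait coding for Connaraceae.

Three nested coding schemes are supported:

* Lemmens' eight-type morphological scoring of heterostylous systems
  (heterotristyly, five flavours of distyly/semihomostyly numbered by type,
  dioecism, homostyly);
* a five-state simplification (distyly, tristyly, semihomostyly, dioecy,
  homostyly) used for multi-state Markov reconstructions;
* a binary scoring (trimorphism vs dimorphism) used for state-dependent
  diversification models.  Semihomostyly is scored trimorphic because it
  occurs only in the context of tristyly; homostyly and dioecy are each known
  from a single species and are pruned from the binary analysis rather than
  forced into either morph class.

The packaged fixture transcribes the study's 35-taxon character table in both
codings.
"""

from __future__ import annotations

import importlib.resources as resources
from typing import Optional

from .characters import BINARY_STATES, FIVE_STATES, MISSING, CharacterMatrix

#: Lemmens-type label -> five-state label.  Types 3, 6 and 7 are distyly
#: variants (differing in which morph is absent and in stamen number); types
#: 2 and 4 are semihomostyly variants.
LEMMENS_TO_FIVE: dict[str, str] = {
    "heterotristyly": "tristyly",
    "type_2": "semihomostyly",
    "type_3": "distyly",
    "type_4": "semihomostyly",
    "type_6": "distyly",
    "type_7": "distyly",
    "dioecism": "dioecy",
    "homostyly": "homostyly",
}

#: Five-state label -> binary label; ``None`` means the taxon is pruned.
FIVE_TO_BINARY: dict[str, Optional[str]] = {
    "tristyly": "trimorphism",
    "semihomostyly": "trimorphism",
    "distyly": "dimorphism",
    "homostyly": None,
    "dioecy": None,
}


def collapse_to_five(state8: Optional[str]) -> Optional[str]:
    """Map a Lemmens-type label to the five-state scheme.

    Missing input is preserved; an unknown label raises ``ValueError``.
    """
    if state8 is MISSING:
        return MISSING
    try:
        return LEMMENS_TO_FIVE[state8]
    except KeyError:
        raise ValueError(f"unknown Lemmens-type label: {state8!r}") from None


def to_binary(matrix5: CharacterMatrix) -> tuple[CharacterMatrix, list[str]]:
    """Recode a five-state matrix to binary morph-number scoring.

    Tristyly and semihomostyly become trimorphism, distyly becomes
    dimorphism.  Taxa scored homostyly or dioecy, and taxa missing in the
    five-state coding, are dropped and returned in the pruned-taxa list so
    the tree can be pruned to match.

    Returns
    -------
    (binary_matrix, pruned_taxa)
    """
    if tuple(matrix5.states) != FIVE_STATES:
        raise ValueError("expected a five-state matrix")
    data: dict[str, Optional[str]] = {}
    pruned: list[str] = []
    for taxon, state in matrix5.data.items():
        if state is MISSING:
            pruned.append(taxon)
            continue
        b = FIVE_TO_BINARY[state]
        if b is None:
            pruned.append(taxon)
        else:
            data[taxon] = b
    out = CharacterMatrix(BINARY_STATES, data)
    if out.is_monomorphic():
        out.degenerate = True  # type: ignore[attr-defined]  # BiSSE fit would be degenerate
    return out, pruned


def load_fixture() -> tuple[CharacterMatrix, CharacterMatrix]:
    """Load the packaged 35-taxon Connaraceae character table.

    Returns the five-state and binary matrices.  One taxon (*Cnestis
    bomiensis*, known only from short-styled specimens) is missing in both
    codings; the homostylous and dioecious taxa are additionally missing in
    the binary coding.
    """
    ref = resources.files("stylotrace.data").joinpath("connaraceae_traits.csv")
    with resources.as_file(ref) as path:
        m5 = CharacterMatrix.from_csv(path, FIVE_STATES, column="state_5")
        mb = CharacterMatrix.from_csv(path, BINARY_STATES, column="state_binary")
    return m5, mb


def fixture_binary_pruned() -> tuple[CharacterMatrix, list[str]]:
    """Binary fixture restricted to scored taxa, plus the pruned-taxa list."""
    _, mb = load_fixture()
    pruned = mb.missing_taxa()
    return mb.drop(pruned), pruned
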