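"""Canonical human ubiquitin constants used throughout the toolkit.

Ubiquitin is a 76-residue protein whose seven lysines (K6, K11, K27, K29,
K33, K48, K63) are the acceptor sites for chains and for acetylation.  Its
two hydrophobic surface patches — centred on I44 and on I36 — mediate the
large majority of ubiquitin-protein interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

#: Canonical 76-residue human ubiquitin sequence (one-letter codes).
SEQUENCE: str = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

#: Lysine positions (1-based).
LYSINES: FrozenSet[int] = frozenset({6, 11, 27, 29, 33, 48, 63})

#: Prolines have no backbone amide and therefore no HSQC cross peak.
PROLINES: FrozenSet[int] = frozenset({19, 37, 38})

N_RESIDUES: int = len(SEQUENCE)


def residue_type(residue_number: int) -> str:
    """One-letter amino-acid code at a 1-based ubiquitin position."""
    if not 1 <= residue_number <= N_RESIDUES:
        raise ValueError(f"residue {residue_number} outside 1..{N_RESIDUES}")
    return SEQUENCE[residue_number - 1]


@dataclass(frozen=True)
class HydrophobicPatch:
    """A named ubiquitin surface epitope (fixed four-residue membership)."""

    name: str
    members: FrozenSet[int]

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError("a hydrophobic patch has exactly four members")


#: I44 patch: L8, I44, H68, V70.
I44_PATCH = HydrophobicPatch("I44", frozenset({8, 44, 68, 70}))

#: I36 patch: L8, I36, L71, L73.
I36_PATCH = HydrophobicPatch("I36", frozenset({8, 36, 71, 73}))

PATCHES = {p.name: p for p in (I44_PATCH, I36_PATCH)}
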