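"""CDR/FR region definitions and key structural position sets.

VHH regions are indexed by IMGT scaffold columns 1-128.  Four CDR
definitions are provided: ``imgt``, ``kabat``, ``chothia`` and their union
``combined``.  The Kabat and Chothia boundaries are shipped pre-converted to
IMGT columns using the standard no-insertion heavy-chain correspondence
(e.g. Kabat H1 31-35 maps to IMGT 36-40 because the conserved FR2 Trp is
Kabat 36 = IMGT 41; Kabat H2 50-65 maps to IMGT 55-74).

Two properties of the combined definition matter for VHH humanization and
are asserted here at import time: IMGT position 40 falls inside combined
CDR1 (it is CDR1 under Kabat although FR2 under IMGT) and position 55 --
the most frequent non-canonical cysteine site -- falls inside combined
CDR2.  Framework-based humanization under the combined definition therefore
never touches either position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable

from .errors import UnknownRegion

#: all IMGT scaffold columns for a VHH domain
SCAFFOLD_POSITIONS = tuple(range(1, 129))

REGION_NAMES = ("fr1", "cdr1", "fr2", "cdr2", "fr3", "cdr3", "fr4")


def _rng(a: int, b: int) -> FrozenSet[int]:
    return frozenset(range(a, b + 1))


@dataclass(frozen=True)
class RegionScheme:
    """A CDR definition over IMGT columns; FRs are the complement."""

    name: str
    cdr1: FrozenSet[int]
    cdr2: FrozenSet[int]
    cdr3: FrozenSet[int]

    @property
    def fr1(self) -> FrozenSet[int]:
        return _rng(1, min(self.cdr1) - 1)

    @property
    def fr2(self) -> FrozenSet[int]:
        return _rng(max(self.cdr1) + 1, min(self.cdr2) - 1)

    @property
    def fr3(self) -> FrozenSet[int]:
        return _rng(max(self.cdr2) + 1, min(self.cdr3) - 1)

    @property
    def fr4(self) -> FrozenSet[int]:
        return _rng(max(self.cdr3) + 1, 128)

    def region(self, name: str) -> FrozenSet[int]:
        name = name.lower()
        if name not in REGION_NAMES:
            raise UnknownRegion(f"unknown region {name!r}; expected one of {REGION_NAMES}")
        return getattr(self, name)

    @property
    def cdr_positions(self) -> FrozenSet[int]:
        return self.cdr1 | self.cdr2 | self.cdr3

    @property
    def fr_positions(self) -> FrozenSet[int]:
        return self.fr1 | self.fr2 | self.fr3 | self.fr4


IMGT = RegionScheme("imgt", _rng(27, 38), _rng(56, 65), _rng(105, 117))
KABAT = RegionScheme("kabat", _rng(36, 40), _rng(55, 74), _rng(105, 117))
CHOTHIA = RegionScheme("chothia", _rng(27, 36), _rng(57, 64), _rng(105, 117))
COMBINED = RegionScheme(
    "combined",
    IMGT.cdr1 | KABAT.cdr1 | CHOTHIA.cdr1,
    IMGT.cdr2 | KABAT.cdr2 | CHOTHIA.cdr2,
    IMGT.cdr3 | KABAT.cdr3 | CHOTHIA.cdr3,
)

SCHEMES = {s.name: s for s in (IMGT, KABAT, CHOTHIA, COMBINED)}

assert 40 in COMBINED.cdr1, "position 40 must be CDR1 under the combined definition"
assert 55 in COMBINED.cdr2, "position 55 must be CDR2 under the combined definition"


def get_scheme(name: str | RegionScheme) -> RegionScheme:
    if isinstance(name, RegionScheme):
        return name
    try:
        return SCHEMES[name.lower()]
    except KeyError:
        raise UnknownRegion(f"unknown scheme {name!r}; expected one of {sorted(SCHEMES)}") from None


#: Hallmark FR2 positions distinguishing VHHs from conventional VH domains
HALLMARK_POSITIONS = (42, 49, 50, 52)

#: Foote-Winter VH Vernier zone mapped to IMGT columns (overridable).
#: Includes 78 and 87, the two Vernier positions probed by point humanization
#: (F78I, V87L) in typical VHH campaigns.
DEFAULT_VERNIER = frozenset({2, 28, 29, 30, 53, 54, 76, 78, 80, 82, 87, 103})


@dataclass(frozen=True)
class KeyPositions:
    """Named sets of structurally critical IMGT positions."""

    hallmark: FrozenSet[int] = frozenset(HALLMARK_POSITIONS)
    vernier: FrozenSet[int] = DEFAULT_VERNIER
    de_loop: FrozenSet[int] = _rng(80, 87)
    preada: FrozenSet[int] = frozenset({12})
    canonical_cys: FrozenSet[int] = frozenset({23, 104})

    def __post_init__(self):
        if self.hallmark & self.vernier:
            raise ValueError("Vernier set must be disjoint from Hallmark positions")

    @property
    def extended_hallmark(self) -> FrozenSet[int]:
        """Hallmark plus position 40, whose residue co-varies with the motif."""
        return self.hallmark | {40}


DEFAULT_KEY_POSITIONS = KeyPositions()


def scheme_to_json(scheme: RegionScheme) -> str:
    return json.dumps(
        {
            "name": scheme.name,
            "cdr1": sorted(scheme.cdr1),
            "cdr2": sorted(scheme.cdr2),
            "cdr3": sorted(scheme.cdr3),
        }
    )


def scheme_from_json(text: str) -> RegionScheme:
    obj = json.loads(text)
    return RegionScheme(
        obj["name"],
        frozenset(obj["cdr1"]),
        frozenset(obj["cdr2"]),
        frozenset(obj["cdr3"]),
    )


def key_positions_from_json(text: str) -> KeyPositions:
    obj = json.loads(text)
    kwargs = {k: frozenset(v) for k, v in obj.items()}
    return KeyPositions(**kwargs)


def positions_in_order(positions: Iterable[int]) -> list[int]:
    return sorted(positions)
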