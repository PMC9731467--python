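"""Relationship census and Dunbar ratios.

Ties are classified by reciprocity and sign: a reciprocal positive pair is a
*best friend* relationship, a one-way positive arc a plain *friend*; the
negative analogues are *worst enemy* and *enemy*.  The Dunbar ratio — the
roughly threefold size step between successive intimacy layers of an ego
network — is estimated per network as one-way count over reciprocal-pair
count (exclusive layers) or, optionally, with the inner layer included in
the outer (cumulative layers).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedMetricError
from .graph import DirectedSignedNetwork, ordered

MODES = ("exclusive", "cumulative")


@dataclass
class RelationshipCensus:
    best_friend_pairs: int
    friend_oneway: int
    worst_enemy_pairs: int
    enemy_oneway: int
    mode: str = "exclusive"

    def to_row(self) -> dict:
        """One CSV-ready row of per-network counts."""
        return {
            "best_friend_pairs": self.best_friend_pairs,
            "friend_oneway": self.friend_oneway,
            "worst_enemy_pairs": self.worst_enemy_pairs,
            "enemy_oneway": self.enemy_oneway,
            "mode": self.mode,
        }


def classify_relationships(
    net: DirectedSignedNetwork, mode: str = "exclusive"
) -> RelationshipCensus:
    """Count reciprocal pairs and one-way arcs by sign.

    Each reciprocal same-sign pair counts once; every other arc counts once
    as one-way.  A conflicting pair (one positive, one negative arc)
    contributes one one-way positive and one one-way negative tie.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    bf = we = f1 = e1 = 0
    seen: set[tuple[str, str]] = set()
    for (i, j), s in net.arcs.items():
        key = ordered(i, j)
        rev = net.arcs.get((j, i))
        if rev == s:
            if key not in seen:
                seen.add(key)
                if s > 0:
                    bf += 1
                else:
                    we += 1
        else:
            if s > 0:
                f1 += 1
            else:
                e1 += 1
    return RelationshipCensus(bf, f1, we, e1, mode)


def dunbar_ratio(census: RelationshipCensus, sign: int) -> float:
    """Layer-size ratio for the requested sign (+1 friends, -1 enemies).

    Exclusive mode: one-way / reciprocal-pair count.  Cumulative mode:
    (one-way + pairs) / pairs.  Raises :class:`UndefinedMetricError` when
    the reciprocal-pair count is zero.
    """
    if sign > 0:
        pairs, oneway = census.best_friend_pairs, census.friend_oneway
    else:
        pairs, oneway = census.worst_enemy_pairs, census.enemy_oneway
    if pairs == 0:
        raise UndefinedMetricError(
            "Dunbar ratio undefined: no reciprocal pairs of the requested sign"
        )
    if census.mode == "cumulative":
        return (oneway + pairs) / pairs
    return oneway / pairs
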