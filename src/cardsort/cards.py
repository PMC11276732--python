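"""Stimulus-space combinatorics: cards, the fixed keycard panel, response matching.

A card is a triple of feature indices, one per dimension (color, shape,
number), each in 1..4.  Keycard ``k`` carries index ``k`` on every dimension,
so a target card "matches" keycard ``k`` on a dimension exactly when its
index on that dimension equals ``k``.  A target card is *unambiguous* when
its three indices are pairwise distinct: it then matches three different
keycards (one per dimension) and shares no feature with the fourth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Union

N_FEATURES = 4

COLOR_NAMES = ("red", "green", "yellow", "blue")
SHAPE_NAMES = ("triangle", "asterisk", "cross", "circle")


class Dimension(Enum):
    """The three sorting dimensions, in their fixed cyclic order."""

    COLOR = "COLOR"
    SHAPE = "SHAPE"
    NUMBER = "NUMBER"

    def __repr__(self) -> str:  # compact in test output
        return self.value


#: Fixed ordering of the dimensions (also the cyclic rule order).
DIMENSIONS: tuple[Dimension, Dimension, Dimension] = (
    Dimension.COLOR,
    Dimension.SHAPE,
    Dimension.NUMBER,
)


class _OddType:
    """Sentinel for a response matching the target on no dimension."""

    _instance = None

    def __new__(cls) -> "_OddType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ODD"


#: Singleton returned by :func:`classify_response` for odd responses.
ODD = _OddType()

ResponseMatch = Union[Dimension, _OddType]


class Card(NamedTuple):
    """A stimulus card as a triple of feature indices, each in 1..4."""

    color: int
    shape: int
    number: int

    def index_on(self, dimension: Dimension) -> int:
        if dimension is Dimension.COLOR:
            return self.color
        if dimension is Dimension.SHAPE:
            return self.shape
        return self.number

    @property
    def is_unambiguous(self) -> bool:
        return (
            self.color != self.shape
            and self.color != self.number
            and self.shape != self.number
        )

    def describe(self) -> str:
        """Human-readable label, e.g. ``'2 green asterisks'``."""
        plural = "s" if self.number > 1 else ""
        return (
            f"{self.number} {COLOR_NAMES[self.color - 1]} "
            f"{SHAPE_NAMES[self.shape - 1]}{plural}"
        )


def _validate_card(card: Card) -> None:
    for value in card:
        if not isinstance(value, int) or not 1 <= value <= N_FEATURES:
            raise ValueError(f"card index out of range 1..{N_FEATURES}: {card}")


#: Response keys, left to right, mapped to keycard positions 1..4.
RESPONSE_KEYS = ("Y", "C", "B", "M")


@dataclass(frozen=True)
class KeycardPanel:
    """The fixed four-keycard panel; keycard ``k`` has index ``k`` everywhere."""

    cards: tuple[Card, Card, Card, Card]
    keys: tuple[str, str, str, str] = RESPONSE_KEYS

    def card_at(self, position: int) -> Card:
        return self.cards[position - 1]

    def key_for(self, position: int) -> str:
        return self.keys[position - 1]

    def position_for_key(self, key: str) -> int:
        return self.keys.index(key.upper()) + 1


def build_keycard_panel() -> KeycardPanel:
    """Return the fixed panel: keycard ``k`` = (k, k, k) under key Y/C/B/M."""
    return KeycardPanel(tuple(Card(k, k, k) for k in range(1, N_FEATURES + 1)))


def enumerate_unambiguous_deck() -> tuple[Card, ...]:
    """All cards with pairwise-distinct indices, in lexicographic order.

    Exhaustive enumeration over the 4**3 index triples; 24 cards survive.
    """
    return tuple(
        card
        for card in itertools.starmap(
            Card, itertools.product(range(1, N_FEATURES + 1), repeat=3)
        )
        if card.is_unambiguous
    )


def classify_response(target: Card, keycard_position: int) -> ResponseMatch:
    """Dimension on which ``target`` matches the chosen keycard, or :data:`ODD`.

    Requires an unambiguous target: for those the match is unique or absent.
    Ambiguous targets signal corrupt input and are rejected.
    """
    _validate_card(target)
    if not target.is_unambiguous:
        raise ValueError(f"ambiguous target card (repeated index): {target}")
    if not 1 <= keycard_position <= N_FEATURES:
        raise ValueError(f"keycard position out of range 1..4: {keycard_position}")
    for dimension in DIMENSIONS:
        if target.index_on(dimension) == keycard_position:
            return dimension
    return ODD


def odd_position(target: Card) -> int:
    """The unique keycard position sharing no feature with ``target``."""
    _validate_card(target)
    if not target.is_unambiguous:
        raise ValueError(f"ambiguous target card (repeated index): {target}")
    (position,) = set(range(1, N_FEATURES + 1)) - set(target)
    return position


def next_dimension(dimension: Dimension) -> Dimension:
    """Successor in the fixed cyclic order COLOR -> SHAPE -> NUMBER -> COLOR."""
    return DIMENSIONS[(DIMENSIONS.index(dimension) + 1) % len(DIMENSIONS)]
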