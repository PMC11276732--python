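"""Constrained pseudo-random target-card sequencing.

The next target is never an exact repeat of the previous one.  Whenever the
previous trial ended in an informative error (incorrect feedback on a
dimension-matching response), the drawn card is stratified by a fair coin:
with probability 0.5 it repeats the previous card's feature on the
disconfirmed ("critical") dimension (a *repetitive* perseveration
opportunity), otherwise it changes that feature (*non-repetitive*).  This
balancing yields a 50% marginal chance of repetitive opportunities
regardless of behavior.  On all other trials the draw is uniform over the
23 legal cards (24 on the first trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .cards import Card, Dimension, DIMENSIONS, N_FEATURES, enumerate_unambiguous_deck

DECK: tuple[Card, ...] = enumerate_unambiguous_deck()
_DECK_POSITION = {card: i for i, card in enumerate(DECK)}

# Pre-split strata: cards sharing / not sharing a given feature index on a
# given dimension.  6 cards share any fixed (dimension, index); 18 do not.
_SHARING: dict[tuple[Dimension, int], tuple[Card, ...]] = {}
_DIFFERING: dict[tuple[Dimension, int], tuple[Card, ...]] = {}
for _dim in DIMENSIONS:
    for _idx in range(1, N_FEATURES + 1):
        _SHARING[(_dim, _idx)] = tuple(
            c for c in DECK if c.index_on(_dim) == _idx
        )
        _DIFFERING[(_dim, _idx)] = tuple(
            c for c in DECK if c.index_on(_dim) != _idx
        )


class OpportunityTag(Enum):
    REPETITIVE = "REPETITIVE"
    NON_REPETITIVE = "NON_REPETITIVE"
    NEUTRAL = "NEUTRAL"

    def __repr__(self) -> str:
        return self.value


@dataclass
class SequencerState:
    """Mutable sequencing context for one session.

    ``critical_dimension`` is the dimension disconfirmed by error feedback on
    the immediately preceding trial; it must be ``None`` after correct
    feedback or an odd response.
    """

    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    previous_card: Optional[Card] = None
    critical_dimension: Optional[Dimension] = None


def draw_next_target(state: SequencerState) -> tuple[Card, OpportunityTag]:
    """Draw the next target card; updates ``state.previous_card`` in place."""
    previous = state.previous_card
    if previous is None:
        card = DECK[int(state.rng.integers(len(DECK)))]
        tag = OpportunityTag.NEUTRAL
    else:
        if previous not in _DECK_POSITION:
            raise ValueError(f"previous card not in the deck: {previous}")
        critical = state.critical_dimension
        if critical is None:
            # uniform over the 23 non-previous cards
            i = int(state.rng.integers(len(DECK) - 1))
            if i >= _DECK_POSITION[previous]:
                i += 1
            card = DECK[i]
            tag = OpportunityTag.NEUTRAL
        else:
            index = previous.index_on(critical)
            if state.rng.random() < 0.5:
                pool = [
                    c for c in _SHARING[(critical, index)] if c != previous
                ]
                tag = OpportunityTag.REPETITIVE
            else:
                pool = list(_DIFFERING[(critical, index)])
                tag = OpportunityTag.NON_REPETITIVE
            card = pool[int(state.rng.integers(len(pool)))]
    state.previous_card = card
    return card, tag
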