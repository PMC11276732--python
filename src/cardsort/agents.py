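"""Parametric synthetic participants.

The agent is a descriptive probabilistic policy (not a cognitive-process
model): it tracks a candidate sorting dimension and lapses with controllable
probabilities.  Separate perseveration probabilities apply in repetitive vs
non-repetitive post-error contexts, so simulated cohorts can realize either
ordering of the two per-occasion error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .cards import Card, Dimension, DIMENSIONS, odd_position
from .engine import Feedback, SessionConfig, SessionRecord, TrialRecord, run_session
from .scoring import informative_error_dimension


@dataclass(frozen=True)
class AgentParams:
    """Lapse probabilities; ``omniscient`` overrides everything (always sorts
    by the true rule — a test fixture)."""

    p_pers_nonrep: float = 0.0
    p_pers_rep: float = 0.0
    p_sle: float = 0.0
    p_ie: float = 0.0
    p_oe: float = 0.0
    omniscient: bool = False

    def __post_init__(self) -> None:
        for name in ("p_pers_nonrep", "p_pers_rep", "p_sle", "p_ie", "p_oe"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")


class Agent:
    """Policy tracking a candidate dimension and the last two informative
    error dimensions."""

    def __init__(self, params: AgentParams):
        self.params = params
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._reset_state()

    def _reset_state(self) -> None:
        self.candidate: Optional[Dimension] = None
        self.prev_target: Optional[Card] = None
        self.prev_feedback: Optional[Feedback] = None
        self.err_dim_1back: Optional[Dimension] = None
        self.err_dim_2back: Optional[Dimension] = None

    def begin_session(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self._reset_state()

    def _random_other(self, excluded: tuple[Dimension, ...]) -> Dimension:
        pool = [d for d in DIMENSIONS if d not in excluded]
        return pool[int(self.rng.integers(len(pool)))]

    def _update_candidate(self, target: Card) -> None:
        p = self.params
        rng = self.rng
        if self.candidate is None:
            self.candidate = DIMENSIONS[int(rng.integers(3))]
        elif self.prev_feedback is Feedback.CORRECT:
            if rng.random() < p.p_sle:  # set loss despite confirmation
                self.candidate = self._random_other((self.candidate,))
        elif self.err_dim_1back is not None:
            d = self.err_dim_1back
            assert self.prev_target is not None
            repeated = target.index_on(d) == self.prev_target.index_on(d)
            p_pers = p.p_pers_rep if repeated else p.p_pers_nonrep
            if rng.random() < p_pers:
                self.candidate = d
            elif self.err_dim_2back is not None and self.err_dim_2back is not d:
                # two distinct dimensions excluded: integrate or fail
                (third,) = (
                    x for x in DIMENSIONS if x is not d and x is not self.err_dim_2back
                )
                if rng.random() < p.p_ie:
                    self.candidate = self.err_dim_2back  # integration failure
                else:
                    self.candidate = third
            else:
                self.candidate = self._random_other((d,))
        # uninformative incorrect feedback (odd response): keep the candidate

    def choose(self, target: Card, rule: Dimension) -> int:
        if self.params.omniscient:
            return target.index_on(rule)
        self._update_candidate(target)
        if self.params.p_oe > 0 and self.rng.random() < self.params.p_oe:
            return odd_position(target)
        assert self.candidate is not None
        return target.index_on(self.candidate)

    def observe(self, record: TrialRecord) -> None:
        self.prev_target = record.target
        self.prev_feedback = record.feedback
        self.err_dim_2back = self.err_dim_1back
        self.err_dim_1back = informative_error_dimension(record)


def simulate_session(
    params: AgentParams,
    config: SessionConfig = SessionConfig(),
    participant_id: str = "sim",
) -> SessionRecord:
    return run_session(Agent(params), config, participant_id)


def simulate_cohort(
    params: AgentParams,
    n_agents: int,
    config: SessionConfig = SessionConfig(),
    master_seed: int = 0,
) -> list[SessionRecord]:
    """Independent sessions with per-agent sub-seeds derived from the master
    seed; reproducible for a fixed (params, config, master_seed)."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_agents)
    sessions = []
    for i, child in enumerate(children, start=1):
        seed = int(child.generate_state(1, dtype=np.uint64)[0])
        sessions.append(
            simulate_session(
                params,
                replace(config, seed=seed),
                participant_id=f"agent_{i:04d}",
            )
        )
    return sessions
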