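"""Session state machine: covert rule schedule, feedback, termination.

The sorting rule starts at the head of the configured dimension order and
advances cyclically each time the participant produces ``category_length``
consecutive correct sorts.  Rule switches are covert: the policy only ever
sees targets and feedback.  A session ends at ``max_trials`` or as soon as
both perseveration-opportunity counters (non-repetitive, repetitive) reach
``occasion_target``, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Protocol

import numpy as np

from .cards import (
    Card,
    Dimension,
    DIMENSIONS,
    ODD,
    ResponseMatch,
    RESPONSE_KEYS,
    classify_response,
)
from .sequencer import OpportunityTag, SequencerState, draw_next_target


class Feedback(Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"

    def __repr__(self) -> str:
        return self.value


class Termination(Enum):
    MAX_TRIALS = "MAX_TRIALS"
    OCCASIONS_REACHED = "OCCASIONS_REACHED"

    def __repr__(self) -> str:
        return self.value


@dataclass(frozen=True)
class SessionConfig:
    """Task parameters.  Timing constants are recorded but do not affect
    simulation semantics."""

    max_trials: int = 240
    occasion_target: int = 20
    category_length: int = 6
    dimension_order: tuple[Dimension, ...] = DIMENSIONS
    feedback_ms: int = 1200
    iti_ms: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        if self.occasion_target < 1:
            raise ValueError("occasion_target must be >= 1")
        if self.category_length < 1:
            raise ValueError("category_length must be >= 1")
        if tuple(sorted(d.value for d in self.dimension_order)) != tuple(
            sorted(d.value for d in DIMENSIONS)
        ):
            raise ValueError("dimension_order must be a permutation of the dimensions")

    def with_seed(self, seed: int) -> "SessionConfig":
        return replace(self, seed=int(seed))


@dataclass
class RuleState:
    """Covert rule bookkeeping; mutated by :func:`play_trial`."""

    current_rule: Dimension
    consecutive_correct: int = 0
    categories_completed: int = 0
    switched_before_this_trial: bool = False


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    target: Card
    rule: Dimension
    chosen_keycard: int
    response_key: str
    matched: ResponseMatch
    feedback: Feedback
    rule_switch_before: bool
    opportunity_tag: OpportunityTag


@dataclass
class SessionRecord:
    participant_id: str
    config: SessionConfig
    trials: list[TrialRecord] = field(default_factory=list)
    termination_reason: Optional[Termination] = None


class Policy(Protocol):
    """A participant model.  ``rule`` is passed to ``choose`` for test
    fixtures (the omniscient policy); behavioral policies must ignore it —
    rule switches are covert."""

    def begin_session(self, rng: np.random.Generator) -> None: ...

    def choose(self, target: Card, rule: Dimension) -> int: ...

    def observe(self, record: TrialRecord) -> None: ...


def play_trial(
    rule_state: RuleState,
    target: Card,
    chosen_keycard: int,
    config: SessionConfig,
    trial_index: int,
    opportunity_tag: OpportunityTag = OpportunityTag.NEUTRAL,
) -> TrialRecord:
    """Score one choice against the covert rule and advance the rule state.

    Correct feedback increments the consecutive-correct counter; incorrect
    feedback resets it.  On reaching ``category_length`` the category counts,
    the rule advances cyclically, the counter resets, and the *next* trial is
    flagged ``rule_switch_before``.
    """
    if not 1 <= chosen_keycard <= 4:
        raise ValueError(f"chosen_keycard out of range 1..4: {chosen_keycard}")
    matched = classify_response(target, chosen_keycard)
    feedback = (
        Feedback.CORRECT if matched is rule_state.current_rule else Feedback.INCORRECT
    )
    record = TrialRecord(
        trial_index=trial_index,
        target=target,
        rule=rule_state.current_rule,
        chosen_keycard=chosen_keycard,
        response_key=RESPONSE_KEYS[chosen_keycard - 1],
        matched=matched,
        feedback=feedback,
        rule_switch_before=rule_state.switched_before_this_trial,
        opportunity_tag=opportunity_tag,
    )
    rule_state.switched_before_this_trial = False
    if feedback is Feedback.CORRECT:
        rule_state.consecutive_correct += 1
        if rule_state.consecutive_correct >= config.category_length:
            rule_state.categories_completed += 1
            rule_state.consecutive_correct = 0
            order = config.dimension_order
            position = order.index(rule_state.current_rule)
            rule_state.current_rule = order[(position + 1) % len(order)]
            rule_state.switched_before_this_trial = True
    else:
        rule_state.consecutive_correct = 0
    return record


def check_termination(
    n_trials: int,
    n_occ_nonrepetitive: int,
    n_occ_repetitive: int,
    config: SessionConfig,
) -> Optional[Termination]:
    """Early stop once both occasion counters reach the target, else the cap."""
    if (
        n_occ_nonrepetitive >= config.occasion_target
        and n_occ_repetitive >= config.occasion_target
    ):
        return Termination.OCCASIONS_REACHED
    if n_trials >= config.max_trials:
        return Termination.MAX_TRIALS
    return None


def run_session(
    policy: Policy,
    config: SessionConfig = SessionConfig(),
    participant_id: str = "sim",
) -> SessionRecord:
    """Run one complete session; deterministic given (policy, config.seed).

    The master seed feeds two independent sub-streams, one for the sequencer
    and one for the policy.
    """
    seq_stream, agent_stream = np.random.SeedSequence(config.seed).spawn(2)
    sequencer = SequencerState(rng=np.random.default_rng(seq_stream))
    policy.begin_session(np.random.default_rng(agent_stream))

    rule_state = RuleState(current_rule=config.dimension_order[0])
    session = SessionRecord(participant_id=participant_id, config=config)
    n_occ_nonrep = 0
    n_occ_rep = 0

    while True:
        trial_index = len(session.trials) + 1
        target, tag = draw_next_target(sequencer)
        try:
            chosen = policy.choose(target, rule_state.current_rule)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"policy failure on trial {trial_index} (target {target})"
            ) from exc
        record = play_trial(rule_state, target, chosen, config, trial_index, tag)
        session.trials.append(record)
        policy.observe(record)

        # informative error => that dimension becomes critical for sequencing
        if record.feedback is Feedback.INCORRECT and record.matched is not ODD:
            sequencer.critical_dimension = record.matched
        else:
            sequencer.critical_dimension = None

        if tag is OpportunityTag.REPETITIVE:
            n_occ_rep += 1
        elif tag is OpportunityTag.NON_REPETITIVE:
            n_occ_nonrep += 1

        reason = check_termination(len(session.trials), n_occ_nonrep, n_occ_rep, config)
        if reason is not None:
            session.termination_reason = reason
            return session
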