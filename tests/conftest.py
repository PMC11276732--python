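import pytest

from cardsort.cards import Card, Dimension, build_keycard_panel, classify_response
from cardsort.engine import (
    Feedback,
    SessionConfig,
    SessionRecord,
    Termination,
    TrialRecord,
)
from cardsort.cards import RESPONSE_KEYS
from cardsort.sequencer import OpportunityTag


@pytest.fixture(scope="session")
def panel():
    return build_keycard_panel()


@pytest.fixture
def default_config():
    return SessionConfig()


@pytest.fixture
def short_config():
    """Small session for fast property tests."""
    return SessionConfig(max_trials=60, occasion_target=6)


def make_trial(
    trial_index: int,
    target: Card,
    chosen_keycard: int,
    rule: Dimension,
    rule_switch_before: bool = False,
    opportunity_tag: OpportunityTag = OpportunityTag.NEUTRAL,
) -> TrialRecord:
    """Build a consistent TrialRecord for hand-written scoring fixtures."""
    matched = classify_response(target, chosen_keycard)
    feedback = Feedback.CORRECT if matched is rule else Feedback.INCORRECT
    return TrialRecord(
        trial_index=trial_index,
        target=target,
        rule=rule,
        chosen_keycard=chosen_keycard,
        response_key=RESPONSE_KEYS[chosen_keycard - 1],
        matched=matched,
        feedback=feedback,
        rule_switch_before=rule_switch_before,
        opportunity_tag=opportunity_tag,
    )


def make_session(trials, config=None, participant_id="fixture") -> SessionRecord:
    return SessionRecord(
        participant_id=participant_id,
        config=config or SessionConfig(),
        trials=list(trials),
        termination_reason=Termination.MAX_TRIALS,
    )
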