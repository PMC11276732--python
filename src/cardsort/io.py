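"""Session-log and measures CSV formats.

Session logs are plain CSV, one row per trial, trials contiguous from 1,
multiple sessions distinguished by ``participant_id``.  Dimensions are
serialized as COLOR/SHAPE/NUMBER, feedback as 1/0, booleans as true/false.
Label/occasion columns are outputs of the scorer and optional on input (the
scorer can regenerate them).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cards import Card, Dimension, ODD, RESPONSE_KEYS
from .engine import (
    Feedback,
    SessionConfig,
    SessionRecord,
    Termination,
    TrialRecord,
    check_termination,
)
from .scoring import LabelledTrial
from .sequencer import OpportunityTag

SESSION_LOG_COLUMNS = [
    "participant_id",
    "trial",
    "target_color",
    "target_shape",
    "target_number",
    "rule",
    "response_key",
    "chosen_keycard",
    "matched_dimension",
    "feedback",
    "rule_switch_before",
    "opportunity_tag",
    "label",
    "pe_occasion",
    "sle_occasion",
    "ie_occasion",
]


class SessionLogError(ValueError):
    """Malformed session-log row; message names the row and column."""


def _bool_str(value: bool) -> str:
    return "true" if value else "false"


def write_session_log(
    path: str | Path,
    sessions: Sequence[SessionRecord],
    labelled: Optional[dict[str, Sequence[LabelledTrial]]] = None,
) -> None:
    """Write one or more sessions; label columns filled when provided."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(SESSION_LOG_COLUMNS)
        for session in sessions:
            items = labelled.get(session.participant_id) if labelled else None
            for i, trial in enumerate(session.trials):
                if items is not None:
                    item = items[i]
                    label = item.label.value
                    pe_occ = item.flags.pe_occasion.value
                    sle_occ = _bool_str(item.flags.sle_occasion)
                    ie_occ = _bool_str(item.flags.ie_occasion)
                else:
                    label = pe_occ = sle_occ = ie_occ = ""
                writer.writerow(
                    [
                        session.participant_id,
                        trial.trial_index,
                        trial.target.color,
                        trial.target.shape,
                        trial.target.number,
                        trial.rule.value,
                        trial.response_key,
                        trial.chosen_keycard,
                        "ODD" if trial.matched is ODD else trial.matched.value,
                        1 if trial.feedback is Feedback.CORRECT else 0,
                        _bool_str(trial.rule_switch_before),
                        trial.opportunity_tag.value,
                        label,
                        pe_occ,
                        sle_occ,
                        ie_occ,
                    ]
                )


def _parse_int(value: str, lo: int, hi: int, row: int, column: str) -> int:
    try:
        parsed = int(value)
    except ValueError:
        raise SessionLogError(f"row {row}: column '{column}' is not an integer: {value!r}")
    if not lo <= parsed <= hi:
        raise SessionLogError(
            f"row {row}: column '{column}' out of range {lo}..{hi}: {parsed}"
        )
    return parsed


def _parse_enum(value: str, allowed: dict, row: int, column: str):
    if value not in allowed:
        raise SessionLogError(
            f"row {row}: column '{column}' must be one of {sorted(allowed)}: {value!r}"
        )
    return allowed[value]


_DIMENSIONS_BY_NAME = {d.value: d for d in Dimension}
_MATCH_BY_NAME = {**_DIMENSIONS_BY_NAME, "ODD": ODD}
_TAG_BY_NAME = {t.value: t for t in OpportunityTag}
_BOOL_BY_NAME = {"true": True, "false": False}


def read_session_log(
    path: str | Path, config: SessionConfig = SessionConfig()
) -> list[SessionRecord]:
    """Read sessions back; inverse of :func:`write_session_log` on trials.

    The config is not stored in the log; the caller supplies it (defaults
    apply).  The termination reason is re-derived from the occasion tags.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != SESSION_LOG_COLUMNS:
            raise SessionLogError(
                f"bad header: expected {SESSION_LOG_COLUMNS}, got {header}"
            )
        sessions: list[SessionRecord] = []
        current: Optional[SessionRecord] = None
        occ = [0, 0]  # non-repetitive, repetitive
        for row_number, row in enumerate(reader, start=2):
            if len(row) != len(SESSION_LOG_COLUMNS):
                raise SessionLogError(
                    f"row {row_number}: expected {len(SESSION_LOG_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            values = dict(zip(SESSION_LOG_COLUMNS, row))
            pid = values["participant_id"]
            if current is None or pid != current.participant_id:
                if current is not None:
                    current.termination_reason = _derive_termination(
                        current, occ, config
                    )
                current = SessionRecord(participant_id=pid, config=config)
                sessions.append(current)
                occ = [0, 0]
            trial_index = _parse_int(values["trial"], 1, 10**9, row_number, "trial")
            if trial_index != len(current.trials) + 1:
                raise SessionLogError(
                    f"row {row_number}: column 'trial' not contiguous: "
                    f"expected {len(current.trials) + 1}, got {trial_index}"
                )
            target = Card(
                _parse_int(values["target_color"], 1, 4, row_number, "target_color"),
                _parse_int(values["target_shape"], 1, 4, row_number, "target_shape"),
                _parse_int(values["target_number"], 1, 4, row_number, "target_number"),
            )
            chosen = _parse_int(values["chosen_keycard"], 1, 4, row_number, "chosen_keycard")
            key = values["response_key"]
            if key != RESPONSE_KEYS[chosen - 1]:
                raise SessionLogError(
                    f"row {row_number}: column 'response_key' {key!r} does not match "
                    f"chosen_keycard {chosen}"
                )
            tag = _parse_enum(values["opportunity_tag"], _TAG_BY_NAME, row_number, "opportunity_tag")
            record = TrialRecord(
                trial_index=trial_index,
                target=target,
                rule=_parse_enum(values["rule"], _DIMENSIONS_BY_NAME, row_number, "rule"),
                chosen_keycard=chosen,
                response_key=key,
                matched=_parse_enum(
                    values["matched_dimension"], _MATCH_BY_NAME, row_number, "matched_dimension"
                ),
                feedback=_parse_enum(
                    values["feedback"],
                    {"1": Feedback.CORRECT, "0": Feedback.INCORRECT},
                    row_number,
                    "feedback",
                ),
                rule_switch_before=_parse_enum(
                    values["rule_switch_before"], _BOOL_BY_NAME, row_number, "rule_switch_before"
                ),
                opportunity_tag=tag,
            )
            current.trials.append(record)
            if tag is OpportunityTag.NON_REPETITIVE:
                occ[0] += 1
            elif tag is OpportunityTag.REPETITIVE:
                occ[1] += 1
        if current is not None:
            current.termination_reason = _derive_termination(current, occ, config)
    return sessions


def _derive_termination(
    session: SessionRecord, occ: list[int], config: SessionConfig
) -> Termination:
    reason = check_termination(len(session.trials), occ[0], occ[1], config)
    return reason if reason is not None else Termination.MAX_TRIALS


def write_measures_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Measures table; undefined values serialize as empty cells."""
    frame.to_csv(path, index=False, na_rep="")


def read_measures_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
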