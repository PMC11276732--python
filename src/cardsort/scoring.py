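"""Trial labelling, occasion counting, per-participant measures, cohort rules.

Label semantics
---------------
* A *perseveration error* repeats the dimension disconfirmed by error
  feedback on the immediately preceding trial.  Its occasion is
  *repetitive* when the previous card's feature on that dimension repeats on
  the current card, *non-repetitive* when it changes; the occasion status is
  a property of the trial, independent of the committed response.
* An *integration error* occasion arises after informative errors on two
  consecutive trials disconfirming two distinct dimensions; re-choosing the
  first-excluded dimension is the integration error (re-choosing the second
  is a perseveration error and takes that label).
* A *set-loss* occasion is any trial following confirmed-correct feedback
  with no covert rule switch in between; a dimension-matching error there is
  a set-loss error.  The first trial after a covert switch is excluded: the
  old-rule response there is an unavoidable switch-signal error.
* The odd response (no shared feature) is an odd error everywhere and is
  never informative about a dimension.

Label precedence on conflicts: OE > PE > IE > SLE > SWITCH_SIGNAL_ERROR >
UNCLASSIFIED_ERROR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .cards import Dimension, ODD
from .engine import Feedback, SessionRecord, TrialRecord


class TrialLabel(Enum):
    CORRECT = "CORRECT"
    PE_REP = "PE_REP"
    PE_NONREP = "PE_NONREP"
    SLE = "SLE"
    IE = "IE"
    OE = "OE"
    SWITCH_SIGNAL_ERROR = "SWITCH_SIGNAL_ERROR"
    UNCLASSIFIED_ERROR = "UNCLASSIFIED_ERROR"

    def __repr__(self) -> str:
        return self.value


class PEOccasion(Enum):
    NONE = "NONE"
    REPETITIVE = "REPETITIVE"
    NON_REPETITIVE = "NON_REPETITIVE"

    def __repr__(self) -> str:
        return self.value


@dataclass(frozen=True)
class OccasionFlags:
    pe_occasion: PEOccasion = PEOccasion.NONE
    sle_occasion: bool = False
    ie_occasion: bool = False
    ie_first_excluded: Optional[Dimension] = None


class LabelledTrial(NamedTuple):
    record: TrialRecord
    label: TrialLabel
    flags: OccasionFlags


def informative_error_dimension(trial: TrialRecord) -> Optional[Dimension]:
    """Dimension disconfirmed by this trial's feedback, if any.

    Incorrect feedback on a dimension-matching response disconfirms that
    dimension; correct feedback and odd responses disconfirm nothing.
    """
    if trial.feedback is Feedback.INCORRECT and trial.matched is not ODD:
        return trial.matched
    return None


def _check_record(trial: TrialRecord) -> None:
    expected = Feedback.CORRECT if trial.matched is trial.rule else Feedback.INCORRECT
    if trial.feedback is not expected:
        raise ValueError(
            f"trial {trial.trial_index}: feedback {trial.feedback} inconsistent "
            f"with matched={trial.matched!r} under rule {trial.rule!r}"
        )


def label_trials(session: SessionRecord) -> list[LabelledTrial]:
    """Assign exactly one label and the occasion flags to every trial."""
    labelled: list[LabelledTrial] = []
    prev: Optional[TrialRecord] = None
    d_prev: Optional[Dimension] = None  # informative error dim of t-1
    d_prev2: Optional[Dimension] = None  # informative error dim of t-2
    for trial in session.trials:
        _check_record(trial)

        pe_occasion = PEOccasion.NONE
        if d_prev is not None and prev is not None:
            if trial.target.index_on(d_prev) == prev.target.index_on(d_prev):
                pe_occasion = PEOccasion.REPETITIVE
            else:
                pe_occasion = PEOccasion.NON_REPETITIVE
        ie_occasion = (
            d_prev is not None and d_prev2 is not None and d_prev2 is not d_prev
        )
        flags = OccasionFlags(
            pe_occasion=pe_occasion,
            sle_occasion=(
                prev is not None
                and prev.feedback is Feedback.CORRECT
                and not trial.rule_switch_before
            ),
            ie_occasion=ie_occasion,
            ie_first_excluded=d_prev2 if ie_occasion else None,
        )

        if trial.feedback is Feedback.CORRECT:
            label = TrialLabel.CORRECT
        elif trial.matched is ODD:
            label = TrialLabel.OE
        elif pe_occasion is not PEOccasion.NONE and trial.matched is d_prev:
            label = (
                TrialLabel.PE_REP
                if pe_occasion is PEOccasion.REPETITIVE
                else TrialLabel.PE_NONREP
            )
        elif flags.ie_occasion and trial.matched is flags.ie_first_excluded:
            label = TrialLabel.IE
        elif flags.sle_occasion:
            label = TrialLabel.SLE
        elif trial.rule_switch_before and prev is not None and trial.matched is prev.rule:
            label = TrialLabel.SWITCH_SIGNAL_ERROR
        else:
            label = TrialLabel.UNCLASSIFIED_ERROR

        labelled.append(LabelledTrial(trial, label, flags))
        d_prev2 = d_prev
        d_prev = informative_error_dimension(trial)
        prev = trial
    return labelled


@dataclass(frozen=True)
class MeasureSet:
    """All per-participant session measures.

    Undefined percentages (zero-occasion denominators) are NaN, never 0.
    ``ese`` is the non-repetitive minus repetitive perseveration percentage;
    ``ese_sum`` is their difference over their sum, defined only when at
    least one perseveration error was committed.
    """

    n_total_trials: int
    n_categories: int
    categories_pct: float
    n_occ_pe: int
    n_pe: int
    n_occ_npe: int
    n_npe: int
    n_occ_rpe: int
    n_rpe: int
    npe_pct: float
    rpe_pct: float
    ese: float
    ese_sum: float
    n_occ_sle: int
    n_sle: int
    sle_pct: float
    n_occ_ie: int
    n_ie: int
    ie_pct: float
    n_oe: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


MEASURE_COLUMNS = tuple(f.name for f in fields(MeasureSet))


def _pct(count: int, occasions: int) -> float:
    return 100.0 * count / occasions if occasions > 0 else math.nan


def compute_measures(
    session: SessionRecord,
    labelled: Optional[Sequence[LabelledTrial]] = None,
) -> MeasureSet:
    """Reduce a labelled session to its per-participant measure row."""
    if labelled is None:
        labelled = label_trials(session)
    n_total = len(labelled)

    # categories recomputed from the feedback stream, independent of the
    # engine's internal counter
    n_categories = 0
    run = 0
    for item in labelled:
        if item.record.feedback is Feedback.CORRECT:
            run += 1
            if run >= session.config.category_length:
                n_categories += 1
                run = 0
        else:
            run = 0

    counts = {label: 0 for label in TrialLabel}
    n_occ_npe = n_occ_rpe = n_occ_sle = n_occ_ie = 0
    for item in labelled:
        counts[item.label] += 1
        if item.flags.pe_occasion is PEOccasion.NON_REPETITIVE:
            n_occ_npe += 1
        elif item.flags.pe_occasion is PEOccasion.REPETITIVE:
            n_occ_rpe += 1
        if item.flags.sle_occasion:
            n_occ_sle += 1
        if item.flags.ie_occasion:
            n_occ_ie += 1

    n_npe = counts[TrialLabel.PE_NONREP]
    n_rpe = counts[TrialLabel.PE_REP]
    npe_pct = _pct(n_npe, n_occ_npe)
    rpe_pct = _pct(n_rpe, n_occ_rpe)
    ese = npe_pct - rpe_pct
    if n_npe + n_rpe > 0 and not math.isnan(ese):
        ese_sum = (npe_pct - rpe_pct) / (npe_pct + rpe_pct)
    else:
        ese_sum = math.nan

    return MeasureSet(
        n_total_trials=n_total,
        n_categories=n_categories,
        categories_pct=_pct(n_categories, n_total),
        n_occ_pe=n_occ_npe + n_occ_rpe,
        n_pe=n_npe + n_rpe,
        n_occ_npe=n_occ_npe,
        n_npe=n_npe,
        n_occ_rpe=n_occ_rpe,
        n_rpe=n_rpe,
        npe_pct=npe_pct,
        rpe_pct=rpe_pct,
        ese=ese,
        ese_sum=ese_sum,
        n_occ_sle=n_occ_sle,
        n_sle=counts[TrialLabel.SLE],
        sle_pct=_pct(counts[TrialLabel.SLE], n_occ_sle),
        n_occ_ie=n_occ_ie,
        n_ie=counts[TrialLabel.IE],
        ie_pct=_pct(counts[TrialLabel.IE], n_occ_ie),
        n_oe=counts[TrialLabel.OE],
    )


def measures_frame(
    cohort: Sequence[MeasureSet],
    participant_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One row per participant, columns in the canonical measure order."""
    frame = pd.DataFrame([m.as_dict() for m in cohort], columns=MEASURE_COLUMNS)
    if participant_ids is not None:
        frame.insert(0, "participant_id", list(participant_ids))
    return frame


@dataclass(frozen=True)
class Exclusion:
    participant: str
    reason: str


def aggregate_and_exclude(
    cohort: pd.DataFrame | Sequence[MeasureSet],
    min_occasions: int = 8,
) -> tuple[pd.DataFrame, list[Exclusion], pd.DataFrame]:
    """Apply the cohort exclusion rules and compute descriptive statistics.

    Excludes participants (a) more than 3 SD below the cohort mean category
    count, (b) more than 3 SD above the cohort mean odd-error count, or (c)
    with fewer than ``min_occasions`` occasions of either perseveration type.
    Returns (retained rows, exclusion report, descriptives).  Descriptives
    (N, mean, SD, median, Q1, Q3, min, max per measure) are computed on the
    retained rows with pairwise deletion of undefined values.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = measures_frame(cohort)
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 rows (SD undefined)")
    frame = cohort.reset_index(drop=True)
    ids = (
        frame["participant_id"].astype(str)
        if "participant_id" in frame.columns
        else frame.index.map(str)
    )

    cat_mean, cat_sd = frame["n_categories"].mean(), frame["n_categories"].std(ddof=1)
    oe_mean, oe_sd = frame["n_oe"].mean(), frame["n_oe"].std(ddof=1)

    exclusions: list[Exclusion] = []
    keep = np.ones(len(frame), dtype=bool)
    for i in range(len(frame)):
        reasons = []
        if frame.loc[i, "n_categories"] < cat_mean - 3 * cat_sd:
            reasons.append("n_categories more than 3 SD below cohort mean")
        if frame.loc[i, "n_oe"] > oe_mean + 3 * oe_sd:
            reasons.append("n_oe more than 3 SD above cohort mean")
        if (
            frame.loc[i, "n_occ_npe"] < min_occasions
            or frame.loc[i, "n_occ_rpe"] < min_occasions
        ):
            reasons.append(
                f"fewer than {min_occasions} occasions of a perseveration type"
            )
        if reasons:
            keep[i] = False
            for reason in reasons:
                exclusions.append(Exclusion(participant=ids[i], reason=reason))

    retained = frame.loc[keep].reset_index(drop=True)
    numeric = retained[list(MEASURE_COLUMNS)]
    descriptives = pd.DataFrame(
        {
            "N": numeric.notna().sum(),
            "mean": numeric.mean(),
            "sd": numeric.std(ddof=1),
            "median": numeric.median(),
            "q1": numeric.quantile(0.25),
            "q3": numeric.quantile(0.75),
            "min": numeric.min(),
            "max": numeric.max(),
        }
    )
    return retained, exclusions, descriptives
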