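"""Independent, naive re-implementations used as test oracles.

These transcribe the labelling definitions directly with explicit list
indexing and share no code with the package's scorer.
"""

from cardsort.cards import ODD


def _informative(trials, j):
    """Dimension disconfirmed by trial j, or None (odd / correct / j < 0)."""
    if j < 0:
        return None
    t = trials[j]
    if t.feedback.value == "INCORRECT" and t.matched is not ODD:
        return t.matched
    return None


def oracle_labels(session):
    """Label names plus occasion tuples, computed naively per trial."""
    trials = session.trials
    out = []
    for i, tr in enumerate(trials):
        e1 = _informative(trials, i - 1)  # previous trial
        e2 = _informative(trials, i - 2)  # two back

        if e1 is not None:
            same_feature = trials[i].target.index_on(e1) == trials[i - 1].target.index_on(e1)
            pe_occ = "REPETITIVE" if same_feature else "NON_REPETITIVE"
        else:
            pe_occ = "NONE"

        ie_occ = e1 is not None and e2 is not None and e2 is not e1
        sle_occ = (
            i > 0
            and trials[i - 1].feedback.value == "CORRECT"
            and not tr.rule_switch_before
        )

        if tr.feedback.value == "CORRECT":
            label = "CORRECT"
        elif tr.matched is ODD:
            label = "OE"
        elif pe_occ != "NONE" and tr.matched is e1:
            label = "PE_REP" if pe_occ == "REPETITIVE" else "PE_NONREP"
        elif ie_occ and tr.matched is e2:
            label = "IE"
        elif sle_occ:
            label = "SLE"
        elif tr.rule_switch_before and i > 0 and tr.matched is trials[i - 1].rule:
            label = "SWITCH_SIGNAL_ERROR"
        else:
            label = "UNCLASSIFIED_ERROR"
        out.append((label, pe_occ, sle_occ, ie_occ))
    return out
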