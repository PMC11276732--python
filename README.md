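# cardsort

A simulatable card-sorting task engine with a full perseveration-error
taxonomy, parametric synthetic participants, and a Bayesian inference layer.

Participants (here: simulated agents) match target cards to one of four
fixed keycards by a covert rule — color, shape, or number — that advances
cyclically after six consecutive correct sorts. The package provides:

- **`cardsort.cards`** — the stimulus space: feature-index cards, the fixed
  keycard panel (keys Y/C/B/M), the 24-card unambiguous deck, and response
  classification (matched dimension or the odd keycard).
- **`cardsort.sequencer`** — constrained pseudo-random target selection: no
  exact repeats, and a fair-coin 50/50 balance of repetitive vs
  non-repetitive perseveration opportunities after informative errors.
- **`cardsort.engine`** — the session state machine: covert rule schedule,
  feedback, category counting, and termination (240-trial cap or early stop
  once both perseveration-occasion counters reach 20).
- **`cardsort.scoring`** — trial labelling (repetitive/non-repetitive
  perseveration, set-loss, integration, odd, switch-signal errors), occasion
  counting, per-participant measures including the error-suppression score
  (nPE% − rPE%), and cohort exclusion rules with descriptive statistics.
- **`cardsort.agents`** — synthetic participants with separate perseveration
  probabilities in repetitive vs non-repetitive post-error contexts, plus
  set-loss, integration-failure, and odd-error rates.
- **`cardsort.bayes`** — JZS (Cauchy-prior) paired-samples Bayes factor, the
  posterior of the standardized effect δ (median and 95% credible interval),
  order-constrained posterior model probabilities (δ > 0 vs δ < 0) via the
  encompassing-prior tail-mass ratio, robustness/sequential curves, and
  stretched-beta correlation Bayes factors. All Bayes factors are natural
  logs.
- **`cardsort.io` / `cardsort.cli`** — CSV session logs and measure tables,
  plus the command-line interface.

## Command-line usage

```sh
# simulate a 100-agent cohort to a session-log CSV
cardsort simulate --n-agents 100 --seed 7 --out sessions.csv \
    --p-pers-nonrep 0.10 --p-pers-rep 0.04 --p-sle 0.05 --p-ie 0.15 --p-oe 0.004

# score it into per-participant measures (+ exclusion report)
cardsort score --in sessions.csv --out measures.csv --exclusions-out excl.json

# full Bayesian report from the measures table (+ correlation Bayes factors)
cardsort analyze --measures measures.csv --out report.json \
    --correlations-out correlations.csv

# Bayesian paired t-test from summary statistics alone
cardsort ttest-summary --mean 5.3 --sd 8.7 --n 489
```

All commands log the seed, version, and a config hash to stderr; identical
seeds and settings produce byte-identical artifacts.

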