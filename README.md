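# beescore

Individual honeybees trained on the same olfactory discrimination task
perform very differently: some switch into a learned state within a
couple of trials and keep responding reliably, others barely respond at
all. `beescore` is an analysis pipeline for quantifying that
heterogeneity from sequential proboscis-extension-response (PER)
conditioning experiments. It is aimed at behavioral neuroscientists
who record trial-level binary responses (PER / no PER) for harnessed
bees and want per-individual performance scores, performer
classification and the accompanying statistical battery, plus a
simulator for protocol-faithful synthetic cohorts.

## The protocol and the score

One experimental run has two phases, each a round of differential
conditioning followed by two retention tests. Conditioning presents 12
alternating trials (6 CS+, 6 CS−, starting with the CS+) of two pure
odors, with only the CS+ reinforced by sucrose. Each retention set
probes the CS+ and CS− at ascending concentrations (10⁻³, 10⁻², pure),
ending with paraffin-oil and plain filter-paper controls — 56 stimulus
events per bee in total.

Six unit-range variables are computed per bee (trial 1 of each
stimulus is never scored, because a response there cannot be
conditioned):

- **Acq-1, Acq-2** — acquisition rate: CS+ responses over conditioning
  trials 2–6 of each phase, ÷ 5;
- **DisCond-1, DisCond-2** — discrimination during conditioning: CS+
  responses *not* followed by a response to the next CS−, ÷ 5;
- **DisT-1,-2, DisT-3,-4** — discrimination during retention: clean
  (CS+ yes, CS− no) same-concentration probe pairs over a phase's two
  retention sets, ÷ 6.

The cumulative performance score is their unweighted sum,

```
P = Acq1 + Acq2 + DisCond1 + DisCond2 + DisT12 + DisT34  ∈ [0, 6],
```

and bees with P ≥ 2.6 are classified as high performers. Because the
denominators are 5 and 6, every valid P-score lies on the 1/30
lattice — a useful integrity check on scored data.

Around the score the package provides the cohort statistics used with
this design (Monte-Carlo Lilliefors normality test, tie-corrected
Mann-Whitney U and Wilcoxon matched-pairs tests, Spearman
rank-correlation matrix, hierarchical R² decomposition of the P-score),
phase-contrast G-tests on response counts, a χ² gene-list overlap test
against a genome background of 13,440 genes, and the 2^−ΔΔCt qPCR fold
change.

The cohort simulator implements the abrupt learner-switch model: each
bee stays naive until, with a per-trial probability, it switches
permanently (within a phase) into a learned state; sensitivity to
diluted odors and spontaneous arousal are correlated with learning
speed, and phase-2 generalization to the CS− is higher. See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
from beescore import (CohortConfig, simulate_cohort, score_cohort,
                      classify_performers, hierarchical_regression)

table, traits = simulate_cohort(CohortConfig(n_bees=171, seed=1))
scores = score_cohort(table)
print(classify_performers(scores).n_high)
reg = hierarchical_regression(scores)
print([round(s.r2_change, 3) for s in reg.steps], reg.final_r2)
```

prints

```
106
[0.787, 0.142, 0.002, 0.023, 0.03, 0.015] 1.0
```

— 106 of the 171 simulated bees classify as high performers, the
phase-1 acquisition rate alone carries 78.7 % of the P-score variance
in this cohort, and the six variables together reach R² = 1 exactly
because the P-score is their sum. The `examples/` directory holds one
short script per capability (simulation + scoring, phase contrasts,
classification + regression, gene-list overlap); each prints the
numbers it computes and a line on what they mean. A thin CLI mirrors
the same operations:

```
beescore simulate --n-bees 171 --seed 1 --out run/
beescore analyze --table run/responses.csv --threshold 2.6 --out run/report/
beescore overlap --list-a a.txt --list-b b.txt --genome-size 13440
```

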