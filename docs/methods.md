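# Methods

## Scoring model

A bee's record is 56 binary responses tiling the two-phase sequential
conditioning protocol. Scoring consumes only the response pattern;
odor identities and inter-trial timing are metadata.

The six behavioral variables divide response counts by the number of
*scorable* presentations. The first conditioning trial of both the
CS+ and the CS− is excluded everywhere — a response before any
reinforcement cannot be a conditioned response — leaving denominators
of 5 for the conditioning variables. The conditioning discrimination
variables pair each CS+ trial with the CS− presentation that
immediately follows it in the alternating schedule; the retention
variables pair each CS+ probe with the same-concentration CS− probe
that follows it, giving 3 pairs per retention set and 6 per phase.

The retention variables are normalized by 6 (pooled over a phase's two
sets), equivalently the mean of the two per-set scores each normalized
to 3. With a per-set normalization of 3 alone the variable could reach
2 and the P-score 8, contradicting its 0–6 range; the pooled
normalization also places every P-score on the 1/30 lattice, which the
published per-bee scores respect (to 2-decimal truncation), and the
package asserts this lattice invariant on all scored output.

High/low classification uses P ≥ 2.6 for "high", with the boundary
value classified high. The threshold is an operational cut inherited
from the array-selection design, not a fitted parameter.

## Cohort statistics

- **Lilliefors test.** The statistic is the KS sup-distance between
  the empirical CDF and a normal CDF with mean and SD estimated from
  the sample. The p-value comes from a seeded Monte-Carlo null
  (default 10,000 standard-normal samples of the same n, identical
  estimator) rather than a tabulated approximation: estimation makes
  the null parameter-free, so the simulated p is exact in distribution
  at any n and fully reproducible under a seed. Samples with n < 5 or
  zero variance are rejected (or reported as NaN inside the
  distribution summary).
- **Mann-Whitney U / Wilcoxon matched-pairs.** Midranks for ties,
  tie-corrected variance in the normal approximation, no continuity
  correction. U is reported as the smaller of the two U statistics,
  T as the smaller signed-rank sum with zero differences dropped. At
  very small n the normal approximation deviates from the exact
  permutation distribution by up to ~0.1 in p; the test suite checks
  both statistics against full enumeration oracles (all C(8,4)
  labelings, all 2⁶ sign flips).
- **Spearman matrix.** Pearson correlation on midranks; a constant
  variable yields NaN against every partner rather than an error;
  p-values by the t approximation on n−2 df.
- **Hierarchical regression.** OLS refit at each of the six steps in
  the fixed entry order (Acq1, Acq2, DisCond1, DisCond2, DisT12,
  DisT34); ΔR²_k = R²_k − R²_{k−1}, F-change = ΔR²·(n−k−1)/(1−R²_k) on
  (1, n−k−1) df; standardized β from the single full model on z-scored
  variables. Because the response is the exact sum of the predictors
  the final step is saturated: R² within 10⁻¹⁰ of 1 is snapped to
  exactly 1.0 and the final F and p are reported as undefined (NaN) —
  a change statistic has no meaning at zero residual variance.
  Rank-deficient designs raise an error naming the offending step.
- **Contingency tests.** G = 2·Σ O·ln(O/E) and Pearson χ², both
  uncorrected (no Yates/Williams), df = 1. The uncorrected dialect is
  the one that reproduces the published overlap χ² values to all four
  printed decimals, and G and χ² agree within 5 % on large balanced
  tables. The phase-contrast builder counts CS± responses over scored
  conditioning trials 2–6 (5·n_bees presentations per phase) or over
  the six retention probes per phase (6·n_bees) — the denominators
  under which the published G statistics (214.8, 96.63) recompute
  exactly from their printed response counts.
- **Gene-list overlap.** Identifiers are whitespace-trimmed and
  deduplicated case-sensitively, with no alias resolution (lists from
  a single platform). The 2×2 partition of the genome (default
  N = 13,440) is tested with the uncorrected χ²; the independence
  expectation of the overlap cell equals the hypergeometric mean
  |A|·|B|/N.

## The simulator

The generator implements the abrupt learner-switch model of
individual acquisition. Per phase, a bee starts naive; before each
CS+ conditioning event from the second onward it switches into the
learned state with probability `switch_prob`, permanently for that
phase. Naive bees respond to everything at `baseline`; learned bees
respond to the CS+ at `asymptote` (attenuated at retention dilutions
by `expit(sensitivity + log10 c)`, pure ≡ 10⁰), to the CS− at a
phase-specific generalization probability, and to oil/paper at
`baseline`. Switching is evaluated independently per phase — the
phases use different odor pairs and cross-phase transfer is not
modeled.

Traits are drawn per bee from a two-component logit-normal mixture
(fast/slow learners, weights 0.69/0.31). Three latent standard
normals drive a draw: one behind `switch_prob`; an "arousal" latent
shared by `sensitivity` and `baseline`; and one shared by the two
generalization probabilities (which keeps phase-2 generalization above
phase-1 whenever the means are ordered that way). `rho_traits`
(default 0.7) correlates the switch and arousal latents, so fast
learners tend to be more odor-sensitive and more spontaneously
responsive — the coupling that yields a positive association between
acquisition rate and control-stimulus responding in simulated cohorts.

Default hyperparameters are soft-calibrated so the components' mean
Acq-1 sit near 0.76 and 0.13 and phase-2 CS− responding clearly
exceeds phase-1; the defaults are a fixed description of the emulated
study conditions, not tuning knobs. `separated_components()` provides
an alternative, deliberately well-separated mixture (P-score component
means near 4.5 and 1.0) for classification-recovery demonstrations.

What the simulator does *not* emulate: continuous associative-strength
dynamics (no Rescorla–Wagner variant), satiation/fatigue or
sensitization drift across the 6.5-hour session, extinction during
unreinforced retention probes, colony or seasonal effects (colony and
month columns are decorative metadata), and any phase-2 change in
switch probability — so the empirical pattern of slow learners
improving in the second phase is not reproduced. Passing tests
therefore certify the pipeline's arithmetic and the qualitative
structure of the model, not distributional fidelity to any real
cohort.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; bees use distinct
child seed sequences of (seed, bee index), so cohorts are reproducible
bee-by-bee and byte-identical across runs. Monte-Carlo checks in the
test suite use 10,000 replicate bees against the closed-form
acquisition expectation (1/5)·Σ_{t=2..6}(1−(1−s)^{t−1}), 5,000 bees
per level for trait monotonicity, 20 seeds for directional cohort
properties, and 200 replicates for the uniformity of the Lilliefors
null p-value; exhaustive oracles cover all 4,096 joint conditioning
response patterns. These sizes keep each check's sampling error well
inside its assertion band.
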