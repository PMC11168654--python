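"""Simulate a small cohort and compute per-bee performance scores.

Each simulated bee runs the full 56-event protocol (two phases of 12
alternating conditioning trials plus two retention sets each).  The
scores are the six unit-range behavioral variables and their sum, the
P-score (0-6); control_responses counts responses to the 8 odorless
stimulations.
"""

from beescore import CohortConfig, score_cohort, simulate_cohort

table, traits = simulate_cohort(CohortConfig(n_bees=20, seed=42))
scores = score_cohort(table)

print(scores.head(5).to_string(index=False))
print()
print(f"cohort mean P-score: {scores.Pscore.mean():.2f} "
      f"(SD {scores.Pscore.std(ddof=1):.2f})")
print("A P-score near 6 means fast CS+ acquisition plus clean CS+/CS-"
      " discrimination in both conditioning and retention; near 0 means"
      " the bee rarely responded or never discriminated.")
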