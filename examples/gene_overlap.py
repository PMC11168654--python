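"""Test gene-list overlap against the honeybee genome background.

Given two gene lists drawn from a genome of 13,440 annotated genes, the
chi-square test on the 2x2 partition (in both / A only / B only /
neither) asks whether they share more members than chance.  The first
call recomputes a published comparison from its printed counts; the
second runs from actual identifier lists.
"""

from beescore import overlap_test, overlap_test_from_counts

res = overlap_test_from_counts(n_a=326, n_b=481, k=24, genome_size=13440)
print(f"lists of {res.n_a} and {res.n_b} genes sharing {res.k} "
      f"(expected {res.expected_overlap:.1f} by chance): "
      f"chi2 = {res.chi2:.4f}, p = {res.p:.6f} -> {res.direction}")

list_a = [f"GB{10000 + i}" for i in range(40)]
list_b = [f"GB{10030 + i}" for i in range(40)]  # 10 shared identifiers
res = overlap_test(list_a, list_b)
print(f"synthetic lists, overlap {res.k} vs expected "
      f"{res.expected_overlap:.2f}: chi2 = {res.chi2:.1f}, "
      f"p = {res.p:.2e} -> {res.direction}")
print("An overlap far above the independence expectation |A||B|/N"
      " indicates the two screens tag a shared gene set.")
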