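"""The statistics layer: Welch t-test, Fisher's exact test, cohort percentages.

Compares per-cell CBF between a control and a mutant group, tests a
beat-mode contingency table, and prints rounded cohort fractions.
"""

from ciliaquant import fisher_exact, proportion_summary, welch_t_test

control_cbf = [7.8, 8.4, 9.1, 8.8, 7.5, 9.4, 8.1, 8.9]
mutant_cbf = [2.1, 0.0, 3.4, 1.2, 0.0, 2.8, 1.9]
res = welch_t_test(control_cbf, mutant_cbf)
print(f"Welch t-test on per-cell CBF: t={res.t:.2f}, df={res.df:.1f}, p={res.p:.2e}")

# beat-mode tallies: rows = groups, columns = (static-or-restricted, beating)
table = [[2, 16], [14, 4]]
p, odds = fisher_exact(table)
print(f"Fisher's exact test on beat modes: p={p:.2e}, odds ratio={odds:.3f}")

for name, k, n in [("sinus disease", 19, 31), ("lower airway disease", 15, 30),
                   ("hearing issues", 19, 31)]:
    print(f"{name}: {proportion_summary(k, n)}")
# Percentages round half-up in exact integer arithmetic, matching how
# cohort fractions are conventionally printed.
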