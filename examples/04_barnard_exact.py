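"""Barnard's unconditional exact test on a small 2x2 table, vs Fisher's.

The table below records 8 of 10 "successes" in row 1 against 3 of 10 in
row 2. Barnard's test fixes only the row sizes and maximizes the tail
probability over the unknown common success probability pi; Fisher's test
conditions on both margins. On small tables Barnard's p is typically the
smaller of the two — the reason it is preferred for discordant-twin
contingency batteries.
"""

from twinepi import Table2x2, barnard_p, fisher_p

table = Table2x2(x1=8, n1=10, x2=3, n2=10)
res = barnard_p(table, alternative="greater")
print(f"table: {table}")
print(f"Wald statistic T = {res.wald_stat:.4f}")
print(f"Barnard p (greater) = {res.p_value:.5f}  (sup at pi = {res.pi_at_sup:.4f})")
print(f"Fisher  p (greater) = {fisher_p(table, 'greater'):.5f}")
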