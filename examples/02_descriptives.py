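"""Descriptive statistics of the epigenetic subsample, publication-table style.

Prints M, Mdn, s, Min, Max, Sk and Ku for the five CpG methylation sites and
the five NEO-PI-R domains. Methylation rows should show strong right skew
(Sk ~ 2) and zero minima; domain rows are roughly symmetric.
"""

import pandas as pd

from twinepi import SimulationConfig, gen_cohort, descriptives_table

cohort = gen_cohort(SimulationConfig(seed=1)).cohort
rows = descriptives_table(cohort, subset="epi")
print(pd.DataFrame(rows).to_string(index=False))
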