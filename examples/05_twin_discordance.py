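"""Discordant-pair battery with a planted methylation-trait association.

Plants a delta = 0.35 effect at (CpG5, Impulsiveness) favoring the "less"
alternative: the higher-methylation co-twin gets the higher Impulsiveness
score with probability 0.85. The 350-cell battery (5 CpG x 35 scales x 2
alternatives) should rank exactly that cell most significant.
"""

from twinepi import SimulationConfig, gen_cohort, run_epigenetic_battery
from twinepi.discordance import summarize_significant
from twinepi.simulate import PlantedEffect

config = SimulationConfig(
    seed=2, planted_effect=PlantedEffect(5, "impulsiveness", 0.35, "less")
)
cells = run_epigenetic_battery(gen_cohort(config).cohort)

top = sorted(cells, key=lambda c: c.p_value)[:5]
print(f"{'cpg':>3s} {'scale':22s} {'alt':8s} {'table':>16s} {'p':>9s}")
for c in top:
    t = c.table
    print(
        f"{c.cpg:3d} {c.scale:22s} {c.alternative:8s} "
        f"{f'{t.x1}/{t.n1} vs {t.x2}/{t.n2}':>16s} {c.p_value:9.5f}"
    )
report = summarize_significant(cells, alpha=0.05)
print(f"\ncells with p <= 0.05: {report['n_significant']} of {report['n_cells']}")
# Each table row is the count of co-twins with the lower trait score among
# the higher- (x1/n1) and lower- (x2/n2) methylation twins of each pair.
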