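"""Select stable reference genes by GeNorm stepwise exclusion.

Simulates a ten-subject blood cohort in the 2 RT x 3 PCR design, computes
relative quantities, then ranks six candidate reference genes by the
stability measure M (average pairwise variation of log2 expression
ratios).  The least stable gene is excluded round by round; the three most
stable genes with M < 0.5 become the reference set.
"""

from earnorm import (SimulationConfig, quantities_wide, quantity_table,
                     simulate_experiment, stepwise_ranking)

table, truth = simulate_experiment(SimulationConfig(), seed=1)
wide = quantities_wide(quantity_table(table))
panel = [g for g in wide.columns if g not in ("BDNF", "EAR")]

report = stepwise_ranking(wide, panel, threshold=0.5)
for rnd in report.rounds:
    ms = ", ".join(f"{g}={m:.3f}" for g, m in sorted(rnd.m_by_gene.items()))
    print(f"round with {len(rnd.remaining_genes)} genes: {ms}")
    print(f"  -> excluded {rnd.excluded}")
print(f"ranking (most stable first): {', '.join(report.ranking)}")
print(f"selected references (M < {report.threshold}): "
      f"{', '.join(report.selected_references)}")
print()
print("Lower M = more stable. The simulator gave GNB2L1/HPRT1/YWHAZ the")
print("least biological noise, and stepwise exclusion recovers exactly")
print("that trio as the reference set.")
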