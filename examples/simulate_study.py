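"""Generate a synthetic shift-work heart study and inspect its structure.

The design mirrors a 3-group rat experiment: control (C), shift worker (W),
and shift worker with restricted feeding (WRF), sampled every 4 h (ZT1..ZT21)
with 3 animals per group and timepoint.  Planted features: group-specific
rhythm fractions and phase clusters, dampened WRF amplitudes, one W replicate
series 8 h out of phase, and a WRF-specific block of fold-changed genes
expressed only in responder animals.
"""

import numpy as np

from circaheart import StudyConfig, generate_study

config = StudyConfig(seed=1, n_genes=2000)
matrix, truth = generate_study(config)

print(f"expression matrix: {matrix.values.shape[0]} genes x "
      f"{matrix.values.shape[1]} samples")
print(f"groups: {matrix.groups()}, ZTs: {sorted({s.zt for s in matrix.samples})}")
for g in ("C", "W", "WRF"):
    n_r = int(truth.genes[f"rhythmic_{g}"].sum())
    print(f"  {g}: {n_r} planted rhythmic genes "
          f"({100 * n_r / len(truth.genes):.1f}%)")
n_de = (truth.genes["de_direction"] != "").sum()
print(f"planted DE block: {n_de} genes "
      f"({(truth.genes['de_direction'] == 'up').sum()} up), "
      f"{len(truth.responder_animals)}/18 WRF responder animals")
print("first sample labels:", [s.label for s in matrix.samples[:4]])
# A rhythmic gene's planted parameters vs its realized values at its peak:
ridx = truth.genes.index[truth.genes["rhythmic_C"]][0]
row = truth.genes.loc[ridx]
print(f"example rhythmic gene {row['gene_id']}: baseline {row['baseline']:.1f} "
      f"fpkm, C amplitude {row['amplitude_C']:.1f}, C peak ZT{row['phase_C']:.1f}")
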