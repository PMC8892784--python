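"""Call rhythmically expressed genes with the six-detector ensemble.

Each gene/group is scored by harmonic (cosinor) regression, Lomb-Scargle,
JTK_CYCLE, ARSER, RAIN, and F24; the six p-values are combined with Fisher's
method and BH-adjusted across genes; genes with q < 0.05 are called rhythmic.
The printed counts reproduce the qualitative shift-work phenotype: fewer
rhythmic genes in W than C, more in WRF, with W/WRF phases clustered.
"""

import numpy as np

from circaheart import StudyConfig, call_rhythmic_genes, generate_study, \
    overlap_rhythmic_sets, phase_histogram

config = StudyConfig(seed=2, n_genes=600)
matrix, truth = generate_study(config)

calls = {}
for i, group in enumerate(("C", "W", "WRF")):
    calls[group] = call_rhythmic_genes(matrix, group, n_perm=1000, seed=10 + i)
    n = int(calls[group]["rhythmic"].sum())
    planted = len(truth.rhythmic_genes(group))
    print(f"{group}: {n} rhythmic genes called (planted {planted})")

print("\nVenn regions (exclusive):")
for region, count in overlap_rhythmic_sets(calls).items():
    print(f"  {region:10s} {count}")

hist = phase_histogram(calls["WRF"])
top = hist.sort_values("count", ascending=False).head(3)
print("\nWRF peak-phase bins (planted clusters at ZT8 and ZT20.5):")
for _, row in top.iterrows():
    print(f"  ZT[{row['bin_start']:.0f},{row['bin_end']:.0f}): "
          f"{row['count']} genes")
strong = calls["C"][calls["C"]["rhythmic"]].nsmallest(1, "q").iloc[0]
print(f"\nstrongest C rhythm: {strong['gene_id']} "
      f"(q={strong['q']:.2e}, peak ZT{strong['phase']:.1f}, "
      f"relative amplitude {strong['rel_amplitude']:.2f})")
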