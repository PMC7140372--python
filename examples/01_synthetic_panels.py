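"""Generate five differentiated synthetic reference panels and a genetic map.

The panels emulate the benchmark's source populations (Bantu-speaking
African, KhoeSan, European, East Asian, South East Asian) under a
Balding–Nichols model: each population's allele frequencies drift away from
a shared ancestral distribution by its `differentiation` parameter.
"""

import numpy as np

from admixbench import SAC_POPULATION_SPECS, make_genetic_map, simulate_panels

gmap = make_genetic_map(chromosome_length_bp=50_000_000, total_cm=50.0, n_points=200, seed=7)
panel = simulate_panels(SAC_POPULATION_SPECS, n_sites=1_000, gmap=gmap, seed=1)

print(f"panel: {panel.n_individuals} individuals, {panel.n_sites} phased biallelic sites")
freq = panel.freq()
print("\nmean absolute frequency difference between populations")
print("(larger = easier for any ancestry caller to tell the pair apart):")
pops = panel.populations
for i, a in enumerate(pops):
    for b in pops[i + 1:]:
        d = np.abs(freq.loc[a] - freq.loc[b]).mean()
        print(f"  {a:<15} vs {b:<15}: {d:.3f}")

panel.write_vcf("scratch_panel.vcf")
panel.write_popmap("scratch_panel.popmap.txt")
print("\nwrote scratch_panel.vcf (phased GT) and scratch_panel.popmap.txt")
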