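"""Express a continuous-migration demographic model and its expectation.

The bundled default is the five-way admixture scenario: a founding pulse
15 generations ago at the previously reported ancestry proportions
(32/30/19/7/12 %). `expected_proportions` evaluates the recursion
a_k(t) = (1 - sum_j m_j(t)) a_k(t-1) + m_k(t) in closed form, which is what
the forward simulator should reproduce on average.
"""

import numpy as np

from admixbench import MigrationSchedule, default_sac_schedule, expected_proportions

sched = default_sac_schedule()
print(f"schedule: G={sched.generations} generations, K={sched.n_ancestries} ancestries")
for anc, a in zip(sched.ancestries, expected_proportions(sched)):
    print(f"  expected final proportion {anc:<15}: {a:.3f}")

# add a late European inflow of 5% per generation over the last 3 generations
m = sched.m.copy()
m[-3:, sched.ancestries.index("European")] = 0.05
late = MigrationSchedule(ancestries=sched.ancestries, m=m)
print("\nwith 5% European inflow in each of the last 3 generations:")
for anc, a in zip(late.ancestries, expected_proportions(late)):
    print(f"  expected final proportion {anc:<15}: {a:.3f}")
print("-> recent migrants inflate their ancestry and dilute all others,")
print("   and carry long undivided tracts into the present generation.")
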