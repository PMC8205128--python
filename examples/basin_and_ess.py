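"""Evolutionary stability and basins of attraction.

A numerical scan confirms that the only evolutionarily stable monomorphic
state is take-and-yield (AllT, q=0) — deterrence is never an ESS.  Yet the
basin of attraction of that state shrinks as reputation information gets
cheaper, which is why deterrence nevertheless dominates in practice.
"""

import numpy as np

from deterrence import PayoffParams, basin_fraction, ess_scan

print("ESS scan at v=1, c=1.5, a=0.1 (all six challenger kinds x 21 q-levels):")
for kind, q in ess_scan(PayoffParams(1.0, 1.5, 0.1)):
    print(f"  evolutionarily stable: challenger={kind}, defender q={q}")
print("Deterrence states fail: (AllR, F) lets defender reactions drift, and")
print("(Disc, F) wastes the information cost against identical defenders.\n")

print("basin of the no-deterrence ESS (15^3 grid of initial states, v=c=1):")
for a in (0.05, 0.1, 0.2, 0.4):
    frac = basin_fraction(PayoffParams(1.0, 1.0, a), grid_resolution=15)
    print(f"  information cost a={a:.2f}: {100 * frac:5.1f}% of starts end in anarchy")
print("Cheap reputation information keeps the anarchic basin small; as a")
print("grows, more initial states collapse into take-and-yield.")
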