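"""Birth and death rates under the three production strategies.

Evaluates the state-dependent rates for a population of n producers and
m cheaters, showing how the quorum-sensing (QS) activation interpolates
between the always-on (AO) and no-production (NP) limits, and where the
pure-producer population balances births against deaths.
"""

from quorumbd import (
    ModelParameters,
    Strategy,
    equilibrium_producers,
    net_growth,
    producer_birth_rate,
)

p = ModelParameters(lambda0=0.2, c=0.15, mu0=0.01, Kg=15, Ka=15, hg=2, ha=2)

print("total producer birth rate at (n=15, m=5):")
for s in (Strategy.NP, Strategy.QS, Strategy.AO):
    rate = producer_birth_rate(15, 5, p, s)
    print(f"  {s.value:>3}: {rate:.4f} per unit time")
# NP never activates production (only the constitutive term remains),
# AO always produces at full cost, QS sits in between: at n = Ka = 15
# activation is exactly half-maximal.

n_star = equilibrium_producers(p)
print(f"\napproximate pure-producer equilibrium n* = {n_star}")
print(f"net growth at (n*={n_star}, m=0): {net_growth(n_star, 0, p, Strategy.AO):+.4f}")
print(f"net growth at (n=10,  m=0): {net_growth(10, 0, p, Strategy.AO):+.4f}")
# n* = round((lambda0 + g - c)/mu0) is where per-capita birth would meet
# the density-dependent death rate if the public-good benefit were
# saturated; demographic noise still drives such populations extinct
# eventually.
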