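"""Cheater fixation probability under each regulation strategy.

Solves the stationary backward-Kolmogorov system for the probability
that an invading cheater lineage takes over the population, starting
from the producer equilibrium with a single cheater.
"""

from quorumbd import (
    ModelParameters,
    Strategy,
    build_generator,
    equilibrium_producers,
    fixation_probability,
    producer_fixation_probability,
)

p = ModelParameters(lambda0=0.2, c=0.15, mu0=0.04)  # n* = 26 fits in N = 60
N = 60
n_star = equilibrium_producers(p)
print(f"invasion start: ({n_star} producers, 1 cheater), grid N = {N}\n")

for s in (Strategy.NP, Strategy.QS, Strategy.AO):
    gen = build_generator(p, s, N=N)
    pi = fixation_probability(gen)
    pi_pr = producer_fixation_probability(gen)
    v = pi.values[n_star, 1]
    print(f"  {s.value:>3}: pi_ch = {v:.5f}   (pi_ch + pi_pr = "
          f"{v + pi_pr.values[n_star, 1]:.6f})")

# QS lowers the cheater's fixation probability relative to AO because
# production (and hence the exploitable cost) only switches on at quorum;
# NP is lowest of all -- with no public good there is nothing to exploit.
# pi_ch + pi_pr = 1 verifies that one strain always fixes first.
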