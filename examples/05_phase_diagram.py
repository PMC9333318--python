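"""Destructive vs constructive quorum sensing over (lambda0, c).

For each cell of a coarse parameter grid, computes the fraction of mixed
starting compositions whose mean extinction time is larger under QS than
under AO.  Fraction 0 means QS is destructive (always shortens
persistence), 1 constructive, in between mixed.
"""

from quorumbd import ModelParameters, phase_diagram

base = ModelParameters(mu0=0.04)
lam_grid = [0.0, 0.1, 0.2, 0.3]
c_grid = [0.0, 0.1, 0.2]

pd_ = phase_diagram(lam_grid, c_grid, base, N=40)

print("fraction of mixed states with T_QS > T_AO  (rows: lambda0, cols: c)\n")
print("           " + "".join(f"c={c:<8}" for c in c_grid))
for i, lam in enumerate(lam_grid):
    row = "".join(f"{pd_.fraction[i, j]:<10.3f}" for j in range(len(c_grid)))
    print(f"lambda0={lam:<4} {row}")
print("\nclassification:")
for i, lam in enumerate(lam_grid):
    print(f"lambda0={lam:<4} " + "  ".join(f"{pd_.classification[i, j]:>12}" for j in range(len(c_grid))))
# Cost-free production (c = 0) makes QS destructive: gating a free benefit
# can only hurt.  Higher costs with a constitutive growth fallback move QS
# toward constructive, where delaying production until quorum pays off.
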