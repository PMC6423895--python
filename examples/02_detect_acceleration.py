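"""Detect human-branch acceleration of one element against its local ARE.

A neutral model is fitted by maximum likelihood on a simulated 2-kb ancient
repeat; a neutral and an accelerated (rho = 3) DHS are then scored with the
dual sub-branch tests. Small p-values on both tests mark acceleration.
"""

from acedhs.hky import Tree
from acedhs.phylo import acceleration_test, fit_neutral_model
from acedhs.simulate import DEFAULT_TREE, SimulationConfig, simulate_alignment

tree = Tree.from_newick(DEFAULT_TREE)
are = simulate_alignment(SimulationConfig(element_length=2_000, seed=1), "are")
neutral = fit_neutral_model(are, tree)
print(f"neutral fit: kappa = {neutral.kappa:.2f}, lnL = {neutral.loglik:.1f}")

for rho, label in ((1.0, "neutral DHS"), (3.0, "accelerated DHS")):
    dhs = simulate_alignment(
        SimulationConfig(element_length=800, human_rate_multiplier=rho, seed=6),
        label.replace(" ", "_"),
    )
    res = acceleration_test(dhs, neutral)
    print(
        f"{label}: rho_hat(A) = {res.rho_a:.2f}, p_A = {res.p_a:.3g}; "
        f"rho_hat(B) = {res.rho_b:.2f}, p_B = {res.p_b:.3g}"
    )
# The accelerated element shows rho_hat near 3 with p-values far below 0.05
# on both tests; the neutral element stays near the rho = 1 boundary.
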