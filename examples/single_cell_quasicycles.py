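"""Noise-induced quasi-cycles of L1 and Alu copy numbers in a single cell.

Simulates one cell of the basic predator-prey model with the Gillespie
algorithm, integrates the matching mean-field equations, and compares the
observed oscillations with the period predicted by the Jacobian's complex
eigenvalue pair at the stable stationary state.
"""

import numpy as np

import retrodyn as rd
from retrodyn.stats import estimate_period_autocorrelation

params = rd.default_parameters("basic")

traj = rd.simulate_cell(params, [250, 250, 100], 700, seed=1)
mf = rd.integrate_mean_field(params, [0.5, 0.5, 0.2], 700)

stable = [p for p in rd.find_stationary_points(params) if p.stable][0]
print("stable stationary concentrations (L, S, R_L):", stable.state)
print("stationary copy numbers:", params.V * stable.state)
print("mean-field final state:", np.round(mf.final_state, 6))

# the deterministic solution damps out, the stochastic one keeps cycling
L = traj.species("L").astype(float)
print("\nstochastic L over generations 100-700:")
print(f"  mean {L[100:].mean():.1f}, sd {L[100:].std():.1f} "
      f"(mean-field limit: {params.V * stable.state[0]:.0f}, damped to constant)")

predicted = stable.period
measured = estimate_period_autocorrelation(L[100:] - L[100:].mean())
print(f"\nquasi-cycle period: predicted 2*pi/|Im lambda| = {predicted:.1f} "
      f"generations, autocorrelation estimate = {measured:.0f} generations")
print("The linearization predicts ~27 generations; demographic noise keeps")
print("exciting the damped predator-prey mode, so the single cell oscillates")
print("indefinitely at that period instead of settling down.")
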