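"""Six-state allosteric sensor benchmark and Monte-Carlo convergence.

The empirical allosteric model (five sequential Ca2+ binding steps, fusion
rate multiplied by f per bound ion) describes release at the calyx of Held
and serves as the benchmark and as a validation target for the stochastic
machinery: its Gillespie estimate of cumulative release converges on the
master-equation solution at the Monte-Carlo rate 1/sqrt(N).
"""

import numpy as np

from synclamp import (
    LOU_2005,
    make_step,
    mc_error_nrmse,
    simulate_allosteric_ensemble,
    solve_allosteric_master,
)

trace = make_step(16.0, 20.0)
sol = solve_allosteric_master(trace, t_eval=np.linspace(0, 20, 401))
print(f"allosteric parameters (literature benchmark): {LOU_2005}")
print(f"master equation: n_T(20 ms) = {sol.n_T[-1]:.4f}, "
      f"peak rate = {sol.peak_rate()[0]:.4f} ms^-1")

for n_events in (1_000, 10_000, 100_000):
    times = simulate_allosteric_ensemble(trace, stop_events=n_events,
                                         rng_seed=2)
    emp = np.searchsorted(np.sort(np.asarray(times)), sol.t[1:],
                          side="right") / times.n_simulations
    err = mc_error_nrmse(emp, sol.n_T[1:])
    print(f"SSA with {n_events:>7d} recorded events "
          f"({times.n_simulations} simulations): NRMSE = {err:.3f}%")
print("\nThe error falls roughly 3-fold per 10-fold increase in events "
      "(1/sqrt(N)); 1e5 events keeps it below ~0.1%.")
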