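"""Syt7-dependent paired-pulse facilitation.

Drives the three clamp architectures with two synthetic AP-evoked Ca2+
transients and measures the paired-pulse ratio PPR = p_v(2)/p_v(1) in
matched 5-ms windows.  Only the Syt1P/Syt7T architecture facilitates:
Syt7's slow membrane exit (k_out = 0.02 ms^-1) leaves a fraction of
tripartite clamps still released when the second AP arrives.
"""

from synclamp import (
    SimulationProtocol,
    make_ap_transient,
    per_ap_efficacy,
    preset,
    simulate_ensemble,
    tripartite_free_probability,
)

ISIS = (20.0, 100.0, 500.0)
N_SIMS = 4000

for name in ("SYT1P", "SYT1P_SYT1T", "SYT1P_SYT7T"):
    row = []
    for isi in ISIS:
        trace = make_ap_transient(
            [1.0, 1.0 + isi], peak=15.0, local_width=0.25,
            residual_amp=0.5, residual_tau=40.0, baseline=0.05,
            t_end=6.0 + isi, coupling_distance_nm=50.0)
        proto = SimulationProtocol(trace=trace, n_simulations=N_SIMS,
                                   rng_seed=3, snapshot_dt=1.0)
        rec = simulate_ensemble(preset(name), proto)
        eff = per_ap_efficacy(rec, [1.0, 1.0 + isi], window_width=5.0)
        entry = f"ISI {isi:>5.0f} ms: PPR = {eff['PPR']:.2f}"
        if name != "SYT1P":
            p_free = tripartite_free_probability(rec, isi)  # just before AP2
            entry += f" (tripartite clamp still released: {p_free:.2f})"
        row.append(entry)
    print(f"{name}:")
    for entry in row:
        print(f"  {entry}")
print("\nFacilitation (PPR > 1) appears only with Syt7 at the tripartite "
      "interface, is strongest at short intervals, and decays away as the "
      "Syt7 clamp is restored (timescale ~ 1/k_diss ~ 70 ms).")
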