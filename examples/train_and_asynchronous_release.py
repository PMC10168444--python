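"""Release during a 100 Hz action-potential train, with replenishment.

Emulates a mossy-fibre-bouton-style burst: ten AP transients at 100 Hz with
per-pulse peak growth (buffer-saturation surrogate) and an accumulating
residual.  Fused sites re-arm after a 2.5 ms refractory period with rate
k_rep = 0.02 ms^-1.  Prints per-AP release efficacies n_T(i), the
facilitation ratio n_T(10)/n_T(1), and the asynchronous release n_Async
after the train for single, dual and mixed clamp architectures.

The trace is also written to / read back from CSV to show how externally
computed waveforms (e.g. from a reaction-diffusion model) plug in.
"""

import tempfile
from pathlib import Path

import numpy as np

from synclamp import (
    SimulationProtocol,
    asynchronous_count,
    make_train,
    per_ap_efficacy,
    preset,
    read_trace,
    simulate_ensemble,
    write_trace,
)

trace = make_train(n_ap=10, freq_hz=100.0, first_peak=20.0, peak_growth=1.05,
                   residual_amp=0.5, residual_tau=100.0, baseline=0.05,
                   tail=100.0)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "train.csv"
    write_trace(trace, path)
    trace = read_trace(path)          # identical after the round trip
ap_times = trace.meta["ap_times_ms"]

print(f"10 x 100 Hz train, peaks {trace.meta['peaks_uM'][0]:.0f} -> "
      f"{trace.meta['peaks_uM'][-1]:.1f} uM, residual accumulating to "
      f"{trace.value_at(ap_times[-1] + 5.0):.1f} uM\n")

for name in ("SYT1P", "SYT1P_SYT1T", "SYT1P_SYT7T", "MIXED_SYT7"):
    proto = SimulationProtocol(trace=trace, n_simulations=1500, rng_seed=4,
                               replenishment_enabled=True)
    rec = simulate_ensemble(preset(name), proto)
    eff = per_ap_efficacy(rec, ap_times, final_window=5.0)
    n_async = asynchronous_count(rec, ap_times[-1] + 5.0, rec.t_end)
    facil = (eff["n_T"][-1] / eff["n_T"][0] if eff["n_T"][0] > 0
             else np.inf)
    print(f"{name:12s} n_T(1) = {eff['n_T'][0]:.4f}  "
          f"n_T(10)/n_T(1) = {facil:6.1f}  n_Async = {n_async:.4f}")

print("\nDual clamps suppress early release and facilitate strongly; "
      "asynchronous tail release needs single-clamp (or Syt7-clamped) "
      "SNAREpins — the dual Syt1 clamp shuts it off.")
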