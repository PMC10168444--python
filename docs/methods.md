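# Methods

## Model

A release site holds one vesicle with `n_snare` (default 6) SNAREpins.
Clamp state is tracked per synaptotagmin C2 domain with the four-state
chain S0 ⇄ S1 ⇄ S2 ⇄ S2M described in the README; the statistical factors
(2·k_on·Ca out of S0, 2·k_off out of S2) follow from two independent,
identical Ca²⁺ sites. Two modelling commitments worth making explicit:

* **No Ca²⁺ unbinding from the inserted state.** The only exit from S2M is
  loop withdrawal at `k_out`; a withdrawn domain is usually re-inserted
  (`k_in ≫ 2·k_off`), which is why the apparent stopped-flow dissociation
  rate is `k_diss = k_out · 2k_off/(2k_off + k_in)` — the escape
  probability per membrane exit. This closed form reproduces the
  measured pairs (k_out 0.67 → k_diss 0.5025 ms⁻¹; 0.02 → 0.015 ms⁻¹) and
  is the quantity `calibration.calibrate_k_out` inverts numerically.
* **A SNAREpin is free only when *all* of its clamp domains are inserted.**
  Each bound synaptotagmin independently arrests zippering; dual clamps
  therefore require two simultaneous releases, which is what buys the dual
  architectures their higher Ca²⁺ cooperativity and lower release rates.

Fusion is a single hazard channel at rate `R(n_free) = A·exp(−(E₀ −
n_free·ΔE))` (energies in k_BT, `A` stored in s⁻¹ and converted to ms⁻¹).
`R` may exceed `A` when `n_free·ΔE > E₀`; that is intentional — states with
n_free ≥ 4 fuse essentially instantly and carry negligible probability.

Units everywhere: ms, µM, k_BT.

## Stochastic engine

The engine is the direct Gillespie method in time-transform form: one
unit-rate exponential is drawn per reaction and consumed across the
piecewise-constant segments of the calcium trace in integrated-hazard
units. For piecewise-constant propensities this is *exact* (no
discretisation error), and it makes densely gridded AP transients cheap
because crossing a segment costs one multiply-compare, not a redraw.
Each SNAREpin's clamp unit (4 states single, 16 dual) is monitored
concurrently; this is the same Markov process as the flat 4⁶/4¹² chain,
sampled unit-wise. A numba-jitted kernel (`fastpath.step_fusion_times`)
specialises the constant-Ca²⁺, homogeneous, no-replenishment case used by
the step sweeps; a Kolmogorov–Smirnov test in the suite pins it to the
generic engine.

Replenishment (train protocols): on fusion the site is empty for a fixed
2.5 ms refractory period, then re-arms after an Exp(k_rep) wait
(k_rep = 0.02 ms⁻¹) with all domains in S0. Mixed-architecture sites
re-sample their clamp assignment on replenishment by default
(`resample_architecture=False` inherits instead).

RNG: every simulation gets its own `SeedSequence(seed, spawn_key=(i,))`
substream, so ensembles are bitwise reproducible and order-independent.

## Master-equation oracles

Two deterministic routes validate the sampler:

* **Allosteric benchmark** (six states + fused): propagated segment-wise
  with 7×7 matrix exponentials — exact for piecewise-constant traces.
  Parameter values are literature-sourced from the original calyx-of-Held
  allosteric sensor study; every oracle-agreement test is
  parameter-agnostic.
* **Lumped clamp-model master equation.** SNAREpins of a homogeneous
  vesicle are exchangeable, so the joint chain lumps onto multisets of unit
  states: C(9,3) = 84 compositions for the single clamp. For the Syt1/Syt1
  dual clamp the two domains within a pin are themselves exchangeable,
  giving 10 unordered pair-states and C(15,6) = 5005 compositions. The
  resulting stiff ODE (rates span 10⁻⁵ – 10⁶ ms⁻¹ because of the fusion
  hazards) is integrated with BDF and an analytic sparse Jacobian,
  rtol 1e-8 / atol 1e-12. The Syt1/Syt7 dual unit is not lumpable within
  the pin (16 states, C(21,6) = 54,264 compositions); the system builds,
  but sparse-LU fill-in makes n_snare = 6 solves impractical, so exactness
  for that architecture is asserted on toy vesicles (n_snare = 2, against
  the fully enumerated product chain) and production numbers come from the
  SSA — the same division of labour the stochastic-simulation literature
  uses. The lumping itself is verified against the unlumped Kronecker
  construction to integrator accuracy for all three architectures.

## Synthetic calcium waveforms

The generators emulate the drive, not the biophysics that produces it:

* **Steps** (1–32 µM) reproduce the flash-photolysis regime.
* **AP transients**: a Gaussian local component (default width 0.25 ms,
  peak tens of µM; the peak stands in for coupling distance — smaller peak
  ≈ larger distance, recorded as a metadata label) plus an exponential
  residual (default 1 µM amplitude in the single-AP default, 40 ms decay)
  summing linearly onto a 0.05 µM baseline. Grids are 0.01 ms within
  ±2 ms of each AP, 0.1 ms elsewhere.
* **Trains**: 10 transients at 100 Hz with optional per-pulse peak growth
  (buffer-saturation surrogate); residuals accumulate by superposition.
  Train protocols here use residual amplitude 0.5 µM with a 100 ms decay so
  the accumulated residual tops out at ~3 µM ("low micromolar") — linear
  superposition of a 1 µM per-AP residual would overshoot what saturating
  extrusion allows.

What these waveforms do **not** capture: spatial Ca²⁺ gradients, buffer
kinetics, channel gating — i.e. the actual waveform at a release site of a
specific synapse. Green plasticity tests therefore establish the
*mechanistic* claims (Syt7 ⇒ facilitation; dual Syt1 ⇒ no asynchronous
release) and not the quantitative per-AP efficacies of any real terminal;
reproducing those requires an externally computed trace via `read_trace`.

## Analysis choices

* n_T(t) is the fusion-time step function normalised by ensemble size;
  without replenishment it equals the cumulative release probability p_v(t).
* Release rates: adaptive equal-count binning (default 50 events/bin,
  floor of 20 in the sweep helper) with a centred 3-bin moving average,
  edges truncated; unsmoothed rates integrate back to n_T exactly. Fixed
  binning defaults to 0.25 ms. The exact adaptive rule is a normative
  choice of this package; peak estimates carry an upward max-of-noisy-bins
  bias of a few percent at typical event counts, visible when compared to
  the master-equation peak.
* Per-AP windows are the contiguous partition [AP_i, AP_{i+1}) with a 5 ms
  final window (right for trains, where n_T(i) should absorb everything up
  to the next AP). For paired pulses at long intervals this design
  conflates the asynchronous tail with the first AP's efficacy, so PPR uses
  matched fixed-width (5 ms) windows — a deliberate deviation, without
  which PPR at 500 ms ISI reads 0.7 for a fully recovered system.
* The tripartite-clamp occupancy P_free is the fraction of tripartite
  domains in S2M over currently docked vesicles, from snapshot statistics
  accumulated on a regular grid during simulation; query it ~1 ms before
  the second AP to avoid counting that AP's own insertions.

## Known limitations and open edges

* The Ca²⁺-step cooperativity of the Syt1/Syt1 dual clamp is steeper here
  (log-log slope ≈ 5.4 over 4–16 µM) than the 2.7–4.3 band the single
  clamp (2.73) and Syt1/Syt7 dual (≈ 3.8) fall into; its 8→16 µM slope is
  4.3. The SSA and the exact master equation agree on this, so it is a
  property of the model as parameterised, not sampling error; the
  discrepancy with the narrower published band most plausibly reflects the
  peak-rate estimator and fit range used on very sparse low-Ca²⁺ dual-clamp
  data, which are not fully specified anywhere we can check.
* Clamp restoration is instantaneous on loop exit and second C2 domains
  are omitted, so synchronous release is an upper estimate and
  facilitation/asynchronous release lower estimates.
* Mixed architectures have no exact oracle (pins are not exchangeable);
  they are validated only through the engine's other guarantees.
* The NRMSE convergence figure depends on the drive: it measures error
  relative to the curve's plateau, so conditions where release saturates
  (16 µM step) sit near 0.06–0.08% at 10⁵ events while partial-release
  conditions sit higher at the same event count.
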