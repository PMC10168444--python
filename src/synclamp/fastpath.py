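"""Compiled fast path for constant-calcium step ensembles.

The Ca2+-step sweeps (release kinetics versus uniform [Ca2+] steps) need
millions of Gillespie events per condition; this module jit-compiles the
homogeneous-architecture, constant-[Ca2+], no-replenishment special case of
the engine with numba.  It returns exactly what the sweeps consume: fusion
times and the free-SNAREpin count at each fusion.  If numba is unavailable
the generic engine in :mod:`synclamp.ssa` is used instead (identical
statistics, slower).

The compiled kernel and the generic engine sample the same Markov process;
their agreement is asserted in the test suite via a two-sample
Kolmogorov-Smirnov check.
"""

from __future__ import annotations

import numpy as np

from .kinetics import ClampArchitecture, DEFAULT_BARRIER, FusionBarrier
from .ssa import SimulationProtocol, compile_pin_chain, simulate_ensemble
from .traces import make_step

__all__ = ["step_fusion_times", "NUMBA_AVAILABLE"]

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a standard install
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _step_kernel(seed, n_sims, max_events, n_pins, targets, rates, n_out,
                 out_rate, released, R, t_end):  # pragma: no cover - jitted
    np.random.seed(seed)
    times = np.empty(max_events)
    nfree_at = np.empty(max_events, np.int64)
    count = 0
    for _ in range(n_sims):
        states = np.zeros(n_pins, np.int64)
        pr_sum = out_rate[0] * n_pins
        nfree = 0
        t = 0.0
        while True:
            total = pr_sum + R[nfree]
            t += np.random.exponential() / total
            if t >= t_end:
                break
            u = np.random.random() * total
            if u >= pr_sum:
                times[count] = t
                nfree_at[count] = nfree
                count += 1
                break
            acc = 0.0
            i = 0
            for i in range(n_pins):
                acc += out_rate[states[i]]
                if u < acc:
                    break
            s = states[i]
            u2 = np.random.random() * out_rate[s]
            acc2 = 0.0
            tgt = targets[s, 0]
            for j in range(n_out[s]):
                acc2 += rates[s, j]
                if u2 < acc2:
                    tgt = targets[s, j]
                    break
            states[i] = tgt
            pr_sum += out_rate[tgt] - out_rate[s]
            nfree += released[tgt] - released[s]
        if count >= max_events:
            break
    return times[:count], nfree_at[:count], count


def step_fusion_times(
    arch: ClampArchitecture,
    ca: float,
    t_end: float = 10.0,
    n_simulations: int = 100_000,
    rng_seed: int = 0,
    barrier: FusionBarrier = DEFAULT_BARRIER,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fusion times under a constant [Ca2+] step.

    Returns ``(fusion_times_ms, n_free_at_fusion, n_simulations_run)``.
    Homogeneous architectures only (the constant-drive fast path).
    """
    if arch.is_mixed:
        raise ValueError("fast path supports homogeneous architectures only")
    if not NUMBA_AVAILABLE:
        proto = SimulationProtocol(
            trace=make_step(ca, t_end), n_simulations=n_simulations,
            rng_seed=rng_seed, record_nfree_at_fusion=True, barrier=barrier,
        )
        rec = simulate_ensemble(arch, proto)
        order = np.argsort(rec.fusion_times)
        nf = rec.n_free_at_event[rec.event_type == 0][order]
        return rec.fusion_times[order], nf.astype(np.int64), rec.total_simulations

    chain = compile_pin_chain(arch.homogeneous_pin)
    S = chain.n_states
    max_out = max(len(tr) for tr in chain.trans)
    targets = np.zeros((S, max_out), np.int64)
    rates = np.zeros((S, max_out))
    n_out = np.zeros(S, np.int64)
    for s, tr in enumerate(chain.trans):
        n_out[s] = len(tr)
        for j, (tgt, c0, c1) in enumerate(tr):
            targets[s, j] = tgt
            rates[s, j] = c0 + ca * c1
    out_rate = rates.sum(axis=1)
    released = np.array(chain.released, np.int64)
    R = barrier.rate_table(arch.n_snare)
    times, nf, count = _step_kernel(
        rng_seed % (2**32), n_simulations, n_simulations, arch.n_snare,
        targets, rates, n_out, out_rate, released, R, float(t_end),
    )
    order = np.argsort(times)
    return times[order], nf[order], n_simulations
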