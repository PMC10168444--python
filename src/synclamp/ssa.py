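"""Exact stochastic simulation of vesicle ensembles under a calcium trace.

Each vesicle carries ``n_snare`` SNAREpins; every clamp domain follows its
four-state chain and the vesicle fuses at the Arrhenius rate of its current
free-SNAREpin count.  Rather than updating one flat 4^6 (or 4^12) Markov
chain, each SNAREpin's clamp unit (4 states for a single clamp, 16 for a
dual clamp) is monitored concurrently — statistically identical to the joint
chain because the units only interact through the fusion channel.

The calcium trace is treated as piecewise constant on its grid.  Sampling
uses the time-transform form of the direct Gillespie method: a unit-rate
exponential is drawn once per reaction and consumed across segments in
integrated-hazard units, which is exact for piecewise-constant propensities
and cheap on densely gridded transients.

With replenishment enabled, a fused site stays empty for a fixed refractory
time (default 2.5 ms) and then re-arms after an exponential wait with rate
``k_rep`` (default 0.02 ms^-1); the incoming vesicle starts with all clamp
domains Ca2+-free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import (
    C2DomainState,
    ClampArchitecture,
    DEFAULT_BARRIER,
    FusionBarrier,
    PinType,
    c2_transition_rates,
)
from .traces import CalciumTrace

__all__ = [
    "SimulationProtocol",
    "ReleaseRecord",
    "SnapshotStats",
    "FreeSnareTrajectory",
    "simulate_vesicle",
    "simulate_ensemble",
    "record_free_snare_trajectory",
    "compile_pin_chain",
]

FUSION = 0
REPLENISH = 1
_EVENT_NAMES = {FUSION: "fusion", REPLENISH: "replenish"}


class PinChain:
    """Compiled jump-chain of one SNAREpin's clamp unit.

    States are tuples of per-slot :class:`~synclamp.kinetics.C2DomainState`
    values enumerated in lexicographic order (index 0 = all slots S0).
    """

    __slots__ = ("pin", "states", "n_states", "trans", "out_const", "out_ca",
                 "released", "trip_free", "n_trip")

    def __init__(self, pin: PinType):
        self.pin = pin
        n_slots = pin.n_slots
        self.states = list(product(range(4), repeat=n_slots))
        index = {s: i for i, s in enumerate(self.states)}
        self.n_states = len(self.states)
        self.trans: list[list[tuple[int, float, float]]] = []
        self.out_const: list[float] = []
        self.out_ca: list[float] = []
        for s in self.states:
            out: list[tuple[int, float, float]] = []
            for slot_idx, (_, params) in enumerate(pin.slots):
                # probe at ca=0 and ca=1 to split constant / ca-linear parts
                for (tgt0, r0), (_, r1) in zip(
                    c2_transition_rates(C2DomainState(s[slot_idx]), 0.0, params),
                    c2_transition_rates(C2DomainState(s[slot_idx]), 1.0, params),
                ):
                    new = list(s)
                    new[slot_idx] = int(tgt0)
                    out.append((index[tuple(new)], r0, r1 - r0))
            self.trans.append(out)
            self.out_const.append(sum(c for _, c, _ in out))
            self.out_ca.append(sum(a for _, _, a in out))
        self.released = [all(v == 3 for v in s) for s in self.states]
        self.n_trip = sum(1 for iface, _ in pin.slots if iface == "tripartite")
        if self.n_trip:
            self.trip_free = [s[1] == 3 for s in self.states]
        else:
            self.trip_free = [False] * self.n_states


@lru_cache(maxsize=64)
def compile_pin_chain(pin: PinType) -> PinChain:
    return PinChain(pin)


@dataclass
class SimulationProtocol:
    """Everything that defines one ensemble simulation.

    ``stop_events`` switches to run-until-N-fusions mode (``n_simulations``
    then acts as a cap on the number of simulations).  ``ca_update_dt`` caps
    the propensity-refresh interval; ``None`` refreshes at the trace's own
    grid points (the generators already grid transients at 0.01 ms).
    ``snapshot_dt`` enables per-vesicle state sampling on a regular grid.
    """

    trace: CalciumTrace
    n_simulations: int | None = 10_000
    stop_events: int | None = None
    t_end: float | None = None
    replenishment_enabled: bool = False
    t_refractory: float = 2.5
    k_rep: float = 0.02
    rng_seed: int = 0
    ca_update_dt: float | None = None
    snapshot_dt: float | None = None
    record_nfree_at_fusion: bool = False
    resample_architecture: bool = True
    barrier: FusionBarrier = field(default_factory=lambda: DEFAULT_BARRIER)

    def __post_init__(self) -> None:
        if self.t_end is None:
            self.t_end = float(self.trace.t[-1])
        if self.t_end > self.trace.t[-1] + 1e-9:
            raise ValueError(
                f"t_end={self.t_end} exceeds trace duration {self.trace.t[-1]}"
            )
        if (self.n_simulations is None or self.n_simulations < 1) and (
            self.stop_events is None or self.stop_events < 1
        ):
            raise ValueError("need n_simulations >= 1 or stop_events >= 1")
        if self.replenishment_enabled and (self.t_refractory < 0 or self.k_rep <= 0):
            raise ValueError("replenishment needs t_refractory >= 0 and k_rep > 0")


@dataclass
class SnapshotStats:
    """Per-grid-point ensemble state statistics over docked vesicles."""

    t: np.ndarray
    docked: np.ndarray          # number of docked (surviving) vesicles
    nfree_sum: np.ndarray
    nfree_sqsum: np.ndarray
    nfree_hist: np.ndarray      # (time, n_free) counts over docked vesicles
    trip_free_sum: np.ndarray   # tripartite slots currently in S2M
    trip_slots: np.ndarray      # tripartite slots present on docked vesicles

    def nfree_fraction(self, n: int) -> np.ndarray:
        """Fraction of docked vesicles with exactly ``n`` free SNAREpins."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.docked > 0,
                            self.nfree_hist[:, n] / self.docked, np.nan)

    def mean_nfree(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.docked > 0, self.nfree_sum / self.docked, np.nan)

    def sd_nfree(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            m = self.nfree_sum / self.docked
            var = self.nfree_sqsum / self.docked - m * m
            return np.where(self.docked > 0, np.sqrt(np.maximum(var, 0.0)), np.nan)


@dataclass
class ReleaseRecord:
    """Fusion / replenishment events from an ensemble simulation.

    Events are stored flat (``sim_id``, ``event_type``, ``t_ms``,
    ``n_free_at_event``); ``n_free_at_event`` is NaN unless snapshot
    recording was enabled.  ``complete`` is False when a ``stop_events``
    request could not be satisfied within the simulation cap.
    """

    sim_id: np.ndarray
    event_type: np.ndarray
    t_ms: np.ndarray
    n_free_at_event: np.ndarray
    total_simulations: int
    t_end: float
    seed: int
    complete: bool = True
    snapshots: SnapshotStats | None = None

    @property
    def fusion_times(self) -> np.ndarray:
        return self.t_ms[self.event_type == FUSION]

    @property
    def n_fusions(self) -> int:
        return int((self.event_type == FUSION).sum())

    def nfree_at_fusion(self) -> np.ndarray:
        vals = self.n_free_at_event[self.event_type == FUSION]
        return vals[~np.isnan(vals)]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sim_id": self.sim_id,
                "event_type": [_EVENT_NAMES[e] for e in self.event_type],
                "t_ms": self.t_ms,
                "n_free_at_event": self.n_free_at_event,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.events_frame().to_csv(path, index=False)
        summary = {
            "n_simulations": self.total_simulations,
            "n_events": int(self.t_ms.size),
            "n_fusions": self.n_fusions,
            "t_end_ms": self.t_end,
            "seed": self.seed,
            "complete": self.complete,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(summary, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReleaseRecord":
        df = pd.read_csv(path)
        summary = json.loads(Path(path).with_suffix(".json").read_text())
        inv = {v: k for k, v in _EVENT_NAMES.items()}
        return cls(
            sim_id=df["sim_id"].to_numpy(np.int64),
            event_type=np.array([inv[e] for e in df["event_type"]], dtype=np.int8),
            t_ms=df["t_ms"].to_numpy(float),
            n_free_at_event=df["n_free_at_event"].to_numpy(float),
            total_simulations=summary["n_simulations"],
            t_end=summary["t_end_ms"],
            seed=summary["seed"],
            complete=summary["complete"],
        )


class _Compiled:
    """Precomputed, trace- and architecture-specific simulation context."""

    def __init__(self, arch: ClampArchitecture, protocol: SimulationProtocol):
        self.arch = arch
        self.protocol = protocol
        edges, values = protocol.trace.segments(protocol.t_end,
                                                max_dt=protocol.ca_update_dt)
        if not np.all(np.isfinite(values)):
            raise ValueError("calcium trace contains non-finite values")
        self.edges = edges.tolist()
        self.values = values.tolist()
        self.chains = {pt: compile_pin_chain(pt) for pt in arch.pin_types}
        self.rates_R = protocol.barrier.rate_table(arch.n_snare).tolist()
        if protocol.snapshot_dt:
            self.sgrid = np.arange(0.0, protocol.t_end + 1e-9,
                                   protocol.snapshot_dt)
        else:
            self.sgrid = np.empty(0)
        m = self.sgrid.size
        self.s_docked = np.zeros(m, dtype=np.int64)
        self.s_nfree = np.zeros(m)
        self.s_nfree2 = np.zeros(m)
        self.s_hist = np.zeros((m, arch.n_snare + 1), dtype=np.int64)
        self.s_tripfree = np.zeros(m)
        self.s_trip = np.zeros(m, dtype=np.int64)
        self.sgrid_list = self.sgrid.tolist()


def _run_one(ctx: _Compiled, rng: np.random.Generator,
             events: list, sim_index: int) -> int:
    """Simulate one release site; append events; return fusion count."""
    proto = ctx.protocol
    edges, values, R = ctx.edges, ctx.values, ctx.rates_R
    t_end = proto.t_end
    rexp = rng.exponential
    runi = rng.random
    record_nfree = proto.record_nfree_at_fusion or proto.snapshot_dt
    sgrid = ctx.sgrid_list
    n_samples = len(sgrid)
    sampling = n_samples > 0

    pins = ctx.arch.sample_pins(rng)
    chains = [ctx.chains[p] for p in pins]
    out_const = [c.out_const for c in chains]
    out_ca = [c.out_ca for c in chains]

    def fresh_state():
        states = [0] * len(chains)
        S_const = sum(oc[0] for oc in out_const)
        S_ca = sum(oa[0] for oa in out_ca)
        return states, S_const, S_ca, 0

    states, S_const, S_ca, nfree = fresh_state()
    ntrip = sum(c.n_trip for c in chains)
    ntripfree = 0
    n_fused = 0
    t = edges[0]
    k = 0
    j = 0
    E = rexp()

    def advance_samples(j, t_to, docked):
        while j < n_samples and sgrid[j] <= t_to + 1e-12:
            if docked:
                ctx.s_docked[j] += 1
                ctx.s_nfree[j] += nfree
                ctx.s_nfree2[j] += nfree * nfree
                ctx.s_hist[j, nfree] += 1
                ctx.s_tripfree[j] += ntripfree
                ctx.s_trip[j] += ntrip
            j += 1
        return j

    while True:
        ca = values[k]
        seg_end = edges[k + 1]
        total = S_const + ca * S_ca + R[nfree]
        need = total * (seg_end - t)
        if E >= need:
            E -= need
            if sampling:
                j = advance_samples(j, seg_end if seg_end < t_end else t_end, True)
            t = seg_end
            k += 1
            if t >= t_end - 1e-12 or k >= len(values):
                return n_fused
            continue
        t_ev = t + E / total
        if sampling:
            j = advance_samples(j, t_ev, True)
        t = t_ev
        E = rexp()
        u = runi() * total
        if u >= total - R[nfree]:
            # --- fusion ---
            n_fused += 1
            events.append((sim_index, FUSION, t,
                           float(nfree) if record_nfree else np.nan))
            if not proto.replenishment_enabled:
                return n_fused
            t_r = t + proto.t_refractory + rexp() / proto.k_rep
            if t_r >= t_end:
                if sampling:
                    j = n_samples  # site empty for the rest; skip samples
                return n_fused
            if sampling:
                while j < n_samples and sgrid[j] <= t_r + 1e-12:
                    j += 1  # site empty: contributes to no docked statistics
            while k + 1 < len(edges) - 1 and edges[k + 1] <= t_r:
                k += 1
            t = t_r
            events.append((sim_index, REPLENISH, t, np.nan))
            if ctx.arch.is_mixed and proto.resample_architecture:
                pins = ctx.arch.sample_pins(rng)
                chains = [ctx.chains[p] for p in pins]
                out_const = [c.out_const for c in chains]
                out_ca = [c.out_ca for c in chains]
                ntrip = sum(c.n_trip for c in chains)
            states, S_const, S_ca, nfree = fresh_state()
            ntripfree = 0
            E = rexp()
            continue
        # --- clamp-domain transition ---
        acc = 0.0
        for i, chain in enumerate(chains):
            s = states[i]
            acc += out_const[i][s] + ca * out_ca[i][s]
            if u < acc:
                s_old = s
                r_pin = out_const[i][s] + ca * out_ca[i][s]
                u2 = runi() * r_pin
                acc2 = 0.0
                tgt = chain.trans[s][-1][0]
                for tgt_c, c0, c1 in chain.trans[s]:
                    acc2 += c0 + ca * c1
                    if u2 < acc2:
                        tgt = tgt_c
                        break
                states[i] = tgt
                S_const += out_const[i][tgt] - out_const[i][s_old]
                S_ca += out_ca[i][tgt] - out_ca[i][s_old]
                if chain.released[tgt] != chain.released[s_old]:
                    nfree += 1 if chain.released[tgt] else -1
                if chain.trip_free[tgt] != chain.trip_free[s_old]:
                    ntripfree += 1 if chain.trip_free[tgt] else -1
                break


def simulate_vesicle(
    arch: ClampArchitecture,
    protocol: SimulationProtocol,
    rng_stream: np.random.Generator | int,
) -> list[tuple[str, float, float]]:
    """Single-site trajectory: list of ``(event_type, t_ms, n_free_at_event)``.

    All clamp domains start Ca2+-free (S0).  Without replenishment the
    trajectory holds at most one fusion event.
    """
    rng = (rng_stream if isinstance(rng_stream, np.random.Generator)
           else np.random.default_rng(rng_stream))
    ctx = _Compiled(arch, protocol)
    events: list = []
    _run_one(ctx, rng, events, 0)
    return [(_EVENT_NAMES[e], t, nf) for _, e, t, nf in events]


def simulate_ensemble(arch: ClampArchitecture,
                      protocol: SimulationProtocol) -> ReleaseRecord:
    """Run the ensemble defined by ``protocol`` and aggregate a record.

    Each simulation uses an independent counter-based RNG substream spawned
    from ``protocol.rng_seed``, so results are bitwise reproducible and
    independent of execution order.
    """
    ctx = _Compiled(arch, protocol)
    events: list = []
    root = np.random.SeedSequence(protocol.rng_seed)
    cap = protocol.n_simulations
    target = protocol.stop_events
    if target is not None and cap is None:
        cap = 10_000_000
    n_run = 0
    n_fused = 0
    complete = True
    while True:
        if target is not None and n_fused >= target:
            break
        if cap is not None and n_run >= cap:
            if target is not None and n_fused < target:
                warnings.warn(
                    f"stop_events={target} not reached after {n_run} "
                    f"simulations ({n_fused} fusions); record flagged partial"
                )
                complete = False
            break
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=protocol.rng_seed, spawn_key=(n_run,)))
        n_fused += _run_one(ctx, rng, events, n_run)
        n_run += 1
    if events:
        sim_id = np.array([e[0] for e in events], dtype=np.int64)
        etype = np.array([e[1] for e in events], dtype=np.int8)
        t_ms = np.array([e[2] for e in events])
        nfree = np.array([e[3] for e in events])
    else:
        sim_id = np.empty(0, dtype=np.int64)
        etype = np.empty(0, dtype=np.int8)
        t_ms = np.empty(0)
        nfree = np.empty(0)
    snaps = None
    if protocol.snapshot_dt:
        snaps = SnapshotStats(ctx.sgrid, ctx.s_docked, ctx.s_nfree,
                              ctx.s_nfree2, ctx.s_hist, ctx.s_tripfree,
                              ctx.s_trip)
    return ReleaseRecord(sim_id, etype, t_ms, nfree, n_run,
                         protocol.t_end, protocol.rng_seed,
                         complete=complete, snapshots=snaps)


@dataclass
class FreeSnareTrajectory:
    """Binned free-SNAREpin statistics plus the fusion-instant distribution."""

    table: pd.DataFrame
    nfree_at_fusion: np.ndarray
    record: ReleaseRecord


def record_free_snare_trajectory(
    arch: ClampArchitecture,
    protocol: SimulationProtocol,
    bin_width: float = 0.25,
) -> FreeSnareTrajectory:
    """Time course of the unclamped-SNAREpin count over docked vesicles.

    Samples every ``bin_width`` ms (default 0.25 ms); returns per-bin mean
    and SD of ``n_free`` over docked vesicles and the unbinned ``n_free``
    values at the instant of fusion.
    """
    proto = SimulationProtocol(**{**protocol.__dict__,
                                  "snapshot_dt": bin_width,
                                  "record_nfree_at_fusion": True})
    rec = simulate_ensemble(arch, proto)
    snaps = rec.snapshots
    table = pd.DataFrame(
        {
            "t_ms": snaps.t,
            "n_docked": snaps.docked,
            "mean_nfree": snaps.mean_nfree(),
            "sd_nfree": snaps.sd_nfree(),
        }
    )
    return FreeSnareTrajectory(table, rec.nfree_at_fusion(), rec)
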