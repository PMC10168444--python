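"""Core kinetic model of the synaptotagmin fusion clamp.

The model pictures each readily-releasable vesicle as carrying ``n_snare``
partially zippered SNARE complexes ("SNAREpins"), each arrested by one or two
synaptotagmin molecules.  A synaptotagmin C2 domain cycles through a four-state
chain: Ca2+-free (S0), singly bound (S1), doubly bound (S2), and doubly bound
with its aliphatic loops inserted into the membrane (S2M).  Membrane insertion
removes that domain's clamp; the clamp is restored instantaneously when the
loops leave the membrane (S2M -> S2).  Ca2+ cannot dissociate from an inserted
domain.

A SNAREpin is "free" when every clamp on it is membrane-inserted.  With ``n``
free SNAREpins the vesicle crosses the fusion barrier at the Arrhenius rate

    R(n) = A * exp(-(E0 - n * dE))        [energies in units of kB*T]

Units throughout: time in ms, Ca2+ concentration in uM, energies in kB*T.
The Arrhenius prefactor ``A`` is stored in s^-1 (the conventional unit) and
converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
import numpy as np

__all__ = [
    "C2DomainState",
    "C2DomainParams",
    "FusionBarrier",
    "PinType",
    "ClampArchitecture",
    "VesicleState",
    "SYT1",
    "SYT7",
    "DEFAULT_BARRIER",
    "PRESET_NAMES",
    "preset",
    "c2_transition_rates",
    "c2_generator",
    "arrhenius_fusion_rate",
    "equilibrium_occupancy",
    "closed_form_kdiss",
    "sample_mixed_architecture",
]


class C2DomainState(IntEnum):
    """States of one synaptotagmin C2 domain."""

    S0 = 0   # no Ca2+ bound
    S1 = 1   # one Ca2+ bound
    S2 = 2   # two Ca2+ bound, loops not inserted
    S2M = 3  # two Ca2+ bound, membrane-inserted (clamp released)


@dataclass(frozen=True)
class C2DomainParams:
    """Rate constants of one C2 domain's Ca2+/membrane cycle.

    Parameters
    ----------
    k_on:
        Per-site Ca2+ association rate (uM^-1 ms^-1).
    K_d:
        Per-site intrinsic dissociation constant (uM).
    k_in:
        Membrane-insertion rate from the doubly bound state (ms^-1).
    k_out:
        Membrane-dissociation (loop exit) rate (ms^-1).
    k_off:
        Per-site Ca2+ dissociation rate (ms^-1); derived as ``k_on * K_d``
        when not given explicitly.
    isoform_label:
        Free-text label ("Syt1", "Syt7", or custom).
    """

    k_on: float
    K_d: float
    k_in: float
    k_out: float
    k_off: float | None = None
    isoform_label: str = "custom"

    def __post_init__(self) -> None:
        if self.k_off is None:
            object.__setattr__(self, "k_off", self.k_on * self.K_d)
        for name in ("k_on", "K_d", "k_in", "k_out", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        expected = self.k_on * self.K_d
        if expected > 0 and abs(self.k_off - expected) > 1e-12 * expected:
            raise ValueError(
                f"k_off={self.k_off} inconsistent with k_on*K_d={expected}"
            )

    def with_(self, **kwargs) -> "C2DomainParams":
        """Return a copy with fields replaced (k_off re-derived unless given)."""
        if "k_off" not in kwargs and ("k_on" in kwargs or "K_d" in kwargs):
            kwargs["k_off"] = None
        return replace(self, **kwargs)


#: Syt1 C2B domain defaults: diffusion-limited binding, intrinsic Kd 150 uM,
#: ~10 us loop insertion, loop exit calibrated to a stopped-flow k_diss of
#: 0.5 ms^-1.
SYT1 = C2DomainParams(k_on=1.0, K_d=150.0, k_in=100.0, k_out=0.67,
                      isoform_label="Syt1")

#: Syt7 C2A domain defaults: same Ca2+ binding, ~30-fold slower loop exit
#: (stopped-flow k_diss of 0.015 ms^-1), the source of its facilitation role.
SYT7 = C2DomainParams(k_on=1.0, K_d=150.0, k_in=100.0, k_out=0.02,
                      isoform_label="Syt7")


@dataclass(frozen=True)
class FusionBarrier:
    """Arrhenius description of the vesicle-membrane fusion barrier.

    ``E0`` is the resting barrier height and ``dE`` the reduction contributed
    by each free SNAREpin, both in kB*T; ``A`` is the attempt-frequency
    prefactor in s^-1.
    """

    E0: float = 26.0
    dE: float = 4.5
    A: float = 2.17e9

    def __post_init__(self) -> None:
        if not (self.E0 > 0 and self.dE > 0 and self.A > 0):
            raise ValueError("FusionBarrier requires E0 > 0, dE > 0, A > 0")

    def rate(self, n_free: int) -> float:
        return arrhenius_fusion_rate(n_free, self)

    def rate_table(self, n_snare: int) -> np.ndarray:
        """R(n) in ms^-1 for n = 0..n_snare."""
        n = np.arange(n_snare + 1)
        return self.A * 1e-3 * np.exp(-(self.E0 - n * self.dE))


DEFAULT_BARRIER = FusionBarrier()


def arrhenius_fusion_rate(n_free: int, b: FusionBarrier) -> float:
    """Fusion rate (ms^-1) of a vesicle with ``n_free`` unclamped SNAREpins.

    ``R(n) = A * exp(-(E0 - n*dE))``; the barrier may go negative for large
    ``n`` (the rate then exceeds ``A``), which is allowed.
    """
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    return b.A * 1e-3 * math.exp(-(b.E0 - n_free * b.dE))


def c2_transition_rates(
    state: C2DomainState, ca: float, p: C2DomainParams
) -> list[tuple[C2DomainState, float]]:
    """Outgoing transitions of the four-state C2-domain chain.

    Two independent identical Ca2+ sites give the statistical factors:
    S0 -> S1 at ``2*k_on*ca`` and S2 -> S1 at ``2*k_off``.  No Ca2+ unbinding
    occurs from the membrane-inserted state.

    Returns a list of ``(target_state, rate_ms^-1)`` pairs.
    """
    if not np.isfinite(ca) or ca < 0:
        raise ValueError(f"ca must be finite and >= 0, got {ca!r}")
    S = C2DomainState
    if state == S.S0:
        return [(S.S1, 2.0 * p.k_on * ca)]
    if state == S.S1:
        return [(S.S0, p.k_off), (S.S2, p.k_on * ca)]
    if state == S.S2:
        return [(S.S1, 2.0 * p.k_off), (S.S2M, p.k_in)]
    if state == S.S2M:
        return [(S.S2, p.k_out)]
    raise ValueError(f"unknown state {state!r}")


def c2_generator(p: C2DomainParams, ca: float) -> np.ndarray:
    """4x4 generator matrix Q of the C2-domain chain at fixed ``ca``.

    Convention: ``Q[i, j]`` is the rate from state i to state j (i != j) and
    rows sum to zero; probabilities evolve as ``dp/dt = Q.T @ p``.
    """
    Q = np.zeros((4, 4))
    for s in C2DomainState:
        for tgt, rate in c2_transition_rates(s, ca, p):
            Q[s, tgt] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def equilibrium_occupancy(ca: float, p: C2DomainParams) -> np.ndarray:
    """Stationary distribution over (S0, S1, S2, S2M) at fixed ``ca``.

    With ``x = k_on*ca / k_off`` the unnormalised weights are
    ``(1, 2x, x^2, x^2 * k_in/k_out)`` (detailed balance along the chain).
    """
    if not np.isfinite(ca) or ca < 0:
        raise ValueError(f"ca must be finite and >= 0, got {ca!r}")
    if ca == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    x = p.k_on * ca / p.k_off
    w = np.array([1.0, 2.0 * x, x * x, x * x * p.k_in / p.k_out])
    return w / w.sum()


def closed_form_kdiss(p: C2DomainParams) -> float:
    """Predicted apparent stopped-flow membrane-dissociation rate (ms^-1).

    After a jump to zero Ca2+ an inserted domain leaves the membrane at
    ``k_out`` but is re-inserted with probability ``k_in / (k_in + 2*k_off)``
    before losing a Ca2+ ion; the apparent single-exponential decay of the
    membrane-bound fraction is ``k_out`` times the escape probability:

        k_diss = k_out * 2*k_off / (2*k_off + k_in)
    """
    denom = 2.0 * p.k_off + p.k_in
    if denom == 0.0:
        return p.k_out
    return p.k_out * 2.0 * p.k_off / denom


# ---------------------------------------------------------------------------
# Clamp architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PinType:
    """Clamp occupancy of a single SNAREpin.

    ``slots`` is an ordered tuple of ``(interface, params)`` pairs; the first
    slot is always the primary interface.  A single-clamp pin has one slot, a
    dual-clamp pin adds a tripartite slot.
    """

    slots: tuple[tuple[str, C2DomainParams], ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError("a SNAREpin needs at least the primary clamp")
        if self.slots[0][0] != "primary":
            raise ValueError("the first clamp slot must be the primary interface")
        if len(self.slots) > 2 or (len(self.slots) == 2
                                   and self.slots[1][0] != "tripartite"):
            raise ValueError("slots must be (primary,) or (primary, tripartite)")

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def tripartite(self) -> C2DomainParams | None:
        return self.slots[1][1] if len(self.slots) == 2 else None


def single_pin(primary: C2DomainParams = SYT1) -> PinType:
    return PinType(slots=(("primary", primary),))


def dual_pin(primary: C2DomainParams = SYT1,
             tripartite: C2DomainParams = SYT1) -> PinType:
    return PinType(slots=(("primary", primary), ("tripartite", tripartite)))


PRESET_NAMES = ("SYT1P", "SYT1P_SYT1T", "SYT1P_SYT7T", "MIXED_SYT1", "MIXED_SYT7")


@dataclass(frozen=True)
class ClampArchitecture:
    """Which clamps sit on each of a vesicle's SNAREpins.

    Homogeneous presets give every pin the same :class:`PinType`.  Mixed
    presets draw, per pin, a single-clamp pin with probability
    ``mix_fraction`` and a dual-clamp pin otherwise (``assignment="bernoulli"``,
    the default) or fix exactly ``round(mix_fraction * n_snare)`` single-clamp
    pins per vesicle (``assignment="fixed"``).
    """

    name: str
    pin_types: tuple[PinType, ...]
    mix_fraction: float | None = None
    n_snare: int = 6
    assignment: str = "bernoulli"

    def __post_init__(self) -> None:
        if self.n_snare < 1:
            raise ValueError("n_snare must be >= 1")
        if self.is_mixed:
            if not (0.0 <= self.mix_fraction <= 1.0):
                raise ValueError("mix_fraction must lie in [0, 1]")
            if len(self.pin_types) != 2:
                raise ValueError("mixed architectures need (single, dual) pin types")
            if self.assignment not in ("bernoulli", "fixed"):
                raise ValueError(f"unknown assignment {self.assignment!r}")
        elif len(self.pin_types) != 1:
            raise ValueError("homogeneous architectures need exactly one pin type")

    @property
    def is_mixed(self) -> bool:
        return self.mix_fraction is not None

    @property
    def homogeneous_pin(self) -> PinType:
        if self.is_mixed:
            raise ValueError(f"{self.name} is a mixed architecture")
        return self.pin_types[0]

    def sample_pins(self, rng: np.random.Generator) -> tuple[PinType, ...]:
        """Clamp assignment for one vesicle."""
        if not self.is_mixed:
            return (self.pin_types[0],) * self.n_snare
        single, dual = self.pin_types
        if self.assignment == "fixed":
            k = round(self.mix_fraction * self.n_snare)
            return (single,) * k + (dual,) * (self.n_snare - k)
        draws = rng.random(self.n_snare)
        return tuple(single if u < self.mix_fraction else dual for u in draws)


def preset(name: str, *, syt1: C2DomainParams = SYT1,
           syt7: C2DomainParams = SYT7, n_snare: int = 6,
           mix_fraction: float = 0.5,
           assignment: str = "bernoulli") -> ClampArchitecture:
    """Build one of the named clamp architectures.

    ``SYT1P``: single Syt1 clamp at the primary interface.
    ``SYT1P_SYT1T`` / ``SYT1P_SYT7T``: dual clamp, tripartite slot occupied
    by Syt1 or Syt7.  ``MIXED_SYT1`` / ``MIXED_SYT7``: per-pin mixture of
    single and the corresponding dual clamp (default mix 0.5, i.e. on average
    3 of 6 pins single-clamped).
    """
    key = name.upper()
    sp, d1, d7 = single_pin(syt1), dual_pin(syt1, syt1), dual_pin(syt1, syt7)
    if key == "SYT1P":
        return ClampArchitecture(key, (sp,), n_snare=n_snare)
    if key == "SYT1P_SYT1T":
        return ClampArchitecture(key, (d1,), n_snare=n_snare)
    if key == "SYT1P_SYT7T":
        return ClampArchitecture(key, (d7,), n_snare=n_snare)
    if key == "MIXED_SYT1":
        return ClampArchitecture(key, (sp, d1), mix_fraction=mix_fraction,
                                 n_snare=n_snare, assignment=assignment)
    if key == "MIXED_SYT7":
        return ClampArchitecture(key, (sp, d7), mix_fraction=mix_fraction,
                                 n_snare=n_snare, assignment=assignment)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def sample_mixed_architecture(
    arch: ClampArchitecture, rng_seed: int | np.random.Generator
) -> tuple[PinType, ...]:
    """Per-SNAREpin clamp assignment for one vesicle of a mixed preset.

    Deterministic given the seed.  For homogeneous presets this simply
    returns ``n_snare`` copies of the single pin type.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    return arch.sample_pins(rng)


@dataclass
class VesicleState:
    """Snapshot of one vesicle: per-pin clamp-domain states plus bookkeeping.

    ``pin_states[i][j]`` is the :class:`C2DomainState` of slot ``j`` on pin
    ``i``.  ``site_status`` is used only when replenishment is enabled.
    """

    pins: tuple[PinType, ...]
    pin_states: list[tuple[C2DomainState, ...]] = field(default_factory=list)
    fused: bool = False
    site_status: str = "occupied"  # occupied | refractory | awaiting_replenishment

    def __post_init__(self) -> None:
        if not self.pin_states:
            self.pin_states = [
                tuple(C2DomainState.S0 for _ in p.slots) for p in self.pins
            ]

    @property
    def n_free(self) -> int:
        """Number of SNAREpins with every clamp slot membrane-inserted."""
        return sum(
            all(s == C2DomainState.S2M for s in states)
            for states in self.pin_states
        )
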