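"""Calcium waveforms that drive the simulations.

A :class:`CalciumTrace` is a piecewise-constant [Ca2+](t) series: the value
``ca[i]`` holds on ``[t[i], t[i+1])`` and ``ca[-1]`` from ``t[-1]`` onwards.
Generators cover the stimuli used throughout: uniform concentration steps
(flash-photolysis style), action-potential-evoked transients (a brief
Gaussian local component riding on a slowly decaying residual), paired
pulses and 100 Hz trains, and the jump-to-zero used in simulated stopped-flow
experiments.  Externally computed waveforms (e.g. from a reaction-diffusion
model) are read from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CalciumTrace",
    "TraceFormatError",
    "make_step",
    "make_ap_transient",
    "make_train",
    "make_egta_jump",
    "read_trace",
    "write_trace",
]


class TraceFormatError(ValueError):
    """Raised for malformed trace CSV files; carries the offending line."""


@dataclass
class CalciumTrace:
    """Piecewise-constant free-calcium time series.

    ``t`` in ms (strictly increasing), ``ca`` in uM (finite, >= 0);
    ``meta`` holds the protocol label, nominal coupling distance and AP times.
    """

    t: np.ndarray
    ca: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.ca.shape:
            raise ValueError("t and ca must be 1-D arrays of equal length")
        if self.t.size < 1:
            raise ValueError("trace must contain at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.ca)) or np.any(self.ca < 0):
            raise ValueError("ca values must be finite and >= 0")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def value_at(self, time: float | np.ndarray) -> np.ndarray:
        """Previous-sample (step) interpolation; constant beyond the ends."""
        idx = np.clip(np.searchsorted(self.t, time, side="right") - 1,
                      0, self.t.size - 1)
        return self.ca[idx]

    def segments(self, t_end: float, max_dt: float | None = None):
        """Breakpoints/values covering ``[t[0], t_end]``.

        Returns ``(edges, values)`` with ``values[i]`` holding on
        ``[edges[i], edges[i+1])``.  If ``max_dt`` is given, segments longer
        than it are subdivided (propensity-refresh interval for the SSA).
        """
        if t_end > self.t[-1] + 1e-9 and self.t.size > 1:
            raise ValueError(
                f"t_end={t_end} exceeds trace duration (ends at {self.t[-1]})"
            )
        edges = self.t[self.t < t_end]
        if edges.size == 0 or edges[0] > self.t[0]:
            edges = np.concatenate([[self.t[0]], edges])
        edges = np.concatenate([edges, [t_end]])
        if max_dt is not None and max_dt > 0:
            pieces = []
            for a, b in zip(edges[:-1], edges[1:]):
                n = max(1, int(np.ceil((b - a) / max_dt - 1e-12)))
                pieces.append(np.linspace(a, b, n + 1)[:-1])
            edges = np.concatenate(pieces + [[t_end]])
        values = self.value_at(edges[:-1])
        return edges, values


def make_step(ca_level: float, t_end: float, baseline: float = 0.0,
              label: str | None = None) -> CalciumTrace:
    """Uniform [Ca2+] step of amplitude ``ca_level`` held over ``[0, t_end]``.

    The flash-photolysis protocol: steps of 1-32 uM probe the Ca2+
    cooperativity of release.
    """
    if ca_level < baseline or baseline < 0:
        raise ValueError("require ca_level >= baseline >= 0")
    t = np.array([0.0, t_end])
    ca = np.array([float(ca_level)] * 2)
    return CalciumTrace(t, ca, meta={"protocol": label or "step",
                                     "ca_level_uM": float(ca_level)})


def _ap_grid(ap_times: np.ndarray, t_end: float, fine_dt: float,
             coarse_dt: float, fine_halfwidth: float) -> np.ndarray:
    """0 .. t_end grid, dense (fine_dt) within +-fine_halfwidth of each AP."""
    pts = [np.arange(0.0, t_end + 0.5 * coarse_dt, coarse_dt)]
    for ap in ap_times:
        lo = max(0.0, ap - fine_halfwidth)
        hi = min(t_end, ap + fine_halfwidth)
        pts.append(np.arange(lo, hi + 0.5 * fine_dt, fine_dt))
        pts.append(np.array([ap]))  # hit the peak exactly
    grid = np.concatenate(pts)
    for ap in ap_times:  # snap epsilon-near points onto the exact AP time
        grid[np.abs(grid - ap) < 1e-9] = ap
    grid = np.unique(grid)
    grid = grid[(grid >= 0.0) & (grid <= t_end)]
    # drop float-epsilon near-duplicates (arange/unique artefacts)
    keep = np.concatenate(([True], np.diff(grid) > 1e-9))
    return grid[keep]


def make_ap_transient(
    ap_times: Sequence[float],
    peak: float | Sequence[float],
    local_width: float = 0.25,
    residual_amp: float = 1.0,
    residual_tau: float = 40.0,
    baseline: float = 0.05,
    t_end: float | None = None,
    fine_dt: float = 0.01,
    coarse_dt: float = 0.1,
    coupling_distance_nm: float | None = None,
) -> CalciumTrace:
    """Action-potential-evoked [Ca2+] transients.

    Each AP at time ``ap`` contributes a Gaussian local component
    ``peak * exp(-(t-ap)^2 / (2*local_width^2))`` (the sub-millisecond
    nano/microdomain seen by a docked vesicle) plus a residual component
    ``residual_amp * exp(-(t-ap)/residual_tau)`` for ``t >= ap`` (the
    low-micromolar tail that outlives channel closure).  Components from all
    APs sum linearly onto ``baseline``.  ``peak`` may be a per-AP sequence to
    emulate facilitating trains (buffer-saturation surrogate).

    The grid is dense (``fine_dt``, default 0.01 ms) within +-2 ms of each AP
    and coarse (``coarse_dt``) elsewhere.
    """
    ap = np.asarray(ap_times, dtype=float)
    if ap.ndim != 1 or ap.size == 0 or np.any(np.diff(ap) <= 0):
        raise ValueError("ap_times must be a non-empty increasing sequence")
    peaks = np.broadcast_to(np.asarray(peak, dtype=float), ap.shape).copy()
    if np.any(peaks < 0) or local_width <= 0 or residual_tau <= 0:
        raise ValueError("peaks must be >= 0 and widths/taus > 0")
    if residual_amp < 0 or baseline < 0:
        raise ValueError("residual_amp and baseline must be >= 0")
    if t_end is None:
        t_end = float(ap[-1] + 5.0 * residual_tau)
    grid = _ap_grid(ap, t_end, fine_dt, coarse_dt, fine_halfwidth=2.0)
    ca = np.full(grid.shape, float(baseline))
    for ap_t, pk in zip(ap, peaks):
        dt = grid - ap_t
        ca += pk * np.exp(-0.5 * (dt / local_width) ** 2)
        tail = dt >= -1e-12
        ca[tail] += residual_amp * np.exp(-np.maximum(dt[tail], 0.0)
                                          / residual_tau)
    meta = {"protocol": "ap_transient", "ap_times_ms": ap.tolist(),
            "peaks_uM": peaks.tolist()}
    if coupling_distance_nm is not None:
        meta["coupling_distance_nm"] = float(coupling_distance_nm)
    return CalciumTrace(grid, ca, meta=meta)


def make_train(
    n_ap: int = 10,
    freq_hz: float = 100.0,
    first_peak: float = 25.0,
    peak_growth: float = 1.0,
    t_start: float = 1.0,
    tail: float = 200.0,
    **kwargs,
) -> CalciumTrace:
    """Train of ``n_ap`` AP transients at ``freq_hz``.

    ``peak_growth`` multiplies the local peak per successive AP (> 1 emulates
    buffer-saturation-driven growth of the local transient); residual
    components accumulate automatically.  Remaining keyword arguments pass
    through to :func:`make_ap_transient`.
    """
    isi = 1000.0 / freq_hz
    ap_times = t_start + isi * np.arange(n_ap)
    peaks = first_peak * peak_growth ** np.arange(n_ap)
    kwargs.setdefault("t_end", float(ap_times[-1] + tail))
    tr = make_ap_transient(ap_times, peaks, **kwargs)
    tr.meta["protocol"] = "ap_train"
    tr.meta["freq_hz"] = float(freq_hz)
    return tr


def make_egta_jump(ca_pre: float, t_jump: float, t_end: float) -> CalciumTrace:
    """Pre-equilibration at ``ca_pre`` then an instantaneous drop to zero.

    The simulated stopped-flow / EGTA protocol: [Ca2+] = ``ca_pre`` on
    ``[0, t_jump)`` and 0 afterwards (``t_jump = 0`` gives an immediate drop).
    """
    if ca_pre <= 0:
        raise ValueError("ca_pre must be > 0")
    if t_jump < 0 or t_end <= t_jump:
        raise ValueError("require 0 <= t_jump < t_end")
    if t_jump == 0.0:
        t = np.array([0.0, t_end])
        ca = np.array([0.0, 0.0])
    else:
        t = np.array([0.0, t_jump, t_end])
        ca = np.array([float(ca_pre), 0.0, 0.0])
    return CalciumTrace(t, ca, meta={"protocol": "egta_jump",
                                     "ca_pre_uM": float(ca_pre),
                                     "t_jump_ms": float(t_jump)})


# ---------------------------------------------------------------------------
# CSV I/O:  '#'-prefixed 'key = value' metadata, then header 't_ms,ca_uM'
# ---------------------------------------------------------------------------

def write_trace(trace: CalciumTrace, path: str | Path) -> None:
    """Write a trace as CSV, metadata in ``#`` header comments."""
    with open(path, "w") as fh:
        for key, val in trace.meta.items():
            fh.write(f"# {key} = {val!r}\n")
        fh.write("t_ms,ca_uM\n")
        for t, ca in zip(trace.t, trace.ca):
            fh.write(f"{t:.12g},{ca:.12g}\n")


def read_trace(path: str | Path) -> CalciumTrace:
    """Read a trace CSV (``t_ms,ca_uM`` with optional ``#`` metadata lines).

    Raises :class:`TraceFormatError` naming the offending line for missing
    columns, non-monotone time, or negative/non-numeric concentrations.
    """
    meta: dict = {}
    ts: list[float] = []
    cas: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = eval(val.strip(), {"__builtins__": {}})
                    except Exception:
                        meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols[:2] != ["t_ms", "ca_uM"]:
                    raise TraceFormatError(
                        f"line {lineno}: expected header 't_ms,ca_uM', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise TraceFormatError(f"line {lineno}: expected two columns, got {line!r}")
            try:
                t, ca = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TraceFormatError(f"line {lineno}: non-numeric value in {line!r}") from exc
            if ts and t <= ts[-1]:
                raise TraceFormatError(
                    f"line {lineno}: time {t} not greater than previous {ts[-1]}"
                )
            if not np.isfinite(ca) or ca < 0:
                raise TraceFormatError(f"line {lineno}: ca must be finite and >= 0, got {ca}")
            ts.append(t)
            cas.append(ca)
    if not header_seen:
        raise TraceFormatError("line 1: missing 't_ms,ca_uM' header")
    if not ts:
        raise TraceFormatError("file contains no data rows")
    return CalciumTrace(np.array(ts), np.array(cas), meta=meta)
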