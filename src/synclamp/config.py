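"""Flat ``key = value`` plain-text configuration files.

Recognised keys: ``syt1.k_on``, ``syt1.K_d``, ``syt1.k_in``, ``syt1.k_out``,
the matching ``syt7.*`` set, ``barrier.E0``, ``barrier.dE``, ``barrier.A``,
``vesicle.n_snare``, ``architecture.preset`` and
``architecture.mix_fraction``.  Unknown keys are preserved on round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .kinetics import (
    SYT1,
    SYT7,
    C2DomainParams,
    ClampArchitecture,
    FusionBarrier,
    preset,
)

__all__ = ["ModelConfig", "load_config", "save_config"]


@dataclass
class ModelConfig:
    """Complete parameterisation of the clamp model."""

    syt1: C2DomainParams
    syt7: C2DomainParams
    barrier: FusionBarrier
    n_snare: int = 6
    architecture_preset: str = "SYT1P"
    mix_fraction: float = 0.5
    extras: dict | None = None

    def architecture(self) -> ClampArchitecture:
        return preset(self.architecture_preset, syt1=self.syt1,
                      syt7=self.syt7, n_snare=self.n_snare,
                      mix_fraction=self.mix_fraction)

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls(syt1=SYT1, syt7=SYT7, barrier=FusionBarrier())


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def load_config(path: str | Path) -> ModelConfig:
    """Parse a flat key=value config file into a :class:`ModelConfig`."""
    kv: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'key = value', "
                             f"got {raw!r}")
        key, _, val = line.partition("=")
        kv[key.strip()] = _parse_value(val)

    def domain(prefix: str, default: C2DomainParams) -> C2DomainParams:
        fields = {}
        for name in ("k_on", "K_d", "k_in", "k_out"):
            if f"{prefix}.{name}" in kv:
                fields[name] = float(kv.pop(f"{prefix}.{name}"))
        return default.with_(**fields) if fields else default

    syt1 = domain("syt1", SYT1)
    syt7 = domain("syt7", SYT7)
    barrier = FusionBarrier(
        E0=float(kv.pop("barrier.E0", 26.0)),
        dE=float(kv.pop("barrier.dE", 4.5)),
        A=float(kv.pop("barrier.A", 2.17e9)),
    )
    return ModelConfig(
        syt1=syt1,
        syt7=syt7,
        barrier=barrier,
        n_snare=int(kv.pop("vesicle.n_snare", 6)),
        architecture_preset=str(kv.pop("architecture.preset", "SYT1P")),
        mix_fraction=float(kv.pop("architecture.mix_fraction", 0.5)),
        extras=kv or None,
    )


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a :class:`ModelConfig` as a flat key=value file."""
    lines = []
    for prefix, p in (("syt1", cfg.syt1), ("syt7", cfg.syt7)):
        for name in ("k_on", "K_d", "k_in", "k_out"):
            lines.append(f"{prefix}.{name} = {getattr(p, name)!r}")
    lines += [
        f"barrier.E0 = {cfg.barrier.E0!r}",
        f"barrier.dE = {cfg.barrier.dE!r}",
        f"barrier.A = {cfg.barrier.A!r}",
        f"vesicle.n_snare = {cfg.n_snare}",
        f"architecture.preset = {cfg.architecture_preset}",
        f"architecture.mix_fraction = {cfg.mix_fraction!r}",
    ]
    for key, val in (cfg.extras or {}).items():
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
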