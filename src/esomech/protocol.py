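"""Stepwise strain-cycle protocol description.

The organ-bath protocol lengthens the strip in fixed millimetre steps with a
two-minute hold at each length while the transducer output is logged every
five seconds. Lengthening reverses once the hold-averaged force exceeds a
threshold chosen to avoid tissue damage (40 mN by default); shortening then
proceeds stepwise and reverses when the averaged force approaches zero
(<= 1 mN, the preload, by default). Agonist doses are applied between
cycles, after a stabilization period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = ["DoseEvent", "StrainProtocol", "three_cycle_protocol"]


@dataclass
class DoseEvent:
    """An agonist dose applied after a completed strain cycle."""

    after_cycle: int
    agonist: str
    concentration: float  # molar

    def __post_init__(self) -> None:
        if self.after_cycle < 0:
            raise ValueError("after_cycle must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class StrainProtocol:
    step_mm: float = 0.8
    hold_s: float = 120.0
    log_interval_s: float = 5.0
    force_reversal_mN: float = 40.0
    shorten_stop_mN: float = 1.0
    preload_mN: float = 1.0
    full_scale_mN: float = 196.0
    n_cycles: int = 1
    max_strain: float = 3.0          # safety cap when reversal is unreachable
    dose_settle_s: float = 240.0     # pre-dose stabilization at constant length
    dose_window_s: float = 300.0     # logged post-dose response window
    dose_events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")
        if self.hold_s <= 0:
            raise ValueError("hold_s must be > 0")
        if self.log_interval_s <= 0 or (self.hold_s / self.log_interval_s) % 1 > 1e-9:
            raise ValueError("log_interval_s must divide hold_s")
        if not 0 < self.force_reversal_mN < self.full_scale_mN:
            raise ValueError("force_reversal_mN must be in (0, full_scale_mN)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        self.dose_events = [
            d if isinstance(d, DoseEvent) else DoseEvent(**d) for d in self.dose_events
        ]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StrainProtocol":
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StrainProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def three_cycle_protocol(carbachol_molar: float = 1e-6) -> StrainProtocol:
    """The reference three-cycle protocol: two basal strain cycles, a
    contractile-agonist challenge (1 uM carbachol) after cycle 2, then a
    third, induced cycle."""
    return StrainProtocol(
        n_cycles=3,
        dose_events=[DoseEvent(after_cycle=2, agonist="carbachol", concentration=carbachol_molar)],
    )
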