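"""Reduction of raw transducer traces to per-cycle tension-strain curves.

Each constant-length hold entered via a commanded-length jump becomes one
step segment; the force is averaged over the hold (time integral divided by
hold duration, preserving tension units) and converted to tension through
the strip cross-section, area = mass / (rho * length), so that
tension = force * length * rho / mass. Cycles are delimited at
shorten-to-lengthen transitions of the step direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import Geometry
from .protocol import StrainProtocol
from .simulate import TransducerTrace

__all__ = [
    "StepSegment",
    "TensionStrainCurve",
    "DoseResponse",
    "force_to_tension",
    "segment_steps",
    "build_cycle_curves",
    "agonist_response",
    "write_curves_csv",
    "read_curves_csv",
]


def force_to_tension(force_mN, mass_mg: float, length_mm: float, rho_mg_per_mm3: float = 1.0):
    """Convert force to tension (mN/mm^2): force / cross-section with
    cross-section = mass / (rho * length). 40 mN on the default 20 mg,
    15 mm strip corresponds to 30 mN/mm^2."""
    if mass_mg <= 0 or length_mm <= 0 or rho_mg_per_mm3 <= 0:
        raise ValueError("mass, length and density must be > 0")
    return force_mN * length_mm * rho_mg_per_mm3 / mass_mg


@dataclass
class StepSegment:
    cycle_index: int
    direction: str  # 'lengthen' | 'shorten'
    commanded_length_mm: float
    strain: float
    start_s: float
    end_s: float
    mean_force_mN: float
    mean_tension_mN_per_mm2: float
    n_samples: int
    flags: list = field(default_factory=list)


@dataclass
class TensionStrainCurve:
    """Ordered (strain, tension) points for one cycle and step direction."""

    cycle_index: int
    direction: str
    strain: np.ndarray
    tension: np.ndarray
    geometry: Optional[Geometry] = None

    def __len__(self) -> int:
        return len(self.strain)


def _geometry_from_trace(trace: TransducerTrace) -> Geometry:
    m = trace.metadata
    return Geometry(L0_mm=m.L0_mm, mass_mg=m.mass_mg, rho_mg_per_mm3=m.rho_mg_per_mm3)


def segment_steps(trace: TransducerTrace, protocol: Optional[StrainProtocol] = None) -> list[StepSegment]:
    """One segment per constant-length hold entered via a length jump.

    The hold window is the ``hold_s`` following the jump (longer
    constant-length stretches, e.g. dose stabilization periods, contribute
    only their first hold to a segment). Direction comes from the sign of
    the jump; the cycle index increments at every shorten-to-lengthen
    transition.
    """
    hold_s = protocol.hold_s if protocol is not None else trace.metadata.hold_s
    log_dt = protocol.log_interval_s if protocol is not None else trace.metadata.log_interval_s
    geo = _geometry_from_trace(trace)
    lengths = trace.commanded_length_mm
    jumps = np.flatnonzero(np.abs(np.diff(lengths)) > 1e-12) + 1
    if jumps.size == 0:
        warnings.warn("trace has no commanded-length changes; no step segments")
        return []

    segments: list[StepSegment] = []
    cycle = 1
    prev_direction: Optional[str] = None
    expected_n = int(round(hold_s / log_dt))
    for idx in jumps:
        jump = lengths[idx] - lengths[idx - 1]
        direction = "lengthen" if jump > 0 else "shorten"
        if prev_direction == "shorten" and direction == "lengthen":
            cycle += 1
        prev_direction = direction
        t_step = trace.time_s[idx - 1]  # step occurs between samples idx-1 and idx
        in_hold = (
            (trace.time_s > t_step)
            & (trace.time_s <= t_step + hold_s + 0.5 * log_dt)
            & (np.abs(lengths - lengths[idx]) < 1e-12)
        )
        forces = trace.force_mN[in_hold]
        flags: list[str] = []
        if forces.size == 0:
            continue
        if forces.size < expected_n:
            flags.append("missing_samples")
        mean_force = float(np.mean(forces))
        strain = lengths[idx] / geo.L0_mm
        segments.append(
            StepSegment(
                cycle_index=cycle,
                direction=direction,
                commanded_length_mm=float(lengths[idx]),
                strain=float(strain),
                start_s=float(trace.time_s[in_hold][0]),
                end_s=float(trace.time_s[in_hold][-1]),
                mean_force_mN=mean_force,
                mean_tension_mN_per_mm2=float(
                    force_to_tension(mean_force, geo.mass_mg, geo.L0_mm, geo.rho_mg_per_mm3)
                ),
                n_samples=int(forces.size),
                flags=flags,
            )
        )
    return segments


def build_cycle_curves(
    segments: Sequence[StepSegment], geometry: Geometry
) -> list[TensionStrainCurve]:
    """Group segments into one tension-strain curve per (cycle, direction),
    in acquisition order (monotone in strain within a direction)."""
    curves: list[TensionStrainCurve] = []
    keys: list[tuple[int, str]] = []
    for seg in segments:
        key = (seg.cycle_index, seg.direction)
        if key not in keys:
            keys.append(key)
    for cycle, direction in keys:
        sel = [s for s in segments if (s.cycle_index, s.direction) == (cycle, direction)]
        curves.append(
            TensionStrainCurve(
                cycle_index=cycle,
                direction=direction,
                strain=np.array([s.strain for s in sel]),
                tension=np.array([s.mean_tension_mN_per_mm2 for s in sel]),
                geometry=geometry,
            )
        )
    return curves


@dataclass
class DoseResponse:
    agonist: str
    concentration: float
    baseline_tension: float
    plateau_tension: float
    induced_tension: float  # mN/mm^2
    flags: list = field(default_factory=list)


def agonist_response(
    trace: TransducerTrace,
    dose_events: Optional[Sequence[tuple]] = None,
    baseline_s: float = 60.0,
    window_s: float = 300.0,
    plateau_s: float = 60.0,
) -> list[DoseResponse]:
    """Induced tension for each recorded dose: post-dose plateau (last
    ``plateau_s`` of the ``window_s`` response window) minus the
    ``baseline_s`` preceding the dose, converted to tension."""
    if dose_events is None:
        dose_events = trace.metadata.dose_times
    geo = _geometry_from_trace(trace)
    out: list[DoseResponse] = []
    for t0, agonist, conc in dose_events:
        flags: list[str] = []
        base_mask = (trace.time_s >= t0 - baseline_s) & (trace.time_s <= t0)
        plat_mask = (trace.time_s >= t0 + window_s - plateau_s) & (trace.time_s <= t0 + window_s)
        # windows must sit at constant commanded length
        for name, mask in (("baseline", base_mask), ("plateau", plat_mask)):
            if not np.any(mask):
                flags.append(f"{name}_window_empty")
                continue
            if np.ptp(trace.commanded_length_mm[mask]) > 1e-12:
                keep_len = trace.commanded_length_mm[mask][-1 if name == "baseline" else 0]
                mask &= np.abs(trace.commanded_length_mm - keep_len) < 1e-12
                flags.append(f"{name}_window_truncated")
        if not np.any(base_mask) or not np.any(plat_mask):
            out.append(DoseResponse(agonist, conc, np.nan, np.nan, np.nan, flags))
            continue
        base = force_to_tension(
            float(np.mean(trace.force_mN[base_mask])), geo.mass_mg, geo.L0_mm, geo.rho_mg_per_mm3
        )
        plat = force_to_tension(
            float(np.mean(trace.force_mN[plat_mask])), geo.mass_mg, geo.L0_mm, geo.rho_mg_per_mm3
        )
        out.append(DoseResponse(agonist, conc, base, plat, plat - base, flags))
    return out


def write_curves_csv(curves: Sequence[TensionStrainCurve], path: str) -> None:
    rows = []
    for c in curves:
        for lam, ten in zip(c.strain, c.tension):
            rows.append(
                {
                    "cycle": c.cycle_index,
                    "direction": c.direction,
                    "strain": lam,
                    "tension_mN_per_mm2": ten,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path: str, geometry: Optional[Geometry] = None) -> list[TensionStrainCurve]:
    df = pd.read_csv(path, comment="#")
    required = {"cycle", "direction", "strain", "tension_mN_per_mm2"}
    if not required.issubset(df.columns):
        raise ValueError(f"curves CSV missing columns {sorted(required - set(df.columns))}")
    curves = []
    for (cycle, direction), grp in df.groupby(["cycle", "direction"], sort=False):
        curves.append(
            TensionStrainCurve(
                cycle_index=int(cycle),
                direction=str(direction),
                strain=grp["strain"].to_numpy(float),
                tension=grp["tension_mN_per_mm2"].to_numpy(float),
                geometry=geometry,
            )
        )
    return curves
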