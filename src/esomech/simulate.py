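"""Forward simulation of organ-bath transducer traces.

Drives the constitutive model through a stepwise strain-cycle protocol and
emits the logged (time, force) series a force transducer would produce:
peak-then-plateau transients at each step, additive Gaussian instrument
noise, clipping at the transducer's full-scale deflection, reversal of
lengthening at the force threshold and of shortening near zero force, and
agonist doses applied between cycles.

Resting (basal) muscle tone is lost once a cycle has stretched the strip
beyond the tone-loss strain; the loss takes effect at the lengthening
reversal of that cycle, so the first lengthening limb still carries tone
while the shortening limb and later cycles do not, until an agonist dose
re-activates the muscle. This reproduces the rightward shift of the second
strain cycle and its restoration by carbachol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mechanics import activation_level, composite_tension, step_transient
from .params import TissueParams
from .protocol import StrainProtocol

__all__ = ["TraceMetadata", "TransducerTrace", "simulate_trace", "write_trace_csv", "read_trace_csv"]


@dataclass
class TraceMetadata:
    L0_mm: float
    mass_mg: float
    rho_mg_per_mm3: float
    tissue_layer: str = "mucosa"
    treatment: str = "vehicle"
    donor_id: str = "D1"
    seed: int = 0
    noise_sd_mN: float = 0.0
    hold_s: float = 120.0
    log_interval_s: float = 5.0
    full_scale_mN: float = 196.0
    dose_times: list = field(default_factory=list)  # (time_s, agonist, molar)
    flags: list = field(default_factory=list)


@dataclass
class TransducerTrace:
    """Logged transducer output plus the commanded-length step function."""

    time_s: np.ndarray
    force_mN: np.ndarray
    commanded_length_mm: np.ndarray
    metadata: TraceMetadata

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("trace times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "force_mN": self.force_mN,
                "commanded_length_mm": self.commanded_length_mm,
            }
        )


class _Recorder:
    def __init__(self, rng: np.random.Generator, noise_sd: float, full_scale: float):
        self.rng = rng
        self.noise_sd = noise_sd
        self.full_scale = full_scale
        self.t: list[np.ndarray] = []
        self.f: list[np.ndarray] = []
        self.length: list[np.ndarray] = []
        self.clock = 0.0

    def log_hold(self, forces: np.ndarray, rel_times: np.ndarray, length_mm: float) -> float:
        """Append one hold's samples; returns the hold-averaged logged force."""
        f = forces + (
            self.rng.normal(0.0, self.noise_sd, size=forces.shape) if self.noise_sd > 0 else 0.0
        )
        f = np.clip(f, 0.0, self.full_scale)
        self.t.append(self.clock + rel_times)
        self.f.append(f)
        self.length.append(np.full_like(f, length_mm))
        self.clock += rel_times[-1]
        return float(np.mean(f))


def simulate_trace(
    protocol: StrainProtocol,
    params: TissueParams,
    noise_sd_mN: float = 0.2,
    seed: int = 0,
    tissue_layer: str = "mucosa",
    treatment: str = "vehicle",
    donor_id: str = "D1",
) -> TransducerTrace:
    """Simulate one strip through the full strain-cycle protocol.

    Identical seeds yield identical traces. Returns the logged trace; any
    protocol anomalies (reversal threshold unreachable before the strain
    cap) are recorded in ``metadata.flags``.
    """
    rng = np.random.default_rng(seed)
    geo = params.geometry
    area = geo.cross_section_mm2
    rec = _Recorder(rng, noise_sd_mN, protocol.full_scale_mN)
    rel = np.arange(
        protocol.log_interval_s,
        protocol.hold_s + 0.5 * protocol.log_interval_s,
        protocol.log_interval_s,
    )

    doses: dict[str, float] = {}
    tone_lost = False
    flags: list[str] = []
    dose_times: list[tuple[float, str, float]] = []

    def activation() -> float:
        basal = 0.0 if tone_lost else params.muscle.basal_tone_fraction
        return activation_level(doses, params.pharm, basal)

    def steady_force(lam: float) -> float:
        return composite_tension(lam, activation(), params) * area

    length = geo.L0_mm

    # baseline hold at L0 (no step, no transient)
    f0 = steady_force(1.0)
    rec.log_hold(np.full_like(rel, f0), rel, length)

    for cycle in range(1, protocol.n_cycles + 1):
        # --- lengthening phase ---
        max_lam = length / geo.L0_mm
        while True:
            next_len = length + protocol.step_mm
            if next_len / geo.L0_mm > protocol.max_strain + 1e-12:
                if "strain_cap_reached" not in flags:
                    flags.append("strain_cap_reached")
                break
            length = next_len
            lam = length / geo.L0_mm
            max_lam = max(max_lam, lam)
            f_ss = steady_force(lam)
            forces = step_transient(f_ss, params.relax, rel, "lengthen")
            mean_f = rec.log_hold(forces, rel, length)
            if mean_f > protocol.force_reversal_mN:
                break
        # basal tone is lost by the stretch; takes effect at reversal
        if max_lam >= params.muscle.tone_loss_strain and params.muscle.basal_tone_fraction > 0:
            tone_lost = True

        # --- shortening phase ---
        while length - protocol.step_mm >= geo.L0_mm - 1e-9:
            length -= protocol.step_mm
            lam = length / geo.L0_mm
            f_ss = steady_force(lam)
            forces = step_transient(f_ss, params.relax, rel, "shorten")
            mean_f = rec.log_hold(forces, rel, length)
            if mean_f <= protocol.shorten_stop_mN:
                break

        # --- between-cycle dose events ---
        for ev in protocol.dose_events:
            if ev.after_cycle != cycle:
                continue
            lam = length / geo.L0_mm
            # pre-dose stabilization at constant length
            n_settle = max(1, int(round(protocol.dose_settle_s / protocol.log_interval_s)))
            rel_settle = protocol.log_interval_s * np.arange(1, n_settle + 1)
            f_pre = steady_force(lam)
            rec.log_hold(np.full_like(rel_settle, f_pre), rel_settle, length)
            dose_times.append((rec.clock, ev.agonist, ev.concentration))
            doses[ev.agonist] = doses.get(ev.agonist, 0.0) + ev.concentration
            f_post = steady_force(lam)
            n_resp = max(1, int(round(protocol.dose_window_s / protocol.log_interval_s)))
            rel_resp = protocol.log_interval_s * np.arange(1, n_resp + 1)
            direction = "lengthen" if f_post >= f_pre else "shorten"
            forces = step_transient(f_post, params.relax, rel_resp, direction)
            rec.log_hold(forces, rel_resp, length)

    meta = TraceMetadata(
        L0_mm=geo.L0_mm,
        mass_mg=geo.mass_mg,
        rho_mg_per_mm3=geo.rho_mg_per_mm3,
        tissue_layer=tissue_layer,
        treatment=treatment,
        donor_id=donor_id,
        seed=seed,
        noise_sd_mN=noise_sd_mN,
        hold_s=protocol.hold_s,
        log_interval_s=protocol.log_interval_s,
        full_scale_mN=protocol.full_scale_mN,
        dose_times=dose_times,
        flags=flags,
    )
    return TransducerTrace(
        time_s=np.concatenate(rec.t),
        force_mN=np.concatenate(rec.f),
        commanded_length_mm=np.concatenate(rec.length),
        metadata=meta,
    )


def write_trace_csv(trace: TransducerTrace, path: str) -> None:
    """Trace CSV dialect: a commented '# key: value' metadata header block
    followed by time_s,force_mN,commanded_length_mm columns."""
    m = trace.metadata
    lines = []
    for key in (
        "L0_mm",
        "mass_mg",
        "rho_mg_per_mm3",
        "tissue_layer",
        "treatment",
        "donor_id",
        "seed",
        "noise_sd_mN",
        "hold_s",
        "log_interval_s",
        "full_scale_mN",
    ):
        lines.append(f"# {key}: {getattr(m, key)}")
    lines.append(f"# dose_times: {json.dumps(m.dose_times)}")
    lines.append(f"# flags: {json.dumps(m.flags)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        trace.to_frame().to_csv(fh, index=False, lineterminator="\n")


def read_trace_csv(path: str) -> TransducerTrace:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_header)
    required = {"time_s", "force_mN", "commanded_length_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV missing columns {sorted(required - set(df.columns))}")
    for key in ("L0_mm", "mass_mg"):
        if key not in header:
            raise ValueError(f"trace CSV missing required metadata: {key}")
    meta = TraceMetadata(
        L0_mm=float(header["L0_mm"]),
        mass_mg=float(header["mass_mg"]),
        rho_mg_per_mm3=float(header.get("rho_mg_per_mm3", 1.0)),
        tissue_layer=header.get("tissue_layer", "mucosa"),
        treatment=header.get("treatment", "vehicle"),
        donor_id=header.get("donor_id", ""),
        seed=int(float(header.get("seed", 0))),
        noise_sd_mN=float(header.get("noise_sd_mN", 0.0)),
        hold_s=float(header.get("hold_s", 120.0)),
        log_interval_s=float(header.get("log_interval_s", 5.0)),
        full_scale_mN=float(header.get("full_scale_mN", 196.0)),
        dose_times=[tuple(x) for x in json.loads(header.get("dose_times", "[]"))],
        flags=json.loads(header.get("flags", "[]")),
    )
    return TransducerTrace(
        time_s=df["time_s"].to_numpy(float),
        force_mN=df["force_mN"].to_numpy(float),
        commanded_length_mm=df["commanded_length_mm"].to_numpy(float),
        metadata=meta,
    )
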