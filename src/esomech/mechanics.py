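"""Forward constitutive model of a one-dimensional tissue strip.

Composite tension is the exact sum of a passive ECM element and an active
muscle element; activation combines agonist Hill occupancies saturatingly
and is attenuated multiplicatively by isoproterenol. Step transients follow
a single-exponential relaxation toward the steady tension.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import (
    ECMParams,
    MuscleParams,
    PharmacologyParams,
    RelaxationParams,
    TissueParams,
)

__all__ = [
    "ecm_tension",
    "activation_level",
    "active_tension",
    "composite_tension",
    "step_transient",
]

CONTRACTILE_AGONISTS = ("carbachol", "histamine")
KNOWN_AGONISTS = CONTRACTILE_AGONISTS + ("isoproterenol",)


def ecm_tension(strain, p: ECMParams):
    """Passive matrix tension at a strain (scalar or array).

    Zero at and below the slack strain lambda_s; above it,
    A_e * ((lam/lambda_s)**k_e - 1), which is continuous at lambda_s and
    strictly increasing beyond.
    """
    lam = np.asarray(strain, dtype=float)
    if np.any(lam < 0):
        raise ValueError("strain must be >= 0")
    out = np.where(
        lam > p.slack_strain,
        p.amplitude * ((np.maximum(lam, p.slack_strain) / p.slack_strain) ** p.exponent - 1.0),
        0.0,
    )
    if np.isscalar(strain) or np.ndim(strain) == 0:
        return float(out)
    return out


def activation_level(
    doses: Mapping[str, float],
    p: PharmacologyParams,
    basal: float = 0.0,
) -> float:
    """Muscle activation in [0, 1] from agonist doses on top of basal tone.

    Contractile agonists combine saturatingly (complement-wise):
    occ = 1 - prod(1 - occ_i), activation = basal + (1 - basal) * occ.
    Isoproterenol multiplies the result by its relaxation factor. With no
    doses the result is exactly ``basal``.
    """
    if not 0 <= basal <= 1:
        raise ValueError("basal must be in [0, 1]")
    for name in doses:
        if name not in KNOWN_AGONISTS:
            raise KeyError(f"unknown agonist: {name!r}")
    miss = 1.0
    for name in CONTRACTILE_AGONISTS:
        c = float(doses.get(name, 0.0))
        miss *= 1.0 - p.occupancy(name, c)
    occ = 1.0 - miss
    act = basal + (1.0 - basal) * occ
    act *= p.relaxation_factor(float(doses.get("isoproterenol", 0.0)))
    return float(np.clip(act, 0.0, 1.0))


def active_tension(strain, activation: float, p: MuscleParams):
    """Active muscle tension: activation * T_max * exp(-((lam-lam_opt)/w)^2).

    Peaks exactly at the optimal strain; zero activation gives zero tension
    at every length.
    """
    if not 0 <= activation <= 1:
        raise ValueError("activation must be in [0, 1]")
    lam = np.asarray(strain, dtype=float)
    out = activation * p.max_tension * np.exp(-(((lam - p.optimal_strain) / p.width) ** 2))
    if np.isscalar(strain) or np.ndim(strain) == 0:
        return float(out)
    return out


def composite_tension(strain, activation: float, params: TissueParams):
    """Total strip tension: exactly ecm_tension + active_tension."""
    return ecm_tension(strain, params.ecm) + active_tension(strain, activation, params.muscle)


def step_transient(f_steady, p: RelaxationParams, t_since_step, direction: str):
    """Force during the hold after a length step.

    Lengthening: F(t) = F_ss * (1 + overshoot * exp(-t/tau)); shortening:
    F(t) = F_ss * (1 - overshoot * exp(-t/tau)), floored at zero. The force
    stabilizes at F_ss within the two-minute hold for the default tau.
    """
    t = np.asarray(t_since_step, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_step must be >= 0")
    if direction == "lengthen":
        out = f_steady * (1.0 + p.peak_overshoot_fraction * np.exp(-t / p.tau_s))
    elif direction == "shorten":
        out = np.maximum(0.0, f_steady * (1.0 - p.peak_overshoot_fraction * np.exp(-t / p.tau_s)))
    else:
        raise ValueError("direction must be 'lengthen' or 'shorten'")
    if np.isscalar(t_since_step) or np.ndim(t_since_step) == 0:
        return float(out)
    return out


def hold_mean_bias(p: RelaxationParams, hold_s: float, log_interval_s: float) -> float:
    """Fractional bias of the hold-averaged force relative to F_ss when the
    transient is sampled at the logging interval over one hold.

    Positive for lengthening holds, negate for shortening. Used to reason
    about (and, in tests, correct for) the averaging bias the stepwise
    protocol imposes on recovered tensions.
    """
    t = np.arange(log_interval_s, hold_s + 0.5 * log_interval_s, log_interval_s)
    return float(p.peak_overshoot_fraction * np.mean(np.exp(-t / p.tau_s)))
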