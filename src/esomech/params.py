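"""Parameter containers for the lumped tissue-strip model.

A strip is modelled as two additive one-dimensional elements acting in
parallel along the bath axis: a passive extracellular-matrix (ECM) element
that is slack below an engagement strain and stiffens as a power law above
it, and an active smooth-muscle element with a single-peaked length-tension
relationship scaled by pharmacological activation. A first-order relaxation
element reproduces the peak-then-plateau force transient seen after each
length step.

All tensions are in mN/mm^2, lengths in mm, masses in mg, times in seconds,
concentrations in molar. Strain is dimensionless, lambda = L / L0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = [
    "ECMParams",
    "MuscleParams",
    "PharmacologyParams",
    "RelaxationParams",
    "Geometry",
    "TissueParams",
    "vehicle_params",
    "cocktail_params",
    "ecm_only_params",
]


@dataclass
class ECMParams:
    """Passive matrix element: zero tension below the slack strain, then
    ``amplitude * ((lam / slack_strain)**exponent - 1)``, continuous at slack.

    The default slack strain of 2.0 reproduces the observation that a
    pre-stretched mucosal strip is infinitely compliant (stiffness = 0) from
    L0 to 2x L0 and stiffens rapidly beyond.
    """

    amplitude: float = 10.0      # tension scale A_e, mN/mm^2
    exponent: float = 6.0        # dimensionless k_e >= 1
    slack_strain: float = 2.0    # lambda_s >= 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("ECM amplitude must be >= 0")
        if self.exponent < 1:
            raise ValueError("ECM exponent must be >= 1")
        if self.slack_strain < 1:
            raise ValueError("ECM slack strain must be >= 1")


@dataclass
class MuscleParams:
    """Active element: Gaussian length-tension curve peaking at the optimal
    strain (filament-overlap optimum, ~2.5x L0 for esophageal tissue).

    ``basal_tone_fraction`` is the activation present with no agonist on
    board; it is lost once the strip has been stretched beyond
    ``tone_loss_strain`` (plastic loss of resting tone, restored only by an
    agonist dose).
    """

    max_tension: float = 10.0        # T_max, mN/mm^2
    optimal_strain: float = 2.5      # lambda_opt
    width: float = 0.6               # Gaussian width w, dimensionless
    basal_tone_fraction: float = 0.3
    tone_loss_strain: float = 2.0

    def __post_init__(self) -> None:
        if self.max_tension < 0:
            raise ValueError("max_tension must be >= 0")
        if self.optimal_strain <= 1:
            raise ValueError("optimal_strain must be > 1")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not 0 <= self.basal_tone_fraction <= 1:
            raise ValueError("basal_tone_fraction must be in [0, 1]")


@dataclass
class PharmacologyParams:
    """Hill dose-response parameters for the contractile agonists and the
    relaxant isoproterenol (multiplicative attenuation of activation)."""

    carbachol_ec50: float = 1e-7     # molar (0.1 uM)
    carbachol_hill: float = 1.5
    histamine_ec50: float = 1e-6     # molar
    histamine_hill: float = 1.0
    isoproterenol_ic50: float = 1e-7
    isoproterenol_hill: float = 1.0

    def __post_init__(self) -> None:
        for name in ("carbachol_ec50", "histamine_ec50", "isoproterenol_ic50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("carbachol_hill", "histamine_hill", "isoproterenol_hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def occupancy(self, agonist: str, concentration: float) -> float:
        """Hill occupancy c^n / (EC50^n + c^n) for a contractile agonist."""
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        if agonist == "carbachol":
            ec50, n = self.carbachol_ec50, self.carbachol_hill
        elif agonist == "histamine":
            ec50, n = self.histamine_ec50, self.histamine_hill
        else:
            raise KeyError(f"unknown contractile agonist: {agonist!r}")
        if concentration == 0:
            return 0.0
        cn = concentration**n
        return cn / (ec50**n + cn)

    def relaxation_factor(self, concentration: float) -> float:
        """Multiplier in [0, 1] applied to activation by isoproterenol;
        1 at zero dose, monotonically nonincreasing in concentration."""
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        if concentration == 0:
            return 1.0
        return 1.0 / (1.0 + (concentration / self.isoproterenol_ic50) ** self.isoproterenol_hill)


@dataclass
class RelaxationParams:
    """First-order step-relaxation: after a length step the force overshoots
    (lengthening) or undershoots (shortening) its new steady value by
    ``peak_overshoot_fraction`` and decays with time constant ``tau_s``.

    tau = 25 s leaves a residual of e^(-120/25) < 1% two minutes after a
    step, i.e. the force has stabilized within the hold.
    """

    tau_s: float = 25.0
    peak_overshoot_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.peak_overshoot_fraction < 0:
            raise ValueError("peak_overshoot_fraction must be >= 0")


@dataclass
class Geometry:
    """Strip geometry. Cross-sectional area is estimated as
    mass / (density * length), so tension = force * length * density / mass.
    The defaults make a 40 mN reading correspond to 30 mN/mm^2."""

    L0_mm: float = 15.0
    mass_mg: float = 20.0
    rho_mg_per_mm3: float = 1.0

    def __post_init__(self) -> None:
        if self.L0_mm <= 0 or self.mass_mg <= 0 or self.rho_mg_per_mm3 <= 0:
            raise ValueError("geometry fields must be > 0")

    @property
    def cross_section_mm2(self) -> float:
        return self.mass_mg / (self.rho_mg_per_mm3 * self.L0_mm)


@dataclass
class TissueParams:
    """Complete parameter set for one simulated strip."""

    ecm: ECMParams = field(default_factory=ECMParams)
    muscle: MuscleParams = field(default_factory=MuscleParams)
    pharm: PharmacologyParams = field(default_factory=PharmacologyParams)
    relax: RelaxationParams = field(default_factory=RelaxationParams)
    geometry: Geometry = field(default_factory=Geometry)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TissueParams":
        return cls(
            ecm=ECMParams(**d.get("ecm", {})),
            muscle=MuscleParams(**d.get("muscle", {})),
            pharm=PharmacologyParams(**d.get("pharm", {})),
            relax=RelaxationParams(**d.get("relax", {})),
            geometry=Geometry(**d.get("geometry", {})),
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "TissueParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def vehicle_params() -> TissueParams:
    """Default (vehicle-treated) mucosal strip parameters."""
    return TissueParams()


def cocktail_params() -> TissueParams:
    """Th2/fibrotic-cocktail-like stiffening: raised ECM amplitude and
    exponent with earlier matrix engagement (leftward shift of the passive
    curve). Muscle and relaxation elements unchanged."""
    p = TissueParams()
    p.ecm = ECMParams(amplitude=12.0, exponent=9.0, slack_strain=1.8)
    return p


def ecm_only_params(
    amplitude: float = 10.0, exponent: float = 6.0, slack_strain: float = 2.0
) -> TissueParams:
    """Matrix-only strip (no active muscle, no basal tone)."""
    p = TissueParams()
    p.ecm = ECMParams(amplitude=amplitude, exponent=exponent, slack_strain=slack_strain)
    p.muscle = MuscleParams(max_tension=0.0, basal_tone_fraction=0.0)
    return p
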