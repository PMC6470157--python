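"""Power-law stiffness analysis and muscle/ECM cycle decomposition.

The tension-strain relation of a strip is summarized by the hyperelastic
power law

    T(lam) = A * lam**k,      lam = L / L0,

with A = e^b and (b, k) obtained by ordinary least squares on the double
natural-log transformed data. Stiffness is the derivative
dT/dlam = A*k*lam**(k-1) (A*k at L0) and compliance its reciprocal. The
exponent k is independent of the L0 calibration and is therefore the
parameter used for group comparisons; an amplitude-free relative stiffness
index k*lam**(k-1) supports comparisons at a fixed strain (e.g. 1.25 L0).

The smooth-muscle contribution is isolated by subtracting the post-stretch
(matrix-only) cycle-2 curve from the basal cycle-1 or agonist-induced
cycle-3 curve; the difference curves peak at the muscle's optimal-overlap
strain (~2.5 L0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .analysis import TensionStrainCurve

__all__ = [
    "PowerLawFit",
    "DifferenceCurve",
    "PeakResult",
    "DecompositionResult",
    "KComparison",
    "fit_power_law",
    "stiffness_at",
    "relative_stiffness_at",
    "compliance_curve",
    "subtract_cycles",
    "find_peak",
    "decompose",
    "compare_k",
]

DEFAULT_TENSION_FLOOR = 0.05  # mN/mm^2; log transform undefined at zero tension
MIN_FIT_POINTS = 6            # ">5 data pairs"


@dataclass
class PowerLawFit:
    A: float
    b: float
    k: float
    r_squared: float
    n_points: int
    n_excluded: int
    strain_range: tuple
    valid: bool = True
    reason: str = ""
    cycle_index: Optional[int] = None
    direction: Optional[str] = None

    def tension(self, strain):
        """Model tension A * lam**k."""
        return self.A * np.asarray(strain, float) ** self.k


def _invalid_fit(reason: str, n_points: int, n_excluded: int, curve=None) -> PowerLawFit:
    return PowerLawFit(
        A=np.nan,
        b=np.nan,
        k=np.nan,
        r_squared=np.nan,
        n_points=n_points,
        n_excluded=n_excluded,
        strain_range=(np.nan, np.nan),
        valid=False,
        reason=reason,
        cycle_index=getattr(curve, "cycle_index", None),
        direction=getattr(curve, "direction", None),
    )


def fit_power_law(
    curve: TensionStrainCurve, min_tension_floor: float = DEFAULT_TENSION_FLOOR
) -> PowerLawFit:
    """OLS of ln(tension) on ln(strain) over points with strain > 1 and
    tension above the floor. Returns an invalid-fit result (not an
    exception) when fewer than six usable points remain."""
    lam = np.asarray(curve.strain, float)
    ten = np.asarray(curve.tension, float)
    keep = (lam > 1.0) & (ten > min_tension_floor)
    n_excluded = int(np.size(lam) - np.count_nonzero(keep))
    if np.count_nonzero(keep) < MIN_FIT_POINTS:
        return _invalid_fit(
            f"needs >= {MIN_FIT_POINTS} points with strain > 1 and tension > floor",
            int(np.count_nonzero(keep)),
            n_excluded,
            curve,
        )
    x = np.log(lam[keep])
    y = np.log(ten[keep])
    res = stats.linregress(x, y)
    return PowerLawFit(
        A=float(np.exp(res.intercept)),
        b=float(res.intercept),
        k=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(np.count_nonzero(keep)),
        n_excluded=n_excluded,
        strain_range=(float(lam[keep].min()), float(lam[keep].max())),
        cycle_index=getattr(curve, "cycle_index", None),
        direction=getattr(curve, "direction", None),
    )


def stiffness_at(fit: PowerLawFit, strain):
    """Stiffness dT/dlam = A*k*lam**(k-1); A*k at lam = 1 (L0)."""
    if not fit.valid:
        raise ValueError(f"invalid fit: {fit.reason}")
    lam = np.asarray(strain, float)
    if np.any(lam < 1):
        raise ValueError("strain must be >= 1")
    out = fit.A * fit.k * lam ** (fit.k - 1.0)
    return float(out) if np.ndim(strain) == 0 else out


def relative_stiffness_at(k: float, strain: float = 1.25) -> float:
    """Amplitude-free stiffness index k*lam**(k-1): the stiffness at a given
    strain deduced from the exponent alone, up to the common scale A.
    Monotone increasing in k for lam >= 1."""
    if strain < 1:
        raise ValueError("strain must be >= 1")
    return float(k * strain ** (k - 1.0))


def compliance_curve(
    source: Union[PowerLawFit, TensionStrainCurve], strain_grid: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise compliance 1/stiffness.

    From a fit, stiffness is analytic on the supplied grid; from a raw
    curve, stiffness is the centered finite difference of tension against
    strain at the curve's own points. Zero stiffness yields an explicit
    ``inf`` marker rather than a finite number.
    """
    if isinstance(source, PowerLawFit):
        if strain_grid is None:
            raise ValueError("strain_grid required when computing compliance from a fit")
        grid = np.asarray(strain_grid, float)
        stiff = stiffness_at(source, grid)
    else:
        order = np.argsort(source.strain)
        lam = np.asarray(source.strain, float)[order]
        ten = np.asarray(source.tension, float)[order]
        if lam.size < 3:
            raise ValueError("need >= 3 points for finite-difference stiffness")
        stiff = np.gradient(ten, lam)
        grid = lam
    with np.errstate(divide="ignore"):
        comp = np.where(stiff > 0, 1.0 / np.where(stiff > 0, stiff, 1.0), np.inf)
    return grid, comp


@dataclass
class DifferenceCurve:
    strain: np.ndarray
    tension: np.ndarray
    has_negative: bool = False
    label: str = ""

    def __len__(self) -> int:
        return len(self.strain)


def subtract_cycles(
    curve_a: TensionStrainCurve, curve_b: TensionStrainCurve, label: str = ""
) -> DifferenceCurve:
    """curve_a minus curve_b on curve_a's strains within the strain overlap,
    with curve_b linearly interpolated. Negative differences are permitted
    and flagged."""
    a_lam = np.asarray(curve_a.strain, float)
    a_ten = np.asarray(curve_a.tension, float)
    order_b = np.argsort(curve_b.strain)
    b_lam = np.asarray(curve_b.strain, float)[order_b]
    b_ten = np.asarray(curve_b.tension, float)[order_b]
    lo = max(a_lam.min(), b_lam.min())
    hi = min(a_lam.max(), b_lam.max())
    keep = (a_lam >= lo - 1e-12) & (a_lam <= hi + 1e-12)
    if not np.any(keep):
        raise ValueError("curves have no overlapping strain support")
    order_a = np.argsort(a_lam[keep])
    lam = a_lam[keep][order_a]
    diff = a_ten[keep][order_a] - np.interp(lam, b_lam, b_ten)
    return DifferenceCurve(
        strain=lam, tension=diff, has_negative=bool(np.any(diff < 0)), label=label
    )


@dataclass
class PeakResult:
    strain: float
    tension: float
    at_boundary: bool = False


def find_peak(curve: DifferenceCurve) -> PeakResult:
    """Sub-grid peak of a difference curve by parabolic refinement.

    A parabola is fit through the maximum sample and its two nearest
    neighbors (both from one side when the maximum sits on a boundary, in
    which case the result is flagged). The refined vertex is clamped to
    within one local grid step of the maximum sample; ties and degenerate
    (non-concave) parabolas fall back to the sampled maximum, ties broken
    toward the lower strain.
    """
    lam = np.asarray(curve.strain, float)
    ten = np.asarray(curve.tension, float)
    if lam.size < 3:
        raise ValueError("need >= 3 points to locate a peak")
    order = np.argsort(lam)
    lam, ten = lam[order], ten[order]
    i = int(np.argmax(ten))  # first occurrence -> lower strain on ties
    boundary = i == 0 or i == lam.size - 1
    if i == 0:
        idx = [0, 1, 2]
        step = lam[1] - lam[0]
    elif i == lam.size - 1:
        idx = [i - 2, i - 1, i]
        step = lam[i] - lam[i - 1]
    else:
        idx = [i - 1, i, i + 1]
        step = min(lam[i] - lam[i - 1], lam[i + 1] - lam[i])
    coeffs = np.polyfit(lam[idx], ten[idx], 2)
    if coeffs[0] >= 0:  # degenerate: no concave vertex
        return PeakResult(strain=float(lam[i]), tension=float(ten[i]), at_boundary=boundary)
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    vertex = float(np.clip(vertex, lam[i] - step, lam[i] + step))
    tension = float(np.polyval(coeffs, vertex))
    return PeakResult(strain=vertex, tension=tension, at_boundary=boundary)


@dataclass
class DecompositionResult:
    muscle_basal: DifferenceCurve
    muscle_induced: Optional[DifferenceCurve]
    peak_basal: PeakResult
    peak_induced: Optional[PeakResult]


def decompose(
    curves: Sequence[TensionStrainCurve], direction: str = "lengthen"
) -> DecompositionResult:
    """Muscle/ECM decomposition by cycle subtraction: cycle1 - cycle2 is the
    basal muscle contribution, cycle3 - cycle2 (when a third, induced cycle
    exists) the agonist-induced contribution."""
    by_cycle = {c.cycle_index: c for c in curves if c.direction == direction}
    if 1 not in by_cycle or 2 not in by_cycle:
        raise ValueError("decomposition requires cycle 1 and cycle 2 curves")
    basal = subtract_cycles(by_cycle[1], by_cycle[2], label="basal")
    induced = None
    peak_induced = None
    if 3 in by_cycle:
        induced = subtract_cycles(by_cycle[3], by_cycle[2], label="induced")
        peak_induced = find_peak(induced)
    return DecompositionResult(
        muscle_basal=basal,
        muscle_induced=induced,
        peak_basal=find_peak(basal),
        peak_induced=peak_induced,
    )


@dataclass
class KComparison:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_k(groups: Mapping[str, Sequence[float]]) -> KComparison:
    """Unpaired two-tailed t-test on fitted exponents k between two groups.

    k is the comparison parameter because it is independent of the L0
    calibration. Degenerate (zero-variance) inputs take an exact-equality
    fast path: p = 1 when the groups coincide, p = 0 otherwise.
    """
    if len(groups) != 2:
        raise ValueError("compare_k requires exactly two groups")
    (la, va), (lb, vb) = groups.items()
    a = np.asarray(list(va), float)
    b = np.asarray(list(vb), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        t_stat, p = (0.0, 1.0) if same else (np.inf * np.sign(a[0] - b[0]), 0.0)
    else:
        t_stat, p = stats.ttest_ind(a, b)
    return KComparison(
        label_a=la,
        label_b=lb,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
    )
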