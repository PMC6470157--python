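"""Reference in silico experiments at the package's study conditions.

Each function runs the full pipeline (simulate -> segment -> curves ->
fit/decompose, or generate panel -> test) at the documented default
conditions and returns summary statistics. These are the experiments behind
the worked examples and the reproduction script; they are ordinary library
code and accept a base seed so that every replicate is reproducible.
"""

from __future__ import annotations

import numpy as np

from .analysis import build_cycle_curves, segment_steps
from .edp import paired_de
from .panel import generate_panel
from .params import TissueParams, cocktail_params, ecm_only_params, vehicle_params
from .protocol import StrainProtocol, three_cycle_protocol
from .simulate import simulate_trace
from .stiffness import compare_k, decompose, fit_power_law

__all__ = [
    "lengthen_fits",
    "ecm_exponent_recovery",
    "decomposition_peaks",
    "fit_quality_r2",
    "cocktail_power",
    "null_panel_fdr",
]

DEFAULT_NOISE_SD = 0.2  # mN, instrument noise on each logged force sample


def lengthen_fits(
    protocol: StrainProtocol, params: TissueParams, noise_sd: float, seed: int
) -> dict[int, "object"]:
    """Simulate one trace and fit the lengthening curve of every cycle."""
    trace = simulate_trace(protocol, params, noise_sd_mN=noise_sd, seed=seed)
    curves = build_cycle_curves(segment_steps(trace, protocol), params.geometry)
    return {
        c.cycle_index: fit_power_law(c) for c in curves if c.direction == "lengthen"
    }


def ecm_exponent_recovery(n_traces: int = 100, seed: int = 0) -> dict:
    """Precision of the fitted power law on matrix-only strips.

    A matrix-only strip (defaults: A_e = 10 mN/mm^2, k_e = 6, slack at
    2x L0) is run through a two-cycle protocol and the post-stretch
    (matrix-characterizing) cycle-2 lengthening curve is fitted. The truth
    for each configuration is the fit of the corresponding noiseless trace;
    the experiment reports the distribution of relative errors of k and A
    under the default instrument noise across seeded replicates.
    """
    protocol = StrainProtocol(n_cycles=2)
    params = ecm_only_params()
    truth = lengthen_fits(protocol, params, 0.0, seed=0)[2]
    ks, As = [], []
    for i in range(n_traces):
        fit = lengthen_fits(protocol, params, DEFAULT_NOISE_SD, seed=seed + i)[2]
        ks.append(fit.k)
        As.append(fit.A)
    k_err = np.abs(np.array(ks) - truth.k) / truth.k
    a_err = np.abs(np.array(As) - truth.A) / truth.A
    return {
        "k_true": truth.k,
        "A_true": truth.A,
        "k_median_rel_err": float(np.median(k_err)),
        "A_median_rel_err": float(np.median(a_err)),
        "n": n_traces,
    }


def decomposition_peaks(n_seeds: int = 20, seed: int = 0) -> dict:
    """Peak strains of the basal (cycle1-cycle2) and induced (cycle3-cycle2)
    muscle difference curves over seeded default three-cycle simulations."""
    protocol = three_cycle_protocol()
    params = vehicle_params()
    basal, induced = [], []
    for i in range(n_seeds):
        trace = simulate_trace(protocol, params, noise_sd_mN=DEFAULT_NOISE_SD, seed=seed + i)
        curves = build_cycle_curves(segment_steps(trace, protocol), params.geometry)
        res = decompose(curves)
        basal.append(res.peak_basal.strain)
        induced.append(res.peak_induced.strain)
    return {
        "basal_mean": float(np.mean(basal)),
        "induced_mean": float(np.mean(induced)),
        "basal": basal,
        "induced": induced,
        "n": n_seeds,
    }


def fit_quality_r2(n_seeds: int = 10, seed: int = 0) -> dict:
    """r^2 of the log-log power-law fits of default noisy lengthening curves
    (all three cycles of the reference protocol)."""
    protocol = three_cycle_protocol()
    params = vehicle_params()
    r2 = []
    for i in range(n_seeds):
        fits = lengthen_fits(protocol, params, DEFAULT_NOISE_SD, seed=seed + i)
        for f in fits.values():
            assert f.valid and f.n_points > 5
            r2.append(f.r_squared)
    return {"min": float(np.min(r2)), "median": float(np.median(r2)), "n_fits": len(r2)}


def cocktail_power(
    n_replicates: int = 200, n_per_arm: int = 8, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Power to detect Th2-cocktail-like stiffening.

    Each replicate simulates ``n_per_arm`` vehicle and cocktail strips
    through a single basal strain cycle, fits k to each lengthening curve,
    and applies the unpaired two-tailed t-test. Reports the fraction of
    replicates in which the cocktail arm has a significantly larger k.
    """
    protocol = StrainProtocol(n_cycles=1)
    veh, ckt = vehicle_params(), cocktail_params()
    significant = 0
    for rep in range(n_replicates):
        groups = {}
        for offset, (label, params) in enumerate((("vehicle", veh), ("cocktail", ckt))):
            ks = []
            for i in range(n_per_arm):
                fit = lengthen_fits(
                    protocol, params, DEFAULT_NOISE_SD,
                    seed=seed + rep * 100 + 50 * offset + i,
                )[1]
                ks.append(fit.k)
            groups[label] = ks
        res = compare_k(groups)
        if res.p_value < alpha and res.difference < 0:  # cocktail mean larger
            significant += 1
    return {"fraction_significant": significant / n_replicates, "n": n_replicates}


def null_panel_fdr(n_seeds: int = 500, n_genes: int = 60, donors: int = 5, seed: int = 0) -> dict:
    """Mean fraction of genes flagged at BH-adjusted p < 0.05 on null panels
    (no treatment effect, fully detected)."""
    fracs = []
    for i in range(n_seeds):
        pm = generate_panel(
            n_genes=n_genes, donors=donors, effect_spec=None, missing_spec=1.0, seed=seed + i
        )
        de = paired_de(pm)
        fracs.append(len(de.significant()) / n_genes)
    return {"mean_fraction_significant": float(np.mean(fracs)), "n": n_seeds}
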