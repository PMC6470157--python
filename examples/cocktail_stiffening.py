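"""Detect cytokine-cocktail-like stiffening from fitted exponents.

Simulates eight vehicle and eight cocktail-parameterized strips (raised
matrix amplitude and exponent, earlier engagement), fits k to each basal
lengthening curve, and compares the groups with an unpaired two-tailed
t-test. Because k is independent of the L0 calibration it is the robust
comparison parameter; the relative stiffness at 1.25x L0 deduced from k
(k * 1.25**(k-1), amplitude-free) moves in the same direction.
"""

import esomech as em
from esomech.experiments import lengthen_fits

protocol = em.StrainProtocol(n_cycles=1)
groups = {}
for offset, (label, params) in enumerate(
    (("vehicle", em.vehicle_params()), ("cocktail", em.cocktail_params()))
):
    ks = [
        lengthen_fits(protocol, params, noise_sd=0.2, seed=50 * offset + i)[1].k
        for i in range(8)
    ]
    groups[label] = ks

res = em.compare_k(groups)
print(f"vehicle  k: mean {res.mean_a:.2f} (n={res.n_a})")
print(f"cocktail k: mean {res.mean_b:.2f} (n={res.n_b})")
print(f"unpaired t-test: t = {res.t_statistic:.2f}, p = {res.p_value:.3g}")
rv = em.relative_stiffness_at(res.mean_a, 1.25)
rc = em.relative_stiffness_at(res.mean_b, 1.25)
print(f"relative stiffness at 1.25 L0 deduced from k: vehicle {rv:.1f}, "
      f"cocktail {rc:.1f} (higher k -> stiffer, lower compliance)")
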