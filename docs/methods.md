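# Methods

## The tissue model

`esomech` treats an ex vivo esophageal strip (mucosa or an isolated smooth
muscle layer) as a lumped, one-dimensional pair of additive elements acting
along the bath axis:

* **Passive extracellular-matrix (ECM) element.** Tension is zero up to a
  slack (engagement) strain λ_s and follows
  `T_ecm(λ) = A_e·((λ/λ_s)^{k_e} − 1)` beyond it — continuous at λ_s,
  strictly increasing above. The slack form encodes the observation that a
  pre-stretched mucosal strip is infinitely compliant (stiffness 0) from L0
  up to about 2×L0 and then stiffens rapidly, as a cross-linked biopolymer
  network does when its fibres straighten.
* **Active smooth-muscle element.** A Gaussian length–tension curve,
  `T_act(λ) = a·T_max·exp(−((λ−λ_opt)/w)²)`, with activation `a ∈ [0, 1]`.
  The Gaussian is the simplest differentiable unimodal form for the
  filament-overlap optimum; `λ_opt = 2.5` places maximal tension at
  2.5×L0, where the subtraction analysis of real strips finds it.
* **Pharmacology.** Contractile agonists (carbachol, histamine) contribute
  Hill occupancies `c^n/(EC50^n + c^n)` which combine **saturatingly**
  (complement-wise): `occ = 1 − Π(1 − occ_i)`, then
  `a = basal + (1 − basal)·occ`. This reproduces mutual augmentation of
  carbachol and histamine with a ceiling at full activation. Isoproterenol
  acts as a multiplicative relaxation factor `1/(1+(c/IC50)^n)` on the
  activation — a β-agonist attenuates force but cannot invert it.
* **Step relaxation.** After each length step the force overshoots
  (lengthening) or undershoots (shortening) its new steady value by a
  fraction `overshoot` and relaxes exponentially with time constant τ:
  `F(t) = F_ss·(1 ± overshoot·e^{−t/τ})`, floored at zero. With τ = 25 s
  the residual at the end of a 2-minute hold is `0.5·e^{−4.8} < 1%`, i.e.
  the force has stabilized within the hold.
* **Basal-tone plasticity.** Resting tone (`basal_tone_fraction`, default
  0.3) is lost once a cycle stretches the strip beyond `tone_loss_strain`
  (default 2.0). The loss takes effect at the lengthening→shortening
  reversal of that cycle: the first lengthening limb carries tone (so the
  basal difference curve peaks at λ_opt), the shortening limb and later
  cycles do not — until an agonist dose re-activates the muscle. This
  reproduces the rightward shift of the second strain cycle and its
  leftward restoration by carbachol.

Composite tension is exactly `T_ecm + T_act`. Geometry converts tension to
transducer force through the cross-section `area = mass/(ρ·length)`, so
`tension = force·length·ρ/mass`; the default strip (20 mg, 15 mm, ρ = 1
mg/mm³) makes a 40 mN reading equal 30 mN/mm².

### Default parameters

| parameter | default | units | notes |
|---|---|---|---|
| A_e | 10 | mN/mm² | ECM tension scale |
| k_e | 6 | – | ECM exponent |
| λ_s | 2.0 | – | ECM engagement strain |
| T_max | 10 | mN/mm² | peak active tension |
| λ_opt | 2.5 | – | optimal-overlap strain |
| w | 0.6 | – | length–tension width |
| basal tone | 0.3 | – | pre-stretch activation |
| tone-loss strain | 2.0 | – | plastic tone loss |
| τ | 25 | s | step-relaxation constant |
| overshoot | 0.5 | – | transient peak fraction |
| carbachol EC50 / n | 0.1 µM / 1.5 | – | Hill parameters |
| histamine EC50 / n | 1 µM / 1.0 | – | chosen, no measured anchor |
| isoproterenol IC50 / n | 0.1 µM / 1.0 | – | relaxation factor |

`T_max = 10 mN/mm²` is calibrated so that the 1 µM carbachol-induced
(cycle-3) curve stays inside the 40 mN reversal window up to ≈2.5×L0,
giving an induced difference curve that peaks near the optimal-overlap
strain with a magnitude of ≈10 mN/mm², as measured mucosal strips do. With
a much larger T_max the induced cycle would hit the safety reversal well
before 2.5×L0 and the peak would be unobservable within the protocol.

The **cocktail parameterization** (`cocktail_params()`) models
Th2/fibrotic stiffening as a purely passive change: A_e 10→12, k_e 6→9,
λ_s 2.0→1.8 (a stiffer matrix engaging earlier, i.e. the leftward shift of
the passive curve). These values were chosen once, from the qualitative
description of cocktail-treated strips, not tuned to any test.

## The simulated protocol

The simulator drives the model through the stepwise organ-bath protocol:
0.8 mm length increments at 2-minute intervals, output logged every 5 s,
lengthening reversed at the first hold whose *averaged logged force*
exceeds 40 mN, shortening reversed when the averaged force falls to the
preload (≤ 1 mN), transducer output clipped to [0, 196 mN], additive
Gaussian instrument noise (default SD 0.2 mN — small against the 1 mN
preload; no noise magnitude is measured for the real instrument). Agonist
doses are applied between cycles after a 4-minute stabilization hold, with
a 5-minute logged response window. A strain cap of 3×L0 guards protocols
that can never reach reversal (flagged in the trace metadata). A
figure-legend vs methods-text discrepancy exists in the source protocol
description (0.72 vs 0.8 mm steps); the package defaults to 0.8 mm with
`step_mm` configurable. Mid-hold dosing is not modelled: doses anchor to
completed cycles, which is what the downstream analysis reads.

## Trace reduction and fitting

Each constant-length hold entered via a commanded-length jump becomes one
step segment; its force is the time-average over the hold (units of
tension are preserved — the axis of the resulting curves is tension, not
tension·time). Cycles are delimited at shorten→lengthen transitions.
Because the average includes the relaxation transient, hold-averaged
tensions carry a known multiplicative bias
`1 + overshoot·⟨e^{−t/τ}⟩ ≈ 1.093` on lengthening holds (the discrete
mean over 5 s samples across 120 s). Being multiplicative, it shifts the
log-log intercept (A) but cancels exactly in the exponent k — one more
reason k is the robust comparison parameter.

The power law `T = A·λ^k` is fitted by OLS on `(ln λ, ln T)`; `A = e^b`.
Points with strain ≤ 1 or tension ≤ 0.05 mN/mm² are excluded (the log is
undefined at zero; the cycle-2 sub-slack region is genuinely tension-free)
and at least six usable points are required — otherwise an invalid-fit
result (with a reason, not an exception) is returned. Stiffness is
`dT/dλ = A·k·λ^{k−1}` (A·k at L0), compliance its reciprocal, with an
explicit `inf` marker where stiffness is zero. Fits default to
lengthening-direction points; shortening fits are available by flag.
Because A extrapolates the fitted line to `ln λ = 0`, far outside the data
support for post-stretch curves, it is markedly noisier than k — and
depends on the L0 calibration, which k does not.

Note that the fitted exponent is an *empirical descriptor*, not the
generator's k_e: the slack-offset ECM law is not itself of the class
`A·λ^k`, so the fitted k of a matrix curve exceeds k_e (and rises after
stretching, since cycle 2 is fit over the steep region just above λ_s —
the same direction seen in real strips). Recovery is therefore assessed
against the fit of the noise-free trace of the same configuration, and
exact parameter recovery is asserted on data generated from the power-law
class itself.

The muscle/ECM decomposition subtracts the cycle-2 curve (linearly
interpolated — curves are sparse and monotone) from cycle 1 (basal) or
cycle 3 (induced) on the strain overlap. The peak of a difference curve is
refined by a parabola through the maximum sample and its two nearest
neighbors; when the maximum sits on the support boundary the two neighbors
come from one side, the vertex is clamped to within one grid step of the
boundary, and the result is flagged. The clamp keeps the sub-grid estimate
stable under noise at the cost of a small downward bias when the physical
peak lies just beyond the last measurable strain (the induced cycle
reverses slightly before 2.5×L0, so its reported peak strain sits at
≈2.43–2.44 rather than 2.50).

Group comparisons use the unpaired two-tailed t-test on fitted k. The
"stiffness at 1.25×L0" comparison is made through the amplitude-free index
`k·λ^{k−1}` (monotone in k): extrapolating each fit's own A below its data
support would invert the comparison artifactually, whereas the deduced
index matches how stiffness differences at short lengths are inferred from
k in practice.

Agonist responses are quantified as (post-dose plateau − pre-dose
baseline) tension, with a 60 s baseline before the dose and the last 60 s
of a 5-minute post-dose window as plateau; truncated windows are flagged.
Carbachol-challenge tensions are normalized per cross-section before any
pooling.

## The panel workflow

`generate_panel` emulates a 96-gene qPCR signature panel on paired
vehicle/treated samples: per-gene baseline `N(6, 1.5²)` log2 intensity, a
per-donor-per-gene random effect `N(0, 0.8²)` shared by both arms (what
makes pairing informative), gene-specific treatment effects on the log2
scale, residual noise `N(0, 0.5²)`, and Bernoulli detection calls. By
default 60/96 of genes are well detected (call probability 0.95) and the
rest poorly (0.25), so a 50% call-rate filter retains a ≈60-gene cluster.
It does **not** emulate ΔΔCt preprocessing, probe saturation, or
correlated gene modules; passing tests show the statistics are correct,
not that real panel data meet their assumptions.

The analysis applies, in order: the call-rate filter (before
normalization/testing), two-way hierarchical clustering (Euclidean
distance, Ward linkage — "Ward" read for an apparent "Wald" typo in the
source description), PCA of the top three variance components (sign fixed
so each component's largest-magnitude loading is positive), per-gene
paired two-tailed t-tests on log2 values with Benjamini–Hochberg step-up
adjustment across testable genes (significance at adjusted p < 0.05),
fold changes as `2^(mean paired log2 difference)` (the geometric-mean
estimator), strict `>` threshold fold-change set logic (a gene at exactly
5.0-fold is excluded from the >5-fold set), and the volcano table
(flag = adjusted p < 0.05 and fold-change magnitude > 2). Undetected
entries of retained genes are treated as missing and that donor's pair is
dropped for that gene; genes left with fewer than two complete pairs get
NaN statistics and are excluded from the BH family. Fold changes are
computed from the same (filtered, unnormalized) log2 values the tests use.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical traces and panels. Sub-seeds for replicate
  experiments are derived as small integer offsets from the base seed.
* Reversal decisions use the *noisy, clipped, logged* samples — what the
  instrument would average — not the latent model force.
* Zero-variance t-test inputs take exact-equality fast paths (p = 1 for
  identical, p = 0 for disjoint constants) rather than returning NaN.
* Degenerate (non-concave) peak parabolas fall back to the sampled
  maximum; ties break toward the lower strain.
* OLS, t-tests, BH, Ward linkage and SVD are delegated to
  scipy/statsmodels/numpy; independent brute-force implementations of
  Ward merge heights, BH step-up, PCA coordinates and the stiffness
  derivative exist only in the test suite as oracles.

## Reference experiment sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance tests
use: 100 seeded matrix-only traces for fit-recovery statistics, 10 seeded
default runs (30 fits) for r², 20 seeds for decomposition peaks, 200
replicates at n = 8 strips/arm for the cocktail power estimate, and 500
null panels (60 genes, 5 donor pairs) for FDR control. These sizes give
stable medians/fractions while keeping a full run around ten seconds.

## Known limitations

* The model is a lumped 1-D element pair: no continuum mechanics, no
  cross-bridge kinetics, no viscoelastic parameter estimation from the
  transients (only their averages are analyzed), no hysteresis-energy
  quantification, no drift or culture-time degradation.
* Tone loss is binary and instantaneous at reversal; real strips lose tone
  gradually and partially.
* The agonist transient reuses the step-relaxation morphology (peak then
  plateau); receptor desensitization is not modelled.
* The panel generator's genes are independent given the donor effect;
  realized co-expression structure (and hence clustering of real panels)
  is richer.
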