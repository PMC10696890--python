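# Methods

This document defines the model implemented by `burdendmf`, the fitting and
evaluation machinery, the synthetic data generator, and the numerical and
statistical design decisions — including the behaviours one should expect at
desk scale.

## Dynamic mean-field network model

Each brain region holds one excitatory (NMDA) and one inhibitory (GABA)
neural-mass population. With gating fractions `S_E`, `S_I` per region `n`
and a structural connectivity matrix `C`:

```
I_E_n = W_E·I_0 + w_plus·J_N·S_E_n + G·J_N·Σ_m C_nm·S_E_m − J_n·S_I_n
I_I_n = W_I·I_0 + J_N·S_E_n − S_I_n + lam·G·J_N·Σ_m C_nm·S_E_m

r_p   = H(I_p; a_p, b_p, d_p, M_p)          (population rate, Hz)

dS_E_n = [ −S_E_n/τ_E + (1 − S_E_n)·γ·r_E_n ] dt + σ dW
dS_I_n = [ −S_I_n/τ_I + r_I_n/1000 ] dt + σ dW
```

Defaults (`DMFParameters`): `W_E=1, W_I=0.7, I_0=0.382 nA, w_plus=1.4,
J_N=0.15 nA, a_E=310 nC⁻¹, b_E=125 Hz, d_E=0.16 s, a_I=615 nC⁻¹,
b_I=177 Hz, d_I=0.087 s, τ_E=100 ms, τ_I=10 ms, γ=0.641/1000, σ=0.01 nA,
dt=1 ms`. Times are in ms and rates in Hz, so both gating drifts carry the
Hz→ms⁻¹ factor 1/1000 (γ includes it; the inhibitory drift divides `r_I`
explicitly). Integration is Euler–Maruyama with uncorrelated Gaussian noise
`σ·√dt` in both gating equations and `S` clamped to [0, 1] after each step.
The numba kernels (`_core`) are deterministic per seed.

### Transfer function and response gain

The frequency–current curve is

```
H(I; a, b, d, M) = M·(aI − b) / (1 − exp(−d·(aI − b)))
```

with the removable singularity at `aI = b` evaluated analytically as `M/d`
(6.25 Hz for the excitatory pool at `M=1`). The gain `M` multiplies the
*response* — it scales the output rate without entering the exponential.
This choice is deliberate: both populations operate below threshold
(`r_E ≈ 3 Hz < 1/d_E`, `r_I ≈ 4 Hz < 1/d_I`), and a gain applied inside the
exponential as well is *decreasing* in `M` in that regime, which would make
a loss of inhibitory gain suppress, rather than raise, excitatory activity —
contradicting the disinhibition phenomenology the model is built to express
(and the monotonicity validated in the acceptance suite). With the
multiplicative response gain, reducing `M_I` raises `r_E` monotonically
(measured at 24 nodes, G=2: mean `r_E` 2.99 → 57.5 Hz as `s_I_abeta` goes
0 → −0.5).

### Burden-to-gain polynomials

Regional amyloid-beta map `A` and tau map `T` (SUVR-like, non-negative)
modulate the gains through

```
M_E_n = (1 + b_E_abeta + s_E_abeta·A_n) · (1 + b_E_tau + s_E_tau·T_n)
M_I_n = (1 + b_I_abeta + s_I_abeta·A_n)            (tau: no inhibitory action)
```

Directional constraints encode the biology: `s_E_abeta ≥ 0` (impaired
glutamate reuptake), `s_E_tau ≤ 0` (loss of excitatory synapses),
`s_I_abeta ≤ 0` (GABAergic interneuron dysfunction), `b_I_tau = s_I_tau = 0`.
Six coefficients remain free; the search box bounds each magnitude by 5.
Products driven non-positive are clamped at `1e-6` (the transfer function
requires positive gain); clamping is counted and logged, since a fit living
on the clamp is degenerate.

### Feedback inhibition control (FIC)

`calibrate_fic` tunes the per-node inhibitory weights `J_n` so every
excitatory pool rests at 3 Hz: simulate a 10 s window (2 s burn-in), move
each `J_n` proportionally to its relative rate error (`η=0.5`), reuse the
same noise seed every iteration, stop when the worst node is within 0.2 Hz.
Non-convergence returns the best iterate with `converged=False` and a
warning. FIC is always calibrated at homogeneous gains (`M=1`) and held
fixed while burden-modulated gains act, so gain effects are measured against
a balanced baseline rather than being re-absorbed by recalibration.

## Hemodynamic forward model

A Balloon–Windkessel model maps excitatory rates to BOLD. The neural drive
is `z = 0.5·r + 3`; vasodilatory signal, inflow, volume and deoxyhemoglobin
follow the standard four-equation system (`κ=0.65 s⁻¹, γ_h=0.41 s⁻¹,
τ_h=0.98 s, α=0.32, ρ=0.34`), integrated at dt=1 ms in logarithmic state
variables (`f̂=log f`, etc.), which keeps the physiologically positive
quantities positive by construction. The log states are clamped to ±15 — a
pure numerical guard reachable only under explosive neural input (it
prevents inflow collapsing to exact zero and dividing by it). The BOLD
signal uses the volume/deoxyhemoglobin read-out with `k1=7ρ, k2=2,
k3=2ρ−0.2, V0=0.02`. Series are downsampled to TR=3 s after a 10 s burn-in.
The kernel is validated against an adaptive-step integration of the
untransformed system (max deviation 2.7e-5 under a time-varying drive).

## Observables and objective

- **Static FC**: Pearson correlations across the full series; model/target
  similarity is the correlation of upper-triangle entries.
- **swFCD**: sliding-window FC (30 volumes, shift 3); the distribution of
  pairwise window-FC similarities. Skipped when a series is shorter than
  window + shift.
- **phFCD**: instantaneous Hilbert phases (demeaned, band 0.008–0.08 Hz);
  the distribution of cosine similarities between phase-coherence patterns
  at all time pairs, with 10 volumes trimmed per edge against filter
  transients.
- **KS distance**: two-sample Kolmogorov–Smirnov statistic between model
  and target distributions (validated against an explicit O(n·m) ECDF
  oracle).

The fitting objective is the mean phFCD-KS over independent trials; trial
seeds derive deterministically from `(seed, eval_index, trial)` so any
experiment is reproducible and common-random-number designs are possible.
Trials producing non-finite BOLD score the maximal distance 1.0.

## Fitting

1. **Working point**: `sweep_g` scores the homogeneous model on a G grid
   (all three observables reported; the phFCD-KS minimum defines G*).
2. **Gain fit**: `optimize_gains` minimizes the objective over the free
   coefficients with an in-package Gaussian-process Bayesian optimizer
   (`optim.gp_minimize`: Matérn-5/2 surrogate, expected-improvement
   acquisition over random + local candidates, deterministic per seed).
   Bounds with `low == high` pin a coefficient (the `restrict_*` helpers
   build the 2-D inhibitory-amyloid search and the single-pathway and
   homogeneous restrictions); `x0` seeds explicit start points, which the
   pipeline uses to guarantee the homogeneous baseline is always evaluated.

## Evaluation

- **Shuffle null** (`shuffle_null`): re-assigns the burden values to random
  regions (independent permutations per protein by default; a joint switch
  exists) and re-scores the optimum. A spatially specific model fits the
  true arrangement better than permuted ones.
- **Burden isolation** (`burden_isolation`): fits amyloid-only, tau-only,
  homogeneous and unrestricted arms. The restricted arms run first and seed
  the unrestricted search (`x0`); every arm's optimum is re-scored on
  common-random-number validation trials, and the unrestricted arm selects
  among its own optimum and the nested ones on those trials. Under CRN this
  makes the unrestricted median structurally ≤ every restricted arm's —
  the finite-budget search honors the model nesting instead of losing to
  winner's-curse noise.
- **Model comparison** (`compare_models`): pairwise two-sided Mann-Whitney
  tests with Benjamini–Hochberg correction and ns/*/**/***/**** annotation.
- **AT(N)** (`atn_classify`): positivity thresholds at 0.9 × the
  subject-weighted cohort mean burden (A: 1.4013, T: 1.6703 on the default
  cohort table; ≥ is positive).
- **Rate scan** (`rate_vs_scaling`): mean rates as `s_I_abeta` varies with
  FIC fixed — the direct read-out of burden-driven disinhibition.
- **Power analysis** (`min_detectable_effect`): Monte-Carlo power curve of
  the rank-sum test (normal approximation with continuity correction,
  decision-equivalent to the exact test at these sample sizes). For
  17-vs-10 groups: `d_min = 1.25`, a minimum detectable objective
  difference of 0.0625 at σ = 0.05.

## Synthetic data

- **Connectome** (`gen_connectome`): bilateral (L/R labels), symmetric,
  non-negative; exponential distance-like decay within hemispheres,
  homotopic links, and a designated hub set (strongest nodes, 10% per
  hemisphere). `log_normalize` applies `log(1+w)` and rescales so the
  maximum node input is exactly 0.7.
- **Burden maps** (`gen_burden_maps`): smooth hemisphere-mirrored Gaussian
  fields scaled to cohort-specific means (HC 1.31/1.53, MCI 1.52/1.80,
  AD 2.01/2.46 for amyloid/tau) with CV 0.25. The tau field's independent
  component is Gram-Schmidt-orthogonalized against the amyloid field, so
  the realized inter-map correlation equals the requested value exactly
  (smooth fields otherwise share large chance correlations at small N).
  When a connectome is supplied, both maps load 0.6 onto standardized log
  node strength — pathology concentrates in hubs, which is what makes the
  burden topography network-relevant and the shuffle test meaningful.
- **Targets** (`gen_target_bold`): forward simulations at chosen
  ground-truth gains. The default recovery ground truth is
  `s_E_abeta=0.23, s_E_tau=−0.26, s_I_abeta=−0.25` — sign structure and
  relative magnitudes of a plausible AD parameterization, scaled so no
  regional gain clamps at SUVR-scale burdens.

## Known behaviours and limitations

- **Homogeneous G-sweep bias**: on targets generated with heterogeneous
  gains, the homogeneous sweep under-estimates G — burden-driven excitation
  substitutes for coupling. On homogeneous targets the sweep recovers the
  generating G exactly; on the shipped AD example it prefers 1.0 over the
  generating 2.0. Interpret G* as a surrogate working point, not an
  estimate of the generating coupling.
- **Budget sensitivity of the gain fit**: with few GP calls and trials the
  in-search objective is noisy and extreme corners of the box (gain-clamped
  regimes) can look spuriously good. Mitigations built in: baseline/nested
  `x0` seeding, CRN validation re-scoring, clamp logging. The acceptance
  suite demonstrates sign-correct recovery at 24 calls × 2 trials with a
  30-vs-30 validation comparison.
- **phFCD is a spatially-marginalized statistic**: it responds strongly to
  the *distribution* of regional gains but only weakly to their placement,
  unless placement changes collective dynamics (e.g. strong disinhibition
  concentrated on hubs near criticality). Shuffle tests should therefore
  use targets with genuinely network-relevant burden topography; the
  validation suite's hub-contrast benchmark yields p ≈ 1.5e-11, while
  mild smooth maps yield no detectable placement effect at desk scale.
- **Desk scale**: 24–40 regions, 100–620 s recordings, minutes per
  experiment. Group-level empirical claims (real cohorts, atlas-scale
  connectomes) are out of scope.
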