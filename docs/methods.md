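# Methods

`gendcm` implements dynamic causal modelling (DCM) for cross-spectral
densities over a network of heterogeneous neural mass models. This note
records the model, the numerical choices, and what the synthetic studies do
and do not demonstrate.

## Neural mass dynamics

Each source is a convolution-based neural mass model. Population *j* of a
source obeys

    dv_j/dt     = v̇_j
    dv̇_j/dt    = ( Σ_l γ_l S(v_l) + Σ_m A_m S(v_m) + I_j
                    − 2 v̇_j − v_j / T_j ) / T_j

equivalent to convolving presynaptic firing rate with the synaptic kernel
`h(t) = (t/T) e^(−t/T)`. The sigmoid `S(v) = 1/(1+e^(−Rv)) − 1/2` converts
membrane potential to a *deviation* in firing rate from baseline; the
subtraction places the operating point exactly at the origin, which is
therefore a fixed point of the assembled system and the point around which
everything is linearized. Signs of `γ` encode transmitter type (GABAergic
negative); extrinsic connections `A` are glutamatergic and positive;
endogenous innovations `I` enter one population per source.

Two models ship:

* **MMC** — motor cortex microcircuit: middle (MP), superficial (SP), deep
  (DP) pyramidal populations and one inhibitory interneuron pool (II);
  14 intrinsic connections; innovations enter MP; the observed signal is the
  mixture 0.2·SP + 0.2·MP + 0.6·DP.
* **BGT** — basal ganglia–thalamus: striatum, external/internal pallidum
  (GPe/GPi), subthalamic nucleus (STN), motor thalamus; 9 intrinsic
  connections covering the direct (Str→GPi→Tha), indirect
  (Str→GPe→STN→GPi→Tha) and STN→GPe feedback paths, with inhibitory
  self-connections on Str, GPe and GPi; innovations enter Str; the observed
  signal is the STN potential.

The default network couples them with four extrinsic connections —
Tha→MP, Tha→DP, DP→Str (corticostriatal) and DP→STN (hyperdirect) — and is
stable at the default prior means, with least-damped modes near 13 and
22 Hz (alpha/beta band), as expected for this circuit.

### Connection-index convention

Published prior tables list coupling strengths by index only; the
index-to-arrow assignment below is a **frozen convention** of this package.
For the cortical model it was chosen so that the two largest prior couplings
land on the dominant laminar pathways (layer 4 → 2/3 and layer 2/3 → 5):

| MMC idx | arrow | sign | | BGT idx | arrow | sign |
|---|---|---|---|---|---|---|
| 1 | MP→MP | − | | 1 | Str→Str | − |
| 2 | MP→SP | + | | 2 | Str→GPe | − |
| 3 | II→MP | − | | 3 | GPe→GPe | − |
| 4 | II→II | − | | 4 | GPe→STN | − |
| 5 | MP→II | + | | 5 | STN→GPe | + |
| 6 | DP→II | + | | 6 | Str→GPi | − |
| 7 | SP→SP | − | | 7 | STN→GPi | + |
| 8 | SP→II | + | | 8 | GPi→GPi | − |
| 9 | II→DP | − | | 9 | GPi→Tha | − |
| 10 | DP→DP | − | | | | |
| 11 | SP→DP | + | | | | |
| 12 | II→SP | − | | | | |
| 13 | SP→MP | + | | | | |
| 14 | MP→DP | + | | | | |

Extrinsic order: A1 = Tha→MP, A2 = Tha→DP, A3 = DP→Str, A4 = DP→STN, with
prior means (110, 588, 672, 127) — chosen so the corticostriatal projection
is stronger than the hyperdirect one. Condition effects on extrinsic
strengths come in three groups: both thalamocortical arrows share one, the
corticostriatal and hyperdirect arrows get one each.

### Units

Internal time unit is **seconds**; time constants and delays are quoted in
ms and converted at the natural-scale boundary. With seconds, the
single-stage loop gain `γ·T·S'(0)` is O(0.25) at the default priors and the
circuit is stable; a ms reading would be wildly unstable, so seconds is the
only consistent interpretation. Frequencies are in Hz; power laws use
`(f / 1 Hz)^(−β)` so the noise amplitudes `α` are dimensionally clean.

## Parameterisation and priors

All nonnegative parameters are lognormal scale factors: `ϑ_i = π_i e^(θ_i)`
with `θ_i ~ N(0, σ_i²)`. Condition-specific effects `B` are additive in
`θ`-space (multiplicative on the natural scale): the baseline condition uses
`π e^θ`, the modulated condition `π e^(θ+B)` on the declared connections.
The shipped two-source network has 76 parameters: γ (14+9), T (4+5), A (4),
B (14+9+3), R (2), delays (4), three power-law noise pairs, and two
lead-field gains. The data log-precision λ has a Gaussian prior
(mean 16, variance 4), deliberately tight-precision so inversion leans on
accuracy rather than priors.

## Spectral forward model

The flow is linearized at the origin (closed-form Jacobian on the hot path;
a central finite-difference linearization, relative step 1e−6, is the
reference implementation and agrees to rounding). Axonal delays are
book-kept per source pair — within-MMC 1 ms, MMC→BGT 8 ms, BGT→MMC 8 ms,
within-BGT 4 ms — expanded to a state-pair matrix `D` that is zero within a
population (leak and structural terms are undelayed, keeping the delay a
synaptic/axonal one), and folded into the Jacobian by the first-order Taylor
embedding

    Jd = (I + D ∘ J)^(−1) J        (x(t−d) ≈ x(t) − d ẋ(t))

This is an accuracy/simplicity trade-off: at ≤ 45 Hz and the default delay
priors the induced eigenvalue error is first-order small, and the
time-domain simulator (which realises delays exactly) matches the embedded
prediction to well under 10% band-normalised error at the priors.

With input matrix `U` (innovations enter the acceleration of MP and Str,
scaled 1/T) and observation rows `L` (lead-field gain × output mixture),

    H(f)  = L (2πi f · I − Jd)^(−1) U
    G(f)  = H diag(g_u) H* + α_c f^(−β_c) 𝟙 + diag(α_s f^(−β_s))
    g_u(f) = 512 · α_u f^(−β_u)

Innovations at the two input sites are independent with identical power
laws; the common observation noise is fully coherent across channels (the 𝟙
matrix); the factor 512 scales the innovations density and is a convention
of the parameter table. An unstable `Jd` (any eigenvalue with nonnegative
real part) raises a flagged error, which the inversion treats as a rejected
step. Per-population spectra (the "virtual electrode" view) use a unit
observation row on one membrane potential and no channel noise.

## Inversion: variational Laplace

The data feature is the stacked real vector of auto-spectra and the real and
imaginary parts of the upper-triangle cross-spectra, per condition and
frequency (4 numbers per frequency per condition for two channels). Both
conditions are fitted jointly with shared θ and free B. The objective is
variational free energy at the posterior mode

    F = −½ e^λ ‖y − g(θ)‖² + n/2 (λ − log 2π)
        − ½ (θ−m)' Π (θ−m) − ½ (λ − 16)² / 4

maximised by Gauss–Newton ascent with Levenberg–Marquardt regularisation:
prediction Jacobian by central differences (step 1e−3 in θ), steps accepted
only if F increases, regulariser doubled on rejection and halved on
acceptance (initial value 4, scaled by the curvature diagonal — small
initial regularisers cannot reach a stable step within the eight-rejection
budget from a cold start), λ updated by its own damped Newton step each
outer iteration. Convergence: ΔF < 0.01 on three consecutive accepted
iterations, at most 64 iterations, or best-so-far with `converged=False`
after eight consecutive rejections. The posterior covariance is the inverse
Gauss–Newton curvature at the optimum. For speed, the finite-difference
Jacobian pushes all perturbed parameter vectors through one batched
resolvent solve; it agrees with the scalar path to machine precision.

Because these inversions are prone to shallow local optima, `multistart`
re-initialises with the previous posterior estimates; from the second
restart a small seeded perturbation (0.1 prior-sd) is added, since an
unperturbed chain restarted at a converged optimum cannot leave it. The
returned result has the highest free energy across restarts.

## Synthetic studies

`generate_study` emulates a two-condition (OFF/ON medication) cohort of 20
hemispheres. Ground truth per hemisphere: log-scale parameters drawn around
the study base with 0.25 prior-sd jitter on couplings, time constants and
extrinsic strengths; the ON condition applies the default effect
B = −0.5 (a ≈ 40% reduction) on GPe→STN, corticostriatal and hyperdirect
couplings, plus 0.05 between-hemisphere jitter. The study base raises the
lead-field gains (θ_L = 4, i.e. two prior sd of the broad gain prior) and
lowers observation noise (θ_α = −2), because at the default priors the
signal path lies orders of magnitude below the observation-noise floor;
with the base values the OFF-condition STN spectrum shows a visible beta
peak that the ON condition suppresses.

Sample CSDs are produced either analytically — the predicted `G(f)` plus
per-frequency complex-Wishart sampling noise — or by the slow validation
path: Euler–Maruyama integration (dt = 0.05 ms, 2 s burn-in) of the delayed
nonlinear dynamics driven by spectrally factorised power-law noise, followed
by a ridge-regularised least-squares MVAR(12) spectral estimate (ridge
1e−6; the estimator's role is feature extraction, so a fully Bayesian MVAR
is not needed). The analytic generator's Wishart degrees of freedom default
to **150**, calibrated so its per-bin scatter matches the across-seed
scatter of MVAR estimates from ~157 s of simulated data (the recording
duration the cohort design assumes); counting one degree of freedom per
3.4 s epoch (≈ 46) would overstate the noise of a parametric estimator
roughly threefold.

What passing tests on these studies show: the full pipeline — generation,
inversion, group statistics — recovers strong condition effects with
correct signs and calibrated null behaviour *under the generator's
assumptions* (the generating model equals the fitted model; stationary
noise; no artefacts, volume conduction, or head-movement confounds). They
do not show that real MEG/LFP recordings would identify the same effects.
One known limitation is documented in the repository notes: at the
calibrated noise level the corticostriatal condition effect is only weakly
identifiable — its reduction can be partially mimicked by striatal
self-inhibition and the shared thalamocortical gain — so its per-hemisphere
sign recovery falls short of the other two pathways unless sampling noise
is much lower.

## Group inference

Per connection, the hemisphere-level posterior-mean B values are tested
against zero with a two-tailed one-sample t-test (df = n−1); the
Benjamini–Hochberg step-up procedure at q = 0.05 controls the false
discovery rate across the full family of 26 condition-effect parameters
(both the family size and q are configurable). Under a null study the
per-connection uncorrected rejection rate is ~0.05 by construction.

## Degenerate inputs and tie-breaks

Zero-variance B columns in the group table get t = 0, p = 1 rather than an
error (clamped connections carry no evidence). Unstable parameter draws in
the study generator are redrawn (≤ 10 attempts, logged). Empty data in the
inversion returns the prior. The delay operator raises a conditioning error
if `(I + D∘J)` is singular. Coherence requires strictly positive
auto-spectra.

## Problem sizes

Default analyses use the 5–45 Hz window with 41 frequencies; the synthetic
cohort studies in the test-suite and the acceptance script run on an
11-point grid with 48-iteration, two-restart inversions, sizes chosen to
keep a full 3-replicate, 60-inversion study on one CPU in minutes while
leaving the statistical conclusions unchanged at full resolution.
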