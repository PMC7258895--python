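# Methods

## Scope and model

`dcmnet` implements a complete dynamic-causal-modelling analysis of an
eight-region bilateral motor network (M1, PM, SMA, S1 per hemisphere,
labelled contralateral/ipsilateral to the moved ankle) probed by a passive
movement block paradigm. The pipeline has five stages: model-space
construction, forward BOLD simulation, variational model inversion,
family-level random-effects Bayesian model selection (RFX-BMS), and
permutation group statistics. All stages run on synthetic data; the cohort
generator is first-class, tested code.

### Neural layer

Bilinear dynamics `dx/dt = (A + u·B)x + C·u` with couplings in Hz.
Off-diagonal entries of `A` are unconstrained (prior mean 0 Hz); diagonal
entries are parameterized as `−0.5·exp(a_i)` so self-inhibition is strictly
negative and the log-scale `a_i` carries a zero-mean prior. `B` is fixed at
zero: no modulatory structure is part of the model space, and a field is
reserved for future use. The external input is a unit boxcar — the ~1 Hz
cycling of the passive movement is deliberately collapsed to a sustained
block drive, since a 4 s TR cannot resolve it and block-design modelling
conventionally treats the block as constant.

The block schedule starts with one 40 s rest block and alternates 40 s
active/inactive blocks to the end of the 400 s session (5 active blocks,
200 s active in total).

### Hemodynamic layer and BOLD read-out

Per region, the extended Balloon model:

    ds/dt = x − D·s − γ(f − 1)
    df/dt = s
    T·dv/dt = f − v^(1/α)
    T·dq/dt = f·(1 − (1−E₀)^(1/f))/E₀ − v^(1/α)·q/v

and `y = V0·(k1(1−q) + k2(1−q/v) + k3(1−v))` with `k1 = 4.3·θ₀·E₀·TE`,
`k2 = ε·r₀·E₀·TE`, `k3 = 1 − ε`. Constants are the de-facto defaults for
1.5 T gradient-echo data: γ = 0.32 s⁻¹, α = 0.32, E₀ = 0.4, V0 = 0.04,
θ₀ = 40.3 s⁻¹, r₀ = 25 s⁻¹, TE = 42 ms. Three hemodynamic parameters are
free per region, as log-scalings of fixed priors: signal decay D (prior
0.64 s⁻¹), transit time T (prior 2 s) and the intra/extravascular signal
ratio ε (prior 1; note `k3 = 1 − ε` may go negative, which the revised BOLD
formulation permits).

### Integration

Classical fixed-step RK4 on a microtime grid of TR/16 = 0.25 s by default;
the first microtime sample of each TR bin is the volume read-out. The input
is held constant across each microstep — block edges align with the grid, so
every step integrates a smooth vector field. At the default step the global
truncation error is ≈ 3×10⁻⁶ of the signal range (measured against an
adaptive reference integrator at rtol 10⁻¹¹); halving the step brings
agreement below 10⁻⁶, which the test suite checks. The integrator is batched
over parameter sets, which makes finite-difference sensitivities during
inversion a single sweep. Non-finite trajectories (unstable couplings
driving `f` or `v` out of domain) raise an error naming the first bad volume
index.

Optional simulator noise: white neural-state noise added per microstep as
`σ·√dt·N(0,1)` (grid-independent injected variance; default σ = 0.01 —
a stand-in, since no magnitude is established for endogenous fluctuations)
and white observation noise at a configurable amplitude SNR (default 10,
measured against the noiseless series' standard deviation).

## Inversion

Deterministic variational Laplace. The session is modelled as
`y = g(θ) + Xβ + e` with a constant and a linear drift always in `X`
(removed by orthogonal projection, with the corresponding loss of effective
degrees of freedom), and white observation noise with scalar precision τ.
Endogenous state fluctuations are *not* filtered explicitly — a deliberate
simplification; they are absorbed into τ. Parameter recovery tests quantify
the cost of this choice.

Under a Gaussian posterior `q(θ) = N(μ, Σ)` the free energy
`F = accuracy − KL(q ‖ prior)` is ascended by Gauss–Newton steps with
step-halving (up to 8 halvings; three consecutive failed steps abort with
`converged=False`). Between parameter steps τ gets a conjugate Gamma update
(hyperprior shape 2, rate 1); the likelihood is evaluated in percent signal
change, which puts that hyperprior on a sensible scale for signals of a few
tenths of a percent. `F` omits the hyperprior's own KL term: the precision
enters as a point estimate, which cancels in model comparisons on common
data. Jacobians are central finite differences (step 10⁻⁴ on the packed
scale) computed in one batched integration sweep.

Prior variances (declared defaults, config-overridable; not reconstructions
of any published setting): extrinsic couplings 1/16, self log-scales 1/64,
input gains 1, hemodynamic log-scales 1/64. The tight self/hemodynamic
priors keep trial steps inside the stable dynamic regime. Convergence is
|ΔF| < 0.01 nats (default) or 64 iterations.

Packing order of the free parameters: masked off-diagonal couplings
(row-major), self log-scales, masked input gains, then per-region (D, T, ε)
log-scales. Model 11 has 20 + 8 + 3 + 24 = 55 free parameters.

### What recovery tests show

On a 3-region reduced system at default noise, posterior-mean couplings
correlate with the truth at r ≈ 0.82 when each subject's two sessions are
averaged (the study design has two runs per subject), and all
self-connections recover with the correct sign. Single sessions give
r ≈ 0.78; even noiseless data caps near r ≈ 0.88 because reciprocal
couplings can trade off along genuine likelihood ridges (near-perfect fits
with displaced parameters). This is a property of the estimation problem,
not of the optimizer.

## Family-level model selection

Per-subject evidence = sum of the subject's session free energies
(conditionally independent runs). Family evidence = log-mean of member-model
evidences (log-sum-exp minus log family size), i.e. a uniform within-family
prior, so 3-member and 4-member families compare without size bias. RFX-BMS
uses the variational Dirichlet scheme (responsibilities
`u_nk ∝ exp(ev_nk + ψ(α_k) − ψ(Σα))`, concentration updates
`α = α₀ + Σu`, convergence Δα < 10⁻⁴, α₀ = 1 per family). Expected
probability is `α/Σα`; exceedance probability is the argmax frequency over
seeded Monte-Carlo Dirichlet draws (10⁶ by default; two independent seeds
agree within 0.002 per family).

With 10 subjects all decisively favouring one family, α = (11,1,…,1):
expected probability 11/14 ≈ 0.786 for the 4-family set, 11/13 ≈ 0.846 for
the 3-family set, exceedance ≈ 0.9986 and ≈ 0.9990. One behaviour worth
knowing: a subject with *flat* evidence does not shrink the posterior
toward uniformity — the variational scheme allocates ambiguous subjects in
proportion to current belief, so the winner's expected probability rises
slightly. The tests assert the correct comparative property (a flat subject
pulls the winner up less than a decisive one).

The winning model is the unique member of the intersection of the two
winning families (`id = 3·(s1−1) + stim`); ties in expected probability are
rejected rather than silently broken.

## Group statistics

Two-sided unpaired permutation tests on the difference of condition means,
per coupling. Unpaired (not subject-paired) is the default because the
published p-values are numerically consistent with unpaired two-sample
statistics on the group summaries; the cohort generator exposes a
between-condition correlation knob for paired designs. Exact enumeration
runs when `C(n_x+n_y, n_x)` ≤ the permutation budget (all 184,756 splits of
a 10-vs-10 cohort exceed the default 10⁴ budget, so that case is
Monte-Carlo); the add-one estimator `(1+b)/(n_perm+1)` never returns zero.
FDR adjustment is standard Benjamini–Hochberg step-up, applied separately
within parameter pools (couplings; input gains; hemodynamic parameters).

The published FDR-adjusted column for this analysis is *not* reproducible by
standard BH on the printed raw p-values (BH on 28 values with smallest raw
p ≈ 0.0045 yields ≈ 0.126, not ≈ 0.0395); whichever adjustment variant
produced it is unknown, so this package uses standard BH and treats only the
raw-p significance pattern as a reproduction target.

## Synthetic cohorts

Two generator modes, because downstream stages consume data at two levels:
group statistics operate on subject-level coupling estimates, while
inversion and BMS operate on raw time series.

* **Parameter tables**: per coupling and condition, `n` Gaussian draws;
  with `moment_match=True` the sample is affinely standardized so its sample
  mean and SD (ddof = 1) equal the configured targets to machine precision.
  Defaults are the published 28-coupling group summaries of the winning
  model. Draws are independent across couplings and conditions (correlation
  knob available, up to 1.0 = shared draws).
* **BOLD sessions**: per-subject coupling matrices from the same draws;
  input gains 0.5 Hz on the model's driven regions and log-normal
  hemodynamic jitter (log-SD 0.1) — both stand-ins, since no group values
  are published for them ("no significant differences" is all that is
  reported); both surfaced in config. The published mean coupling matrices
  are *linearly unstable* as dynamical systems (largest real eigenvalue
  ≈ +0.2 Hz), so sampled subjects inherit that instability; the generator
  therefore applies a uniform negative diagonal shift per subject until the
  largest real eigenvalue is ≤ −0.25 Hz (margin configurable, shift logged
  in the self log-scales), with resampling-based retries as an alternative
  when stabilization is disabled. Parameter-table mode is untouched by this.

What the generator does *not* emulate: lesion anatomy, subject-specific
hemodynamic topography, motion artifacts, scanner drift beyond the linear
confound, or any spatial/voxel structure. Passing tests therefore show the
*machinery* is correct under the study's design and printed group moments —
not that real stroke fMRI would yield these estimates.

## Pipeline and problem sizes

`run_replication` persists per-stage artifacts (model space JSON, parameter
CSV, per-session evidence CSVs, BMS JSONs, statistics CSV, report JSON) so
any stage can be re-run from its upstream files. Fast mode exercises
selection and statistics end-to-end with decisive evidence stubs in
seconds. Full mode simulates BOLD cohorts and inverts every candidate model
per session sequentially; results are independent of execution order. The
test suite exercises full mode on a reduced configuration (2 subjects, 2
models, 160 s sessions) and the recovery and calibration properties on
3-region systems and 200-replicate null cohorts — sizes chosen to keep the
default suite deep but quick while still touching every code path; the
same code scales to the complete 12-model, 10-subject configuration.

## Known limitations

* Deterministic inversion under state noise mis-attributes endogenous
  fluctuations to observation noise; coupling estimates attenuate
  accordingly (quantified above).
* A single scalar noise precision is shared across regions.
* Exceedance probabilities are Monte-Carlo, not analytic; with the default
  10⁶ draws the standard error is ≈ 0.0005 near p = 0.5 and far smaller in
  the decisive regime.
* The free energy omits hyperprior KL terms, so absolute values are not
  comparable across different noise treatments — only across models on the
  same data, which is the only use made of them.
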