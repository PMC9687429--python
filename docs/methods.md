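# Methods

## The virtual patient

The simulated patient is the four-state "identifiable virtual patient"
glucose–insulin model. Subcutaneously infused insulin `u` [μU/min]
passes through a subcutaneous compartment `I_SC` and a plasma
compartment `I` (time constants τ₁, τ₂ ≈ 49, 47 min, clearance
C_I = 2010 mL/min), drives a remote insulin effect
`I_EFF` (rate p₂, sensitivity S_I), and glucose obeys

    dG/dt = −(GEZI + I_EFF)·G + EGP + RA(t)

with glucose effectiveness at zero insulin GEZI = 2.2×10⁻³ min⁻¹ and
endogenous production EGP = 1.33 mg/dL/min. Meals enter through the
appearance rate `RA(t) = CH·s/(V_G τ_m²)·e^(−s/τ_m)` (s = time since
the meal, CH in mg), a gamma-like kernel that peaks at `s = τ_m`
(≈ 40.5 min) and integrates to CH/V_G; multiple meals superpose
linearly. Useful closed forms used as test anchors: the zero-insulin
equilibrium G = EGP/GEZI ≈ 604.5 mg/dL and the constant-infusion fixed
point G = EGP/(GEZI + S_I·u/C_I) (≈ 82.0 mg/dL at 50 U/day for the mean
patient).

The model is assumed-smooth, single-pool-per-compartment, with no
glucose counter-regulation, no renal excretion at high glycemia and no
insulin-independent saturation — its validity region is the
normo-to-moderately-hyperglycemic range the controller is supposed to
keep patients in, which is why trajectories crossing a configurable
sanity ceiling (default 1000 mg/dL) raise a diagnostic error instead of
being trusted.

## Variability model

* **Interpatient**: each of the nine parameters is drawn independently
  from Normal(mean, 5% of mean); non-positive draws are redrawn. At a
  5% coefficient of variation the truncation is astronomically rare, so
  redraw-vs-clip is immaterial, but redraw keeps the distribution clean.
* **Intrapatient**: every parameter is scaled by
  `1 + 0.10·sin(2πt/1440 + φ)` — a ±10% circadian swing. The phase is
  not physiologically identified; the default is a common zero phase at
  simulation start (midnight) for all parameters, with per-parameter
  random phases available as an option. The choice is recorded in the
  trace metadata.
* **Meals**: three daily meals at 07:30/12:30/19:30 ± 30 min with
  42/66/51 ± 3.5/5.5/4.25 g of carbohydrate, drawn independently per
  day; a day's times are redrawn as a block if not strictly increasing.

What the generator does **not** emulate: CGM sensor noise and dropout
(the controller reads true G), exercise, stress, snacks, pump
quantization, day-to-day meal correlation. Passing tests therefore show
correctness of the method under the stated idealized study conditions,
not clinical performance.

## The controller

The control design deliberately ignores the patient model. The plant is
abstracted as `dx/dt = f + b·u + d` with x = G; choosing the
"no-knowledge" estimates f̂ = 0 and |b̂| = 1 and a constant target
x_d = 110 mg/dL, feedback linearization gives `u = λ·x̃ + d̂` with
x̃ = G − x_d, λ = 1 min⁻¹, and d̂ the output of an 11-neuron Gaussian
RBF network over x̃ (centers −25 … 100 mg/dL, widths 5–200 mg/dL).
A Lyapunov argument for the error/weight dynamics yields the adaptation
law `dw/dt = η·x̃·φ(x̃)`, guarded by a projection operator that keeps
‖w‖₂ ≤ ϑ = 3×10⁴ — the hard safety cap against unbounded insulin
commands. Commands are clamped at u_min = 0 (a pump cannot remove
insulin); no upper actuation limit is set by default.

Sign convention: taken literally, b̂ = +1 makes the loop positive
feedback (insulin *lowers* glucose, so the physical input gain is
negative) and diverges. The implementation therefore uses the
stabilizing equivalent b̂ = −1 consistently in the control law and in
the pretraining regression; the literal convention remains available
behind `literal_gain_sign` for demonstration. With this convention d̂
converges to the (positive) insulin requirement, dimensionally
consistent with ϑ ≈ the μU/min scale of a ~43 U/day basal.

Discretization: glucose is sampled and the command updated every 5 min;
u is held constant in between (zero-order hold) while the ODE is
integrated by classical fixed-step RK4. The adaptation law is advanced
once per sample by explicit Euler **including the Δt factor**
(Δw = η·x̃·φ·Δt). With η = 0.5 and typical first-day errors this brings
the weights to the ϑ scale within a few hours — a learning phase of
less than one day — and converges to the continuous-time law as
Δt → 0 (verified by a property test). The tangential projection step on
the norm boundary can overshoot by O(‖Δw‖²); the update renormalizes
onto the ball, which is the standard discrete projection.

Learning-rate schedules (piecewise constant per protocol day):
scratch 0.50 / 0.10 / 0.05 / 0.01 on days 1 / 2–3 / 4–7 / ≥8; hybrid
0 (basal days 1–3) / 0.50 / 0.10 / 0.05 / 0.01 on days 4 / 5–6 / 7 / ≥8.

## Pretraining from basal therapy (hybrid protocol)

During the three basal-therapy days the loop runs at a constant
50 U/day with adaptation frozen (the training happens offline from the
recorded data, so no online learning competes with it), collecting
(x̃, u) pairs at every sample. The regression targets are
d_j = u_j − λ·x̃_j, i.e. the values the network must output for the
control law to replay each recorded infusion. The weights are the
minimum-norm least-squares (pseudoinverse) solution.

That solution can violate the projection bound: representing a
near-constant ≈35 000 μU/min requirement with narrow, non-normalized
Gaussians needs coefficients of norm ≈ 8×10⁴ > ϑ. Rescaling the weight
vector onto the bound would scale the *output* down by the same factor
(to ≈12 500 μU/min) and grossly under-dose at handover. Instead the fit
is shrunk by Tikhonov regularization, using the smallest ridge
parameter whose solution lies on the ϑ-ball (found by bisection on the
SVD form). This preserves the represented policy to ~1% while
satisfying the ‖w(0)‖ ≤ ϑ precondition of the projection law. When the
unconstrained solution already satisfies the bound — e.g. in the
parameter-recovery case — it is returned unchanged.

## Initialization

Initial states are not part of the protocol definition; patients start
at the steady state of a configurable initial glycemia G₀ = 140 mg/dL
(inverting the fixed-point formulas for the implied constant infusion).
This produces the expected brief hyperglycemic transient at controller
start: with w(0) = 0 the command is essentially λ·x̃ ≈ 30 μU/min,
glucose drifts up toward the zero-insulin equilibrium, and the day-1
learning pulls it back as d̂ grows.

## Numerics and problem sizes

* RK4 step: 10⁻³ min for reference fidelity. The package's studies and
  tests run at 10⁻² min, validated by a property test showing the two
  closed-loop trajectories agree to < 0.01 mg/dL over a full day — far
  below CGM resolution. The inner loop is compiled with numba and
  cross-validated stage-for-stage against a pure-Python reference
  (agreement ~10⁻¹² mg/dL).
* Parameters are modulated at the three distinct RK4 stage times; meal
  kernels older than 60·τ_m are dropped in the compiled path (below
  double-precision relevance) so long schedules stay O(active meals).
* Negative state components (round-off only: the exact flow preserves
  non-negativity for u ≥ 0) are clamped to zero and logged.
* Metric conventions: TIR is the closed band [70, 180] mg/dL, so
  TIR+TAR+TBR = 100 exactly; level-2 bands (>250, <54) are included in
  their level-1 totals; SD is population (divide by n); percentiles use
  linear interpolation. Analysis windows exclude the first three days
  (scratch learning phase or basal phase).
* Replicated study sizes: 20 patients × 7 days (both short protocols)
  and 1 patient × 63 days, each over three seeds — the cohort sizes of
  the study design; seed-averaging smooths the meal/cohort sampling
  noise in the headline metrics.

## Known limitations

* The empirical stability checks (bounded weights, error entering a
  neighbourhood of the target) are necessary, not sufficient, evidence
  of the Lyapunov argument; the approximation-error bound ε and optimal
  weights w* have no computable runtime counterpart.
* The learned policy is a static curve d̂(x̃); it compensates meals only
  after glucose rises, so postprandial peaks up to ~220 mg/dL remain —
  consistent with the moderate TAR of a few percent.
* Hybrid handover quality depends on the basal phase actually exciting
  the error axis; a patient held perfectly flat would yield a
  rank-deficient regression (handled, but the policy then extrapolates).
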