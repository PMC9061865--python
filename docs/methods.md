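# Methods

## Release model

Cumulative fractional release is a convex combination of up to three
mechanism kernels, each a monotone map from time to [0, 1]:

* **Initial burst** — drug at or near the particle surface transfers to the
  medium as a first-order interfacial process, `1 − exp(−k_b t)`. The
  assumption is that no drug is dissolved in the medium at t = 0 and that
  the transferable pool is a fixed fraction θ_b of the load.
* **Degradation–relaxation** — hydrolysis of the polyester backbone and
  relaxation of polymer chains releases entrapped drug sigmoidally. The
  kernel is a Prout–Tompkins-type (autocatalytic) logistic in natural-
  exponential form, `1/(1 + exp(−k_r (t − t_max)))`; `t_max` is both the
  maximum-rate point and the 50%-release time of this mechanism. The
  linearized form `ln(x/(1−x))` is linear in t.
* **Fickian diffusion** — radial diffusion out of a homogeneous sphere with
  a constant effective diffusivity, symmetry at the center, sink (zero
  concentration) surface for t > 0, and uniform initial loading. The
  implementation uses the separation-of-variables series
  `1 − (6/π²) Σ n⁻² exp(−n²π² D_e t_sec / r1²)`; an independent implicit
  finite-difference solution of the same boundary-value problem serves as a
  cross-check in the test suite, not as the implementation.

The two-stage (BR) model weighs burst and relaxation as (θ_b, 1 − θ_b); the
three-stage (BRD) model adds diffusion with θ_b + θ_r + θ_d = 1. Weights are
genuine fractions of total release, so every composite curve is bounded and
nondecreasing.

Temperature enters through Arrhenius laws on each rate parameter:
`p(T) = A exp(−Ea/(R T))` with R = 1.9872 cal/(mol K) and T in kelvin
(K = °C + 273.15). `t_max` carries a negative activation energy — it shrinks
as temperature rises.

## Units and geometry

Times are in days at every interface; `k_b`, `k_r` in 1/day; `t_max` in
days; `D_e` in cm²/s, converted internally with 86 400 s/day; particle
radius in cm. The default radius, 7.1×10⁻⁶ cm, is half the 142 nm mean
hydrodynamic diameter of the PEGylated PLGA particles the packaged parameter
tables describe; it is overridable everywhere the diffusion kernel appears
(the effective quantity is D_e/r1², so a different radius rescales fitted
diffusivities). Activation energies are reported in kcal/mol and stored in
cal/mol.

## Numerical choices

* **Series truncation** — terms are added until the next term is below
  `tol` (default 10⁻¹², dimensionless), hard cap 10 000 terms with a
  warning. At t = 0 the kernel returns exactly 0 by special case (the
  untruncated series sums to 1 there, and any truncation would be badly
  wrong). Near t = 0⁺ the early-time law 6√(τ/π) − 3τ (τ = D_e t_sec/r1²)
  is the accuracy check.
* **Clamping** — floating-point spill outside [0, 1] is clipped only within
  10⁻¹²; larger violations raise, since they indicate a bug rather than
  roundoff.
* **Fitting** — bounded trust-region-reflective least squares (unweighted
  residuals) over θ_b ∈ [0,1], rates in (0, 100] 1/day, t_max ∈ (0,
  10·max t]. The residual surface is multimodal, so fits start from a fixed
  lattice: θ_b ∈ {0.2, 0.5, 0.8}, k_b ∈ {0.5, 2, 5}, k_r ∈ {0.05, 0.2, 1},
  t_max ∈ {0.25, 0.5, 0.75}·max(t), extended for the three-stage model with
  θ_r ∈ {0.1, 0.4} and log₁₀D_e ∈ {−19, −17, −15} (486 starts). A
  deterministic two-phase scheme keeps this affordable: every start is
  screened with loose tolerances and a small iteration cap, then the eight
  best candidates are polished at full tolerance; the lowest-cost polished
  solution is returned. Optional ±10% lattice jitter is available (seeded,
  off by default).
* **Constraints** — θ_b + θ_r ≤ 1 is enforced by the substitution θ_b = u,
  θ_r = (1 − u)v, u, v ∈ [0, 1], not by penalties; D_e is optimized as
  log₁₀D_e over [−22, −12]. Parameters within 10⁻⁶ of a box bound are
  flagged `at_bound` in the result.
* **Identifiability** — when a mechanism's weight fits to (near) zero, that
  mechanism's shape parameters are structurally unidentifiable; the weight
  is flagged at-bound and the remaining parameters are still recovered. The
  tabulated 57 °C three-stage set (θ_r ≈ 2.6×10⁻⁹) exercises exactly this
  case.
* **Arrhenius regression** — OLS of ln(value) on 1/T; Ea = −slope·R,
  A = exp(intercept), no log-space bias correction (matching the standard
  linearization procedure). Two modes: `all` (default) uses every
  temperature; `endpoints` uses only the lowest and highest. The endpoints
  mode exists because tabulated constants produced by two-point
  linearizations are reproduced far more closely by it — with the packaged
  three-temperature tables, endpoint regression matches every published
  prefactor to ≤0.3%, while three-point OLS can miss prefactors by large
  factors (the intercept amplifies input rounding exponentially). The
  acceptance script therefore reports endpoint-mode constants.

## Synthetic data

The generator emulates the dialysis release experiment behind the packaged
tables: profiles sampled at 30 evenly spaced times over 0–27 days
(including the t = 0 measurement), default medium 30 mL with 1 mL withdrawn
and replenished per sample, at 37/47/57 °C. Measurement noise is additive
iid Gaussian on the fraction scale, default sd = 0.01, truncated to [0, 1]
with a warning — a declared stand-in, since the source experiments report
triplicates but no error model. The sampling-withdrawal mass balance
`M_k = V·C_k + v·Σ_{i<k} C_i` and its inverse convert between cumulative
released mass and the concentrations an aliquot would actually read.

What the generator does **not** emulate: dialysis-membrane transport lag
(negligible in the free-dye control), autocorrelated or heteroscedastic
measurement error, inter-batch particle variability, and drift of the θ
weights within one experiment. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated noise model, not
robustness to every artifact of real release data.

## Parametric sweep

The temperature sweep evaluates the release surface over (by default)
33–60 °C in 1 °C steps and 0–27 days in 0.1-day steps, with all rate
parameters driven by their Arrhenius laws. How the θ weights vary with
temperature is not determined by any law and is the largest genuinely open
modeling choice; the sweep therefore requires an explicit θ policy — fixed
constants (CLI default: the middle-temperature fitted values) or linear
interpolation of the per-temperature fitted weights. Temperatures outside
the 33–60 °C validity window warn (extrapolation beyond the regressed
range) rather than error.

## Design notes

* The fitting and regression layers are scikit-learn-style estimators
  (`BurstRelaxationModel`, `BurstRelaxationDiffusionModel`,
  `ArrheniusRegression`) so they compose with sklearn pipelines and model
  selection; the module-level functions `fit_br`/`fit_brd`/`fit_arrhenius`
  are thin wrappers.
* The packaged parameter tables retain a published inconsistency: the
  two-stage degradation prefactor appears with two different values in
  different places of the source material. Back-calculation from
  k_r(37 °C) and the activation energy supports 4 321 997.7158 1/day,
  stored as canonical; the alternate is kept, flagged, in
  `tables.KRO_DISCREPANCY`.
* Each temperature is fitted separately and the Arrhenius regression runs
  on the fitted constants afterwards — no simultaneous multi-temperature
  global fit, preserving the two-step structure of the original analysis.
  No confidence intervals or bootstrap are provided.

## Problem sizes

Test and acceptance runs use 30-point profiles, 50 Monte-Carlo replicates
for the noisy-recovery study, 41 time points against the 240-shell
finite-difference oracle, and the full multistart lattices. These sizes were
chosen so the statistical checks are well-resolved while the whole suite
completes in about a minute and a half on one CPU.
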