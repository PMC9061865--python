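# nanorelease

Temperature-dependent, multi-mechanism drug-release kinetics for
biodegradable (PLGA-type) nanoparticles.

Controlled release from hydrolytically degradable nanoparticles is usually
multiphasic: a rapid **initial burst** of surface-proximal drug, a sigmoidal
stage driven by **degradation–relaxation** of the polymer matrix, and slow
**Fickian diffusion** through the particle. This package models cumulative
fractional release M<sub>t</sub>/M<sub>∞</sub> as a convex combination of
those mechanisms, fits the models to experimental release profiles, and
captures how every rate parameter responds to incubation temperature through
Arrhenius laws — so release curves can be predicted across a temperature
range, not just at the temperatures measured. It is aimed at formulation and
drug-delivery scientists analyzing in-vitro dissolution/release data.

## The models

Two-stage burst + relaxation (BR) model, with weight θ<sub>b</sub>:

```
Mt/M∞(t) = θb (1 − e^(−k_b t)) + (1 − θb) / (1 + e^(−k_r (t − t_max)))
```

Three-stage burst + relaxation + diffusion (BRD) model, with
θ<sub>b</sub> + θ<sub>r</sub> + θ<sub>d</sub> = 1:

```
Mt/M∞(t) = θb (1 − e^(−k_b t))
         + θr / (1 + e^(−k_r (t − t_max)))
         + θd [1 − (6/π²) Σ_{n≥1} n⁻² e^(−n²π² D_e t / r1²)]
```

* `k_b` — first-order burst constant (1/day)
* `k_r`, `t_max` — Prout–Tompkins-type relaxation rate (1/day) and its
  50%-release midpoint (days)
* `D_e` — effective diffusivity (cm²/s) in the Crank sphere series, particle
  radius `r1` (default 7.1×10⁻⁶ cm, a 142 nm particle), sink boundary,
  uniform initial loading
* every rate parameter obeys `p(T) = A·exp(−Ea/(R·T))`; a negative Ea
  encodes parameters that shrink with temperature (t_max)

Fitting is bounded trust-region nonlinear least squares from a deterministic
multistart lattice; the θ simplex constraint is enforced by
reparameterization and D<sub>e</sub> is searched in log space. Models are
compared with the adjusted coefficient of determination
`R²adj = 1 − (1 − R²)(n − 1)/(n − p − 1)`.

## Worked example

Fit the two-stage model to a synthetic 30-point, 27-day profile generated
from the tabulated 37 °C parameter set with 1% measurement noise, then
regress the burst constant's temperature dependence:

```python
from nanorelease import (ArrheniusRegression, NoiseSpec, celsius_to_kelvin,
                         fit_br, generate_profile)
from nanorelease.tables import br_params_at

params = br_params_at(37)
profile = generate_profile(params, noise=NoiseSpec(sd=0.01, seed=1),
                           temperature_K=310.15)
result = fit_br(profile)
g = result.params
print(f"theta_b = {g.theta_b:.4f}   k_b = {g.k_b:.4f} 1/day")
print(f"k_r     = {g.k_r:.4f}   t_max = {g.t_max:.4f} days")
print(f"R2 = {result.r_squared:.4f}   adjusted R2 = {result.r_squared_adjusted:.4f}")

reg = ArrheniusRegression(mode="endpoints").fit(
    celsius_to_kelvin([37, 47, 57]), [1.8053, 2.2306, 2.7337])
print(f"Ea = {reg.activation_energy_kcal_:.4f} kcal/mol, A = {reg.prefactor_:.4f} 1/day")
```

prints

```
theta_b = 0.5537   k_b = 1.8761 1/day
k_r     = 0.1070   t_max = 20.2730 days
R2 = 0.9971   adjusted R2 = 0.9966
Ea = 4.2215 kcal/mol, A = 1703.0412 1/day
```

The fit recovers the generating parameters (θb=0.5567, k_b=1.8053,
k_r=0.1109, t_max=20.1849) to within a few percent at this noise level, and
the regression of the three burst constants against reciprocal absolute
temperature yields the burst activation energy (≈4.22 kcal/mol) and
prefactor.

The same operations are available from a shell:

```sh
nanorelease synth --theta-b 0.5567 --k-b 1.8053 --k-r 0.1109 --t-max 20.1849 \
    --sd 0.01 --seed 1 --output profile.csv
nanorelease fit profile.csv --model br --output report.csv
nanorelease sweep --model br --output surface.csv   # 33–60 °C release surface
```

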