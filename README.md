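# fretkit

Analysis toolkit for **photoisomerizable multichromophoric systems**: tethered
dye pairs (e.g. two DCM-type donor-π-acceptor chromophores on a flexible
linker) that exchange excitation energy by FRET while each unit can
photoswitch between an emissive *E* form and a dark *Z* form. The package is
aimed at photophysicists and molecular modellers who want to go from
chromophore-pair geometry trajectories and spectra to transfer efficiencies,
conformational kinetics, photoswitching kinetics and fluorescence-decay
parameters with testable, reproducible code.

It implements, as one pipeline with synthetic ground truth for every stage:

- **Förster theory** — spectral overlap J(λ) = ∫F̄_D(λ)ε_A(λ)λ⁴dλ, Förster
  radius R0⁶ = 9000 ln10 κ²Φ_D⁰J / (128π⁵N_A n⁴), orientation factor
  κ² = (sinθ_D sinθ_A cosφ − 2cosθ_D cosθ_A)² computed equivalently from
  angles or dipole vectors, efficiency E = 1/(1 + (R_DA/R0)⁶), fundamental and
  homo-FRET-depolarized anisotropy, and Z-isomer absorptivity reconstruction
  from photostationary spectra.
- **Trajectory FRET** — per-frame pair geometry from geometry tables or
  atomistic coordinates, instantaneous E(t) with per-frame (dynamic) κ²,
  efficiency histograms, and distance-stratified mean efficiencies.
- **Markov state models** — tICA, k-means microstates, (reversible) MSM
  estimation with implied-timescale and Chapman–Kolmogorov validation, PCCA+
  metastable lumping, transition-path-theory fluxes with pathway percentages,
  and free-energy landscapes F = −k_BT ln P.
- **Photoisomerization kinetics** — per-photon excitation fates via an exact
  absorbing Markov chain over chromophore units (homo-hopping, hetero-
  quenching), species-level kinetics on the 2ⁿ isomer configurations,
  photostationary states and absorbance traces under irradiation schedules.
- **TCSPC global analysis** — reconvolution simulation and fitting of decay
  histograms with shared lifetimes across curves, Poisson-weighted χ²_R and
  intensity fractions f_i = a_iτ_i/Σa_jτ_j.
- **Synthetic dynamics** — a hidden-Markov generator of metastable tether
  conformations with planted state paths, rates and pathways, used as ground
  truth throughout the test suite.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from fretkit import (ForsterPairParams, overlap_integral, forster_radius,
                     fret_trace, stratify_by_distance, geometry_features)
from fretkit.synthetic import dcm_like_spectra, preset_scenario, simulate_scenario
from fretkit import msm as M

# Förster parameters from spectra (synthetic DCM-like bands here)
absorption, emission = dcm_like_spectra()
J = overlap_integral(emission, absorption)
R0 = forster_radius(J, kappa2=2/3, phiD0=0.25, n=1.407)
print(f"J  = {J:.3e} nm^4 M^-1 cm^-1")   # J  = 1.420e+14 nm^4 M^-1 cm^-1
print(f"R0 = {R0:.2f} nm")               # R0 = 2.85 nm

# instantaneous FRET along a synthetic folded/unfolded tether trajectory,
# using a literature-scale overlap integral for a hetero (E/Z) pair
params = ForsterPairParams(J=1.03e13, phiD0=0.25, n=1.407)   # dynamic kappa2
frames, truth = simulate_scenario(preset_scenario("EZ-like"), 40000, seed=0)
trace = fret_trace(frames, params)
print(f"mean E_FRET = {100 * trace.mean_efficiency:.1f}%")
strat = stratify_by_distance(trace)
for lab, n, m in zip(strat.labels, strat.counts, strat.mean_efficiency):
    print(f"  {lab:>16}: {n:5d} frames, mean E = {100 * m:.1f}%")
```

Output:

```
J  = 1.420e+14 nm^4 M^-1 cm^-1
R0 = 2.85 nm
mean E_FRET = 59.7%
         R_DA <= 1: 16817 frames, mean E = 97.2%
      1 < R_DA < 2:  5980 frames, mean E = 86.8%
         R_DA >= 2: 17203 frames, mean E = 13.5%
```

The trace mean is a mixture of a compact folded state (near-unit transfer)
and an extended state where the distance, and at larger separations the
orientation factor, suppress transfer — the characteristic bimodal efficiency
distribution of a flexible tether.

Conformational kinetics of the six-well scenario through the full MSM
pipeline:

```python
spec = preset_scenario("six-well")
frames, truth = simulate_scenario(spec, 40000, seed=2)
X = geometry_features(frames)                       # (R_DA, theta_D, theta_A)
Y = M.tica_fit(X, lag=25).transform(X, n_components=3, scale="kinetic")
dtraj, _ = M.cluster_kmeans(Y, 200, seed=0)
model = M.estimate_msm(dtraj, lag=25, reversible=True)
part = M.pcca(model, 6)
print(f"slowest implied timescale: {model.timescales(1)[0] * spec.dt / 1000:.2f} ns")
# slowest implied timescale: 1.10 ns   (planted: 1.19 ns)
```

Transition-path analysis (`M.coarse_fluxes`) on the same model recovers the
planted dominant folding pathway A → S3 → S4 → B as the top flux path (52% of
the reactive flux at this trajectory length).

A command line mirrors the library: `fretkit forster`, `fretkit fret-trace`,
`fretkit msm`, `fretkit synth`, `fretkit photokin`, `fretkit tcspc`
(see `--help` on each).

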