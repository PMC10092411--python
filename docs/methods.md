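# Methods

This note documents the models implemented in `fretkit`, the choices made
where the design was genuinely open, and what the synthetic ground truth does
and does not establish about real data.

## Förster theory core (`fretkit.forster`, `fretkit.spectra`)

The transfer efficiency of a donor/acceptor pair at distance R_DA is

    E = 1 / (1 + (R_DA / R0)^6),

with the Förster radius from

    R0^6 = 9000 ln(10) κ² Φ_D⁰ J / (128 π⁵ N_A n⁴).

The overlap integral J = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ uses the donor emission
area-normalized over its own support (∫ F̄_D dλ = 1), so that J carries units
of nm⁴ M⁻¹ cm⁻¹ and R0 comes out in nm. Quadrature is trapezoidal on the
union of the two wavelength grids restricted to the common window, with
linear interpolation; disjoint supports give J = 0 rather than an error.
The closed form is evaluated from the fundamental constants; with
J = 1.03×10¹³ nm⁴ M⁻¹ cm⁻¹, κ² = 2/3, Φ_D⁰ = 0.25 and n = 1.407 it gives
R0 ≈ 1.84 nm, matching the familiar Å-units constant 8.79×10⁻⁵ to 0.2%
(the small difference is the precision of that rounded constant).

The orientation factor is computed two ways that are held to agree to 1e-10:
from the spherical angles, κ² = (sinθ_D sinθ_A cosφ − 2 cosθ_D cosθ_A)², and
from the vectors, κ = μ̂_D·μ̂_A − 3(μ̂_D·R̂)(μ̂_A·R̂). The dihedral φ is
right-handed about R̂; when a dipole is parallel to the separation vector the
dihedral is undefined and set to 0 (κ² is then insensitive to it). The
isotropic dynamic average ⟨κ²⟩ = 2/3 is used as a Monte-Carlo check, not as a
modelling default: trajectory efficiencies use the per-frame κ²(t) unless a
fixed value is requested.

Steady-state anisotropy: r0 = 0.4·(3cos²β − 1)/2 for one-photon excitation
with inter-dipole angle β (β = 15° gives 0.36). Homo-transfer depolarization
is modelled as a two-population mixture, r̄ = (1−p)·r0 + p·r_et with
r_et = 0.016 by default (post-hop emission from a nearly randomly oriented
chromophore); this linear model is the minimal quantitative form of the
depolarization argument and is trivially invertible for the hop
probability p.

The Z-isomer absorptivity reconstruction inverts Beer–Lambert additivity at a
photostationary state with known conversion fraction α_Z; negative values
(measurement noise) are clipped to zero with a warning rather than raised,
since small negatives are routine in practice.

## Trajectory FRET (`fretkit.trajectory`)

Input is either the whitespace geometry-table dialect (header-declared units:
nm, ps; gzip accepted) or atomistic coordinates with chromophore definitions,
in which case the reference point is the atom nearest the chromophore's mass
center and the dipole direction comes from a configured atom pair. Per frame
the pipeline computes R_DA, the two polar angles, the dihedral, κ², a
per-frame R0 (dynamic-κ² policy by default), and E(t). All frames carry equal
weight (uniform sampling cadence assumed).

Distance stratification uses closed outer bounds (R_DA ≤ e₁ and R_DA ≥ e₂
belong to the outer classes; default edges 1 and 2 nm); empty classes report
NaN means, never 0, and count-weighted class means must reproduce the global
mean to 1e-9 (tested).

## Synthetic metastable dynamics (`fretkit.synthetic`)

The generator emulates the statistical structure of a flexible two-chromophore
tether: a hidden Markov chain over metastable conformational states, each
emitting R_DA from a log-normal (median, log-σ) and dipole angles from
reflected/wrapped Gaussians about state means. Geometry frames are constructed
to realize the sampled (R_DA, θ_D, θ_A, φ) exactly: donor at the origin,
acceptor along a random direction, dipoles built in the frame of that
direction. Default cadence is 5 ps/frame and the reference trajectory length
is 40 000 frames (200 ns).

Presets:

- `EZ-like` / `EE-like` / `two-state-minimal`: folded state (R median 0.9 nm,
  σ_log 0.15) vs unfolded (2.5 nm, 0.12) with folded occupancies 0.55 / 0.80 /
  0.70 and escape probability 0.004 per step from the folded state. The
  folded-state emission puts >95% of frames below 1.3 nm.
- `six-well`: six states on a folding ladder (R medians 2.6 → 0.8 nm, dipole
  angles sweeping 0.35 → 2.8 rad, σ_log 0.04, angular σ 0.08 rad). The jump
  matrix is built from symmetric edge conductances over target occupancies
  (0.20, 0.10, 0.15, 0.20, 0.20, 0.15), which makes it reversible by
  construction. Three parallel branches lead from the unfolded source A
  through intermediates to S4 and on to the compact sink B; the S3 branch
  carries the largest conductance, making A→S3→S4→B the planted dominant
  pathway (~71% of the reactive flux by transition-path theory on the
  planted matrix, vs ~19% and ~10% for the S2 and S1 branches). Escape
  probabilities ~1–1.5% per step give dwell times of 0.3–1.2 ns at 5 ps per
  frame, i.e. relaxation timescales (slowest ≈ 1.2 ns) in the regime where a
  ~0.1 ns-lag Markov model is appropriate.

Intra-state fluctuations are i.i.d. by default so that closed-form and
Monte-Carlo oracles are exact; an optional OU smoothing with configurable
correlation time correlates the underlying standard-normal deviates within
each dwell (resetting at state changes), adding realistic intra-state memory
while preserving every per-state marginal exactly.

What the generator does *not* reproduce: continuous (non-metastable) barrier
crossings, state-dependent emission overlap and slow intra-state modes of real
force-field dynamics, solvent memory, and any coupling between distance and
orientation within a state. Passing the recovery tests therefore shows the
estimators are correct on data satisfying their assumptions, not that a real
trajectory of this length identifies six states.

## Markov state models (`fretkit.msm`)

- **tICA** solves the symmetrized generalized eigenproblem C(τ)v = λC(0)v on
  mean-free features, ε = 1e-10 regularization on C(0), null directions
  dropped with a warning. The transform offers whitened output and a
  "kinetic" scaling that multiplies each component by its eigenvalue.
  Microstate clustering uses the kinetic scaling: with whitening alone,
  noise-only components receive unit variance and Euclidean k-means produces
  impure microstates even for well-separated states (observed to bias implied
  timescales downward by tens of percent on planted data).
- **Clustering**: k-means (k-means++ init, fixed seed, single init) with
  k = 200 by default.
- **MSM estimation**: sliding-window counts, restriction to the largest
  strongly connected set (warning with retained fraction), row-normalized
  maximum likelihood by default, detailed-balance MLE (fixed-point iteration,
  tol 1e-10) as the reversible option. Implied timescales −τ/ln|λ|; non-
  positive eigenvalues report NaN. The Chapman–Kolmogorov test compares
  metastable-set self-transition probabilities of [T(τ)]^k against re-
  estimated T(kτ).
- **PCCA+** (Röblitz–Weber inner-simplex): top-m right eigenvectors, vertex
  search, membership transform clipped to the simplex. The pipeline feeds it
  reversible estimates: sampled non-reversible matrices can carry complex
  eigenvalue pairs in the top-m block, which destabilizes the simplex
  construction (the code falls back to real parts with a warning, but the
  lumping quality degrades).
- **TPT**: forward committor from the linear system, backward committor from
  the time-reversed chain, gross flux f_ij = π_i q⁻_i T_ij q⁺_j, net flux as
  positive part, coarse-grained by summing gross flux over metastable sets
  before netting. Pathways by iterative max-bottleneck (widest-path) removal;
  a pathway's percentage is its flux over the total reactive flux. Total flux
  is cut-invariant to 1e-8 (tested on ≤6-state models).
- **FEL**: F = −ln P on a 2-D histogram, in k_BT units, empty bins +∞ (no
  fabricated barriers), minimum shifted to 0.
- **Cosine content** of PCA projections flags diffusion-like sampling;
  values near 1 mean the component is indistinguishable from a random walk.
  The discriminating power grows with feature dimension (a 2-D walk gives
  highly variable values; ≥20-D walks give c₁ > 0.9 reliably).

## Photokinetics (`fretkit.photokinetics`)

The mechanism is formalized in two layers. Per photon, an absorbing Markov
chain over the chromophore units of one molecule: at each visited unit the
excitation transfers to neighbour v with probability E_uv (homo E→E or hetero
E→Z; the dark Z form does not transfer), isomerizes the resident unit with
the remaining probability times that isomer's quantum yield, or decays. The
chain is solved exactly with the fundamental matrix; outcome probabilities
sum to 1 to 1e-12. A consequence worth noting: homo-hopping among identical E
units redistributes *where* isomerization happens but cannot change the total
isomerization yield — quenching requires the hetero channel.

At the species level, first-order kinetics on the 2ⁿ isomer configurations
(n ≤ 3): unit u of a species is excited at rate flux·ε_isomer(u)(λ) and each
excitation's fate maps the species to one with one unit flipped. The
generator's columns sum to zero (molecule conservation, held to 1e-9 relative
through any irradiation schedule); with no FRET the n-unit system factorizes
exactly into independent single units (tested to 1e-8). Schedules are
propagated segment-wise with the matrix exponential; photostationary states
come from the generator's null space. EZ/ZE merging is a reporting view; the
dynamics runs on the full configuration space.

The demo parameter set (`dcm_like_params`) places the visible-light PSS in
the E-rich regime (Φ_EZ = 0.05, Φ_ZE = 0.35, Z band blue-shifted to 420 nm
but retaining absorptivity at 457–485 nm). In that regime increasing the
hetero-transfer probability raises A_PSS-485/A_PSS-335 toward 1 *and*
shortens the time to reach the PSS, reproducing the measured
monomer < dimer < trimer ordering. The model also shows this is
regime-dependent: with negligible Z absorptivity at the irradiation
wavelength the PSS is Z-rich and hetero transfer *slows* equilibration, since
the final E→Z conversion step is throttled — a useful falsifiable prediction
rather than a defect. Excited-state absorption, bleaching, triplets and
thermal back-isomerization are neglected (clean two-state photoswitches).

## TCSPC global analysis (`fretkit.tcspc`)

Decays are multi-exponential models discretely convolved with the normalized
IRF, scaled to the peak count, plus a constant background, with channel-wise
Poisson noise. The fitter minimizes the Poisson-weighted residual
(counts − model)²/max(counts, 1) with lifetimes shared across curves and
per-curve amplitudes, scale and background solved by non-negative least
squares at every lifetime evaluation (variable projection). Lifetimes are
searched in log-space with 5 starts spread ×3 / ÷3 (then randomized) around a
moment-based initial estimate. χ²_R uses dof = channels(counts ≥ 1) − free
parameters; lifetimes closer than a 1.2 ratio trigger a degeneracy warning.
Intensity fractions f_i = a_iτ_i/Σa_jτ_j; report-time rounding is two
decimals and never enters computation.

Default synthetic-study conditions: 1024 channels at 12 ps, 60 ps fwhm
Gaussian IRF, 10⁴ peak counts, background 2 counts. Under these conditions a
single-curve biexponential fit recovers the dominant lifetime within ±0.03 ns
in ≥90% of seeds; the tri-exponential configuration with a 3–7% amplitude
third component reaches the same precision only in a *global* fit over a
series of curves sharing lifetimes — which is how such series are analyzed in
practice, and why global analysis is the default recommendation.

## Problem sizes

Test and acceptance runs use 40 000-frame trajectories (100 000 for the
timescale-recovery check, where the slowest planted mode of ~240 frames
otherwise leaves too few transitions for a ±15% comparison), 10⁶-sample
Monte-Carlo averages, 10⁶-step chains for transition-matrix recovery, and
50-seed decay-recovery studies. These sizes keep every sampling check at ≥3σ
resolution while the full suite runs in about a minute.
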