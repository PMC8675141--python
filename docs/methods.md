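# Methods

## The excitonic model

`excitonsh` describes a system of `N_C` chromophores in the Frenkel
picture.  The electronic basis is the global ground state `|gs>` plus
quasi-diabatic states `|ai>` in which chromophore `a` carries its
`i`-th localized excitation while every other chromophore is in its
ground state; each `|ai>` is conceptually the antisymmetrized product
of monomer wavefunctions built from mutually orthogonal orbital sets,
so the basis is orthonormal and excitations on the *same* chromophore
never couple.  The Hamiltonian is

    H = E_gs |gs><gs| + Σ_ai (E_gs + ΔE_ai) |ai><ai| + Σ_{ai≠bj} V_ai,bj |ai><bj|

with site energies `ΔE_ai = E_i^(a) − E_0^(a)` (vertical monomer
excitation energies) and Coulomb-dominated couplings `V_ai,bj`.  The
ground state is an eigenstate by construction; diagonalizing the
excitonic block gives adiabatic states `|K> = Σ C_ai,K |ai>` whose
energies and (frozen-coefficient, Hellmann–Feynman) gradients

    ∇E_K = ∇E_gs + Σ_ai C²_ai,K ∇ΔE_ai + Σ_{ai≠bj} C_ai,K C_bj,K ∇V_ai,bj

drive the nuclear dynamics.

When the chromophores embed each other as a molecular-mechanics
environment, the ground-state energy removes the double-counted MM
content as `E_gs = Σ_a E_0^(a) − (N_C − 1) E_MM`, where each per-site
energy `E_0^(a)` contains the MM energies of the other monomers, their
mutual MM interactions, and the QM/MM interaction of site `a` with each
of them.  For two chromophores this reduces to
`E(QM,a) + E(QM,b) + E(QM/MM,ab) + E(QM/MM,ba) − E(MM,ab)`; the
`EnergyLedger` type keeps the decomposition explicit and the identity
is tested term by term.

## Couplings

Transition densities are modeled as sums of spherical Gaussians at
atomic centers — the analytic analog of the one-center AO-pair
structure that survives in neglect-of-differential-overlap schemes, in
which the exchange contribution to the coupling vanishes identically
(it is therefore omitted, not approximated).  Three schemes are
implemented behind one interface:

- **EC (exact Coulomb)** — the closed-form double sum over Gaussian
  pairs, `Σ w_p w_q erf(r/(√2 s))/r` with `s² = σ_p² + σ_q²`.
  Validated against 3D numerical quadrature of `ρ_A·φ_B` to 1e-8
  hartree.
- **TC (transition charges)** — atomic monopoles fitted to the
  cloud's electrostatic potential (TrESP): constrained linear least
  squares on a merged-sphere grid (4 shells at 1.4/1.6/1.8/2.0 × a
  3 bohr exclusion radius, ≈1 point/bohr²), total charge pinned to
  zero, dipole constraint optional (off by default; with it on, at
  least five non-collinear atoms are required for feasibility).
  Couplings are then plain Coulomb sums.
- **Point dipole** — the far-field limit, kept as an asymptotic
  check.

Coupling gradients differentiate the Coulomb sums at frozen
charges/weights ("static" gradients).  The TC scheme converges to the
EC value from above as the separation grows; the relative deviation
falls below 1% once the clouds stop interpenetrating, which the
`distance_scan` table reports together with an `overlapping` flag.

## Model chromophores

The synthetic backend replaces a quantum-chemistry engine with
azobenzene-like torsional units that make every other module testable
without any electronic-structure package.  Each site has one angle θ
and three *diabatic* reference curves (hartree):

    D_0(θ) = (W/2)(1 − cos 2θ) + (Δ_cis/2)(1 + cos θ)     W = 0.06, Δ_cis = 0.02
    D_i(θ) = A_i − (B_i/2)(1 − cos 2θ)                    A_1 = 0.10, B_1 = 0.05
                                                          A_2 = 0.16, B_2 = 0.04

The ground curve has a trans well at θ = π (energy 0) and a cis well at
θ = 0 (energy Δ_cis); the first excited curve funnels toward θ = π/2
and crosses the ground curve at θ ≈ 1.96 and ≈ 1.08 (and mirror
angles).  The states the site actually exports are monomer *adiabats*:
each adjacent diabat pair is coupled by a seam-localized interaction
`v(θ) = V exp(−ΔD²/(2(3V)²))` with `V = (c/2)|Δslope|` at the seam, so
the avoided crossing has gap `2V` and angular width equal to the
funnel-softness parameter `c` (default 0.05 rad).  Energies are the
smooth two-level branch functions, gradients their exact derivatives,
and interstate overlaps come from the same model's mixing angles
`α(θ) = ½ atan2(2v, ΔD)` through an orthogonal character frame
`U(θ)`; the overlap block between successive geometries is
`S = U(θ_t)ᵀ U(θ_{t+Δt})`, which makes overlaps compose exactly and
places the character swap exactly at the seam.  Because energies,
gradients and overlaps all derive from one analytic model, the
adiabatic surfaces are smooth everywhere and the integrator conserves
energy through the funnel.

Choosing `c` trades transfer efficiency against recrossing: the seam
behaves like a Landau–Zener crossing with `V_eff = (c/2)|Δslope|`, so
larger `c` accelerates both decay *and* re-excitation when the hot
ground-state rotor re-visits the seam (the model has no bath to carry
the photon energy away).  `c = 0.05` lets a thermal-trans ensemble
excited to the lower manifold decay with a delay of tens of fs and an
overall lifetime well under 2 ps.

Transition densities are ±q point pairs (or Gaussian pairs for EC) at
the ends of a rigid arm (5 bohr) perpendicular to the stack axis:
`q(θ) = q₀|sin(θ/2)|` (q₀ = 0.46 e) for the bright, strongly coupled
(ππ*-like) manifold and the constant `0.05·q₀` for the dark, weakly
coupled (nπ*-like) manifold.  At the default 6 Å stack the
bright–bright coupling is ≈86 meV and the dark–dark coupling
≈0.2 meV, so strong and weak excitons coexist as in stacked
bichromophoric photoswitches, and the parallel-dipole (H-aggregate)
geometry puts almost all oscillator strength in the upper Davydov
component.  The default reduced torsional inertia is 1.0e5 m_e·bohr²
(the order of magnitude of a CNNC torsion), which makes 0.1 fs
integration comfortably stable.

Two deliberate simplifications: the torsion dependence of the
transition charges is fully analytic, so the model's default coupling
gradients include the dq/dθ term ("full" mode) and the dynamics is
exactly conservative; the "static" mode (frozen charges) reproduces
the approximation used with fitted charges in production codes.  And
the bright state is funnel-shallow: a bright diabat deep enough to
cross the nπ*-like diabat would necessarily also dive below the ground
diabat (the nπ* funnel minimum lies below the ground curve's
perpendicular maximum), recreating uncoupled surface crossings.  The
model dimer therefore demonstrates excitation-energy transfer and
Davydov physics in the strong manifold and complete photochemistry in
the weak manifold, but has no within-site ππ*→nπ* conversion channel;
sequential-chain kinetics is exercised on synthetic traces.

A separate `LinearCrossingSystem` provides two one-exciton sites whose
site energies cross linearly with a constant coupling — the minimal
arena for trivial-crossing and Landau–Zener tests.

## Surface hopping with local diabatization

Nuclei follow one adiabatic surface by velocity Verlet; the electronic
amplitudes advance one step per nuclear step (Δt = 0.1 fs default for
both).  Each step assembles the excitonic-basis overlap matrix from
the per-chromophore blocks — the overlap of two product states
factorizes into one non-ground factor per involved chromophore times
`S_00^(c)` over the uninvolved ones — transforms it by `C(t)` on the
bra side and `C(t+Δt)` on the ket side, symmetrically orthogonalizes
it (`T = S(SᵀS)^(−1/2)` by SVD; the closest orthogonal matrix in the
Frobenius norm), and propagates

    c(t+Δt) = Tᵀ · diag(exp(−i Ē_K Δt)) · c(t),   Ē = (E(t)+E(t+Δt))/2,

which is exactly norm-preserving.  Because the propagation follows
overlaps rather than nonadiabatic coupling vectors, trivial (unavoided)
crossings need no special care: the amplitudes follow the diabatic
character and the fewest-switches machinery hops the active state with
probability approaching one.  New adiabatic coefficient columns are
sign-aligned to make the diagonal of S positive, which keeps the
assembled overlap well-conditioned for the orthogonalization.

Hopping probabilities realize fewest switches as population-flux
apportionment: the total probability of leaving the active state
equals its fractional population loss over the step (zero if the
population grew) and is shared among the other states in proportion to
their population gains.  Accepted hops rescale all velocities by a
common factor to conserve total energy — no nonadiabatic-coupling
direction exists in this scheme — and energetically forbidden hops are
frustrated, leaving velocities unchanged (no reversal).  Decoherence
uses an overlap-based correction (ODC): per non-active state an
auxiliary trajectory propagates on that state's surface (force taken
at the main geometry) from the point where the state last acquired
amplitude; the amplitude is damped by the ratio of frozen-Gaussian
overlaps (width σ = 1 au per coordinate, damping only) and collapsed
to zero when the overlap falls below S_min = 0.005, the active state
absorbing the norm defect.  Trajectories stop after ≥100 fs
continuously on the ground state, and a total-energy drift between
hops above 1e-3 hartree flags a trajectory for exclusion from
ensemble statistics.

Initial conditions come from ground-state thermal trajectories
(Andersen thermostat by default: per-coordinate Maxwell resampling at
a set collision rate; a global-rescale stochastic thermostat is
provided as the alternative).  A snapshot/state pair is selectable
when its vertical excitation energy lies in the requested window, and
acceptance is proportional to `|μ_0K|²` normalized to the ensemble
maximum, so bright states are populated according to their radiative
transition probability and dark states are never selected.

Randomness is handled by one seed per run; per-trajectory generators
are spawned from it and logged, making every output bit-reproducible
from (config, seed).

## Analysis

Excitonic (quasi-diabatic) populations use the trajectory-count
estimator: at each time the active state contributes its squared
coefficients `|C_ai,K|²` to the label populations and ground-state
trajectories contribute to the ground label; finished trajectories are
held in their final state when grids are ragged.  EET events are
counted as direct dominant-label switches between a chosen label pair
(dominance = argmax `|C_ai,K|²`, ties to the lowest label).
Quantum yields classify final geometries (default: any torsion within
π/4 of 0 mod 2π is cis photoproduct) and report the binomial
uncertainty `σ_Φ = √(Φ(1−Φ)/N)` over the non-excluded count.  Decay
kinetics follow a first-order irreversible model: upper population
`exp(−t/τ₂)`, lower population a delayed exponential
`exp(−(t−t₀)/τ̃₁)` (the delay reflects the twisting needed to reach
the seam), overall lifetime `τ₁ = t₀ + τ̃₁`; the sequential mode fits
the upper trace and the corresponding chain-with-delay closed form
jointly.  Absorption spectra accumulate oscillator strengths
`f_K = (2/3)ΔE_K|μ_K|²` per adiabatic state from snapshot ensembles
with Gaussian broadening; the total is exactly the per-state sum.

## Numerical choices

- Units: hartree/bohr/au internally; eV, Å, fs at all interfaces.
- Eigenvalues ascending; eigenvector signs fixed by making the
  largest-magnitude component positive (reproducible label maps);
  degenerate uncoupled blocks are accepted and only invariants are
  guaranteed there.
- Löwdin orthogonalization aborts a trajectory when the smallest
  singular value of S drops below 1e-8 (states leaving the propagated
  space).
- Kinetic fits run Levenberg–Marquardt on |parameters| with data-scale
  initial guesses; non-convergence raises with the guess reported.
- The Gaussian-Coulomb kernel uses the analytic r→0 limit `√(2/π)/s`,
  so coincident centers are well-defined for clouds; point-charge
  coincidence raises an error naming both chromophores.

## What the tests do and do not show

The synthetic backend emulates torsional photoisomerization with
coexisting weak and strong exciton manifolds, trivial crossings, and
thermally sampled initial conditions.  It does not emulate multi-mode
vibrational energy flow (each chromophore has one coordinate and there
is no bath, so a hot photoproduct keeps rotating), triplet-pair or
charge-transfer states, exchange contributions to the coupling, or any
specific molecule's energetics.  Green tests therefore certify the
machinery — Hamiltonian assembly, coupling algebra and gradients,
overlap factorization, norm-conserving propagation, hopping and
decoherence bookkeeping, estimator and fit correctness — on a model
where every reference value is analytic or independently recomputed,
not the quantitative photophysics of any real compound.

## Problem sizes used in the shipped checks

Worked examples are instantaneous (a 2×2 diagonalization and a
one-dimensional fit on a 3001-point grid).  Property checks use 100
trajectories for trivial-crossing robustness, 200 for the
Landau–Zener comparison, a 1 ps single trajectory for energy
conservation, 10⁴–10⁵ draws for sampling statistics, and a 30 ps
thermostat run for equipartition; the full suite completes in under
two minutes on one CPU.
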