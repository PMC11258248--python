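# Methods

This note documents the models, algorithms and numerical choices behind
`polyhop`, the assumptions they carry, and what the package's tests do and
do not demonstrate.

## Units and constants

Energies in eV, lengths in Å, times in fs, masses in amu. Angular
(torsion-like) coordinates are in radians and carry a moment of inertia in
amu·Å², so one kinetic-energy conversion covers both coordinate types
(1 amu·Å²/fs² = 103.642697 eV). ħ = 0.6582119569 eV·fs. Couplings are
evaluated in atomic units and reported in cm⁻¹ with
1 Hartree = 219474.6314 cm⁻¹ and 1 bohr = 0.529177211 Å. Photon
energy↔wavelength uses λ[nm] = 1239.8419/E[eV]. Times are stored in fs
internally; picoseconds appear only at reporting boundaries.

## Model Hamiltonians

Dynamics runs on analytic diabatic potential matrices, diagonalized exactly
at every geometry. Eigenvector phases follow a deterministic convention
(largest-magnitude component positive), so repeated evaluations are bitwise
identical; along a trajectory, continuity with the previous step's
eigenvectors overrides the static convention. Adiabatic gradients are
Hellmann–Feynman contractions of the analytic diabatic gradients.

Two model families ship with the package:

- **1-D two-state scattering models** (`AvoidedCrossing1D`): the classic
  single-avoided-crossing form V₁₁ = A(1 − e^(−Bx)) (odd-symmetrized),
  V₂₂ = −V₁₁, V₁₂ = C e^(−Dx²). The defaults are the standard literature
  parameters (A = 0.01 Ha, B = 1.6 bohr⁻¹, C = 0.005 Ha, D = 1 bohr⁻²,
  m = 2000 mₑ) converted to package units. Used for engine validation
  against exact quantum dynamics.
- **Carotenoid surrogate** (`CarotenoidSurrogate`): three (configurable)
  states over two reduced coordinates — BLA x (Å, mass 10 amu) and a lumenal
  torsion φ (rad, inertia 50 amu·Å²). Diagonals are displaced harmonic
  wells: the ground state has a positive BLA minimum (+0.06 Å, alternating
  bonds, stiff planar torsion), S₁ sits near zero BLA with a soft torsion
  (weakened C=C bonds), S₂ is displaced to larger BLA so that a trajectory
  photoexcited at the Franck–Condon point crosses the S₂/S₁ seam within tens
  of fs (diabatic coupling 0.03 eV gives a Landau–Zener hop probability of
  order 0.2 per passage — femtosecond internal conversion over a few
  vibrational periods). The S₀–S₁ coupling is a logistic switch in BLA
  (amplitude 0.10 eV, center −0.03 Å, width 0.012 Å) plus a 0.05·sin²φ
  torsional term: the two decay channels of carotenoid photophysics,
  inverted bond alternation and backbone distortion. The s-cis
  parameterization shifts the torsional baseline off planarity
  (`conformer_offset`, 0.25 rad) and stiffens the torsion — narrow
  distributions — while s-trans is planar but soft. The S₀–S₁ adiabatic gap
  decreases monotonically as BLA goes negative *up to* the avoided-crossing
  seam (asserted on BLA ∈ [−0.12, 0] Å at torsions up to 0.4 rad); past the
  seam the gap is coupling-dominated and turns around, which is physically
  expected and deliberately outside the asserted grid.

Masses default to ~10 amu for BLA-like and ~50 amu·Å² for torsion-like
coordinates, putting vibrational periods in the 20–600 fs range so that
femtosecond-to-picosecond dynamics emerges at 300 K energy scales. Model
definitions round-trip through a versioned YAML schema
(`polyhop-model/1`: model name, parameters).

## The surface-hopping engine

Nuclei follow velocity-Verlet on the active adiabatic surface (NVE; no
thermostat during production). Electronic amplitudes are integrated in a
**locally diabatic representation**: the adiabatic basis at time t defines
a frozen basis for the step; the Hamiltonian interpolates linearly from
diag(E(t)) to T·diag(E(t+dt))·Tᵀ, where T is the Löwdin-orthogonalized
matrix of eigenvector overlaps between the two geometries; each electronic
substep applies the exact exponential of its midpoint Hamiltonian (exactly
unitary — the coefficient norm is conserved to ~1e-12 per step regardless
of substep count; substeps control accuracy, not stability). This avoids
nonadiabatic coupling vectors entirely, which is also why velocity
rescaling at hops is isotropic along the full velocity vector rather than
along a coupling direction. A near-singular overlap (too large a nuclear
step through a seam) triggers a warning and proceeds with the renormalized
factors.

Hop probabilities follow the fewest-switches prescription in its
locally-diabatic form: the net loss of active-state population over the
step, 1 − ρ_aa(t+dt)/ρ_aa(t), is distributed over target states in
proportion to their positive entries in the population-transfer
decomposition M[j,k] = Re[c_j*(t+dt) P_jk c_k(t)] of the full step
propagator P (rows of M sum to the new populations). In a two-state system
this reduces exactly to "hop probability = fractional population loss",
which is how the engine's hop probabilities are oracle-checked. Negative
contributions are zeroed and the vector is clipped to sum ≤ 1.

At an accepted hop the velocities are rescaled by √(1 − ΔE/KE) so total
energy is exactly conserved; an uphill hop with insufficient kinetic energy
is frustrated (velocities kept by default, or reversed under the `reverse`
policy) and never produces NaN. Energy drift between hops beyond a
tolerance (default 1e-3 eV) aborts the trajectory with the offending frame
index.

**Decoherence.** Two corrections are implemented. The *energy-based*
scheme damps non-active amplitudes with the standard time constant
τ_k = ħ/|ΔE_k| · (1 + C/E_kin), C = 0.1 Hartree by default. The *overlap*
scheme (default) tracks, for each populated non-active state, an auxiliary
displacement integrated from the force difference between that surface and
the active one, and evaluates a frozen-Gaussian position-overlap
exp(−Σᵢ mᵢδxᵢ²/4σ²) with mass-weighted width σ = 6 amu^½·Å; when the
overlap falls below 1e-3 the state's amplitude collapses onto the active
state (amplitude zeroed, population transferred by renormalization — when
every non-active state has decohered this leaves the active coefficient at
magnitude 1). Auxiliary displacements reset at hops and collapses. Both
width and threshold are configurable; they are engine parameters, not
fitted quantities.

**Initial conditions.** `sample_initial_conditions` draws ground-ensemble
phase-space frames uniformly with replacement and selects the initial
excited state with probability ∝ |μ(S₀→k)|², optionally restricted to an
excitation energy window — photoexcitation according to the transition
dipole moment. Ensembles use one independent RNG stream per trajectory,
seeded base_seed + index, so runs are reproducible and order-independent.

Defaults: nuclear timestep 0.1 fs, 100 electronic substeps. The validation
ensembles in the test suite use 20–25 substeps, which is converged for the
model curvatures involved (the electronic propagator is checked against a
dense matrix-exponential oracle at 1e-8).

## Engine validation (what the tests show)

- **Exact-quantum benchmark**: 1000 FSSH trajectories through the 1-D
  avoided crossing at ≈ 20 a.u. incident momentum, with positions and
  momenta sampled from the Wigner distribution of a 10-bohr Gaussian
  wavepacket, are compared against a split-operator wavepacket propagation
  (8192-point grid, 0.05 fs steps; convergence checked against finer grids
  and steps). Lower-surface transmission agrees within 3 binomial standard
  errors (measured difference ≈ 0.01 against T_lower ≈ 0.535).
- **Internal consistency**: the ensemble fraction on each surface tracks
  the mean electronic populations within 3σ on the same run (difference
  ≈ 0.003 at n = 1000, no decoherence, single passage).
- **Conservation**: total energy is flat to < 2e-3 eV across every
  trajectory including through hops; a soft single-surface harmonic mode
  conserves energy to < 1e-6 of the total over 1 ps at the default
  timestep.

These are engine-level checks on model potentials. They do not demonstrate
anything about real CP29 photophysics; the package deliberately contains no
electronic structure, no atomistic force field and no QM/MM embedding.

## Kinetic analysis

Populations are occupation fractions of the active state on a common time
grid. Everything above S₁ is pooled into one "upper" reservoir before
fitting (the upper-state lifetime is reported as a single τ₂). The
sequential model is

    P_upper(t) = e^(−t/τ₂)
    P_S1(t)   = Σᵢ wᵢ · τᵢ/(τᵢ−τ₂) · (e^(−t/τᵢ) − e^(−t/τ₂)),  Σ wᵢ = 1

fitted jointly (shared τ₂) by nonlinear least squares with unit weights on
an evenly spaced grid; initial guesses (τ₂, τ₁, τ₁′, w) = (100 fs, 1 ps,
20 ps, 0.3); the τᵢ → τ₂ degenerate limit uses the analytic form
(t/τ₂)e^(−t/τ₂). An alternative "delayed independent bi-exponential" model
is implemented for comparison; the sequential feed is the default because
it is the physically motivated form for a relay S₂→S₁→S₀. The fit flags an
unidentifiable slow channel (w → 0/1 or τ₁ ≈ τ₁′). Noise-free
self-consistency is ≤ 1e-4 relative across admissible parameter ranges.
Reporting precision follows the field's conventions: lifetimes to 0.1 ps,
weights to 0.1%, ratios to two decimals.

## Geometry descriptors

BLA = mean(single-bond lengths) − mean(double-bond lengths), positive in
the alternating ground state. Dihedrals use the signed IUPAC (right-handed)
convention, reported in (−180°, 180°]; planar-trans is 180°, planar-cis 0°.
The distortion index is D = (1/N) Σᵢ (1 − |cos θᵢ|) over a named set of
C=C dihedrals — zero iff all planar (either basin), 1 at a 90° twist, and
D = 0.10 corresponds to a ≈ 26° mean twist, consistent with the
distortion-channel threshold D_Lum > 0.10. D_Lum runs over dd1–dd4
(lumenal), D_Strom over dd5–dd9 (stromal); since the form is a mean, the
total D lies between the two partial values. Conformers classify from ds2
alone: |ds2| ≥ 90° → s-trans (the 90° tie-break is s-trans by convention);
frame labels aggregate to trajectory labels by majority vote where needed.

Hop-channel characterization annotates every S₁→S₀ hop: *BLA channel* if
BLA < −0.02 Å; *distortion channel* if D_Lum > 0.10 at BLA ≥ −0.02 Å (the
channels are disjoint by construction); summaries count hops per channel
and the fraction occurring before a cutoff (default 2 ps). A
photoisomerization event is a dihedral series crossing 90° and dwelling in
the opposite planar basin for a configurable number of frames.

The conjugation topology (bond lists, dihedral quartets, lumenal/stromal
partition) is always explicit input — there is no automatic conjugation
perception. A 22-atom lutein-like chain builder and a NeRF-style
internal-coordinate chain constructor are provided for fixtures and demos.

## ESA spectra

Every frame with the active state on S₁ contributes, for each state n > 1,
a unit-area Gaussian at Eₙ − E₁ weighted by |μ(S₁→Sₙ)|²; the sum is
normalized by the number of contributing frames (frames are weighted
uniformly over trajectories and time — the simplest defensible convention).
Default grid 1.5–3.5 eV at 0.005 eV with σ = 0.05 eV broadening, which
cleanly resolves a 0.06 eV conformer shift; both are configurable, and
time-windowed spectra are available. Peaks are grid argmaxima refined by a
local quadratic, ties resolve to the lower energy, and peak shifts report
ΔE and Δλ separately (Δλ from the two peak wavelengths, not converted from
ΔE, because the eV→nm map is nonlinear).

## Couplings

Transition densities are represented as atomic transition charges (TrEsp
picture); the coupling is the bare charge–charge Coulomb sum in atomic
units, reported in cm⁻¹. No dielectric screening is applied by default (an
optional scalar factor is available); charge-based couplings are expected
to differ from transition-density integrals by a few tens of cm⁻¹ while
staying in the same range — this is the known fidelity of the
representation, not an error to be corrected here. The point-dipole formula
over the derived dipoles (Σqᵢrᵢ) is a far-field cross-check only: it
refuses to evaluate when the center separation is under 3× either cloud
radius, and agrees with the charge sum to 5% for compact clouds at large
separation (exactly the regime where the multipole expansion is valid).
EET favorability is the fraction of paired frames with acceptor S₁ below
donor Q_y.

## The synthetic-ensemble generator

The generator emulates the statistical structure of a surface-hopping
production campaign so the analysis stack can be exercised end to end. Its
defaults encode the study conditions this package targets: two
conformational sets — A: 396 trajectories, all s-cis; B: 386, half s-trans
(the two rotamers are equally represented in the protein conformation that
stabilizes both) — propagated 15 ps with 10 fs frames. Hop times follow the
sequential kinetic model with per-(set, conformer) parameters taken from
the reference lifetime table (A: τ₂ = 135 fs, τ₁ = 1.0 ps at 20.1%,
τ₁′ = 21.2 ps; B s-cis: 162 fs / 1.2 ps at 22.2% / 25.0 ps; B s-trans:
141 fs / 1.1 ps at 59.0% / 16.7 ps): the upper→S₁ time is Exp(τ₂), the S₁
residence a w:1−w mixture of Exp(τ₁) and Exp(τ₁′), truncated at the window
(survivors end on S₁, as in a truncated production run).

Descriptor series are exact-discretization Ornstein–Uhlenbeck processes
(correlation time 100 fs) with state- and conformer-dependent stationary
targets: ds2 centered at 180° (s-trans) or 0° (s-cis) with 8° spread; ds1
at +80° versus −50°; BLA mean +0.10 Å on the ground state relaxing to 0 on
S₁, with the s-trans spread (0.020 Å) broader than s-cis (0.012 Å); per-C=C
twist spreads of 8–13° that widen by 1.6× on the lumenal side once S₁ is
populated. Fast-channel S₁→S₀ hops are assigned hop-frame descriptors in
the inverted-BLA channel (BLA < −0.02 Å) or the lumenal-distortion channel
(D_Lum > 0.10) with a configurable mix (default 0.67 BLA-driven — the true
split is only countable from scatter plots, so it is exposed as a free
parameter rather than asserted). Energy samples: chlorophyll Q_y at
2.00 ± 0.04 eV (narrow, rigid macrocycle); carotenoid S₁ vertical energies
2.2 ± 0.6 eV for s-trans (extremely wide, reaching below Q_y) versus
2.35 ± 0.12 eV for s-cis (never below); S₁→Sₙ ESA gaps centered 2.30 eV
(s-trans) versus 2.24 eV (s-cis) with 0.10 eV spread. Values the reference
tables do not print (spreads, correlation times, the channel mix) were
chosen once as field-realistic and are not tuning knobs.

What the generator does *not* emulate: quantum coherences, frame-level
energy conservation, correlations between descriptors and hop times beyond
the channel assignment, or any real protein structure. Passing end-to-end
tests on generated ensembles therefore demonstrates that the analysis
stack is correct and statistically calibrated — not that the underlying
photophysics is reproduced from first principles.

End-to-end calibration: fitting populations of generated set-B ensembles
recovers the generating weighted-average S₁ lifetime within 25% at n = 400
and within 10% at n = 5000 (fixed seeds; the bi-exponential fit of a
two-conformer mixture on a finite window is itself an approximation, which
these bands absorb). The S₁ residence-time distribution passes a
Kolmogorov–Smirnov test against the target mixture at α = 0.01 (5000
trajectories on a 200 ps window so truncation is negligible).

## File formats

XYZ dialect: standard atom-count line, comment line carrying `t= <fs>`,
then element + three floats; reduced-coordinate trajectories use
pseudo-atoms X0, X1, … with the coordinate in the x column. The per-frame
sidecar CSV (versioned `polyhop-sidecar/1`) stores time, active state,
adiabatic energies, coefficient magnitude/phase, velocities and
transition-dipole magnitudes, printed at 12 significant digits so
write→read round-trips are exact at that precision. Topology files and run
manifests are versioned YAML; manifests echo the configuration and seeds
verbatim and deliberately carry no timestamps, so identical runs produce
byte-identical artifacts.

## Problem sizes

The shipped validation uses 1000-trajectory scattering ensembles (150 fs,
0.1 fs steps), an 8192-point wavepacket grid, 782-trajectory synthetic
ensembles over 15 ps with 10 fs frames, and a 5000-trajectory ensemble for
distribution-level checks — sizes chosen so the whole suite runs in
minutes on one CPU while keeping every statistical comparison at 3σ or a
stated tolerance.

## Known limitations

- The surrogate's two nuclear degrees of freedom cannot dissipate
  electronic energy into a bath, so microcanonical back-hopping is visible
  in demos; picosecond S₁ lifetimes are emulated statistically by the
  generator, not integrated by the engine.
- Isotropic velocity rescaling is a convention forced by the absence of
  coupling vectors; other rescaling choices would change frustrated-hop
  statistics on stiff models.
- The overlap-decoherence auxiliary dynamics is a first-order
  approximation to full frozen-Gaussian bookkeeping (momentum-space overlap
  neglected); its width/threshold defaults are conventions, configurable.
- The D index implemented is the bounded mean-cosine form; other bounded
  planarity measures would shift the 0.10 distortion threshold's meaning.
- TrEsp couplings carry the documented few-tens-of-cm⁻¹ fidelity relative
  to transition-density integrals and include no environment screening by
  default.
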