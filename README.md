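# polyhop

Fewest-switches surface hopping on analytic model potentials, plus the
trajectory-analysis stack used to characterize carotenoid excited-state
dynamics in light-harvesting complexes: population kinetics, conjugated-chain
geometry descriptors, excited-state absorption (ESA) spectra and
transition-charge Coulomb couplings.

## The scientific problem

Plants protect themselves from excess sunlight by nonphotochemical quenching
(NPQ): light-harvesting antenna complexes switch into a state that dissipates
chlorophyll excitation as heat. A leading hypothesis is excitation energy
transfer (EET) from chlorophyll Q_y states to the optically dark S₁ state of
a nearby carotenoid — in the minor antenna CP29, the lutein in the L1 pocket.
Transient-absorption experiments see two dark carotenoid species: the normal
S₁ (lifetime ~13 ps) and a short-lived, blue-shifted "S*" state (~6 ps)
associated with quenched complexes.

The computational picture behind this package: the carotenoid can sit in two
rotamers about the first single bond of the conjugated chain on the lumenal
side (dihedral ds2 ≈ 180° s-trans versus ≈ 0° s-cis). Nonadiabatic
surface-hopping ensembles show the s-trans conformer decays faster
(bi-exponential S₁ decay with a larger fast-channel weight) and absorbs
bluer — i.e. the S* fingerprint — while its S₁ energy distribution is wide
enough to dip below the chlorophyll Q_y energies, making EET quenching
energetically downhill.

`polyhop` packages desk-scale versions of every computational step of that
workflow:

- **fssh_engine / models** — Tully's fewest-switches surface hopping with
  *locally diabatic* electronic propagation (amplitudes integrated from
  overlap matrices of adiabatic eigenvectors at successive geometries, no
  nonadiabatic coupling vectors needed), overlap- or energy-based decoherence
  corrections, energy-conserving isotropic velocity rescaling at hops, and
  analytic model Hamiltonians: 1-D scattering benchmarks and a reduced
  carotenoid surrogate over bond-length alternation (BLA) and a lumenal
  torsion.
- **kinetics** — population curves P_k(t) from trajectory ensembles and the
  sequential kinetic fit: upper pool decays as exp(−t/τ₂), S₁ follows the
  sequential-feed bi-exponential Σᵢ wᵢ τᵢ/(τᵢ−τ₂)(e^{−t/τᵢ} − e^{−t/τ₂}),
  with τ₁^avg = w·τ₁ + (1−w)·τ₁′.
- **geometry** — BLA (mean single-bond minus mean double-bond length), named
  chain dihedrals ds1–ds9 / dd1–dd9, bounded distortion indices
  D = ⟨1 − |cos θ|⟩ (total, lumenal, stromal), conformer classification,
  hop-channel characterization (BLA < −0.02 Å versus D_Lum > 0.10) and
  photoisomerization detection.
- **spectra** — S₁→Sₙ ESA accumulation (one Gaussian per transition per
  S₁-active frame, weight |μ₁ₙ|²), peak location and conformer shifts.
- **couplings** — TrEsp-style Coulomb couplings between atomic transition
  charges (in cm⁻¹), a point-dipole far-field cross-check, and
  donor/acceptor energy-gap (EET favorability) statistics.
- **synthetic** — a generator of mock trajectory ensembles with the
  statistical structure the analysis assumes (hop times from the sequential
  kinetic model, Ornstein–Uhlenbeck descriptor series with state-dependent
  means, conformer-dependent energy distributions), so the full pipeline is
  testable without quantum-chemistry trajectories.

## Worked example

`examples/fit_population_kinetics.py` generates the default two-set
synthetic ensemble (396 + 386 = 782 trajectories over 15 ps) and fits the
sequential model per set and conformer:

```
A/all        tau2 =   131 fs   tau1 =  0.8 ps (18.9%)   tau1' = 19.1 ps   tau1_avg = 15.6 ps
B/all        tau2 =   150 fs   tau1 =  1.4 ps (45.3%)   tau1' = 20.6 ps   tau1_avg = 11.9 ps
B/s-cis      tau2 =   149 fs   tau1 =  1.2 ps (24.1%)   tau1' = 22.5 ps   tau1_avg = 17.3 ps
B/s-trans    tau2 =   151 fs   tau1 =  1.5 ps (66.9%)   tau1' = 17.5 ps   tau1_avg =  6.8 ps

s-trans / s-cis lifetime ratio: 0.39 (the short-lived s-trans population is the S*-like component)
```

Read: all trajectories leave the bright upper states within ~150 fs; the
s-trans S₁ population decays more than twice as fast as the s-cis one
because its fast channel carries ~3× the weight, and the resulting lifetime
ratio (0.39 here, sampling noise of a finite ensemble included) is the
quantity compared against the experimental S*/S₁ ratio of ≈ 0.46.

The other example scripts each cover one capability: `run_surface_hopping.py`
(FSSH mechanics on the carotenoid surrogate), `hop_channel_analysis.py`
(fast-decay channels at the S₁→S₀ hops), `esa_spectra.py` (per-conformer ESA
peaks and the s-trans blue shift), `couplings_and_gaps.py` (TrEsp couplings
and EET favorability). A thin CLI mirrors the pipeline:
`polyhop generate | simulate | fit-populations | geometry | esa | couple |
report`.

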