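# Methods

`vibromap` studies how a covalent phospho-modification and cross-link
density change vibrational energy transport and mechanical stability in a
protein-like chain, at desk scale.  All physics runs on harmonic spring
networks and coarse-grained bead-spring models; nothing here requires an
all-atom force field, solvent, or external data.

## Units and constants

Lengths are Å (structures, transport) or nm (pulling), masses amu, times
ps.  Potential energies are kcal/mol on the Å side and kJ/mol on the nm
side; both are exactly compatible with (amu, length, ps) mechanics through
1 kcal/mol = 418.400 amu Å² ps⁻² and 1 kJ/mol = 1 amu nm² ps⁻².  Angular
frequencies convert to wavenumbers via ν̃ = ω/(2πc) with
c = 0.0299792458 cm/ps, i.e. 1 ps⁻¹ = 5.30884 cm⁻¹.  k_B =
1.98720×10⁻³ kcal mol⁻¹ K⁻¹; quantum occupations use the second radiation
constant hc/k_B = 1.43877 cm·K.

## Normal-mode analysis

The desk-scale potential is a harmonic spring network: either an elastic
network (all pairs within a cutoff, default 12 Å at 1 kcal mol⁻¹ Å⁻²,
natural lengths taken from the reference geometry) or an explicit spring
list.  The Hessian is analytic — per spring
K = k[uuᵀ + (1 − r₀/r)(I − uuᵀ)] — mass-weighted by 1/√(mᵢmⱼ), and
diagonalised with `numpy.linalg.eigh`.  Eigenvalues below 10⁻⁸ of the
spectral maximum are rigid-body modes (exactly 6 for a 3-D non-collinear
structure); a negative eigenvalue beyond that tolerance aborts with an
unstable-mode count, because every downstream quantity assumes a minimum.
Eigenvector signs are fixed by making the first non-negligible component
positive, so reruns are bit-stable.

Minimisation runs a staged schedule — steepest descent (budget 10,000
steps), conjugate gradient (50,000 steps, tolerance 10⁻⁶ kcal/mol), then
L-BFGS (500,000 steps, 10⁻⁷ kcal/mol) — each stage stopping early when the
energy change per accepted step falls below its tolerance.  Step budgets
are caps, not quotas; a structure already at a minimum reports zero
productive steps.

Heat capacity is the quantum harmonic sum
C_v = k_B Σ x²eˣ/(eˣ−1)², x = hcν̃/k_BT over internal modes, evaluated as
(x / 2sinh(x/2))² for stability; the classical limit (one k_B per internal
mode) is returned alongside since the two bracket every admissible value.

## Energy diffusivity and communication maps

Per-mode transport follows Allen–Feldman harmonic theory.  With
mass-weighted force-constant blocks Φᵢⱼ and displacement differences
rᵢ − rⱼ, the velocity matrix is
W_ab = (1/2√(ω_aω_b)) Σᵢⱼ (rᵢ − rⱼ) e_a(i)·Φᵢⱼ·e_b(j)  (Å/ps),
the heat-flux element S_ab = ½(ω_a+ω_b) W_ab, and

  D_a = (π / d ω_a²) Σ_{b≠a} |S_ab|² g_η(ω_a − ω_b)   [Å²/ps]

with d the spatial dimension and g_η a unit-area Gaussian standing in for
the delta function of an infinite system.  The width η defaults to 3× the
local mean mode spacing (±5 modes), which adapts to the spectral density;
partners beyond 7η contribute < 10⁻¹⁰ and are skipped, identically in the
scalar and the map paths so the decomposition stays exact.  Rigid-body
modes are excluded everywhere.

A published frequency-band convention is kept: a band is the
`modes_per_band` (default 10) modes nearest each center, ties toward lower
frequency.  The paper-scale centers (50–400 cm⁻¹) suit all-atom spectra;
for synthetic bead models the pipeline instead spreads six centers over
the 10th–90th percentile of the actual spectrum.  Thermal averaging is
classical by default (equipartition: a uniform band mean, scaled by
T/300 K so maps at different temperatures differ by amplitude); Bose
weighting of band centers is available by flag.

The residue×residue communication map decomposes the band- and thermally
averaged diffusivity over residue pairs.  Restricting the double sum in
S_ab to i∈I, j∈J gives partial elements S_ab^(IJ); each partner term
w_ab|S_ab|² is apportioned over pairs proportionally to |S_ab^(IJ)|².
This keeps every entry non-negative, makes pairs with no force-constant
coupling exactly zero, and sums over all ordered pairs to the global value
to round-off (the projection alternative — S·S^(IJ) — partitions exactly
too but produces negative entries of ~30% of the maximum on these models,
which no map convention tolerates).  Per-residue VED profiles are map row
sums; the published color bands (red > 10⁷, orange 9–10×10⁶, blue
8–9×10⁶, in the figure scale's units) are applied either literally or
after rescaling the red threshold to a chosen percentile of the data,
since synthetic maps live on a different absolute scale.

### Wave-packet oracle

Transport values are validated against an independent brute-force
estimate: exact harmonic propagation of a kinetic-energy kick at one site
(rigid modes projected out; optionally band-passed), site energies
E_i = ½q̇ᵢ² + ½qᵢ(Hq)ᵢ, and the energy-weighted mean-square displacement
⟨R²(t)⟩.  In a finite system ⟨R²⟩ saturates at the uniform-energy plateau
(mean squared distance from the source), so the asymptotic slope is fitted
over the first contiguous window where ⟨R²⟩ lies in [0.2, 0.6] of that
plateau — past the ballistic transient, before boundary saturation — and
D = slope/2d.  The estimate is then insensitive to the requested t_max.
On 64-bead mass-disordered chains (masses uniform in [0.8, 1.2]),
seed-averaged band diffusivities agree with the oracle to ~10%, well
inside the 25% acceptance band; per-seed, per-band scatter is larger
because a single wave packet is one phase-coherent realisation.

## Synthetic structures and trajectories

Generators are pure functions of spec + seed.  Bead-per-residue geometries:
ideal helix (rise 1.5 Å, twist 100°, radius 2.3 Å), extended chain
(3.8 Å), cubic lattice.  Bead mass is 110 amu (mean residue mass).

The homolog pair emulates a phosphorylated/unmodified contrast: two
identical helices where model A carries 9 cross-links placed uniformly at
random (|i−j| ≥ 3) in the C-terminal ~40% of the chain plus a phospho-like
modification — +79 amu (a PO₃ moiety) on one bead and one stiff spring to
the bead 7 ordinals downstream, mimicking a modified-aspartate/partner
contact — while model B carries 2 cross-links (a subset of A's) and no
modification.  For normal-mode work the springs are an ENM (cutoff 10 Å,
k = 1) plus stiffer cross-links (k = 3) and a stiffest phospho contact
(k = 10, kcal mol⁻¹ Å⁻²): the contrast must be visible above the
backbone network without dominating the spectrum.

Harmonic trajectories draw frames independently from the classical
equilibrium distribution (mode amplitude variance k_BT/ω² in mass-weighted
coordinates; rigid modes unexcited; frame 0 is the reference).  They
emulate equilibrium fluctuation statistics only — no time correlation, no
anharmonicity, no solvent — so passing RMSD/RMSF tests certifies the
estimators and the equipartition scaling (amplitude ∝ √T), not kinetics of
real proteins.

## Trajectory metrics

Superposition is Kabsch SVD with mass weights by default, determinant
corrected to a proper rotation; collinear sets are rejected.  RMSD series
superpose every frame onto a reference frame; the summary mean ± SD skips
an equilibration window (default 10% of frames, configurable as a count).
RMSF superposes all frames onto the mean structure (two refinement
passes), then reports per-residue mass-weighted RMS fluctuations; on
harmonic trajectories the profile matches the closed-form covariance
within 1% at 20,000 frames.  Salt bridges are acidic side-chain oxygens
(ASP/GLU, plus the phosphoaspartate label) within 4.0 Å of basic
side-chain nitrogens (LYS/ARG/HIS); hydrogen bonds use a geometric
criterion (donor–acceptor ≤ 3.5 Å, donor–H–acceptor ≥ 120°, hydrogens
assigned to the nearest N/O within 1.25 Å).  Both detectors are
deterministic and order-independent.

## Coarse-grained pulling

The pulling model is a bead-spring chain (nm/kJ units): backbone springs
between consecutive beads, weak next-nearest-neighbour springs for
enthalpic bending rigidity, and breakable cross-links that vanish
permanently once stretched past threshold.  Defaults: cross-link
k = 4,000 kJ mol⁻¹ nm⁻² with rupture extension 0.15 nm — a rupture
barrier of ½kΔr² = 45 kJ/mol ≈ 18 k_BT at 300 K, the scale of a strong
hydrogen-bond cluster, so rupture is enthalpy-dominated but thermally
assisted — backbone 10× the cross-link stiffness, angle springs
10,000 kJ mol⁻¹ nm⁻².  The angle springs matter: a bare bead-spring chain
is an entropic coil whose tension at fixed extension *grows* with
temperature, which at this scale would mask — and in development did
invert — the physically expected thermal softening of rupture.

Dynamics are BAOAB Langevin (friction 1 ps⁻¹, 2 fs step), reducing to
velocity Verlet with friction off; with the thermostat off and zero pull
rate total energy is conserved to 10⁻⁴ over 100 ps at a 1 fs step.  A
harmonic restraint (default 1,500 kJ mol⁻¹ nm⁻²) couples the group-B/
group-A center-of-mass separation along z to a virtual point moving at
0.01 nm/ps; force, separation and energy are recorded every 1 ps.  Runs
end at a configured extension multiple (default 3× the initial end-to-end
distance) or earlier once every cross-link has ruptured and the load has
decayed below half its running peak — beyond that the profile is pure
backbone stretching, not unfolding.

The characteristic rupture force of a pull is the mean (or max) of the
10-ps-smoothed restraint force at the logged rupture events.  Smoothing is
essential: the raw restraint force carries thermal center-of-mass jitter
of order √(κk_BT) (≈60 kJ mol⁻¹ nm⁻¹ here), and the raw global maximum of
a profile is typically the terminal backbone ramp — neither is an
unfolding force.  A second, profile-only detector finds drops of ≥20%
below the trailing-window maximum (window 20 ps, drops from below 5% of
peak load ignored) and cross-checks the integrator's break log; the force
curve also shows helix-unwinding transitions that break no link, so
event-for-event identity between the two detectors is not expected and
not asserted.

Across five seeded pulls per condition, the 9-link model sustains ~1.4–1.7×
the 2-link model's mean rupture force at both 300 K and 340 K, and the
2-link model softens by ~10% from 300 K to 340 K.  The 9-link model's
softening is weaker than the seed-to-seed scatter (≈ −3% ± 4%): its late
ruptures are cooperative, with load redistribution pinning the failure
force near the threshold value, so its temperature trend should be read as
"no hardening" rather than a resolved decrease.

## Problem sizes

Defaults keep every stage interactive on one core: transport and map
algebra on 32–64-bead models (seconds), oracle comparisons on 64-bead
chains, fluctuation statistics on a 20-residue helix with 2×10⁴ frames,
and twenty pulls of 48-bead models (~2 minutes, the integrator is
numba-compiled).  All sizes are configuration values, not limits of the
implementation.

## Known limitations

- Harmonic transport only: no anharmonic decay, no quantum dynamics beyond
  occupation weights; diffusivities of a perfect lattice diverge as the
  broadening shrinks (flagged, not "converged").
- The communication map's pair apportionment is one defensible convention;
  absolute entries depend on it, although orderings and contrasts were
  stable under the alternatives tried.
- The phospho patch places ideal tetrahedral geometry and spreads −2 e
  over the terminal oxygens; it claims no force-field accuracy and is
  meant to be relaxed by minimisation.
- CG rupture is a hard extension threshold, not a Morse/Bell escape;
  loading-rate dependence of rupture forces is therefore much weaker than
  in activated models.
- Synthetic homolog models share an idealised helix geometry; only
  orderings and trends (modified vs unmodified, 300 K vs 340 K), not
  absolute forces or diffusivities, are claimed to transfer to proteins.
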