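# Methods

## Model

`polscat` implements the interacting point-dipole picture of molecular
polarizability: a molecule is N atoms at fixed Cartesian coordinates, each
with an isotropic, frequency-independent polarizability volume αᵢ (Å³).
An applied optical field induces a dipole on every atom; each dipole also
feels the field of all other induced dipoles through the dipole field
tensor T_ij (Å⁻³). The model captures how atomic *arrangement* — not just
composition — sets the optical response: head-to-tail dipole chains
reinforce (elongated molecules are hyper-polarizable along their axis),
side-by-side dipoles screen (compact shapes respond less than the sum of
their atoms).

Assumptions worth stating plainly:

- Linear response to a monochromatic field; no hyperpolarizability.
- Atomic polarizabilities are scalars; anisotropy emerges only from
  geometry. The default table (H 0.514, C 1.405, N 1.105, O 0.862, S 2.900,
  P 3.630 Å³) is referenced at 589.3 nm and applied unchanged at other
  wavelengths — dispersion is ignored.
- No permanent charges, electrostatics, or force evaluation: this is a
  pure optical-response model, not a polarizable force field.
- Clusters in vacuum/implicit medium; no periodic boundary conditions.

### Thole damping

The bare dipole tensor diverges as atoms approach (the polarization
catastrophe). Below the damping length s = 1.662 (αᵢαⱼ)^{1/6} the tensor's
isotropic part is scaled by 4v³−3v⁴ and its anisotropic part by v⁴
(v = r/s), corresponding to a linearly tapered smeared dipole density. The
two branches agree exactly at r = s; the implementation uses the damped
branch for r ≤ s (the tie is immaterial by continuity). Pairs closer than
0.1 Å are rejected as corrupt input rather than damped: such separations
are never physical in a deposited structure.

### Solving

The coupled dipoles form a symmetric 3N×3N block system with αᵢ⁻¹·I on
the diagonal. Pair blocks beyond a threshold radius Δr_t are dropped;
since |T| falls off as r⁻³, the average polarizability converges quickly
in Δr_t, and 30 Å (the default) recovers the unthresholded value to
better than 1% on dense protein-scale clusters (verified in the test
suite on a 2000-atom random cluster at heavy-atom density ~0.05 Å⁻³,
minimum separation 1.5 Å). A threshold below the minimum pair distance
decouples all atoms and returns exactly Σαᵢ. Neighbour pairs come from a
k-d tree and the matrix is stored in block-sparse (BSR) form, so memory
scales with retained pairs.

Systems with N < 700 are solved by dense LU (one factorization reused for
the three field directions); larger ones by MINRES (the matrix is
symmetric but not guaranteed positive definite) at relative tolerance
10⁻⁶. The contract is a residual relative to ‖b‖; because scipy's MINRES
stops on an ‖A‖-scaled estimate, the solver restarts with a tighter
internal rtol until the ‖b‖-relative residual is met, and raises if it
cannot. An optional block-Jacobi preconditioner (inverse diagonal = αᵢ·I)
exists but is off by default. The tensor assembled from the three solves
is symmetrized by (α+αᵀ)/2 before eigen-decomposition; asymmetry above
1e-4 relative (a symptom of an unconverged solve) triggers a warning.

## Structures

PDB input is parsed with gemmi; MODEL blocks become frames. Alternate
locations keep the highest occupancy (ties: alphabetically first ID).
Missing element fields fall back to atom-name heuristics (leading letters
after digits; a small whitelist of two-letter elements, deliberately
excluding "Ca" because protein CA is the alpha carbon). Preprocessing can
(a) drop HETATM records — waters, ions, ligands and crystallization
agents are not part of the molecule in solution — and (b) apply a
united-atom rule deleting every hydrogen whose nearest heavy atom is a
carbon within 1.2 Å, emulating the grouping of aliphatic hydrogens into
their parent carbon; hydrogens on N/O/S are kept. The carbon α is *not*
enlarged for absorbed hydrogens: the default table is used as-is, and the
rule is a distance criterion because a testable operational definition is
preferable to bond perception. Preprocessing is idempotent and preserves
atom order.

## Synthetic inputs

The fixture generators define the conditions under which the package is
tested, download-free:

- `carbon_cube(2.0)` / `carbon_line(8, 2.0)`: the worked shape-effect
  geometries.
- `methane`, `water`, `ethane`: standard experimental gas-phase geometries
  (CH 1.091 Å tetrahedral; OH 0.9572 Å, 104.52°; staggered CC 1.534 Å).
  Reference interacting-dipole values are matched within 2%; residual
  differences are coordinate sensitivity, not model error.
- `diamond(a, k)` / `diamond_sphere(a, R)`: cubic diamond lattice clusters,
  8 atoms per conventional cell, minimum distance a√3/4.
- `random_cluster(n, box, min_dist, seed)`: uniform carbon cluster with a
  minimum-separation constraint at protein heavy-atom density; used for
  solver and threshold properties.
- `thermal_frames(base, n, σ, rotate, seed)`: Gaussian coordinate jitter
  (per-coordinate σ in Å) with optional uniform random rigid rotations,
  emulating thermal deformation plus free tumbling. It does *not* emulate
  correlated collective motions, solvent damping or realistic amplitude
  spectra, so passing fluctuation tests demonstrate the statistics
  pipeline, not MD realism.

All generators are bit-reproducible given a seed.

## Optics conventions

Polarizabilities are volumes (Å³, Gaussian convention α_SI/4πε₀) and enter
the scattering formulas converted to m³, with the *relative* medium
permittivity ε_m = n_m². The wavenumber k = 2π/λ uses the vacuum
wavelength. This combination reproduces the reference magnitudes: a
2100 Å³ excess polarizability at λ = 780 nm focused to w = 1 μm in water
scatters 2.5×10⁻¹⁷ of the incident power, and resolving 1700 → 2100 Å³
with two 10 ns windows needs I_min ≈ 5.1 MW/μm².

The minimum-intensity formula is provided in two modes. `printed` evaluates
the standard closed form
I_min = [48 c n_m² π h/(k⁴λ)] · (α_a²τ_a + α_b²τ_b)/|α_a²τ_a − α_b²τ_b|².
`derived` recomputes the same bound self-consistently from the plane-wave
scattered power, photon counting and the shot-noise criterion; it differs
from `printed` by exactly n_m², because the closed form is consistent with
a scattered power carrying ε_m to the first power rather than ε_m². Both
are exposed; `printed` is the default and matches the reference numbers.
The self-consistency property (mean count step equals combined shot noise
at I_min) holds to 1e-6 when counts use the `printed` convention.

The displaced-medium polarizability is reconstructed as
ᾱ_m = V_mol · ρ_water · α_water with V_mol from molecular mass × partial
specific volume (default 0.73 cm³/g), α_water = 1.45 Å³ and
ρ_water = 0.0334 Å⁻³; a 66.5 kDa protein displaces ≈8.1×10⁴ Å³, giving
ᾱ_m ≈ 3.9×10³ Å³. All pieces are overridable; a constant ᾱ_m is used for
every frame of a trajectory.

## Trajectories and state comparison

Frames are processed independently (results are order-invariant), with no
alignment: rotation is signal for the direction-resolved vector magnitudes
and irrelevant to the eigenvalue average. Fluctuation statistics report
mean, percent range, percent sample standard deviation and the standard
error (std/√n, in percent of the mean); the SEM reading assumes roughly
Gaussian fluctuations. State comparisons report signed percent changes for
consecutive pairs (cycling back to the first state when more than two are
given) in each structure's own deposited coordinate frame, plus optional
per-direction minimum resolving intensities.

## Known limitations

- **Bulk diamond.** Estimating the diamond refractive index from a
  cluster-average per-atom polarizability plus Lorentz–Lorenz (ρ = 8/a³)
  converges slowly: spherical clusters of radius 12/15/18.6 Å (1268/2494/
  4779 atoms) give n = 2.82/2.77/2.72, and Richardson extrapolation in 1/R
  lands near n ≈ 2.55 — still above the experimental 2.417. The sphere is
  the right shape (its depolarization exactly cancels the local-field
  correction in the continuum limit), surface atoms are simply under-
  screened at any feasible size. The package reports what the stated
  procedure actually produces rather than a corrected value; treat
  finite-cluster bulk indices as upper bounds.
- Dispersion is ignored; polarizability tables are single-wavelength.
- Non-uniform illumination is accepted as per-atom fields but no field
  solver is included (plasmonic hot spots must be supplied externally).
- No Mie corrections or detector model: all scattered photons are assumed
  collected.
- Unthresholded (all-pair) assembly is refused above 20,000 atoms; use a
  threshold there. Problem sizes used in the shipped tests (≤4779 atoms,
  ≤2000-atom dense comparisons) were chosen so the full suite runs on a
  single CPU in a couple of minutes.
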