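# Methods

## Density models

Two density sources share one evaluation interface.

**Wavefunction densities.** A single-determinant wavefunction is stored as
nuclei, unnormalized Cartesian Gaussian primitives and occupied molecular
orbitals, the layout of the WFX interchange format (MO coefficients absorb
primitive normalization, so primitives are evaluated exactly as stored).
The density is the occupation-weighted sum of squared orbitals,
ρ(r) = Σₖ nₖ (Σₚ c₍ₖₚ₎ gₚ(r))², which is non-negative by construction and
accepts open-shell occupations (0 ≤ nₖ ≤ 2) without special-casing.
Gradients are analytic throughout; finite differences appear only as a test
oracle.  The WFX "Primitive Types" integers map to Cartesian powers in the
standard AIM ordering (1 = s; 2–4 = p; 5–10 = dxx, dyy, dzz, dxy, dxz, dyz;
11–20 = fxxx, fyyy, fzzz, fxxy, fxxz, fyyz, fxyy, fxzz, fyzz, fxyz).  Only
MO-based evaluation is implemented (no density-matrix path); pure
spherical-harmonic basis functions and ECPs are out of scope.

**Analytic Gaussian atoms.** A fixture "atom" is a spherical density
N (α/π)^{3/2} exp(−α|r−R|²) that integrates to exactly N electrons.  For an
isolated atom every pipeline quantity has a closed form: the ρ = iso
envelope is the sphere of radius r* = sqrt(ln(N(α/π)^{3/2}/iso)/α), the
envelope volume is (4/3)πr*³, and the charge centroid sits on the nucleus,
so the molecular dipole is Σ (Z−N) R in atomic units.  Gaussians lack
nuclear cusps and shell structure; that is irrelevant here because the
quantities under test (partitioning, quadrature, aggregation) do not depend
on cusp behavior.

## Grid construction

The integration grid is uniform and isotropic.  The box encloses, per
center, the radius at which that center's density term falls to the density
floor (1e−7 e/bohr³ by default), expanded by 2 bohr of padding; spacing
defaults to 0.10 bohr.  For wavefunction sources the per-center radius uses
the on-nucleus density and the most diffuse exponent on that center as a
conservative amplitude/decay estimate — the padding absorbs the slack.  The
grid is *centered on the box midpoint*, so a mirror-image system yields a
bit-for-bit mirror-image voxel lattice; this is what makes enantiomer AED
equality hold to ~1e−12 rather than merely to quadrature order.  Densities
below 1e−300 are treated as numerically zero; small positive values are
never clamped.

## Basin assignment (near-grid ascent)

Every voxel at or above the density floor launches a steepest-ascent
trajectory over the 26-neighbor stencil.  At each step the
central-difference gradient g is computed (one-sided at the grid boundary),
the lattice step is sᵢ = round(gᵢ/max|g|) ∈ {−1,0,1}, and the rounding
error is accumulated in a correction vector c += g/max|g| − s; whenever a
component of c exceeds 1/2 in magnitude the step is shifted by its sign and
the correction reduced by one.  This is the standard lattice-bias
correction for grid ascent: without it, basin boundaries develop
stair-step artifacts aligned with the lattice.  If the corrected step is
null, leaves the grid, or fails to increase the density, the walker falls
back to the steepest on-grid neighbor (score (ρₙ−ρᵥ)/|d|, ties broken by
lowest linear voxel index — a stated, deterministic tie-break) and the
correction resets.  Because density increases strictly along every
trajectory, termination is guaranteed.

Each voxel runs its own complete trajectory; labels are never inherited
from voxels visited mid-path, whose correction state would differ.  The
assignment is therefore an exact deterministic function of the density
grid, and the compiled (numba) kernel is validated voxel-for-voxel against
an independently written pure-Python walker implementing the same stepping
rule.  Trajectories end at grid local maxima; a maximum within 1.2 grid
spacings of a nucleus is that nucleus's attractor, while farther
("non-nuclear") maxima are merged into the basin of the nearest nucleus and
counted through the module logger — moiety AED needs all density attributed
to atoms, and such maxima are rare and flagged rather than fatal.

## Basin integrals

Populations use midpoint quadrature with uniform voxel weight h³ over the
*full* basin down to the density floor; volumes count only basin voxels
inside the ρ ≥ iso envelope (iso = 0.001 e/bohr³ by default, the
conventional van-der-Waals-like boundary used in published AED work).
Published per-atom tables can be read as either full-basin or
envelope-clipped populations; full-basin matches standard AIM reporting
and is the default, with `clip_populations_to_envelope=True` exposing the
alternative.  No boundary-voxel weighting is applied; quadrature error is
controlled empirically by grid-halving (Cauchy) convergence tests and the
conservation checks below.  The dipole is μ = Σ_A Z_A R_A − h³ Σ r ρ(r) in
atomic units, converted at 1 a.u. = 2.541746 D; it is reported for the
whole (capped) molecule, matching how dipoles accompany AED tables.

## AED, classification, comparison

AED = ΣN/ΣV over the moiety atoms; cap atoms are excluded by explicit
listing in the moiety definition (automatic cap perception from
connectivity is deliberately out of scope).  The bioisosterism decision
threshold on the percent difference versus the reference group defaults to
35% and is *inclusive* at the boundary, reading the reported upper bound as
attained.  R² between condition vectors is the squared Pearson correlation
(identical to single-predictor OLS R²).  Cross-condition sensitivity is
100·(max−min)/min per molecule — the claim under test is overall
insensitivity across all conditions, not drift from one anchor — with a
reference-condition variant available.  Dipole R² is reported alongside but
carries no pass/fail meaning, since dipole scales differ between solvation
models even when trends agree.

## Synthetic fixtures and what they do (not) show

The generator samples well-separated Gaussian atoms: pairwise separations
of at least 9 bohr (resampled up to 1000 times) guarantee that every atom's
density at every inter-atomic midpoint is below 1e−6 of either peak, so
basin boundaries lie in numerically empty space and the closed forms hold.
Defaults — populations 1–10 e, exponents 1.0–2.5 bohr⁻², iso 0.001 —
give peak densities and envelope radii of the same order as second-row
atoms.  `perturb_polarization` emulates the solvent response seen in
per-atom tables: electrons move from donor to acceptor atoms (total N
conserved exactly), acceptor envelopes swell by a chosen fraction and donor
exponents are re-solved (bracketed Brent root-finding on the closed-form
volume) so the total volume is preserved to solver precision — opposing
per-atom trends, nearly constant total, nearly constant AED.
`jitter_exponents` adds the small residual, non-compensating part of a
condition change (~0.1% volume drift) used by the dataset emulation.

Overlapping-atom systems appear only in invariant tests (conservation,
symmetry), never in value tests, because basin boundaries have no closed
form under overlap.  Passing on these fixtures validates the partitioning,
quadrature and aggregation machinery — not DFT-level physics: real
wavefunctions have cusps, diffuse tails and covalent basins whose absolute
Nᵢ/Vᵢ can only be cross-checked against an external AIM engine.

## Problem sizes and numerical defaults

Production spacing 0.10 bohr (typical fixture grids of 10–25 M voxels
integrate in seconds thanks to the separable analytic evaluation and the
compiled ascent kernel); density floor 1e−7; padding 2 bohr; envelope
iso 0.001.  At these settings, on 20 random fixtures, Σᵢ Nᵢ matches the
exact electron count to ≲1e−4 %, envelope volumes match closed forms to
≲0.1%, and mirror-image AEDs agree to ~1e−12 relative.  Oracle-equivalence
checks of the basin kernel run on coarse (≤40³) grids where the exhaustive
pure-Python walker is affordable.

## Known limitations

- WFX is the only wavefunction dialect (no WFN/fchk/molden); solvent-
  polarized WFX files are assumed to encode nothing beyond MO coefficients.
- No critical-point search, Laplacian maps, or interatomic surface meshes;
  the partition is purely grid-based.
- Midpoint quadrature without boundary weighting slightly staircases
  envelope volumes; halve the spacing when sub-0.1% volumes matter.
- Closed-form expectations require the well-separated regime; fixtures do
  not emulate covalent bonding, cusps, or real continuum-solvent physics.
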