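# Methods

This note documents the models implemented in `facetsolv`, the defaults
chosen where the method leaves room, and what the synthetic fixtures do
and do not establish.

## Crystal and face geometry

Crystals are triclinic cells with an asymmetric unit of rigid molecules
expanded by symmetry operators (read from CIF via gemmi, or constructed
directly).  Fractional coordinates are wrapped to [0, 1); molecules are
kept whole across cell boundaries by unwrapping each bonded atom to the
image nearest its bonded partner.  When a CIF carries no bond list,
bonds are perceived by distance: r < 1.2 × (sum of Cordero covalent
radii).  Atoms produced by different operators that coincide within
0.3 Å are merged (special positions); distinct atoms closer than 0.5 Å
raise a structure error.

Interplanar spacings come from the reciprocal metric,
d = 1/|h **b₁** + k **b₂** + l **b₃**|, and the reticular area — the
projection of one unit cell onto the face — from the slab-geometry
identity S·d = V, which holds for every face of every cell and is
enforced as a test invariant.

Molar masses use the IUPAC 2021 standard atomic weights bundled as a
data table (ibuprofen 206.28, ethanol 46.07, water 18.02, furosemide
monomer 330.74 g/mol); they are computed from composition and can be
overridden in configuration.

## Intermolecular energies

Rigid-molecule interaction energies are accumulated in three channels
(kcal/mol; favorable = negative):

* **van der Waals**: 12-6 form E = D₀[(R₀/r)¹² − 2(R₀/r)⁶] with
  geometric-mean combination for both R₀ and D₀.  The Dreiding family
  offers both exp-6 and 12-6 nonbonded forms; the 12-6 form is the
  default here because it has no catastrophic short-range attraction.
  Parameters ship as a CSV table users can replace bit-exactly.
* **Coulomb**: K·qᵢqⱼ/(εr) with K = 332.0637 kcal·Å·mol⁻¹·e⁻²
  (e²/4πε₀Å) and constant dielectric ε = 1 by default; a
  distance-dependent dielectric is available by flag.  Charges are an
  input contract (enriched CIF or sidecar CSV); a built-in
  element-level partial-equalization (Gasteiger-style) assigner is
  provided for convenience and is explicitly an approximation.
* **Hydrogen bond**: 12-10 well over the donor–acceptor distance,
  D_hb[5(R_hb/R)¹² − 6(R_hb/R)¹⁰]·cos⁴θ with θ the donor–H–acceptor
  angle, applied to typed donor-H···acceptor triples inside a 3.5 Å /
  90° screening window and attributed to the H···acceptor pair.
  Defaults D_hb = 9.5 kcal/mol, R_hb = 2.75 Å.  Workflows built on this
  potential family frequently leave the hydrogen-bond variant, charge
  scheme and dielectric unstated, so all of these are configuration,
  not fact; absolute energies depend on them, relative comparisons much
  less so.

No distance cutoff is applied inside a finite slab by default (all
pairs are summed); an optional cutoff exists for speed and is off in
validation runs.  Intramolecular terms are never computed — probes and
slab molecules are rigid.

## Surface slabs

A slab exposing (hkl) is a W×L×H supercell (default 3×3×2) built on a
unimodular re-basing of the lattice: two integer lattice vectors
spanning the (hkl) plane are found by extended-Euclid reduction, and
the third advances exactly one interplanar spacing along the normal.
The slab frame puts the outward normal on +X with in-plane fractional
coordinates (v, w).  Two interplanar spacings of thickness suffice for
probes that do not penetrate deeply; a warning is raised when the slab
is thinner than the largest molecule.

Termination: the cut plane defaults to the widest gap in the stacking
phases of molecular centroids along the normal — the cut severing the
fewest intermolecular contacts — and is exposed as a fractional offset
so alternative terminations (which matter when a face can expose
different functional groups) can be scanned.  Molecules are included
iff their centroid falls inside the slab region, which keeps them whole
and makes termination deterministic: the same crystal, face and repeat
always produce the identical slab.  There is no surface relaxation.

**Rugosity** has no single standard definition; the default here is
peak-to-valley height: the topmost atomic height is sampled on a
lateral grid over one reticular area (an atom counts toward a grid
point within a 1 Å lateral capture radius), and rugosity is max − min
of the sampled heights.  An externally determined value can be injected
unchanged, which decouples the rate model from this choice.

## Grid scan and rank statistics

The probe's principal axes are the eigenvectors of the unit-weight
gyration tensor of its atomic coordinates, ordered by descending
eigenvalue with deterministic sign fixing.  Poses enumerate planes
(1 Å apart, plane 1 anchored at the surface reference height, 8 planes
by default), lateral points over one central reticular tile (1 Å
equivalent steps by default; the in-plane step is not fixed by the
method and is configurable), and intrinsic rotations about the three
principal axes in 30° steps (12³ = 1728 orientations per point).
Symmetry-equivalent orientations of symmetric probes are deliberately
not deduplicated, matching raw pose counting; a per-grid-point-minimum
mode implements the alternative reading in which only the best
orientation per point counts.  The scan is exhaustive and
deterministic; overlapping poses (atoms closer than 0.1 Å) are skipped
and counted, never fatal.

Each pose with total energy at or below the cutoff (−2 kcal/mol by
default; per-probe overrides allow the weaker −1.5 kcal/mol used for
weakly interacting probes) becomes one interaction; the number of
records is the face's interaction rank.  The averaging window for the
surface interaction energy E_s is selected in (rank, energy) space by
intersecting two least-squares lines: the tail line through the final
5% of ranks, and the head line through the prefix [1..m] that maximizes
R², with m searched over [max(10, 1% of rank), 50% of rank].  The
"best line through the steep beginning" is under-specified in words;
the bounded R²-maximizing prefix is this package's contract for it.
When the lines are near-parallel (an "all-strong" curve with no
asymptotic tail) or intersect outside the curve, the head window m is
used with a warning.  E_s is the arithmetic mean of the selected
strongest energies.  Component percentages are 100·ΣE_c/ΣE_total over
the selected records (not the full record set — the choice that can
legitimately produce small negative percentages when a channel opposes
the total); computing them over all records is available as an option.

## Dissolution model

E_b(hkl) = Σ E/R over molecules toward the face (positive displacement
along the outward normal) whose pair energy stabilizes by at least
0.01 kcal/mol; the inclusion rule is "stabilizing at least the
threshold", since including only near-zero terms would defeat the
sum's purpose.  The lattice sum grows in cubic shells and stops when
the outermost shell's strongest pair energy falls below the threshold;
failure to converge raises an error carrying the residual.

E_d = E_s(solvent)/MW_solvent − E_s(solute)/MW_solute.  Molecular
weight is the normalization that best matches experiment among the
candidates (atom count, molecular volume, molecular weight); the
furosemide dimer probe is normalized by the monomer mass — the only
convention that reproduces the published differentials from the
published surface energies, recorded here as a numerically derived
convention.  Probes whose interactions all fall below the cutoff (water
on ibuprofen) are excluded from E_d.

E_b,mod combines the normalized binding energy, E_d, and the face
geometry.  No canonical functional form exists for this combination
(tabulated reference values do not determine one — factorization
attempts give face-inconsistent geometric factors), so it is a
configurable callable with default

E_b,mod = −(E_b/MW + E_d) · S_hkl · rugosity / V_cell,

a sign-positive form scaling the total stabilization by the
dimensionless exposed-roughness fraction of the cell; externally
determined E_b,mod values can be injected verbatim, and every
rate-ratio validation in this package's tests runs through injected
tabulated values, so the model validation does not depend on this
default.
Rate ratios R_rel,D(i,j) = E_b,mod,i/E_b,mod,j satisfy
R(i,j)·R(j,i) = 1 and are invariant to a common scale; the percent
discrepancy against experiment is 100·|pred − exp|/exp.

## Synthetic fixtures and what passing tests show

The toy generator produces three deterministic crystal families —
apolar (dispersion only), polar-pair (donor/acceptor, exercising the
hydrogen-bond channel) and grooved (a 1.5 Å corrugated top layer for
rugosity) — on P1 or P-1 lattices with optional seeded jitter, plus
single-atom, diatomic and O–H probes.  Fixture force-field types use
round numbers (R₀ = 3.0 Å, D₀ = 0.1 kcal/mol) so closed-form checks
are exact.  An independent brute-force oracle (plain nested loops, its
own pose enumeration and rotation code) re-computes entire scans on
these fixtures; production and oracle agree to better than 10⁻⁹
kcal/mol per pose.

The synthetic rank-curve generator emulates two-segment curves with
additive Gaussian noise; monotonicity after noising is restored by a
running maximum, which keeps perturbations local and preserves the
nominal segment slopes (a global re-sort would replace a near-flat tail
with the order statistics of the noise).  The two-line selection
recovers constructed breakpoints within 10% noiselessly and within 15%
in median over 50 seeded replicates at σ = 0.05 kcal/mol.

The slab edge-effect check compares central-tile pose energies between
3×3 and 5×5 slabs on a toy cell sized (a = 10 Å against a 3 Å vdW
radius) so the slab is wide relative to the interaction range, in
proportion with the molecular crystals the method targets; every
recorded pose changes by less than 2%.

Fixtures exercise code paths, not chemistry: passing tests demonstrate
that the geometry, energy kernel, statistics and model arithmetic are
implemented correctly, not that any particular force-field
parameterization reproduces absolute reference surface energies.  Full
reproduction of the reference scans additionally requires the licensed
crystal structures (CCDC IBPRAC and FURSEM03), per-face geometric
parameters, and the exact charge scheme and potential variant behind
the tabulated energies — none of which the tables themselves supply;
the rate-model validations in this package therefore run from the
tabulated energies.

## Problem sizes

Unit and acceptance tests run toy scans of a few hundred poses over
18–50-atom slabs (seconds on one core); the rank-statistics simulations
use curves of 1 000–6 000 points and 30–50 replicates.  These sizes were
chosen so every check is exhaustive rather than sampled.

## Known limitations

* Rigid probes and slabs only: no conformer search, no pose refinement,
  no solvation continuum, no surface relaxation or dipole correction.
* The scan's interaction rank counts every sub-cutoff pose by default;
  a per-grid-point-minimum mode is provided for workflows that count
  only the best orientation per point.
* The E_b,mod geometric combination is this package's own default, as
  discussed above.
* Absolute energies depend on charge assignment and hydrogen-bond
  parameters that the method's description leaves open; predictions
  should be treated as relative rankings.
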