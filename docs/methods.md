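# Methods

## Scope and conventions

All analysis operates on a planar bilayer whose normal is the z axis of a
rectangular periodic box.  Coordinates and box lengths are nanometres
(PDB files in angstrom are converted on read), times nanoseconds, energies
kJ mol⁻¹, charges elementary charges.  In-plane (x, y) distances always use
the minimum-image convention.  z is treated non-periodically for leaflet
and depth logic — the bilayer is bounded in z and a solvated membrane stack
never wraps a leaflet through the wall — but periodically for contact and
energy distances, where a peptide chain may straddle the box boundary.
Molecules are assumed whole; a validator rejects frames in which
consecutive atoms of one molecule are further apart than half the smallest
box length (a bond-free heuristic for wrapped molecules; no bond topology
is ever inferred).

## Bilayer centering and leaflets

The bilayer center is the midpoint between the mean phosphorus z of the two
leaflets, recomputed **per frame**.  Because the leaflet split itself
requires a center, the estimator bootstraps: split about the median
phosphorus z, then iterate the midpoint-of-means once.  The midpoint of
leaflet means (rather than the global phosphorus mean) is robust to unequal
leaflet populations.  A lipid is assigned to the upper leaflet iff its
phosphorus z is positive in the centered frame.  Centering is idempotent
and z-translation-equivariant; assignment is invariant under rigid in-plane
motion and whole-frame z shifts.

## Depth, z-displacement, thickness

The position of a residue is the z of its lowest atom; the insertion depth
of a chain is the time average, over the analysis window, of the z of its
deepest residue (positive = upper leaflet).  Head-group disorder is the
per-frame RMS deviation of a leaflet's phosphorus z about that leaflet's
own frame mean, time averaged — by construction invariant under
whole-leaflet translation, and equal to the jitter amplitude σ for
independent Gaussian displacements.  The thickness map grids the x-y plane
(default spacing 0.25 nm) and assigns each cell, per frame, the mean z of
upper-leaflet phosphorus atoms within a smoothing radius (default 1.0 nm,
minimum image in-plane) of the cell center minus the same for the lower
leaflet; cell values are averaged over frames where both leaflets
contribute.  Cells a leaflet never reaches are reported as missing, never
interpolated.  The smoothing radius and grid spacing are free parameters of
the estimator (exposed on the CLI); all lipids enter the reference, with no
exclusion of peptide-proximal lipids.

## Order parameters

S_CD = 0.5⟨3 cos²θ − 1⟩ with θ the angle between each C–H bond and +z,
averaged over both hydrogens of a carbon, the selected lipids and the
window frames; the bilayer normal is fixed at +z (the box is flat; no local
normal estimation).  The peptide-proximity filter keeps lipids with any
atom within 1.0 nm (minimum image) of any non-hydrogen peptide atom,
re-evaluated every frame so the selection tracks a diffusing peptide; with
no peptide the filter is vacuous.  Hydrogens are associated to tail carbons
by proximity (< 0.15 nm) once, on the first analysed frame.  For
united-atom chains the two C–H unit vectors of interior carbon Cᵢ are
rebuilt tetrahedrally: perpendicular components about the bisector of the
Cᵢ→Cᵢ₋₁ and Cᵢ→Cᵢ₊₁ directions, in and out of the local chain plane, with
half the H–C–H angle of 54.74°; chain-terminal carbons, which lack two
neighbours, are excluded from the profile.

## Contacts and association

An atomic contact is a non-hydrogen pair within 0.54 nm, **inclusive** —
"within" is read as ≤, a measure-zero choice fixed for reproducibility.
Region series use 1-based residue ranges (N-terminal 1–19, C-terminal
20–37 by default); asymmetric region pairs are counted in both chain
orders so the series is invariant under relabelling the chains.  The
monomeric criterion requires the minimum non-hydrogen inter-chain distance
(minimum image in all three dimensions) to exceed 1.4 nm in **every** frame
of the window; the minimum is taken over non-hydrogen atoms for consistency
with the contact definition.

## Energy decomposition

Per-residue peptide–lipid energies are truncated real-space pair sums:
electrostatic f·qᵢqⱼ/r (f = 138.935485 kJ mol⁻¹ nm e⁻²) with a 1.2 nm
cutoff, Lennard-Jones C12ᵢⱼ/r¹² − C6ᵢⱼ/r⁶ with a 1.4 nm cutoff, no
switching or shifting.  C6/C12 combine geometrically by default (the
GROMOS convention); Lorentz–Berthelot on σ/ε is available.  A mesh-Ewald
reciprocal-space energy cannot be attributed to residue pairs, so absolute
electrostatic magnitudes differ systematically from an Ewald total; the
reproducible output is the per-residue *ranking* (the +2-charged
N-terminal lysine dominates, then the arginine).  "Per lipid" divides by
all lipids in the system, not only interacting ones.  Water and ions are
excluded.  Both the residue-wise and the head/tail split are partitions of
the identical pair sum, so each conserves the whole-peptide total exactly
(machine precision); this is asserted, not assumed.

## Secondary structure

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal mol⁻¹ with
distances in angstrom and a bond iff E < −0.5; any distance under 0.5 Å is
treated as a clash (no bond).  Missing amide hydrogens are rebuilt 1 Å from
N along the preceding residue's C→O direction — the construction the
original DSSP program uses (we prefer it over an N-neighbour-bisector
placement because it maximises agreement with reference DSSP
implementations, against which the assigner is tested).  Two consecutive
i→i+4 turns mark an α-helix (H), i→i+3 a 3₁₀ (G), i→i+5 a π helix (I);
intra-chain bridges mark strand (E, simplified single-code ladders);
unassigned turn interiors T; CA-direction bends over 70° S; default coil.
Precedence H > E > G > I > T > S.  Bridges are intra-chain only — the
helical systems this package targets show no β structure, and inter-chain
sheets are out of scope.  Helix content is the per-frame percentage of
residues in {H, G, I} (a strict {H} mode is a flag), reported as mean ± sd
(population sd over frames).  First/last chain residues cannot satisfy the
two-turn pattern, so an ideal 37-residue helix scores 35/37 = 94.6%.

## The synthetic generator

The generator emulates the reference study conditions: an anionic
bilayer of 2×64 single-chain lipids (one phosphorus head atom at charge −1,
a 16-carbon ordered acyl chain) on a jittered rectangular lattice in a
5×7×9 nm box, phosphate planes at ±2.2 nm, and one or two 37-residue
amylin-sequence peptides built as ideal α-helices (φ = −57°, ψ = −47°,
standard backbone internal coordinates; CA–CA 0.380 nm, rise ≈ 0.15
nm/residue) with +1 side-chain pseudo-atoms on Lys1 and Arg11 and +1 on the
N-terminal amine (total +3, with +2 on residue 1).  Partial dihedral
windows build helix-in-coil conformations for planted helix-content
truths; the planted helical set is the dihedral window clipped at the
chain termini, validated against an independent DSSP implementation.

Frames are independent identically-distributed copies: each *molecule*
receives an independent rigid Gaussian displacement (σ default 0.05 nm per
coordinate) per frame.  Every metric here is a time average of a static
observable, so no integrator is needed; rigid-body jitter emulates
positional disorder (lipid protrusion, peptide diffusion) while preserving
internal geometry exactly — hence planted C–H angles, secondary structure
and contacts are stable under noise, which is what makes exact
planted-truth tests possible.  What the generator does **not** emulate:
conformational dynamics, chain disorder gradients along the tail, solvent
and counterions, sterics (lipids and peptide atoms may overlap, so van der
Waals magnitudes on peptide presets are non-physical; electrostatic
structure is meaningful), and area/volume fluctuations.  Passing tests
therefore demonstrate estimator correctness, not force-field realism.

Planted truths and their constructions:

* **Order parameters.** Explicit-hydrogen mode places two mirror C–H unit
  vectors at exactly the prescribed angle θ₀ to +z (default 63.435°, i.e.
  S_CD = −0.2, a typical fluid-chain magnitude).  United-atom mode omits
  hydrogens and tilts an all-trans zigzag by α with cos²α = 1 − 3 cos²θ₀,
  chosen so the tetrahedral reconstruction returns exactly θ₀; this is
  solvable only for θ₀ ∈ [54.74°, 125.26°] (a CH₂ reconstruction cannot
  point both hydrogens near the normal), enforced with an error.
* **Thickness.** The upper phosphate plane is optionally depressed by a
  Gaussian dimple (amplitude 0.8 nm, width 1.2 nm in the dimer preset; the
  whole lipid shifts rigidly).  The ground-truth field is the smoothing
  kernel evaluated analytically on the noise-free planted lattice — the
  exact expectation of the estimator under jitter.  The pointwise
  continuous dimple is *not* the reference because a 1.0 nm-radius local
  average provably attenuates a 1.2 nm-wide Gaussian by ~20% at its
  center; the planted truth is the smoothed field, computed independently
  of the estimator code path.
* **Contacts.** The contact dimer is a V-shaped pair: C-terminal ends
  0.5 nm apart (axis to axis), N-terminal ends splayed by 10° in-plane
  and separated in z, so planted contacts exist only in the 20–37 region
  (verified on the clean frame by a naive double loop, stored as truth).
* **Depth / center / leaflets.** Per-residue minimum z, the lab-frame
  bilayer-center offset and leaflet labels are recorded exactly from the
  clean configuration.

Preset geometry: `1mono` places the single helix nearly in-plane (tilt
10°) with the deepest (N-terminal) residue at +1.5 nm — the charged
N-terminus 0.7 nm below the phosphate plane, inside the electrostatic
cutoff, mirroring the lysine-anchored binding mode; `dimer1` has chain A
traversing to the lower phosphate plane (deepest residue −2.0 nm, tilt
25°) with chain B near the midplane, plus the thinning dimple under the
dimer; `2mono` is two `1mono`-like chains ≥ 2.5 nm apart; `pure` has no
peptide.  All presets keep 2×64 lipids (the generator does not remove
sterically overlapping lipids, so lipid counts do not vary between
presets).  Default trajectories are 51 frames at 3 ns spacing (a 150 ns
span), analysed over the protocol windows: last 50 ns for depth, energies,
z-displacement and helix content; last 20 ns for order parameters.

## Numerical and design choices

* Thickness/grid defaults (spacing 0.25 nm, radius 1.0 nm) balance map
  resolution against per-cell sample count for ~64 lipids per leaflet; both
  are CLI-exposed.
* File round trips through GRO retain 0.001 nm precision; exact
  planted-truth tests therefore run on in-memory trajectories, file-based
  tests at 6×10⁻⁴ nm tolerance.
* The analysis report embeds its configuration, input SHA-256 checksums and
  the package version, and contains no timestamps: rerunning a
  configuration reproduces the report and all metric tables byte for byte.
* Error handling favours loud failure (missing parameters name the atom;
  empty leaflets, empty windows and overlapping selections raise) except
  inside the orchestrator, where one failed metric is recorded with its
  reason and the rest continue.

## Known limitations

* Flat-normal assumption: all angular quantities use +z; strongly curved
  or undulating membranes need local-normal estimation this package does
  not provide.
* The Kabsch–Sander assigner simplifies DSSP's ladder bookkeeping (no
  B vs E distinction, no inter-chain sheets); agreement with reference
  DSSP is asserted at ≥ 95% on helix and extended fixtures, not on sheets.
* Electrostatics are truncated real-space sums; absolute energies are not
  comparable to Ewald-based totals.
* The generator's i.i.d. frames carry no autocorrelation, so error bars
  estimated from its trajectories understate those of real MD.
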