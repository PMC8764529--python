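# Methods

This note records the models implemented in cofkit, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Coordinate handling and binding-site geometry

PDB input is parsed through gemmi after a fixed-column pre-validation
pass that reports the 1-based line number of any malformed ATOM/HETATM
record. Only the first MODEL of a multi-model file is kept. Alternate
locations are resolved to the highest-occupancy conformer; exact ties go
to the earliest alt-loc letter (A before B). This is deterministic and
matches common practice. Output via `write_pdb` round-trips coordinates
to the PDB format's three decimals (max error < 5×10⁻⁴ Å) and
occupancies to two.

**Planes.** An sp2 group's plane is the total-least-squares plane: the
normal is the singular direction of smallest variance of the centered
member coordinates, and `rms_residual` is the RMS point-to-plane
distance. Collinear or coincident member sets are rejected rather than
silently fitted. Plane residuals and out-of-plane distances are
rigid-motion invariant to 10⁻⁹ Å (property-tested).

**Hydrogen bonds.** The deposited structures in this enzyme family are
typically at ~2.4 Å resolution without reliable hydrogen positions, so
H-bonds are defined on heavy atoms only: one N/O atom in the ligand, one
in the protein or a water, with donor–acceptor distance in a 2.4–3.5 Å
window by default. No angular criterion is applied; H-bond quality is
instead characterized by the out-of-π-plane distortion, the distance of
the partner atom from the plane of the sp2 group it bonds to. Carboxylate
groups are found geometrically (a carbon with exactly two oxygens within
1.4 Å plus an attached carbon within 1.75 Å; the plane uses all four
atoms). Peptide-amide planes use {CAᵢ, Cᵢ, Oᵢ, Nᵢ₊₁} for a carbonyl-O
partner and the preceding residue's {CA, C, O} plus the N itself for an
amide-N partner; chain termini that lack flanking atoms simply carry no
plane. When the ligand side belongs to a carboxylate, that plane takes
precedence and the protein atom is the measured partner. Donor/acceptor
labels are a convention on heavy atoms (a lone N donates; for O···O
pairs the protein/water side is labelled donor); detection and the
distortion statistic are symmetric in the labelling.

**Contacts.** The contact table reports every protein-atom/ligand-atom
pair within 4.0 Å (default), plus bridged contacts through a water
oxygen or Mg²⁺ within 3.5 Å of both sides; a bridged record's distance
is protein-atom→bridge. Cutoffs are exposed as CLI flags since published
interaction tables in this family do not state theirs. Contacts are
averaged over all chains containing the ligand; a contact present in
only some chains is averaged over those, with the per-chain listing
retained. Output ordering is (residue number, protein atom, ligand
atom), deterministic. Contacts within one chain only are considered —
each protomer binds its own ligand in the structures this targets.

**Superposition.** Kabsch via SVD with the determinant correction, so
reflections are excluded. Near-collinear point sets are solved but
flagged unstable with a warning. The optimum is property-tested against
1000 random rigid motions and cross-checked against an independent
library solver.

**Carboxylate rotation.** Given two poses in a common frame, the axis is
the O→O direction of the two carboxylate oxygens, sign-aligned and
averaged between the poses; the angle is measured between the
projections, onto the plane normal to that axis, of the vectors from the
O–O midpoint to a reference atom (default C2, the carbon bonded to the
carboxylate). The result is unsigned in [0°, 180°]. A reference atom
within 10⁻⁶ Å of the axis is rejected as degenerate. Group displacement
is the plain Euclidean distance of one named atom between poses, which
for a pure axis rotation equals the chord `2r·sin(θ/2)` (tested).

**Metals.** For each ion of the requested element, all N/O atoms within
the coordination cutoff (default 2.8 Å) are listed with distances,
categorized as protein / ligand / water, sorted by distance.

## Alignment screening

Alignments are consumed (aligned FASTA or Clustal), never computed;
`.` gaps are normalized to `-`, residue numbers and columns are 1-based.
Needleman–Wunsch uses linear gap scoring with deterministic tie-breaking
(diagonal, then gap-in-second, then gap-in-first) and defaults
match +1 / mismatch 0 / gap −1: the goal is identity measurement between
close homologs, not remote-homology detection, so no substitution matrix
is offered. Percent identity counts columns where both rows agree on a
residue, over columns where at least one row has a residue — for
near-identical sequence pairs this choice is insensitive, and it is the
documented, tested convention. The diagnostic screen calls Ser/Thr in
the target column tolerant, a gap indeterminate, anything else
non-tolerant; the tolerated set is overridable.

## Assay quantification

Peak areas are trapezoidal integrals of the XIC inside a per-species
retention-time window, after subtracting the straight baseline through
the first and last in-window points (toggleable; it cancels constant or
linearly drifting background and leaves a noiseless Gaussian peak's area
essentially unchanged).

Normalization needed one design decision. Normalizing each time point's
areas by that time point's species total would make every normalized
time course constant in time (the ratio `kₛt / Σkⱼt` has no slope), so
slope-based rates would degenerate. The pipeline therefore applies **one
denominator per replicate** — the summed AUC over the whole time course,
either across all product species (mode `total`) or of a named reference
species such as the FO core supplied at fixed input (mode `reference`).
This rescales each replicate uniformly, preserves the time structure,
and makes the fitted rate *ratios* — hence the turnover percentages —
invariant to the mode and to any uniform intensity rescaling (tested).
The standalone `normalize_area` function keeps snapshot semantics
(divide a species→area map by its total or by the reference entry).

Rates are ordinary least-squares slopes over the linear 0–20 min range
(inclusive endpoints; later, saturating points are excluded). Relative
turnover per replicate is `rᵢ = 100·kᵢ/Σⱼkⱼ` after clamping negative
slopes to zero with a warning (a replicate with all-zero rates is an
error, not a silent NaN). Reported statistics are the arithmetic mean
and sample SD (ddof = 1; 0 for a single replicate).

## Thermal-shift binding

The two-state model uses van 't Hoff ΔG with ΔCp = 0 by default
(`delta_cp` is opt-in), ligand in large excess (free ≈ total), R = 8.314
J mol⁻¹ K⁻¹, temperatures in K internally with °C accepted on CSV input.
The observable is two linear baselines mixed by f_u. For protein that
co-purifies with a fraction φ of tightly bound product, the observable is
modeled as the φ-weighted mixture of a product-loaded subpopulation —
stabilized by the stoichiometric product pool, [GPPG] = φ·[P] — and the
remainder titrated by the GTP series. The exact parameterization used in
published supplementary fits of this kind is not always stated; this
model is the minimal standard one and is stated explicitly rather than
guessed.

Fitting is trust-region least squares over shared (T_m, ln ΔH_u, ln K_D)
plus four baseline parameters per curve, with multistart initialization
(default 8 starts; T_m spread ±10 K around the apo transition located by
the steepest smoothed slope, K_D log-spaced 10⁻⁷–10⁻³ M and seeded-
shuffled). Curves indistinguishable from a straight line (residual
amplitude below 10× the second-difference noise estimate) are rejected
as transition-free; apo-only input returns a result flagged
"K_D unidentifiable" rather than a spurious number. Confidence intervals
are linearized (Jacobian-based, 95%). The feasibility grid refits
thermodynamics and baselines at each fixed (φ, K_D,GTP, K_D,GPPG) and
keeps points with RSS ≤ min·(1+threshold); at φ = 0 the surface is flat
along the K_D,GPPG axis by construction, and the minimum is always
feasible.

## Synthetic data

Each generator takes a spec dataclass with a mandatory seed and draws
from a single `numpy.random.default_rng(seed)` stream, so identical
specs reproduce byte-identical outputs.

- **Pockets**: an idealized planar carboxylate (1.25 Å C–O, 120°,
  1.52 Å C–C; optionally extended with a schematic glycerate/diphosphate
  arm) with donor nitrogens placed at exactly the planted out-of-plane
  offsets and in-window heavy distances (default 2.9 Å, inflated when a
  large offset demands it; offsets ≥ 3.45 Å are rejected as infeasible).
  Mg²⁺ sites sit > 10 Å away with exact octahedral 2.1 Å water shells so
  they cannot contaminate the planted H-bond set. Chain A is exact;
  further chains are 60 Å translated copies with optional Gaussian
  jitter, so planted truths refer to chain A.
- **Ligand pairs**: an exact rotation of the base pose about the O–O
  axis; truth records the folded angle and per-atom displacements.
- **Homolog sets**: i.i.d. substitutions at the chosen rate outside the
  diagnostic position, the diagnostic residue forced to each planted
  label, and seeded single-residue deletions/insertions shaping the true
  alignment. Truth records the diagnostic column and the S/T-rule labels.
- **Assay runs**: per replicate/time/species, a Gaussian peak whose area
  is `rate · min(t, t_sat)` with multiplicative noise of the chosen CV
  (defaults: rates 0.65/0.265/0.085 for 3-PG/2-PL/PEP, five time points
  over 0–20 min, saturation after 20 min, 2% CV, three replicates —
  matching a competitive specificity assay read in triplicate). All
  species share one peak width and sampling density, so quadrature error
  cancels exactly in area ratios; m/z targets and retention times are
  arbitrary fixed instrument-like constants.
- **Melting curves**: the forward model plus Gaussian signal noise
  (defaults T_m 320 K, ΔH_u 300 kJ/mol, K_D 10 µM, 10 µM protein,
  0.5 K steps over 293–363 K, a seven-point 0–200 µM titration).

What the generators do **not** emulate: real chemistry (no force-field
geometry, no realistic mass spectra or isotope patterns), alignment
uncertainty (classification tests supply the true alignment, so they
validate the rule and the column mapping, not an aligner), instrument
preprocessing (350/330 nm ratioing, scattering), or biological replicate
structure beyond i.i.d. noise. Passing tests therefore demonstrate
correctness of the computational chain on known ground truth, not
robustness to every artefact of real data.

## Problem sizes and tolerances in the test suite

Oracle tests compare against naive re-implementations: O(n²) double
loops for H-bonds/contacts/metal shells on 100 seeded pockets, memoized
recursion for alignment scores on 8-mers, fine-grid quadrature for peak
areas, closed-form OLS for rates, and 1000 random rigid motions for the
superposition optimum. Stochastic recovery tests use 3 seeded triplicate
assay datasets at 2% noise (recovery within 2 percentage points;
noiseless recovery within 0.1), and 50 seeded melting titrations at
~1% signal noise on a 1 K temperature grid with 4 multistarts (K_D
within 2× truth in ≥ 90% of runs; noiseless recovery within 1%). Exact
geometric constructions are asserted at 10⁻⁶–10⁻⁹ absolute tolerance.
The deposited-structure and published-sequence checks fetch from
RCSB/NCBI at run time and fail when those services are unreachable.

## Known limitations

- PDB only; no mmCIF, electron density, refinement, electrostatics or
  docking.
- The H-bond donor/acceptor assignment is a heavy-atom heuristic and
  should not be read as a hydrogen-position inference.
- Contact bridging considers single water/Mg²⁺ intermediates only.
- The DSF model assumes ΔCp = 0 by default and free-ligand ≈
  total-ligand; strongly sub-stoichiometric titrations would need the
  protein-concentration correction it does not implement.
- Percent identity depends mildly on the alignment and denominator
  convention; the implemented convention is stated above and the
  pairwise aligner's tie-breaking is deterministic, so results are
  reproducible but may differ from other tools by fractions of a point.
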