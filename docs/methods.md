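# Methods

This note defines the models implemented in `qnsmech`, the default
parameters, and the numerical choices behind them.  Defaults live in
`qnsmech.pipeline.PipelineConfig`; every one can be overridden per call or
through the TOML run configuration.

## Active-site cluster model

A finite cluster is carved from the full structure by keeping every
residue that has at least one heavy atom within the inclusion radius
(default **12.0 Å**) of any heavy atom of the catalytic residue;
`from_atom` restricts the reference to a single atom (e.g. the thiolate
sulfur).  Inclusion is all-or-nothing per residue, so no residue is ever
split.

Truncation creates backbone discontinuities.  Each is neutralized with a
hydrogen cap placed along the severed bond vector: a residue whose
source-chain predecessor was removed gets an H on its backbone nitrogen at
1.01 Å (neutral amine), and one whose successor was removed gets an H on
its backbone carbonyl carbon at 1.09 Å (aldehyde).  Cap positions are
derived from the excised neighbour's coordinates in the source structure;
if a cap would land within 0.8 Å of an existing atom it is displaced along
the bisector.  Original atom coordinates are never modified.

Atoms are partitioned for constrained optimization: backbone atoms
(N, CA, C, O, OXT) and side chains of non-reactive residues are **rigid**;
the ligand, the caps and the side chains of declared reactive residues are
**mobile**.  Ligand truncation (`truncate_ligand`) keeps a named atom
subset and caps severed covalent bonds (heavy-atom pairs closer than
1.85 Å) with hydrogens at element-specific bond lengths
(N–H 1.01, C–H 1.09, O–H 0.96, S–H 1.34 Å).

## Constrained reaction-coordinate scan

The reaction coordinate is the distance between one reacting atom pair.
The schedule steps from the start distance toward the covalent target in
**0.4 Å** coarse steps while still more than **1.0 Å** (switch offset)
above the target, then **0.1 Å** fine steps, ending exactly at the
covalent target (C–S default **1.81 Å**).  At each step the mobile atoms
are relaxed under the distance constraint: an L-BFGS-B minimization
alternated with an exact projection of the reacting pair onto the
constraint surface, seeded from the previous step's geometry.  Rigid atoms
are restored bitwise after every iteration.

The transition state is the profile maximum, refined by one bisection pass
at half the fine step, so the reported barrier position is resolved to
0.05 Å.  Activation energy is E(TS) − E(first point); reaction enthalpy is
E(last) − E(first).  `compare_profiles` tabulates labelled profiles sorted
by activation energy.

Energy backends are pluggable through a two-method protocol.  Included:
an analytic pair-potential backend (Morse and avoided-crossing forms) and
an external-program adapter that writes an input deck, invokes a
configured executable and parses the final heat of formation; the adapter
raises immediately if the executable is absent.

The synthetic scan generator plants a barrier by coupling two harmonic
diabats through a constant off-diagonal term W, giving the lower adiabat
E(d) = ½(E₁+E₂) − √(¼(E₁−E₂)² + W²).  The product-side curvature and W
are drawn from deliberately soft ranges (k₂ ∈ [6, 10] kcal/mol/Å²,
W ∈ [12, 18] kcal/mol) so the barrier-top curvature stays below roughly
80 kcal/mol/Å², which is what a 0.05 Å position resolution needs to pin
the height within 0.1 kcal/mol.  The reactant-side force constant and the
diabat offset are solved so the planted height and position are exact
stationary properties of the adiabat, then verified against a dense-grid
scan (±0.05 kcal/mol, ±0.02 Å) before the fixture is returned; infeasible
requests raise with diagnostics rather than silently shifting the truth.

## Surface sampling and contact mapping

Atomic surfaces are sampled with a deterministic golden-spiral point set
(default **960 points per atom**, minimum 92) on probe-expanded spheres
(Bondi van der Waals radii).  A point is buried if it falls strictly
inside any other atom's expanded sphere (Shrake–Rupley); each surviving
point carries an equal area weight.  A lone atom's area converges to the
analytic 4π(r+probe)² within 1 % at 960 points.

Contact mapping uses a **1.5 Å** probe on the substrate surface.  Each
exposed surface point is assigned to its **nearest** receptor atom, and
counted only if that atom lies within the **3.0 Å** proximity cutoff;
nearest-atom assignment makes per-residue areas an exact partition of the
counted surface (no double counting).  Per-residue areas are classified
none (0), minor (< **0.5 Å²**) or major (≥ 0.5 Å²).  `contact_trace`
tabulates areas and classes across labelled reaction states.

Mutation screening applies analytic side-chain edits: deletions
(Leu→Ala/Val, Ser→Gly, Val→Ala, Thr→Ser), a methyl addition placed
tetrahedrally at 1.52 Å opposite the mean of existing bond vectors
(Ser→Thr, Leu→Ile), and Asn→Ser, encoded as deleting the amide and
renaming the remaining γ-carbon position to a hydroxyl oxygen so the edit
stays a pure atom-set operation.  Pure deletions can only shrink the
mutated residue's own contact area, a property the tests enforce for every
supported shrinking edit.

## Interface metrics

Solvent-accessible surface area uses a **1.4 Å** water probe (distinct
from the 1.5 Å contact probe).  Buried interface area per protomer is
(SASA(A) + SASA(B) − SASA(AB)) / 2.  Pairwise inventories across the
interface:

- **salt bridges**: Asp/Glu carboxylate O to Lys/Arg/His side-chain N at
  ≤ **4.0 Å**, one minimum-distance bridge per residue pair;
- **hydrogen bonds**: N/O donor–acceptor pairs at ≤ **3.35 Å**, with a
  D–H···A angle ≥ 90° enforced when an explicit donor hydrogen (within
  1.3 Å of the donor) is present;
- **nonbonded contacts**: heavy-atom pairs at ≤ **3.9 Å**, excluding pairs
  already counted as hydrogen bonds;
- **polar contacts** (ligand–protein): N/O/S pairs at ≤ **3.5 Å**.

The dimer fixture plants each category at margin-separated distances
(3.95 Å bridges, 2.90 Å hydrogen bonds, 3.70 Å C–C contacts on a jittered
grid, decoys at 5.5 Å) so all three counts are recovered exactly at the
default cutoffs and no planted pair leaks into another category.

## Binding kinetics

Sensorgrams follow the 1:1 Langmuir model: association
R(t) = R_eq (1 − e^{−(k_a C + k_d) t}) with
R_eq = R_max C / (C + K_D), and exponential dissociation from the
association endpoint.  Fitting is a global nonlinear least-squares
(Levenberg–Marquardt) over all curves simultaneously, parameterized in
log(k_a), log(k_d), log(R_max) to keep rates positive and the problem
well scaled.  Standard errors come from the Jacobian at the optimum via
the delta method.  **K_D is reported as k_d / k_a exactly**, never fit as
an independent parameter.  A single-concentration fit carries a warning,
since one curve constrains k_obs = k_a C + k_d but separates the rates
poorly.

## Determinism and fixtures

Every stochastic routine takes an explicit seed; sub-seeds are derived
through `numpy.random.default_rng` draws bounded below 2³¹.  Fixture
generators return a manifest (seed, kind, planted truth) alongside the
structures, and rerunning any generator or the full pipeline with the
same configuration reproduces outputs byte for byte.  The pipeline stamps
each JSON report with a 16-hex-digit SHA-256 hash of the sorted
configuration, so provenance of a result directory is checkable from the
files alone.
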