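# Methods

This note records the models implemented in `linkgag`, their assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Oligosaccharide geometry

Monosaccharides (GlcUA, GlcNAc, GalNAc) are rigid idealized ⁴C₁ chairs:
ring atoms on a hexagon of radius 1.45 Å with ±0.25 Å alternating pucker,
heavy-atom substituents placed along idealized axial/equatorial directions
(β-anomeric O1 equatorial; O4 equatorial for the gluco series, axial for
GalNAc — the only atom that differs between the two HexNAc templates).
Hydroxyl hydrogens are not modeled; restraints and contact analysis use
heavy atoms, and the N-acetyl methyl carbon (C8) carries the hydrophobic
pocket restraint. Bond lengths are literature-standard (C–C 1.52, C–O
1.41–1.42, C–N 1.45 Å).

Chains are built non-reducing → reducing (ring 1 = non-reducing terminus).
The glycosidic oxygen position is defined by the donor's anomeric O1; the
acceptor template is rigidly superposed so its O3/O4 lands exactly there
while Φ and Ψ are realized by natural-extension-reference-frame placement of
the acceptor's Cx and C(x+1). Because the three-point correspondence matches
the template's internal distances exactly, the superposition is exact, so

* builds realize requested torsions to < 10⁻⁶° (round trip
  build → measure);
* intra-ring geometry is invariant under any torsion change;
* the glycosidic C1–O bond length always equals the template value, which
  is why the model filter's "distorted bond" check (deviation > 0.05 Å) can
  only fire on structures re-read from disk or produced by other tools.

Dihedral convention (stated in all outputs and checked against map
headers): Φ = O5(i)–C1(i)–Og–Cx(i+1), Ψ = C1(i)–Og–Cx(i+1)–C(x+1)(i+1),
heavy atoms only, x = 3 for β1,3 (donated by GlcUA) and x = 4 for β1,4
(donated by a HexNAc). Angles live in [−180°, 180°).

Hybrid naming caveat: `HA4C4` carries chondroitin at its **non-reducing**
end (GalNAc at rings 2 and 4) and `C4HA4` the reverse; the name reads
reducing-end-first. The parser documents this prominently rather than
inferring from the string order, because the two readings are easy to
confuse.

## Φ/Ψ maps

Each linkage type carries a periodic energy grid over [−180°, 180°)²
(default spacing 10°), normalized so the global minimum is 0, interpolated
bilinearly with wraparound. A linkage is *favored* when its energy is within
a cutoff of the minimum; default cutoff 4 kcal/mol — two contour intervals
of a 2 kcal/mol contour spacing, on the reasoning that a torsion "well
outside" the preferred region is more than one contour away. The cutoff is a
CLI flag and a function argument; model acceptance is the conjunction over
linkages, so raising the cutoff can only enlarge the accepted set.

The molecular-dynamics surfaces this screening emulates are not
redistributable, so the bundled defaults are smooth two-basin surrogates
(periodic Gaussian wells on a 10° grid; primary basins at (−80°, −120°) for
β1,3 and (−80°, −110°) for β1,4, secondary basins ~3 kcal/mol shallower).
They are explicitly approximations: any quantitative screening decision
against experimental data should use user-supplied grids in the documented
text format (3-line header: linkage, spacing, convention; then the matrix).
No test asserts the defaults' absolute energies.

## Complex modeling

The receptor is rigid throughout (its coordinate array is write-protected;
a checksum test verifies no operation mutates it). The ligand has
7 × 2 torsional plus 6 rigid-body degrees of freedom.

Restraints are flat-bottomed quadratics:

* **Ring stacking** — zero when the sugar-ring/receptor-ring centroid
  distance is ≤ target *and* the ring-normal angle is ≤ 30°; otherwise
  k·(d − target)² + k_ang·(Δangle in rad)², k = 1 kcal/(mol·Å²),
  k_ang = 10 kcal/(mol·rad²). The His45/ring-1 stack uses target 3.5 Å;
  the Tyr59/ring-5 and Tyr78/ring-6 stacks use 4.0 Å.
* **Distance upper bounds** — k·max(0, d − bound)². Ring-4 N-acetyl methyl
  carbon to Ile61 CD1: bound 4.5 Å (a typical CH₃···CH₃ hydrophobic
  contact; no value is reported, so this is a configurable design choice).
  Lys11 NZ/ring-3 carboxylate and Arg81 NH1/ring-7 carboxylate: 4.0 Å.
  Tyr12 OH/ring-4 O4: 3.5 Å.

The modeling set is `groove_restraints()` (the interactions the original
binding model was built on) plus `refinement_restraints()` (the two new
ones: the His45 stack and the Ile61 methyl bound). Encoding the prior groove
interactions as restraints is the package's reading of "built as before,
plus two extra restraints": with only the two new restraints the objective
is flat once they are satisfied and the chain tail is unconstrained, which
is physically wrong for a groove binder and was rejected during design. A
generic surface-complementarity reward was also tried and rejected: against
a sparse synthetic receptor it rewards shallow interpenetration (the
quadratic clash penalty has zero gradient at the steric boundary) and
degrades the ensemble.

**Clash model.** A receptor/ligand atom pair clashes when
d < scale·(r_i + r_j) with scale 0.7 and standard vdW radii (C 1.70, N 1.55,
O 1.52, S 1.80 Å); the penalty is the quadratic overlap sum and pairs that
participate in a restraint are excluded. Neighbor search uses a k-d tree;
a brute-force all-pairs oracle cross-checks the counts in the tests.

**Annealing.** Objective = restraint energy + 10 × clash penalty + Σ map
energies. Seeded Metropolis annealing (800 steps, geometric cooling
2.0 → 0.01) perturbs one random torsion pair (σ = 8°) or the rigid frame
(σ = 3° rotation, 0.3 Å translation) per step, tracking the best state,
followed by a Powell polish (≤ 3000 evaluations). Numerical choices that
matter:

* *Initialization* — a Kabsch fit of ligand anchor points onto receptor
  restraint targets, one candidate per stacking-normal side (the binding
  face is unknown a priori), each refined by a rigid-only Powell pre-fit of
  the smooth restraint term; the best candidate under the full objective
  starts the anneal.
* *Clash margin* — the optimizer scores clashes at 1.05 × the filter scale
  so finished models clear the acceptance boundary instead of resting
  exactly on it (the quadratic penalty has zero gradient at the limit).
* *Fallback* — if the annealed basin fails the acceptance rules, a second
  polish from the initial pose runs and the better endpoint is kept.
* Determinism: a fixed seed reproduces the trajectory and final model
  bit-for-bit.

**Filtering.** A model is accepted iff every glycosidic bond length is
within 0.05 Å of template (the torsion-space stand-in for "distorted
bonds", see above), the residual clash count is zero, the restraint energy
is below 0.1, and every linkage is favored on its map. Rejections carry a
reason (seed, rule) in a TSV report. Acceptance is monotone in both the
clash scale and the Φ/Ψ cutoff. Ensemble size defaults to 20, cycling the
members of a multi-model receptor file.

**Contacts.** A ring contacts the protein when any of its heavy atoms is
within 4.0 Å (configurable) of any receptor heavy atom. On the synthetic
receptor the refined ensemble's modal contact count is 7 of 8 rings (the
reducing-end ring carries no groove feature and hangs free).

## CSP and register inference

Peak lists are whitespace-delimited Sparky-style text (label, w1 = heavy
nucleus, w2 = ¹H). Δδ = complex − reference per matched label; a dimension
is significant when |Δδ| strictly exceeds its threshold (defaults 0.05 ppm
for ¹H, 0.20 ppm for ¹⁵N; a value exactly at threshold is not significant).
Unmatched labels are reported, and Δδ is antisymmetric under swapping the
two lists.

The groove model and reporter rules are in the README. Two inference
details: a register whose predicted class for some reporter is
*unclassified* (no predicate holds, e.g. Ala49 for a short oligomer ending
mid-groove) imposes no constraint for that reporter — this is how the
distinct short-oligomer peaks are handled without guessing their cause; and
observed classes that no candidate can produce are returned as *uncovered*
rather than silently dropped, so noisy panels degrade loudly. Exchange
between co-selected registers is not modeled; they are reported as
coexisting. The overhang (≤ 2 per end) and occupancy (≥ 4 in groove) rules
are the loosest consistent with all the reported register assignments
(dual registers of the 10-mer need overhang 2; the 4-mers need 4-ring
occupancy); both are configurable on `GrooveModel`.

## ITC

One site, N equivalent sites per protein. Volume bookkeeping uses a
*growing active volume*: cell solutes are conserved and each injection
(5 µl default, 26 injections) dilutes the cell while adding syringe ligand.
This choice (over an overflow model, which ejects bound complex and breaks
the identity by ~0.4% under the standard protocol) makes the saturating
cumulative heat equal N·ΔH·(protein moles in the cell) to numerical
precision, a limit the tests check at 0.1%. The complex concentration uses
the subtraction-free quadratic root, stable at arbitrarily large K_b.
Defaults: cell volume 1.4 ml (the instrument-nominal value; not reported),
0.015 mM cell protein, 0.24 mM syringe ligand, 298.15 K,
R = 1.9872 × 10⁻³ kcal·mol⁻¹·K⁻¹.

Fitting: least squares over (N, log₁₀K_b, ΔH) via lmfit, blank series
subtracted point-wise first, first-injection discard available but off by
default. Starting values: N = 1, ΔH from the total evolved heat against the
cell protein content, and log₁₀K_b scanned over {3, 4.5, 6, 7.5, 9} with
the best initial residual kept — the scan costs little and removes the
classic c-curve initialization failure. Non-convergence (or a residual RMS
above half the signal) flags the result; it is never raised silently.
Reported uncertainties are fit covariance errors, labeled as such — the
published table mixes per-experiment standard errors and fit errors by row,
so no attempt is made to match printed uncertainties.

Derived columns: ΔG = −RT ln K_b at 298.15 K, TΔS = ΔH − ΔG (an arithmetic
identity, checked to 10⁻¹²), percent = 100·K_b/K_b(reference) printed at
one decimal below 100 and as a whole number at or above 100. Two caveats
the reproduction report makes visible instead of hiding: printed ΔG values
derive from per-experiment averaging and can differ from −RT ln(mean K_b)
by ≲ 0.1 kcal/mol, and two percent cells (91.4, 20.2) round from unrounded
K_b values and differ by 0.1 from the recomputed column.

## Synthetic data: what it emulates and what it does not

The **receptor fixture** is a deliberately non-physical scaffold: only the
groove anchor side chains (His45 imidazole, Lys11/Lys63/Arg81 terminal
groups, Tyr12/Tyr59/Tyr78, Ile61, the Cys47–Cys68 sulfur pair), placed
around a reference HA₈^AN conformer built at the surrogate-map minima.
Anchor directions maximize clearance from the rest of the ligand
(deterministic Fibonacci-sphere search), so the reference pose has zero
restraint energy, zero clashes, and rings 1–7 (not 8) in contact. There is
no backbone, no groove wall, and no electrostatics: passing the modeling
tests shows the optimizer recovers a pose known to satisfy the restraints,
not that the method would find the right pose on a real protein. A real
multi-model PDB receptor drops in anywhere the fixture is used.

**CSP panels** invert the inference logic: each reporter's complex peak
sits at a class-canonical position (class offsets are fixed constants
≥ 5 × threshold apart, so classes are unambiguous at zero noise;
dual-register species emit one peak per distinct class; unclassified
reporters stay at the free position). Zero-noise panels therefore
round-trip exactly — by construction, a property test of the logic, not
evidence about real spectra, where class positions are not known a priori.

**ITC series** are simulated from the reported panel parameters under the
published protocol; the blank is a constant dilution heat. All generators
are seed-deterministic.

## Problem sizes

The test suite anneals one 20-model HA₈ ensemble on the fixture receptor
(plus a handful of short-schedule models) and fits 100 noisy titration
replicates; the acceptance script fits one titration and enumerates one
register problem. These sizes match the study design (20-member ensemble,
26-injection titrations) and run in minutes on a single CPU.

## Known limitations

* Ring pucker, exocyclic ω rotamers, solvation and electrostatics are out
  of scope; salt bridges appear only as distance restraints and reported
  contacts, not as energy terms.
* The torsion-space objective is a declared reinterpretation of the
  original Cartesian restrained-minimization protocol, which is not fully
  recoverable from its description; the published 20 → 10 model split is
  therefore not a reproduction target, only the filter's properties are.
* Default Φ/Ψ maps are surrogates (see above).
* The one-site fit assumes identical independent sites; dual-register
  binders violate this and their fitted K_b is an occupancy-weighted
  average, as the reported table itself notes for the affected rows.
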