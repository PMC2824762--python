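# Methods

## Scope and model

The package analyses the geometry of DNA passing through a sliding
clamp and the biochemistry used to probe it. Its computational core is
four procedures:

1. **Ideal B-form duplex construction.** Duplexes are built on a
   straight helical axis (+z, base pair 1 at z = 0) from canonical
   fiber parameters: rise 3.38 Å/bp and twist 36.0°/bp, both
   configurable. Internal base and sugar geometry comes from a single
   embedded idealized heavy-atom template per deoxynucleotide (A 21,
   C 19, G 22, T 20 heavy atoms including one phosphate group). The
   template is schematic — dimensionally realistic (phosphate backbone
   at ~9.6 Å radius, paired C1′–C1′ separation 10.4 Å with the pair
   midpoint exactly on the axis) but not fiber-refined, because
   everything downstream consumes only base-pair centers, backbone
   positions and atom counts. Propeller, buckle, groove asymmetry and
   sequence-dependent bending are deliberately absent. Overhang
   nucleotides are never given coordinates; the per-strand 5′-phosphate
   policy is explicit (5′-OH default) because deposited compositions
   depend on whether a modeled strand begins mid-chain.

2. **Axis and span measurement.** The DNA helical axis is the principal
   component of the base-pair centers (total least squares), oriented
   5′→3′ along strand 1. The clamp ring axis is measured two ways: the
   *symmetry* method superposes each subunit onto the next (Cα Kabsch),
   takes each step's rotation axis and averages them, with the maximum
   pairwise angular scatter reported as quality; the *plane* method
   uses the total-least-squares plane normal through all Cα. Symmetry
   is the default because the quantity of interest is the rotation
   axis of the ring, which a pseudo-symmetry operator approximates
   best; on real structures the two methods are expected to agree
   within ~3°. Tilt is the unsigned angle between the two axes, folded
   to [0°, 90°], since only magnitudes are physically meaningful here.
   Clamp face planes sit at the 5th/95th percentiles of the Cα axial
   coordinates (configurable) so surface loops do not inflate the
   apparent thickness. A duplex terminus is classified `through` beyond
   the distal plane, `partial` between the planes, `opening` within
   ±4 Å of the proximal plane (≈ one bp rise, giving the qualitative
   category a numeric width), and `outside` proximal of that.

3. **Composite-model construction.** Given a loader–DNA complex and a
   loader–clamp complex sharing an equivalent anchor subunit, the
   anchor chains are superposed (Cα Kabsch over all alignable
   positions; unequal-length chains are matched by global sequence
   alignment) and the DNA is transferred into the clamp complex's frame
   by the inverse transform. The transferred duplex is extended by
   aligning an ideal duplex onto its last 4 bp (8 C1′ atoms — enough
   points for a stable local superposition) and appending ideal base
   pairs. Anchor RMSD above 5 Å is treated as wrong-chain input;
   extension atoms within 1.5 Å of clamp atoms are recorded as clash
   warnings, never silently fixed, and no energy minimization is
   attempted. Every stage is logged with its parameters and transforms;
   the build is a pure function of inputs and log, so replays are
   bit-identical.

4. **Assay fits.** One-site binding, Y = B·X/(K + X), is fit by
   bounded nonlinear least squares; initialization is B₀ = max(Y) and
   K₀ = X nearest half-maximal Y, rerun from three deterministic
   multiplicative jitters (×0.3, ×1, ×3 on K₀) with the best RSS kept;
   standard errors come from the covariance at the optimum. No
   ligand-depletion (quadratic) correction is applied — the simple
   hyperbola is the model of record, and a depletion-aware variant is
   out of scope. ATPase rates are the OLS slope of A₃₄₀ vs time over a
   closed window (default 100–500 s, ≥ 10 points), converted to µM
   ATP/s via ε₃₄₀(NADH) = 6220 M⁻¹cm⁻¹ and a configurable pathlength
   (instrument-dependent), assuming 1:1 NADH:ADP. Relative rates divide
   by a reference condition (exactly 1 by construction) and are
   independent of ε and pathlength, which is why they are the
   cross-condition quantity.

## Conventions

- **Ring-axis orientation.** The direction points proximal → distal
  (from the loader-binding face through the ring), so axial coordinates
  increase as the DNA threads away from the loader and the span
  classification reads naturally. When proximal marker coordinates are
  supplied they therefore project at negative axial values; without
  markers the sign is fixed deterministically (largest-magnitude
  component positive), which is irrelevant for tilt but matters for
  span — supply markers when classifying real structures.
- **Entry convention.** A duplex "entering at" a face plane puts the
  duplex terminus (junction boundary) at the plane, with base pair 1's
  center one rise along the duplex axis inside. With this convention,
  the minimum length to span a ring of thickness T at tilt θ is
  ⌈T / (rise·cos θ)⌉ exactly.
- **Truncation series.** Base pair 1 is the loader-proximal terminus
  (the primer-template junction side); shorter constructs share it and
  lose base pairs from the blunt end, matching how the DNA-30/25/20/
  15/13 construct series was made.
- **Contacts.** Distance cutoffs are closed intervals; the default
  4.0 Å is a typical salt-bridge/H-bond heavy-atom distance and is
  exposed in configuration because no single value is canonical. The
  phosphate filter is {P, OP1, OP2, O5′, O3′}; the side-chain polar
  filter keeps N/O atoms beyond Cβ.
- **Structure handling.** Author residue numbering is never changed;
  waters are flagged, not deleted, so protein+DNA atom counts match
  deposited totals; alternate locations keep the highest-occupancy
  conformer as primary with ties broken by label order (deterministic
  geometry); only model 1 of multi-model files is read.
- **Inventory.** The Lys/Arg inventory over the central-pore helices
  ships with default author-numbering ranges (8–24, 70–82, 139–152,
  204–216) derived from inspection of the deposited clamp's secondary
  structure; they are user-overridable, and whatever count the ranges
  yield is surfaced, not adjusted toward an expected number.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *geometric and statistical structure* the
analysis assumes, not molecular reality:

- Pseudo-clamps are Cα-only subunits (the axis and span code consume Cα
  exclusively), copied by exact 360°/n rotations, hollow by
  construction, with residue names cycling a fixed 20-mer so Lys/Arg
  positions are known. Defaults — three subunits, 32 Å outer radius,
  27 Å axial thickness, 60 pseudo-atoms per subunit — give a ring of
  clamp-like proportions.
- Tilted-duplex and dismantled-fixture generators retain their ground
  truth, so every geometric measurement has a closure test: the
  recovered value must match the construction parameter (tilt to
  < 0.5°, transferred-DNA placement to < 1e-6 Å). This closure is the
  module's reason to exist.
- Titrations default to K_d = 100 nM and B_max = 0.12 with Gaussian
  noise σ = 5% of B_max on a six-point grid spanning 0.25–8 × K_d
  (25–800 nM); the mutant scenario uses K_d = 500 nM (5× weaker) with
  the grid extended to 3200 nM to preserve the same relative span.
  Timecourses are linear A₃₄₀ decays (−2×10⁻⁴ AU/s, σ = 10⁻³ AU,
  sampled every 2 s over 0–600 s).
- Passing tests on these fixtures demonstrates the estimators and
  geometry are correct, *not* that real crystal structures are well
  modeled: real clamps are only pseudo-symmetric, real DNA in a clamp
  can be partially disordered with very high B factors, and real
  titrations can show ligand depletion. The deposited-structure
  validation script exists for exactly that gap.

## Problem sizes

The default test suite and the acceptance script use 25–40 bp duplexes,
rings of 180–360 pseudo-atoms, 200 simulated titrations (plus 20
replicate pairs for the fold-change), 500 timecourse replicates in the
slope-bias check, and a 12° rotation grid (30×16×30 orientations) for
the superposition oracle — sizes chosen so every closure property is
exercised at tight tolerances while the whole battery runs in seconds
on one CPU.

## Known limitations

- The B-form template is schematic: do not use built duplexes for
  base-resolution structural comparison, only for axis/backbone/count
  work.
- The β clamp's six-fold domain-level pseudo-symmetry requires a
  user-supplied domain map for the symmetry axis method (its two chains
  each contribute three similar domains); the plane method is the
  practical default there.
- The composite extension assumes the transferred duplex's last 4 bp
  are well-modeled; with fewer than 4 transferred pairs the extension
  refuses to run.
- No open-clamp model is generated: an out-of-plane opened clamp can
  only be supplied by the user and aligned on the subunit contacting
  the loader's A subunit.
- Single-stranded overhangs are metadata only (reported by `anneal`,
  never built), so overhang–clamp interactions are outside the model.
- `fit_one_site` reports non-convergence rather than raising, and
  `compare_fits` refuses non-converged inputs; uncertainty on the K_d
  ratio uses first-order (relative-error) propagation, which is
  adequate when the SEs are small relative to the estimates.
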