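# Methods

This note documents the models, conventions and numerical choices
behind each analysis stage, what the synthetic test bed does and does
not emulate, and the known limitations.

## Units and identity conventions

Coordinates, boxes, distances and RMSF are in Ångström (PDB
convention); Lennard-Jones σ is stored in nanometres (force-field
convention) and converted once, inside the energy evaluator; ε and all
energies are kJ/mol; charges are in elementary-charge units, masses in
amu, times in picoseconds. A residue is identified by
(chain id, author residue number) exactly as in the source structure —
marker residue numbers are structure-specific and therefore always
configuration (the SSTR2 preset is data, not code). Atom indices are
0-based in the API and 1-based in user-facing output.

## Activation classification

Two geometric markers quantify class-A GPCR activation: the Cα–Cα
distance between a TM5-adjacent and a TM7 residue (contraction on
activation) and the Cα angle over three residues spanning TM6's
intracellular end (outward swing on activation). A frame is active iff
distance < d₀ AND angle > θ₀, with strict inequalities — boundary
frames are inactive, a measure-zero choice in practice. The AND
combination is the default because the two markers report distinct
necessary hallmarks of the active state; the combination is exposed as
configuration (`combine="or"`) since reasonable analyses could accept
either marker alone. The active fraction over replicates is pooled
frame-weighted (total active frames over total frames); the unweighted
per-replicate mean and range are always reported alongside so the
spread across replicates is visible.

## Interaction energy

The evaluator computes the pairwise short-range nonbonded energy
between the ligand and receptor groups:

- Coulomb: k·qᵢqⱼ/rᵢⱼ with k = 1389.35458 kJ·mol⁻¹·Å·e⁻²
  (= 138.935458 kJ·mol⁻¹·nm·e⁻², the CODATA-derived value of
  N_A e²/4πε₀);
- Lennard-Jones 12-6: 4εᵢⱼ[(σᵢⱼ/r)¹² − (σᵢⱼ/r)⁶] with
  Lorentz–Berthelot combination (σ arithmetic, ε geometric mean), the
  Amber-family convention matching the provenance of typical GAFF2 /
  ff19SB parameter sets;
- minimum-image pair distances under an orthorhombic box;
- plain (unshifted) truncation at 10 Å, applied atom-pair-wise.

Deliberate deviation from MD engines: no Ewald/PME long-range
electrostatics. A mesh sum cannot be decomposed exactly into group or
residue contributions; only the pairwise short-range part can. Absolute
totals therefore differ from engine-reported energies, while
per-residue decompositions and comparisons *between* ligands remain
meaningful. No 1–4 exclusions or scaling apply because ligand and
receptor are separate molecules; intra-group energies are out of scope.

The per-residue decomposition bins the identical pair-energy matrix by
residue on the chosen side, so conservation (Σ residues = group total)
holds to floating-point identity, not merely to a tolerance — this is
checked on random systems against an independent all-pairs double loop.

Uncertainty convention: the ± printed per replicate is the standard
deviation of per-frame energies within that trajectory; across
replicates the report additionally gives the mean and sd of replicate
means. Both are reported because fluctuation magnitudes and
between-replicate scatter answer different questions, and neither is
canonically "the" error bar.

## RMSF

Per-atom RMSF_i = sqrt(⟨|x_i(t) − ⟨x_i⟩|²⟩) after rigid-body alignment
of every retained frame on an alignment selection, two-pass: align to
the first frame, average, re-align the original frames to that mean,
recompute the mean. The alignment selection defaults to all receptor
Cα atoms; the choice of alignment reference is a documented convention
of this package, exposed as configuration. Under PBC each frame is
first made contiguous by unwrapping every atom to the image nearest the
frame's first atom, which makes the result exactly invariant to
re-wrapping; this assumes the analyzed structure fits within half a box
edge, true for any receptor in a sensibly sized cell. The per-residue
value is the RMSF of the residue's selected (Cα) atom and the headline
statistic is the sum over the selection (e.g. ECL2): loop closure over
the ligand shows up as a smaller sum.

Kabsch superposition is implemented via the SVD of the weighted
covariance matrix with the determinant-correction that forbids
reflections; degenerate (collinear) references raise. The batched path
used by RMSF shares the same rotation solver; the single-pair API is
cross-checked in tests against an independent superposition routine and
a random-rotation search.

## Contacts and penetration

A receptor residue is in contact in a frame when its minimum atom–atom
minimum-image distance to any ligand atom is ≤ cutoff (3.0 Å default,
inclusive at the boundary). All atoms including hydrogens participate
by default (`heavy_atoms_only` excludes them). The census counts
residues whose occupancy over retained frames reaches a threshold
(default 0.5); the mean per-frame contact count is reported alongside
so both the thresholded-membership and per-frame-average readings of
"residues in contact" are available. Side-chain classes: hydrophobic
{ALA VAL LEU ILE MET PHE TRP PRO TYR}, charged {ASP GLU LYS ARG HIS},
polar-uncharged {SER THR ASN GLN CYS GLY}; tyrosine and proline are
placed hydrophobic and histidine charged — conventions, overridable
wholesale via a JSON table.

Penetration metrics are mass-weighted center-of-mass distances between
chosen residue pairs, per frame under minimum image; residues
straddling a box boundary are unwrapped to the first atom's image
before the mass-weighted mean. Between-system differences are reported
as Δ = mean(B) − mean(A), sign convention stated in the output.

## Synthetic test bed

The generator builds a Cα scaffold (compact helix of one atom per
residue) in which the five marker residues are placed explicitly so the
planted (distance, angle) values are exact: active reference (17.0 Å,
55°) and inactive reference (21.0 Å, 35°), bracketing the 19.0 Å / 45°
thresholds with margins of 2 Å and 10°. Frames are i.i.d. draws: a
Bernoulli(f_active) state choice selects the reference, then isotropic
Gaussian noise of per-residue amplitude σ (default 0.10 Å per
coordinate) is added to every atom. A margin guard rejects
specifications whose marker noise could plausibly flip a
classification (margins must exceed 5σ on the distance and 5× the
small-angle jitter scale σ√2/arm on the angle), so planted states are
recovered frame-exactly with overwhelming probability. A pseudo-ligand
pocket places 1–3-atom residues with stated charges/σ/ε/masses at
stated distances from anchor residues, giving closed-form planted
energies, contact occupancies and COM distances.

What this emulates: the geometry of a two-state activation equilibrium,
known fluctuation amplitudes, and a pocket with known energetics — the
quantities every stage must recover. What it does not: temporal
correlation (frames are independent, so convergence behaves like ideal
Bernoulli/Gaussian sampling, faster than correlated MD), coupled
collective motions, solvent/membrane atoms, and ligand mobility beyond
noise. Passing recovery tests therefore validates the estimators'
correctness, not their statistical efficiency on correlated data.

Default problem sizes were chosen so closed-form recovery tolerances
are comfortably resolved: 10⁴ frames for binomial fraction recovery
(99% CI half-width ≈ 1.3 percentage points at f = 0.5), 2–5×10⁴ frames
for RMSF amplitude recovery within 2% of σ√3, 30-residue scaffolds with
marker residues 10/20 and 12/15/5. The bundled acceptance study uses
two systems × 3 replicates × 4000 frames.

## I/O

Multi-model PDB is the mandatory trajectory dialect (strict PDB 3.3
fixed columns, parsed with biotite); models with differing atom counts
raise a ragged-trajectory error, malformed records a parse error. A
CRYST1 cell is used as the box only when orthorhombic (α=β=γ=90°);
otherwise analyses proceed without PBC and a warning is logged —
triclinic minimum image is out of scope. HETATM records are accepted
(chelator-ion entities are non-standard); atoms in neither the ligand
nor receptor group (waters, ions, lipids) ride along in frames and are
ignored by every analysis. PDB files carry no force-field information,
so a versioned JSON sidecar supplies per-atom charge, σ, ε, mass and
the named group selections; it is validated on read (violations are
collected and reported together, never one at a time). Result writers
are deterministic — fixed column order, sorted keys, 6 significant
digits — and stamp a provenance block (config hash, seed, discard
window), so identical inputs give byte-identical outputs.

## Degenerate inputs and tie-breaks

Zero-length angle arms, coincident superposition references and r = 0
atom pairs raise typed errors rather than returning NaN. Energies are
exactly zero beyond the cutoff (pair excluded, not shifted) and the
contact test is inclusive at its cutoff; the two conventions differ
because the energy cutoff is a truncation boundary while the contact
cutoff is a membership definition. Frames at exactly a classification
threshold are inactive. The discard window keeps frames with
time ≥ discard; stride subsampling starts at the first retained frame.

## Known limitations

- Orthorhombic PBC only; no triclinic cells.
- No long-range electrostatics (by design, see above); absolute energies
  are not comparable to PME engine output.
- RMSF unwrapping assumes the structure spans less than half a box.
- The synthetic ensemble is i.i.d.; autocorrelation-aware error
  estimates (block averaging) are not implemented.
- Binary trajectory formats (XTC/DCD) are not read; convert to
  multi-model PDB first.
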