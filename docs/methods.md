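# Methods

This note records the conventions, models and numerical choices behind
`lowres-audit`, in the order data flows through the package.

## Coordinate model and I/O policy

Structures are parsed with gemmi into a flat residue/atom model, one
`ChainModel` per chain. Policy decisions, all of which mirror common
single-conformer validation practice:

* Only altloc blank or `A` atoms are kept (configurable via
  `read_structure(keep_altlocs=...)`). Zero-occupancy atoms are kept;
  occupancy is clamped into [0, 1].
* Waters and non-amino-acid heteroatoms are dropped. The accepted residue
  set is the 20 standard codes plus MSE, renamed to MET on input.
* Residue numbering is author numbering (`auth_seq_id`), so ranges quoted
  in the literature apply verbatim; single-character numeric chain IDs
  ("2") are accepted.
* All writers round coordinates to 0.001 Å — the PDB fixed-column
  precision — in every output format, so PDB and mmCIF renderings of one
  model parse back to identical coordinates and dihedrals. This is why
  the cross-format round-trip test can demand |Δdihedral| < 10⁻³°.

## Dihedral conventions

Torsions use the IUPAC sign convention (the implementation is
cross-checked against `gemmi.calculate_dihedral` in the test suite) and
live in (−180°, 180°]. A torsion is invariant under reversing the atom
order and flips sign under mirror reflection; both properties are tested.

ω(i) describes the peptide bond *preceding* residue i:
ω(i) = dih(Cα(i−1), C(i−1), N(i), Cα(i)). Consequently a
"cis-nonproline" is a cis peptide whose residue i is not proline. Cutoffs:
|ω| ≤ 30° cis, |ω| ≥ 150° trans, twisted in between; boundary values are
assigned by those inequalities exactly. Two residues count as bonded only
when the C(i−1)–N(i) distance is below 2.5 Å; across a gap all spanning
dihedrals (φ(i), ω(i), ν(i), ψ(i−1)) are null, never spurious.

The Cα-trace virtual dihedrals μ_in/μ_out are reported only where the
full five-Cα window i−2…i+2 is present and unbroken, even though each
individual quadruple would be computable one residue further out — the
window is the context in which these angles are interpreted. The CO–CO
virtual dihedral is fixed here as ν(i) = dih(O(i−1), Cα(i−1), Cα(i),
O(i)). Published contour sets may define their ν differently, so contour
table files carry a convention tag and are never silently mixed.

## Contour tables

A contour table is a binned probability surface over any subset of the
per-residue dihedrals, stored as self-describing text (dimension names,
bin edges in degrees, convention tag, row-major probabilities). On load,
bin masses are converted to *coverage percentiles*: a bin's score is the
total mass of bins no more populated than itself, so a uniform table
scores 1.0 everywhere and a sharp peak scores ≈ 0 off-peak. Lookups
interpolate multilinearly between bin centres; values inside the domain
but outside the centre lattice clamp to the nearest centre; values
outside the domain score 0 with a warning. Scores below 0.01 / 0.05 are
the 1% / 5% outlier levels. Empirical contour fitting from curated
high-resolution sets is out of scope — tables are an input.

## Two-model comparison

Residues pair by (chain, residue number, insertion code). Pairs whose
residue names differ are flagged "realigned" (a register shift) and are
excluded from the statistics; unpaired and realigned counts are reported
so the denominator of any fraction is always diagnosable. The changed
flag is the OR of four strict inequalities: max shared non-H-atom
displacement > 2 Å, or circular Δφ, Δψ, Δω > 45°. Displacement is
measured in the models' native frame — two models refined into the same
map share a frame, and superposing would hide real movement; an optional
least-squares superposition exists for models that do not share a frame.

**Peptide misorientation.** The measure must be exactly the injected
angle for a synthetic flip and must not change when one model is rigidly
moved. Aligning only the Cα(i)→Cα(i+1) axes cannot guarantee the second
property (the spin about the axis is unresolved), so the implemented
measure superposes the local Cα trace — Cα of residues i−1…i+2, atoms no
peptide flip moves — by least squares, then reports
|dih(O_b′, Cα_a(i), Cα_a(i+1), O_a(i))|, the azimuth of the rotated
carbonyl O about the axis. With fewer than three pairable framing Cα
(chain termini), the axis-alignment fallback is used. The circular
difference of ν is computed alongside as an independent misorientation
measure; both appear in every report. Misoriented means rotation > 60°.

**Wrong-minimum transitions.** Coarse Ramachandran basin polygons
(versioned package data; α, β including its ψ-wrap near −180°, left-α,
else "other") identify minima — they are deliberately not outlier
contours, because basin identity, not rarity, is what distinguishes a
residue refined into the wrong minimum. A residue transitions when its
basin label changes *and* Δφ or Δψ exceeds 45°.

## Barbed-wire analysis

Five per-residue criteria, all computed from the model alone:

| criterion | rule | default |
|---|---|---|
| packing | CB (Cα for GLY) neighbours within radius from residues ≥ 4 apart in sequence, any chain; flag when count < minimum | 8 Å, < 3 |
| ψ | ψ inside the rarely populated band between the helical and extended basins | [60°, 110°] |
| ω | peptide cis-nonproline or twisted | — |
| CaBLAM-style | contour score < 1%; without a table, ν further than 90° from both canonical values (helix −34.2°, strand −138.4°, computed from the package's own ideal-geometry builder) | — |
| geometry | any backbone bond length or angle ≥ 4σ from the packaged ideal values | 4σ |

Residues at pLDDT ≥ 70 are confident. Remaining runs are scanned with a
7-residue sliding window: a window is barbed wire when ≥ 4 of its
residues carry ≥ 2 criterion flags *and* its packing-flag density is
≥ 0.5; runs shorter than the window use the same fractions. Residues in
any barbed window are barbed wire, other low-confidence residues are
near-folded, and runs shorter than 3 residues merge into their
neighbour. Segmentation is fully deterministic, and adding flags can
only grow barbed-wire segments. Pruning removes barbed-wire residues,
logs each removed range, and refuses to return an empty model. Every
threshold lives in `BarbedWireConfig`, is overridable from a flat YAML
config (unknown keys rejected), and is echoed into the JSON report.

These defaults are this package's own tuning: the criteria names and the
pLDDT bands (70 confident, < 65 near-folded possible, < 50
disorder-associated) follow the published description of the approach,
but the published tool's tuned thresholds are not available, so the
values above are validated only against the synthetic generator (below).

## Synthetic data

The generator defines the conditions under which the pipeline is
validated.

* **Chain builder.** Sequential internal-coordinate (NeRF) placement
  from packaged ideal covalent geometry (Engh–Huber-style values:
  N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, with σ).
  Backbone N, Cα, C, O only; O is placed in the peptide plane trans to
  the next N; Cβ at ideal tetrahedral geometry on request (packing
  needs it). Dihedral round-trip is exact to ~10⁻¹³°.
* **Injectors.** A peptide flip rotates {C(i), O(i), N(i+1)} rigidly
  about the Cα(i)→Cα(i+1) axis by θ, so the recovered rotation equals θ
  by construction and flips at disjoint positions commute. A cis
  injector rotates the downstream chain about the C(i−1)–N(i) bond to
  set ω exactly, leaving every other internal dihedral unchanged.
* **AlphaFold-like fixtures.** *barbed_wire*: extended chain
  (φ ∈ [−160°, −60°]), ψ uniform inside the flagged band, 20% twisted ω,
  10% of C–N bonds stretched to 1.50 Å, per-residue pLDDT uniform
  [30, 60]. *near_folded*: a compact three-helix bundle (helices at
  φ=−63°, ψ=−43°, joined by a fixed four-residue turn chosen once so
  that > 95% of interior residues have ≥ 3 packing neighbours), clean
  geometry, pLDDT [50, 68]. *chimera*: a confident bundle (pLDDT
  [80, 95]) with a barbed-wire C-terminal tail (pLDDT [40, 50], length
  min(40, n/3)), plus residue-level ground-truth labels. All randomness
  flows through `numpy.random.default_rng(seed)` (PCG64), so fixtures
  are bit-reproducible across platforms.

What the generator does **not** emulate: side chains beyond Cβ, real
B-factor physics, experimental noise, density, multi-chain complexes, or
sequence-dependent conformational preferences. Passing the recovery
tests therefore demonstrates the *mechanics* of the criteria and
segmentation, not their error rates on real depositions. One known
artefact: a randomly built extended tail occasionally wanders back into
contact with the bundle, where it is genuinely packed and scores
accordingly; residue-level balanced accuracy pooled over 50 chimera
fixtures is ≈ 95% rather than 100% mainly for this reason, with
window-edge smearing at segment boundaries contributing the rest.

## Problem sizes

The validation suite and the acceptance script run entirely on generated
data: 100 random-dihedral chains of 5–25 residues for the round-trip
bound, flips at 10°–180° in 10° steps, 50 chimera fixtures of 100
residues for segmentation scoring. The audits of the published
helicase rebuild (PDB 3ja8 → 6eyc: the 116 cis-nonproline census, the
1229-residue / 32.5% change census, and the 15-misoriented-peptide /
2-cis-nonproline counts in chain 2 residues 201–335) require those
coordinate files, which are far too large to vendor; the corresponding
tests fetch them from the wwPDB (or a cached copy under `scratch/pdb`)
and fail with an explanatory message when run without network access.

## Known limitations

* The ν convention here is declared, not asserted to match any published
  contour set; supplying a table with a different convention tag is the
  supported way to substitute one.
* The misorientation measure is a declared definition; published counts
  based on an unpublished measure may differ near the 60° threshold,
  which is why reports carry both the rotation-angle and the
  ν-difference census.
* Ramachandran basin polygons are coarse by design and versioned; they
  are unsuitable for outlier calling.
* The barbed-wire thresholds are generator-validated defaults, not a
  reproduction of the published tool's tuning.
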