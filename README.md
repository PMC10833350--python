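# lowres-audit

Backbone-geometry auditing for protein models built into sparse data.

At local resolutions worse than ~2.5 Å the carbonyl-O protrusion vanishes
from the density, so the orientation of each peptide plane cannot be read
from the map. The most common backbone error in this regime is a
**misoriented (flipped) peptide**: a large rotation of the C=O group about
the Cα(i)–Cα(i+1) axis that barely moves the Cα trace but shifts the
preceding ψ and the following φ by a comparable amount, after which
Ramachandran-restrained refinement pulls both residues into the *wrong*
minimum and hides the outlier. Related symptoms are spurious
**cis-nonproline** peptides (genuine ones occur roughly once per 3000
residues) and, in low-confidence AI predictions, **barbed wire**: long,
loopy, unpacked strands with dire local geometry that should be pruned
before a model is used for molecular replacement or docking.

`lowres-audit` is a library plus CLI for diagnosing these problems:

* **Dihedral audit** — φ, ψ, ω per residue; cis/twisted/trans peptide
  classification (|ω| ≤ 30° cis, ≥ 150° trans); Cα-trace virtual
  dihedrals μ_in(i) = dih(Cα(i−2), Cα(i−1), Cα(i), Cα(i+1)),
  μ_out(i) = dih(Cα(i−1), Cα(i), Cα(i+1), Cα(i+2)) and the CO–CO virtual
  dihedral ν(i) = dih(O(i−1), Cα(i−1), Cα(i), O(i)), scored against a
  pluggable empirical contour table with 1% / 5% outlier levels.
* **Two-model comparison** — pair residues of an original and a rebuilt
  model, report max non-H displacement, circular Δφ/Δψ/Δω, the peptide
  rotation angle about the Cα–Cα axis, Ramachandran wrong-minimum
  transitions, and a census with the standard thresholds (changed =
  > 2 Å and/or > 45° in φ/ψ/ω; misoriented = > 60°).
* **Barbed-wire analysis** — five per-residue criteria (packing, ψ, ω,
  virtual-dihedral outliers, covalent geometry) segment low-pLDDT chains
  into confident / near-folded / barbed-wire stretches and prune the
  barbed wire.
* **Synthetic fixtures** — an internal-coordinate (NeRF) chain builder
  with exact dihedral round-trip, peptide-flip and cis injectors, and
  pLDDT-annotated barbed-wire / near-folded / chimera generators, so the
  whole pipeline is testable without downloading anything.

## Worked example

Build an ideal 20-residue α-helix, flip one peptide by 150°, and compare:

```sh
lowres-audit synth helix --n 20 --out helix.pdb
lowres-audit synth helix --n 20 --flip 9:150 --out flipped.pdb
lowres-audit compare helix.pdb flipped.pdb
```

prints (abridged):

```json
{
  "n_paired": 20,
  "n_changed": 2,
  "fraction_changed": 0.1,
  "n_misoriented": 1,
  "n_misoriented_by_nu": 2,
  "n_wrong_minimum": 2,
  "thresholds": {"displacement": 2.0, "dihedral": 45.0, "peptide": 60.0}
}
```

One peptide was rotated, so one peptide exceeds the 60° misorientation
threshold, and exactly its two flanking residues (ψ of the first, φ of
the second) moved by more than 45°, landing in a different Ramachandran
basin — the wrong-minimum signature. The ν-based measure sees two
peptides because the rotated carbonyl O enters the CO–CO virtual
dihedrals of both adjacent peptides.

Segment and prune a low-confidence prediction-like model:

```sh
lowres-audit synth chimera --n 100 --seed 1 --out chimera.pdb --truth truth.csv
lowres-audit barbedwire chimera.pdb --report bw.json --prune pruned.pdb
```

The report lists segments such as `confident 1–67 (mean pLDDT 86.9)` and
`barbed_wire 68–100 (mean pLDDT 43.9)`; the pruned model keeps the
compact core.

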