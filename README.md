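# hpas

Tools for building and curating datasets of ***cata*-condensed
hetero-polycyclic aromatic systems** (cc-hPAS) — fused-ring molecules in
which every atom belongs to at most two rings, assembled from aromatic and
antiaromatic monocycles containing B, N, O and S. Such compounds are prime
candidates for organic semiconductors and optoelectronics, and data-driven
screening of their chemical space needs large, uniformly computed,
well-annotated collections of structures and properties.

`hpas` provides the data-generation machinery around (but not including)
the quantum-chemistry engines:

* **Randomized enumeration** — grows molecules by sequential ring fusion
  from an 11-block library (benzene, pyridine, pyrazine, borinine,
  1,4-diborinine, 1,4-dihydro-1,4-diborinine, borole, pyrrole, furan,
  thiophene, cyclobutadiene). Each fusion is a reaction SMARTS applied at a
  C–C bond whose two carbons each belong to exactly one ring, which
  guarantees *cata*-condensation and keeps heteroatoms off fused bonds.
  Generation is seeded and fully reproducible; duplicates are removed by
  standard InChI.
* **Structural annotation** — ring, atom, heteroatom, heterocycle and
  per-building-block counts, plus the number of branches of the dualist
  graph (the tree whose nodes are rings and edges are fused bonds).
* **Property bookkeeping** — the frontier-orbital gap
  `Gap = LUMO − HOMO`, the adiabatic ionization potential
  `AIP = E_tot(cation) − E_tot(neutral)` and electron affinity
  `AEA = E_tot(anion) − E_tot(neutral)`; geometry validity filters
  (convergence, imaginary frequencies, bonds > 2.0 Å, atom clashes
  < 0.1 Å); and minimal RMSD between conformations via SVD-based rigid
  superposition.
* **Semiempirical→DFT correction** — a per-property multi-linear model
  `corrected = Σ_e c_e·n_e + β·baseline + intercept` over the six element
  counts {H, C, B, S, O, N}, a dimensionless slope on the tight-binding
  (GFN1-xTB) baseline value, and an intercept. Coefficients fitted against
  CAM-B3LYP-D3BJ/def2-SVP references ship with the package; refitting on
  any paired table uses OLS with an 80/20 train/test split.
* **Synthetic fixtures** — paired property tables with known linear
  structure, geometry pairs for RMSD work, and a deterministic mock
  calculator, so the whole pipeline is testable without external engines.

## Worked example

```python
from hpas import (GenerationConfig, generate_dataset, annotate_structure,
                  default_models, apply_correction, load_default_library,
                  eligible_fusion_bonds, symmetry_unique_bonds)

lib = load_default_library()            # the 11 blocks, benzene weighted 10:1
pyridine = lib["pyridine"].parent_mol()
print(len(eligible_fusion_bonds(pyridine)),     # 4  C-C fusion sites
      len(symmetry_unique_bonds(pyridine)))     # 2  symmetry-unique sites

records = generate_dataset(GenerationConfig(target_count=20, seed=1))
r = records[0]
print(r.name, "+".join(r.block_sequence))
row = annotate_structure(r)
print(row.rings, row.heterocycles, row.formula, row.branch)

homo = default_models()["homo"]
counts = {"h": 6, "c": 6, "b": 0, "s": 0, "o": 0, "n": 0}
print(round(apply_correction(homo, counts, -13.0), 4))
```

prints

```
4 2
pas000000 cyclobutadiene+benzene+thiophene+benzene+benzene+pyrrole+benzene+pyridine
8 3 C27H14N2S 0
-9.7186
```

Pyridine exposes four C–C ring bonds but only two distinct fusion sites
(the molecule's mirror symmetry makes the others equivalent). The 20
seeded generation attempts here all yielded distinct molecules; the first
is an 8-ring system built from the printed block sequence, with 3
heterocyclic rings and an unbranched (catafusene chain) dualist graph. The
last line corrects a hypothetical tight-binding HOMO of −13.0 eV for
benzene (6 C, 6 H) toward the DFT scale with the shipped coefficients.

The same workflows are available from the shell:

```bash
hpas generate --count 1000 --seed 1 --out-sdf out.sdf --out-csv out.csv
hpas fit --pairs pairs.csv --property homo --out-model homo.json
hpas correct --in-csv out.csv --models table-defaults --out-csv corrected.csv
```

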