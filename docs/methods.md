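# Methods

This note documents the models and procedures implemented in `hpas`, the
defaults they ship with, and the numerical and design choices behind them.

## Scope and the calculator boundary

The package covers structure enumeration, structural annotation, derived
electronic properties, validity filtering, RMSD comparison, and the
composition-based correction of semiempirical property values toward DFT.
It deliberately does **not** run geometry optimizations or electronic-
structure calculations: those are modeled as an abstract calculator
contract (`EnergyRecord` + `Geometry`), and a deterministic mock
implementation (`hpas.synthetic.mock_calculator`) stands in for tests and
examples. Its numbers are plausible in scale but not physically
meaningful.

## Enumeration model

A molecule is grown by sequential annulation of monocyclic building
blocks. The library holds 11 blocks — benzene, pyridine, pyrazine,
borinine, 1,4-diborinine, 1,4-dihydro-1,4-diborinine, borole, pyrrole,
furan, thiophene, cyclobutadiene — each encoded as a one-reactant,
one-product reaction SMARTS whose reactant pattern is always
`[#6;R1:1]~[#6;R1:2]`: a bond between two carbons that each belong to
exactly one ring. Restricting fusion to such bonds has two structural
consequences that hold by construction and are asserted in bulk tests:

* **cata-condensation** — no atom ever belongs to more than two rings;
* **carbon-only fused bonds** — heteroatoms (B, N, O, S) never sit on a
  fused bond, because only C–C bonds react.

One growth step applies the next block's reaction at *every* eligible
bond, sanitizes the raw products, deduplicates them by standard InChI, and
selects one survivor uniformly at random; everything else is discarded.
A full generation draws a ring count `n`, draws `n` blocks i.i.d., seeds
the molecule with the first block and performs `n − 1` growth steps.

Defaults:

| parameter | default | rationale |
|---|---|---|
| ring-count range | 2–10 | two rings up to ten-ring systems; larger systems add cost without new structure–property signal |
| size law | discretized Poisson bump, rate 8.5, truncated to [2, 10] | biases generation toward 8–9-ring molecules of intermediate size; the exact published law is configurable via `size_weights` |
| block weights | benzene 10, all others 1 | 10:1 benzene bias gives a realistic hydrocarbon-rich composition; p(benzene) = 10/20 = 0.5 |
| dead-end policy | retry with a fresh (n, blocks) sample, up to 25 times | a growth step can in principle yield no valid product; retrying keeps runs total |
| name scheme | `pas` + zero-padded 6-digit index | a fixed 9-character alphanumeric identifier |

All randomness flows through one `numpy.random.Generator` seeded from the
configuration, so a `(config, seed)` pair reproduces a dataset — including
file output — exactly.

### Orientation multiplicity and symmetry

A reaction SMARTS matches one bond in two atom-map directions. Both
orientations are applied and products merged by InChI, which makes the
orientation choice irrelevant. Symmetry-equivalent fusion sites are
detected *operationally*: two bonds are equivalent when annulating a fixed
probe block (benzene) at them yields the same product InChI set. This
matches how distinctness matters downstream (distinct products) and is
directly testable against brute force, which the suite does for all 11
parent rings.

### Sanitization repair

Raw reaction products occasionally carry inconsistent bond-order or
aromaticity flags (the product templates for the antiaromatic blocks are
written in aromatic notation that the perception model may reject). The
repair ladder is: (1) standard sanitization; (2) a SMILES round-trip,
letting the parser re-derive a Kekulé assignment; products failing both
are dropped with a logged skip. Aromaticity of stored products follows
RDKit's default model — four-membered and borole rings are therefore
typically *not* counted aromatic, and the `aromatic_rings` descriptor is
defined under that model.

### Deduplication

Standard InChI (default layers) is the identity key everywhere: within a
growth step, across a dataset, and in tests. If a different InChI dialect
were used, edge-case tautomer collapsing could differ.

## Structural descriptors

Element counts include explicit hydrogens; formulas are Hill-ordered.
Per-block ring counts are **provenance-first**: the construction history
is the ground truth, because after fusion a ring is no longer the isolated
heterocycle it came from and substructure re-perception is ambiguous. For
records without provenance, a per-ring fallback classifies each SSSR ring
by size and element content (the two 4C+2B six-rings are told apart by
B–H hydrogens) and logs a warning.

`branch` counts the nodes of degree ≥ 3 in the dualist graph — nodes are
rings, edges are shared fused bonds — which for a cata-condensed system is
a tree (edges = rings − 1, asserted in bulk). This is the standard notion
separating branched from unbranched catafusenes. Peri-fused input (an atom
in three rings) is rejected with an error.

## Electronic properties and filters

With orbital energies in eV and total energies in Hartree:

* `Gap = LUMO − HOMO` (neutral records only; a negative gap is returned
  and logged, not raised);
* `AIP = (E_tot^cation − E_tot^neutral) × 27.211386245988` eV;
* `AEA = (E_tot^anion − E_tot^neutral) × 27.211386245988` eV.

The Hartree→eV constant is CODATA and fixed in one place. Orbital-order
sanity (`HOMO−1 ≤ HOMO`, `LUMO ≤ LUMO+1`) is enforced on construction;
`HOMO ≤ LUMO` is *not*, since some methods invert frontier orbitals for
open-shell species.

The validity filter fails a structure when optimization did not converge,
any imaginary frequency is present, any *declared* bond exceeds 2.0 Å, or
any atom–atom distance falls below 0.1 Å. The bond criterion applies to
the declared bond list only; the clash criterion to all pairs. The same
filter is reused unchanged for the cationic and anionic forms.

RMSD between two conformations uses the SVD-based optimal rigid
superposition (proper rotation enforced, via
`scipy.spatial.transform.Rotation.align_vectors`) with atom correspondence
by index. All atoms including hydrogens enter by default; a
`heavy_only` switch drops hydrogens. A dense-rotation-grid oracle in the
test suite confirms the minimal-RMSD property to 1e-3 Å. The bulk summary
`rmsd_fraction_below(values, 0.2)` reports the fraction of structure pairs
agreeing to better than 0.2 Å.

## Correction model

Per property (HOMO, LUMO, Gap, AIP, AEA, E_tot), the corrected value is

```
corrected = Σ_e coef_e · n_e + β · baseline + intercept,   e ∈ {H,C,B,S,O,N}
```

eight parameters in total. Element counts are the only structural
information used — the model needs no geometry. Units are eV for all
properties except the total energy (Hartree), and each model object
carries its unit. The shipped coefficients derive from 52,000 paired
GFN1-xTB / CAM-B3LYP-D3BJ/def2-SVP calculations; the anomalously large
sulfur coefficient of the total-energy model (−395.19 Eh per S atom)
absorbs a systematic per-sulfur offset between the two methods.

Refitting uses plain (unweighted) ordinary least squares on a single
uniform random train split (default 80%), with metrics (R², RMSE, MAE)
computed on the held-out split. No interaction terms or nonlinear
alternatives are fitted. A regressor column that is identically zero — an
element absent from every molecule — is excluded from the solve and its
coefficient pinned to 0 with a warning, keeping the design full-rank.
R² is reported as missing when the reference has zero variance.

## Synthetic data

The fixture generator emulates exactly the statistical structure the
correction model assumes: element counts drawn uniformly from ranges
typical of 2–10-ring systems (C 8–40, H 6–22, B/S/O/N 0–4 each), baseline
values drawn normally (default mean −13 eV, sd 1 eV, the scale of a
tight-binding HOMO), and reference values equal to the generator model's
prediction plus Gaussian noise (default sd 0.16, echoing a typical
orbital-energy residual). Geometry pairs are random 1.5-Å-step chains
under a random rigid motion plus per-atom jitter.

What the synthetic fixtures deliberately do **not** reproduce: real
composition histograms (counts are independent and uniform, real ones are
coupled through the block chemistry), heteroscedastic or structured
residuals, correlated errors between properties, and any geometric realism
beyond bond lengths. Passing tests on synthetic data therefore demonstrate
correctness of the algorithms — exact linear-parameter recovery, RMSD
minimality, filter thresholds — not predictive accuracy on real
calculations.

## Problem sizes used in the shipped checks

The test suite exercises a shared 200-molecule seeded generation run for
bulk structural assertions and the end-to-end pipeline, a 1,000-attempt
run for the acceptance-level structural guarantees, and synthetic tables
of 200–5,000 rows for the regression properties. `scripts/acceptance.py`
performs an independent 1,000-attempt run. These sizes give stable
statistics (binomial/multinomial tolerances are derived at 3σ) while
keeping a full run to minutes on a single CPU.

## Known limitations

* Exhaustive enumeration is intentionally absent (the randomized protocol
  is the published method); a brute-force enumerator exists only as a test
  oracle at small ring counts.
* Ring perception is SSSR-based throughout.
* RMSD uses index correspondence, not a symmetry-corrected atom mapping;
  for symmetric molecules it can overestimate the minimal deviation.
* The correction scheme applies to neutral-state properties only.
* NFOD, dipole computation and frequency analysis are out of scope; the
  dipole column is carried as an opaque three-component field.
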