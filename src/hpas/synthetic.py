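"""Synthetic fixtures: paired property tables, geometry pairs, mock calculator.

Everything downstream of structure generation needs calculator output that
this package deliberately does not produce itself.  This module fabricates
statistically structured stand-ins:

* paired semiempirical/DFT property tables whose reference values follow a
  known linear composition-dependent offset plus Gaussian noise — the exact
  statistical structure the correction model assumes;
* pairs of conformations related by a rigid motion plus per-atom jitter, for
  RMSD and validity-filter work;
* a deterministic mock calculator that supplies plausible geometries and
  energies for all three charge states of a generated molecule.

None of the numbers are physically meaningful; compositions span the ranges
typical of 2-10-ring cata-condensed systems (roughly 14-60 atoms) so the
fixtures stress the same regime as real data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .blocklib import mol_from_smiles
from .correction import CorrectionModel, PairedPropertyTable, default_models
from .energetics import HARTREE_TO_EV, EnergyRecord, Geometry
from .enumerator import MoleculeRecord
from .errors import ContractError

#: Element-count ranges (inclusive) mimicking 2-10-ring cc-hPAS compositions.
DEFAULT_COMPOSITION_RANGES = {
    "c": (8, 40),
    "h": (6, 22),
    "b": (0, 4),
    "s": (0, 4),
    "o": (0, 4),
    "n": (0, 4),
}


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic paired property table.

    ``generator_model`` is the ground-truth linear map; ``noise_sd`` the
    standard deviation of the Gaussian noise added to the reference values
    (default 0.16, the scale of a typical orbital-energy residual in eV).
    ``baseline_loc``/``baseline_sd`` control the normal law of the baseline
    values.
    """

    n_molecules: int = 1000
    generator_model: CorrectionModel | None = None
    noise_sd: float = 0.16
    composition_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_RANGES)
    )
    baseline_loc: float = -13.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ContractError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")
        if self.generator_model is None:
            self.generator_model = default_models()["homo"]


def synth_paired_table(spec: SyntheticSpec) -> PairedPropertyTable:
    """Sample a paired table whose reference obeys the generator model."""
    rng = np.random.default_rng(spec.seed)
    model = spec.generator_model
    data = {}
    for element, (lo, hi) in spec.composition_ranges.items():
        data[element] = rng.integers(lo, hi + 1, size=spec.n_molecules)
    data["baseline"] = rng.normal(
        spec.baseline_loc, spec.baseline_sd, size=spec.n_molecules
    )
    frame = pd.DataFrame(data)
    beta = model.parameter_vector()
    x = frame[[*"hcbson"]].to_numpy(dtype=float)
    clean = x @ beta[:6] + beta[6] * frame["baseline"].to_numpy() + beta[7]
    frame["reference"] = clean + rng.normal(0.0, spec.noise_sd, size=spec.n_molecules)
    return PairedPropertyTable(
        data=frame, property_key=model.property_key, units=model.units
    )


def synth_geometry_pair(
    n_atoms: int,
    displacement_sd: float,
    seed: int = 0,
    rigid: bool = True,
) -> tuple[Geometry, Geometry]:
    """A random chain geometry and a perturbed copy of it.

    The first geometry is a random walk with 1.5-A steps (consecutive atoms
    bonded); the second is the same structure under a random rigid motion
    (rotation + translation, unless ``rigid=False``) plus isotropic Gaussian
    displacement of scale ``displacement_sd`` per atom.
    """
    if n_atoms < 3:
        raise ContractError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_atoms - 1, 3))
    steps = 1.5 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    bonds = tuple((i, i + 1) for i in range(n_atoms - 1))
    first = Geometry(symbols=("C",) * n_atoms, coords=coords, bonds=bonds)

    moved = coords.copy()
    if rigid:
        from scipy.spatial.transform import Rotation

        rotation = Rotation.random(rng=rng)
        moved = rotation.apply(moved) + rng.normal(scale=5.0, size=3)
    moved = moved + rng.normal(scale=displacement_sd, size=moved.shape)
    second = Geometry(symbols=first.symbols, coords=moved, bonds=bonds)
    return first, second


def _stable_seed(*parts) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def mock_calculator(
    record: MoleculeRecord, charge: int, seed: int = 0
) -> tuple[Geometry, EnergyRecord]:
    """Deterministic fake calculator output for one charge state.

    Coordinates come from the 2D ring-template layout (planar, ~1.5-A
    bonds), so they always pass the validity filters.  Energies follow
    seeded composition-dependent formulas arranged so that the cation lies
    above the neutral (AIP > 0) while the anion offset changes sign with
    composition, giving nontrivial AIP/AEA arithmetic.
    """
    if charge not in (-1, 0, 1):
        raise ContractError(f"unsupported charge state {charge}")
    mol = mol_from_smiles(record.smiles)
    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    geometry = Geometry(symbols=symbols, coords=coords, bonds=bonds)

    mol_h = Chem.AddHs(mol)
    counts = {
        e: sum(1 for a in mol_h.GetAtoms() if a.GetSymbol() == e.upper())
        for e in "hcbson"
    }
    rng = np.random.default_rng(_stable_seed(record.inchi, seed))
    # pseudo-atomization energy in Hartree, loosely scaled per element
    e_neutral = -(
        38.0 * counts["c"]
        + 0.55 * counts["h"]
        + 24.6 * counts["b"]
        + 398.1 * counts["s"]
        + 75.1 * counts["o"]
        + 54.6 * counts["n"]
    ) + rng.normal(0.0, 0.05)
    heteroatoms = counts["b"] + counts["s"] + counts["o"] + counts["n"]
    homo = -(5.9 + 0.04 * heteroatoms) + rng.normal(0.0, 0.15)
    gap = max(0.6, 3.8 - 0.25 * record.n_rings + rng.normal(0.0, 0.2))
    lumo = homo + gap
    ip_ev = 6.8 + 0.08 * counts["n"] - 0.04 * counts["s"] + rng.normal(0.0, 0.2)
    aea_ev = -1.2 + 0.5 * counts["b"] - 0.3 * (counts["o"] + counts["s"]) + rng.normal(
        0.0, 0.3
    )

    if charge == 0:
        e_tot = e_neutral
    elif charge == 1:
        e_tot = e_neutral + ip_ev / HARTREE_TO_EV
    else:
        e_tot = e_neutral + aea_ev / HARTREE_TO_EV

    record_out = EnergyRecord(
        charge=charge,
        homo=homo,
        homo_minus1=homo - 0.4 - abs(rng.normal(0.0, 0.1)),
        lumo=lumo,
        lumo_plus1=lumo + 0.4 + abs(rng.normal(0.0, 0.1)),
        e_tot=e_tot,
        zpe=0.003 * sum(counts.values()),
        dispersion=-0.002 * sum(counts.values()),
        converged=True,
        n_imag=0,
    )
    return geometry, record_out
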