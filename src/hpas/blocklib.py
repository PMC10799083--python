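"""Building-block library and single-bond ring fusion.

The generation chemistry lives here: a library of 11 monocyclic building
blocks (aromatic and antiaromatic rings of 4-6 atoms containing B, N, O or
S), each carrying a reaction SMARTS that annulates the block across one C-C
bond of a growing molecule.  Fusion is restricted to bonds whose two atoms
are both carbon and each belong to exactly one ring, which guarantees that
every product is *cata*-condensed (no atom in more than two rings) and that
heteroatoms never end up on a fused bond.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import ConfigurationError, InvalidStructureError

logger = logging.getLogger(__name__)

#: Reactant pattern shared by every fusion transformation: a bond between two
#: carbons that each belong to exactly one ring.
FUSION_REACTANT = "[#6;R1:1]~[#6;R1:2]"

#: Keys of the 11 default building blocks, in library order.
DEFAULT_BLOCK_KEYS = (
    "benzene",
    "pyridine",
    "pyrazine",
    "borinine",
    "14diborinine",
    "dhdiborinine",
    "borole",
    "pyrrole",
    "furan",
    "thiophene",
    "cyclobutadiene",
)

_PROTECTED = "_protected"

_REACTION_CACHE: dict[str, AllChem.ChemicalReaction] = {}


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES, raising :class:`InvalidStructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"could not parse SMILES {smiles!r}")
    return mol


def to_inchi(mol: Chem.Mol) -> str:
    """Standard InChI of a molecule; the package-wide deduplication key."""
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise InvalidStructureError(
            f"InChI generation failed for {Chem.MolToSmiles(mol)}"
        )
    return inchi


@dataclass(frozen=True)
class BuildingBlock:
    """One library entry: a parent ring plus its annulation transformation.

    Parameters
    ----------
    key:
        Short identifier, e.g. ``"pyridine"`` or ``"14diborinine"``.
    parent_smiles:
        SMILES of the isolated monocycle (used to seed a growing molecule).
    fusion_smarts:
        One-reactant, one-product reaction SMARTS whose reactant is
        :data:`FUSION_REACTANT` and whose product template draws the new ring
        across the matched bond.
    ring_size:
        Number of atoms in the ring (4, 5 or 6).
    weight:
        Nonnegative sampling weight used during randomized generation.
    """

    key: str
    parent_smiles: str
    fusion_smarts: str
    ring_size: int
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigurationError(f"block {self.key!r}: negative weight")
        try:
            rxn = AllChem.ReactionFromSmarts(self.fusion_smarts)
        except Exception as exc:  # rdkit raises RuntimeError subclasses
            raise ConfigurationError(
                f"block {self.key!r}: fusion SMARTS does not parse: {exc}"
            ) from exc
        if rxn.GetNumReactantTemplates() != 1 or rxn.GetNumProductTemplates() != 1:
            raise ConfigurationError(
                f"block {self.key!r}: fusion SMARTS must be one-reactant/one-product"
            )
        reactant = self.fusion_smarts.split(">>")[0]
        if reactant != FUSION_REACTANT:
            raise ConfigurationError(
                f"block {self.key!r}: reactant pattern {reactant!r} differs from "
                f"{FUSION_REACTANT!r}"
            )
        parent = mol_from_smiles(self.parent_smiles)
        ring_atoms = sum(1 for a in parent.GetAtoms() if a.IsInRing())
        if ring_atoms != self.ring_size:
            raise ConfigurationError(
                f"block {self.key!r}: ring_size {self.ring_size} does not match "
                f"parent ring of {ring_atoms} atoms"
            )

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        # parsing reaction SMARTS is comparatively slow and fuse_at_bond is
        # called in tight loops during generation, so cache per SMARTS string
        rxn = _REACTION_CACHE.get(self.fusion_smarts)
        if rxn is None:
            rxn = AllChem.ReactionFromSmarts(self.fusion_smarts)
            rxn.Initialize()
            _REACTION_CACHE[self.fusion_smarts] = rxn
        return rxn

    def parent_mol(self) -> Chem.Mol:
        """Fresh sanitized molecule of the isolated parent ring."""
        return mol_from_smiles(self.parent_smiles)


@dataclass
class BlockLibrary:
    """Ordered collection of building blocks with unique keys."""

    blocks: list[BuildingBlock] = field(default_factory=list)

    def __post_init__(self):
        keys = [b.key for b in self.blocks]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate block keys in library")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, key: str) -> BuildingBlock:
        for block in self.blocks:
            if block.key == key:
                return block
        raise KeyError(key)

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(b.key for b in self.blocks)

    @property
    def weights(self) -> dict[str, float]:
        return {b.key: b.weight for b in self.blocks}

    def with_weights(self, weights: dict[str, float]) -> "BlockLibrary":
        """Copy of the library with selected sampling weights replaced."""
        unknown = set(weights) - set(self.keys)
        if unknown:
            raise ConfigurationError(f"unknown block keys: {sorted(unknown)}")
        return BlockLibrary(
            [replace(b, weight=weights.get(b.key, b.weight)) for b in self.blocks]
        )

    def to_config(self) -> dict:
        """Plain-dict form suitable for YAML/JSON serialization."""
        return {
            "blocks": [
                {
                    "key": b.key,
                    "parent_smiles": b.parent_smiles,
                    "fusion_smarts": b.fusion_smarts,
                    "ring_size": b.ring_size,
                    "weight": b.weight,
                }
                for b in self.blocks
            ]
        }

    @classmethod
    def from_config(cls, config: dict) -> "BlockLibrary":
        try:
            entries = config["blocks"]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError("library config lacks a 'blocks' list") from exc
        return cls([BuildingBlock(**entry) for entry in entries])

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "BlockLibrary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_config(yaml.safe_load(fh))


def load_default_library() -> BlockLibrary:
    """The default 11-block library with a 10:1 benzene sampling bias.

    Loaded from the packaged ``data/blocks.yaml`` config; every
    :class:`BuildingBlock` validates its SMARTS and ring size on construction,
    so a corrupted config fails loudly with the offending block named.
    """
    resource = importlib.resources.files("hpas.data").joinpath("blocks.yaml")
    library = BlockLibrary.from_config(yaml.safe_load(resource.read_text()))
    if library.keys != DEFAULT_BLOCK_KEYS:
        raise ConfigurationError(
            f"default library keys {library.keys} differ from {DEFAULT_BLOCK_KEYS}"
        )
    return library


def eligible_fusion_bonds(mol: Chem.Mol) -> list[int]:
    """Bond indices at which a new ring may be annulated.

    A bond qualifies when it is a ring bond, both atoms are carbon, and each
    atom belongs to exactly one ring — the condition that keeps growth
    cata-condensed and heteroatoms off fused bonds.  The returned order is
    canonical (sorted by the canonical-rank pair of the bond's atoms) so
    downstream sampling is reproducible across runs.
    """
    if mol is None:
        raise InvalidStructureError("molecule is None")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise InvalidStructureError(f"unsanitizable molecule: {exc}") from exc
    ring_info = mol.GetRingInfo()
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    found = []
    for bond in mol.GetBonds():
        if not bond.IsInRing():
            continue
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a1.GetAtomicNum() != 6 or a2.GetAtomicNum() != 6:
            continue
        if ring_info.NumAtomRings(a1.GetIdx()) != 1:
            continue
        if ring_info.NumAtomRings(a2.GetIdx()) != 1:
            continue
        found.append(bond.GetIdx())

    def sort_key(bond_idx: int):
        bond = mol.GetBondWithIdx(bond_idx)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rank_pair = tuple(sorted((ranks[i], ranks[j])))
        return (*rank_pair, *sorted((i, j)))

    return sorted(found, key=sort_key)


def fuse_at_bond(
    mol: Chem.Mol, bond_idx: int, block: BuildingBlock
) -> list[Chem.Mol]:
    """Annulate ``block`` across one bond; return distinct sanitized products.

    The block's reaction SMARTS is applied with every atom except the two bond
    endpoints protected, so only the requested bond reacts; both atom-map
    orientations of the match are run and the products are deduplicated by
    standard InChI.  Each product is sanitized (with a SMILES round-trip
    retry that repairs double-bond placement artefacts of the raw reaction
    output); products that cannot be made chemically valid are dropped with a
    logged skip.  The result is sorted by InChI and each product carries its
    InChI in the ``_inchi`` molecule property.
    """
    bond = mol.GetBondWithIdx(bond_idx)
    keep = {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
    work = Chem.Mol(mol)
    for atom in work.GetAtoms():
        if atom.GetIdx() in keep:
            if atom.HasProp(_PROTECTED):
                atom.ClearProp(_PROTECTED)
        else:
            atom.SetProp(_PROTECTED, "1")

    products: dict[str, Chem.Mol] = {}
    for (raw,) in block.reaction.RunReactants((work,)):
        # reaction output copies reactant atom properties; the protection
        # marks must not leak into the product
        for atom in raw.GetAtoms():
            if atom.HasProp(_PROTECTED):
                atom.ClearProp(_PROTECTED)
        product = _sanitize_product(raw)
        if product is None:
            logger.info(
                "skipping invalid fusion product of %s at bond %d", block.key, bond_idx
            )
            continue
        if not _is_cata(product, expected_rings=mol.GetRingInfo().NumRings() + 1):
            logger.info(
                "skipping non-cata fusion product of %s at bond %d",
                block.key,
                bond_idx,
            )
            continue
        try:
            inchi = to_inchi(product)
        except InvalidStructureError:
            continue
        product.SetProp("_inchi", inchi)
        products.setdefault(inchi, product)
    return [products[k] for k in sorted(products)]


def symmetry_unique_bonds(
    mol: Chem.Mol,
    bonds: list[int] | None = None,
    probe: BuildingBlock | None = None,
) -> list[int]:
    """One representative bond per symmetry-equivalence class.

    Two fusion sites are equivalent exactly when annulating a fixed probe
    block (benzene by default) at them gives the same set of product InChIs —
    the operational notion of "same site" that matters for enumeration.  The
    representative of each class is the bond with the lowest canonical-rank
    pair, which makes the output deterministic.
    """
    if bonds is None:
        bonds = eligible_fusion_bonds(mol)
    if probe is None:
        probe = _benzene_probe()
    signatures: dict[frozenset, int] = {}
    for bond_idx in bonds:  # bonds arrive in canonical order
        signature = frozenset(
            p.GetProp("_inchi") for p in fuse_at_bond(mol, bond_idx, probe)
        )
        signatures.setdefault(signature, bond_idx)
    return sorted(signatures.values(), key=bonds.index)


def _benzene_probe() -> BuildingBlock:
    global _PROBE
    if _PROBE is None:
        _PROBE = load_default_library()["benzene"]
    return _PROBE


_PROBE: BuildingBlock | None = None


def _sanitize_product(raw: Chem.Mol) -> Chem.Mol | None:
    """Sanitize a raw reaction product, repairing bond-order artefacts.

    First attempt: standard sanitization of the template output.  On failure
    the product is round-tripped through SMILES, which lets the parser
    re-derive a consistent Kekulé assignment.  Returns ``None`` when both
    attempts fail.
    """
    mol = Chem.Mol(raw)
    try:
        Chem.SanitizeMol(mol)
        return Chem.RemoveHs(mol)
    except Exception:
        pass
    try:
        smiles = Chem.MolToSmiles(raw)
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            return Chem.RemoveHs(mol)
    except Exception:
        pass
    return None


def _is_cata(mol: Chem.Mol, expected_rings: int | None = None) -> bool:
    """True when every atom is in at most two SSSR rings (and the ring count
    matches, when given)."""
    ring_info = mol.GetRingInfo()
    if expected_rings is not None and ring_info.NumRings() != expected_rings:
        return False
    return all(
        ring_info.NumAtomRings(a.GetIdx()) <= 2 for a in mol.GetAtoms()
    )
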