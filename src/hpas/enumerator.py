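"""Randomized growth of cata-condensed hetero-polycyclic aromatic systems.

The workflow mirrors the seven-step protocol the library is built around:

1. draw a ring count ``n`` from a size distribution peaked at 8-9 rings,
2. draw ``n`` building blocks i.i.d. with a 10:1 bias toward benzene,
3. initialize the nascent molecule with the first block,
4. annulate the next block at every available C-C fusion bond,
5. sanitize the candidates and deduplicate them by InChI,
6. select one surviving candidate uniformly at random,
7. repeat 4-6 until the block list is exhausted.

All randomness flows through a single :class:`numpy.random.Generator`, so a
``(config, seed)`` pair reproduces a dataset exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import blocklib
from .blocklib import BlockLibrary, BuildingBlock, load_default_library, to_inchi
from .errors import ConfigurationError, DeadEndError

logger = logging.getLogger(__name__)

#: Rate of the discretized Poisson bump used as the default ring-count law.
DEFAULT_SIZE_RATE = 8.5

#: Number of fresh (n, block list) samples tried before a generation gives up.
DEFAULT_MAX_RETRIES = 25


def default_size_weights(n_min: int = 2, n_max: int = 10) -> dict[int, float]:
    """Ring-count weights proportional to a Poisson(8.5) bump on [n_min, n_max].

    The discretized bump peaks at 8-9 rings, biasing generation toward
    molecules of intermediate size while never exceeding ``n_max``.
    """
    rate = DEFAULT_SIZE_RATE
    return {
        n: math.exp(-rate) * rate**n / math.factorial(n)
        for n in range(n_min, n_max + 1)
    }


@dataclass
class GenerationConfig:
    """Parameters of a randomized generation run.

    ``size_weights`` maps ring counts to categorical weights (defaults to the
    8-9-peaked bump over ``[n_min, n_max]``); ``block_weights`` overrides the
    library's per-block sampling weights (defaults to benzene 10, others 1).
    """

    n_min: int = 2
    n_max: int = 10
    size_weights: dict[int, float] | None = None
    block_weights: dict[str, float] | None = None
    seed: int = 0
    target_count: int = 100
    max_retries: int = DEFAULT_MAX_RETRIES

    def __post_init__(self):
        if not 1 <= self.n_min <= self.n_max:
            raise ConfigurationError("need 1 <= n_min <= n_max")
        if self.size_weights is None:
            self.size_weights = default_size_weights(self.n_min, self.n_max)
        weights = [self.size_weights.get(n, 0.0) for n in self.ns]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigurationError(
                "size_weights must be nonnegative with positive total on [n_min, n_max]"
            )
        if self.target_count < 1:
            raise ConfigurationError("target_count must be >= 1")

    @property
    def ns(self) -> list[int]:
        return list(range(self.n_min, self.n_max + 1))

    def size_probabilities(self) -> np.ndarray:
        w = np.array([self.size_weights.get(n, 0.0) for n in self.ns], dtype=float)
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "n_min": self.n_min,
            "n_max": self.n_max,
            "size_weights": dict(self.size_weights),
            "block_weights": None if self.block_weights is None else dict(self.block_weights),
            "seed": self.seed,
            "target_count": self.target_count,
            "max_retries": self.max_retries,
        }


@dataclass(frozen=True)
class MoleculeRecord:
    """One generated molecule with identifiers and block provenance.

    ``inchi`` is the deduplication key within a dataset; ``block_sequence``
    is the addition order of the consumed building blocks, so for generated
    records ``n_rings == len(block_sequence)``.
    """

    name: str
    smiles: str
    inchi: str
    block_sequence: tuple[str, ...] | None
    n_rings: int

    def __post_init__(self):
        if self.block_sequence is not None and len(self.block_sequence) != self.n_rings:
            raise ConfigurationError(
                f"record {self.name!r}: n_rings={self.n_rings} but "
                f"{len(self.block_sequence)} blocks in provenance"
            )

    def mol(self) -> Chem.Mol:
        return blocklib.mol_from_smiles(self.smiles)


def make_name(index: int, prefix: str = "pas") -> str:
    """Sequential 9-character alphanumeric name, e.g. ``pas000042``."""
    name = f"{prefix}{index:06d}"
    if len(name) != 9:
        raise ConfigurationError(f"name {name!r} is not 9 characters")
    return name


def sample_ring_count(config: GenerationConfig, rng: np.random.Generator) -> int:
    """Draw a ring count from the configured size distribution."""
    return int(rng.choice(config.ns, p=config.size_probabilities()))


def sample_block_sequence(
    n: int,
    config: GenerationConfig,
    rng: np.random.Generator,
    library: BlockLibrary | None = None,
) -> list[str]:
    """Draw ``n`` block keys i.i.d. with the configured block weights."""
    if n < 1:
        raise ConfigurationError("need n >= 1")
    if library is None:
        library = load_default_library()
    if config.block_weights is not None:
        library = library.with_weights(config.block_weights)
    keys = list(library.keys)
    weights = np.array([library[k].weight for k in keys], dtype=float)
    if weights.sum() <= 0:
        raise ConfigurationError("all block weights are zero")
    p = weights / weights.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=p)]


def grow_one_step(
    nascent: Chem.Mol, block: BuildingBlock, rng: np.random.Generator
) -> Chem.Mol:
    """Annulate ``block`` at every eligible bond, then pick one product.

    Candidates from all fusion sites are pooled, deduplicated by InChI and
    one survivor is selected uniformly at random; all other candidates are
    discarded.  Raises :class:`DeadEndError` when no eligible bond yields a
    valid product.
    """
    bonds = blocklib.eligible_fusion_bonds(nascent)
    if not bonds:
        raise DeadEndError("no eligible C-C fusion bond on nascent molecule")
    candidates: dict[str, Chem.Mol] = {}
    for bond_idx in bonds:
        for product in blocklib.fuse_at_bond(nascent, bond_idx, block):
            candidates.setdefault(product.GetProp("_inchi"), product)
    if not candidates:
        raise DeadEndError(f"no valid product when adding block {block.key!r}")
    keys = sorted(candidates)
    return candidates[keys[int(rng.integers(len(keys)))]]


def grow_from_sequence(
    block_keys: list[str],
    rng: np.random.Generator,
    library: BlockLibrary | None = None,
) -> Chem.Mol:
    """Grow a molecule by consuming an explicit ordered block list."""
    if library is None:
        library = load_default_library()
    nascent = library[block_keys[0]].parent_mol()
    for key in block_keys[1:]:
        nascent = grow_one_step(nascent, library[key], rng)
    return nascent


def generate_molecule(
    config: GenerationConfig,
    rng: np.random.Generator,
    library: BlockLibrary | None = None,
) -> MoleculeRecord:
    """One full generation attempt (steps 1-7), with dead-end retries.

    A dead end (a growth step with no valid product) aborts the attempt and
    a fresh ring count and block list are sampled, up to
    ``config.max_retries`` times.
    """
    if library is None:
        library = load_default_library()
    for attempt in range(config.max_retries):
        n = sample_ring_count(config, rng)
        sequence = sample_block_sequence(n, config, rng, library)
        try:
            mol = grow_from_sequence(sequence, rng, library)
        except DeadEndError as exc:
            logger.info("generation attempt %d dead-ended: %s", attempt + 1, exc)
            continue
        return MoleculeRecord(
            name="",
            smiles=Chem.MolToSmiles(mol),
            inchi=to_inchi(mol),
            block_sequence=tuple(sequence),
            n_rings=mol.GetRingInfo().NumRings(),
        )
    raise DeadEndError(
        f"generation failed {config.max_retries} times in a row"
    )


def generate_dataset(
    config: GenerationConfig,
    library: BlockLibrary | None = None,
) -> list[MoleculeRecord]:
    """Run ``target_count`` generations, deduplicate by InChI, assign names.

    Each generation is an independent draw from the configured law; records
    with an InChI already present are dropped (first occurrence wins), so the
    result holds at most ``target_count`` unique molecules.  Names are
    assigned sequentially after deduplication.
    """
    if library is None:
        library = load_default_library()
    rng = np.random.default_rng(config.seed)
    seen: dict[str, MoleculeRecord] = {}
    duplicates = 0
    for _ in range(config.target_count):
        record = generate_molecule(config, rng, library)
        if record.inchi in seen:
            duplicates += 1
            continue
        seen[record.inchi] = record
    logger.info(
        "generated %d unique molecules (%d duplicates removed)",
        len(seen),
        duplicates,
    )
    return [
        MoleculeRecord(
            name=make_name(i),
            smiles=r.smiles,
            inchi=r.inchi,
            block_sequence=r.block_sequence,
            n_rings=r.n_rings,
        )
        for i, r in enumerate(seen.values())
    ]
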