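"""Randomized growth workflow: sampling laws, growth steps, dataset assembly."""

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from hpas.blocklib import eligible_fusion_bonds, fuse_at_bond, to_inchi
from hpas.enumerator import (
    GenerationConfig,
    MoleculeRecord,
    generate_dataset,
    generate_molecule,
    grow_from_sequence,
    grow_one_step,
    make_name,
    sample_block_sequence,
    sample_ring_count,
)
from hpas.errors import ConfigurationError, DeadEndError


def exhaustive_reachable_inchis(library, sequence):
    """Brute-force oracle: all InChIs reachable by consuming ``sequence``."""
    level = {None: library[sequence[0]].parent_mol()}
    for key in sequence[1:]:
        nxt = {}
        for mol in level.values():
            for bond in eligible_fusion_bonds(mol):
                for product in fuse_at_bond(mol, bond, library[key]):
                    nxt[product.GetProp("_inchi")] = product
        level = nxt
    return set(level)


class TestRingCountSampling:
    def test_degenerate_distribution(self):
        config = GenerationConfig(size_weights={3: 1.0})
        rng = np.random.default_rng(0)
        assert all(sample_ring_count(config, rng) == 3 for _ in range(50))

    def test_default_law_bounds_and_mode(self):
        config = GenerationConfig()
        rng = np.random.default_rng(123)
        draws = [sample_ring_count(config, rng) for _ in range(10_000)]
        assert min(draws) >= 2 and max(draws) <= 10
        counts = np.bincount(draws, minlength=11)
        assert counts.argmax() in (8, 9)

    def test_histogram_matches_weights(self):
        config = GenerationConfig()
        rng = np.random.default_rng(5)
        draws = np.array([sample_ring_count(config, rng) for _ in range(20_000)])
        observed = np.array([(draws == n).sum() for n in config.ns])
        expected = config.size_probabilities() * len(draws)
        assert stats.chisquare(observed, expected).pvalue > 1e-3

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            GenerationConfig(size_weights={5: -1.0})
        with pytest.raises(ConfigurationError):
            GenerationConfig(size_weights={1: 1.0})  # outside [n_min, n_max]


class TestBlockSampling:
    def test_degenerate_weights(self, library):
        config = GenerationConfig(block_weights={k: 0.0 for k in library.keys if k != "benzene"})
        rng = np.random.default_rng(0)
        assert sample_block_sequence(4, config, rng, library) == ["benzene"] * 4

    def test_benzene_frequency_is_half(self, library):
        # 10:1 bias over 11 blocks => p(benzene) = 10/20 = 0.5
        config = GenerationConfig()
        rng = np.random.default_rng(2)
        n = 20_000
        sequence = sample_block_sequence(n, config, rng, library)
        freq = sequence.count("benzene") / n
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_seeded_determinism(self, library):
        config = GenerationConfig(seed=9)
        a = sample_block_sequence(30, config, np.random.default_rng(9), library)
        b = sample_block_sequence(30, config, np.random.default_rng(9), library)
        assert a == b


class TestGrowth:
    def test_single_product_step_is_naphthalene(self, library):
        rng = np.random.default_rng(0)
        benzene = library["benzene"].parent_mol()
        grown = grow_one_step(benzene, library["benzene"], rng)
        assert Chem.MolToSmiles(grown) == Chem.CanonSmiles("c1ccc2ccccc2c1")

    def test_step_lands_in_two_member_product_set(self, library):
        reachable = exhaustive_reachable_inchis(library, ["pyridine", "14diborinine"])
        assert len(reachable) == 2
        for seed in range(10):
            rng = np.random.default_rng(seed)
            grown = grow_one_step(
                library["pyridine"].parent_mol(), library["14diborinine"], rng
            )
            assert to_inchi(grown) in reachable

    def test_forced_sequence_lands_in_reachable_set(self, library):
        sequence = ["pyridine", "14diborinine", "benzene"]
        reachable = exhaustive_reachable_inchis(library, sequence)
        assert len(reachable) == 5  # 3 via the three-site bicyclic, 2 via the other
        for seed in range(12):
            mol = grow_from_sequence(sequence, np.random.default_rng(seed), library)
            assert to_inchi(mol) in reachable

    def test_dead_end_raises(self, library):
        # a bare ring always has a fusion site, so force the no-bond branch
        with pytest.raises(DeadEndError):
            grow_one_step(Chem.MolFromSmiles("CC"), library["benzene"], np.random.default_rng(0))


class TestGenerate:
    def test_single_block_molecule(self, library):
        config = GenerationConfig(n_min=1, n_max=1, size_weights={1: 1.0},
                                  block_weights={k: float(k == "thiophene") for k in library.keys})
        record = generate_molecule(config, np.random.default_rng(0), library)
        assert record.n_rings == 1
        assert record.block_sequence == ("thiophene",)
        assert record.inchi == to_inchi(library["thiophene"].parent_mol())

    def test_dataset_is_deterministic_and_unique(self, library):
        config = GenerationConfig(target_count=12, seed=42)
        a = generate_dataset(config, library)
        b = generate_dataset(config, library)
        assert [(r.name, r.smiles, r.inchi, r.block_sequence) for r in a] == [
            (r.name, r.smiles, r.inchi, r.block_sequence) for r in b
        ]
        inchis = [r.inchi for r in a]
        assert len(set(inchis)) == len(inchis) <= 12

    def test_names_are_nine_character_sequential(self):
        assert make_name(0) == "pas000000"
        assert make_name(123456) == "pas123456"
        with pytest.raises(ConfigurationError):
            make_name(1234567)

    def test_record_provenance_consistency(self):
        with pytest.raises(ConfigurationError):
            MoleculeRecord(name="pas000000", smiles="c1ccccc1", inchi="x",
                           block_sequence=("benzene",), n_rings=2)

    def test_bulk_run_structural_invariants(self, dataset200):
        """Every generated molecule is cata-condensed with carbon-only fused
        atoms, ring count equal to its provenance length, and in [2, 10]."""
        assert len({r.inchi for r in dataset200}) == len(dataset200)
        for record in dataset200:
            assert 2 <= record.n_rings <= 10
            assert len(record.block_sequence) == record.n_rings
            mol = record.mol()
            ri = mol.GetRingInfo()
            assert ri.NumRings() == record.n_rings
            for atom in mol.GetAtoms():
                n_rings = ri.NumAtomRings(atom.GetIdx())
                assert n_rings <= 2
                if n_rings == 2:
                    assert atom.GetAtomicNum() == 6
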