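import random
import zlib
from collections import Counter

import numpy as np
import pytest
from rdkit import Chem

from holopls import hologram as hg
from holopls.molecule_io import standardize
from tests._oracles import crc32_oracle, naive_fragment_counts
from tests.conftest import mol_from_smiles


def cfg(mn, mx, flags, L=353):
    return hg.HologramConfig(min_atoms=mn, max_atoms=mx, distinctions=frozenset(flags), length_L=L)


def renumbered(mol, seed):
    order = list(range(mol.mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    return standardize(Chem.RenumberAtoms(mol.mol, order), mol.id)


class TestConfig:
    def test_defaults_are_best_model(self):
        c = hg.HologramConfig()
        assert (c.min_atoms, c.max_atoms, c.length_L) == (5, 8, 353)
        assert c.distinctions == {"A", "C"}

    @pytest.mark.parametrize("kwargs", [
        dict(min_atoms=0, max_atoms=4),
        dict(min_atoms=5, max_atoms=4),
        dict(min_atoms=1, max_atoms=12),
        dict(length_L=100),
        dict(distinctions=frozenset("AX")),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hg.HologramConfig(**kwargs)

    def test_dict_roundtrip(self):
        c = cfg(2, 6, "ABD", 257)
        assert hg.HologramConfig.from_dict(c.to_dict()) == c


class TestEnumeration:
    def test_benzene_counts(self):
        occ = hg.enumerate_fragments(mol_from_smiles("c1ccccc1"), cfg(1, 4, "A"))
        assert len(occ) == 24
        assert len({o.key for o in occ}) == 4

    def test_ethanol_counts(self):
        occ = hg.enumerate_fragments(mol_from_smiles("CCO"), cfg(1, 2, "A"))
        assert len(occ) == 5
        assert len({o.key for o in occ}) == 4

    def test_methane_single_heavy(self):
        occ = hg.enumerate_fragments(mol_from_smiles("C"), cfg(1, 4, "A"))
        assert len(occ) == 1

    def test_size_window_monotonicity(self):
        m = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        totals = [len(hg.enumerate_fragments(m, cfg(1, mx, "AC"))) for mx in range(1, 9)]
        assert totals == sorted(totals)
        assert len(hg.enumerate_fragments(m, cfg(2, 6, "AC"))) <= len(
            hg.enumerate_fragments(m, cfg(1, 7, "AC"))
        )

    def test_enumeration_cap(self):
        m = mol_from_smiles("c1ccc(-c2ccccc2)cc1")
        tight = hg.HologramConfig(min_atoms=1, max_atoms=8, enumeration_cap=10)
        with pytest.raises(hg.EnumerationCapExceeded):
            hg.enumerate_fragments(m, tight)

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "c1ccc2ncccc2c1", "CC(C)(C)CO"])
    @pytest.mark.parametrize("flags", ["A", "AC", "ABC", "ABCDH"])
    def test_matches_naive_oracle(self, smiles, flags):
        m = mol_from_smiles(smiles)
        config = cfg(1, 6, flags)
        occ = Counter(o.key for o in hg.enumerate_fragments(m, config))
        assert occ == naive_fragment_counts(m, config)


class TestCanonicalKeys:
    def test_propane_terminal_symmetry(self):
        m = mol_from_smiles("CCC")
        # RDKit order for CCC: atoms 0 and 2 are terminal
        k0 = hg.canonical_fragment_key(m, [0], "A")
        k2 = hg.canonical_fragment_key(m, [2], "A")
        assert k0.key == k2.key

    def test_connection_flag_distinguishes_parent_degree(self):
        m = mol_from_smiles("CCC")
        terminal = hg.canonical_fragment_key(m, [0], "AC")
        middle = hg.canonical_fragment_key(m, [1], "AC")
        assert terminal.key != middle.key

    def test_path_vs_triangle(self):
        path = hg.canonical_fragment_key(mol_from_smiles("CCC"), [0, 1, 2], "A")
        ring = hg.canonical_fragment_key(mol_from_smiles("C1CC1"), [0, 1, 2], "A")
        assert path.key != ring.key

    def test_bond_flag_distinguishes_orders(self):
        single = hg.canonical_fragment_key(mol_from_smiles("CC"), [0, 1], "B")
        double = hg.canonical_fragment_key(mol_from_smiles("C=C"), [0, 1], "B")
        assert single.key != double.key
        # without B the edge is unlabeled but aromaticity (A) may still differ;
        # pure ethane vs ethene heavy-atom graphs collapse without A/B flags
        s2 = hg.canonical_fragment_key(mol_from_smiles("CC"), [0, 1], "")
        d2 = hg.canonical_fragment_key(mol_from_smiles("C=C"), [0, 1], "")
        assert s2.key == d2.key

    def test_donor_acceptor_flag(self):
        ether_o = hg.canonical_fragment_key(mol_from_smiles("COC"), [1], "D")
        alcohol_o = hg.canonical_fragment_key(mol_from_smiles("CCO"), [2], "D")
        assert ether_o.key != alcohol_o.key  # acceptor-only vs donor+acceptor

    def test_hydrogen_flag_adds_nodes(self):
        m = mol_from_smiles("C")
        occ = hg.enumerate_fragments(m, cfg(1, 5, "H"))
        # CH4 H-explicit: C, 4xH, 4xC-H, plus larger H-C-H stars
        sizes = Counter(o.atom_count for o in occ)
        assert sizes[1] == 5 and sizes[2] == 4

    def test_disconnected_subset_rejected(self):
        with pytest.raises(ValueError):
            hg.canonical_fragment_key(mol_from_smiles("CCC"), [0, 2], "A")

    def test_relabeling_invariance_of_keys(self):
        m = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        config = cfg(1, 5, "AC")
        base = Counter(o.key for o in hg.enumerate_fragments(m, config))
        for seed in range(20):
            perm = Counter(o.key for o in hg.enumerate_fragments(renumbered(m, seed), config))
            assert perm == base


class TestHashing:
    def test_range_and_determinism(self):
        key = hg.FragmentKey(key="C,0,ar;C,0,ar|0-1:-", atom_count=2)
        for L in sorted(hg.ALLOWED_LENGTHS):
            b = hg.hash_to_bin(key, L)
            assert 1 <= b <= L
            assert b == hg.hash_to_bin(key, L)

    def test_against_independent_crc_oracle(self):
        m = mol_from_smiles("c1ccccc1")
        occ = hg.enumerate_fragments(m, cfg(4, 4, "A"))
        key = occ[0]  # 4-carbon aromatic path
        expected = crc32_oracle(key.key.encode("utf-8")) % 353 + 1
        assert hg.hash_to_bin(key, 353) == expected
        assert crc32_oracle(key.key.encode("utf-8")) == zlib.crc32(key.key.encode("utf-8"))

    def test_empty_key_rejected(self):
        with pytest.raises(ValueError):
            hg.hash_to_bin(hg.FragmentKey(key="", atom_count=1), 353)


class TestHologram:
    def test_empty_occurrences(self):
        h = hg.build_hologram([], 53)
        assert h.total_fragments == 0 and not h.bins.any()

    def test_benzene_total(self):
        occ = hg.enumerate_fragments(mol_from_smiles("c1ccccc1"), cfg(1, 4, "A"))
        h = hg.build_hologram(occ, 353)
        assert h.bins.sum() == h.total_fragments == 24

    def test_relabeled_identical(self):
        m = mol_from_smiles("c1ccccc1")
        config = cfg(1, 4, "A")
        base = hg.build_hologram(hg.enumerate_fragments(m, config), 353).bins
        for seed in range(20):
            other = hg.build_hologram(hg.enumerate_fragments(renumbered(m, seed), config), 353).bins
            assert (other == base).all()

    def test_total_conserved_across_lengths(self):
        m = mol_from_smiles("CC(=O)Nc1ccc(O)cc1")
        occ = hg.enumerate_fragments(m, cfg(1, 5, "AC"))
        assert hg.build_hologram(occ, 53).bins.sum() == hg.build_hologram(occ, 353).bins.sum()

    def test_bad_length(self):
        with pytest.raises(ValueError):
            hg.build_hologram([], 100)


class TestMatrix:
    def test_identical_molecules_identical_rows(self):
        mols = [mol_from_smiles("c1ccccc1", "a"), mol_from_smiles("c1ccccc1", "b")]
        X, ids, failures = hg.hologram_matrix(mols, cfg(1, 4, "A"))
        assert not failures and ids == ["a", "b"]
        assert (X[0] == X[1]).all()

    def test_shape_and_row_sums(self):
        smiles = ["CCO", "c1ccccc1", "CCN", "C1CCCCC1"]
        mols = [mol_from_smiles(s, f"m{i}") for i, s in enumerate(smiles)]
        config = cfg(1, 3, "AC")
        X, ids, _ = hg.hologram_matrix(mols, config)
        assert X.shape == (4, 353)
        for row, m in zip(X, mols):
            assert row.sum() == len(hg.enumerate_fragments(m, config))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            hg.hologram_matrix([], cfg(1, 3, "A"))

    def test_failing_molecule_aborts_unless_skipped(self):
        mols = [mol_from_smiles("c1ccc(-c2ccccc2)cc1", "big"), mol_from_smiles("CCO", "ok")]
        config = hg.HologramConfig(min_atoms=1, max_atoms=8, enumeration_cap=10)
        with pytest.raises(RuntimeError):
            hg.hologram_matrix(mols, config)
        X, ids, failures = hg.hologram_matrix(mols, config, skip_errors=True)
        assert ids == ["ok"] and len(failures) == 1 and failures[0][0] == "big"
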