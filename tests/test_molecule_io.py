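import random

import numpy as np
import pytest
from rdkit import Chem

from holopls import molecule_io as mio
from tests._oracles import greedy_maxmin_by_hand
from tests.conftest import mol_from_smiles


def shuffled_smiles(smiles: str, seed: int) -> str:
    """Same molecule, randomly renumbered atoms."""
    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)


class TestLoadAndStandardize:
    def test_benzene_smi(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("c1ccccc1 benzene\n")
        result = mio.load_molecules(p)
        assert len(result.molecules) == 1 and not result.rejects
        m = result.molecules[0]
        assert m.id == "benzene"
        assert m.num_heavy_atoms == 6
        assert all(d["element"] == "C" and d["aromatic"] for _, d in m.graph.nodes(data=True))

    def test_ethanol_degrees(self):
        m = mol_from_smiles("CCO")
        assert m.num_heavy_atoms == 3
        degs = sorted(d["heavy_degree"] for _, d in m.graph.nodes(data=True))
        assert degs == [1, 1, 2]

    def test_salt_stripping_keeps_largest_fragment(self):
        m = mol_from_smiles("CC(=O)[O-].[Na+]", "salt")
        assert m.num_heavy_atoms == 4
        assert "Na" not in m.canonical_smiles

    def test_tie_single_fragment_kept(self):
        m = mol_from_smiles("C.C")
        assert m.num_heavy_atoms == 1

    def test_quinoline(self):
        m = mol_from_smiles("c1ccc2ncccc2c1")
        assert m.num_heavy_atoms == 10
        arom_n = [d for _, d in m.graph.nodes(data=True) if d["element"] == "N" and d["aromatic"]]
        assert len(arom_n) == 1

    @pytest.mark.parametrize("smiles", ["c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "C1CCNCC1"])
    def test_canonical_smiles_order_invariant(self, smiles):
        reference = mol_from_smiles(smiles).canonical_smiles
        for seed in range(5):
            assert mol_from_smiles(shuffled_smiles(smiles, seed)).canonical_smiles == reference

    def test_standardize_idempotent(self):
        m = mol_from_smiles("CC(=O)[O-].[Na+]")
        again = mio.standardize(m.mol, m.id)
        assert again.canonical_smiles == m.canonical_smiles

    def test_unparsable_record_rejected_not_dropped(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("c1ccccc1 ok\nnot_a_smiles)( bad\nCCO ok2\n")
        result = mio.load_molecules(p)
        assert [m.id for m in result.molecules] == ["ok", "ok2"]
        assert len(result.rejects) == 1
        assert result.rejects[0].line_no == 2

    def test_missing_file_fatal(self):
        with pytest.raises(FileNotFoundError):
            mio.load_molecules("/nonexistent/file.smi")

    def test_sdf_roundtrip(self, tmp_path):
        p = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(p))
        for smi, name in [("c1ccccc1", "benzene"), ("CCO", "ethanol")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", name)
            writer.write(mol)
        writer.close()
        result = mio.load_molecules(p)
        assert [m.id for m in result.molecules] == ["benzene", "ethanol"]


class TestFingerprints:
    def test_order_invariance(self):
        base = mio.circular_fingerprint(mol_from_smiles("CC(=O)Nc1ccc(O)cc1"))
        for seed in range(3):
            fp = mio.circular_fingerprint(mol_from_smiles(shuffled_smiles("CC(=O)Nc1ccc(O)cc1", seed)))
            assert fp.on_bits == base.on_bits

    def test_benzene_vs_cyclohexane_differ(self):
        a = mio.circular_fingerprint(mol_from_smiles("c1ccccc1"))
        b = mio.circular_fingerprint(mol_from_smiles("C1CCCCC1"))
        assert mio.tanimoto_distance(a, b) > 0

    def test_methane_nonempty(self):
        fp = mio.circular_fingerprint(mol_from_smiles("C"))
        assert len(fp.on_bits) >= 1

    def test_n_bits_too_small(self):
        with pytest.raises(ValueError):
            mio.circular_fingerprint(mol_from_smiles("C"), n_bits=32)


def fp(bits, mol_id="x", n_bits=2048):
    return mio.CircularFingerprint(id=mol_id, on_bits=frozenset(bits), n_bits=n_bits)


class TestTanimoto:
    def test_identical_zero(self):
        assert mio.tanimoto_distance(fp({1, 5, 9}), fp({1, 5, 9})) == 0.0

    def test_disjoint_one(self):
        assert mio.tanimoto_distance(fp({1, 2}), fp({3, 4})) == 1.0

    def test_direct_formula(self):
        assert mio.tanimoto_distance(fp({1, 2, 3}), fp({2, 3, 4})) == pytest.approx(0.5)

    def test_both_empty_zero_by_convention(self):
        assert mio.tanimoto_distance(fp(set()), fp(set())) == 0.0

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            mio.tanimoto_distance(fp({1}), fp({1}, n_bits=1024))

    def test_symmetry(self):
        a, b = fp({1, 2, 3, 7}), fp({2, 9})
        assert mio.tanimoto_distance(a, b) == mio.tanimoto_distance(b, a)


SMILES_POOL = ["c1ccccc1", "CCO", "CCN", "C1CCCCC1", "c1ccncc1", "CC(=O)O", "CCCC"]


class TestMaxMin:
    def fps(self, smiles_list):
        return [mio.circular_fingerprint(mol_from_smiles(s, f"m{i}")) for i, s in enumerate(smiles_list)]

    def test_select_all(self):
        fps = self.fps(SMILES_POOL[:4])
        result = mio.maxmin_diverse_select(fps, 4, seed=0)
        assert sorted(result.selected_ids) == sorted(f.id for f in fps)
        assert result.remaining_ids == []

    def test_partition_invariant(self):
        fps = self.fps(SMILES_POOL)
        result = mio.maxmin_diverse_select(fps, 3, seed=5)
        all_ids = {f.id for f in fps}
        assert set(result.selected_ids) | set(result.remaining_ids) == all_ids
        assert set(result.selected_ids) & set(result.remaining_ids) == set()

    def test_duplicates_deferred(self):
        # two duplicates: the second of the pair can only appear via a distance-0 pick
        fps = self.fps(["c1ccccc1", "c1ccccc1", "CCO", "C1CCCCC1"])
        for seed in range(8):
            result = mio.maxmin_diverse_select(fps, 3, seed=seed)
            dup_picks = [i for i, mid in enumerate(result.selected_ids) if mid in ("m0", "m1")]
            if len(dup_picks) == 2:
                # the second duplicate pick must coincide with a zero min-distance
                second = max(dup_picks)
                assert result.min_distance_trace[second - 1] == pytest.approx(0.0)

    def test_matches_hand_run_greedy(self):
        fps = self.fps(SMILES_POOL[:5])
        n = len(fps)
        dist = np.array([[mio.tanimoto_distance(fps[i], fps[j]) for j in range(n)] for i in range(n)])
        for seed in range(5):
            result = mio.maxmin_diverse_select(fps, 3, seed=seed)
            first = [f.id for f in fps].index(result.selected_ids[0])
            expected = greedy_maxmin_by_hand(dist, first, 3)
            assert result.selected_ids == [fps[i].id for i in expected]

    def test_deterministic(self):
        fps = self.fps(SMILES_POOL)
        a = mio.maxmin_diverse_select(fps, 4, seed=11)
        b = mio.maxmin_diverse_select(fps, 4, seed=11)
        assert a.selected_ids == b.selected_ids
        assert a.min_distance_trace == b.min_distance_trace

    def test_oversized_selection_rejected(self):
        fps = self.fps(SMILES_POOL[:3])
        with pytest.raises(ValueError):
            mio.maxmin_diverse_select(fps, 4, seed=0)
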