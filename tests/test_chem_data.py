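"""Molecule containers, QM9 ingestion, splits, energy baseline, fingerprints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placemol import chem_data as cd
from placemol.chem_data import (Composition, Fingerprint, HARTREE_TO_EV,
                                Molecule, MoleculeDataset, ParseError,
                                composition, fit_energy_baseline, load_qm9,
                                path_fingerprint, read_xyz,
                                relative_atomic_energy, split_dataset,
                                tanimoto, write_xyz)
from placemol.fixtures import ToySpec, curated_fixture, make_toy_dataset
from placemol.validity import perceive_bonds


def _qm9_record(index, types, positions, props_ha):
    """One QM9-style extended-XYZ record (15 property fields, Hartree)."""
    values = {"A": 1.0, "B": 1.0, "C": 1.0, "mu": 0.0, "alpha": 10.0,
              "homo": -0.2, "lumo": 0.05, "gap": 0.25, "r2": 100.0,
              "zpve": 0.1, "U0": -40.0, "U": -40.0, "H": -40.0, "G": -40.0,
              "Cv": 5.0}
    values.update(props_ha)
    line2 = f"gdb {index}\t" + "\t".join(f"{values[k]:.6f}"
                                         for k in cd.QM9_FIELDS)
    lines = [str(len(types)), line2]
    for z, r in zip(types, positions):
        lines.append(f"{cd.Z_TO_SYMBOL[z]}\t{r[0]:.6f}\t{r[1]:.6f}\t"
                     f"{r[2]:.6f}\t-0.1")
    lines.append("100.0 200.0 300.0")  # frequencies line, as in QM9 files
    lines.append("C C")
    lines.append("InChI=1S/C InChI=1S/C")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def qm9_dir(tmp_path):
    m = curated_fixture("methane")
    for i in range(1, 4):
        (tmp_path / f"dsgdb9nsd_{i:06d}.xyz").write_text(
            _qm9_record(i, m.types, m.positions + 0.001 * i,
                        {"U0": -40.0 - i, "gap": 0.25}))
    return tmp_path


class TestQM9Ingestion:
    def test_loads_each_record_with_ev_conversion(self, qm9_dir):
        ds = load_qm9(qm9_dir)
        assert len(ds) == 3
        assert ds[0].id == "gdb_1"
        assert ds[0].properties["U0"] == pytest.approx(-41.0 * HARTREE_TO_EV)
        assert ds[0].properties["gap"] == pytest.approx(0.25 * HARTREE_TO_EV)
        assert ds[0].properties["alpha"] == pytest.approx(10.0)  # not energetic

    def test_star_caret_exponent_quirk(self, tmp_path):
        m = curated_fixture("h2")
        rec = _qm9_record(1, m.types, m.positions, {})
        rec = rec.replace("0.250000", "2.5*^-1")
        (tmp_path / "a.xyz").write_text(rec)
        ds = load_qm9(tmp_path)
        assert ds[0].properties["gap"] == pytest.approx(0.25 * HARTREE_TO_EV)

    def test_atom_count_mismatch_names_record(self, tmp_path):
        m = curated_fixture("methane")
        rec = _qm9_record(1, m.types, m.positions, {})
        bad = rec.replace("5\ngdb", "4\ngdb", 1)
        (tmp_path / "bad.xyz").write_text(bad)
        with pytest.raises(ParseError, match="bad.xyz"):
            load_qm9(tmp_path)

    def test_unreadable_path(self, tmp_path):
        with pytest.raises(IOError):
            load_qm9(tmp_path / "missing")

    def test_malformed_property_line(self, tmp_path):
        (tmp_path / "x.xyz").write_text("1\nonly three fields\nH 0 0 0\n")
        with pytest.raises(ParseError, match="x.xyz"):
            load_qm9(tmp_path)


class TestXYZRoundTrip:
    @pytest.mark.parametrize("name", ["methane", "ethanol", "h2",
                                      "cis_difluoroethene"])
    def test_coordinates_and_types_survive(self, tmp_path, name):
        mol = curated_fixture(name)
        write_xyz(tmp_path / "m.xyz", [mol])
        back = read_xyz(tmp_path / "m.xyz")[0]
        np.testing.assert_allclose(back.positions, mol.positions, atol=1e-6)
        np.testing.assert_array_equal(back.types, mol.types)

    def test_multi_record(self, tmp_path):
        mols = [curated_fixture("methane"), curated_fixture("h2")]
        write_xyz(tmp_path / "m.xyz", mols)
        back = read_xyz(tmp_path / "m.xyz")
        assert [m.n_atoms for m in back] == [5, 2]


class TestComposition:
    def test_ethane_counts_and_fractions(self):
        comp = composition(curated_fixture("ethane"))
        assert comp.count_map == {6: 2, 1: 6}
        assert comp.fractions[6] == pytest.approx(0.25)
        assert comp.fractions[1] == pytest.approx(0.75)

    def test_single_atom(self):
        comp = composition(Molecule(np.zeros((1, 3)), np.array([1])))
        assert comp.count_map == {1: 1}
        assert comp.fractions == {1: 1.0}

    def test_c7h11no_formula(self, rng):
        types = np.array([6] * 7 + [1] * 11 + [7] + [8])
        pos = rng.normal(size=(20, 3)) * 5
        comp = composition(Molecule(pos, types))
        assert comp.count_map == {6: 7, 1: 11, 7: 1, 8: 1}
        assert comp.formula() == "C7H11N1O1"

    def test_permutation_invariant(self, rng):
        mol = curated_fixture("ethanol")
        perm = rng.permutation(mol.n_atoms)
        shuffled = Molecule(mol.positions[perm], mol.types[perm])
        assert composition(mol) == composition(shuffled)


class TestSplitDataset:
    @pytest.fixture()
    def toy100(self):
        return make_toy_dataset(ToySpec(palette=(6,), seed=3), 100)

    def test_deterministic_under_seed(self, toy100):
        kw = dict(n_pool=10, n_train=8, n_val=2, seed=5,
                  validity_filter=lambda m: True)
        a = split_dataset(toy100, **kw)
        b = split_dataset(toy100, **kw)
        for sa, sb in zip(a, b):
            assert [m.id for m in sa] == [m.id for m in sb]

    def test_disjoint_and_remainder_arithmetic(self, toy100):
        n_invalid = 0

        def validity(m):  # declare every 7th molecule invalid
            nonlocal n_invalid
            bad = int(m.id.split("-")[1]) % 7 == 0
            return not bad

        train, val, test = split_dataset(toy100, 20, 15, 5, seed=1,
                                         validity_filter=validity)
        ids = [m.id for m in train] + [m.id for m in val] + [m.id for m in test]
        assert len(set(ids)) == len(ids)
        n_bad = sum(1 for m in toy100 if int(m.id.split("-")[1]) % 7 == 0)
        assert len(test) == 100 - n_bad - 20

    def test_excluded_molecules_stay_in_test(self, toy100):
        keep = lambda m: m.n_atoms != 5  # noqa: E731
        train, val, test = split_dataset(toy100, 10, 8, 2, exclusion_filter=keep,
                                         seed=2, validity_filter=lambda m: True)
        assert all(m.n_atoms != 5 for m in train)
        assert all(m.n_atoms != 5 for m in val)
        assert any(m.n_atoms == 5 for m in test)

    def test_overdemand_raises(self, toy100):
        with pytest.raises(ValueError):
            split_dataset(toy100, 200, 8, 2, seed=0,
                          validity_filter=lambda m: True)
        with pytest.raises(ValueError):
            split_dataset(toy100, 10, 8, 2, exclusion_filter=lambda m: False,
                          seed=0, validity_filter=lambda m: True)


class TestEnergyBaseline:
    def test_exactly_determined_two_species(self):
        h2 = Molecule(np.array([[0, 0, 0], [0, 0, 0.74]]), np.array([1, 1]),
                      properties={"energy": -2.0})
        h4 = Molecule(np.array([[0, 0, 0], [0, 0, 0.74], [3, 0, 0],
                                [3, 0, 0.74]]), np.array([1, 1, 1, 1]),
                      properties={"energy": -4.0})
        base = fit_energy_baseline(MoleculeDataset([h2, h4]), "energy")
        assert base.per_type_energy[1] == pytest.approx(-1.0)

    def test_recovers_generating_coefficients(self):
        coeffs = {6: -5.0, 8: -7.5}
        ds = make_toy_dataset(ToySpec(palette=(6, 8), size_min=3, size_max=9,
                                      energy_coeffs=coeffs, energy_noise=0.02,
                                      seed=11), 300)
        base = fit_energy_baseline(ds, "energy")
        for z, c in coeffs.items():
            assert base.per_type_energy[z] == pytest.approx(
                c, abs=5 * 0.02 / np.sqrt(300))

    def test_relative_energy_arithmetic(self):
        base = cd.EnergyBaseline({1: -1.0})
        h2 = Molecule(np.array([[0, 0, 0], [0, 0, 0.74]]), np.array([1, 1]),
                      properties={"energy": -2.5})
        assert relative_atomic_energy(h2, base, "energy") == pytest.approx(-0.25)

    def test_exact_residual_identity_on_fit_split(self):
        ds = make_toy_dataset(ToySpec(palette=(6, 8), size_min=3, size_max=9,
                                      energy_coeffs={6: -5.0, 8: -7.5},
                                      energy_noise=0.5, seed=12), 120)
        base = fit_energy_baseline(ds, "energy")
        rae = np.array([relative_atomic_energy(m, base, "energy") for m in ds])
        n = np.array([m.n_atoms for m in ds], dtype=float)
        # atom-count vector is in the design column space -> exact orthogonality
        assert abs((rae * n * n).sum()) / (n * n).sum() < 1e-9

    def test_rank_deficient_names_type(self):
        # oxygen count never varies independently of carbon count
        mols = []
        for k in (2, 4, 6):
            pos = np.arange(3 * 2 * k).reshape(-1, 3) * 1.0
            types = np.array([6, 8] * k)
            mols.append(Molecule(pos, types, properties={"energy": -k * 12.5}))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_energy_baseline(MoleculeDataset(mols), "energy")


class TestFingerprints:
    def test_deterministic_and_graph_only(self):
        eth = curated_fixture("ethanol")
        fp1 = path_fingerprint(eth, perceive_bonds(eth))
        fp2 = path_fingerprint(eth, perceive_bonds(eth))
        assert fp1 == fp2
        # a rotated conformer shares the bond graph, hence the fingerprint
        rot = Molecule(eth.positions @ _rotation(0.7), eth.types)
        assert path_fingerprint(rot, perceive_bonds(rot)) == fp1

    def test_methane_vs_ethane_differ(self):
        m, e = curated_fixture("methane"), curated_fixture("ethane")
        assert path_fingerprint(m, perceive_bonds(m)) != \
            path_fingerprint(e, perceive_bonds(e))

    def test_tanimoto_examples(self):
        a = np.zeros(1024, dtype=bool)
        b = np.zeros(1024, dtype=bool)
        a[[1, 2, 3]] = True
        b[[2, 3, 4]] = True
        fa, fb = Fingerprint.from_array(a), Fingerprint.from_array(b)
        assert tanimoto(fa, fb) == pytest.approx(0.5)
        assert tanimoto(fa, fa) == 1.0
        empty = Fingerprint.from_array(np.zeros(1024, dtype=bool))
        assert tanimoto(empty, empty) == 1.0
        assert tanimoto(fa, empty) == 0.0

    def test_tanimoto_against_toolkit(self):
        from rdkit import Chem, DataStructs

        m, e = curated_fixture("methane"), curated_fixture("ethanol")
        gm, ge = perceive_bonds(m), perceive_bonds(e)
        ours = tanimoto(path_fingerprint(m, gm), path_fingerprint(e, ge))
        fpm = Chem.RDKFingerprint(gm.to_rdkit(), minPath=1, maxPath=7,
                                  fpSize=1024)
        fpe = Chem.RDKFingerprint(ge.to_rdkit(), minPath=1, maxPath=7,
                                  fpSize=1024)
        assert ours == pytest.approx(DataStructs.TanimotoSimilarity(fpm, fpe))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1023), max_size=40),
           st.lists(st.integers(0, 1023), max_size=40))
    def test_tanimoto_symmetric_bounded(self, bits_a, bits_b):
        a = np.zeros(1024, dtype=bool)
        b = np.zeros(1024, dtype=bool)
        a[bits_a] = True
        b[bits_b] = True
        fa, fb = Fingerprint.from_array(a), Fingerprint.from_array(b)
        s = tanimoto(fa, fb)
        assert s == tanimoto(fb, fa)
        assert 0.0 <= s <= 1.0


def _rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
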