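"""Parsing, annotation, and neighborhood extraction."""

import numpy as np
import biotite.structure as bst
import pytest

from holoprot import (
    ParseError,
    Structure,
    add_noise,
    annotate,
    extract_neighborhoods,
    make_polyalanine,
    read_structure,
)
from holoprot.structure import RESIDUE_FORMAL_CHARGE, load_charge_table


def _pdb_line(ser, name, alt, res, chain, resid, xyz, occ, elem):
    return (f"ATOM  {ser:5d} {name:<4s}{alt}{res:<3s} {chain}{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {elem:>2s}")


def _toy_atom_array(coords, elements, res_ids=None, res_names=None, atom_names=None):
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=float)
    arr.chain_id = np.full(n, "A", dtype="U4")
    arr.res_id = np.asarray(res_ids if res_ids is not None else np.ones(n), dtype=int)
    arr.res_name = np.asarray(res_names if res_names is not None else ["ALA"] * n,
                              dtype="U5")
    arr.atom_name = np.asarray(atom_names if atom_names is not None
                               else [f"C{i}" for i in range(n)], dtype="U6")
    arr.element = np.asarray(elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


class TestReadStructure:
    def test_polyalanine_round_trip(self, tmp_path):
        st = make_polyalanine(3)
        path = tmp_path / "tri.pdb"
        st.to_pdb(path)
        back = read_structure(path)
        assert back.n_residues == 3
        for i in range(3):
            sl = back.residue_slice(i)
            assert sl.stop - sl.start == 5  # N, CA, C, O, CB
        np.testing.assert_allclose(back.coords, st.coords, atol=1e-3)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            _pdb_line(1, "N", " ", "ALA", "A", 1, (0, 0, 0), 1.0, "N"),
            _pdb_line(2, "CA", "A", "ALA", "A", 1, (1.458, 0, 0), 0.6, "C"),
            _pdb_line(3, "CA", "B", "ALA", "A", 1, (2.458, 0, 0), 0.4, "C"),
            _pdb_line(4, "C", " ", "ALA", "A", 1, (2.0, 1.3, 0), 1.0, "C"),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        st = read_structure(path)
        ca = st.backbone_coords(0, "CA")
        assert ca[0] == pytest.approx(1.458, abs=1e-3)  # altloc A (occ 0.6) won
        assert st.array.array_length() == 3

    def test_water_removed(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", " ", "ALA", "A", 1, (0, 0, 0), 1.0, "C"),
            _pdb_line(2, "O", " ", "HOH", "A", 2, (5, 0, 0), 1.0, "O"),
            "END",
        ]
        path = tmp_path / "wat.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert read_structure(path).array.array_length() == 1

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises((ParseError, ValueError)):
            read_structure(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestAnnotate:
    def test_sasa_matches_dense_quadrature_oracle(self):
        """Shrake-Rupley at the working point count vs a 10x denser oracle run."""
        st = make_polyalanine(3)
        coarse = annotate(st.copy())              # working default point count
        dense = annotate(st.copy(), sasa_points=2560)
        total_c = coarse.array.sasa.sum()
        total_d = dense.array.sasa.sum()
        assert total_c == pytest.approx(total_d, rel=0.02)

    def test_buried_atom_zero_sasa(self):
        # one carbon at the centre of a dense two-shell cage (plus an H to
        # select the element-generic radius set)
        pts = [np.zeros(3)]
        for radius, n in ((2.2, 40), (3.6, 80)):
            golden = (1 + np.sqrt(5)) / 2
            i = np.arange(n)
            z = 1 - (2 * i + 1) / n
            phi = 2 * np.pi * i / golden
            s = np.sqrt(1 - z**2)
            pts.extend(radius * np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1))
        pts.append(np.array([50.0, 0.0, 0.0]))
        elems = ["C"] * (len(pts) - 1) + ["H"]
        arr = _toy_atom_array(pts, elems)
        st = annotate(Structure(arr))
        assert st.array.sasa[0] == 0.0

    def test_charge_table_sums_to_formal_charges(self):
        table = load_charge_table()
        sums = {}
        for (res, _), q in table.items():
            sums[res] = sums.get(res, 0.0) + q
        for res, total in sums.items():
            assert total == pytest.approx(RESIDUE_FORMAL_CHARGE.get(res, 0.0))

    def test_charges_assigned_by_lookup(self):
        arr = _toy_atom_array(
            [(0, 0, 0), (1.5, 0, 0), (3.0, 0, 0)], ["N", "C", "C"],
            res_ids=[1, 1, 1], res_names=["LYS"] * 3,
            atom_names=["NZ", "CE", "CA"],
        )
        st = annotate(Structure(arr))
        assert st.array.charge[0] == 1.0
        assert st.array.charge[1] == 0.0


class TestExtractNeighborhoods:
    def test_focal_residue_excluded_and_radius_strict(self):
        st = make_polyalanine(14)
        annotate(st)
        nbs = extract_neighborhoods(st, radius=10.0)
        assert len(nbs) == 14
        res_of = st.residue_index_of_atoms()
        for i, nb in enumerate(nbs):
            assert nb.max_radius() < 10.0
            # no point may coincide with a focal-residue atom position
            ca = st.backbone_coords(i, "CA")
            own = st.coords[res_of == i] - ca
            for p in nb.atom_coords:
                assert np.linalg.norm(own - p, axis=1).min() > 1e-6

    def test_far_apart_residues_have_empty_neighborhoods(self):
        arr = _toy_atom_array(
            [(0, 0, 0), (1.458, 0, 0), (2.0, 1.3, 0),
             (50, 0, 0), (51.458, 0, 0), (52.0, 1.3, 0)],
            ["N", "C", "C"] * 2,
            res_ids=[1, 1, 1, 2, 2, 2], res_names=["ALA"] * 6,
            atom_names=["N", "CA", "C"] * 2,
        )
        nbs = extract_neighborhoods(Structure(arr), channels=("carbon", "nitrogen"))
        assert [nb.n_atoms for nb in nbs] == [0, 0]

    def test_neighbor_at_known_distance_recentred(self):
        arr = _toy_atom_array(
            [(0, 0, 0), (1.458, 0, 0), (2.0, 1.3, 0), (5.458, 0, 0)],
            ["N", "C", "C", "O"],
            res_ids=[1, 1, 1, 2], res_names=["ALA", "ALA", "ALA", "GLY"],
            atom_names=["N", "CA", "C", "O"],
        )
        nbs = extract_neighborhoods(Structure(arr), channels=("oxygen",))
        nb1 = nbs[0]  # focal residue 1, CA at (1.458, 0, 0); O neighbor 4 A away
        assert nb1.n_atoms == 1
        assert np.linalg.norm(nb1.atom_coords[0]) == pytest.approx(4.0)

    def test_translation_invariance(self):
        st = make_polyalanine(10)
        moved = st.transformed(translation=np.array([11.0, -3.0, 7.0]))
        nbs0 = extract_neighborhoods(st, channels=("carbon",))
        nbs1 = extract_neighborhoods(moved, channels=("carbon",))
        for a, b in zip(nbs0, nbs1):
            # identical up to the rounding of the translated coordinates
            np.testing.assert_allclose(a.atom_coords, b.atom_coords, atol=1e-9)

    def test_charge_channel_requires_annotation(self):
        st = make_polyalanine(5)
        with pytest.raises(ValueError):
            extract_neighborhoods(st, channels=("carbon", "charge"))


class TestAddNoise:
    def test_sigma_zero_identity_and_determinism(self):
        st = make_polyalanine(8)
        nb = extract_neighborhoods(st, channels=("carbon",))[3]
        same = add_noise(nb, 0.0, seed=5)
        np.testing.assert_array_equal(same.atom_coords, nb.atom_coords)
        a = add_noise(nb, 0.4, seed=7)
        b = add_noise(nb, 0.4, seed=7)
        np.testing.assert_array_equal(a.atom_coords, b.atom_coords)
        c = add_noise(nb, 0.4, seed=8)
        assert not np.array_equal(a.atom_coords, c.atom_coords)

    def test_negative_sigma_rejected(self):
        st = make_polyalanine(5)
        nb = extract_neighborhoods(st, channels=("carbon",))[2]
        with pytest.raises(ValueError):
            add_noise(nb, -0.1, seed=0)

    def test_empirical_sd_matches_sigma(self):
        from holoprot import make_random_neighborhood
        nb = make_random_neighborhood(10_000, radius=9.0, seed=0)
        noisy = add_noise(nb, 0.5, seed=1)
        diff = noisy.atom_coords - nb.atom_coords
        assert np.std(diff) == pytest.approx(0.5, rel=0.03)
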