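"""Structure I/O: format round-trips, fractional/Cartesian conversion,
disorder resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evpkit import (
    AtomRecord,
    CrystalCell,
    MolecularStructure,
    cart_to_frac,
    frac_to_cart,
    read_structure,
    resolve_disorder,
    write_structure,
)
from evpkit.exceptions import FormatError, InputError, ValidationError


def _structure(coords, elements=None, bonds=None, cell=None):
    coords = np.asarray(coords, dtype=float)
    elements = elements or ["C"] * len(coords)
    atoms = [
        AtomRecord(e, c, label=f"{e}{i + 1}")
        for i, (e, c) in enumerate(zip(elements, coords))
    ]
    return MolecularStructure(atoms, bonds or [], cell=cell)


class TestReaders:
    def test_xyz_coordinates_pass_through(self, tmp_path):
        path = tmp_path / "three.xyz"
        path.write_text("3\ncomment\nC 0 0 0\nC 1.5 0 0\nO 0 1.5 0\n")
        s = read_structure(path)
        assert len(s) == 3 and not s.bonds
        assert [a.element for a in s.atoms] == ["C", "C", "O"]
        assert s.distance(1, 2) == pytest.approx(1.5 * math.sqrt(2))

    def test_sdf_two_atoms_one_bond(self, tmp_path):
        molblock = (
            "two\n  evpkit\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.5000    0.0000    0.0000 C   0  0\n"
            "  1  2  1  0\n"
            "M  END\n"
        )
        path = tmp_path / "two.sdf"
        path.write_text(molblock)
        s = read_structure(path)
        assert len(s) == 2
        assert s.bonds == [(0, 1, 1)]

    def test_unreadable_file_names_input_error(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\nc\nC 0 0 0\nC nan_is_fine? no no\n")
        with pytest.raises(InputError, match="line 4"):
            read_structure(path)

    def test_unknown_element_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\nc\nZz 0 0 0\n")
        with pytest.raises(ValidationError, match="element"):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_structure(tmp_path / "nope.xyz")

    def test_cif_roundtrip_converts_to_cartesian(self, tmp_path):
        cell = CrystalCell(5, 6, 7, 80, 95, 100)
        s = _structure([[0, 0, 0], [1.5, 0, 0], [0.3, 1.2, 0.8]],
                       ["C", "O", "N"], cell=cell)
        path = tmp_path / "s.cif"
        write_structure(s, path)
        back = read_structure(path)
        assert back.cell == cell
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-4)
        assert [a.element for a in back.atoms] == ["C", "O", "N"]

    def test_cif_without_cell_is_format_error(self, tmp_path):
        path = tmp_path / "nocell.cif"
        path.write_text(
            "data_x\nloop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "C1 C 0 0 0\n"
        )
        with pytest.raises(FormatError, match="cell"):
            read_structure(path)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["sdf", "xyz"])
    def test_read_write_read_preserves_atoms(self, tmp_path, rng, fmt):
        coords = rng.normal(scale=3.0, size=(8, 3))
        elements = ["C", "C", "O", "N", "C", "H", "H", "F"]
        bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1)] if fmt == "sdf" else []
        s = _structure(coords, elements, bonds)
        p1 = tmp_path / f"a.{fmt}"
        write_structure(s, p1, fmt)
        s2 = read_structure(p1, fmt)
        p2 = tmp_path / f"b.{fmt}"
        write_structure(s2, p2, fmt)
        s3 = read_structure(p2, fmt)
        assert [a.element for a in s3.atoms] == elements
        np.testing.assert_allclose(s3.coords, coords, atol=1e-4)
        if fmt == "sdf":
            assert s3.bonds == bonds


class TestFracCart:
    def test_orthogonal_cell_is_componentwise_scaling(self):
        cell = CrystalCell(10, 10, 10, 90, 90, 90)
        np.testing.assert_allclose(
            frac_to_cart(cell, [0.1, 0.2, 0.3]), [1.0, 2.0, 3.0], atol=1e-12
        )

    def test_origin_is_fixed_point(self):
        cell = CrystalCell(5, 6, 7, 80, 95, 100)
        np.testing.assert_allclose(frac_to_cart(cell, [0, 0, 0]), [0, 0, 0])

    def test_triclinic_matches_textbook_matrix_oracle(self):
        a, b, c = 5.0, 6.0, 7.0
        al, be, ga = map(math.radians, (80.0, 95.0, 100.0))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        v = math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
        M = np.array([
            [a, b * cg, c * cb],
            [0, b * sg, c * (ca - cb * cg) / sg],
            [0, 0, c * v / sg],
        ])
        cell = CrystalCell(a, b, c, 80, 95, 100)
        np.testing.assert_allclose(
            frac_to_cart(cell, [0.5, 0.5, 0.5]), M @ [0.5, 0.5, 0.5], atol=1e-12
        )

    def test_agrees_with_gemmi(self):
        import gemmi

        cell = CrystalCell(5.1, 6.2, 7.3, 83.0, 97.5, 101.0)
        g = gemmi.UnitCell(5.1, 6.2, 7.3, 83.0, 97.5, 101.0)
        for frac in ([0.1, 0.2, 0.3], [0.9, -0.4, 1.7]):
            ours = frac_to_cart(cell, frac)
            theirs = g.orthogonalize(gemmi.Fractional(*frac))
            np.testing.assert_allclose(
                ours, [theirs.x, theirs.y, theirs.z], atol=1e-9
            )

    def test_roundtrip_identity_for_seeded_random_cells(self, rng):
        for _ in range(100):
            lengths = rng.uniform(3, 30, size=3)
            angles = rng.uniform(60, 120, size=3)
            try:
                cell = CrystalCell(*lengths, *angles)
            except ValidationError:
                continue  # rare degenerate angle combination
            frac = rng.uniform(-1, 2, size=3)
            back = cart_to_frac(cell, frac_to_cart(cell, frac))
            np.testing.assert_allclose(back, frac, atol=1e-10)

    @given(
        st.floats(0.1, 179.9),
        st.floats(0.1, 179.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_cell_volume_nonnegative_or_rejected(self, alpha, gamma):
        try:
            cell = CrystalCell(5, 6, 7, alpha, 100.0, gamma)
        except ValidationError:
            return
        assert cell.volume > 0

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValidationError):
            CrystalCell(5, 6, 7, 10, 10, 170)  # impossible angle triple
        with pytest.raises(ValidationError):
            CrystalCell(-1, 6, 7, 90, 90, 90)


class TestDisorder:
    def test_no_disorder_is_identity(self):
        s = _structure([[0, 0, 0], [1, 0, 0]], ["C", "O"])
        assert resolve_disorder(s) is s

    def test_majority_site_kept(self):
        atoms = [
            AtomRecord("C", [0, 0, 0], label="C1"),
            AtomRecord("O", [1, 0, 0], label="O1", occupancy=0.7),
            AtomRecord("O", [1.1, 0, 0], label="O1", occupancy=0.3),
        ]
        out = resolve_disorder(MolecularStructure(atoms))
        assert len(out) == 2
        kept = out.atoms[1]
        assert kept.coords[0] == pytest.approx(1.0)
        assert kept.occupancy == 1.0

    def test_tie_keeps_first_listed(self):
        atoms = [
            AtomRecord("O", [1, 0, 0], label="O1", occupancy=0.5),
            AtomRecord("O", [2, 0, 0], label="O1", occupancy=0.5),
        ]
        out = resolve_disorder(MolecularStructure(atoms))
        assert len(out) == 1
        assert out.atoms[0].coords[0] == pytest.approx(1.0)
        assert out.atoms[0].occupancy == 1.0


class TestInvariants:
    def test_bond_index_validation(self):
        with pytest.raises(ValidationError):
            _structure([[0, 0, 0]], bonds=[(0, 1, 1)])
        with pytest.raises(ValidationError, match="self-bond"):
            _structure([[0, 0, 0], [1, 1, 1]], bonds=[(0, 0, 1)])

    def test_occupancy_bounds(self):
        with pytest.raises(ValidationError):
            AtomRecord("C", [0, 0, 0], occupancy=0.0)
        with pytest.raises(ValidationError):
            AtomRecord("C", [0, 0, 0], occupancy=1.2)
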