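"""Read, write and normalise 3D molecular structures.

Supported formats are SDF/MOL (V2000), plain XYZ and small-molecule CIF
(core dictionary).  Whatever the source, atoms end up as Cartesian
coordinates in Å; CIF fractional coordinates are converted through the
standard crystallographic orthogonalisation (a along x, b in the xy
plane).  Only the asymmetric unit of a CIF is read — no space-group
symmetry expansion is performed, which is sufficient here because the
analysis needs a single molecule.

Angles are degrees and lengths are Å at every module boundary.  Atom
indices are 0-based internally; user-facing messages use 1-based indices
(the SDF convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .exceptions import FormatError, InputError, ValidationError

RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

#: MDL bond-order codes used in ``MolecularStructure.bonds``:
#: 1, 2, 3 are single/double/triple, 4 is aromatic.
_RDKIT_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}
_MDL_BOND_TYPES = {v: k for k, v in _RDKIT_BOND_ORDERS.items()}


def _check_element(symbol: str) -> str:
    """Normalise an element symbol, raising ValidationError if unknown."""
    sym = symbol.strip()
    sym = sym[:1].upper() + sym[1:].lower()
    try:
        if _PT.GetAtomicNumber(sym) <= 0:
            raise ValueError(sym)
    except Exception:
        raise ValidationError(f"unknown element symbol {symbol!r}") from None
    return sym


@dataclass
class AtomRecord:
    """One atom: element, Cartesian coordinates (Å), text label and
    crystallographic site occupancy (1 for non-disordered atoms)."""

    element: str
    coords: np.ndarray
    label: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.element = _check_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValidationError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords must be finite")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValidationError(
                f"occupancy must be in (0, 1], got {self.occupancy}"
            )


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell parameters: lengths a, b, c in Å, angles alpha, beta,
    gamma in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise ValidationError(
                    f"cell angle {name} must be in (0, 180), got {ang}"
                )
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValidationError("degenerate cell: volume <= 0")

    @property
    def volume(self) -> float:
        """Cell volume in Å^3 (closed form from the six parameters)."""
        ca, cb, cg = (
            math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma)
        )
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional.

        Convention: a lies along x, b in the xy plane.
        """
        ca, cb, cg = (
            math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma)
        )
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )


@dataclass
class MolecularStructure:
    """An ordered list of atoms plus bonds, an optional crystal cell and
    a provenance string recording where the structure came from."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    cell: CrystalCell | None = None
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(
                    f"bond ({i + 1}, {j + 1}) references a missing atom"
                )
            if i == j:
                raise ValidationError(f"self-bond on atom {i + 1}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of Cartesian coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array has the wrong shape")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularStructure(atoms, list(self.bonds), self.cell, self.source)

    def distance(self, i: int, j: int) -> float:
        """Distance in Å between atoms i and j (0-based)."""
        return float(np.linalg.norm(self.atoms[i].coords - self.atoms[j].coords))


# ---------------------------------------------------------------------------
# fractional <-> Cartesian


def frac_to_cart(cell: CrystalCell, frac) -> np.ndarray:
    """Convert fractional coordinates to Cartesian Å for the given cell."""
    frac = np.asarray(frac, dtype=float)
    return cell.orthogonalization_matrix @ frac


def cart_to_frac(cell: CrystalCell, cart) -> np.ndarray:
    """Inverse of :func:`frac_to_cart`."""
    cart = np.asarray(cart, dtype=float)
    return np.linalg.solve(cell.orthogonalization_matrix, cart)


# ---------------------------------------------------------------------------
# readers


def read_structure(path, fmt: str = "auto") -> MolecularStructure:
    """Read a structure file and normalise it to Cartesian Å.

    ``fmt`` is one of ``sdf``, ``xyz``, ``cif`` or ``auto`` (inferred from
    the file extension; ``.mol`` counts as sdf).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        fmt = {"mol": "sdf", "sd": "sdf"}.get(ext, ext)
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "cif":
        return _read_cif(path)
    raise InputError(f"unknown format {fmt!r} (expected sdf, xyz, cif or auto)")


def _read_sdf(path: Path) -> MolecularStructure:
    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise InputError(f"{path}: not a readable V2000 SDF/MOL record")
    if mol.GetNumConformers() == 0:
        raise InputError(f"{path}: SDF record carries no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(
            AtomRecord(
                element=atom.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                label=f"{atom.GetSymbol()}{i + 1}",
            )
        )
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _RDKIT_BOND_ORDERS.get(b.GetBondType(), 1),
        )
        for b in mol.GetBonds()
    ]
    return MolecularStructure(atoms, bonds, source=f"sdf:{path}")


def _read_xyz(path: Path) -> MolecularStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise InputError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise InputError(f"{path}, line 1: expected the atom count") from None
    atoms = []
    for ln, line in enumerate(lines[2 : 2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise InputError(
                f"{path}, line {ln}: expected 'element x y z', got {line!r}"
            )
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise InputError(
                f"{path}, line {ln}: could not parse coordinates in {line!r}"
            ) from None
        atoms.append(
            AtomRecord(parts[0], np.array(xyz), label=f"{parts[0]}{ln - 2}")
        )
    if len(atoms) != natoms:
        raise InputError(
            f"{path}: header promises {natoms} atoms, found {len(atoms)}"
        )
    return MolecularStructure(atoms, [], source=f"xyz:{path}")


_CIF_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def _cif_number(raw: str) -> float:
    # strip a parenthesised s.u., e.g. "1.5423(8)"
    return float(raw.split("(")[0])


def _read_cif(path: Path) -> MolecularStructure:
    import gemmi

    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:
        raise InputError(f"{path}: unreadable CIF ({exc})") from None

    vals = [block.find_value(tag) for tag in _CIF_CELL_TAGS]
    if any(v is None for v in vals):
        missing = [t for t, v in zip(_CIF_CELL_TAGS, vals) if v is None]
        raise FormatError(f"{path}: CIF without cell parameters ({missing[0]} ...)")
    a, b, c, al, be, ga = (_cif_number(v) for v in vals)
    cell = CrystalCell(a, b, c, al, be, ga)

    table = block.find(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    if len(table) == 0:
        # core CIF also allows the dotted mmCIF-style tags
        table = block.find(
            "_atom_site.",
            ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
        )
    if len(table) == 0:
        raise FormatError(f"{path}: CIF has no _atom_site_fract_* loop")
    occ_col = block.find_loop("_atom_site_occupancy")
    occs = [_cif_number(v) for v in occ_col] if occ_col else None

    atoms = []
    for idx, row in enumerate(table):
        try:
            frac = np.array([_cif_number(row[2]), _cif_number(row[3]), _cif_number(row[4])])
        except ValueError:
            raise InputError(
                f"{path}: bad fractional coordinates in _atom_site row {idx + 1}"
            ) from None
        occ = occs[idx] if occs is not None else 1.0
        atoms.append(
            AtomRecord(
                element=row[1],
                coords=frac_to_cart(cell, frac),
                label=row[0],
                occupancy=min(occ, 1.0) if occ > 0 else occ,
            )
        )
    return MolecularStructure(atoms, [], cell=cell, source=f"cif:{path}")


# ---------------------------------------------------------------------------
# writers


def write_structure(structure: MolecularStructure, path, fmt: str = "auto") -> None:
    """Write a structure as SDF, XYZ or CIF (fmt inferred from extension
    when ``auto``)."""
    path = Path(path)
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        fmt = {"mol": "sdf"}.get(ext, ext)
    if fmt == "sdf":
        _write_sdf(structure, path)
    elif fmt == "xyz":
        _write_xyz(structure, path)
    elif fmt == "cif":
        _write_cif(structure, path)
    else:
        raise InputError(f"unknown format {fmt!r} (expected sdf, xyz or cif)")


def to_rdkit(structure: MolecularStructure) -> Chem.Mol:
    """Build an (unsanitised) RDKit molecule mirroring the structure's
    atom order, bonds and coordinates."""
    rw = Chem.RWMol()
    for atom in structure.atoms:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in structure.bonds:
        rw.AddBond(i, j, _MDL_BOND_TYPES.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(structure.atoms))
    for i, atom in enumerate(structure.atoms):
        conf.SetAtomPosition(i, [float(x) for x in atom.coords])
    mol = rw.GetMol()
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


def _write_sdf(structure: MolecularStructure, path: Path) -> None:
    mol = to_rdkit(structure)
    mol.SetProp("_Name", structure.source or "evpkit structure")
    Chem.MolToMolFile(mol, str(path), kekulize=False)


def _write_xyz(structure: MolecularStructure, path: Path) -> None:
    lines = [str(len(structure.atoms)), structure.source or "evpkit structure"]
    for atom in structure.atoms:
        x, y, z = atom.coords
        lines.append(f"{atom.element} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _write_cif(structure: MolecularStructure, path: Path) -> None:
    cell = structure.cell
    if cell is None:
        # synthesize a padded orthorhombic box so the file is self-contained
        xyz = structure.coords
        span = xyz.max(axis=0) - xyz.min(axis=0) + 10.0
        cell = CrystalCell(*(float(s) for s in span), 90.0, 90.0, 90.0)
        origin = xyz.min(axis=0) - 5.0
        structure = structure.with_coords(xyz - origin)
        structure.cell = cell
    lines = [
        "data_evpkit",
        f"_cell_length_a {cell.a:.4f}",
        f"_cell_length_b {cell.b:.4f}",
        f"_cell_length_c {cell.c:.4f}",
        f"_cell_angle_alpha {cell.alpha:.4f}",
        f"_cell_angle_beta {cell.beta:.4f}",
        f"_cell_angle_gamma {cell.gamma:.4f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for i, atom in enumerate(structure.atoms):
        frac = cart_to_frac(cell, atom.coords)
        label = atom.label or f"{atom.element}{i + 1}"
        lines.append(
            f"{label} {atom.element} {frac[0]:.6f} {frac[1]:.6f} {frac[2]:.6f} "
            f"{atom.occupancy:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# disorder


def resolve_disorder(structure: MolecularStructure) -> MolecularStructure:
    """Collapse crystallographic disorder to a single site per group.

    Atoms sharing a label form a disorder group; the highest-occupancy
    site wins, ties go to the first listed.  Kept atoms get occupancy 1.
    Structures without shared labels pass through unchanged (bonds are
    preserved only in that case — disordered structures from CIF carry
    no bonds yet).
    """
    from collections import Counter

    counts = Counter(a.label for a in structure.atoms)
    if not any(v > 1 for v in counts.values()):
        return structure

    best: dict[str, int] = {}
    for idx, atom in enumerate(structure.atoms):
        if counts[atom.label] == 1:
            continue
        cur = best.get(atom.label)
        if cur is None or atom.occupancy > structure.atoms[cur].occupancy:
            best[atom.label] = idx
    keep = [
        idx
        for idx, atom in enumerate(structure.atoms)
        if counts[atom.label] == 1 or best[atom.label] == idx
    ]
    atoms = []
    for idx in keep:
        atom = structure.atoms[idx]
        if counts[atom.label] > 1:
            atom = replace(atom, occupancy=1.0)
        atoms.append(atom)
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [
        (remap[i], remap[j], order)
        for i, j, order in structure.bonds
        if i in remap and j in remap
    ]
    return MolecularStructure(atoms, bonds, structure.cell, structure.source)
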