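"""Scaffold registry and automatic attachment-point detection.

A scaffold entry pairs a short id with a SMARTS pattern whose two
attachment positions carry atom maps ``:1`` and ``:2``.  Matching a
structure against an entry yields the :class:`~evpkit.evp_core.AttachmentSpec`
needed for the exit-vector computation: the tagged scaffold atoms become
C1/C2 and their non-scaffold neighbours become X1/X2 (heavy atoms
preferred over hydrogen; among several heavy neighbours the lowest atom
index wins, which makes matching deterministic for a given input file).

Structures without bond information (XYZ, CIF) first pass through
covalent-radius bond perception: two atoms are bonded when their
distance does not exceed the sum of covalent radii plus a configurable
tolerance (0.45 Å by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from .evp_core import AttachmentSpec, EVPParameters
from .exceptions import (
    MissingHydrogensError,
    RegistryConflictError,
    ScaffoldNotFoundError,
    ValidationError,
)
from .structio import MolecularStructure, to_rdkit

#: extra slack on top of the covalent-radius sum when perceiving bonds, Å
DEFAULT_BOND_TOLERANCE = 0.45

_PT = Chem.GetPeriodicTable()


@dataclass
class ScaffoldEntry:
    """One registry record: id, human-readable description, SMARTS
    pattern with two mapped attachment positions and (optionally) the
    literature exit-vector parameters of the scaffold class."""

    id: str
    pattern: str
    description: str = ""
    reference_params: EVPParameters | None = None

    def __post_init__(self) -> None:
        query = Chem.MolFromSmarts(self.pattern)
        if query is None:
            raise ValidationError(f"scaffold {self.id!r}: malformed SMARTS pattern")
        maps = sorted(
            a.GetAtomMapNum() for a in query.GetAtoms() if a.GetAtomMapNum()
        )
        if maps != [1, 2]:
            raise ValidationError(
                f"scaffold {self.id!r}: pattern must tag exactly two attachment "
                f"positions with atom maps :1 and :2"
            )
        self._query = query
        self._map_to_query_idx = {
            a.GetAtomMapNum(): a.GetIdx()
            for a in query.GetAtoms()
            if a.GetAtomMapNum()
        }


class ScaffoldRegistry:
    """Ordered registry of scaffold entries; ids are unique."""

    def __init__(self, entries: list[ScaffoldEntry] | None = None) -> None:
        self._entries: dict[str, ScaffoldEntry] = {}
        for entry in entries or []:
            self.register(entry)

    def register(self, entry: ScaffoldEntry) -> None:
        if entry.id in self._entries:
            raise RegistryConflictError(
                f"scaffold id {entry.id!r} is already registered"
            )
        self._entries[entry.id] = entry

    def get(self, scaffold_id: str) -> ScaffoldEntry:
        try:
            return self._entries[scaffold_id]
        except KeyError:
            raise ScaffoldNotFoundError(
                f"unknown scaffold id {scaffold_id!r}; known: "
                + ", ".join(self._entries)
            ) from None

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def ids(self) -> list[str]:
        return list(self._entries)


def _load_builtin_registry() -> ScaffoldRegistry:
    text = (
        resources.files("evpkit").joinpath("data/scaffolds.tsv").read_text()
    )
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, pattern, description = line.split("\t")
        entries.append(ScaffoldEntry(sid, pattern, description))
    return ScaffoldRegistry(entries)


_default_registry: ScaffoldRegistry | None = None


def default_registry() -> ScaffoldRegistry:
    """The built-in registry (ortho_benzene, bcp_12, bch_12, oxa_bch),
    loaded once from the packaged config."""
    global _default_registry
    if _default_registry is None:
        _default_registry = _load_builtin_registry()
    return _default_registry


def list_scaffolds(registry: ScaffoldRegistry | None = None) -> list[ScaffoldEntry]:
    """All entries in stable (registration) order."""
    return list(registry or default_registry())


# ---------------------------------------------------------------------------
# bond perception and matching


def perceive_bonds(
    structure: MolecularStructure, tolerance: float = DEFAULT_BOND_TOLERANCE
) -> MolecularStructure:
    """Add single bonds between atoms closer than the sum of their
    covalent radii plus ``tolerance`` Å.  Intended for XYZ/CIF input
    that carries no connection table."""
    coords = structure.coords
    radii = np.array(
        [_PT.GetRcovalent(a.element) for a in structure.atoms], dtype=float
    )
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    bonds = [
        (int(i), int(j), 1)
        for i, j in zip(*np.nonzero((dist < cutoff) & (dist > 0.4)))
        if i < j
    ]
    return MolecularStructure(
        list(structure.atoms), bonds, structure.cell, structure.source
    )


def match_attachment(
    structure: MolecularStructure,
    entry: ScaffoldEntry,
    bond_tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> AttachmentSpec:
    """Locate the scaffold of ``entry`` in ``structure`` and return the
    four attachment-defining atoms.

    The first substructure match (under the structure's own atom order)
    whose two tagged positions both carry a non-scaffold heavy
    substituent wins.  A tagged position carrying only hydrogens
    disqualifies its match; a tagged position with no neighbours at all
    in a hydrogen-free structure raises MissingHydrogensError, because
    an unmodelled hydrogen cannot be told apart from a missing
    substituent.
    """
    if not structure.bonds:
        structure = perceive_bonds(structure, bond_tolerance)
    mol = to_rdkit(structure)
    has_any_hydrogen = any(a.element == "H" for a in structure.atoms)

    # uniquify=False keeps symmetry-equivalent orderings of the same atom
    # set, e.g. the two one-carbon bridges of a cage — only one of which
    # may bear the substituent
    matches = mol.GetSubstructMatches(entry._query, uniquify=False, maxMatches=10000)
    if not matches:
        raise ScaffoldNotFoundError(
            f"no match for scaffold {entry.id!r} in {structure.source or 'structure'}"
        )

    bare_position = None
    for match in matches:
        scaffold_atoms = set(match)
        picks = []
        for map_num in (1, 2):
            pos = match[entry._map_to_query_idx[map_num]]
            heavy, hydrogens = [], []
            for nb in mol.GetAtomWithIdx(pos).GetNeighbors():
                if nb.GetIdx() in scaffold_atoms:
                    continue
                (hydrogens if nb.GetAtomicNum() == 1 else heavy).append(nb.GetIdx())
            if heavy:
                picks.append((pos, min(heavy)))
            elif hydrogens:
                picks.append(None)  # position substituted only by H
            else:
                picks.append(None)
                if not has_any_hydrogen:
                    bare_position = pos
        if all(p is not None for p in picks):
            (c1, x1), (c2, x2) = picks
            return AttachmentSpec(c1, c2, x1, x2)

    if bare_position is not None:
        raise MissingHydrogensError(
            f"scaffold {entry.id!r} matches, but attachment atom "
            f"{bare_position + 1} has no substituent and the structure carries "
            f"no hydrogens; add hydrogens or pass explicit atom indices"
        )
    raise ScaffoldNotFoundError(
        f"scaffold {entry.id!r} matches, but no match has heavy substituents "
        f"on both attachment positions"
    )
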