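"""Generate the geometries the analysis is exercised on.

Three kinds of synthetic input are produced, so the whole pipeline runs
without any external structure download:

* an analytic ideal ortho-disubstituted benzene fragment (a regular
  hexagon with exit atoms on the external radial bisectors), whose
  exit-vector parameters have exact closed forms — r = a, d = a + b,
  phi1 = phi2 = 120°, theta = 0;
* force-field 3D models of the saturated cage scaffolds
  (bicyclo[1.1.1]pentane, bicyclo[2.1.1]hexane and the
  2-oxabicyclo[2.1.1]hexane), assembled from a template plus two
  substituent fragments, embedded with a fixed random seed and
  minimised with MMFF94 (UFF fallback);
* Gaussian coordinate-noise perturbations for robustness testing.

The default substituents — phenyl and carboxyl — emulate the
crystallised 1-aryl cage carboxylic acids whose measured geometry the
analysis is compared against; the oxa-cage template fixes the anti
diastereomer (carboxyl pointing away from the ether bridge), the isomer
the photochemical route delivers and the one seen in the crystal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .evp_core import AttachmentSpec
from .exceptions import GenerationError, ScaffoldNotFoundError, ValidationError
from .scaffolds import ScaffoldRegistry, default_registry, match_attachment
from .structio import AtomRecord, MolecularStructure, write_structure

#: assembly templates: dummy [*:1] takes substituent 1 (aryl side),
#: [*:2] takes substituent 2 (acid side)
BUILD_TEMPLATES: dict[str, str] = {
    "bcp_12": "[*:1]C12C([*:2])C(C1)C2",
    "bch_12": "[*:1]C12C([*:2])CC(C1)C2",
    "oxa_bch": "[*:2][C@@H]1[C@@H]2CO[C@@]1([*:1])C2",
}

#: default substituent fragments (phenyl toward position 1, carboxyl
#: toward position 2), as dummy-labelled SMILES
DEFAULT_SUBSTITUENTS = ("[*:1]c1ccccc1", "[*:2]C(=O)O")


@dataclass(frozen=True)
class BuildRecipe:
    """Everything needed to (re)build one 3D cage model deterministically."""

    scaffold_id: str
    substituents: tuple[str, str] = DEFAULT_SUBSTITUENTS
    seed: int = 7
    n_conformers: int = 20
    optimizer: str = "MMFF94"

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValidationError("n_conformers must be >= 1")
        if self.optimizer not in ("MMFF94", "UFF"):
            raise ValidationError("optimizer must be MMFF94 or UFF")


def build_ortho_benzene(
    a: float = 1.39, b: float = 1.50
) -> tuple[MolecularStructure, AttachmentSpec]:
    """Ideal ortho-disubstituted benzene fragment.

    ``a`` is the aromatic C–C length, ``b`` the exocyclic C–X length
    (both Å).  The ring is a regular planar hexagon of side a centred at
    the origin (so the circumradius equals a); the two exit atoms sit on
    the external radial bisectors of adjacent vertices at distance b.
    Closed forms: r = a, phi1 = phi2 = 120°, theta = 0 and
    d = 2 (a + b) sin 30° = a + b.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("bond lengths a and b must be positive")
    ring = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        ring.append(np.array([a * math.cos(ang), a * math.sin(ang), 0.0]))
    scale = (a + b) / a
    exits = [ring[0] * scale, ring[1] * scale]
    atoms = [
        AtomRecord("C", pos, label=f"C{i + 1}") for i, pos in enumerate(ring)
    ]
    atoms += [
        AtomRecord("C", exits[0], label="X1"),
        AtomRecord("C", exits[1], label="X2"),
    ]
    # Kekulé ring orders keep the fragment recognisably aromatic on write
    bonds = [(k, (k + 1) % 6, 1 + (k % 2)) for k in range(6)]
    bonds += [(0, 6, 1), (1, 7, 1)]
    structure = MolecularStructure(
        atoms, bonds, source=f"synthetic:ortho_benzene a={a} b={b}"
    )
    return structure, AttachmentSpec(0, 1, 6, 7)


def _assemble(recipe: BuildRecipe) -> Chem.Mol:
    template = BUILD_TEMPLATES.get(recipe.scaffold_id)
    if template is None:
        raise ScaffoldNotFoundError(
            f"no build template for scaffold {recipe.scaffold_id!r}; "
            f"templates exist for: {', '.join(BUILD_TEMPLATES)}"
        )
    core = Chem.MolFromSmiles(template)
    combined = core
    for frag_smiles in recipe.substituents:
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            raise ValidationError(f"bad substituent fragment {frag_smiles!r}")
        combined = Chem.CombineMols(combined, frag)
    try:
        mol = Chem.molzip(combined)
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ValidationError(
            f"could not assemble {recipe.scaffold_id} with substituents "
            f"{recipe.substituents}: {exc}"
        ) from None
    return mol


def build_cage_3d(
    recipe: BuildRecipe, registry: ScaffoldRegistry | None = None
) -> tuple[MolecularStructure, AttachmentSpec]:
    """Deterministic 3D model of a substituted cage scaffold.

    Embeds ``n_conformers`` conformers with a fixed seed, minimises each
    with the requested force field (MMFF94 by default, falling back to
    UFF when MMFF lacks parameters) and keeps the lowest-energy
    conformer; energy ties go to the lower conformer index.  The
    returned provenance records seed, force field and energy.
    """
    registry = registry or default_registry()
    entry = registry.get(recipe.scaffold_id)
    mol = Chem.AddHs(_assemble(recipe))

    params = AllChem.ETKDGv3()
    params.randomSeed = int(recipe.seed)
    cids = list(AllChem.EmbedMultipleConfs(mol, recipe.n_conformers, params))
    if not cids:
        params.useRandomCoords = True
        cids = list(AllChem.EmbedMultipleConfs(mol, recipe.n_conformers, params))
    if not cids:
        raise GenerationError(
            f"conformer embedding failed for scaffold {recipe.scaffold_id!r}"
        )

    force_field = recipe.optimizer
    if force_field == "MMFF94" and not AllChem.MMFFHasAllMoleculeParams(mol):
        force_field = "UFF"
    if force_field == "MMFF94":
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    energies = [energy for _converged, energy in results]
    best = int(np.argmin(energies))  # argmin takes the first of tied minima

    conf = mol.GetConformer(cids[best])
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(
            AtomRecord(
                atom.GetSymbol(),
                np.array([pos.x, pos.y, pos.z]),
                label=f"{atom.GetSymbol()}{i + 1}",
            )
        )
    from .structio import _RDKIT_BOND_ORDERS

    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _RDKIT_BOND_ORDERS.get(b.GetBondType(), 1),
        )
        for b in mol.GetBonds()
    ]
    structure = MolecularStructure(
        atoms,
        bonds,
        source=(
            f"synthetic:{recipe.scaffold_id} seed={recipe.seed} "
            f"ff={force_field} n_conformers={recipe.n_conformers} "
            f"energy={energies[best]:.4f}"
        ),
    )
    spec = match_attachment(structure, entry)
    return structure, spec


def perturb_coordinates(
    structure: MolecularStructure, sigma: float, seed: int
) -> MolecularStructure:
    """Add isotropic Gaussian noise (s.d. ``sigma`` Å) to every
    coordinate, reproducibly under ``seed``."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return structure
    rng = np.random.default_rng(seed)
    noisy = structure.coords + rng.normal(0.0, sigma, size=(len(structure), 3))
    out = structure.with_coords(noisy)
    out.source = f"{structure.source} +noise(sigma={sigma}, seed={seed})"
    return out


def write_fixtures(outdir, seed: int = 7, n_conformers: int = 20) -> list[str]:
    """Regenerate the canonical test fixtures (XYZ + SDF per scaffold)
    into ``outdir``; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    benzene, _ = build_ortho_benzene()
    for fmt in ("xyz", "sdf"):
        path = outdir / f"ortho_benzene.{fmt}"
        write_structure(benzene, path, fmt)
        written.append(str(path))
    for sid in BUILD_TEMPLATES:
        structure, _ = build_cage_3d(
            BuildRecipe(sid, seed=seed, n_conformers=n_conformers)
        )
        for fmt in ("xyz", "sdf"):
            path = outdir / f"{sid}.{fmt}"
            write_structure(structure, path, fmt)
            written.append(str(path))
    return written
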