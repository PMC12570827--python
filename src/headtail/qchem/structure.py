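"""SMILES → 3D structure preparation for the quantum backend.

A single conformer is generated by distance-geometry embedding (seeded,
hence reproducible) and relaxed with the Universal Force Field, capped at
5000 steps.  Only neutral closed-shell molecules are accepted: the
reactivity analysis downstream is restricted to RHF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..errors import EmbeddingError, SmilesParseError, UnsupportedSpeciesError

__all__ = ["Structure3D", "embed_3d"]

DEFAULT_SEED = 42
DEFAULT_MAX_UFF_STEPS = 5000


@dataclass(frozen=True)
class Structure3D:
    """Atomic symbols plus Cartesian coordinates in Å (one conformer)."""

    atom_symbols: tuple[str, ...]
    coordinates: np.ndarray       # (N, 3) Å
    total_charge: int
    spin_multiplicity: int
    embed_seed: int

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if len(coords) > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.5:
                raise ValueError(f"atoms closer than 0.5 Å (min {d.min():.3f})")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), ""]
        for sym, (x, y, z) in zip(self.atom_symbols, self.coordinates):
            lines.append(f"{sym} {x: .8f} {y: .8f} {z: .8f}")
        return "\n".join(lines) + "\n"


def _check_closed_shell(mol: Chem.Mol) -> None:
    if Chem.GetFormalCharge(mol) != 0:
        raise UnsupportedSpeciesError(
            f"net charge {Chem.GetFormalCharge(mol)}: RHF backend is "
            "restricted to neutral species")
    if any(a.GetNumRadicalElectrons() for a in mol.GetAtoms()):
        raise UnsupportedSpeciesError("radical species are not closed-shell")
    nelec = sum(a.GetAtomicNum() for a in mol.GetAtoms()) + sum(
        a.GetTotalNumHs() for a in mol.GetAtoms())
    if nelec % 2:
        raise UnsupportedSpeciesError(
            f"odd electron count ({nelec}): not a closed-shell molecule")


def embed_3d(smiles: str, seed: int = DEFAULT_SEED,
             max_uff_steps: int = DEFAULT_MAX_UFF_STEPS) -> Structure3D:
    """Embed one seeded conformer of a single-component SMILES and relax it
    with UFF.  Deterministic for a fixed seed."""
    if "." in smiles:
        raise ValueError("embed_3d expects a single component; split on '.' first")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    _check_closed_shell(mol)
    mol = Chem.AddHs(mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EmbeddingError(f"conformer embedding failed for {smiles!r}")
    try:
        AllChem.UFFOptimizeMolecule(mol, maxIters=max_uff_steps)
    except Exception as exc:  # pragma: no cover - UFF setup failures are rare
        raise EmbeddingError(f"UFF optimization failed for {smiles!r}: {exc}")

    conf = mol.GetConformer()
    return Structure3D(
        atom_symbols=tuple(a.GetSymbol() for a in mol.GetAtoms()),
        coordinates=np.array(conf.GetPositions(), dtype=float),
        total_charge=0,
        spin_multiplicity=1,
        embed_seed=int(seed),
    )
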