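"""Quantum-chemistry backend: 3D embedding, RHF/STO-3G, nucleophilicity.

The public entry point for the rest of the pipeline is
:func:`profile_for_smiles`, which caches converged reactivity profiles per
(canonical SMILES, seed) so repeated pipeline stages reuse one SCF run.
"""

from __future__ import annotations

from functools import lru_cache

from .basis import SUPPORTED_ELEMENTS, BasisSet, build_basis
from .reactivity import (ReactivityProfile, homo_mulliken_populations,
                         nucleophilicity_profile)
from .scf import WavefunctionSummary, run_rhf
from .structure import (DEFAULT_MAX_UFF_STEPS, DEFAULT_SEED, Structure3D,
                        embed_3d)

__all__ = [
    "BasisSet", "build_basis", "SUPPORTED_ELEMENTS",
    "Structure3D", "embed_3d", "DEFAULT_SEED", "DEFAULT_MAX_UFF_STEPS",
    "WavefunctionSummary", "run_rhf",
    "ReactivityProfile", "homo_mulliken_populations", "nucleophilicity_profile",
    "profile_for_smiles",
]


@lru_cache(maxsize=256)
def profile_for_smiles(smiles: str, seed: int = DEFAULT_SEED,
                       basis: str = "STO-3G", method: str = "RHF",
                       max_uff_steps: int = DEFAULT_MAX_UFF_STEPS) -> ReactivityProfile:
    """Embed, run the SCF, and return the ranked nucleophilicity profile.

    Atom indices in the profile match the canonical atom order of
    ``smiles`` (heavy atoms first, hydrogens appended).
    """
    structure = embed_3d(smiles, seed=seed, max_uff_steps=max_uff_steps)
    wfn = run_rhf(structure, basis=basis, method=method)
    return nucleophilicity_profile(wfn)
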