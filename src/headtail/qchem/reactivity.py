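"""Per-atom HOMO populations and the atomic nucleophilicity index.

The nucleophilicity index of atom X is

    R_X = p_X / (1 - eps_HOMO)

where ``p_X`` is the Mulliken gross population of the HOMO on atom X
(overlap-weighted; summing to 1 over the molecule) and ``eps_HOMO`` is the
HOMO energy in hartree.  The denominator is atom-independent, so the R_X
ranking always coincides with the p_X ranking for a single molecule; the
denominator matters only when comparing across molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scf import WavefunctionSummary

__all__ = ["ReactivityProfile", "homo_mulliken_populations",
           "nucleophilicity_profile"]


@dataclass(frozen=True)
class ReactivityProfile:
    """Ranked per-atom nucleophilicity for one molecule.

    Atom indexing follows the structure passed to the SCF: heavy atoms
    first (canonical SMILES order), then hydrogens.
    """

    homo_population: np.ndarray   # p_X per atom, sums to 1
    nucleophilicity: np.ndarray   # R_X per atom
    ranking: np.ndarray           # atom indices, R_X descending, ties by index
    homo_energy: float            # hartree
    atom_symbols: tuple[str, ...]

    def rank_of(self, atom_index: int) -> int:
        return int(np.where(self.ranking == atom_index)[0][0])


def homo_mulliken_populations(wfn: WavefunctionSummary,
                              fold_hydrogens: bool = False,
                              raw_coefficients: bool = False) -> np.ndarray:
    """Partition the (normalized) HOMO onto atoms.

    Default is the Mulliken gross population ``p_a = C_a * (S C)_a``; with
    ``raw_coefficients`` the literal squared-coefficient sum is used and
    renormalized to 1.  ``fold_hydrogens`` adds each hydrogen's share to
    its nearest heavy atom (off by default; heads/tails are heavy atoms
    regardless).
    """
    c = wfn.mo_coefficients[:, wfn.homo_index]
    if raw_coefficients:
        per_ao = c * c
        per_ao = per_ao / per_ao.sum()
    else:
        per_ao = c * (wfn.ao_overlap @ c)
    pops = np.zeros(wfn.n_atoms)
    np.add.at(pops, wfn.ao_to_atom, per_ao)
    if fold_hydrogens:
        heavy = [i for i, s in enumerate(wfn.atom_symbols) if s != "H"]
        # fold H shares into the heavy atom with the largest AO overlap link
        for i, s in enumerate(wfn.atom_symbols):
            if s != "H" or not heavy:
                continue
            ao_h = np.where(wfn.ao_to_atom == i)[0]
            links = [
                (np.abs(wfn.ao_overlap[np.ix_(ao_h, np.where(wfn.ao_to_atom == j)[0])]).max(), j)
                for j in heavy]
            pops[max(links)[1]] += pops[i]
            pops[i] = 0.0
    return pops


def nucleophilicity_profile(wfn: WavefunctionSummary,
                            fold_hydrogens: bool = False,
                            raw_coefficients: bool = False) -> ReactivityProfile:
    """Compute R_X for every atom and rank the atoms (descending).

    Ties are broken by the lower atom index (stable sort on descending R_X).
    """
    eps = wfn.homo_energy
    if eps >= 1.0:
        raise ValueError(
            f"HOMO energy {eps:.4f} hartree >= 1: nucleophilicity denominator "
            "(1 - eps) would be non-positive; the SCF solution is suspect")
    p = homo_mulliken_populations(wfn, fold_hydrogens=fold_hydrogens,
                                  raw_coefficients=raw_coefficients)
    r = p / (1.0 - eps)
    ranking = np.argsort(-r, kind="stable")
    return ReactivityProfile(
        homo_population=p,
        nucleophilicity=r,
        ranking=ranking,
        homo_energy=float(eps),
        atom_symbols=wfn.atom_symbols,
    )
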