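"""Restricted Hartree–Fock with DIIS convergence acceleration.

The only supported model chemistry is RHF/STO-3G — the level at which the
nucleophilicity ranking is defined and validated.  The SCF retries once
with damping plus a level shift if plain DIIS fails to converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ..errors import SCFConvergenceError, UnsupportedSpeciesError
from . import integrals
from .basis import BasisSet, build_basis
from .structure import Structure3D

__all__ = ["WavefunctionSummary", "run_rhf"]

SUPPORTED_BASES = ("STO-3G",)
SUPPORTED_METHODS = ("RHF",)


@dataclass(frozen=True)
class WavefunctionSummary:
    """Converged closed-shell SCF solution in the AO basis."""

    mo_coefficients: np.ndarray   # (nao, nmo), column n = MO n
    ao_overlap: np.ndarray        # (nao, nao)
    orbital_energies: np.ndarray  # (nmo,), hartree, non-decreasing
    homo_index: int
    ao_to_atom: np.ndarray        # AO index -> atom index
    atom_symbols: tuple[str, ...]
    n_electrons: int
    total_energy: float           # hartree, incl. nuclear repulsion

    @property
    def nao(self) -> int:
        return self.ao_overlap.shape[0]

    @property
    def n_atoms(self) -> int:
        return int(self.ao_to_atom.max()) + 1

    @property
    def homo_energy(self) -> float:
        return float(self.orbital_energies[self.homo_index])


def _nuclear_repulsion(charges: np.ndarray, coords: np.ndarray) -> float:
    e = 0.0
    for i in range(len(charges)):
        for j in range(i):
            e += charges[i] * charges[j] / np.linalg.norm(coords[i] - coords[j])
    return e


def _scf_loop(H, S, eri, nocc, *, level_shift=0.0, damping=0.0,
              conv_tol=1e-9, max_cycle=200):
    """Return (C, eps, E_elec, converged)."""
    X = scipy.linalg.fractional_matrix_power(S, -0.5).real
    eps, Cp = np.linalg.eigh(X.T @ H @ X)
    C = X @ Cp
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    e_old = 0.0
    errs: list[np.ndarray] = []
    focks: list[np.ndarray] = []
    for _cycle in range(max_cycle):
        J, K = integrals.build_jk(eri, D)
        F = H + J - 0.5 * K
        e_elec = 0.5 * np.sum(D * (H + F))
        err = F @ D @ S - S @ D @ F
        # DIIS extrapolation
        errs.append(err)
        focks.append(F.copy())
        if len(errs) > 8:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            n = len(errs)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for a in range(n):
                for b in range(n):
                    B[a, b] = np.sum(errs[a] * errs[b])
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:n]
                F = sum(wi * Fi for wi, Fi in zip(w, focks))
            except np.linalg.LinAlgError:
                pass
        Feff = F
        if level_shift > 0.0:
            Feff = F + level_shift * (S - 0.5 * S @ D @ S)
        eps, Cp = np.linalg.eigh(X.T @ Feff @ X)
        C = X @ Cp
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        if damping > 0.0:
            D_new = (1.0 - damping) * D_new + damping * D
        d_err = np.max(np.abs(D_new - D))
        D = D_new
        if abs(e_elec - e_old) < conv_tol and d_err < 1e-6 \
                and np.max(np.abs(err)) < 1e-6:
            # final diagonalization without any shift for clean eigenvalues
            J, K = integrals.build_jk(eri, D)
            F = H + J - 0.5 * K
            eps, Cp = np.linalg.eigh(X.T @ F @ X)
            C = X @ Cp
            e_elec = 0.5 * np.sum((2.0 * C[:, :nocc] @ C[:, :nocc].T) * (H + F))
            return C, eps, e_elec, True
        e_old = e_elec
    return C, eps, e_old, False


def run_rhf(structure: Structure3D, basis: str = "STO-3G",
            method: str = "RHF", conv_tol: float = 1e-9,
            max_cycle: int = 200) -> WavefunctionSummary:
    """Run a closed-shell SCF and summarize the wavefunction.

    Raises
    ------
    ValueError
        For a basis set or method outside the supported model chemistry.
    UnsupportedSpeciesError
        For open-shell electron counts.
    SCFConvergenceError
        If the SCF fails even after the damped, level-shifted retry.
    """
    if basis.upper().replace(" ", "") != "STO-3G":
        raise ValueError(
            f"unsupported basis {basis!r}; this build supports: {SUPPORTED_BASES}")
    if method.upper() != "RHF":
        raise ValueError(
            f"unsupported method {method!r}; this build supports: {SUPPORTED_METHODS}")

    bset: BasisSet = build_basis(list(structure.atom_symbols),
                                 structure.coordinates)
    nelec = int(bset.atom_charges.sum()) - structure.total_charge
    if nelec % 2:
        raise UnsupportedSpeciesError(f"odd electron count ({nelec})")
    nocc = nelec // 2

    S, T = integrals.overlap_kinetic(
        bset.ao_powers, bset.ao_centers, bset.ao_prim_start,
        bset.ao_prim_count, bset.prim_exps, bset.prim_coefs)
    V = integrals.nuclear_attraction(
        bset.ao_powers, bset.ao_centers, bset.ao_prim_start,
        bset.ao_prim_count, bset.prim_exps, bset.prim_coefs,
        bset.atom_charges, bset.atom_coords)
    eri = integrals.eri_compound(
        bset.ao_powers, bset.ao_centers, bset.ao_prim_start,
        bset.ao_prim_count, bset.prim_exps, bset.prim_coefs)
    H = T + V

    C, eps, e_elec, ok = _scf_loop(H, S, eri, nocc,
                                   conv_tol=conv_tol, max_cycle=max_cycle)
    if not ok:
        C, eps, e_elec, ok = _scf_loop(H, S, eri, nocc, level_shift=0.3,
                                       damping=0.3, conv_tol=conv_tol,
                                       max_cycle=2 * max_cycle)
    if not ok:
        raise SCFConvergenceError("SCF did not converge (after damped retry)")

    e_nuc = _nuclear_repulsion(bset.atom_charges, bset.atom_coords)
    return WavefunctionSummary(
        mo_coefficients=C,
        ao_overlap=S,
        orbital_energies=eps,
        homo_index=nocc - 1,
        ao_to_atom=bset.ao_to_atom,
        atom_symbols=tuple(structure.atom_symbols),
        n_electrons=nelec,
        total_energy=float(e_elec + e_nuc),
    )
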