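"""Minimal Gaussian basis-set library (STO-3G) and basis construction.

The STO-3G parameters below are the published least-squares three-Gaussian
fits to Slater orbitals with Pople's standard zeta scale factors; only the
elements that occur in supported monomers (H, C, N, O, F) are included.
Exponents are in bohr^-2; contraction coefficients refer to normalized
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSet", "build_basis", "SUPPORTED_ELEMENTS", "ATOMIC_NUMBER"]

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9}

# element -> list of shells; each shell is (angular momentum l, [(exp, coef), ...])
_STO3G: dict[str, list[tuple[int, list[tuple[float, float]]]]] = {
    "H": [
        (0, [(3.425250914, 0.1543289673),
             (0.6239137298, 0.5353281423),
             (0.1688554040, 0.4446345422)]),
    ],
    "C": [
        (0, [(71.61683735, 0.1543289673),
             (13.04509632, 0.5353281423),
             (3.530512160, 0.4446345422)]),
        (0, [(2.941249355, -0.09996722919),
             (0.6834830964, 0.3995128261),
             (0.2222899159, 0.7001154689)]),
        (1, [(2.941249355, 0.1559162750),
             (0.6834830964, 0.6076837186),
             (0.2222899159, 0.3919573931)]),
    ],
    "N": [
        (0, [(99.10616896, 0.1543289673),
             (18.05231239, 0.5353281423),
             (4.885660238, 0.4446345422)]),
        (0, [(3.780455879, -0.09996722919),
             (0.8784966449, 0.3995128261),
             (0.2857143744, 0.7001154689)]),
        (1, [(3.780455879, 0.1559162750),
             (0.8784966449, 0.6076837186),
             (0.2857143744, 0.3919573931)]),
    ],
    "O": [
        (0, [(130.7093214, 0.1543289673),
             (23.80886605, 0.5353281423),
             (6.443608313, 0.4446345422)]),
        (0, [(5.033151319, -0.09996722919),
             (1.169596125, 0.3995128261),
             (0.3803889600, 0.7001154689)]),
        (1, [(5.033151319, 0.1559162750),
             (1.169596125, 0.6076837186),
             (0.3803889600, 0.3919573931)]),
    ],
    "F": [
        (0, [(166.6791340, 0.1543289673),
             (30.36081233, 0.5353281423),
             (8.216820672, 0.4446345422)]),
        (0, [(6.464803249, -0.09996722919),
             (1.502281245, 0.3995128261),
             (0.4885884864, 0.7001154689)]),
        (1, [(6.464803249, 0.1559162750),
             (1.502281245, 0.6076837186),
             (0.4885884864, 0.3919573931)]),
    ],
}

SUPPORTED_ELEMENTS = frozenset(_STO3G)

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092


def _cartesian_powers(l: int) -> list[tuple[int, int, int]]:
    """Cartesian components of an l shell in a fixed lexicographic order."""
    return [(lx, ly, l - lx - ly) for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    l = lx + ly + lz
    pref = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(_double_factorial(2 * lx - 1)
                  * _double_factorial(2 * ly - 1)
                  * _double_factorial(2 * lz - 1))
    return pref / den


@dataclass(frozen=True)
class BasisSet:
    """Flattened Cartesian-Gaussian AO basis for one molecule.

    Coordinates are stored in bohr.  Each AO carries its own primitive
    block so the integral kernels can stay shell-agnostic.
    """

    ao_powers: np.ndarray        # (nao, 3) int cartesian exponents
    ao_centers: np.ndarray       # (nao, 3) float, bohr
    ao_prim_start: np.ndarray    # (nao,) index into prim arrays
    ao_prim_count: np.ndarray    # (nao,)
    prim_exps: np.ndarray        # (nprim_total,)
    prim_coefs: np.ndarray       # (nprim_total,) normalized-contraction coefs
    ao_to_atom: np.ndarray       # (nao,) atom index per AO
    ao_labels: tuple[str, ...]
    atom_charges: np.ndarray     # (natom,) nuclear charges
    atom_coords: np.ndarray      # (natom, 3), bohr

    @property
    def nao(self) -> int:
        return len(self.ao_powers)


def build_basis(symbols: list[str], coords_angstrom: np.ndarray) -> BasisSet:
    """Construct the STO-3G AO basis for a molecule.

    Raises ``ValueError`` for elements outside the built-in library.
    """
    unknown = sorted({s for s in symbols if s not in _STO3G})
    if unknown:
        raise ValueError(
            f"no basis parameters for element(s) {unknown}; "
            f"supported elements: {sorted(SUPPORTED_ELEMENTS)}")
    coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM

    powers, centers, starts, counts = [], [], [], []
    exps, coefs, ao_atom, labels = [], [], [], []
    shell_names = {0: "s", 1: "p", 2: "d"}
    for iatom, sym in enumerate(symbols):
        for l, prims in _STO3G[sym]:
            for lx, ly, lz in _cartesian_powers(l):
                # normalize primitives, then the contraction as a whole
                a = np.array([p[0] for p in prims])
                c = np.array([p[1] for p in prims])
                c = c * np.array([_primitive_norm(ai, lx, ly, lz) for ai in a])
                # contracted self-overlap for a 1-center cartesian gaussian
                ia, ja = np.meshgrid(a, a, indexing="ij")
                ee = ia + ja
                l_tot = lx + ly + lz
                num = (_double_factorial(2 * lx - 1)
                       * _double_factorial(2 * ly - 1)
                       * _double_factorial(2 * lz - 1))
                s_self = (np.outer(c, c)
                          * (np.pi / ee) ** 1.5 * num / (2.0 * ee) ** l_tot).sum()
                c = c / np.sqrt(s_self)

                starts.append(len(exps))
                counts.append(len(prims))
                exps.extend(a.tolist())
                coefs.extend(c.tolist())
                powers.append((lx, ly, lz))
                centers.append(coords[iatom])
                ao_atom.append(iatom)
                comp = "" if l == 0 else "xyz"[np.argmax([lx, ly, lz])] if l == 1 else f"{lx}{ly}{lz}"
                labels.append(f"{iatom}:{sym}:{shell_names[l]}{comp}")

    return BasisSet(
        ao_powers=np.array(powers, dtype=np.int64),
        ao_centers=np.array(centers, dtype=float),
        ao_prim_start=np.array(starts, dtype=np.int64),
        ao_prim_count=np.array(counts, dtype=np.int64),
        prim_exps=np.array(exps, dtype=float),
        prim_coefs=np.array(coefs, dtype=float),
        ao_to_atom=np.array(ao_atom, dtype=np.int64),
        ao_labels=tuple(labels),
        atom_charges=np.array([ATOMIC_NUMBER[s] for s in symbols], dtype=float),
        atom_coords=coords,
    )
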