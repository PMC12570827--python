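"""Quantum backend: integrals against closed-form oracles, SCF against
literature energies, Mulliken populations and the nucleophilicity index."""

import numpy as np
import pytest
from scipy.special import erf

from headtail.errors import UnsupportedSpeciesError
from headtail.qchem import (ReactivityProfile, embed_3d,
                            homo_mulliken_populations,
                            nucleophilicity_profile, run_rhf)
from headtail.qchem.basis import BOHR_PER_ANGSTROM, build_basis
from headtail.qchem.integrals import (eri_compound, nuclear_attraction,
                                      overlap_kinetic)
from headtail.qchem.scf import WavefunctionSummary
from headtail.qchem.structure import Structure3D

BOHR = 1.0 / BOHR_PER_ANGSTROM   # Å per bohr


def _h2(r_bohr=1.4):
    return Structure3D(("H", "H"),
                       np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_bohr * BOHR]]),
                       0, 1, 0)


def _water():
    r, ang = 0.9572, np.deg2rad(104.52)
    return Structure3D(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0],
                  [r * np.cos(ang), r * np.sin(ang), 0.0]]), 0, 1, 0)


class TestIntegralOracles:
    """s-type integrals recomputed in-test from textbook closed forms."""

    def _basis(self, r_bohr):
        return build_basis(["H", "H"], np.array([[0.0, 0.0, 0.0],
                                                 [0.0, 0.0, r_bohr * BOHR]]))

    @pytest.mark.parametrize("r_bohr", [0.9, 1.4, 2.5, 5.0])
    def test_s_overlap_and_kinetic_closed_form(self, r_bohr):
        b = self._basis(r_bohr)
        S, T = overlap_kinetic(b.ao_powers, b.ao_centers, b.ao_prim_start,
                               b.ao_prim_count, b.prim_exps, b.prim_coefs)
        a_exp = b.prim_exps[:3]
        a_c = b.prim_coefs[:3]
        s_ref = t_ref = 0.0
        for ai, ci in zip(a_exp, a_c):
            for aj, cj in zip(a_exp, a_c):
                p = ai + aj
                mu = ai * aj / p
                s_prim = (np.pi / p) ** 1.5 * np.exp(-mu * r_bohr ** 2)
                s_ref += ci * cj * s_prim
                t_ref += ci * cj * mu * (3.0 - 2.0 * mu * r_bohr ** 2) * s_prim
        assert S[0, 1] == pytest.approx(s_ref, abs=1e-12)
        assert T[0, 1] == pytest.approx(t_ref, abs=1e-12)
        assert S[0, 0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("r_bohr", [1.0, 1.4, 3.0])
    def test_ssss_repulsion_closed_form(self, r_bohr):
        b = self._basis(r_bohr)
        eri = eri_compound(b.ao_powers, b.ao_centers, b.ao_prim_start,
                           b.ao_prim_count, b.prim_exps, b.prim_coefs)
        a_exp = b.prim_exps[:3]
        a_c = b.prim_coefs[:3]
        za = np.array([0.0, 0.0, 0.0])
        zb = np.array([0.0, 0.0, r_bohr])

        def f0(t):
            return 1.0 if t < 1e-14 else 0.5 * np.sqrt(np.pi / t) * erf(np.sqrt(t))

        # (aa|bb): bra on atom A, ket on atom B
        ref = 0.0
        for a1, c1 in zip(a_exp, a_c):
            for a2, c2 in zip(a_exp, a_c):
                p = a1 + a2
                for a3, c3 in zip(a_exp, a_c):
                    for a4, c4 in zip(a_exp, a_c):
                        q = a3 + a4
                        theta = p * q / (p + q)
                        pref = 2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                        ref += (c1 * c2 * c3 * c4 * pref
                                * f0(theta * r_bohr ** 2))
        ij_aa = 0                       # compound index of (0,0)
        kl_bb = 1 * 2 // 2 + 1          # compound index of (1,1)
        assert eri[ij_aa, kl_bb] == pytest.approx(ref, rel=1e-10)

    def test_point_charge_attraction_closed_form(self):
        b = self._basis(1.4)
        V = nuclear_attraction(b.ao_powers, b.ao_centers, b.ao_prim_start,
                               b.ao_prim_count, b.prim_exps, b.prim_coefs,
                               b.atom_charges, b.atom_coords)
        a_exp = b.prim_exps[:3]
        a_c = b.prim_coefs[:3]
        ref = 0.0
        for zc in (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.4])):
            for ai, ci in zip(a_exp, a_c):
                for aj, cj in zip(a_exp, a_c):
                    p = ai + aj
                    t = p * np.dot(zc, zc)     # AO 0 sits at the origin
                    f0 = 1.0 if t < 1e-14 else \
                        0.5 * np.sqrt(np.pi / t) * erf(np.sqrt(t))
                    ref -= ci * cj * 2 * np.pi / p * f0
        assert V[0, 0] == pytest.approx(ref, rel=1e-10)


class TestRHF:
    def test_h2_matches_literature_energy(self):
        # classic RHF/STO-3G value at R = 1.4 bohr
        wfn = run_rhf(_h2())
        assert wfn.total_energy == pytest.approx(-1.1167, abs=2e-3)
        assert wfn.nao == 2
        assert wfn.homo_index == 0
        c = np.abs(wfn.mo_coefficients[:, 0])
        assert c[0] == pytest.approx(c[1], abs=1e-8)   # bonding sigma

    def test_water_energy_and_dimensions(self):
        wfn = run_rhf(_water())
        assert wfn.nao == 7                    # O(5) + 2 x H(1)
        assert wfn.homo_index == 4             # 10 electrons, 5 occupied MOs
        assert wfn.total_energy == pytest.approx(-74.963, abs=1e-2)
        assert wfn.homo_energy < 0.0

    def test_orbital_orthonormality(self):
        wfn = run_rhf(_water())
        c, s = wfn.mo_coefficients, wfn.ao_overlap
        assert np.abs(c.T @ s @ c - np.eye(wfn.nao)).max() < 1e-6

    def test_total_mulliken_population_equals_electron_count(self):
        wfn = run_rhf(_water())
        nocc = wfn.homo_index + 1
        d = 2.0 * wfn.mo_coefficients[:, :nocc] @ wfn.mo_coefficients[:, :nocc].T
        assert np.sum(d * wfn.ao_overlap) == pytest.approx(wfn.n_electrons,
                                                           abs=1e-5)

    def test_orbital_energies_non_decreasing(self):
        wfn = run_rhf(_water())
        assert np.all(np.diff(wfn.orbital_energies) > -1e-10)

    @pytest.mark.parametrize("kwargs", [{"basis": "6-31G*"},
                                        {"method": "B3LYP"}])
    def test_unsupported_model_chemistry_raises(self, kwargs):
        with pytest.raises(ValueError, match="supports"):
            run_rhf(_h2(), **kwargs)

    def test_unsupported_element_raises(self):
        with pytest.raises(ValueError, match="basis parameters"):
            build_basis(["S"], np.zeros((1, 3)))


class TestEmbedding:
    def test_seeded_embedding_is_deterministic(self):
        s1 = embed_3d("C=CC(N)=O", seed=7)
        s2 = embed_3d("C=CC(N)=O", seed=7)
        assert np.array_equal(s1.coordinates, s2.coordinates)

    def test_ethene_double_bond_length_in_range(self):
        s = embed_3d("C=C", seed=42)
        d = np.linalg.norm(s.coordinates[0] - s.coordinates[1])
        assert 1.30 <= d <= 1.40
        assert s.n_atoms == 6

    def test_radical_is_unsupported(self):
        with pytest.raises(UnsupportedSpeciesError):
            embed_3d("[CH3]")

    def test_charged_species_is_unsupported(self):
        with pytest.raises(UnsupportedSpeciesError):
            embed_3d("[NH4+]")

    def test_multi_component_refused(self):
        with pytest.raises(ValueError, match="single component"):
            embed_3d("C.C")

    def test_xyz_export_roundtrip(self):
        s = embed_3d("C=C", seed=42)
        lines = s.to_xyz().strip().splitlines()
        assert lines[0] == "6"
        assert len(lines) == 8
        assert lines[2].split()[0] == "C"


class TestReactivity:
    def test_homo_population_sums_to_one(self):
        wfn = run_rhf(_water())
        assert homo_mulliken_populations(wfn).sum() == pytest.approx(1.0,
                                                                     abs=1e-6)

    def test_ethene_carbons_symmetry_equivalent(self):
        wfn = run_rhf(embed_3d("C=C", seed=42))
        p = homo_mulliken_populations(wfn)
        assert abs(p[0] - p[1]) < 1e-3

    def test_butadiene_terminal_exceeds_inner_as_in_hueckel(self):
        """Independent oracle: the Hückel HOMO of a 4-site chain puts more
        weight on the terminal than the inner carbons."""
        adj = np.zeros((4, 4))
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1.0
        evals, evecs = np.linalg.eigh(-adj)    # energies alpha + beta*lambda
        homo = evecs[:, 1]                     # 4 pi electrons -> 2nd lowest
        hk = homo ** 2
        assert hk[0] > hk[1]                   # the model's prediction
        wfn = run_rhf(embed_3d("C=CC=C", seed=42))
        p = homo_mulliken_populations(wfn)
        assert p[0] > p[1]
        assert p[3] > p[2]
        assert abs(p[0] - p[3]) < 1e-3 and abs(p[1] - p[2]) < 1e-3

    def test_nucleophilicity_algebra(self):
        wfn = run_rhf(embed_3d("C=CC(N)=O", seed=42))
        prof = nucleophilicity_profile(wfn)
        assert np.all(prof.nucleophilicity >= -1e-12)
        assert prof.nucleophilicity.sum() == pytest.approx(
            1.0 / (1.0 - prof.homo_energy), abs=1e-9)
        # constant positive denominator: R ranking == p ranking
        assert np.array_equal(prof.ranking,
                              np.argsort(-prof.homo_population, kind="stable"))

    def test_fold_hydrogens_conserves_total(self):
        wfn = run_rhf(embed_3d("C=C", seed=42))
        p = homo_mulliken_populations(wfn, fold_hydrogens=True)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p[2:] == 0.0)            # H shares folded away

    def test_homo_above_one_hartree_rejected(self):
        wfn = WavefunctionSummary(
            mo_coefficients=np.eye(2), ao_overlap=np.eye(2),
            orbital_energies=np.array([1.5, 2.0]), homo_index=0,
            ao_to_atom=np.array([0, 1]), atom_symbols=("H", "H"),
            n_electrons=2, total_energy=0.0)
        with pytest.raises(ValueError, match="denominator"):
            nucleophilicity_profile(wfn)

    def test_full_profile_deterministic_across_runs(self):
        p1 = nucleophilicity_profile(run_rhf(embed_3d("C1CO1", seed=11)))
        p2 = nucleophilicity_profile(run_rhf(embed_3d("C1CO1", seed=11)))
        assert np.array_equal(p1.nucleophilicity, p2.nucleophilicity)
        assert np.array_equal(p1.ranking, p2.ranking)
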