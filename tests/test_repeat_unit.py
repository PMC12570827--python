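"""Graph edits: ring opening, condensation, tagging and their invariants."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import RWMol

from headtail.assigner import ClassAssignment, resolve_class
from headtail.chemio import canonical_mol
from headtail.fgroups import (ClassCandidate, FunctionalGroupMatch,
                              candidate_classes, match_groups)
from headtail.harness import collapse_tokens
from headtail.qchem import ReactivityProfile
from headtail.repeat_unit import (apply_condensation_edits,
                                  assemble_repeat_unit, open_ring,
                                  select_tail_atom, tag_monomer)


def _assignment_for(smiles, fix_lactones=False, profiles=None):
    comps = smiles.split(".")
    mols = [canonical_mol(c)[1] for c in comps]
    matches = [match_groups(c, component_index=i) for i, c in enumerate(comps)]
    cands = candidate_classes(matches, mols, fix_lactones=fix_lactones)
    getter = profiles if profiles is not None else _real_profile(comps)
    return resolve_class(cands, getter), mols, matches, getter


def _real_profile(comps):
    from headtail.qchem import profile_for_smiles

    def getter(ci):
        return profile_for_smiles(comps[ci], seed=42)
    return getter


def _heavy_atoms(smiles):
    return Chem.MolFromSmiles(smiles.replace("[*:1]", "").replace(
        "[*:2]", "")) or None


class TestOpenRing:
    def test_epoxide_breaks_on_the_unsubstituted_side(self):
        can, mol = canonical_mol("CC1CO1")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        rw, tail, msg = open_ring(mol, o_idx, "polyether")
        assert msg == ""
        tail_atom = mol.GetAtomWithIdx(tail)
        assert tail_atom.GetSymbol() == "C"
        assert sum(1 for n in tail_atom.GetNeighbors()
                   if n.GetAtomicNum() > 1) == 2   # the CH2, not the CH(CH3)

    def test_lactone_breaks_the_acyl_oxygen_bond(self):
        can, mol = canonical_mol("CC1CC(=O)O1")
        ring_o = next(a.GetIdx() for a in mol.GetAtoms()
                      if a.GetSymbol() == "O" and a.IsInRing())
        rw, tail, msg = open_ring(mol, ring_o, "polyether")
        tail_atom = mol.GetAtomWithIdx(tail)
        assert any(b.GetBondType() == Chem.BondType.DOUBLE
                   for b in tail_atom.GetBonds())   # acyl carbon

    def test_head_outside_ring_is_a_warned_noop(self):
        can, mol = canonical_mol("CCO")
        rw, tail, msg = open_ring(mol, 2, "polyether")
        assert tail is None
        assert msg == "head-not-in-ring"

    def test_fused_ring_head_is_refused(self):
        can, mol = canonical_mol("C1CC2CCC1O2")    # bridged bicyclic ether
        o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        rw, tail, msg = open_ring(mol, o_idx, "polyether")
        assert msg == "unsupported-topology"

    def test_heavy_atom_count_is_conserved(self):
        can, mol = canonical_mol("C1CCCCCO1")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        rw, tail, _ = open_ring(mol, o_idx, "polyether")
        assert rw.GetNumAtoms() == mol.GetNumAtoms()


class TestCondensationEdits:
    def test_lactic_acid_loses_exactly_the_acid_hydroxyl(self):
        can, mol = canonical_mol("CC(O)C(=O)O")
        matches = match_groups(can)
        acid = next(m for m in matches if m.pattern_name == "carboxylic_acid")
        alcohol = next(m for m in matches
                       if m.pattern_name == "aliphatic_alcohol")
        head = alcohol.atom_indices[1]
        rw, msg = apply_condensation_edits(mol, head, acid.atom_indices[0],
                                           matches)
        assert msg == ""
        assert rw.GetNumAtoms() == mol.GetNumAtoms() - 1

    def test_tail_without_leaving_group_fails_cleanly(self):
        can, mol = canonical_mol("NCCC=O")     # aldehyde, no acid OH
        rw, msg = apply_condensation_edits(mol, 0, 3, match_groups(can))
        assert rw is None
        assert "edit-failed" in msg


class TestTagging:
    def test_tags_are_exactly_one_head_and_one_tail(self):
        can, mol = canonical_mol("CCO")
        tm = tag_monomer(RWMol(mol), 0, 2)
        assert tm.is_valid
        assert tm.tagged_smiles.count("[*:1]") == 1
        assert tm.tagged_smiles.count("[*:2]") == 1

    def test_canonical_form_stable_under_reparsing(self):
        can, mol = canonical_mol("CCO")
        tm = tag_monomer(RWMol(mol), 0, 2)
        assert Chem.MolToSmiles(Chem.MolFromSmiles(tm.tagged_smiles)) == \
            tm.canonical_form

    def test_overfilled_valence_reported_not_silently_emitted(self):
        can, mol = canonical_mol("C(F)(F)(F)F")   # no open slot on carbon
        tm = tag_monomer(RWMol(mol), 0, 1)
        assert not tm.is_valid
        assert "sanitization failed" in tm.message


class TestSelectTail:
    def test_vinyl_tail_is_the_bond_partner(self):
        assignment = ClassAssignment(
            "polyvinyl", FunctionalGroupMatch("alkene", (0, 1)),
            ClassCandidate("polyvinyl",
                           (FunctionalGroupMatch("alkene", (0, 1)),)))
        assert select_tail_atom(assignment, [], head=0) == 1
        assert select_tail_atom(assignment, [], head=1) == 0

    def test_missing_electrophile_returns_none(self):
        assignment = ClassAssignment(
            "polyamide", FunctionalGroupMatch("primary_amine", (0, 1)),
            ClassCandidate("polyamide",
                           (FunctionalGroupMatch("primary_amine", (0, 1)),)))
        assert select_tail_atom(assignment, [], head=0) is None


class TestAssembly:
    def test_vinyl_tags_sit_on_the_former_double_bond(self):
        assignment, mols, matches, getter = _assignment_for("C=CC(N)=O")
        res = assemble_repeat_unit(assignment, mols, matches, getter)
        assert res.status == "ok"
        (ht,) = res.head_tail
        bond = mols[0].GetBondBetweenAtoms(ht.head_atom, ht.tail_atom)
        assert bond is not None                      # adjacent atoms
        assert bond.GetBondType() == Chem.BondType.DOUBLE
        assert set(assignment.winning_match.atom_indices) == \
            {ht.head_atom, ht.tail_atom}

    def test_amide_condensation_repeat_unit(self):
        assignment, mols, matches, getter = _assignment_for("NCCCCCCCCCC(=O)O")
        res = assemble_repeat_unit(assignment, mols, matches, getter)
        assert res.status == "ok"
        assert collapse_tokens(res.tagged_smiles) == \
            collapse_tokens("[*:1]NCCCCCCCCCC(=O)[*:2]")
        (ht,) = res.head_tail
        assert mols[0].GetAtomWithIdx(ht.head_atom).GetSymbol() == "N"
        assert mols[0].GetAtomWithIdx(ht.tail_atom).GetSymbol() == "C"

    def test_alkyne_route_leaves_a_double_bond(self):
        assignment, mols, matches, getter = _assignment_for("C#CC")  # propyne
        res = assemble_repeat_unit(assignment, mols, matches, getter)
        assert res.status == "ok"
        mol = Chem.MolFromSmiles(res.tagged_smiles)
        assert any(b.GetBondType() == Chem.BondType.DOUBLE
                   for b in mol.GetBonds())

    def test_urethane_pair_tags_every_component(self):
        assignment, mols, matches, getter = _assignment_for(
            "OCCOCCO.O=C=NCCCCCCN=C=O")
        res = assemble_repeat_unit(assignment, mols, matches, getter)
        assert res.status == "ok"
        assert len(res.tagged) == 2
        for tm in res.tagged:
            assert tm.tagged_smiles.count("[*:1]") == 1
            assert tm.tagged_smiles.count("[*:2]") == 1

    def test_ring_opening_conserves_heavy_atoms(self):
        for smiles in ("C1CO1", "CC1CO1", "C1CCCCCO1", "O=C1CCN1"):
            assignment, mols, matches, getter = _assignment_for(smiles)
            res = assemble_repeat_unit(assignment, mols, matches, getter)
            assert res.status == "ok"
            tagged = Chem.MolFromSmiles(res.tagged_smiles)
            n_heavy_tagged = sum(1 for a in tagged.GetAtoms()
                                 if a.GetAtomicNum() > 1)
            assert n_heavy_tagged == mols[0].GetNumAtoms()

    def test_every_emitted_unit_parses_and_recanonicalizes(self):
        for smiles in ("C=CC(N)=O", "CC(O)C(=O)O", "C1CO1"):
            assignment, mols, matches, getter = _assignment_for(smiles)
            res = assemble_repeat_unit(assignment, mols, matches, getter)
            for tm in res.tagged:
                assert tm.is_valid
                assert Chem.MolToSmiles(Chem.MolFromSmiles(tm.tagged_smiles)) \
                    == tm.canonical_form
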